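import filecmp

import numpy as np
import pandas as pd
import pytest

from methylrescue.difftest import call_dmrs
from methylrescue.io_formats import ValidationError, read_obo
from methylrescue.synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_methylome,
    simulate_study,
    write_study,
)


class TestConfig:
    def test_probability_bounds_validated(self):
        with pytest.raises(ValidationError):
            SimulationConfig(rescue_prob_dr=1.2)

    def test_delta_must_exceed_dmr_threshold(self):
        with pytest.raises(ValidationError):
            SimulationConfig(delta=0.05)


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_files(self, small_config, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        write_study(simulate_study(small_config), a)
        write_study(simulate_study(small_config), b)
        diff = filecmp.dircmp(a, b)
        assert not diff.diff_files and not diff.left_only and not diff.right_only
        calls_diff = filecmp.dircmp(a / "calls", b / "calls")
        assert not calls_diff.diff_files

    def test_different_seed_changes_output(self, small_config):
        m1 = simulate_methylome(small_config)
        m2 = simulate_methylome(small_config.replace(seed=small_config.seed + 1))
        assert not m1.bin_truth["young_level"].equals(m2.bin_truth["young_level"])


class TestMethylome:
    def test_bimodal_mass_exceeds_60_percent(self, default_bin_matrix):
        levels = default_bin_matrix.sample_levels.to_numpy().ravel()
        tail = ((levels <= 0.1) | (levels >= 0.8)).mean()
        assert tail > 0.60

    def test_aging_effects_have_full_delta(self, default_study):
        t = default_study.methylome.bin_truth
        aging = t.loc[t["aging"] != "none"]
        d = (aging["old_level"] - aging["young_level"]).to_numpy()
        assert np.allclose(np.abs(d), 0.2)
        assert (d[aging["aging"] == "hyper"] > 0).all()
        assert (d[aging["aging"] == "hypo"] < 0).all()

    def test_coverage_respects_floor(self, default_study):
        calls = next(iter(default_study.methylome.calls.values()))
        assert int(calls["total_reads"].min()) >= 5

    def test_subthreshold_sites_exercise_filter(self):
        cfg = SimulationConfig(seed=4, n_islands=200, subthreshold_fraction=0.2)
        sim = simulate_methylome(cfg)
        calls = next(iter(sim.calls.values()))
        assert (calls["total_reads"] < 5).any()

    def test_dmr_caller_sensitivity_and_fpr(self, default_study, default_bin_matrix):
        m = default_bin_matrix
        dmrs = call_dmrs(m.sample_levels, m.sample_sheet, "young", "old").set_index("feature_id")
        truth = default_study.methylome.bin_truth
        aging = truth.index[truth["aging"] != "none"]
        null = truth.index[truth["aging"] == "none"]
        sensitivity = dmrs.loc[aging, "significant"].mean()
        fpr = dmrs.loc[null, "significant"].mean()
        assert sensitivity >= 0.90
        assert fpr <= 0.07
        # called directions agree with the truth on detected aging bins
        hit = dmrs.loc[aging].loc[lambda d: d["significant"]]
        assert (hit["direction"] == truth.loc[hit.index, "aging"]).all()


class TestExpression:
    def test_single_odeg_labeling(self, default_study):
        t = default_study.expression.gene_truth
        odeg = t.loc[t["label"] == "ODEG"]
        udeg = t.loc[t["label"] == "UDEG"]
        assert (odeg["old_mean"] > odeg["young_mean"]).all()
        assert (udeg["old_mean"] < udeg["young_mean"]).all()

    def test_no_effects_means_no_degs(self):
        from methylrescue.difftest import call_degs

        cfg = SimulationConfig(seed=6, n_genes=300, aging_deg_fraction=0.0)
        sim = simulate_expression(cfg)
        assert (sim.gene_truth["label"] == "none").all()
        degs = call_degs(sim.fpkm, sim.sample_sheet, "young", "old")
        # only chance calls at the 5% level survive with no true effects
        assert degs["significant"].mean() < 0.12

    def test_rescued_genes_return_to_young(self, default_study):
        t = default_study.expression.gene_truth
        rescued = t.loc[t["rescued_DR"]]
        assert (rescued["DR_mean"] == rescued["young_mean"]).all()
        unres = t.loc[(t["label"] != "none") & ~t["rescued_DR"]]
        assert (unres["DR_mean"] == unres["old_mean"]).all()


class TestAnnotation:
    def test_obo_depths_recovered(self, small_study, tmp_path):
        p = tmp_path / "go.obo"
        p.write_text(small_study.annotation.obo_text)
        onto = read_obo(p)
        assert onto["GO:0000001"].min_depth == 0
        leaf_depths = {t.min_depth for t in onto.terms.values() if t.term_id.startswith("GO:10")}
        assert leaf_depths <= {2, 3}
        # diamond leaves (extra tier-1 parent) keep min_depth 2
        assert onto["GO:1000000"].min_depth == 2

    def test_constructed_term_enriches_first(self, small_study):
        from methylrescue.enrich import enrich

        anno = small_study.annotation.gene2go
        background = {f"gene{i:05d}" for i in range(small_study.config.n_genes)}
        # pick one annotated term and use its member genes as the study set
        term = next(iter({t for ts in anno.values() for t in ts}))
        study = {g for g, ts in anno.items() if term in ts}
        out = enrich(study, background, anno, small_study.annotation.ontology)
        assert out.loc[0, "term_id"] == term

    def test_genes_land_on_bins(self, small_study, small_bin_matrix):
        from methylrescue.annotate import map_dmrs_to_genes

        truth = small_study.methylome.bin_truth
        aging = truth.loc[truth["aging"] != "none"]
        dmrs = pd.DataFrame({"feature_id": aging.index})
        rec = map_dmrs_to_genes(dmrs, small_study.annotation.gene_models)
        annotated = rec.loc[rec["gene_id"] != "", "dmr_id"].nunique()
        assert annotated > 0.4 * len(aging)  # aging bins are hosted first

    def test_zero_overlap_construction_unannotated(self, small_study):
        from methylrescue.annotate import map_dmrs_to_genes

        genes = small_study.annotation.gene_models.assign(chrom="chrZ")
        dmrs = pd.DataFrame({"feature_id": small_study.methylome.bin_truth.index[:20]})
        rec = map_dmrs_to_genes(dmrs, genes)
        assert (rec["gene_id"] == "").all()


class TestTrajectoryGroundTruth:
    def test_full_rescue_recovers_lambda(self):
        from methylrescue.binning import compute_bin_matrix
        from methylrescue.trajectory import fit_trajectory

        cfg = SimulationConfig(seed=13, rescue_prob_dr=1.0, rescue_prob_rall=1.0, rescue_prob_rdrl=1.0)
        sim = simulate_methylome(cfg)
        m = compute_bin_matrix(sim.calls, sim.sample_sheet)
        fit = fit_trajectory(m.group_levels(), treated="DR", response="treated-old")
        assert fit.lambda_hat == pytest.approx(0.565, abs=0.02)
        fit2 = fit_trajectory(m.group_levels(), treated="RALL", response="treated-young")
        assert fit2.lambda_hat == pytest.approx(0.5585, abs=0.02)
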