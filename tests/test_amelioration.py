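import numpy as np
import pandas as pd
import pytest

from methylrescue.amelioration import (
    amelioration_summary,
    classify_deg_amelioration,
    classify_dmr_amelioration,
    overlap_sets,
)
from methylrescue.synthetic_data import SimulationConfig, make_deg_fixture, simulate_methylome


def _aging(rows):
    df = pd.DataFrame(rows, columns=["feature_id", "direction", "significant"])
    return df


def _levels(rows):
    return pd.DataFrame(rows, columns=["feature_id", "young", "old", "DR"]).set_index("feature_id")


class TestRescueRule:
    def test_dmr_rule_cases(self):
        aging = _aging(
            [
                ("hyper_rescued", "hyper", True),
                ("hyper_worse", "hyper", True),
                ("hypo_tie", "hypo", True),
                ("hypo_rescued", "hypo", True),
                ("not_significant", "hyper", False),
            ]
        )
        levels = _levels(
            [
                ("hyper_rescued", 0.6, 0.8, 0.7),   # lower than old -> ameliorated
                ("hyper_worse", 0.6, 0.8, 0.85),    # moved further up -> not
                ("hypo_tie", 0.4, 0.2, 0.2),        # exact tie fails the strict rule
                ("hypo_rescued", 0.4, 0.2, 0.3),    # higher than old -> ameliorated
                ("not_significant", 0.6, 0.8, 0.7),
            ]
        )
        calls = classify_dmr_amelioration(aging, levels, "DR").set_index("feature_id")
        assert calls.loc["hyper_rescued", "ameliorated"]
        assert not calls.loc["hyper_worse", "ameliorated"]
        assert not calls.loc["hypo_tie", "ameliorated"]
        assert calls.loc["hypo_rescued", "ameliorated"]
        assert "not_significant" not in calls.index  # only significant aging calls classified

    def test_deg_rule_cases(self):
        aging = _aging([("odeg", "ODEG", True), ("udeg_up", "UDEG", True), ("udeg_down", "UDEG", True)])
        means = _levels([("odeg", 3.0, 10.0, 7.0), ("udeg_up", 6.0, 2.0, 5.0), ("udeg_down", 6.0, 2.0, 1.0)])
        calls = classify_deg_amelioration(aging, means, "DR").set_index("feature_id")
        assert calls.loc["odeg", "ameliorated"]
        assert calls.loc["udeg_up", "ameliorated"]
        assert not calls.loc["udeg_down", "ameliorated"]

    def test_missing_feature_in_levels_is_error(self):
        from methylrescue.io_formats import ValidationError

        aging = _aging([("bin1", "hyper", True)])
        levels = _levels([("other", 0.5, 0.7, 0.6)])
        with pytest.raises(ValidationError, match="bin1"):
            classify_dmr_amelioration(aging, levels, "DR")

    def test_boundary_treated_equals_old_or_young(self):
        rng = np.random.default_rng(0)
        young = rng.random(40)
        old = np.clip(young + rng.choice([-0.3, 0.3], 40), 0, 1)
        aging = _aging([(f"b{i}", "hyper" if old[i] > young[i] else "hypo", True) for i in range(40)])
        as_old = pd.DataFrame({"young": young, "old": old, "DR": old}, index=[f"b{i}" for i in range(40)])
        as_young = pd.DataFrame({"young": young, "old": old, "DR": young}, index=[f"b{i}" for i in range(40)])
        assert classify_dmr_amelioration(aging, as_old, "DR")["ameliorated"].sum() == 0
        assert classify_dmr_amelioration(aging, as_young, "DR")["ameliorated"].all()

    def test_ameliorated_subset_of_significant(self, default_study, default_bin_matrix):
        from methylrescue.difftest import call_dmrs

        m = default_bin_matrix
        dmrs = call_dmrs(m.sample_levels, m.sample_sheet, "young", "old")
        calls = classify_dmr_amelioration(dmrs, m.group_levels(), "DR")
        sig = set(dmrs.loc[dmrs["significant"], "feature_id"])
        assert set(calls["feature_id"]) <= sig
        assert set(calls.loc[calls["ameliorated"], "feature_id"]) <= sig


class TestGeneratorContract:
    def test_truth_level_fraction_equals_empirical_rescue_rate(self):
        """At sigma = 0, classifying on true group levels yields exactly the
        generator's realised rescue fraction (ties on non-rescued bins fail)."""
        cfg = SimulationConfig(seed=9, n_islands=800, noise_sd=0.0)
        sim = simulate_methylome(cfg)
        t = sim.bin_truth
        aging = t.loc[t["aging"] != "none"]
        aging_calls = pd.DataFrame(
            {"feature_id": aging.index, "direction": aging["aging"], "significant": True}
        )
        levels = t.rename(columns={"young_level": "young", "old_level": "old", "DR_level": "DR"})
        calls = classify_dmr_amelioration(aging_calls, levels, "DR")
        assert calls["ameliorated"].sum() == int(aging["rescued_DR"].sum())

    @pytest.mark.parametrize("lam,expect_all", [(1.0, False), (0.0, True)])
    def test_degenerate_lambdas(self, lam, expect_all):
        cfg = SimulationConfig(
            seed=10, n_islands=400, noise_sd=0.0,
            lambda_dr=lam, rescue_prob_dr=1.0,
        )
        sim = simulate_methylome(cfg)
        t = sim.bin_truth
        aging = t.loc[t["aging"] != "none"]
        aging_calls = pd.DataFrame(
            {"feature_id": aging.index, "direction": aging["aging"], "significant": True}
        )
        levels = t.rename(columns={"young_level": "young", "old_level": "old", "DR_level": "DR"})
        calls = classify_dmr_amelioration(aging_calls, levels, "DR")
        if expect_all:  # lambda 0: treated == young, every aging bin rescued
            assert calls["ameliorated"].all()
        else:  # lambda 1: treated == old, ties everywhere
            assert calls["ameliorated"].sum() == 0


class TestAggregates:
    def test_printed_rescue_percentages_from_exact_fixture(self):
        aging_degs, group_means = make_deg_fixture()
        calls = classify_deg_amelioration(aging_degs, group_means, "DR")
        summary = amelioration_summary(calls).set_index("aging_direction")
        assert summary.loc["ODEG", "n_aging"] == 839
        assert summary.loc["ODEG", "n_ameliorated"] == 770
        assert round(100 * summary.loc["ODEG", "fraction"], 2) == 91.78
        assert summary.loc["UDEG", "n_ameliorated"] == 203
        assert round(100 * summary.loc["UDEG", "fraction"], 2) == 81.85
        assert summary.loc["all", "n_aging"] == 1087
        assert summary.loc["all", "n_ameliorated"] == 973
        assert round(100 * summary.loc["all", "fraction"], 2) == 89.51


class TestOverlap:
    def _calls(self, ids, direction="ODEG"):
        return pd.DataFrame(
            {"feature_id": ids, "aging_direction": direction, "ameliorated": True}
        )

    def test_disjoint_and_identical(self):
        a = self._calls(["g1", "g2", "g3"])
        b = self._calls(["g4", "g5", "g6", "g7"])
        ov = overlap_sets(a, b)
        assert ov["intersection"] == 0 and ov["union"] == 7
        same = overlap_sets(a, a)
        assert same["fraction"] == 1.0

    def test_partial_overlap(self):
        ov = overlap_sets(self._calls(["g1", "g2", "g3"]), self._calls(["g2", "g3", "g4"]))
        assert ov["intersection"] == 2 and ov["union"] == 4
        assert ov["fraction"] == pytest.approx(0.5)
        assert ov["features"] == ["g2", "g3"]

    def test_per_direction_split(self):
        a = pd.concat([self._calls(["g1"], "ODEG"), self._calls(["g2"], "UDEG")])
        b = pd.concat([self._calls(["g1"], "ODEG"), self._calls(["g3"], "UDEG")])
        ov = overlap_sets(a, b)
        assert ov["per_direction"]["ODEG"]["intersection"] == 1
        assert ov["per_direction"]["UDEG"]["intersection"] == 0
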