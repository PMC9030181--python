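"""End-to-end orchestration: simulate -> bins -> calls -> integration.

``run_all`` chains every stage into one run directory and records a
manifest (config snapshot, seed, package version, per-file SHA-256
digests).  Each stage writes the same TSV dialects the standalone CLI
subcommands consume, so any stage can be re-run in isolation on the run
directory's intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .amelioration import (
    amelioration_summary,
    classify_deg_amelioration,
    classify_dmr_amelioration,
    overlap_sets,
)
from .annotate import dmg_summary, map_dmrs_to_genes
from .binning import compute_bin_matrix
from .correlate import correlate_pairs
from .difftest import call_degs, call_dmrs
from .enrich import enrich
from .io_formats import MethylRescueError, load_bin_matrix, read_expression_table, write_tsv
from .synthetic_data import SimulationConfig, simulate_study, write_study
from .trajectory import fit_trajectory, quadrant_summary

__all__ = ["run_all", "RunError"]

logger = logging.getLogger(__name__)

TREATED = ("DR", "RALL")


class RunError(MethylRescueError):
    """A pipeline stage failed; the message names the stage."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    outdir: str | Path,
    config: SimulationConfig | None = None,
    min_reads: int = 5,
    max_gap: int = 1000,
    p_threshold: float = 0.05,
    delta_threshold: float = 0.1,
    promoter_upstream: int = 2000,
    alpha: float = 0.01,
    min_depth_keep: int = 3,
) -> dict:
    """Run the full pipeline on a synthetic study and write a run directory.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Any stage failure raises :class:`RunError` naming the stage; files from
    completed stages are left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or SimulationConfig()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "parameters": {
            "min_reads": min_reads,
            "max_gap": max_gap,
            "p_threshold": p_threshold,
            "delta_threshold": delta_threshold,
            "promoter_upstream": promoter_upstream,
            "alpha": alpha,
            "min_depth_keep": min_depth_keep,
        },
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    summary: dict = {}

    def _stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"][name] = {"outputs": []}

    def _record(name: str, *paths: Path) -> None:
        for p in paths:
            manifest["stages"][name]["outputs"].append({"path": str(p.relative_to(outdir)), "sha256": _digest(p)})

    try:
        stage = "simulate"
        _stage(stage)
        sim = simulate_study(config)
        study_paths = write_study(sim, outdir / "study")
        _record(stage, *study_paths.values())

        stage = "bins"
        _stage(stage)
        matrix = compute_bin_matrix(sim.methylome.calls, sim.methylome.sample_sheet, min_reads=min_reads, max_gap=max_gap)
        bins_path = outdir / "bins.tsv"
        write_tsv(matrix.to_frame(), bins_path)
        _record(stage, bins_path)
        summary["n_bins"] = len(matrix.bins)
        # downstream stages consume the written TSVs (not the in-memory
        # full-precision values) so each stage is exactly reproducible standalone
        sheet = sim.methylome.sample_sheet
        sample_levels = load_bin_matrix(bins_path, sheet)
        group_levels = pd.DataFrame(
            {g: sample_levels[sheet.samples_in(g)].mean(axis=1) for g in sheet.groups}
        )
        fpkm = read_expression_table(study_paths["fpkm"], sheet)

        stage = "dmr"
        _stage(stage)
        dmrs = call_dmrs(sample_levels, sheet, "young", "old", p_threshold, delta_threshold)
        dmr_path = outdir / "dmr_young_old.tsv"
        write_tsv(dmrs, dmr_path)
        _record(stage, dmr_path)
        summary["n_aging_dmrs"] = int(dmrs["significant"].sum())

        stage = "deg"
        _stage(stage)
        degs = call_degs(fpkm, sheet, "young", "old", p_threshold)
        deg_path = outdir / "deg_young_old.tsv"
        write_tsv(degs, deg_path)
        _record(stage, deg_path)
        summary["n_aging_degs"] = int(degs["significant"].sum())

        stage = "ameliorate"
        _stage(stage)
        expr_group_means = pd.DataFrame(
            {g: fpkm[sheet.samples_in(g)].mean(axis=1) for g in sheet.groups}
        )
        amelio_dmr: dict[str, pd.DataFrame] = {}
        amelio_deg: dict[str, pd.DataFrame] = {}
        for g in TREATED:
            amelio_dmr[g] = classify_dmr_amelioration(dmrs, group_levels, g)
            amelio_deg[g] = classify_deg_amelioration(degs, expr_group_means, g)
            p1, p2 = outdir / f"amelio_dmr_{g}.tsv", outdir / f"amelio_deg_{g}.tsv"
            write_tsv(amelio_dmr[g], p1)
            write_tsv(amelio_deg[g], p2)
            _record(stage, p1, p2)
            summary[f"dmr_ameliorated_fraction_{g}"] = float(amelio_dmr[g]["ameliorated"].mean())
            summary[f"deg_ameliorated_fraction_{g}"] = float(amelio_deg[g]["ameliorated"].mean())
            # noise-free reference: classify on the generator's true group levels
            truth_levels = sim.methylome.bin_truth.rename(
                columns={"young_level": "young", "old_level": "old", **{f"{t}_level": t for t in TREATED}}
            )
            truth_calls = classify_dmr_amelioration(
                dmrs.loc[dmrs["feature_id"].isin(truth_levels.index)], truth_levels, g
            )
            summary[f"dmr_ameliorated_fraction_truth_{g}"] = float(truth_calls["ameliorated"].mean())
            s1, s2 = outdir / f"amelio_dmr_{g}_summary.tsv", outdir / f"amelio_deg_{g}_summary.tsv"
            write_tsv(amelioration_summary(amelio_dmr[g]), s1)
            write_tsv(amelioration_summary(amelio_deg[g]), s2)
            _record(stage, s1, s2)

        stage = "overlap"
        _stage(stage)
        ov = overlap_sets(amelio_deg["DR"], amelio_deg["RALL"])
        ov_path = outdir / "overlap_deg.json"
        ov_path.write_text(json.dumps(ov, indent=1, default=str))
        _record(stage, ov_path)
        summary["deg_overlap_fraction"] = ov["fraction"]

        stage = "trajectory"
        _stage(stage)
        for g in TREATED:
            fit = fit_trajectory(group_levels, treated=g, response="treated-old")
            fit_path = outdir / f"trajectory_{g}.tsv"
            scatter_path = outdir / f"trajectory_{g}_scatter.tsv"
            write_tsv(fit.to_frame(), fit_path)
            write_tsv(fit.scatter, scatter_path)
            _record(stage, fit_path, scatter_path)
            summary[f"lambda_hat_{g}"] = fit.lambda_hat
            summary[f"slope_{g}"] = fit.slope
            summary[f"pcc_{g}"] = fit.pcc
            summary[f"quadrant_opposing_{g}"] = quadrant_summary(fit)["opposing"]

        stage = "annotate"
        _stage(stage)
        dmg_records: dict[str, pd.DataFrame] = {}
        for g in TREATED:
            amel = amelio_dmr[g].loc[amelio_dmr[g]["ameliorated"]]
            dmg_records[g] = map_dmrs_to_genes(amel, sim.annotation.gene_models, upstream=promoter_upstream)
            p = outdir / f"dmgs_{g}.tsv"
            write_tsv(dmg_records[g], p)
            _record(stage, p)
            counts = dmg_summary(dmg_records[g])
            summary[f"n_dmgs_{g}"] = int(
                dmg_records[g].loc[dmg_records[g]["gene_id"] != "", "gene_id"].nunique()
            )
            s = outdir / f"dmgs_{g}_summary.tsv"
            write_tsv(counts, s)
            _record(stage, s)

        stage = "correlate"
        _stage(stage)
        for g in TREATED:
            annotated = dmg_records[g].loc[dmg_records[g]["gene_id"] != ""]
            deg_genes = set(amelio_deg[g].loc[amelio_deg[g]["ameliorated"], "feature_id"])
            pairs = sorted(
                {
                    (rec.gene_id, rec.dmr_id)
                    for rec in annotated.itertuples(index=False)
                    if rec.gene_id in deg_genes and rec.gene_id in fpkm.index
                }
            )
            corr = correlate_pairs(fpkm, sample_levels, pairs)
            p = outdir / f"corr_{g}.tsv"
            write_tsv(corr, p)
            _record(stage, p)
            summary[f"n_significant_correlations_{g}"] = int(corr["significant"].sum()) if len(corr) else 0

        stage = "enrich"
        _stage(stage)
        background = set(fpkm.index)
        for g in TREATED:
            study = set(amelio_deg[g].loc[amelio_deg[g]["ameliorated"], "feature_id"]) & background
            result = enrich(study, background, sim.annotation.gene2go, sim.annotation.ontology, alpha, min_depth_keep)
            p = outdir / f"enrich_deg_{g}.tsv"
            write_tsv(result, p)
            _record(stage, p)
            summary[f"n_enriched_terms_{g}"] = int(result["significant"].sum()) if len(result) else 0
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RunError(f"stage {stage!r} failed: {exc}") from exc

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest["summary"] = summary
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
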