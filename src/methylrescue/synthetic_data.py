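"""Synthetic study generator with known ground truth.

Emulates the structure of an RRBS + RNA-seq aging-intervention study in
mouse hippocampus: five groups (young, old, DR, RALL, RDRL) x 3 replicates;
CpG sites clustered in islands so that adjacency binning recovers one bin
per island (mean bin length ~ 212 bp); a bimodal bin-methylation baseline
(mass near 0 and in 0.8-1.0); aging effects of |delta| > 0.1 on a minority
of bins; and treated-group methylomes that are convex mixtures
``lambda * old + (1 - lambda) * young`` on rescued bins and identical to
old elsewhere, so the rescue signal is the only systematic treated-vs-old
difference.  Read counts are drawn binomially around the per-sample bin
truth with negative-binomial coverage floored at the read filter.

Expression is generated analogously: log-normal baseline FPKM, fold-change
effects on aging DEGs, treated means pulled back to young on rescued genes,
log-normal replicate noise.

All randomness flows from ``config.seed`` through fixed per-component
sub-streams, so identical configs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GROUPS,
    Ontology,
    SampleSheet,
    ValidationError,
    format_region,
    write_cpg_table,
    write_expression_table,
    write_tsv,
)

__all__ = [
    "SimulationConfig",
    "MethylomeSim",
    "ExpressionSim",
    "AnnotationSim",
    "StudySim",
    "simulate_methylome",
    "simulate_expression",
    "simulate_annotation",
    "simulate_study",
    "make_deg_fixture",
    "write_study",
]

TREATED_GROUPS = ("DR", "RALL", "RDRL")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; defaults emulate the study design."""

    seed: int = 0

    # genome / island layout (tuned for a ~212 bp mean bin length)
    n_chromosomes: int = 5
    n_islands: int = 5000
    sites_per_island_mean: float = 8.0
    spacing_min: int = 10
    spacing_max: int = 50
    island_gap_min: int = 2500
    island_gap_max: int = 5000

    # design
    n_samples_per_group: int = 3

    # baseline bin methylation: bimodal Beta mixture plus a thin mid band
    w_low: float = 0.45
    a_low: float = 0.4
    b_low: float = 8.0
    w_high: float = 0.45
    a_high: float = 12.0
    b_high: float = 1.5

    # coverage
    coverage_floor: int = 5
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0
    subthreshold_fraction: float = 0.0

    # aging methylation effects and treatment rescue
    aging_dmr_fraction: float = 0.10
    hyper_fraction: float = 0.5
    delta: float = 0.2
    lambda_dr: float = 0.565
    lambda_rall: float = 0.5585
    lambda_rdrl: float = 0.565
    rescue_prob_dr: float = 0.835
    rescue_prob_rall: float = 0.79
    rescue_prob_rdrl: float = 0.835
    noise_sd: float = 0.02

    # expression
    n_genes: int = 2000
    aging_deg_fraction: float = 0.10
    odeg_fraction: float = 0.772
    log2fc_min: float = 1.0
    log2fc_max: float = 2.0
    expr_rescue_prob_dr: float = 0.90
    expr_rescue_prob_rall: float = 0.72
    expr_rescue_prob_rdrl: float = 0.90
    expr_baseline_log2_mean: float = 3.0
    expr_baseline_log2_sd: float = 1.5
    expr_noise_sd: float = 0.25

    # annotation
    gene_bin_fraction: float = 0.3
    promoter_upstream: int = 2000
    n_go_terms: int = 30
    genes_per_term: int = 25

    def __post_init__(self) -> None:
        probs = {
            "w_low": self.w_low,
            "w_high": self.w_high,
            "aging_dmr_fraction": self.aging_dmr_fraction,
            "hyper_fraction": self.hyper_fraction,
            "rescue_prob_dr": self.rescue_prob_dr,
            "rescue_prob_rall": self.rescue_prob_rall,
            "rescue_prob_rdrl": self.rescue_prob_rdrl,
            "expr_rescue_prob_dr": self.expr_rescue_prob_dr,
            "expr_rescue_prob_rall": self.expr_rescue_prob_rall,
            "expr_rescue_prob_rdrl": self.expr_rescue_prob_rdrl,
            "aging_deg_fraction": self.aging_deg_fraction,
            "odeg_fraction": self.odeg_fraction,
            "gene_bin_fraction": self.gene_bin_fraction,
            "subthreshold_fraction": self.subthreshold_fraction,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} = {value} outside [0, 1]")
        for lam in (self.lambda_dr, self.lambda_rall, self.lambda_rdrl):
            if not 0.0 <= lam <= 1.0:
                raise ValidationError(f"mixing coefficient {lam} outside [0, 1]")
        if not self.delta > 0.1:
            raise ValidationError("aging effect delta must exceed the DMR threshold 0.1")
        if self.delta > 0.5:
            raise ValidationError("delta > 0.5 cannot be placed without clipping")
        if self.noise_sd < 0 or self.coverage_floor < 1:
            raise ValidationError("noise_sd must be >= 0 and coverage_floor >= 1")
        if self.w_low + self.w_high > 1.0:
            raise ValidationError("baseline mixture weights exceed 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def lambdas(self) -> dict[str, float]:
        return {"DR": self.lambda_dr, "RALL": self.lambda_rall, "RDRL": self.lambda_rdrl}

    @property
    def rescue_probs(self) -> dict[str, float]:
        return {"DR": self.rescue_prob_dr, "RALL": self.rescue_prob_rall, "RDRL": self.rescue_prob_rdrl}

    @property
    def expr_rescue_probs(self) -> dict[str, float]:
        return {
            "DR": self.expr_rescue_prob_dr,
            "RALL": self.expr_rescue_prob_rall,
            "RDRL": self.expr_rescue_prob_rdrl,
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


@dataclass
class MethylomeSim:
    calls: dict[str, pd.DataFrame]
    sample_sheet: SampleSheet
    bin_truth: pd.DataFrame
    config: SimulationConfig


@dataclass
class ExpressionSim:
    fpkm: pd.DataFrame
    sample_sheet: SampleSheet
    gene_truth: pd.DataFrame
    config: SimulationConfig


@dataclass
class AnnotationSim:
    gene_models: pd.DataFrame
    gene2go: dict[str, set[str]]
    obo_text: str
    ontology: Ontology
    config: SimulationConfig


@dataclass
class StudySim:
    methylome: MethylomeSim
    expression: ExpressionSim
    annotation: AnnotationSim
    config: SimulationConfig


def _baseline_levels(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Bimodal baseline: mass near 0, mass in 0.8-1.0, a thin mid band."""
    u = rng.random(n)
    low = rng.beta(config.a_low, config.b_low, size=n)
    high = rng.beta(config.a_high, config.b_high, size=n)
    mid = rng.uniform(0.1, 0.9, size=n)
    levels = np.where(u < config.w_low, low, np.where(u < config.w_low + config.w_high, high, mid))
    return np.clip(levels, 0.0, 1.0)


def simulate_methylome(config: SimulationConfig) -> MethylomeSim:
    """Generate per-sample CpG call tables and the per-bin ground truth.

    Aging direction is assigned by headroom — bins with baseline < 0.5
    become hypermethylated with age, bins >= 0.5 hypomethylated — so every
    aging bin carries the full |delta| effect without clipping; the
    configured hyper fraction is honoured as closely as the baseline strata
    allow.
    """
    rng = _rng(config, 1)
    sheet = SampleSheet.default_design(config.n_samples_per_group)

    # island layout: one island per eventual bin
    n_sites = 2 + rng.poisson(max(config.sites_per_island_mean - 2.0, 0.0), size=config.n_islands)
    chrom_of = np.minimum(
        (np.arange(config.n_islands) * config.n_chromosomes) // config.n_islands,
        config.n_chromosomes - 1,
    )
    positions: list[np.ndarray] = []
    bin_chrom: list[str] = []
    cursor = {c: 10_000 for c in range(config.n_chromosomes)}
    for i in range(config.n_islands):
        c = int(chrom_of[i])
        gap = int(rng.integers(config.island_gap_min, config.island_gap_max + 1))
        start = cursor[c] + gap
        spacings = rng.integers(config.spacing_min, config.spacing_max + 1, size=n_sites[i] - 1)
        pos = start + np.concatenate([[0], np.cumsum(spacings)])
        positions.append(pos)
        bin_chrom.append(f"chr{c + 1}")
        cursor[c] = int(pos[-1])

    starts = np.array([p[0] for p in positions])
    ends = np.array([p[-1] + 1 for p in positions])
    regions = [format_region(c, s, e) for c, s, e in zip(bin_chrom, starts, ends)]

    # baseline and aging effects
    young = _baseline_levels(rng, config.n_islands, config)
    n_aging = int(round(config.aging_dmr_fraction * config.n_islands))
    low_bins = np.flatnonzero(young < 0.5)
    high_bins = np.flatnonzero(young >= 0.5)
    n_hyper = min(int(round(n_aging * config.hyper_fraction)), low_bins.size)
    n_hypo = min(n_aging - n_hyper, high_bins.size)
    hyper_idx = rng.choice(low_bins, size=n_hyper, replace=False)
    hypo_idx = rng.choice(high_bins, size=n_hypo, replace=False)
    aging = np.full(config.n_islands, "none", dtype=object)
    aging[hyper_idx] = "hyper"
    aging[hypo_idx] = "hypo"
    old = young.copy()
    old[hyper_idx] += config.delta
    old[hypo_idx] -= config.delta
    old = np.clip(old, 0.0, 1.0)

    group_truth = {"young": young, "old": old}
    rescued: dict[str, np.ndarray] = {}
    is_aging = aging != "none"
    for g in TREATED_GROUPS:
        lam = config.lambdas[g]
        res = is_aging & (rng.random(config.n_islands) < config.rescue_probs[g])
        rescued[g] = res
        group_truth[g] = np.where(res, lam * old + (1.0 - lam) * young, old)

    # per-sample bin levels: treated groups carry clipped biological noise on
    # top of the mixture; young/old replicates differ only via read sampling
    sample_bin_levels: dict[str, np.ndarray] = {}
    for sample in sheet.samples:
        g = sheet.group_of(sample)
        if g in TREATED_GROUPS and config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, size=config.n_islands)
            sample_bin_levels[sample] = np.clip(group_truth[g] + noise, 0.0, 1.0)
        else:
            sample_bin_levels[sample] = group_truth[g]

    # site-level arrays
    bin_index = np.repeat(np.arange(config.n_islands), n_sites)
    site_pos = np.concatenate(positions)
    site_chrom = np.repeat(np.array(bin_chrom, dtype=object), n_sites)
    total_sites = site_pos.size
    sub = np.zeros(total_sites, dtype=bool)
    if config.subthreshold_fraction > 0:
        sub = rng.random(total_sites) < config.subthreshold_fraction

    nb_n = config.coverage_dispersion
    nb_mean = max(config.coverage_mean - config.coverage_floor, 0.0)
    nb_p = nb_n / (nb_n + nb_mean) if nb_mean > 0 else 1.0

    calls: dict[str, pd.DataFrame] = {}
    for sample in sheet.samples:
        truth = sample_bin_levels[sample][bin_index]
        coverage = config.coverage_floor + rng.negative_binomial(nb_n, nb_p, size=total_sites)
        if sub.any():
            coverage = np.where(
                sub, rng.integers(1, max(config.coverage_floor, 2), size=total_sites), coverage
            )
        meth = rng.binomial(coverage, truth)
        df = pd.DataFrame(
            {
                "chrom": site_chrom,
                "pos": site_pos,
                "strand": "+",
                "context": "CpG",
                "methylated_reads": meth,
                "total_reads": coverage,
            }
        )
        df["level"] = df["methylated_reads"] / df["total_reads"]
        df["sample_id"] = sample
        calls[sample] = df.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)

    truth_df = pd.DataFrame(
        {
            "region": regions,
            "chrom": bin_chrom,
            "start": starts,
            "end": ends,
            "n_sites": n_sites,
            "aging": aging,
            "young_level": young,
            "old_level": old,
            **{f"{g}_level": group_truth[g] for g in TREATED_GROUPS},
            **{f"rescued_{g}": rescued[g] for g in TREATED_GROUPS},
        }
    ).set_index("region", drop=False)
    truth_df.index.name = None
    return MethylomeSim(calls=calls, sample_sheet=sheet, bin_truth=truth_df, config=config)


def simulate_expression(config: SimulationConfig) -> ExpressionSim:
    """Generate the gene x sample FPKM table and per-gene ground truth."""
    rng = _rng(config, 2)
    sheet = SampleSheet.default_design(config.n_samples_per_group)
    n = config.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    young = np.exp2(rng.normal(config.expr_baseline_log2_mean, config.expr_baseline_log2_sd, size=n))
    n_deg = int(round(config.aging_deg_fraction * n))
    deg_idx = rng.choice(n, size=n_deg, replace=False)
    n_odeg = int(round(n_deg * config.odeg_fraction))
    odeg_idx = deg_idx[:n_odeg]
    udeg_idx = deg_idx[n_odeg:]
    label = np.full(n, "none", dtype=object)
    label[odeg_idx] = "ODEG"
    label[udeg_idx] = "UDEG"
    fc = rng.uniform(config.log2fc_min, config.log2fc_max, size=n)
    old = young.copy()
    old[odeg_idx] = young[odeg_idx] * np.exp2(fc[odeg_idx])
    old[udeg_idx] = young[udeg_idx] * np.exp2(-fc[udeg_idx])

    group_mean = {"young": young, "old": old}
    rescued: dict[str, np.ndarray] = {}
    is_deg = label != "none"
    for g in TREATED_GROUPS:
        res = is_deg & (rng.random(n) < config.expr_rescue_probs[g])
        rescued[g] = res
        group_mean[g] = np.where(res, young, old)

    fpkm = {}
    for sample in sheet.samples:
        g = sheet.group_of(sample)
        noise = np.exp2(rng.normal(0.0, config.expr_noise_sd, size=n))
        fpkm[sample] = group_mean[g] * noise
    fpkm_df = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"))

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "label": label,
            "young_mean": young,
            "old_mean": old,
            **{f"{g}_mean": group_mean[g] for g in TREATED_GROUPS},
            **{f"rescued_{g}": rescued[g] for g in TREATED_GROUPS},
        }
    ).set_index("gene_id", drop=False)
    truth.index.name = None
    return ExpressionSim(fpkm=fpkm_df, sample_sheet=sheet, gene_truth=truth, config=config)


def make_deg_fixture(
    n_odeg: int = 839,
    n_odeg_rescued: int = 770,
    n_udeg: int = 248,
    n_udeg_rescued: int = 203,
    n_null: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic noise-free aging-DEG table and group-mean matrix.

    Rescued ODEGs have the treated mean below old, rescued UDEGs above old;
    non-rescued genes sit exactly at the old mean (a tie, which the strict
    rescue rule does not count).  Returns (aging_degs call table,
    gene x group mean-FPKM DataFrame) sized to the requested counts.
    """
    rows = []
    means = []
    idx = 0

    def add(direction: str, rescued_flag: bool, significant: bool = True) -> None:
        nonlocal idx
        gene = f"fx{idx:05d}"
        idx += 1
        if direction == "ODEG":
            y, o = 2.0, 8.0
            t = 4.0 if rescued_flag else o
        elif direction == "UDEG":
            y, o = 8.0, 2.0
            t = 4.0 if rescued_flag else o
        else:
            y = o = t = 3.0
        rows.append(
            {
                "feature_id": gene,
                "mean_a": y,
                "mean_b": o,
                "delta": o - y,
                "statistic": float("nan"),
                "p_value": 0.001 if significant else 0.9,
                "direction": direction,
                "significant": significant,
            }
        )
        means.append({"gene_id": gene, "young": y, "old": o, "DR": t, "RALL": t, "RDRL": t})

    for i in range(n_odeg):
        add("ODEG", i < n_odeg_rescued)
    for i in range(n_udeg):
        add("UDEG", i < n_udeg_rescued)
    for _ in range(n_null):
        add("none", False, significant=False)

    aging_degs = pd.DataFrame(rows)
    group_means = pd.DataFrame(means).set_index("gene_id")
    return aging_degs, group_means


def _go_dag(config: SimulationConfig) -> tuple[dict[str, dict], str]:
    """A small biological_process is_a DAG with known depths (0..3+)."""
    terms: dict[str, dict] = {}

    def add(tid: str, name: str, parents: list[str]) -> None:
        terms[tid] = {"name": name, "namespace": "biological_process", "is_a": parents}

    root = "GO:0000001"
    add(root, "biological_process", [])
    tier1 = [f"GO:000100{i}" for i in range(1, 4)]
    for i, t in enumerate(tier1):
        add(t, f"broad process {i + 1}", [root])
    tier2 = [f"GO:00020{i:02d}" for i in range(1, 7)]
    for i, t in enumerate(tier2):
        add(t, f"mid process {i + 1}", [tier1[i % len(tier1)]])
    leaves = [f"GO:10{i:05d}" for i in range(config.n_go_terms)]
    for i, t in enumerate(leaves):
        parents = [tier2[i % len(tier2)]]
        if i % 5 == 0:  # a diamond: second is_a parent one tier up
            parents.append(tier1[i % len(tier1)])
        add(t, f"specific process {i + 1}", parents)

    lines = ["format-version: 1.2", "ontology: go", ""]
    for tid, data in terms.items():
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {data['name']}")
        lines.append(f"namespace: {data['namespace']}")
        for p in data["is_a"]:
            lines.append(f"is_a: {p} ! {terms[p]['name']}")
        lines.append("")
    return terms, "\n".join(lines) + "\n"


def simulate_annotation(config: SimulationConfig, methylome: MethylomeSim | None = None) -> AnnotationSim:
    """Gene models placed over the simulated bins, GO annotations, and an OBO DAG.

    Genes reuse the expression table's ids.  A configurable fraction of bins
    hosts a gene, aging bins first so that DMR -> DMG annotation has signal;
    hosts alternate between gene-body overlap and promoter overlap.
    """
    rng = _rng(config, 3)
    if methylome is None:
        methylome = simulate_methylome(config)
    truth = methylome.bin_truth
    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]

    n_host = min(config.n_genes, int(round(config.gene_bin_fraction * len(truth))))
    aging_first = truth.sort_values(
        by=["aging", "region"], key=lambda s: (s != "none") if s.name == "aging" else s, ascending=[False, True]
    )
    hosts = aging_first.head(n_host)

    rows = []
    for i, (_, b) in enumerate(hosts.iterrows()):
        gene_id = gene_ids[i]
        if i % 2 == 0:  # bin inside the gene body
            start = max(0, int(b["start"]) - 200)
            end = int(b["end"]) + 500
            strand = "+"
        else:  # bin inside the + strand promoter
            start = int(b["end"]) + 100
            end = start + 1200
            strand = "+"
        rows.append({"gene_id": gene_id, "chrom": b["chrom"], "strand": strand, "start": start, "end": end})
    gene_models = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])

    terms, obo_text = _go_dag(config)
    leaves = [t for t, d in terms.items() if t.startswith("GO:10")]
    gene2go: dict[str, set[str]] = {}
    for t in leaves:
        members = rng.choice(config.n_genes, size=min(config.genes_per_term, config.n_genes), replace=False)
        for m in members:
            gene2go.setdefault(gene_ids[int(m)], set()).add(t)

    import io

    import obonet

    graph = obonet.read_obo(io.StringIO(obo_text))
    ontology = Ontology.from_graph(graph)
    return AnnotationSim(
        gene_models=gene_models, gene2go=gene2go, obo_text=obo_text, ontology=ontology, config=config
    )


def simulate_study(config: SimulationConfig) -> StudySim:
    """The full synthetic study: methylome, expression, annotation."""
    methylome = simulate_methylome(config)
    expression = simulate_expression(config)
    annotation = simulate_annotation(config, methylome)
    return StudySim(methylome=methylome, expression=expression, annotation=annotation, config=config)


def write_study(sim: StudySim, outdir: str | Path) -> dict[str, Path]:
    """Write every input file of the pipeline in its canonical dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sheet_path = outdir / "samples.tsv"
    sim.methylome.sample_sheet.to_tsv(sheet_path)
    paths["samples"] = sheet_path

    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    for sample, calls in sim.methylome.calls.items():
        p = calls_dir / f"{sample}.tsv"
        write_cpg_table(calls, p)
        paths[f"calls/{sample}"] = p

    fpkm_path = outdir / "fpkm.tsv"
    write_expression_table(sim.expression.fpkm, fpkm_path)
    paths["fpkm"] = fpkm_path

    genes_path = outdir / "genes.bed"
    with open(genes_path, "w") as fh:
        for g in sim.annotation.gene_models.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    paths["genes"] = genes_path

    gene2go_path = outdir / "gene2go.tsv"
    with open(gene2go_path, "w") as fh:
        for gene in sorted(sim.annotation.gene2go):
            for term in sorted(sim.annotation.gene2go[gene]):
                fh.write(f"{gene}\t{term}\n")
    paths["gene2go"] = gene2go_path

    obo_path = outdir / "go.obo"
    obo_path.write_text(sim.annotation.obo_text)
    paths["obo"] = obo_path

    write_tsv(sim.methylome.bin_truth.reset_index(drop=True), outdir / "truth_bins.tsv")
    write_tsv(sim.expression.gene_truth.reset_index(drop=True), outdir / "truth_genes.tsv")
    paths["truth_bins"] = outdir / "truth_bins.tsv"
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    return paths
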