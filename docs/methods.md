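# Methods

## Scope and data model

The pipeline operates on three external inputs — per-CpG methylation call
tables (one per sample), a gene × sample FPKM matrix, and annotation files
(gene models in BED6 or knownGene-like TSV, gene→GO mappings, a GO OBO
file) — tied together by a sample sheet mapping samples to groups
(young, old, DR, RALL, RDRL by convention; any labels work). Alignment,
methylation calling and transcript quantification are upstream of the
pipeline and out of scope.

Internally all coordinates are 0-based half-open; user-facing bin names
are 1-based inclusive region strings (`chr1:135502252-135502293`), the
convention genome browsers print. Strand is kept on sites but bins are
strand-agnostic, and symmetric CpG pairs are not collapsed: collapsing
would change bin counts and the procedure being modelled does not mention
it.

## Binning

Sites pass the filter when context is CpG and total reads ≥ 5 (inclusive
at the boundary). The bin set is computed once, from sites retained in
**all** samples (intersection): this guarantees a complete bin × sample
matrix with no imputation. An alternative mode (`min_samples=k`) keeps
sites covered in ≥ k samples and imputes a missing bin/sample level with
the bin's available-sample mean; it is off by default.

Bins are maximal runs of retained sites with adjacent gaps ≤ 1 kb ("no
more than" is inclusive: a gap of exactly 1000 bp does not split). The bin
level is the unweighted mean over member sites' proportions (not
read-weighted), per sample; group levels are unweighted means over the
group's samples. Bin spans run from the first to the last member site,
not padded to fixed windows, which matches region strings whose spans are
tens of bp.

## Moderated two-sample test

Per feature, with groups of size nₐ and n_b (d = nₐ + n_b − 2 residual
df), the pooled variance s² is shrunk toward a prior:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d)
    t   = (mean_b − mean_a) / (s̃·√(1/nₐ + 1/n_b)),   t ~ Student(d + d₀)

d₀ = 0 reduces to the classical pooled t (verified to 10 significant
figures against scipy); d₀ = ∞ pins the variance at s₀² and uses the
normal reference.

The prior is fitted across features by moments on log variances: with
e_g = log s_g² − ψ(d/2) + log(d/2), under the hierarchical model
σ_g² ~ s₀²·d₀/χ²(d₀) one has Var(e) = ψ′(d/2) + ψ′(d₀/2), so the excess
of Var(e) over the sampling term identifies d₀ through the inverse
trigamma (Newton iteration), and E(e) identifies s₀². Guard rails:
< 10 usable features → d₀ = 0 (no shrinkage); no excess spread (or all
variances identical) → d₀ = ∞ at the common value. The implementation is
cross-checked against Bioconductor limma's `lmFit`/`eBayes` on a shared
matrix in the test suite (prior and statistics agree to ≤ 0.1%).

Methylation is tested on raw bin proportions; this mirrors the modelled
procedure, which hands bin levels to the linear-model machinery directly.
An arcsine-square-root transform is available as a flag for users who
prefer variance stabilisation. Expression is tested on log₂(FPKM + 1) as
a documented stand-in for count-based differential expression; the
negative-binomial isoform machinery of the original tooling is out of
scope, while direction classes and thresholds are preserved.

Selection uses **raw** p-values (DMR: p < 0.05 and |Δ| > 0.1, both
strict; DEG: p < 0.05) exactly as the thresholds are stated; a
Benjamini–Hochberg FDR column is emitted for reference but never used for
selection.

## Trajectory regression

For bins, x = old − young and y = treated − old (or treated − young).
If treated = λ·old + (1 − λ)·young then y = (λ − 1)·x (resp. λ·x), so the
OLS slope estimates λ − 1 (resp. λ), and the two axis choices differ by
exactly 1 (an identity used as a cross-check on every dataset). The
regression keeps an unconstrained intercept — the fitted intercepts on
synthetic data are ~10⁻³ — and λ̂ uses the slope only. The Pearson
correlation is computed on the same (x, y) pairs. Quadrant counts exclude
bins lying on either axis, since the argument concerns signed changes.

Error analysis worth knowing: both axes share the old (or young) group's
measurement error, which enters the covariance as −Var(e_old) on the
treated − old axis. With replicate noise confined to the treated groups
(see the generator below) and read-sampling noise at ~30× coverage over
~8 sites × 3 replicates, the residual slope bias is ≈ −0.005 at
Var(x) ≈ 0.004; putting extra per-sample noise on young/old inflates this
several-fold.

## Amelioration

Only significant young-vs-old calls with a direction are classified.
The rule is strictly directional on group means: hyper DMR / ODEG
ameliorated iff treated mean < old mean; hypo / UDEG iff treated mean >
old mean; exact ties are **not** ameliorated. No significance is required
of the treated-vs-old contrast (an optional moderated-test gate exists
for users who want one). Consequence on noisy data: a feature whose
treated truth equals old is a fair coin, so with rescue probability ρ the
expected measured fraction is ρ + (1 − ρ)/2, while classifying against
noise-free levels returns exactly the realised ρ. `run_all` reports both
(`dmr_ameliorated_fraction_{group}` and `..._truth_{group}`), and real
studies should read the measured number with this inflation in mind.

## Annotation and correlation

Promoters are 2 kb upstream of the TSS (strand-aware, clipped at 0);
the span is a convention the source procedure never fixes, so it is a
parameter and DMG counts depend on it. Overlap is ≥ 1 bp half-open
intersection; a DMR hitting both promoter and body of a gene yields two
records, and unannotated DMRs are kept with an empty gene field. The
production path is a per-chromosome sorted sweep, tested against a
brute-force all-pairs scan.

Expression–methylation correlation uses all 15 samples (df = 13), which
reproduces every printed PCC/p pair of the motivating analysis to the
printed precision; p comes from t = r·√(n−2)/√(1−r²), two-sided, and
significance is |r| > 0.5 with p < 0.05, uncorrected.

## GO over-representation

P(X ≥ k) for X ~ Hypergeom(N, K, n) per term with ≥ 1 study gene, counts
taken from direct annotations only (no ancestor closure). The Bonferroni
divisor m is the number of terms tested (those with ≥ 1 study gene),
recorded implicitly by the result table length. "Top three levels" is
interpreted as minimum is_a depth from the namespace root ∈ {0, 1, 2},
computed breadth-first; such terms are excluded from the significant set
but retained in output. Significance is p < 0.01. Depth semantics (min
vs max path) and the exact test universe are interpretations; both are
configurable.

## Synthetic-data generator

What it emulates, and the defaults (all drawn from one seeded
`numpy.random.Generator` with fixed sub-streams, so outputs are
byte-identical per seed):

- **Islands → bins.** 5,000 islands over 5 chromosomes; sites per island
  2 + Poisson(6); intra-island spacing U{10..50} bp (mean bin length
  ≈ 210 bp); inter-island gaps ≥ 2.5 kb so binning recovers islands
  exactly.
- **Baseline levels.** 0.45·Beta(0.4, 8) + 0.45·Beta(12, 1.5) +
  0.10·U(0.1, 0.9): bimodal with > 60% of mass in [0, 0.1] ∪ [0.8, 1.0].
- **Aging effects.** 10% of bins shift by δ = 0.2. Direction is assigned
  by headroom (baseline < 0.5 → hyper, ≥ 0.5 → hypo) so every aging bin
  carries the full |Δ| without clipping; the nominal hyper:hypo split is
  honoured as far as the baseline strata allow.
- **Treatment.** Each aging bin is rescued with probability ρ (DR 0.835,
  RALL 0.79); rescued bins get treated = λ·old + (1 − λ)·young (DR
  λ = 0.565, RALL λ = 0.5585), non-rescued bins stay exactly at old, so
  the rescue signal is the only systematic treated-vs-old difference.
  Treated samples add truncated Gaussian noise (σ = 0.02, clipped to
  [0, 1]); young/old replicates differ only through read sampling.
- **Reads.** Coverage = 5 + NegBin(mean 25, dispersion 10) per
  site/sample (floor 5 so the read filter passes everything by default;
  `subthreshold_fraction` injects shallow sites to exercise it);
  methylated reads ~ Binomial(coverage, bin truth).
- **Expression.** 2,000 genes, log-normal baseline (log₂ mean 3, sd 1.5);
  10% aging DEGs (ODEG fraction 0.772 mirroring the observed 839:248
  imbalance) with |log₂FC| ~ U(1, 2); rescued genes (DR 0.90, RALL 0.72)
  return to the young mean, others stay at old; log-normal replicate
  noise (sd 0.25 on log₂).
- **Annotation.** 30% of bins (aging first) host a gene, alternating
  body/promoter placement, reusing the expression gene ids; a small
  biological_process is_a DAG (depths 0–3, with diamonds) is written as
  OBO alongside a gene→term table.

What it does **not** emulate: read-level bisulfite sequences, realistic
chromosomal CpG maps, batch effects, covariates, count overdispersion
structure in expression, or annotation bias. Passing tests therefore
demonstrate the correctness and calibration of the pipeline's statistics
under the stated generative model, not performance on any real cohort.

Under these defaults the DMR caller reaches ≥ 90% sensitivity at ≤ 7%
false positive rate, the moderated test's type-I error is 0.05 ± 0.015 at
10,000 null features, and the prior estimator recovers (d₀ = 4, s₀²)
within ±1 / ±20% at 5,000 features — all asserted in the test suite.

## Problem sizes and numerical choices

The default simulation (5,000 bins × 15 samples, ~40k sites/sample;
2,000 genes) runs the full pipeline in a few seconds and was chosen as
the smallest size at which the mixture slope stabilises to within ±0.02;
the orchestrated test run uses 1,000 bins. Floats in TSVs carry 6
significant digits; downstream stages of `run_all` re-read the written
TSVs rather than in-memory values, so standalone subcommand reruns are
byte-identical to the orchestrated outputs. Ties, degenerate inputs:
zero-variance features with no shrinkage get p ∈ {0, 1} by mean equality
with a warning; constant vectors abort a correlation pair with a log
entry; a zero-variance baseline aborts the trajectory fit; |r| = 1 gives
p = 0 with a warning.

## Known limitations

- The moderated t on proportions ignores the mean–variance relationship
  of methylation fractions; the arcsine option mitigates but the default
  mirrors the modelled procedure.
- The DEG stand-in is not a count model; borderline DEGs near p = 0.05
  will differ from negative-binomial callers.
- Promoter span (2 kb) and GO depth filtering are conventions; DMG counts
  and enriched-term lists depend on them.
- The amelioration rule is binary and directional; it does not grade the
  percent of the aging change recovered.
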