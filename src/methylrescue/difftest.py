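"""Two-group differential tests with empirical-Bayes variance shrinkage.

The per-feature test is a moderated two-sample t: the pooled residual
variance s_g^2 (d = n_a + n_b - 2 degrees of freedom) is shrunk toward a
prior variance s0^2 with weight d0 prior degrees of freedom,

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

and the statistic (mean_b - mean_a) / (s~_g * sqrt(1/n_a + 1/n_b)) is
referred to a Student t distribution with d + d0 degrees of freedom.  With
d0 = 0 this is exactly the classical pooled-variance two-sample t; with
d0 = inf the variance is fully replaced by s0^2 and the reference
distribution is normal.

The prior (d0, s0^2) is fitted across features by the method of moments on
log sample variances: under the hierarchical model sigma_g^2 ~
s0^2 * d0 / chisq(d0), the excess variance of log s_g^2 over the
trigamma(d/2) sampling term identifies d0 through the trigamma function.

Methylation bins are tested on raw bin levels (optionally arcsine-sqrt
transformed); expression is tested on log2(FPKM + 1).  Differentially
methylated regions (DMRs) require p < 0.05 and |group mean difference| >
0.1; differentially expressed genes (DEGs) require p < 0.05 and are classed
ODEG (higher in the older/second group) or UDEG (lower).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import SampleSheet, ValidationError

__all__ = [
    "ShrinkagePrior",
    "estimate_prior",
    "moderated_two_sample_test",
    "call_dmrs",
    "call_degs",
    "expression_summary",
]

logger = logging.getLogger(__name__)

MIN_FEATURES_FOR_PRIOR = 10


@dataclass(frozen=True)
class ShrinkagePrior:
    """Variance prior: d0 prior degrees of freedom, s0_sq prior variance.

    ``d0 = 0`` disables shrinkage (classical t); ``d0 = math.inf`` pins every
    feature's variance at ``s0_sq``.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or not self.s0_sq > 0:
            raise ValidationError(f"invalid prior d0={self.d0}, s0_sq={self.s0_sq}")


NO_SHRINKAGE = ShrinkagePrior(d0=0.0, s0_sq=1.0)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(variances: np.ndarray, df: float) -> ShrinkagePrior:
    """Fit (d0, s0_sq) by moments on log sample variances.

    ``variances`` are per-feature pooled sample variances, each on ``df``
    residual degrees of freedom.  Features with zero or non-finite variance
    are dropped.  With fewer than 10 usable features, or when the moment
    equations cannot be solved, shrinkage is disabled (d0 = 0, s0_sq = the
    mean variance).  When the log variances show no excess spread over
    sampling noise, d0 = inf with s0_sq at the common value.
    """
    v = np.asarray(variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < MIN_FEATURES_FOR_PRIOR:
        fallback = float(np.mean(v)) if v.size else 1.0
        return ShrinkagePrior(d0=0.0, s0_sq=fallback)
    if np.all(v == v[0]):  # no spread at all: variance is known exactly
        return ShrinkagePrior(d0=math.inf, s0_sq=float(v[0]))
    z = np.log(v)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if not math.isfinite(emean):
        return ShrinkagePrior(d0=0.0, s0_sq=float(np.mean(v)))
    if evar <= 0:
        return ShrinkagePrior(d0=math.inf, s0_sq=float(math.exp(emean)))
    # excess spread of log variances identifies d0: evar = trigamma(d0/2)
    d0 = 2.0 * _trigamma_inverse(evar)
    if not math.isfinite(d0) or d0 <= 0:
        return ShrinkagePrior(d0=math.inf, s0_sq=float(math.exp(emean)))
    s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return ShrinkagePrior(d0=d0, s0_sq=s0_sq)


def _pooled(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Group means, pooled variance, and residual df for feature x sample arrays."""
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValidationError("each group needs at least 2 samples")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    d = n_a + n_b - 2
    return mean_a, mean_b, ss / d, d


def moderated_two_sample_test(
    values_a: np.ndarray, values_b: np.ndarray, prior: ShrinkagePrior = NO_SHRINKAGE
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p for each feature (rows) of two group arrays.

    Accepts 1-D vectors (one feature) or 2-D feature x sample arrays.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    squeeze = np.asarray(values_a).ndim == 1
    mean_a, mean_b, s_sq, d = _pooled(a, b)
    delta = mean_b - mean_a
    n_a, n_b = a.shape[1], b.shape[1]
    scale = math.sqrt(1.0 / n_a + 1.0 / n_b)

    if math.isinf(prior.d0):
        s_tilde = np.full_like(s_sq, prior.s0_sq)
        df_total = math.inf
    else:
        s_tilde = (prior.d0 * prior.s0_sq + d * s_sq) / (prior.d0 + d)
        df_total = d + prior.d0

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = delta / (np.sqrt(s_tilde) * scale)
    degenerate = s_tilde == 0
    if degenerate.any():
        warnings.warn("zero variance in both groups with no shrinkage; p set by mean equality")
        inf_stat = np.where(delta > 0, np.inf, np.where(delta < 0, -np.inf, 0.0))
        stat = np.where(degenerate, inf_stat, stat)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(stat), df_total)
    p = np.where(np.isinf(stat), 0.0, p)
    p = np.where((stat == 0) & degenerate, 1.0, p)
    if squeeze:
        return float(stat[0]), float(p[0])
    return stat, p


def _run_test(
    matrix: pd.DataFrame,
    sample_sheet: SampleSheet,
    group_a: str,
    group_b: str,
    prior: ShrinkagePrior | None,
) -> pd.DataFrame:
    for g in (group_a, group_b):
        if g not in sample_sheet.groups:
            raise ValidationError(f"unknown group {g!r}; sheet has {sample_sheet.groups}")
    a = matrix[sample_sheet.samples_in(group_a)].to_numpy(float)
    b = matrix[sample_sheet.samples_in(group_b)].to_numpy(float)
    if prior is None:
        _, _, s_sq, d = _pooled(a, b)
        prior = estimate_prior(s_sq, d)
        logger.info("estimated variance prior d0=%.3g s0_sq=%.3g", prior.d0, prior.s0_sq)
    stat, p = moderated_two_sample_test(a, b, prior)
    out = pd.DataFrame(
        {
            "feature_id": matrix.index,
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "statistic": np.atleast_1d(stat),
            "p_value": np.atleast_1d(p),
        }
    )
    out["delta"] = out["mean_b"] - out["mean_a"]
    # BH-FDR is reported for reference only; selection always uses raw p
    pvals = out["p_value"].to_numpy()
    m = pvals.size
    fdr = np.empty(m)
    if m:
        order = np.argsort(pvals, kind="mergesort")
        ranked = pvals[order] * m / (np.arange(m) + 1.0)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        fdr[order] = np.minimum(ranked, 1.0)
    out["bh_fdr"] = fdr
    return out[["feature_id", "mean_a", "mean_b", "delta", "statistic", "p_value", "bh_fdr"]]


def call_dmrs(
    bin_matrix: pd.DataFrame,
    sample_sheet: SampleSheet,
    group_a: str,
    group_b: str,
    p_threshold: float = 0.05,
    delta_threshold: float = 0.1,
    prior: ShrinkagePrior | None = None,
    arcsine_transform: bool = False,
) -> pd.DataFrame:
    """Differentially methylated regions between two groups.

    A bin is a significant DMR when p < ``p_threshold`` and the absolute
    group mean difference exceeds ``delta_threshold`` (both strict).
    Direction is hyper (delta > 0) or hypo (delta < 0), with delta =
    mean(group_b) - mean(group_a); reported means/delta are always on the
    raw methylation scale even when the test runs on arcsine-sqrt values.
    """
    test_matrix = bin_matrix
    if arcsine_transform:
        test_matrix = np.arcsin(np.sqrt(bin_matrix.clip(0.0, 1.0)))
    out = _run_test(test_matrix, sample_sheet, group_a, group_b, prior)
    if arcsine_transform:
        a = bin_matrix[sample_sheet.samples_in(group_a)].mean(axis=1).to_numpy()
        b = bin_matrix[sample_sheet.samples_in(group_b)].mean(axis=1).to_numpy()
        out["mean_a"], out["mean_b"], out["delta"] = a, b, b - a
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    out.loc[out["delta"] == 0, "direction"] = "none"
    out["significant"] = (out["p_value"] < p_threshold) & (out["delta"].abs() > delta_threshold)
    return out


def call_degs(
    fpkm_matrix: pd.DataFrame,
    sample_sheet: SampleSheet,
    group_a: str,
    group_b: str,
    p_threshold: float = 0.05,
    prior: ShrinkagePrior | None = None,
) -> pd.DataFrame:
    """Differentially expressed genes between two groups on log2(FPKM + 1).

    Direction is ODEG when expression is higher in ``group_b`` (the older or
    treated group by convention) and UDEG when lower.  Genes with all-zero
    FPKM in both groups are dropped with a log entry.  Reported means are
    group mean FPKM on the raw scale; the statistic and p come from the
    moderated test on the log scale.
    """
    cols = sample_sheet.samples_in(group_a) + sample_sheet.samples_in(group_b)
    allzero = (fpkm_matrix[cols] == 0).all(axis=1)
    if allzero.any():
        logger.info("skipping %d gene(s) with all-zero FPKM in both groups", int(allzero.sum()))
    expr = fpkm_matrix.loc[~allzero]
    log_expr = np.log2(expr + 1.0)
    out = _run_test(log_expr, sample_sheet, group_a, group_b, prior)
    raw_a = expr[sample_sheet.samples_in(group_a)].mean(axis=1).to_numpy()
    raw_b = expr[sample_sheet.samples_in(group_b)].mean(axis=1).to_numpy()
    out["mean_a"], out["mean_b"], out["delta"] = raw_a, raw_b, raw_b - raw_a
    out["direction"] = np.where(out["delta"] > 0, "ODEG", "UDEG")
    out.loc[out["delta"] == 0, "direction"] = "none"
    out["significant"] = (out["p_value"] < p_threshold) & (out["direction"] != "none")
    return out


def expression_summary(
    fpkm_matrix: pd.DataFrame,
    sample_sheet: SampleSheet,
    group_a: str = "young",
    group_b: str = "old",
    fpkm_floor: float = 1.0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Expressed-gene counts per group and MA coordinates for group_b vs group_a.

    Returns (per-group count of genes whose group-mean FPKM exceeds the
    floor, per-gene DataFrame with mean expression of the two groups and
    log2 fold change b/a on raw FPKM; genes with a zero group mean get
    an infinite or undefined fold change and are left as such).
    """
    counts = pd.Series(
        {
            g: int((fpkm_matrix[sample_sheet.samples_in(g)].mean(axis=1) > fpkm_floor).sum())
            for g in sample_sheet.groups
        },
        name="n_expressed",
    )
    a = fpkm_matrix[sample_sheet.samples_in(group_a)].mean(axis=1)
    b = fpkm_matrix[sample_sheet.samples_in(group_b)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(b.to_numpy() / a.to_numpy())
    ma = pd.DataFrame(
        {
            "gene_id": fpkm_matrix.index,
            "mean_expression": ((a + b) / 2.0).to_numpy(),
            "log2_fold_change": log2fc,
        }
    ).reset_index(drop=True)
    return counts, ma
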