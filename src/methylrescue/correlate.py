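"""Expression-methylation correlation across samples.

For a (gene, bin) pair the Pearson product-moment coefficient r is computed
over the matched per-sample FPKM and bin methylation values, and the
two-sided p-value comes from the exact null distribution of r for bivariate
normal data: t = r * sqrt(n - 2) / sqrt(1 - r^2) referred to Student t with
n - 2 degrees of freedom.  A pair is called significant when |r| > 0.5 and
p < 0.05.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError

__all__ = ["pearson_r", "pearson_pvalue", "correlate_pairs"]

logger = logging.getLogger(__name__)

PCC_THRESHOLD = 0.5
P_THRESHOLD = 0.05


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 paired samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx * dx))
    sy = np.sqrt(np.sum(dy * dy))
    if sx == 0 or sy == 0:
        raise ValidationError("constant vector: correlation undefined")
    return float(np.clip(np.sum(dx * dy) / (sx * sy), -1.0, 1.0))


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for an observed Pearson r over n paired samples."""
    if n < 3:
        raise ValidationError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"r = {r} outside [-1, 1]")
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: p-value is 0 at machine precision")
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def correlate_pairs(
    expression_matrix: pd.DataFrame,
    bin_matrix: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Correlate each (gene, bin) pair across all shared samples.

    Both matrices must cover the same samples (columns).  Pairs whose
    expression or methylation vector is constant are skipped with a log
    entry.  Significance: |r| > 0.5 and p < 0.05.
    """
    expr_samples = list(expression_matrix.columns)
    if set(expr_samples) != set(bin_matrix.columns):
        raise ValidationError("expression and bin matrices cover different samples")
    meth = bin_matrix[expr_samples]

    rows = []
    for gene_id, region in pairs:
        if gene_id not in expression_matrix.index:
            raise ValidationError(f"gene {gene_id!r} missing from expression matrix")
        if region not in meth.index:
            raise ValidationError(f"bin {region!r} missing from bin matrix")
        x = expression_matrix.loc[gene_id].to_numpy(float)
        y = meth.loc[region].to_numpy(float)
        try:
            r = pearson_r(x, y)
        except ValidationError as exc:
            logger.info("skipping pair (%s, %s): %s", gene_id, region, exc)
            continue
        p = pearson_pvalue(r, x.size)
        rows.append(
            {
                "gene_id": gene_id,
                "region": region,
                "r": r,
                "n": x.size,
                "p_value": p,
                "significant": abs(r) > PCC_THRESHOLD and p < P_THRESHOLD,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "region", "r", "n", "p_value", "significant"])
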