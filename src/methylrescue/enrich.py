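"""GO over-representation with no parent propagation and a depth filter.

For each term annotating at least one study gene the upper-tail
hypergeometric probability P(X >= k) of drawing k or more annotated genes
in a study of size n from a population of N genes of which K are annotated
is computed.  Counts are *not* propagated to ancestor terms: a gene counts
only for the terms it is directly annotated to.  Bonferroni correction
multiplies by the number of terms tested (those with >= 1 study gene).
Terms in the shallowest ontology levels (min_depth < 3 by default, i.e. the
root and its first two tiers) are excluded from the significant list but
kept in the full table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Ontology, ValidationError

__all__ = ["hypergeom_tail", "enrich"]

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_DEPTH_KEEP = 3


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K annotated, n drawn)."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValidationError(f"inconsistent hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    study_genes: set[str],
    background_genes: set[str],
    annotations: dict[str, set[str]],
    ontology: Ontology | None = None,
    alpha: float = DEFAULT_ALPHA,
    min_depth_keep: int = DEFAULT_MIN_DEPTH_KEEP,
) -> pd.DataFrame:
    """Over-representation of study genes in directly-annotated GO terms.

    Returns one row per term with at least one study gene, sorted by
    p-value: counts, hypergeometric p, Bonferroni-adjusted p (m = number of
    terms tested), the term's min_depth (when an ontology is given), and
    the significance call p < alpha with min_depth >= min_depth_keep.
    """
    study = set(study_genes)
    background = set(background_genes)
    stray = study - background
    if stray:
        raise ValidationError(
            f"study gene(s) absent from background: {', '.join(sorted(stray)[:5])}"
        )

    term_pop: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene not in background:
            continue
        for term in terms:
            term_pop.setdefault(term, set()).add(gene)

    N = len(background)
    n = len(study)
    rows = []
    for term, pop_genes in term_pop.items():
        study_hits = pop_genes & study
        if not study_hits:
            continue
        K = len(pop_genes)
        k = len(study_hits)
        p = hypergeom_tail(k, n, K, N)
        if ontology is not None and term in ontology:
            name = ontology[term].name
            depth = ontology[term].min_depth
        else:
            name = term
            depth = np.nan
        rows.append(
            {
                "term_id": term,
                "name": name,
                "study_count": k,
                "study_size": n,
                "population_count": K,
                "population_size": N,
                "p_value": p,
                "min_depth": depth,
                "study_genes": ",".join(sorted(study_hits)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "study_count", "study_size", "population_count",
            "population_size", "p_value", "min_depth", "study_genes",
        ],
    )
    m = len(out)
    out["bonferroni"] = np.minimum(1.0, out["p_value"] * m)
    depth_ok = out["min_depth"].isna() | (out["min_depth"] >= min_depth_keep)
    out["significant"] = (out["p_value"] < alpha) & depth_ok
    out = out.sort_values(["p_value", "term_id"], kind="mergesort", ignore_index=True)
    return out[
        [
            "term_id", "name", "study_count", "study_size", "population_count",
            "population_size", "p_value", "bonferroni", "min_depth", "significant",
            "study_genes",
        ]
    ]
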