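"""Mapping DMRs onto promoters and gene bodies.

A gene whose promoter (a fixed window upstream of the transcription start
site, strand-aware) or body overlaps a DMR by at least 1 bp is a
differentially methylated gene (DMG).  The promoter span is a convention,
not a measured quantity — DMG counts depend on it, so it is exposed as a
parameter (default 2 kb).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import parse_region

__all__ = ["promoter_of", "map_dmrs_to_genes", "dmg_summary"]

DEFAULT_UPSTREAM = 2000


def promoter_of(start: int, end: int, strand: str, upstream: int = DEFAULT_UPSTREAM) -> tuple[int, int]:
    """Promoter interval (0-based half-open) upstream of the TSS, clipped at 0."""
    if strand == "+":
        return max(0, start - upstream), start
    return end, end + upstream


def map_dmrs_to_genes(
    dmrs: pd.DataFrame,
    gene_models: pd.DataFrame,
    upstream: int = DEFAULT_UPSTREAM,
    carry_columns: tuple[str, ...] = ("aging_direction", "ameliorated"),
) -> pd.DataFrame:
    """One record per (gene, region class, DMR) overlap.

    ``dmrs`` must carry a ``feature_id`` column of region strings; columns
    named in ``carry_columns`` are propagated when present.  A DMR that
    overlaps both the promoter and the body of one gene yields two records.
    DMRs overlapping nothing (including DMRs on chromosomes absent from the
    gene set) are retained with an empty gene_id and region class.
    """
    carried = [c for c in carry_columns if c in dmrs.columns]

    # candidate intervals: gene bodies plus promoters, grouped per chromosome
    intervals: dict[str, list[tuple[int, int, str, str]]] = {}
    for g in gene_models.itertuples(index=False):
        p_start, p_end = promoter_of(g.start, g.end, g.strand, upstream)
        intervals.setdefault(g.chrom, []).append((g.start, g.end, g.gene_id, "gene_body"))
        if p_end > p_start:
            intervals.setdefault(g.chrom, []).append((p_start, p_end, g.gene_id, "promoter"))
    arrays = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        starts = np.array([iv[0] for iv in ivs])
        ends = np.array([iv[1] for iv in ivs])
        arrays[chrom] = (starts, ends, ivs)

    records = []
    for row in dmrs.itertuples(index=False):
        region = row.feature_id
        chrom, start, end = parse_region(region)
        extra = {c: getattr(row, c) for c in carried}
        hits = []
        if chrom in arrays:
            starts, ends, ivs = arrays[chrom]
            # sorted sweep: any interval starting before the DMR ends is a candidate
            hi = int(np.searchsorted(starts, end, side="left"))
            for i in range(hi):
                if ends[i] > start:
                    hits.append(ivs[i])
        if hits:
            for _s, _e, gene_id, region_class in hits:
                records.append({"gene_id": gene_id, "region_class": region_class, "dmr_id": region, **extra})
        else:
            records.append({"gene_id": "", "region_class": "", "dmr_id": region, **extra})
    return pd.DataFrame(records, columns=["gene_id", "region_class", "dmr_id", *carried])


def dmg_summary(dmg_records: pd.DataFrame) -> pd.DataFrame:
    """Gene-level DMG counts, deduplicated by gene within each aging direction."""
    annotated = dmg_records.loc[dmg_records["gene_id"] != ""]
    if "aging_direction" in annotated.columns:
        counts = (
            annotated.drop_duplicates(["gene_id", "aging_direction"])
            .groupby("aging_direction")
            .size()
            .rename("n_genes")
            .reset_index()
        )
    else:
        counts = pd.DataFrame({"aging_direction": ["all"], "n_genes": [annotated["gene_id"].nunique()]})
    return counts
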