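"""CpG site filtering and adjacency binning.

A bin is a maximal run of retained CpG sites in which consecutive sites on
one chromosome are no more than ``max_gap`` bp apart (1 kb by default).
Each bin's methylation level, per sample, is the unweighted mean of its
member sites' methylation proportions; group levels are unweighted means
over that group's samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SampleSheet, ValidationError, format_region

__all__ = ["Bin", "BinMatrix", "filter_sites", "intersect_sites", "build_bins", "bin_levels", "compute_bin_matrix"]

DEFAULT_MIN_READS = 5
DEFAULT_MAX_GAP = 1000


@dataclass(frozen=True)
class Bin:
    """A genomic interval spanning adjacent retained CpG sites.

    ``start``/``end`` are the 0-based half-open span from the first member
    site to one past the last; consecutive member positions differ by at
    most the binning gap.
    """

    chrom: str
    start: int
    end: int
    site_positions: tuple[int, ...]

    @property
    def region(self) -> str:
        return format_region(self.chrom, self.start, self.end)

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_sites(calls: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS, context: str = "CpG") -> pd.DataFrame:
    """Keep only calls in the requested context with total_reads >= min_reads.

    The read threshold is inclusive: a site covered by exactly ``min_reads``
    reads is retained.
    """
    keep = (calls["context"] == context) & (calls["total_reads"] >= min_reads)
    return calls.loc[keep].reset_index(drop=True)


def intersect_sites(calls_by_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Sites (chrom, pos) present in every sample's filtered calls."""
    if not calls_by_sample:
        raise ValidationError("no samples provided")
    common: pd.Index | None = None
    for calls in calls_by_sample.values():
        idx = pd.MultiIndex.from_frame(calls[["chrom", "pos"]])
        common = idx if common is None else common.intersection(idx)
    out = common.to_frame(index=False)
    return out.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)


def build_bins(sites: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> list[Bin]:
    """Greedy left-to-right partition of sorted sites into adjacency bins.

    A new bin starts whenever the chromosome changes or the distance to the
    previous site exceeds ``max_gap`` ("no more than" — a gap of exactly
    ``max_gap`` stays in the same bin).
    """
    bins: list[Bin] = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        pos = np.sort(sub["pos"].to_numpy())
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for chunk in np.split(pos, breaks):
            bins.append(
                Bin(chrom=str(chrom), start=int(chunk[0]), end=int(chunk[-1]) + 1, site_positions=tuple(int(p) for p in chunk))
            )
    return bins


@dataclass
class BinMatrix:
    """Bin x sample methylation levels plus the bin definitions.

    ``sample_levels`` is indexed by region string with one column per
    sample; every entry is in [0, 1].
    """

    bins: list[Bin]
    sample_levels: pd.DataFrame
    sample_sheet: SampleSheet

    @property
    def regions(self) -> list[str]:
        return list(self.sample_levels.index)

    @property
    def n_sites(self) -> pd.Series:
        return pd.Series({b.region: b.n_sites for b in self.bins}, name="n_sites").reindex(self.sample_levels.index)

    def group_levels(self) -> pd.DataFrame:
        """Per-group bin levels: unweighted mean over each group's samples."""
        cols = {}
        for group in self.sample_sheet.groups:
            cols[group] = self.sample_levels[self.sample_sheet.samples_in(group)].mean(axis=1)
        return pd.DataFrame(cols, index=self.sample_levels.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.sample_levels.copy()
        out.insert(0, "n_sites", self.n_sites)
        out.insert(0, "region", out.index)
        return out.reset_index(drop=True)


def bin_levels(bins: list[Bin], calls_by_sample: dict[str, pd.DataFrame], sample_sheet: SampleSheet) -> BinMatrix:
    """Average member-site methylation per bin and sample.

    Every member site must carry a call in every sample (guaranteed when the
    bins were built on the sample intersection); a missing combination is an
    error, not silently imputed.
    """
    site_to_region: dict[tuple[str, int], str] = {}
    for b in bins:
        for p in b.site_positions:
            site_to_region[(b.chrom, p)] = b.region

    regions = [b.region for b in bins]
    levels = pd.DataFrame(index=pd.Index(regions, name="region"), dtype=float)
    for sample_id in sample_sheet.samples:
        calls = calls_by_sample[sample_id]
        key = pd.MultiIndex.from_frame(calls[["chrom", "pos"]])
        mapped = pd.Series([site_to_region.get(k) for k in key], index=calls.index)
        sub = calls.loc[mapped.notna(), "level"].groupby(mapped.dropna()).mean()
        col = sub.reindex(regions)
        if col.isna().any():
            missing = col.index[col.isna()][0]
            raise ValidationError(f"sample {sample_id!r} has no calls for bin {missing}")
        counts = calls.loc[mapped.notna()].groupby(mapped.dropna()).size().reindex(regions)
        expected = pd.Series({b.region: b.n_sites for b in bins}).reindex(regions)
        if (counts != expected).any():
            bad = counts.index[counts != expected][0]
            raise ValidationError(f"sample {sample_id!r} misses member sites of bin {bad}")
        levels[sample_id] = col
    return BinMatrix(bins=bins, sample_levels=levels, sample_sheet=sample_sheet)


def compute_bin_matrix(
    calls_by_sample: dict[str, pd.DataFrame],
    sample_sheet: SampleSheet,
    min_reads: int = DEFAULT_MIN_READS,
    max_gap: int = DEFAULT_MAX_GAP,
    min_samples: int | None = None,
) -> BinMatrix:
    """Filter, intersect, bin, and average in one call.

    By default only sites passing the read filter in *all* samples enter the
    bin set, which guarantees a complete bin x sample matrix.  With
    ``min_samples = k`` a site present in at least k samples is kept and a
    missing (bin, sample) level is imputed by the bin's mean over available
    samples.
    """
    filtered = {s: filter_sites(calls_by_sample[s], min_reads=min_reads) for s in sample_sheet.samples}
    if min_samples is None:
        sites = intersect_sites(filtered)
        bins = build_bins(sites, max_gap=max_gap)
        return bin_levels(bins, filtered, sample_sheet)

    counts: dict[tuple[str, int], int] = {}
    for calls in filtered.values():
        for k in zip(calls["chrom"], calls["pos"]):
            counts[k] = counts.get(k, 0) + 1
    keep = [k for k, c in counts.items() if c >= min_samples]
    sites = pd.DataFrame(keep, columns=["chrom", "pos"]).sort_values(["chrom", "pos"], ignore_index=True)
    bins = build_bins(sites, max_gap=max_gap)

    site_to_region = {(b.chrom, p): b.region for b in bins for p in b.site_positions}
    regions = [b.region for b in bins]
    levels = pd.DataFrame(index=pd.Index(regions, name="region"), dtype=float)
    for sample_id in sample_sheet.samples:
        calls = filtered[sample_id]
        key = pd.Series(
            [site_to_region.get(k) for k in zip(calls["chrom"], calls["pos"])], index=calls.index
        )
        levels[sample_id] = calls.loc[key.notna(), "level"].groupby(key.dropna()).mean().reindex(regions)
    # impute a sample's missing bin level with the bin's available-sample mean
    row_means = levels.mean(axis=1)
    levels = levels.apply(lambda col: col.fillna(row_means))
    if levels.isna().any().any():
        raise ValidationError("bins with no coverage in any sample cannot be imputed")
    return BinMatrix(bins=bins, sample_levels=levels, sample_sheet=sample_sheet)
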