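"""Readers and writers for every external file the pipeline touches.

Coordinate convention: internally every interval is 0-based half-open
``[start, end)``; user-facing region strings are 1-based inclusive
(``chr1:135502252-135502293``), the convention genome browsers print.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "CPG_COLUMNS",
    "MethylRescueError",
    "ParseError",
    "ValidationError",
    "SampleSheet",
    "OntologyTerm",
    "Ontology",
    "read_cpg_table",
    "write_cpg_table",
    "read_expression_table",
    "write_expression_table",
    "read_gene_models",
    "read_gene2go",
    "read_obo",
    "format_region",
    "parse_region",
    "write_tsv",
    "read_result_tsv",
    "load_bin_matrix",
]

GROUPS = ("young", "old", "DR", "RALL", "RDRL")

#: canonical per-CpG call table columns (tab-separated, 1-based positions on disk)
CPG_COLUMNS = ["chrom", "pos", "strand", "context", "methylated_reads", "total_reads"]


class MethylRescueError(Exception):
    """Base class for pipeline errors."""


class ParseError(MethylRescueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(MethylRescueError):
    """Parsed content violates a contract (counts, coordinates, bookkeeping)."""


# ---------------------------------------------------------------------------
# region strings


def format_region(chrom: str, start: int, end: int) -> str:
    """Render a 0-based half-open interval as a 1-based inclusive region string."""
    return f"{chrom}:{start + 1}-{end}"


_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)[-–](?P<end>\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:first-last`` (1-based inclusive) to (chrom, start, end) 0-based half-open."""
    m = _REGION_RE.match(region)
    if m is None:
        raise ParseError(f"malformed region string: {region!r}")
    start = int(m.group("start")) - 1
    end = int(m.group("end"))
    if not start < end:
        raise ValidationError(f"empty or inverted region: {region!r}")
    return m.group("chrom"), start, end


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleSheet:
    """Maps each sample to its experimental group.

    The design this pipeline targets is five groups (young, old, DR, RALL,
    RDRL) with three biological replicates each, but any two-plus-sample
    grouping is accepted.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValidationError("sample sheet is empty")
        object.__setattr__(self, "mapping", dict(self.mapping))

    @property
    def samples(self) -> list[str]:
        return list(self.mapping)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g)
        return list(seen)

    def group_of(self, sample_id: str) -> str:
        try:
            return self.mapping[sample_id]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} not in sample sheet") from None

    def samples_in(self, group: str) -> list[str]:
        out = [s for s, g in self.mapping.items() if g == group]
        if not out:
            raise ValidationError(f"group {group!r} has no samples")
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(_text_lines(path), start=1):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            sample, group = parts
            if sample in mapping:
                raise ValidationError(f"{path}: duplicate sample id {sample!r}")
            mapping[sample] = group
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#sample_id\tgroup\n")
            for s, g in self.mapping.items():
                fh.write(f"{s}\t{g}\n")

    @classmethod
    def default_design(cls, n_per_group: int = 3, groups: Iterable[str] = GROUPS) -> "SampleSheet":
        """The study layout: each group with ``n_per_group`` replicate samples."""
        return cls({f"{g}_{i + 1}": g for g in groups for i in range(n_per_group)})


def _text_lines(path: str | Path) -> Iterable[str]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line


# ---------------------------------------------------------------------------
# CpG call tables


def read_cpg_table(path: str | Path, sample_id: str, dialect: str = "auto") -> pd.DataFrame:
    """Read one sample's per-CpG methylation calls.

    Two dialects are accepted: the canonical 6-column TSV
    (chrom, pos 1-based, strand, context, methylated_reads, total_reads) and
    BS-Seeker2 CGmap (8 columns; strand inferred from the nucleotide column).

    Returns a DataFrame sorted by (chrom, pos) with 0-based positions and a
    derived ``level`` column (methylated/total).
    """
    rows: list[tuple] = []
    for lineno, line in enumerate(_text_lines(path), start=1):
        parts = line.split("\t")
        use = dialect
        if use == "auto":
            use = "cgmap" if len(parts) == 8 else "tsv"
        try:
            if use == "cgmap":
                chrom, nuc, pos_s, ctx, _dinuc, _lvl, meth_s, total_s = parts
                strand = "+" if nuc.upper() == "C" else "-"
                context = {"CG": "CpG"}.get(ctx, ctx)
            else:
                chrom, pos_s, strand, context, meth_s, total_s = parts
            pos = int(pos_s)
            meth = int(meth_s)
            total = int(total_s)
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        if total <= 0:
            raise ValidationError(f"{path}: line {lineno}: total_reads must be positive")
        if meth < 0 or meth > total:
            raise ValidationError(
                f"{path}: line {lineno}: methylated_reads {meth} outside [0, {total}]"
            )
        rows.append((chrom, pos - 1, strand, context, meth, total))

    df = pd.DataFrame(rows, columns=CPG_COLUMNS)
    df["level"] = df["methylated_reads"] / df["total_reads"]
    df["sample_id"] = sample_id
    return df.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)


def write_cpg_table(calls: pd.DataFrame, path: str | Path) -> None:
    """Write calls back in the canonical 6-column dialect (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CPG_COLUMNS) + "\n")
        for row in calls.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.context}\t"
                f"{row.methylated_reads}\t{row.total_reads}\n"
            )


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(path: str | Path, sample_sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Read a gene x sample FPKM matrix (first column gene_id, header row required)."""
    df = pd.read_csv(path, sep="\t", comment=None)
    first = df.columns[0]
    if first.startswith("#"):
        df = df.rename(columns={first: first.lstrip("#")})
        first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "gene_id"
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene_id(s): {', '.join(map(str, dup[:5]))}")
    df = df.astype(float)
    if (df.values < 0).any():
        bad = df.index[(df.values < 0).any(axis=1)][0]
        raise ValidationError(f"{path}: negative FPKM for gene {bad!r}")
    if sample_sheet is not None:
        unknown = [c for c in df.columns if c not in sample_sheet.mapping]
        if unknown:
            raise ValidationError(f"{path}: samples not in sample sheet: {', '.join(unknown)}")
    return df


def write_expression_table(fpkm: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\t" + "\t".join(fpkm.columns) + "\n")
        for gene, row in fpkm.iterrows():
            fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row.values) + "\n")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, collapse_by_name: bool = False) -> pd.DataFrame:
    """Read gene spans from BED6 or a knownGene-like TSV.

    Both dialects carry 0-based starts natively, so no shift is applied.
    knownGene-like rows are ``name chrom strand txStart txEnd``.  Returns a
    DataFrame with columns gene_id, chrom, strand, start, end (0-based
    half-open).  With ``collapse_by_name`` rows sharing a gene_id on one
    chromosome/strand are merged to the union of their spans.
    """
    rows = []
    for lineno, line in enumerate(_text_lines(path), start=1):
        parts = line.split("\t")
        try:
            if len(parts) >= 6 and parts[1].isdigit() and parts[2].isdigit():
                chrom, start_s, end_s, gene_id, _score, strand = parts[:6]
            elif len(parts) >= 5:
                gene_id, chrom, strand, start_s, end_s = parts[:5]
            else:
                raise ValueError(f"expected BED6 or knownGene columns, got {len(parts)}")
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        if strand not in ("+", "-"):
            raise ValidationError(
                f"{path}: line {lineno}: strand {strand!r} (required for promoter inference)"
            )
        if start >= end:
            raise ValidationError(f"{path}: line {lineno}: tx_start >= tx_end")
        rows.append((gene_id, chrom, strand, start, end))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    if collapse_by_name:
        genes = (
            genes.groupby(["gene_id", "chrom", "strand"], as_index=False)
            .agg(start=("start", "min"), end=("end", "max"))
            [["gene_id", "chrom", "strand", "start", "end"]]
        )
    return genes.sort_values(["chrom", "start"], kind="mergesort", ignore_index=True)


# ---------------------------------------------------------------------------
# gene -> GO annotations


def read_gene2go(path: str | Path) -> dict[str, set[str]]:
    """Read gene-to-GO-term annotations from 2-column TSV or GAF 2.x.

    GAF rows are recognised by their column count (>= 15); only the
    DB-object-symbol (col 3) and GO id (col 5) are consumed.
    """
    anno: dict[str, set[str]] = {}
    for lineno, line in enumerate(_text_lines(path), start=1):
        if line.startswith("!"):
            continue
        parts = line.split("\t")
        if len(parts) >= 15:
            gene, term = parts[2], parts[4]
        elif len(parts) == 2:
            gene, term = parts
        else:
            raise ParseError(f"{path}: line {lineno}: expected 2-column TSV or GAF row")
        anno.setdefault(gene, set()).add(term)
    return anno


# ---------------------------------------------------------------------------
# ontology


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    namespace: str
    parent_ids: tuple[str, ...]
    min_depth: int


@dataclass
class Ontology:
    """GO is_a DAG with per-term minimum depth from its namespace root.

    Roots (terms with no is_a parent) have depth 0; every other term's
    min_depth is the shortest is_a path to a root, computed breadth-first.
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> OntologyTerm:
        return self.terms[term_id]

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_graph(cls, graph: nx.MultiDiGraph) -> "Ontology":
        isa = nx.DiGraph()
        meta: dict[str, dict] = {}
        for node, data in graph.nodes(data=True):
            meta[node] = data
            isa.add_node(node)
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                isa.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(isa):
            cycle = nx.find_cycle(isa)
            path = " -> ".join(edge[0] for edge in cycle) + " -> " + cycle[-1][1]
            raise ValidationError(f"is_a cycle in ontology: {path}")

        roots = [n for n in isa.nodes if isa.out_degree(n) == 0]
        depth: dict[str, int] = {r: 0 for r in roots}
        queue = deque(roots)
        children_of: dict[str, list[str]] = {n: [] for n in isa.nodes}
        for child, parent in isa.edges:
            children_of[parent].append(child)
        while queue:
            node = queue.popleft()
            for child in children_of[node]:
                if child not in depth:
                    depth[child] = depth[node] + 1
                    queue.append(child)

        terms = {}
        for node in isa.nodes:
            data = meta.get(node, {})
            terms[node] = OntologyTerm(
                term_id=node,
                name=data.get("name", node),
                namespace=data.get("namespace", ""),
                parent_ids=tuple(sorted(isa.successors(node))),
                min_depth=depth[node],
            )
        return cls(terms)


def read_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2 file (id/name/namespace/is_a; obsolete terms dropped)."""
    graph = obonet.read_obo(str(path))
    return Ontology.from_graph(graph)


# ---------------------------------------------------------------------------
# generic TSV output


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a result table with a '#'-prefixed header line and stable float text."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format=float_format)


def read_result_tsv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline TSV; the last leading '#' line is the column header."""
    header: str | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header = line
            else:
                break
    if header is None:
        return pd.read_csv(path, sep="\t")
    names = header.lstrip("#").rstrip("\n").split("\t")
    return pd.read_csv(path, sep="\t", comment="#", header=None, names=names)


def load_bin_matrix(path: str | Path, sample_sheet: "SampleSheet") -> pd.DataFrame:
    """Sample-level bin matrix from a bins.tsv (region, n_sites, one col/sample)."""
    df = read_result_tsv(path).set_index("region")
    return df[[c for c in df.columns if c in sample_sheet.mapping]]
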