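"""Readers, writers and shared domain types.

All genomic coordinates are 0-based, half-open.  Gene identifiers are
case-sensitive opaque strings; no alias resolution is attempted.
Every reader validates its input and raises :class:`FormatError` with the
offending location; every writer/reader pair is an exact inverse on valid
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "Segment",
    "GeneSet",
    "GeneSetCollection",
    "DirectedEdge",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_seg",
    "write_seg",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "write_graph",
    "validate_annotation",
]

ANNOTATION_COLUMNS = ["chrom", "start", "end", "gene_id", "is_tf"]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_markers", "mean"]


class FormatError(ValueError):
    """Malformed input file; the message names the offending location."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (log-scale) expression values.

    Rows follow ``gene_ids``, columns follow ``sample_ids``; ids are unique
    and every value is finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise FormatError(f"duplicate gene id {dup}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise FormatError(f"duplicate sample id {dup}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value for gene {self.gene_ids[i]}, "
                f"sample {self.sample_ids[j]}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class Segment:
    """One constant-copy-number stretch of a sample's genome."""

    sample_id: str
    chrom: str
    start: int
    end: int
    num_markers: int
    mean_log_ratio: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"segment start {self.start} >= end {self.end} "
                f"(sample {self.sample_id}, chrom {self.chrom})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name} has no members")


GeneSetCollection = dict[str, GeneSet]


@dataclass(frozen=True)
class DirectedEdge:
    """A directed regulatory or pathway edge; self-loops are rejected."""

    source: str
    target: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise FormatError(f"self-loop edge on {self.source}")


# ---------------------------------------------------------------------------
# helpers


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _parse_float(token: str, where: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise FormatError(f"non-numeric value {token!r} at {where}") from None
    if not math.isfinite(v):
        raise FormatError(f"non-finite value {token!r} at {where}")
    return v


def _parse_int(token: str, where: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"non-integer value {token!r} at {where}") from None


def _split_line(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with a header row of sample ids and gene ids in column 1."""
    path = Path(path)
    with path.open() as fh:
        header = _split_line(fh.readline())
        if len(header) < 2:
            raise FormatError(f"{path.name}: header must name at least one sample")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split_line(line)
            if len(fields) != len(header):
                raise FormatError(
                    f"{path.name} line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            gene = fields[0]
            if gene in set(gene_ids):
                raise FormatError(f"duplicate gene id {gene}")
            gene_ids.append(gene)
            row = [
                _parse_float(tok, f"{path.name} line {lineno}, column {sample_ids[k]}")
                for k, tok in enumerate(fields[1:])
            ]
            rows.append(row)
    if not gene_ids:
        raise FormatError(f"{path.name}: no gene rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# SEG


def _check_non_overlapping(segments: Sequence[Segment]) -> None:
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"overlapping segments for sample {sample} chrom {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def read_seg(path: str | Path) -> list[Segment]:
    """Read a 6-column SEG file (sample, chrom, start, end, num_markers, mean)."""
    path = Path(path)
    segments: list[Segment] = []
    with path.open() as fh:
        header = _split_line(fh.readline())
        if len(header) != 6:
            raise FormatError(f"{path.name}: expected 6 SEG columns, got {len(header)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = _split_line(line)
            if len(f) != 6:
                raise FormatError(
                    f"{path.name} line {lineno}: expected 6 fields, got {len(f)}"
                )
            where = f"{path.name} line {lineno}"
            segments.append(
                Segment(
                    sample_id=f[0],
                    chrom=f[1],
                    start=_parse_int(f[2], where),
                    end=_parse_int(f[3], where),
                    num_markers=_parse_int(f[4], where),
                    mean_log_ratio=_parse_float(f[5], where),
                )
            )
    _check_non_overlapping(segments)
    return sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start))


def write_seg(segments: Sequence[Segment], path: str | Path) -> None:
    _check_non_overlapping(segments)
    ordered = sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start))
    with Path(path).open("w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for s in ordered:
            fh.write(
                f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t"
                f"{s.num_markers}\t{s.mean_log_ratio:.10g}\n"
            )


# ---------------------------------------------------------------------------
# annotation (BED-like: chrom, start, end, gene_id, is_tf)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check column set, unique gene ids and start < end; returns the table."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise FormatError(f"annotation missing columns: {missing}")
    bad = annotation[annotation["start"] >= annotation["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise FormatError(
            f"annotation gene {row['gene_id']}: start {row['start']} >= end {row['end']}"
        )
    dup = _first_duplicate(annotation["gene_id"].tolist())
    if dup is not None:
        raise FormatError(f"duplicate gene id {dup} in annotation")
    if annotation["is_tf"].isna().any():
        raise FormatError("annotation is_tf flag undefined for some genes")
    return annotation


def read_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    with path.open() as fh:
        header = _split_line(fh.readline())
        if header[: len(ANNOTATION_COLUMNS)] != ANNOTATION_COLUMNS:
            raise FormatError(
                f"{path.name}: expected header {ANNOTATION_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = _split_line(line)
            if len(f) < 5:
                raise FormatError(f"{path.name} line {lineno}: expected 5 fields")
            where = f"{path.name} line {lineno}"
            if f[4] not in {"0", "1", "True", "False", "true", "false"}:
                raise FormatError(f"{where}: is_tf must be boolean, got {f[4]!r}")
            rows.append(
                {
                    "chrom": f[0],
                    "start": _parse_int(f[1], where),
                    "end": _parse_int(f[2], where),
                    "gene_id": f[3],
                    "is_tf": f[4] in {"1", "True", "true"},
                }
            )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return validate_annotation(df)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annotation)
    out = annotation[ANNOTATION_COLUMNS].copy()
    out["is_tf"] = out["is_tf"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets: GeneSetCollection = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_line(line)
            if len(f) < 3:
                raise FormatError(
                    f"{path.name} line {lineno}: GMT line needs >= 3 fields"
                )
            name, desc, members = f[0], f[1], [g for g in f[2:] if g]
            if name in sets:
                raise FormatError(f"{path.name} line {lineno}: duplicate set {name}")
            if not members:
                raise FormatError(f"{path.name} line {lineno}: set {name} is empty")
            sets[name] = GeneSet(name, desc, frozenset(members))
    return sets


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(sets):
            gs = sets[name]
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# SIF edge lists


def read_edge_list(path: str | Path) -> list[DirectedEdge]:
    """Read SIF-like rows ``source<TAB>relation<TAB>target``."""
    path = Path(path)
    edges: list[DirectedEdge] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_line(line)
            if len(f) != 3:
                raise FormatError(
                    f"{path.name} line {lineno}: expected 3 SIF fields, got {len(f)}"
                )
            if f[0] == f[2]:
                raise FormatError(f"{path.name} line {lineno}: self-loop on {f[0]}")
            edges.append(DirectedEdge(source=f[0], target=f[2], label=f[1]))
    return edges


def write_edge_list(edges: Sequence[DirectedEdge], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in sorted(edges, key=lambda e: (e.source, e.target)):
            fh.write(f"{e.source}\t{e.label or 'regulates'}\t{e.target}\n")


# ---------------------------------------------------------------------------
# attributed graphs


def write_graph(
    nodes_with_attrs: Mapping[str, Mapping[str, object]],
    edges_with_attrs: Sequence[tuple[str, str, Mapping[str, object]]],
    path: str | Path,
    format: str = "sif",
) -> None:
    """Write an attributed graph as SIF or GraphML (Cytoscape-loadable).

    Every edge endpoint must be a declared node; SIF uses the ``edge_origin``
    or ``label`` attribute as the relation column.
    """
    for u, v, _ in edges_with_attrs:
        for node in (u, v):
            if node not in nodes_with_attrs:
                raise FormatError(f"edge references undeclared node {node}")
    if format == "sif":
        with Path(path).open("w") as fh:
            for u, v, attrs in sorted(edges_with_attrs, key=lambda e: (e[0], e[1])):
                rel = attrs.get("edge_origin") or attrs.get("label") or "interacts"
                fh.write(f"{u}\t{rel}\t{v}\n")
            connected = {n for u, v, _ in edges_with_attrs for n in (u, v)}
            for n in sorted(set(nodes_with_attrs) - connected):
                fh.write(f"{n}\n")
    elif format == "graphml":
        g = nx.MultiDiGraph()
        for n in sorted(nodes_with_attrs):
            g.add_node(n, **{k: _graphml_value(v) for k, v in nodes_with_attrs[n].items()})
        for u, v, attrs in sorted(edges_with_attrs, key=lambda e: (e[0], e[1])):
            g.add_edge(u, v, **{k: _graphml_value(w) for k, w in attrs.items()})
        nx.write_graphml(g, str(path))
    else:
        raise ValueError(f"unknown graph format {format!r}")


def _graphml_value(v: object) -> object:
    if isinstance(v, (str, int, float, bool)):
        return v
    return str(v)
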