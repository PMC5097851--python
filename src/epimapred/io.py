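"""Readers and writers for WIG signal, BED6 annotations, expression TSVs
and the score-matrix interchange TSV.

Coordinate convention: all internal positions are 1-based and inclusive.
BED's 0-based half-open coordinates are converted exactly once, at parse
time: TSS = chromStart+1 for ``+`` genes and chromEnd for ``-`` genes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionVector",
    "GeneAnnotation",
    "ParseError",
    "ScoreMatrix",
    "SignalRecord",
    "read_expression",
    "read_gene_annotation",
    "read_score_matrix",
    "read_wig",
    "write_expression",
    "write_score_matrix",
]


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""


class SignalRecord(NamedTuple):
    """One WIG-derived read-equivalent: ``weight`` reads at ``pos`` (1-based)."""

    chrom: str
    pos: int
    weight: float


class GeneAnnotation(NamedTuple):
    """A gene's TSS locus; strand determines which BED end is the TSS."""

    gene_id: str
    chrom: str
    tss: int
    strand: str


@dataclass
class ExpressionVector:
    """Per-gene expression values Y, ordered by ``gene_ids``."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != len(self.values):
            raise ValueError("gene_ids and values differ in length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in expression vector")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ScoreMatrix:
    """The M x N matrix X of gene-level epigenetic scores.

    When ``has_bias`` the last column is the all-ones bias term appended for
    the regression intercept; transforms and quantile normalisation leave it
    untouched.
    """

    gene_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    has_bias: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.gene_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.feature_names)} features"
            )
        if self.has_bias and not np.all(self.values[:, -1] == 1.0):
            raise ValueError("has_bias set but last column is not all ones")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.feature_names
        )


# --------------------------------------------------------------------------
# WIG


def _wig_directive(line: str, path: str, lineno: int) -> dict:
    fields = line.split()
    out: dict = {"kind": fields[0]}
    for tok in fields[1:]:
        if "=" not in tok:
            raise ParseError(f"{path}:{lineno}: malformed directive token {tok!r}")
        k, v = tok.split("=", 1)
        out[k] = v
    if "chrom" not in out:
        raise ParseError(f"{path}:{lineno}: step directive missing chrom=")
    return out


def read_wig(path: str | Path) -> list[SignalRecord]:
    """Parse a UCSC wiggle file (variableStep / fixedStep dialects).

    A record with value ``v`` (and any span) yields a single
    :class:`SignalRecord` of weight ``v`` at the record's start coordinate:
    values are read as read-equivalent counts, not per-base coverage, so
    integral WIG values keep histone scores exact.  Pre-expand spans
    upstream if per-base semantics are wanted.
    """
    path = Path(path)
    records: list[SignalRecord] = []
    mode: dict | None = None
    fixed_i = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(("track", "browser")):
                continue
            head = line.split()[0]
            if head == "variableStep":
                mode = _wig_directive(line, str(path), lineno)
            elif head == "fixedStep":
                mode = _wig_directive(line, str(path), lineno)
                for req in ("start", "step"):
                    if req not in mode:
                        raise ParseError(f"{path}:{lineno}: fixedStep missing {req}=")
                mode["start"] = int(mode["start"])
                mode["step"] = int(mode["step"])
                fixed_i = 0
            elif mode is None:
                raise ParseError(
                    f"{path}:{lineno}: data line before any step directive"
                )
            elif mode["kind"] == "variableStep":
                fields = line.split()
                if len(fields) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: variableStep data needs 2 columns"
                    )
                try:
                    pos, value = int(fields[0]), float(fields[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if pos < 1:
                    raise ParseError(f"{path}:{lineno}: position {pos} < 1")
                if value < 0:
                    raise ParseError(f"{path}:{lineno}: negative value {value}")
                records.append(SignalRecord(mode["chrom"], pos, value))
            else:  # fixedStep
                try:
                    value = float(line)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if value < 0:
                    raise ParseError(f"{path}:{lineno}: negative value {value}")
                pos = mode["start"] + fixed_i * mode["step"]
                fixed_i += 1
                records.append(SignalRecord(mode["chrom"], pos, value))
    return records


def write_wig(records: Iterable[SignalRecord], path: str | Path) -> None:
    """Write records as per-chromosome variableStep sections (sorted by position)."""
    by_chrom: dict[str, list[SignalRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    with open(path, "w") as fh:
        for chrom in sorted(by_chrom):
            fh.write(f"variableStep chrom={chrom}\n")
            for rec in sorted(by_chrom[chrom], key=lambda r: r.pos):
                w = rec.weight
                fh.write(f"{rec.pos} {int(w) if w == int(w) else w}\n")


# --------------------------------------------------------------------------
# BED6


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED6 file into TSS annotations (1-based, strand-aware)."""
    path = Path(path)
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: BED6 requires 6 columns (strand missing?)"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {name!r}")
            seen.add(name)
            tss = start_i + 1 if strand == "+" else end_i
            out.append(GeneAnnotation(name, chrom, tss, strand))
    return out


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    """Write TSS annotations as single-base BED6 records."""
    with open(path, "w") as fh:
        for g in genes:
            # single-base interval whose strand-aware TSS reproduces g.tss
            start, end = (g.tss - 1, g.tss)
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


# --------------------------------------------------------------------------
# Expression TSV


def read_expression(path: str | Path) -> ExpressionVector:
    """Two-column TSV (gene_id, abundance); optional ``gene_id`` header."""
    path = Path(path)
    ids: list[str] = []
    vals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and fields[0] in ("gene_id", "gene"):
                continue
            try:
                value = float(fields[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric abundance {fields[1]!r}"
                ) from exc
            ids.append(fields[0])
            vals.append(value)
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ParseError(f"{path}: duplicate gene rows {dupes}")
    return ExpressionVector(ids, np.asarray(vals))


def write_expression(expr: ExpressionVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tabundance\n")
        for gid, val in zip(expr.gene_ids, expr.values):
            fh.write(f"{gid}\t{float(val)!r}\n")


# --------------------------------------------------------------------------
# Score matrix TSV


def write_score_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    """TSV with a ``#features:`` metadata line, gene_id row labels, full precision."""
    with open(path, "w") as fh:
        fh.write("#features: " + " ".join(matrix.feature_names) + "\n")
        fh.write(f"#has_bias: {str(matrix.has_bias).lower()}\n")
        fh.write("gene_id\t" + "\t".join(matrix.feature_names) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_score_matrix(path: str | Path) -> ScoreMatrix:
    path = Path(path)
    has_bias = False
    header_lines = 0
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#features:"):
            raise ParseError(f"{path}:1: missing '#features:' header line")
        header_lines += 1
        pos = fh.tell()
        line = fh.readline()
        if line.startswith("#has_bias:"):
            has_bias = line.split(":", 1)[1].strip() == "true"
            header_lines += 1
        else:
            fh.seek(pos)
        body = fh.read()
    if not body.strip() or not body.startswith("gene_id"):
        raise ParseError(f"{path}: missing gene_id column header")
    try:
        df = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged rows: {exc}") from exc
    if df.isna().any().any():
        raise ParseError(f"{path}: ragged or non-numeric rows")
    return ScoreMatrix(
        gene_ids=[str(g) for g in df.index],
        feature_names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        has_bias=has_bias,
    )
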