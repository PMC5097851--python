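"""Gene-level epigenetic scores from TSS-proximal ChIP-seq signal.

For gene ``m`` and epigenetic feature ``n`` the raw score is

    x_{m,n} = sum over reads r with |d(r,m)| <= d*  of  w(r) * phi(r, m)

where ``d(r,m)`` is the bp distance from the read to the TSS of ``m``
(downstream positive, strand-aware), ``d*`` is the window half-width
(default 2000 bp, the typical width of ChIP-seq binding regions) and
``phi`` is 1 for histone modifications (sum-of-tags) or the exponentially
decaying affinity ``exp(-|d|/d0)`` (default d0 = 5000 bp) for
transcription factors.  A read within ``d*`` of several TSSs contributes
to every such gene.  The window predicate is inclusive at both ends.

Scores are computed as a one-round MapReduce program: the mapper takes a
read, looks up qualifying genes in a sorted per-chromosome TSS index
(binary search, O(log M)) and emits ``(gene_id, w * phi)``; the reducer
sums per gene.  Assembled columns are then log- (or arsinh-) transformed
and quantile-normalised for regression.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .engine import EngineConfig, MapReduceProgram, execute_program
from .io import GeneAnnotation, ScoreMatrix, SignalRecord

__all__ = [
    "EpigeneticScorer",
    "ScoreColumn",
    "ScoringConfig",
    "TssIndex",
    "assemble_score_matrix",
    "genes_within",
    "mr_epigenetic_scores",
    "phi",
    "quantile_normalise",
    "transform_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    """Kernel choice and window parameters for score aggregation."""

    d_star: int = 2000
    d0: float = 5000.0
    kind: str = "histone"

    def __post_init__(self) -> None:
        if self.d_star <= 0:
            raise ValueError("d_star must be positive")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.kind not in ("histone", "tf"):
            raise ValueError(f"kind must be 'histone' or 'tf', got {self.kind!r}")


class ScoreColumn(NamedTuple):
    """One column X_*,n of the score matrix, aligned to ``gene_ids``."""

    feature_name: str
    gene_ids: tuple[str, ...]
    values: np.ndarray


def phi(distance: float, config: ScoringConfig) -> float:
    """Read-gene association weight at signed distance ``distance`` (bp).

    Histone mode counts tags (constant 1); tf mode decays as exp(-|d|/d0)
    so affinity falls off symmetrically on both sides of the TSS.
    """
    if config.kind == "histone":
        return 1.0
    return float(np.exp(-abs(distance) / config.d0))


@dataclass
class TssIndex:
    """Sorted per-chromosome arrays of TSS loci supporting O(log M) range queries."""

    gene_ids: list[str]
    _chrom_tss: dict[str, np.ndarray] = field(default_factory=dict)
    _chrom_rows: dict[str, np.ndarray] = field(default_factory=dict)
    _chrom_strands: dict[str, np.ndarray] = field(default_factory=dict)
    _warned: set = field(default_factory=set)

    @classmethod
    def build(cls, annotations: Sequence[GeneAnnotation]) -> "TssIndex":
        gene_ids = [a.gene_id for a in annotations]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene_ids in annotation set")
        index = cls(gene_ids=gene_ids)
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for row, a in enumerate(annotations):
            by_chrom.setdefault(a.chrom, []).append(
                (a.tss, row, 1 if a.strand == "+" else -1)
            )
        for chrom, entries in by_chrom.items():
            entries.sort()
            index._chrom_tss[chrom] = np.array([e[0] for e in entries], dtype=np.int64)
            index._chrom_rows[chrom] = np.array([e[1] for e in entries], dtype=np.int64)
            index._chrom_strands[chrom] = np.array(
                [e[2] for e in entries], dtype=np.int64
            )
        return index

    def __len__(self) -> int:
        return len(self.gene_ids)

    def query(self, chrom: str, pos: int, d_star: int) -> list[tuple[str, int]]:
        """Genes with |pos - tss| <= d_star, with strand-aware signed distances."""
        tss = self._chrom_tss.get(chrom)
        if tss is None:
            if chrom not in self._warned:
                logger.warning("chromosome %s absent from TSS index", chrom)
                self._warned.add(chrom)
            return []
        lo = int(np.searchsorted(tss, pos - d_star, side="left"))
        hi = int(np.searchsorted(tss, pos + d_star, side="right"))
        out = []
        rows, strands = self._chrom_rows[chrom], self._chrom_strands[chrom]
        for i in range(lo, hi):
            d = (pos - int(tss[i])) * int(strands[i])
            out.append((self.gene_ids[int(rows[i])], d))
        return out


def genes_within(
    index: TssIndex, chrom: str, pos: int, d_star: int
) -> list[tuple[str, int]]:
    """Genes whose TSS lies within ``d_star`` bp of ``pos`` (inclusive).

    Distances are signed strand-aware: positive downstream of the TSS.
    Unknown chromosomes return an empty list (logged once per chromosome).
    """
    return index.query(chrom, pos, d_star)


# --------------------------------------------------------------------------
# MapReduce scoring program


def _score_mapper(index: TssIndex, config: ScoringConfig, key, value):
    chrom, pos = key
    weight = value
    return [
        (gene_id, weight * phi(d, config))
        for gene_id, d in index.query(chrom, pos, config.d_star)
    ]


def _sum_reducer(key, values):
    return [(key, sum(values))]


def mr_epigenetic_scores(
    signal: Iterable[SignalRecord],
    index: TssIndex,
    config: ScoringConfig,
    engine: EngineConfig | None = None,
    feature_name: str = "feature",
) -> ScoreColumn:
    """Compute one score column X_*,n over all genes in ``index``.

    Runs the one-round read->gene MapReduce program; genes with no signal
    in their window receive 0.  Output is identical for any worker count.
    """
    pairs = [((rec.chrom, rec.pos), float(rec.weight)) for rec in signal]
    program = MapReduceProgram(
        rounds=[(functools.partial(_score_mapper, index, config), _sum_reducer)]
    )
    result = execute_program(program, pairs, engine)
    totals = dict(result)
    values = np.array([totals.get(g, 0.0) for g in index.gene_ids], dtype=float)
    return ScoreColumn(feature_name, tuple(index.gene_ids), values)


def assemble_score_matrix(
    columns: Sequence[ScoreColumn],
    add_bias: bool = True,
    gene_ids: Sequence[str] | None = None,
) -> ScoreMatrix:
    """Stack score columns into the M x N design matrix, bias column last.

    All columns must share the same gene ordering; a mismatch raises with
    the symmetric difference of the gene sets.  With no columns at all,
    ``gene_ids`` must be given and the result is the M x 1 bias matrix.
    """
    if not columns:
        if gene_ids is None or not add_bias:
            raise ValueError("with zero columns, gene_ids and add_bias are required")
        ones = np.ones((len(gene_ids), 1))
        return ScoreMatrix(list(gene_ids), ["bias"], ones, has_bias=True)
    gene_ids = columns[0].gene_ids
    for col in columns[1:]:
        if col.gene_ids != gene_ids:
            diff = set(col.gene_ids) ^ set(gene_ids)
            if diff:
                raise ValueError(f"gene sets differ; symmetric difference {sorted(diff)}")
            raise ValueError("columns share genes but in different orders")
    values = np.column_stack([c.values for c in columns])
    names = [c.feature_name for c in columns]
    if add_bias:
        values = np.column_stack([values, np.ones(len(gene_ids))])
        names = names + ["bias"]
    return ScoreMatrix(list(gene_ids), names, values, has_bias=add_bias)


# --------------------------------------------------------------------------
# Transforms


def transform_scores(
    X: ScoreMatrix, method: str = "log", pseudocount: float = 1.0
) -> ScoreMatrix:
    """Log (ln(x + pseudocount)) or arsinh transform of the non-bias columns."""
    values = X.values.copy()
    cols = slice(0, values.shape[1] - 1) if X.has_bias else slice(None)
    block = values[:, cols]
    if method == "log":
        if np.any(block + pseudocount <= 0):
            raise ValueError("log transform of non-positive score + pseudocount")
        values[:, cols] = np.log(block + pseudocount)
    elif method == "arsinh":
        values[:, cols] = np.arcsinh(block)
    else:
        raise ValueError(f"unknown transform {method!r}")
    return ScoreMatrix(X.gene_ids, X.feature_names, values, X.has_bias)


def _qn_values(block: np.ndarray) -> np.ndarray:
    """Quantile-normalise columns to the mean order-statistic reference.

    Ties within a column receive the mean of their tied reference values,
    preserving within-column rank order.
    """
    m, _ = block.shape
    reference = np.sort(block, axis=0).mean(axis=1)
    out = np.empty_like(block)
    for j in range(block.shape[1]):
        order = np.argsort(block[:, j], kind="stable")
        sorted_vals = block[order, j]
        assigned = np.empty(m)
        i = 0
        while i < m:
            k = i
            while k + 1 < m and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            assigned[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = assigned
    return out


def quantile_normalise(X: ScoreMatrix) -> ScoreMatrix:
    """Force every non-bias column onto the common mean-order-statistic scale."""
    n_data = X.values.shape[1] - (1 if X.has_bias else 0)
    if n_data < 2:
        logger.warning("quantile_normalise: single data column, returned unchanged")
        return ScoreMatrix(X.gene_ids, X.feature_names, X.values.copy(), X.has_bias)
    values = X.values.copy()
    values[:, :n_data] = _qn_values(values[:, :n_data])
    return ScoreMatrix(X.gene_ids, X.feature_names, values, X.has_bias)


# --------------------------------------------------------------------------
# Estimator facade


class EpigeneticScorer(BaseEstimator, TransformerMixin):
    """Transformer from ChIP-seq signal records to per-gene score columns.

    ``fit`` takes the gene annotation (a sequence of
    :class:`~epimapred.io.GeneAnnotation`) and builds the TSS index;
    ``transform`` takes signal records and returns the (M, 1) raw score
    column in the fitted gene order.

    Parameters
    ----------
    kind : {'histone', 'tf'}
        Association kernel: tag counting or exponential decay.
    d_star : int
        Window half-width in bp.
    d0 : float
        Decay constant in bp (tf kernel only).
    workers, backend :
        MapReduce engine configuration.
    """

    def __init__(
        self,
        kind: str = "histone",
        d_star: int = 2000,
        d0: float = 5000.0,
        workers: int = 1,
        backend: str = "serial",
    ):
        self.kind = kind
        self.d_star = d_star
        self.d0 = d0
        self.workers = workers
        self.backend = backend

    def fit(self, X: Sequence[GeneAnnotation], y=None) -> "EpigeneticScorer":
        annotations = list(X)
        if not annotations:
            raise ValueError("empty annotation set")
        self.scoring_config_ = ScoringConfig(d_star=self.d_star, d0=self.d0, kind=self.kind)
        self.tss_index_ = TssIndex.build(annotations)
        self.gene_ids_ = list(self.tss_index_.gene_ids)
        return self

    def transform(self, X: Iterable[SignalRecord]) -> np.ndarray:
        if not hasattr(self, "tss_index_"):
            raise ValueError("EpigeneticScorer is not fitted; call fit first")
        col = mr_epigenetic_scores(
            X,
            self.tss_index_,
            self.scoring_config_,
            EngineConfig(self.workers, self.backend),
        )
        return col.values.reshape(-1, 1)

    def score_column(self, signal: Iterable[SignalRecord], name: str) -> ScoreColumn:
        """Named ScoreColumn variant of :meth:`transform`."""
        return ScoreColumn(name, tuple(self.gene_ids_), self.transform(signal)[:, 0])
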