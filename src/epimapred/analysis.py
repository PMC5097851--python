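"""Cross-cell-line evaluation, residual clustering and coefficient summaries.

The directed cross-evaluation trains a regularised expression model on one
cell-line (lambda tuned by 1-SE cross-validation within the training
cell-line only) and tests it on every cell-line, recording adjusted R^2
per ordered (train, test) pair — K cell-lines give K^2 directed
combinations, 64 for the canonical eight.

Residuals eps = Y - Yhat from the per-cell-line fits form a genes x
cell-lines matrix; hierarchical clustering of its columns (default
1 - Pearson correlation distance, average linkage) groups cell-lines whose
prediction errors co-vary, i.e. whose expression departs from the
epigenetic model in the same genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .engine import EngineConfig
from .io import ExpressionVector, ScoreMatrix
from .regression import ModelFit, RidgeExpressionModel, adjusted_r2, predict

__all__ = [
    "CellLineDataset",
    "CrossEvalMatrix",
    "ResidualDendrogram",
    "align_datasets",
    "beta_summary",
    "cluster_cell_lines",
    "cross_cell_line_eval",
    "residual_matrix",
]


@dataclass
class CellLineDataset:
    """Matched epigenetic scores and expression for one cell-line."""

    name: str
    scores: ScoreMatrix
    expression: ExpressionVector

    def __post_init__(self) -> None:
        if self.scores.gene_ids != self.expression.gene_ids:
            raise ValueError(
                f"{self.name}: scores and expression gene_ids disagree; "
                "align with align_datasets first"
            )


@dataclass
class CrossEvalMatrix:
    """Adjusted R^2 per directed (train, test) cell-line pair; rows = training."""

    cell_line_names: list[str]
    adj_r2: np.ndarray
    lambdas: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.adj_r2, index=self.cell_line_names, columns=self.cell_line_names
        )

    @property
    def n_combinations(self) -> int:
        return self.adj_r2.size


@dataclass
class ResidualDendrogram:
    """Agglomerative clustering of cell-lines by residual profiles."""

    leaf_names: list[str]
    linkage_matrix: np.ndarray
    metric: str
    linkage: str

    def merge_order(self) -> list[tuple[frozenset, float]]:
        """Clusters in merge order as (leaf-name sets, height)."""
        n = len(self.leaf_names)
        clusters: dict[int, frozenset] = {
            i: frozenset([self.leaf_names[i]]) for i in range(n)
        }
        out = []
        for step, (a, b, height, _size) in enumerate(self.linkage_matrix):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + step] = merged
            out.append((merged, float(height)))
        return out

    def siblings(self, name_a: str, name_b: str) -> bool:
        """True when the two leaves are merged directly with each other."""
        for merged, _h in self.merge_order():
            if merged == frozenset([name_a, name_b]):
                return True
            if name_a in merged or name_b in merged:
                return False
        return False

    def to_newick(self) -> str:
        """Serialise as Newick; branch lengths from merge-height differences."""
        tree = sch.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def align_datasets(datasets: list[CellLineDataset]) -> list[CellLineDataset]:
    """Restrict every dataset to the shared gene universe, sorted by gene_id."""
    common = set(datasets[0].scores.gene_ids)
    for ds in datasets[1:]:
        common &= set(ds.scores.gene_ids)
    if not common:
        raise ValueError("empty gene intersection across datasets")
    universe = sorted(common)
    out = []
    for ds in datasets:
        rows = {g: i for i, g in enumerate(ds.scores.gene_ids)}
        idx = np.array([rows[g] for g in universe])
        expr_rows = {g: i for i, g in enumerate(ds.expression.gene_ids)}
        eidx = np.array([expr_rows[g] for g in universe])
        out.append(
            CellLineDataset(
                ds.name,
                ScoreMatrix(
                    universe,
                    list(ds.scores.feature_names),
                    ds.scores.values[idx],
                    ds.scores.has_bias,
                ),
                ExpressionVector(universe, ds.expression.values[eidx]),
            )
        )
    return out


def fit_cell_lines(
    datasets: list[CellLineDataset],
    lambda_mode="1se",
    seed: int = 0,
    grid=None,
    cv: int = 10,
    engine: EngineConfig | None = None,
) -> dict[str, ModelFit]:
    """Per-cell-line ridge fits; lambda by 1-SE CV unless a float is given."""
    engine = engine or EngineConfig()
    fits = {}
    for ds in datasets:
        model = RidgeExpressionModel(
            lam="auto" if lambda_mode == "1se" else float(lambda_mode),
            grid=grid,
            cv=cv,
            random_state=seed,
            workers=engine.workers,
            backend=engine.backend,
        )
        model.fit(ds.scores, ds.expression)
        fits[ds.name] = model.fit_result_
    return fits


def cross_cell_line_eval(
    datasets: list[CellLineDataset],
    lambda_mode="1se",
    seed: int = 0,
    grid=None,
    cv: int = 10,
    engine: EngineConfig | None = None,
) -> CrossEvalMatrix:
    """Train on every cell-line, test on every cell-line (directed pairs).

    Lambda is tuned within the training cell-line only; the test data never
    informs the model.  Entry (i, j) is the adjusted R^2 of the model
    trained on dataset i evaluated on dataset j; the diagonal is the
    same-cell-line fit.
    """
    if len(datasets) < 2:
        raise ValueError("cross-evaluation needs at least 2 datasets")
    datasets = align_datasets(datasets)
    fits = fit_cell_lines(datasets, lambda_mode, seed, grid, cv, engine)
    names = [ds.name for ds in datasets]
    k = len(datasets)
    values = np.empty((k, k))
    lambdas = {}
    for i, train in enumerate(datasets):
        fit = fits[train.name]
        lambdas[train.name] = fit.lam
        for j, test in enumerate(datasets):
            yhat = predict(fit, test.scores)
            p = test.scores.shape[1] - (1 if test.scores.has_bias else 0)
            values[i, j] = adjusted_r2(test.expression, yhat, p)
    return CrossEvalMatrix(names, values, lambdas)


def residual_matrix(
    datasets: list[CellLineDataset], fits: dict[str, ModelFit]
) -> pd.DataFrame:
    """Genes x cell-lines matrix of residuals eps = Y - X beta_hat."""
    columns = {}
    gene_ids = datasets[0].scores.gene_ids
    for ds in datasets:
        if ds.scores.gene_ids != gene_ids:
            raise ValueError(f"{ds.name}: gene order differs; align datasets first")
        if ds.name not in fits:
            raise ValueError(f"no fit supplied for dataset {ds.name}")
        yhat = predict(fits[ds.name], ds.scores)
        columns[ds.name] = ds.expression.values - yhat
    return pd.DataFrame(columns, index=gene_ids)


def cluster_cell_lines(
    residuals: pd.DataFrame,
    metric: str = "correlation",
    linkage: str = "average",
) -> ResidualDendrogram:
    """Hierarchically cluster cell-lines (columns) by their residual profiles.

    Default distance is 1 - Pearson correlation with average linkage;
    any scipy ``pdist`` metric / ``linkage`` method may be named instead.
    """
    if residuals.shape[1] < 2:
        raise ValueError("clustering needs at least 2 cell-line columns")
    values = residuals.to_numpy(dtype=float).T  # one row per cell-line
    if metric == "correlation":
        stds = values.std(axis=1)
        for name, s in zip(residuals.columns, stds):
            if s == 0:
                raise ValueError(
                    f"column {name!r} is constant; correlation distance undefined"
                )
    dists = pdist(values, metric=metric)
    Z = sch.linkage(dists, method=linkage)
    return ResidualDendrogram(list(residuals.columns), Z, metric, linkage)


def beta_summary(fits: list[ModelFit]) -> pd.DataFrame:
    """Distribution of each fitted coefficient across cell-lines.

    One row per feature with min, lower quartile, median, upper quartile
    and max (linear-interpolated percentiles).
    """
    if not fits:
        raise ValueError("no fits supplied")
    names = fits[0].feature_names
    for f in fits[1:]:
        if f.feature_names != names:
            raise ValueError("fits disagree on feature names")
    betas = np.vstack([f.beta for f in fits])  # fits x features
    q = np.percentile(betas, [0, 25, 50, 75, 100], axis=0)
    return pd.DataFrame(
        q.T,
        index=names,
        columns=["min", "q1", "median", "q3", "max"],
    )
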