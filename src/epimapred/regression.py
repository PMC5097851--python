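"""Expression models Y = X beta + eps via MapReduce-decomposed least squares.

The fit decomposes the normal equations into the two large products
A = MRMultiply(X^T, X) and B = MRMultiply(X^T, Y), both run through the
MapReduce engine, followed by a single-node solve of the small N x N
system (the communication overhead of MapReduce cannot be amortised
across small matrices; a numerically stable solve replaces the explicit
inverse).

L2 regularisation (ridge) is supported both in closed form,
beta = (X^T X + lambda D)^{-1} X^T Y, and through the equivalent data
augmentation: stacking sqrt(lambda) D rows under X and zeros under Y and
fitting OLS.  D is the identity by default (every coefficient penalised,
bias included); ``penalize_bias=False`` zeroes the bias entry.

lambda is selected by the one-standard-error rule over a log-spaced grid:
the largest lambda whose mean 10-fold cross-validated MSE is within one
standard error of the minimum, with folds formed by a seeded permutation
of genes into near-equal blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .engine import EngineConfig, MapReduceProgram, execute_program
from .io import ExpressionVector, ScoreMatrix

__all__ = [
    "ModelFit",
    "RidgeExpressionModel",
    "adjusted_r2",
    "fit_ols",
    "fit_ridge",
    "fit_ridge_augmented",
    "mr_multiply",
    "predict",
    "select_lambda",
]

DEFAULT_GRID = np.logspace(-4, 4, 50)

_COND_LIMIT = 1e12


@dataclass
class ModelFit:
    """A fitted linear model: coefficients, regularisation, fit diagnostics."""

    feature_names: list[str]
    beta: np.ndarray
    lam: float
    yhat: np.ndarray
    residuals: np.ndarray
    adj_r2: float
    cv_table: list[tuple[float, float, float]] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "beta": dict(zip(self.feature_names, map(float, self.beta))),
            "lambda": float(self.lam),
            "adj_r2": float(self.adj_r2),
            "cv_table": [
                {"lambda": float(l), "mean_cv_mse": float(m), "se": float(s)}
                for l, m, s in self.cv_table
            ],
            "seed": self.seed,
        }


# --------------------------------------------------------------------------
# MapReduce matrix multiplication


def _mm_mapper(key, value):
    # ("A", i, j) -> keyed by shared index j; ("B", j, k) likewise
    tag, a, b = key
    if tag == "A":
        return [(b, ("A", a, value))]
    return [(a, ("B", b, value))]


def _mm_join_reducer(key, values):
    # values are canonically sorted, so all ("A", ...) precede ("B", ...)
    a_entries = [(i, v) for tag, i, v in values if tag == "A"]
    b_entries = [(k, v) for tag, k, v in values if tag == "B"]
    return [((i, k), av * bv) for i, av in a_entries for k, bv in b_entries]


def _identity_mapper(key, value):
    return [(key, value)]


def _mm_sum_reducer(key, values):
    return [(key, sum(values))]


def mr_multiply(
    A: np.ndarray, B: np.ndarray, engine: EngineConfig | None = None
) -> np.ndarray:
    """Matrix product C = A x B computed as a two-round MapReduce program.

    Round 1 joins A's rows with B's columns on the shared inner index and
    emits partial products keyed by (i, k); round 2 sums them.  Because
    reducer value lists are canonically sorted, the floating-point
    summation order — and hence the result — is identical for any worker
    count.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.asarray(B, dtype=float)
    b_vector = B.ndim == 1
    B2 = B.reshape(-1, 1) if b_vector else np.atleast_2d(B)
    if A.shape[1] != B2.shape[0]:
        raise ValueError(f"dimension mismatch: {A.shape} x {B2.shape}")
    pairs: list = []
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            pairs.append((("A", i, j), float(A[i, j])))
    for j in range(B2.shape[0]):
        for k in range(B2.shape[1]):
            pairs.append((("B", j, k), float(B2[j, k])))
    program = MapReduceProgram(
        rounds=[(_mm_mapper, _mm_join_reducer), (_identity_mapper, _mm_sum_reducer)]
    )
    result = execute_program(program, pairs, engine)
    C = np.zeros((A.shape[0], B2.shape[1]))
    for (i, k), value in result:
        C[i, k] = value
    return C[:, 0] if b_vector else C


# --------------------------------------------------------------------------
# Fitting


def _design(X) -> tuple[np.ndarray, list[str], bool]:
    if isinstance(X, ScoreMatrix):
        return X.values, list(X.feature_names), X.has_bias
    arr = np.atleast_2d(np.asarray(X, dtype=float))
    return arr, [f"x{j}" for j in range(arr.shape[1])], False


def _response(Y) -> np.ndarray:
    if isinstance(Y, ExpressionVector):
        return Y.values
    return np.asarray(Y, dtype=float).ravel()


def _penalty_diag(n_features: int, has_bias: bool, penalize_bias: bool) -> np.ndarray:
    d = np.ones(n_features)
    if has_bias and not penalize_bias:
        d[-1] = 0.0
    return d


def _solve_penalised(A: np.ndarray, b: np.ndarray, lam: float, d: np.ndarray) -> np.ndarray:
    system = A + lam * np.diag(d)
    cond = np.linalg.cond(system)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"X^T X (+ lambda D) is ill-conditioned (cond ~ {cond:.3g}); "
            "increase the regularisation strength lambda"
        )
    return scipy.linalg.solve(system, b, assume_a="sym")


def adjusted_r2(Y, yhat, n_predictors: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(M-1)/(M-p-1), with R^2 = 1 - SSE/SST."""
    y = _response(Y)
    yh = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yh):
        raise ValueError("Y and yhat differ in length")
    m = len(y)
    if m <= n_predictors + 1:
        raise ValueError(f"need M > n_predictors + 1 (M={m}, p={n_predictors})")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("Y has zero variance; adjusted R^2 undefined")
    r2 = 1.0 - float(np.sum((y - yh) ** 2)) / sst
    return 1.0 - (1.0 - r2) * (m - 1) / (m - n_predictors - 1)


def _finish_fit(
    Xd: np.ndarray,
    names: list[str],
    has_bias: bool,
    y: np.ndarray,
    beta: np.ndarray,
    lam: float,
    cv_table: list,
    seed: int | None,
) -> ModelFit:
    yhat = Xd @ beta
    p = Xd.shape[1] - (1 if has_bias else 0)
    return ModelFit(
        feature_names=names,
        beta=beta,
        lam=lam,
        yhat=yhat,
        residuals=y - yhat,
        adj_r2=adjusted_r2(y, yhat, p),
        cv_table=cv_table,
        seed=seed,
    )


def fit_ridge(
    X,
    Y,
    lam: float,
    penalize_bias: bool = True,
    engine: EngineConfig | None = None,
) -> ModelFit:
    """Closed-form ridge fit beta = (X^T X + lambda D)^{-1} X^T Y.

    The two large products X^T X and X^T Y are computed with
    :func:`mr_multiply`; the N x N solve runs single-node.  ``lam=0``
    reduces exactly to ordinary least squares.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    Xd, names, has_bias = _design(X)
    y = _response(Y)
    if Xd.shape[0] != len(y):
        raise ValueError(f"X has {Xd.shape[0]} rows but Y has {len(y)}")
    if Xd.shape[0] <= Xd.shape[1]:
        raise ValueError("need more genes than predictors (M > N)")
    A = mr_multiply(Xd.T, Xd, engine)
    b = mr_multiply(Xd.T, y, engine)
    d = _penalty_diag(Xd.shape[1], has_bias, penalize_bias)
    beta = _solve_penalised(A, b, lam, d)
    return _finish_fit(Xd, names, has_bias, y, beta, lam, [], None)


def fit_ols(X, Y, engine: EngineConfig | None = None) -> ModelFit:
    """Ordinary least squares via the MapReduce normal-equation route."""
    return fit_ridge(X, Y, 0.0, engine=engine)


def fit_ridge_augmented(
    X,
    Y,
    lam: float,
    penalize_bias: bool = True,
    engine: EngineConfig | None = None,
) -> ModelFit:
    """Ridge via data augmentation: OLS on [X; sqrt(lambda) D] and [Y; 0].

    Numerically equivalent to :func:`fit_ridge`; kept as the independent
    route for verifying the augmentation identity.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    Xd, names, has_bias = _design(X)
    y = _response(Y)
    d = _penalty_diag(Xd.shape[1], has_bias, penalize_bias)
    X_aug = np.vstack([Xd, np.sqrt(lam) * np.diag(d)])
    y_aug = np.concatenate([y, np.zeros(Xd.shape[1])])
    A = mr_multiply(X_aug.T, X_aug, engine)
    b = mr_multiply(X_aug.T, y_aug, engine)
    beta = _solve_penalised(A, b, 0.0, np.zeros(Xd.shape[1]))
    return _finish_fit(Xd, names, has_bias, y, beta, lam, [], None)


def predict(fit: ModelFit, X) -> np.ndarray:
    """Model predictions yhat = X beta for a (new) design matrix."""
    Xd, _, _ = _design(X)
    if Xd.shape[1] != len(fit.beta):
        raise ValueError(
            f"X has {Xd.shape[1]} columns but model has {len(fit.beta)} coefficients"
        )
    return Xd @ fit.beta


# --------------------------------------------------------------------------
# Cross-validated lambda selection (one-standard-error rule)


def _cv_folds(m: int, k: int, seed: int) -> list[np.ndarray]:
    if k > m:
        raise ValueError(f"k_folds={k} exceeds number of genes M={m}")
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(m), k)]


def select_lambda(
    X,
    Y,
    grid=None,
    k_folds: int = 10,
    seed: int = 0,
    penalize_bias: bool = True,
    engine: EngineConfig | None = None,
) -> tuple[float, list[tuple[float, float, float]]]:
    """Pick lambda by the 1-SE rule over ``grid`` (default 50 points, 1e-4..1e4).

    For each fold the training-set Gram products are computed once with
    :func:`mr_multiply` (they do not depend on lambda), then every grid
    value is solved against them.  Returns the largest grid lambda whose
    mean k-fold CV MSE is within one standard error (of the k fold errors
    at the minimising lambda) of the minimum, together with the full CV
    table of (lambda, mean MSE, SE) rows.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(grid < 0):
        raise ValueError("lambda grid must be non-negative")
    grid = np.sort(grid)
    Xd, _, has_bias = _design(X)
    y = _response(Y)
    folds = _cv_folds(len(y), k_folds, seed)
    d = _penalty_diag(Xd.shape[1], has_bias, penalize_bias)

    fold_mse = np.empty((len(grid), k_folds))
    for f, test_idx in enumerate(folds):
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        X_tr, y_tr = Xd[mask], y[mask]
        X_te, y_te = Xd[test_idx], y[test_idx]
        A = mr_multiply(X_tr.T, X_tr, engine)
        b = mr_multiply(X_tr.T, y_tr, engine)
        for g, lam in enumerate(grid):
            beta = _solve_penalised(A, b, float(lam), d)
            fold_mse[g, f] = float(np.mean((y_te - X_te @ beta) ** 2))

    mean_mse = fold_mse.mean(axis=1)
    se = fold_mse.std(axis=1, ddof=1) / np.sqrt(k_folds)
    best = int(np.argmin(mean_mse))
    threshold = mean_mse[best] + se[best]
    eligible = np.nonzero(mean_mse <= threshold)[0]
    selected = float(grid[eligible.max()])
    table = [
        (float(l), float(m), float(s)) for l, m, s in zip(grid, mean_mse, se)
    ]
    return selected, table


# --------------------------------------------------------------------------
# Estimator facade


class RidgeExpressionModel(BaseEstimator, RegressorMixin):
    """L2-regularised linear model of expression from epigenetic scores.

    Parameters
    ----------
    lam : 'auto' or float
        Regularisation strength; 'auto' selects it by the 1-SE rule over
        ``grid`` with ``cv``-fold cross-validation.
    grid : array-like or None
        Candidate lambdas (default 50 log-spaced points in [1e-4, 1e4]).
    cv : int
        Number of CV folds for lambda selection.
    penalize_bias : bool
        Whether the bias column (if present) is penalised; the strict
        identity-penalty default penalises every coefficient.
    random_state : int
        Seed for the CV fold permutation.
    workers, backend :
        MapReduce engine configuration for the large matrix products.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Fitted coefficients (bias coefficient included, if a bias column
        was in the design).
    lambda_ : float
        The lambda actually used.
    cv_table_ : list of (lambda, mean CV MSE, SE)
        Empty when ``lam`` was given explicitly.
    adj_r2_ : float
        Adjusted R^2 of the fit on the training data.
    fit_result_ : ModelFit
        The full fit record (predictions, residuals, provenance).
    """

    def __init__(
        self,
        lam="auto",
        grid=None,
        cv: int = 10,
        penalize_bias: bool = True,
        random_state: int = 0,
        workers: int = 1,
        backend: str = "serial",
    ):
        self.lam = lam
        self.grid = grid
        self.cv = cv
        self.penalize_bias = penalize_bias
        self.random_state = random_state
        self.workers = workers
        self.backend = backend

    def _engine(self) -> EngineConfig:
        return EngineConfig(self.workers, self.backend)

    def fit(self, X, y) -> "RidgeExpressionModel":
        engine = self._engine()
        Xd, names, has_bias = _design(X)
        yv = _response(y)
        if Xd.shape[0] != len(yv):
            raise ValueError(f"X has {Xd.shape[0]} rows but y has {len(yv)}")
        if not np.all(np.isfinite(Xd)) or not np.all(np.isfinite(yv)):
            raise ValueError("X and y must be finite")
        cv_table: list = []
        if self.lam == "auto":
            lam, cv_table = select_lambda(
                X,
                y,
                grid=self.grid,
                k_folds=self.cv,
                seed=self.random_state,
                penalize_bias=self.penalize_bias,
                engine=engine,
            )
        else:
            lam = float(self.lam)
        result = fit_ridge(X, y, lam, penalize_bias=self.penalize_bias, engine=engine)
        result.cv_table = cv_table
        result.seed = self.random_state if self.lam == "auto" else None
        self.fit_result_ = result
        self.coef_ = result.beta
        self.lambda_ = result.lam
        self.cv_table_ = cv_table
        self.adj_r2_ = result.adj_r2
        self.feature_names_ = names
        self.n_features_in_ = Xd.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise ValueError("RidgeExpressionModel is not fitted; call fit first")
        return predict(self.fit_result_, X)
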