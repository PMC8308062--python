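"""L1-penalized linear models, the regularization path, and the split design.

The solver minimizes

    (1/2n) * ||y - X beta - b||^2 + lambda * ||beta||_1

by cyclic coordinate descent with warm starts along a decreasing geometric
lambda grid, on column-standardized features with a centered response. The
single-coordinate update is the soft threshold S(rho, lambda) =
sign(rho) * max(|rho| - lambda, 0). At lambda >= lambda_max = max_j
|x_j' y| / n the solution is exactly zero, which anchors the grid.

Binary case/control responses are fitted by the same penalized least squares
on 0/1 labels (a linear probability model); the regularization strength is
then selected by AUC instead of correlation.

The split design mirrors a biobank analysis: all sibling-pair members are
withheld as the evaluation set; the remaining samples train five predictors,
each with its own randomly drawn validation set used to pick lambda. The
five retained predictors form the ensemble whose spread quantifies training
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import EnsembleError, SelectionError, UsageError

DEFAULT_N_LAMBDA = 100
DEFAULT_LAMBDA_MIN_RATIO = 1e-3
DEFAULT_TOL = 1e-7
DEFAULT_MAX_SWEEPS = 10_000


# ---------------------------------------------------------------------------
# predictor container


@dataclass
class SparseLinearPredictor:
    """A fitted sparse linear predictor on standardized features.

    ``weights`` are on the standardized-feature scale; ``feature_means`` and
    ``feature_sds`` map back to the raw scale. ``intercept`` is the training
    response mean, so score = intercept + z(X) @ weights.
    """

    namespace: str  # "snps" | "biomarkers"
    feature_ids: list[str]
    weights: np.ndarray
    intercept: float
    lam: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    fold: int = -1
    metadata: dict = field(default_factory=dict)

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.weights != 0.0)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def raw_weights(self) -> np.ndarray:
        """Per-unit-of-raw-feature effect sizes."""
        return self.weights / self.feature_sds

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.feature_means) / self.feature_sds
        return self.intercept + Z @ self.weights


# ---------------------------------------------------------------------------
# coordinate descent kernel


@njit(cache=True)
def _cd_solve(X, y, lam, beta, r, tol, max_sweeps):  # pragma: no cover - numba
    """Solve one lambda in place; X column-standardized, r = y - X @ beta."""
    n, p = X.shape
    for sweep in range(max_sweeps):
        # full cyclic sweep
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            acc = 0.0
            for i in range(n):
                acc += X[i, j] * r[i]
            rho = bj + acc / n
            if rho > lam:
                bn = rho - lam
            elif rho < -lam:
                bn = rho + lam
            else:
                bn = 0.0
            d = bn - bj
            if d != 0.0:
                beta[j] = bn
                for i in range(n):
                    r[i] -= X[i, j] * d
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            return sweep + 1
        # iterate the active set to convergence before the next full sweep
        active = np.flatnonzero(beta)
        for _ in range(max_sweeps):
            max_da = 0.0
            for k in range(active.size):
                j = active[k]
                bj = beta[j]
                acc = 0.0
                for i in range(n):
                    acc += X[i, j] * r[i]
                rho = bj + acc / n
                if rho > lam:
                    bn = rho - lam
                elif rho < -lam:
                    bn = rho + lam
                else:
                    bn = 0.0
                d = bn - bj
                if d != 0.0:
                    beta[j] = bn
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    ad = abs(d)
                    if ad > max_da:
                        max_da = ad
            if max_da < tol:
                break
    return max_sweeps


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize with the population-SD convention.

    Returns (Z, means, sds); zero-variance columns get sd 1 so their z-scores
    are zero and the penalty leaves them out.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    return np.asfortranarray((X - means) / sds), means, sds


def lambda_grid(
    Z: np.ndarray,
    yc: np.ndarray,
    n_lambda: int = DEFAULT_N_LAMBDA,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Geometric grid from lambda_max down to min_ratio * lambda_max."""
    n = len(yc)
    lam_max = float(np.max(np.abs(Z.T @ yc)) / n)
    if lam_max <= 0:
        raise UsageError("response is orthogonal to every feature; no path to compute")
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str] | None = None,
    namespace: str = "snps",
    lambdas: np.ndarray | None = None,
    n_lambda: int = DEFAULT_N_LAMBDA,
    min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    fold: int = -1,
) -> list[SparseLinearPredictor]:
    """Fit the full regularization path with warm starts.

    X is raw-scale; it is standardized internally and the constants stored on
    every returned predictor. The first grid point is lambda_max, whose
    solution is identically zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise UsageError("non-finite values in the design or response")
    if X.shape[0] != len(y):
        raise UsageError("X and y have different numbers of samples")
    Z, means, sds = standardize(X)
    intercept = float(y.mean())
    yc = y - intercept
    if lambdas is None:
        lambdas = lambda_grid(Z, yc, n_lambda=n_lambda, min_ratio=min_ratio)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]

    lam_max = float(np.max(np.abs(Z.T @ yc)) / len(yc))
    beta = np.zeros(X.shape[1])
    r = yc.copy()
    path = []
    for lam in lambdas:
        if lam < lam_max * (1.0 - 1e-12):  # at lam >= lam_max beta = 0 exactly
            _cd_solve(Z, yc, float(lam), beta, r, tol, max_sweeps)
            # the update-size stop rule can understate coefficient error on
            # ill-conditioned designs; verify stationarity and polish if needed
            t = tol
            while kkt_violation(Z, yc, beta, float(lam)) > 1e-8 and t > 1e-15:
                t /= 100.0
                _cd_solve(Z, yc, float(lam), beta, r, t, max_sweeps)
        path.append(
            SparseLinearPredictor(
                namespace=namespace,
                feature_ids=list(feature_ids),
                weights=beta.copy(),
                intercept=intercept,
                lam=float(lam),
                feature_means=means,
                feature_sds=sds,
                fold=fold,
            )
        )
    return path


def kkt_violation(Z: np.ndarray, yc: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Largest stationarity violation of a solution (0 for an exact optimum).

    For active coordinates the residual correlation must equal
    lam * sign(beta_j); for inactive ones its magnitude must not exceed lam.
    """
    n = len(yc)
    g = Z.T @ (yc - Z @ beta) / n
    active = beta != 0.0
    v_active = np.abs(g[active] - lam * np.sign(beta[active])).max(initial=0.0)
    v_inactive = np.maximum(np.abs(g[~active]) - lam, 0.0).max(initial=0.0)
    return float(max(v_active, v_inactive))


# ---------------------------------------------------------------------------
# split design


@dataclass
class FoldSplit:
    """The training / validation / evaluation split design.

    All sibling-pair members form the evaluation set, disjoint from every
    training and validation set. Each of the five folds trains on the
    non-sibling samples minus its own validation draw.
    """

    training: list[list[str]]
    validation: list[list[str]]
    evaluation: list[str]
    cohorts: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.training)

    def validate(self) -> None:
        ev = set(self.evaluation)
        for k, (tr, va) in enumerate(zip(self.training, self.validation)):
            tr, va = set(tr), set(va)
            if tr & va:
                raise UsageError(f"fold {k}: training and validation overlap")
            if (tr | va) & ev:
                raise UsageError(f"fold {k}: evaluation samples leak into training/validation")


def make_splits(
    sample_ids: list[str],
    sibling_pairs: list[tuple[str, str]],
    n_folds: int = 5,
    n_validation: int = 1000,
    seed: int = 0,
) -> FoldSplit:
    """Withhold all siblings for evaluation; build per-fold validation draws.

    Validation sets are disjoint across folds so the five training sets
    differ slightly, giving the ensemble its spread.
    """
    sib = [s for pair in sibling_pairs for s in pair]
    sib_set = set(sib)
    missing = sib_set - set(sample_ids)
    if missing:
        raise UsageError(f"sibling ids not in cohort: {sorted(missing)[:5]}")
    pool = [s for s in sample_ids if s not in sib_set]
    if len(pool) < n_folds * n_validation + 1:
        raise UsageError(
            f"{len(pool)} non-sibling samples cannot supply {n_folds} disjoint "
            f"validation sets of {n_validation}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    training, validation = [], []
    for k in range(n_folds):
        va_idx = perm[k * n_validation : (k + 1) * n_validation]
        va = [pool[i] for i in va_idx]
        va_set = set(va)
        training.append([s for s in pool if s not in va_set])
        validation.append(va)
    split = FoldSplit(training=training, validation=validation, evaluation=sib)
    split.validate()
    return split


# ---------------------------------------------------------------------------
# model selection and ensembles


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def validation_metric(scores: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "correlation":
        return _pearson(scores, y)
    if metric == "auc":
        from .evaluate import auc

        return auc(scores, y)
    raise UsageError(f"unknown metric {metric!r}")


def select_lambda(
    path: list[SparseLinearPredictor],
    X_val: np.ndarray,
    y_val: np.ndarray,
    metric: str = "correlation",
) -> SparseLinearPredictor:
    """Pick the path entry maximizing the validation metric.

    Ties break toward larger lambda (the sparser model); the path is ordered
    by decreasing lambda so the first maximizer wins.
    """
    if not path:
        raise SelectionError("empty regularization path")
    y_val = np.asarray(y_val, dtype=float)
    if np.all(y_val == y_val[0]):
        raise SelectionError("validation response is constant; metric undefined")
    best, best_val = None, -np.inf
    for pred in path:
        val = validation_metric(pred.predict(X_val), y_val, metric)
        if val > best_val:
            best, best_val = pred, val
    best.metadata["validation_metric"] = metric
    best.metadata["validation_value"] = best_val
    return best


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: list[str],
    folds: FoldSplit,
    metric: str = "correlation",
    feature_ids: list[str] | None = None,
    namespace: str = "snps",
    **path_kwargs,
) -> list[SparseLinearPredictor]:
    """One selected predictor per fold (the five-member ensemble)."""
    folds.validate()
    index = {s: i for i, s in enumerate(sample_ids)}
    ensemble = []
    for k in range(folds.n_folds):
        try:
            tr = [index[s] for s in folds.training[k]]
            va = [index[s] for s in folds.validation[k]]
            path = lasso_path(
                X[tr], y[tr], feature_ids=feature_ids, namespace=namespace, fold=k, **path_kwargs
            )
            ensemble.append(select_lambda(path, X[va], y[va], metric=metric))
        except Exception as exc:  # noqa: BLE001 - annotate the failing fold
            raise EnsembleError(f"fold {k} failed: {exc}") from exc
    return ensemble


# ---------------------------------------------------------------------------
# ordinary least squares


@dataclass
class DensePredictor:
    """Unpenalized linear predictor (minimum-norm when rank-deficient)."""

    feature_ids: list[str]
    weights: np.ndarray
    intercept: float
    rank_deficient: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.weights


def ols_fit(X: np.ndarray, y: np.ndarray, feature_ids: list[str] | None = None) -> DensePredictor:
    """Least squares with an intercept; minimum-norm solution if singular."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(X)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    return DensePredictor(
        feature_ids=list(feature_ids),
        weights=coef[1:],
        intercept=float(coef[0]),
        rank_deficient=rank < design.shape[1],
    )
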