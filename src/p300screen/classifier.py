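"""L1-regularized linear discriminant (LASSO-LDA) and accumulated-score voting.

The discriminant regresses class labels y in {-1, +1} on the feature
vectors with squared loss and an L1 penalty,

    beta = argmin sum_i (y_i - b - x_i . w)^2 + lambda * ||w||_1,

solved along the LARS-lasso regularization path; the penalty is chosen by
k-fold cross-validated squared error on a logarithmic grid.  A repetition
is scored marker by marker with s(x) = w.x (the bias is constant across the
markers of a trial and is dropped for voting), and the selected target is
the marker whose scores accumulated over the first l trials are maximal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.interpolate import interp1d
from sklearn.linear_model import LassoLars, lars_path
from sklearn.model_selection import KFold

from p300screen.errors import ConfigurationError
from p300screen.preprocessing import FeatureVector


@dataclass
class LassoLdaModel:
    """Fitted sparse linear discriminant: weights, bias, chosen penalty."""

    w: np.ndarray
    b: float
    lam: float
    cv_folds: int
    lambda_grid: np.ndarray | None = None
    cv_mse: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)

    @property
    def support(self) -> np.ndarray:
        """Indices of the nonzero (selected) features."""
        return np.flatnonzero(self.w)

    @property
    def d(self) -> int:
        return self.w.size


class LinearScorer(Protocol):
    """Pluggable scorer contract: anything with fit and a linear score."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearScorer": ...

    def decision_scores(self, X: np.ndarray) -> np.ndarray: ...


def _validate_training_data(X: np.ndarray, y: np.ndarray, cv_folds: int) -> None:
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ConfigurationError("X must be n x d and y length n")
    if set(np.unique(y)) != {-1, 1}:
        raise ConfigurationError("y must contain both classes, labeled -1 and +1")
    if cv_folds < 2:
        raise ConfigurationError("cv_folds must be >= 2")
    if X.shape[0] < cv_folds:
        raise ConfigurationError("need at least cv_folds training rows")


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 50, min_ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced penalties from the all-zero solution down to near zero.

    The grid top is the smallest penalty with an all-zero solution,
    max |X_c^T y_c| / n on centered data (LARS scaling).
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    lam_max = np.abs(Xc.T @ yc).max() / X.shape[0]
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def _path_coefs_at(alphas_path, coefs_path, grid):
    """Evaluate the piecewise-linear LARS-lasso coefficient path at grid
    penalties; above the path start coefficients are zero, below its end they
    are held at the last knot."""
    if len(alphas_path) < 2:  # degenerate path (e.g. centered y is zero)
        return np.repeat(coefs_path[:, -1:], len(grid), axis=1)
    interp = interp1d(
        alphas_path[::-1],
        coefs_path[:, ::-1],
        axis=1,
        bounds_error=False,
        fill_value=(coefs_path[:, -1], coefs_path[:, 0]),
        assume_sorted=True,
    )
    return interp(grid)  # d x len(grid)


def fit_lasso_lda(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 1e-4,
    max_iter: int = 300,
) -> LassoLdaModel:
    """Fit the L1-penalized label regression, choosing lambda by k-fold CV.

    Folds are contiguous (no shuffling) so fitting is deterministic; no
    class re-balancing is applied.  max_iter caps the number of LARS path
    steps, bounding both compute and the reachable model size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_training_data(X, y, cv_folds)
    grid = (
        np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        if lambda_grid is not None
        else default_lambda_grid(X, y, n_lambdas, lambda_min_ratio)
    )

    cv_sse = np.zeros(grid.size)
    for train_idx, val_idx in KFold(n_splits=cv_folds).split(X):
        Xtr, ytr = X[train_idx], y[train_idx]
        x_mean, y_mean = Xtr.mean(axis=0), ytr.mean()
        alphas, _, coefs = lars_path(
            Xtr - x_mean, ytr - y_mean, method="lasso", max_iter=max_iter
        )
        coefs_grid = _path_coefs_at(alphas, coefs, grid)
        preds = (X[val_idx] - x_mean) @ coefs_grid + y_mean
        cv_sse += ((preds - y[val_idx][:, None]) ** 2).sum(axis=0)
    cv_mse = cv_sse / X.shape[0]
    best = float(grid[int(np.argmin(cv_mse))])  # ties go to the larger penalty

    final = LassoLars(alpha=best, fit_intercept=True, max_iter=max_iter)
    final.fit(X, y)
    return LassoLdaModel(
        w=np.asarray(final.coef_, dtype=float),
        b=float(final.intercept_),
        lam=best,
        cv_folds=cv_folds,
        lambda_grid=grid,
        cv_mse=cv_mse,
    )


def score(
    model: LassoLdaModel,
    x: np.ndarray | FeatureVector,
    include_bias: bool = False,
) -> float:
    """Linear score s(x) = w.x (+ b).  Voting uses include_bias=False: the
    bias is constant across the feature vectors of a trial."""
    values = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    if values.shape != model.w.shape:
        raise ConfigurationError(
            f"feature vector length {values.size} != model dimension {model.d}"
        )
    s = float(model.w @ values)
    return s + model.b if include_bias else s


@dataclass
class ScoreMatrix:
    """Per-repetition scores s(x) indexed by (marker, trial)."""

    scores: np.ndarray  # n_markers x n_trials
    repetition: int = -1
    true_target: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ConfigurationError("scores must be n_markers x n_trials")

    @property
    def n_markers(self) -> int:
        return self.scores.shape[0]

    @property
    def n_trials(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class SelectionResult:
    selected: int
    l_used: int
    accumulated: np.ndarray


def score_repetition(
    model: LassoLdaModel, features: list[FeatureVector]
) -> ScoreMatrix:
    """Score every feature vector of one repetition into a marker x trial grid."""
    if not features:
        raise ConfigurationError("empty repetition")
    reps = {f.repetition for f in features}
    if len(reps) != 1:
        raise ConfigurationError(f"features span repetitions {sorted(reps)}")
    n_trials = max(f.trial for f in features) + 1
    n_markers = max(f.marker_id for f in features) + 1
    scores = np.full((n_markers, n_trials), np.nan)
    true_target = None
    for f in features:
        scores[f.marker_id, f.trial] = score(model, f)
        if f.label == 1:
            true_target = f.marker_id
    if np.isnan(scores).any():
        raise ConfigurationError("repetition is missing (marker, trial) scores")
    return ScoreMatrix(scores, repetition=reps.pop(), true_target=true_target)


def select_target(scores: ScoreMatrix, l: int) -> SelectionResult:
    """Accumulate the first ``l`` trials per marker and take the argmax;
    ties break toward the lowest marker index."""
    if not 1 <= l <= scores.n_trials:
        raise ConfigurationError(
            f"l={l} outside the available 1..{scores.n_trials} trials"
        )
    accumulated = scores.scores[:, :l].sum(axis=1)
    return SelectionResult(
        selected=int(np.argmax(accumulated)),
        l_used=l,
        accumulated=accumulated,
    )
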