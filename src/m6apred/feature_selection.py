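"""Elastic-net feature selection on the fused feature matrix.

The selector fits a continuous-response elastic net on the 0/1 labels,

    min_w  1/(2n) ||y - Xw||^2  +  alpha*beta ||w||_1
                               +  alpha*(1-beta)/2 ||w||_2^2,

by cyclic coordinate descent on internally standardized features, and
keeps the columns with nonzero coefficients.  beta mixes the lasso
(beta=1) and ridge (beta=0) penalties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from m6apred.encoders import FeatureMatrix
from m6apred.sequence_io import FoldAssignment

__all__ = [
    "SelectionModel",
    "AlphaSweepResult",
    "fit_elastic_net",
    "apply_selection",
    "sweep_alpha",
]


@dataclass
class SelectionModel:
    """Fitted elastic net: coefficients, surviving columns, standardization."""

    alpha: float
    beta: float
    coefficients: np.ndarray  # on the standardized scale
    center: np.ndarray  # per-feature mean
    scale: np.ndarray  # per-feature std (1.0 where constant)
    intercept: float
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients != 0.0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "alpha": self.alpha,
                    "beta": self.beta,
                    "coefficients": self.coefficients.tolist(),
                    "center": self.center.tolist(),
                    "scale": self.scale.tolist(),
                    "intercept": self.intercept,
                    "n_iter": self.n_iter,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            alpha=obj["alpha"],
            beta=obj["beta"],
            coefficients=np.array(obj["coefficients"]),
            center=np.array(obj["center"]),
            scale=np.array(obj["scale"]),
            intercept=obj["intercept"],
            n_iter=obj["n_iter"],
        )


def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def fit_elastic_net(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    alpha: float,
    beta: float = 0.5,
    *,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SelectionModel:
    """Fit the elastic net by cyclic coordinate descent.

    Features are standardized internally (mean 0, std 1; constant columns
    are left at scale 1 and receive zero coefficients) and the response is
    centered, so no explicit intercept enters the penalty.  Convergence is
    declared when the largest coefficient change in a full sweep is below
    ``tol``.  The objective value after each sweep is recorded in
    ``objective_trace`` (it is non-increasing).

    Raises on ``alpha < 0``, ``beta`` outside [0, 1], or single-class y.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xv.shape[0] != len(y):
        raise ValueError("X and y sample counts differ")
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class")

    n, d = Xv.shape
    center = Xv.mean(axis=0)
    scale = Xv.std(axis=0)
    constant = scale == 0.0
    scale = np.where(constant, 1.0, scale)
    Xs = (Xv - center) / scale
    y_mean = y.mean()
    yc = y - y_mean

    l1 = alpha * beta
    l2 = alpha * (1.0 - beta)
    col_sq = (Xs**2).sum(axis=0) / n  # 1.0 for non-constant standardized cols

    w = np.zeros(d)
    resid = yc.copy()  # resid = yc - Xs @ w

    def objective() -> float:
        return (
            0.5 / n * float(resid @ resid)
            + l1 * float(np.abs(w).sum())
            + 0.5 * l2 * float(w @ w)
        )

    trace = [objective()]
    n_iter = 0
    for sweep in range(max_iter):
        max_delta = 0.0
        for j in range(d):
            if constant[j]:
                continue
            xj = Xs[:, j]
            rho = (xj @ resid) / n + col_sq[j] * w[j]
            w_new = _soft_threshold(rho, l1) / (col_sq[j] + l2)
            delta = w_new - w[j]
            if delta != 0.0:
                resid -= delta * xj
                w[j] = w_new
                max_delta = max(max_delta, abs(delta))
        trace.append(objective())
        n_iter = sweep + 1
        if max_delta < tol:
            break

    return SelectionModel(
        alpha=alpha,
        beta=beta,
        coefficients=w,
        center=center,
        scale=scale,
        intercept=y_mean,
        objective_trace=trace,
        n_iter=n_iter,
    )


def apply_selection(X: FeatureMatrix, model: SelectionModel) -> FeatureMatrix:
    """Restrict a feature matrix to the columns the model retained."""
    if X.n_features != len(model.coefficients):
        raise ValueError(
            f"matrix has {X.n_features} columns but model was fitted on "
            f"{len(model.coefficients)}"
        )
    selected = model.selected
    if len(selected) == 0:
        raise ValueError(
            "selection model retained no features; refit with a smaller alpha"
        )
    return X.select_columns(selected)


@dataclass
class AlphaSweepResult:
    """Per-alpha CV accuracy / retained dimension, and the chosen alpha.

    The chosen alpha maximizes mean CV accuracy; ties break toward the
    smaller retained dimension, then the smaller alpha.
    """

    grid: list[float]
    cv_accuracy: list[float]
    dimension: list[int]
    chosen_alpha: float
    errors: dict[float, str] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["alpha\tcv_accuracy\tdimension"]
        for a, acc, dim in zip(self.grid, self.cv_accuracy, self.dimension):
            lines.append(f"{a}\t{acc:.6f}\t{dim}")
        Path(path).write_text("\n".join(lines) + "\n")


def sweep_alpha(
    X: FeatureMatrix,
    y: np.ndarray,
    grid: Sequence[float],
    beta: float,
    cv: FoldAssignment,
    evaluate_fold: Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], float],
) -> AlphaSweepResult:
    """Grid-search alpha by nested fold-safe selection + downstream accuracy.

    For each alpha and each CV fold, the elastic net is fitted on the
    training portion only, both portions are restricted to the selected
    columns, and ``evaluate_fold(X_train, y_train, X_test, y_test)`` returns
    the held-out accuracy of the downstream classifier.  An alpha whose fit
    or evaluation fails is recorded in ``errors`` and excluded from the
    choice rather than aborting the sweep.
    """
    if len(grid) == 0:
        raise ValueError("empty alpha grid")
    y = np.asarray(y, dtype=float)
    accuracies: list[float] = []
    dimensions: list[int] = []
    errors: dict[float, str] = {}
    for a in grid:
        try:
            fold_accs = []
            fold_dims = []
            for train_idx, test_idx in cv:
                sel = fit_elastic_net(X.values[train_idx], y[train_idx], a, beta)
                cols = sel.selected
                if len(cols) == 0:
                    raise ValueError("no features retained")
                fold_accs.append(
                    evaluate_fold(
                        X.values[np.ix_(train_idx, cols)],
                        y[train_idx],
                        X.values[np.ix_(test_idx, cols)],
                        y[test_idx],
                    )
                )
                fold_dims.append(len(cols))
            accuracies.append(float(np.mean(fold_accs)))
            dimensions.append(int(round(np.mean(fold_dims))))
        except Exception as exc:  # noqa: BLE001 - per-alpha isolation is the contract
            errors[a] = str(exc)
            accuracies.append(float("nan"))
            dimensions.append(-1)

    valid = [i for i, a in enumerate(grid) if a not in errors]
    if not valid:
        raise ValueError(f"every alpha in the grid failed: {errors}")
    best = min(valid, key=lambda i: (-accuracies[i], dimensions[i], grid[i]))
    return AlphaSweepResult(
        grid=list(grid),
        cv_accuracy=accuracies,
        dimension=dimensions,
        chosen_alpha=float(grid[best]),
        errors=errors,
    )
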