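"""Regression performance statistics for permeability QSAR models.

Two flavours of the coefficient of determination are used side by side in
this package, following common QSAR reporting practice:

* :func:`r_squared` — ``1 − Σ(y−ŷ)²/Σ(y−ȳ)²``.  It compares the model
  against the mean predictor and can be negative for models worse than
  the mean.
* :func:`r_squared_cov` — the squared Pearson correlation
  ``(cov(y,ŷ)/√(var(y)·var(ŷ)))²``, always in [0, 1].  It ignores
  systematic shifts and rescalings of the predictions.

Cross-validated statistics (``context="cv"``) are computed per validation
fold and averaged across all folds and repeats; resubstitution statistics
evaluate the model on its own training data and diagnose overfitting
rather than predictive performance.

The gain-curve *relative Gini score* (:func:`relative_gini`) measures how
well a model *sorts* molecules by the outcome: 1 for a model whose
predictions order the molecules exactly as the outcomes do, near 0 for a
random ordering, negative for an anti-sorted model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "RegressionMetrics",
    "r_squared",
    "r_squared_cov",
    "rmse",
    "mae",
    "pearson",
    "relative_gini",
    "summarize",
]

_CONTEXTS = ("resubstitution", "cv", "holdout")


def _as_pair(observed, predicted, min_len=1):
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.ndim != 1 or p.ndim != 1:
        raise ValueError("observed and predicted must be one-dimensional")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} observed vs {p.shape[0]} predicted")
    if y.shape[0] < min_len:
        raise ValueError(f"need at least {min_len} observations, got {y.shape[0]}")
    return y, p


def r_squared(observed, predicted) -> float:
    """Coefficient of determination against the mean predictor.

    ``R² = 1 − Σ(y−ŷ)² / Σ(y−ȳ)²``.  Unbounded below: a model may score
    arbitrarily negative when its predictions are shifted or scaled badly.
    """
    y, p = _as_pair(observed, predicted, min_len=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are constant; R² undefined")
    return 1.0 - float(np.sum((y - p) ** 2)) / ss_tot


def r_squared_cov(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted, in [0, 1]."""
    r = pearson(observed, predicted)
    return r * r


def rmse(observed, predicted) -> float:
    """Root mean-square error ``√(Σ(y−ŷ)²/N)``."""
    y, p = _as_pair(observed, predicted, min_len=1)
    return float(np.sqrt(np.mean((y - p) ** 2)))


def mae(observed, predicted) -> float:
    """Mean absolute error; less sensitive to outliers than RMSE."""
    y, p = _as_pair(observed, predicted, min_len=1)
    return float(np.mean(np.abs(y - p)))


def pearson(observed, predicted) -> float:
    """Product-moment correlation coefficient in [−1, 1]."""
    y, p = _as_pair(observed, predicted, min_len=2)
    sy = y - y.mean()
    sp = p - p.mean()
    vy = float(np.sum(sy * sy))
    vp = float(np.sum(sp * sp))
    if vy == 0.0 or vp == 0.0:
        raise ValueError("constant vector: Pearson correlation undefined")
    r = float(np.sum(sy * sp)) / np.sqrt(vy * vp)
    return float(np.clip(r, -1.0, 1.0))


def _gain_curve_auc(order: np.ndarray, group_key: np.ndarray, shifted: np.ndarray) -> float:
    """Trapezoidal area under the cumulative-gain curve for a given ordering.

    ``order`` indexes the items from first-picked to last; ``group_key`` is
    the sort key in that order, used to pool tied groups so the curve
    advances by a straight segment per tie group (equivalent to averaging
    over all within-group orderings).
    """
    n = order.shape[0]
    total = float(shifted.sum())
    gains = shifted[order]
    keys = group_key
    # boundaries where the key changes: curve vertices
    change = np.nonzero(np.diff(keys))[0]
    ends = np.concatenate([change, [n - 1]])
    xs = np.concatenate([[0.0], (ends + 1) / n])
    ys = np.concatenate([[0.0], np.cumsum(gains)[ends] / total])
    return float(np.trapezoid(ys, xs))


def relative_gini(observed, predicted) -> float:
    """Gain-curve relative Gini score of a regression model's ordering.

    Items are sorted by prediction, best first; the cumulative share of the
    outcome is accumulated against the cumulative share of items, and the
    area between that curve and the diagonal is divided by the same area
    for the ideal (outcome-sorted) ordering.  Outcomes are translated by
    their minimum before accumulation so the curve is well defined for
    all-negative quantities such as logPe.  Tied predictions are pooled
    into straight segments, so a constant predictor scores exactly 0.
    """
    y, p = _as_pair(observed, predicted, min_len=2)
    shifted = y - y.min()
    if shifted.sum() == 0.0:
        raise ValueError("observed values are constant; relative Gini undefined")
    # model curve: descending predictions
    order_m = np.argsort(-p, kind="stable")
    auc_m = _gain_curve_auc(order_m, p[order_m], shifted)
    # ideal curve: descending outcomes
    order_i = np.argsort(-y, kind="stable")
    auc_i = _gain_curve_auc(order_i, y[order_i], shifted)
    return (auc_m - 0.5) / (auc_i - 0.5)


@dataclass(frozen=True)
class RegressionMetrics:
    """Bundle of the statistics reported for one model on one data context."""

    r2: float
    r2_cov: float
    rmse: float
    mae: float
    pearson: float
    n: int
    context: str

    def __post_init__(self):
        if self.context not in _CONTEXTS:
            raise ValueError(f"context must be one of {_CONTEXTS}, got {self.context!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "RegressionMetrics":
        return cls(**json.loads(s))


def summarize(observed, predicted, context: str) -> RegressionMetrics:
    """Compute all scalar metrics consistently on one (observed, predicted) pair."""
    y, p = _as_pair(observed, predicted, min_len=2)
    return RegressionMetrics(
        r2=r_squared(y, p),
        r2_cov=r_squared_cov(y, p),
        rmse=rmse(y, p),
        mae=mae(y, p),
        pearson=pearson(y, p),
        n=int(y.shape[0]),
        context=context,
    )
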