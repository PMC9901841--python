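"""Repeated cross-validation and random-forest recursive feature elimination.

Descriptor sets computed for small QSAR datasets are heavily redundant
(many pairwise correlations above 0.8), so dimensionality is reduced with
a wrapper method: backwards recursive feature elimination (RFE) driven by
random-forest variable importance, evaluated under an outer resampling of
repeated K-fold cross-validation (default 20-fold × 3 repeats).  Inside
each resample the forest is fit on the analysis part only, descriptors
are ranked, and for each candidate subset size the top-ranked subset is
refit and scored on the held-out fold — the ranking never sees the
validation fold, so subset-size selection incorporates the variation due
to feature selection itself.  The chosen size minimises the
fold-averaged RMSE (ties break to the smaller, more parsimonious size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedKFold

from .chemdata import DescriptorTable
from .metrics import rmse

__all__ = [
    "CVPlan",
    "RFEProfile",
    "make_repeated_folds",
    "iter_fold_indices",
    "rf_importance",
    "rfe_random_forest",
    "default_candidate_sizes",
]


@dataclass(frozen=True)
class CVPlan:
    """Repeated K-fold plan: k folds × repeats, seeded."""

    k: int = 20
    repeats: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


@dataclass
class RFEProfile:
    """Outcome of one RFE run: the CV error profile and the chosen subset."""

    candidate_sizes: list[int]
    rmse_cv_by_size: dict[int, float]
    chosen_size: int
    final_ranking: list[str]
    chosen_descriptors: list[str]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "candidate_sizes": self.candidate_sizes,
                "rmse_cv_by_size": {str(k): v for k, v in self.rmse_cv_by_size.items()},
                "chosen_size": self.chosen_size,
                "final_ranking": self.final_ranking,
                "chosen_descriptors": self.chosen_descriptors,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def write_manifest(self, path) -> None:
        """Plain-text descriptor manifest, one name per line."""
        with open(path, "w") as fh:
            fh.write("\n".join(self.chosen_descriptors) + "\n")


def make_repeated_folds(n: int, plan: CVPlan) -> np.ndarray:
    """Fold label per (repeat, sample); folds within a repeat differ by ≤1 in size."""
    if n < plan.k:
        raise ValueError(f"cannot make {plan.k} folds from {n} samples")
    labels = np.empty((plan.repeats, n), dtype=int)
    rkf = RepeatedKFold(n_splits=plan.k, n_repeats=plan.repeats, random_state=plan.seed)
    for i, (_, val_idx) in enumerate(rkf.split(np.zeros((n, 1)))):
        repeat, fold = divmod(i, plan.k)
        labels[repeat, val_idx] = fold
    return labels


def iter_fold_indices(n: int, plan: CVPlan):
    """Yield (repeat, fold, analysis_idx, validation_idx) over the plan."""
    labels = make_repeated_folds(n, plan)
    idx = np.arange(n)
    for repeat in range(plan.repeats):
        for fold in range(plan.k):
            val = idx[labels[repeat] == fold]
            yield repeat, fold, idx[labels[repeat] != fold], val


def _forest(n_trees: int, seed) -> RandomForestRegressor:
    return RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, DescriptorTable):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


def rf_importance(
    X,
    y,
    seed: int = 0,
    method: str = "impurity",
    n_trees: int = 500,
    n_permutations: int = 10,
) -> pd.Series:
    """Random-forest variable importance for every descriptor.

    ``method="impurity"`` (default) uses the forest's built-in
    mean-decrease-in-impurity scores; ``method="permutation"`` scores the
    mean drop in R² when each descriptor is permuted.
    """
    X_df = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant target: importance undefined")
    forest = _forest(n_trees, seed).fit(X_df.to_numpy(), y)
    if method == "impurity":
        scores = forest.feature_importances_
    elif method == "permutation":
        result = permutation_importance(
            forest, X_df.to_numpy(), y, n_repeats=n_permutations, random_state=seed
        )
        scores = result.importances_mean
    else:
        raise ValueError(f"unknown importance method {method!r}")
    return pd.Series(scores, index=list(X_df.columns)).sort_values(ascending=False)


def default_candidate_sizes(n_descriptors: int) -> list[int]:
    """Geometric-ish grid 1, 2, 4, … up to and including the full size."""
    sizes = []
    s = 1
    while s < n_descriptors:
        sizes.append(s)
        s *= 2
    sizes.append(n_descriptors)
    return sizes


def rfe_random_forest(
    X,
    y,
    candidate_sizes=None,
    plan: CVPlan = CVPlan(),
    importance: str = "impurity",
    n_trees: int = 500,
) -> RFEProfile:
    """Backwards feature elimination with random-forest importance under repeated CV.

    For each resample the forest is fit and descriptors ranked on the
    analysis part only; each candidate subset size is then refit on its
    top-ranked descriptors and scored (RMSE) on the held-out fold.  RMSE
    is averaged over all folds and repeats per size; the minimising size
    wins, ties going to the smaller subset.  The final ranking is refit
    on all data and truncated to the chosen size.
    """
    X_df = _as_frame(X)
    y = np.asarray(y, dtype=float)
    names = list(X_df.columns)
    Xv = X_df.to_numpy(dtype=float)
    n, p = Xv.shape

    if candidate_sizes is None:
        candidate_sizes = default_candidate_sizes(p)
    sizes = sorted({int(s) for s in candidate_sizes})
    if not sizes:
        raise ValueError("empty candidate size list")
    if sizes[0] < 1 or sizes[-1] > p:
        raise ValueError(f"candidate sizes must lie in [1, {p}]")

    fold_rmse = {s: [] for s in sizes}
    for repeat, fold, ana, val in iter_fold_indices(n, plan):
        fold_seed = plan.seed + 1000 * repeat + fold
        ranking = np.argsort(
            -_forest(n_trees, fold_seed).fit(Xv[ana], y[ana]).feature_importances_,
            kind="stable",
        )
        for s in sizes:
            cols = ranking[:s]
            sub = _forest(n_trees, fold_seed).fit(Xv[np.ix_(ana, cols)], y[ana])
            fold_rmse[s].append(rmse(y[val], sub.predict(Xv[np.ix_(val, cols)])))

    rmse_by_size = {s: float(np.mean(v)) for s, v in fold_rmse.items()}
    chosen_size = min(sizes, key=lambda s: (rmse_by_size[s], s))

    final_scores = _forest(n_trees, plan.seed).fit(Xv, y).feature_importances_
    final_order = np.argsort(-final_scores, kind="stable")
    final_ranking = [names[i] for i in final_order]
    return RFEProfile(
        candidate_sizes=sizes,
        rmse_cv_by_size=rmse_by_size,
        chosen_size=chosen_size,
        final_ranking=final_ranking,
        chosen_descriptors=final_ranking[:chosen_size],
    )
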