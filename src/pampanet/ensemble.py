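"""Stacked Rprop+ MLP ensemble with an SD-based applicability domain.

Two base multilayer perceptrons of different architecture (defaults:
20-15-5 and 30-20-10 hidden units) are trained on the full training
table; a small meta network (default 2-1 hidden units) is then trained
in the *second space* whose inputs are the base models' predictions and
whose target is the experimental logPe — Breiman-style stacked
regression.  Because the base models strongly overfit the small training
tables typical of PAMPA datasets, the default meta features are the base
models' resubstitution predictions (matching the historical protocol);
out-of-fold meta features are available as the statistically safer
alternative via ``meta_feature_mode="out_of_fold"``.

Prediction reliability is judged by the spread of the base models: for a
compound *j* with base predictions y_1…y_k,

    SD(j) = √( Σ (y_i − ȳ)² / (k − 1) ),

and the applicability-domain threshold is three times the largest SD
observed on the training molecules.  Predictions with larger SD are
still returned, flagged as outside the domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .chemdata import (
    DescriptorTable,
    ScalingParams,
    apply_minmax_scaler,
    fit_minmax_scaler,
)
from .metrics import RegressionMetrics, mae, pearson, r_squared, r_squared_cov, rmse, summarize
from .pampa import PERMEABILITY_CUTOFF, classify_permeability
from .rprop_mlp import MLPModel, RpropConfig, init_mlp, predict_batch, train_rprop_plus
from .selection import CVPlan, _as_frame, iter_fold_indices

__all__ = [
    "BaseLearnerSpec",
    "StackedEnsembleRegressor",
    "PredictionRecord",
    "cv_evaluate_base",
    "base_prediction_correlation",
    "train_stacked_ensemble",
    "ensemble_sd",
    "compute_ad_threshold",
    "fit_linear_baseline",
    "surrogate_tree",
    "save_model",
    "load_model",
]

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Name, architecture and optimiser settings of one constituent network."""

    name: str
    hidden_sizes: tuple
    rprop: RpropConfig = field(default_factory=RpropConfig)

    def __post_init__(self):
        if len(self.hidden_sizes) == 0:
            raise ValueError("base learners require at least one hidden layer")


def default_base_specs(max_steps: int = 100_000) -> list[BaseLearnerSpec]:
    """The two historical base architectures NN1 (20,15,5) and NN2 (30,20,10)."""
    cfg = RpropConfig(max_steps=max_steps)
    return [
        BaseLearnerSpec("NN1", (20, 15, 5), cfg),
        BaseLearnerSpec("NN2", (30, 20, 10), cfg),
    ]


def default_meta_spec(max_steps: int = 100_000) -> BaseLearnerSpec:
    return BaseLearnerSpec("EnsembleNN", (2, 1), RpropConfig(max_steps=max_steps))


@dataclass(frozen=True)
class PredictionRecord:
    """One molecule's prediction with its reliability assessment."""

    id: str
    predicted_log_pe: float
    sd: float
    inside_domain: bool
    permeability_class: str


# ---------------------------------------------------------------------------
# Eq.-4 spread and the AD threshold


def ensemble_sd(base_predictions) -> float:
    """Sample standard deviation of the base-model predictions for one molecule."""
    preds = np.asarray(base_predictions, dtype=float)
    if preds.size < 2:
        raise ValueError("need at least two base predictions")
    mean = preds.mean()
    return float(np.sqrt(np.sum((preds - mean) ** 2) / (preds.size - 1)))


def compute_ad_threshold(train_sds) -> float:
    """Applicability-domain threshold: three times the maximum training SD."""
    sds = np.asarray(train_sds, dtype=float)
    if sds.size == 0:
        raise ValueError("empty training SD list")
    return 3.0 * float(sds.max())


# ---------------------------------------------------------------------------
# Base-model cross-validation


def _train_spec(spec: BaseLearnerSpec, X, y, seed: int):
    """Train one network for a spec, retrying once with a fresh seed on divergence."""
    if spec.rprop.seed is not None:
        seed = spec.rprop.seed
    sizes = [X.shape[1], *spec.hidden_sizes, 1]
    try:
        return train_rprop_plus(init_mlp(sizes, seed=seed), X, y, spec.rprop)
    except FloatingPointError:
        return train_rprop_plus(init_mlp(sizes, seed=seed + 7919), X, y, spec.rprop)


def cv_evaluate_base(spec: BaseLearnerSpec, X, y, plan: CVPlan, random_state: int = 0):
    """Repeated-CV evaluation of one base architecture.

    The network is refit inside every fold; fold-level statistics are
    averaged across all folds and repeats.  Returns the averaged
    :class:`RegressionMetrics` (context ``"cv"``) and the per-fold RMSE
    vector, kept for model-correlation analysis.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    per_fold = {"r2": [], "r2_cov": [], "rmse": [], "mae": [], "pearson": []}
    for repeat, fold, ana, val in iter_fold_indices(len(y), plan):
        model, _ = _train_spec(spec, X[ana], y[ana], random_state + 100 * repeat + fold)
        pred = predict_batch(model, X[val])
        per_fold["r2"].append(r_squared(y[val], pred))
        per_fold["r2_cov"].append(r_squared_cov(y[val], pred))
        per_fold["rmse"].append(rmse(y[val], pred))
        per_fold["mae"].append(mae(y[val], pred))
        per_fold["pearson"].append(pearson(y[val], pred))
    metrics = RegressionMetrics(
        r2=float(np.mean(per_fold["r2"])),
        r2_cov=float(np.mean(per_fold["r2_cov"])),
        rmse=float(np.mean(per_fold["rmse"])),
        mae=float(np.mean(per_fold["mae"])),
        pearson=float(np.mean(per_fold["pearson"])),
        n=len(y),
        context="cv",
    )
    return metrics, np.asarray(per_fold["rmse"])


def base_prediction_correlation(per_fold_rmse_a, per_fold_rmse_b) -> float:
    """Pearson correlation of two models' fold-level RMSE under a shared CV plan.

    Low correlation means the models err on different resamples and carry
    complementary information worth stacking.
    """
    a = np.asarray(per_fold_rmse_a, dtype=float)
    b = np.asarray(per_fold_rmse_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold-RMSE vectors must come from the same CV plan")
    return pearson(a, b)


# ---------------------------------------------------------------------------
# The stacked estimator


class StackedEnsembleRegressor(RegressorMixin, BaseEstimator):
    """Stacked Rprop+ MLP ensemble with min–max scaling and an SD applicability domain.

    Parameters
    ----------
    base_specs : list of BaseLearnerSpec, optional
        Base architectures; defaults to NN1 (20,15,5) and NN2 (30,20,10).
    meta_spec : BaseLearnerSpec, optional
        Meta network; defaults to 2-1 hidden units.
    meta_feature_mode : {"resubstitution", "out_of_fold"}
        Whether the meta network is trained on the base models'
        resubstitution predictions (default, the historical protocol) or
        on out-of-fold CV predictions.
    cv : CVPlan
        Plan used to build out-of-fold meta features.
    scale : bool
        Fit internal 0–1 min–max scaling of the descriptors (and of the
        target, inverted at prediction time).  Disable if the caller
        scales externally.
    random_state : int
        Base seed for all weight initialisations.

    Attributes
    ----------
    base_models_ : list of MLPModel
    meta_model_ : MLPModel
    scaling_ : ScalingParams or None
    descriptor_manifest_ : list of str or None
    ad_threshold_ : float
        Three times the maximum training-set ensemble SD.
    train_sds_ : ndarray
        Per-training-molecule ensemble SD (logPe units).
    """

    def __init__(
        self,
        base_specs=None,
        meta_spec=None,
        meta_feature_mode="resubstitution",
        cv=CVPlan(k=10, repeats=1, seed=0),
        scale=True,
        random_state=0,
    ):
        self.base_specs = base_specs
        self.meta_spec = meta_spec
        self.meta_feature_mode = meta_feature_mode
        self.cv = cv
        self.scale = scale
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _coerce(self, X):
        """Return (values, descriptor names or None) from table/frame/array."""
        if isinstance(X, DescriptorTable):
            return X.values, X.descriptor_names
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        return np.asarray(X, dtype=float), None

    def _prepare_new(self, X):
        vals, names = self._coerce(X)
        if self.descriptor_manifest_ is not None and names is not None:
            missing = [n for n in self.descriptor_manifest_ if n not in names]
            if missing:
                raise ValueError(f"input lacks descriptors from the model manifest: {missing}")
            frame = X.data if isinstance(X, DescriptorTable) else X
            vals = frame[self.descriptor_manifest_].to_numpy(dtype=float)
        elif vals.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} descriptors, got {vals.shape[1]}"
            )
        if self.scaling_ is not None:
            span = self.scaling_.maxs - self.scaling_.mins
            span = np.where(span == 0, 1.0, span)
            vals = (vals - self.scaling_.mins) / span
            vals[:, self.scaling_.constant] = 0.0
        return vals

    def _from_unit(self, y01):
        return y01 * (self.y_max_ - self.y_min_) + self.y_min_

    def _base_predict_raw(self, Xs) -> np.ndarray:
        """Base-model predictions in logPe units, shape (n, k)."""
        cols = [self._from_unit(predict_batch(m, Xs)) for m in self.base_models_]
        return np.column_stack(cols)

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y):
        if self.meta_feature_mode not in ("resubstitution", "out_of_fold"):
            raise ValueError(f"unknown meta_feature_mode {self.meta_feature_mode!r}")
        specs = self.base_specs if self.base_specs is not None else default_base_specs()
        if len(specs) < 2:
            raise ValueError("stacking requires at least two base learners")
        meta_spec = self.meta_spec if self.meta_spec is not None else default_meta_spec()

        vals, names = self._coerce(X)
        y = np.asarray(y, dtype=float)
        if vals.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.descriptor_manifest_ = names
        self.n_features_in_ = vals.shape[1]

        if self.scale:
            table = DescriptorTable(
                pd.DataFrame(vals, columns=names or range(vals.shape[1])).rename(
                    columns=str
                ),
                backend="in-memory",
            )
            self.scaling_ = fit_minmax_scaler(table)
            Xs = apply_minmax_scaler(table, self.scaling_).values
        else:
            self.scaling_ = None
            Xs = vals

        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        if self.y_min_ == self.y_max_:
            raise ValueError("constant target")
        y01 = (y - self.y_min_) / (self.y_max_ - self.y_min_)

        self.base_models_ = []
        self.base_traces_ = []
        for i, spec in enumerate(specs):
            model, trace = _train_spec(spec, Xs, y01, self.random_state + 17 * i)
            self.base_models_.append(model)
            self.base_traces_.append(trace)

        if self.meta_feature_mode == "resubstitution":
            meta01 = np.column_stack([predict_batch(m, Xs) for m in self.base_models_])
        else:
            meta01 = np.empty((len(y), len(specs)))
            for repeat, fold, ana, val in iter_fold_indices(len(y), self.cv):
                for i, spec in enumerate(specs):
                    m, _ = _train_spec(
                        spec, Xs[ana], y01[ana],
                        self.random_state + 17 * i + 100 * repeat + fold,
                    )
                    meta01[val, i] = predict_batch(m, Xs[val])

        self.meta_model_, self.meta_trace_ = _train_spec(
            meta_spec, meta01, y01, self.random_state + 5003
        )

        base_logpe = self._base_predict_raw(Xs)
        self.train_sds_ = np.array([ensemble_sd(row) for row in base_logpe])
        self.ad_threshold_ = compute_ad_threshold(self.train_sds_)
        self._Xs_train_ = Xs
        return self

    def predict(self, X):
        check_is_fitted(self, "meta_model_")
        Xs = self._prepare_new(X)
        meta_in = np.column_stack([predict_batch(m, Xs) for m in self.base_models_])
        return self._from_unit(predict_batch(self.meta_model_, meta_in))

    def predict_with_ad(
        self, X, ids=None, cutoff: float = PERMEABILITY_CUTOFF
    ) -> list[PredictionRecord]:
        """Per-molecule prediction, ensemble SD, domain flag and −6.2 class.

        Molecules outside the applicability domain are still predicted,
        only flagged as unreliable.
        """
        check_is_fitted(self, "meta_model_")
        Xs = self._prepare_new(X)
        if ids is None:
            if isinstance(X, DescriptorTable):
                ids = X.molecule_ids
            elif isinstance(X, pd.DataFrame):
                ids = [str(i) for i in X.index]
            else:
                ids = [f"mol_{i}" for i in range(Xs.shape[0])]
        base_logpe = self._base_predict_raw(Xs)
        meta_in = (base_logpe - self.y_min_) / (self.y_max_ - self.y_min_)
        preds = self._from_unit(predict_batch(self.meta_model_, meta_in))
        records = []
        for mol_id, pred, row in zip(ids, preds, base_logpe):
            sd = ensemble_sd(row)
            records.append(
                PredictionRecord(
                    id=str(mol_id),
                    predicted_log_pe=float(pred),
                    sd=sd,
                    inside_domain=bool(sd <= self.ad_threshold_),
                    permeability_class=classify_permeability(float(pred), cutoff),
                )
            )
        return records

    # -- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "meta_model_")
        return {
            "schema_version": _SCHEMA_VERSION,
            "meta_feature_mode": self.meta_feature_mode,
            "base_models": [m.to_dict() for m in self.base_models_],
            "meta_model": self.meta_model_.to_dict(),
            "descriptor_manifest": self.descriptor_manifest_,
            "scaling": None
            if self.scaling_ is None
            else {
                "names": self.scaling_.names,
                "mins": self.scaling_.mins.tolist(),
                "maxs": self.scaling_.maxs.tolist(),
                "fitted_on": self.scaling_.fitted_on,
            },
            "y_min": self.y_min_,
            "y_max": self.y_max_,
            "ad_threshold": self.ad_threshold_,
            "train_sds": self.train_sds_.tolist(),
            "n_features_in": self.n_features_in_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StackedEnsembleRegressor":
        if d.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {d.get('schema_version')!r}"
            )
        est = cls(meta_feature_mode=d["meta_feature_mode"])
        est.base_models_ = [MLPModel.from_dict(m) for m in d["base_models"]]
        est.meta_model_ = MLPModel.from_dict(d["meta_model"])
        est.descriptor_manifest_ = d["descriptor_manifest"]
        est.scaling_ = (
            None
            if d["scaling"] is None
            else ScalingParams(
                names=d["scaling"]["names"],
                mins=np.asarray(d["scaling"]["mins"]),
                maxs=np.asarray(d["scaling"]["maxs"]),
                fitted_on=d["scaling"]["fitted_on"],
            )
        )
        est.scale = est.scaling_ is not None
        est.y_min_ = d["y_min"]
        est.y_max_ = d["y_max"]
        est.ad_threshold_ = d["ad_threshold"]
        est.train_sds_ = np.asarray(d["train_sds"])
        est.n_features_in_ = d["n_features_in"]
        return est


def save_model(ensemble: StackedEnsembleRegressor, path) -> None:
    """Persist the full deployable model as a single versioned JSON document."""
    with open(path, "w") as fh:
        json.dump(ensemble.to_dict(), fh)


def load_model(path) -> StackedEnsembleRegressor:
    """Load a model saved by :func:`save_model`; bit-exact weight round-trip."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt or truncated model file {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ValueError(f"corrupt model file {path}: not a JSON object")
    return StackedEnsembleRegressor.from_dict(payload)


def train_stacked_ensemble(
    specs, meta_spec, X, y, plan: CVPlan | None = None,
    mode: str = "resubstitution", random_state: int = 0,
) -> StackedEnsembleRegressor:
    """Functional wrapper over :class:`StackedEnsembleRegressor`."""
    est = StackedEnsembleRegressor(
        base_specs=list(specs),
        meta_spec=meta_spec,
        meta_feature_mode=mode,
        cv=plan or CVPlan(k=10, repeats=1, seed=random_state),
        random_state=random_state,
    )
    return est.fit(X, y)


# ---------------------------------------------------------------------------
# Baselines and interpretation


def fit_linear_baseline(X_subset, y, plan: CVPlan, X_holdout=None, y_holdout=None):
    """Ordinary least squares on a small descriptor subset, CV-evaluated.

    Returns ``(model, metrics)`` where ``metrics`` maps context →
    :class:`RegressionMetrics` for ``"cv"``, ``"resubstitution"`` and —
    when a holdout pair is supplied — ``"holdout"``.
    """
    X_df = _as_frame(X_subset)
    Xv = X_df.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if p < 2:
        raise ValueError("need at least two descriptors")
    if n <= p:
        raise ValueError("need more molecules than descriptors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xv])) < p + 1:
        raise ValueError("rank-deficient design matrix")

    per_fold = {"r2": [], "r2_cov": [], "rmse": [], "mae": [], "pearson": []}
    for repeat, fold, ana, val in iter_fold_indices(n, plan):
        lm = LinearRegression().fit(Xv[ana], y[ana])
        pred = lm.predict(Xv[val])
        per_fold["r2"].append(r_squared(y[val], pred))
        per_fold["r2_cov"].append(r_squared_cov(y[val], pred))
        per_fold["rmse"].append(rmse(y[val], pred))
        per_fold["mae"].append(mae(y[val], pred))
        per_fold["pearson"].append(pearson(y[val], pred))
    cv_metrics = RegressionMetrics(
        r2=float(np.mean(per_fold["r2"])),
        r2_cov=float(np.mean(per_fold["r2_cov"])),
        rmse=float(np.mean(per_fold["rmse"])),
        mae=float(np.mean(per_fold["mae"])),
        pearson=float(np.mean(per_fold["pearson"])),
        n=n,
        context="cv",
    )
    model = LinearRegression().fit(Xv, y)
    metrics = {
        "cv": cv_metrics,
        "resubstitution": summarize(y, model.predict(Xv), "resubstitution"),
    }
    if X_holdout is not None and y_holdout is not None:
        Xh = X_holdout.data.to_numpy(dtype=float) if isinstance(X_holdout, DescriptorTable) else np.asarray(X_holdout, dtype=float)
        metrics["holdout"] = summarize(
            np.asarray(y_holdout, dtype=float), model.predict(Xh), "holdout"
        )
    return model, metrics


def surrogate_tree(
    X,
    y,
    max_depth: int = 4,
    min_samples_leaf: int = 5,
    cutoff: float = PERMEABILITY_CUTOFF,
    random_state: int = 0,
):
    """Single CART regression tree for interpretation, on scaled-and-centred descriptors.

    Returns ``(tree, scaler, leaf_report)``.  The leaf report lists, per
    leaf, the mean logPe, member count and percentage, and the
    higher/lower permeability class of the leaf mean relative to the
    cutoff.
    """
    X_df = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant target")
    scaler = StandardScaler().fit(X_df.to_numpy(dtype=float))
    Xs = scaler.transform(X_df.to_numpy(dtype=float))
    tree = DecisionTreeRegressor(
        max_depth=max_depth, min_samples_leaf=min_samples_leaf, random_state=random_state
    ).fit(Xs, y)
    leaves = tree.apply(Xs)
    rows = []
    for leaf in np.unique(leaves):
        members = leaves == leaf
        mean_lp = float(y[members].mean())
        rows.append(
            {
                "leaf": int(leaf),
                "mean_log_pe": mean_lp,
                "n": int(members.sum()),
                "pct": 100.0 * members.sum() / len(y),
                "permeability_class": classify_permeability(mean_lp, cutoff),
            }
        )
    report = pd.DataFrame(rows).sort_values("mean_log_pe").reset_index(drop=True)
    report.attrs["feature_names"] = list(X_df.columns)
    report.attrs["root_feature"] = (
        list(X_df.columns)[tree.tree_.feature[0]] if tree.tree_.feature[0] >= 0 else None
    )
    return tree, scaler, report
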