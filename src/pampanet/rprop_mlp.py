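"""Feedforward MLP regression trained with resilient backpropagation (Rprop+).

The network computes

    o(x) = w0 + Σ_j w_j · f(w_0j + w_jᵀ x)

with logistic hidden units ``f(z) = 1/(1+e^(−z))`` (stacked for several
hidden layers) and an identity output unit, and is trained full-batch to
minimise the sum-of-squares error

    E = ½ Σ_l Σ_h (o_lh − y_lh)².

Rprop+ is a first-order method that uses only the *sign* of each partial
derivative ∂E/∂w: every weight carries its own step size Δ, grown by
``eta_plus`` while the gradient sign is stable and shrunk by
``eta_minus`` on a sign change, in which case the previous update is
reverted (weight backtracking) and the stored gradient zeroed so the
next step is taken fresh.  No global learning rate is required.  Step
sizes are clamped to [delta_min, delta_max]; training stops when the
largest absolute partial derivative falls below ``threshold`` or after
``max_steps`` iterations.  Defaults are the canonical Riedmiller–Braun
constants: eta_plus 1.2, eta_minus 0.5, delta_init 0.1, delta_min 1e−6,
delta_max 50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "MLPModel",
    "RpropConfig",
    "TrainTrace",
    "init_mlp",
    "forward",
    "batch_error",
    "gradient",
    "train_rprop_plus",
    "RpropMLPRegressor",
]


@dataclass
class RpropConfig:
    """Hyperparameters of the Rprop+ optimiser."""

    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_init: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0
    threshold: float = 0.01
    max_steps: int = 100_000
    seed: int | None = None  # pins weight init; None lets the trainer derive it

    def __post_init__(self):
        if not (0 < self.eta_minus < 1 < self.eta_plus):
            raise ValueError("need eta_minus in (0,1) and eta_plus > 1")
        if not (0 < self.delta_min <= self.delta_init <= self.delta_max):
            raise ValueError("need 0 < delta_min <= delta_init <= delta_max")
        if self.threshold <= 0:
            raise ValueError("stopping threshold must be positive")


@dataclass
class TrainTrace:
    """Outcome of one training run."""

    final_error: float
    reached_threshold: float
    steps: int
    converged: bool


@dataclass
class MLPModel:
    """Weights and shape of one network.

    ``weights[k]`` has shape (n_out_k, n_in_k); ``intercepts[k]`` has
    shape (n_out_k,).  Hidden activations are logistic; the single output
    neuron is linear.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    intercepts: list[np.ndarray]
    hidden_activation: str = "logistic"
    output_activation: str = "identity"
    seed: int | None = None

    def __post_init__(self):
        sizes = self.layer_sizes
        if len(sizes) < 2 or sizes[0] < 1 or sizes[-1] != 1 or any(s < 1 for s in sizes):
            raise ValueError(f"invalid layer sizes {sizes}: need >=1 input, hidden >=1, 1 output")
        for k, (w, b) in enumerate(zip(self.weights, self.intercepts)):
            if w.shape != (sizes[k + 1], sizes[k]) or b.shape != (sizes[k + 1],):
                raise ValueError(f"layer {k} weight shapes inconsistent with {sizes}")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError(f"non-finite weights in layer {k}")

    def copy(self) -> "MLPModel":
        return MLPModel(
            list(self.layer_sizes),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.intercepts],
            self.hidden_activation,
            self.output_activation,
            self.seed,
        )

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "intercepts": [b.tolist() for b in self.intercepts],
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            layer_sizes=list(d["layer_sizes"]),
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            intercepts=[np.asarray(b, dtype=float) for b in d["intercepts"]],
            hidden_activation=d.get("hidden_activation", "logistic"),
            output_activation=d.get("output_activation", "identity"),
            seed=d.get("seed"),
        )


def init_mlp(layer_sizes, seed: int = 0) -> MLPModel:
    """Standard-normal weight initialisation, deterministic per seed.

    ``layer_sizes`` runs input → hidden … → output; the output layer must
    have exactly one neuron.  ``(n, 1)`` with no hidden layer gives a
    single linear neuron.
    """
    sizes = [int(s) for s in layer_sizes]
    rng = np.random.default_rng(seed)
    weights = [rng.standard_normal((sizes[k + 1], sizes[k])) for k in range(len(sizes) - 1)]
    intercepts = [rng.standard_normal(sizes[k + 1]) for k in range(len(sizes) - 1)]
    return MLPModel(sizes, weights, intercepts, seed=seed)


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_pass(model: MLPModel, X: np.ndarray):
    """Return per-layer activations; activations[0] is the input batch."""
    acts = [X]
    a = X
    n_layers = len(model.weights)
    for k, (w, b) in enumerate(zip(model.weights, model.intercepts)):
        z = a @ w.T + b
        a = z if k == n_layers - 1 else _logistic(z)
        acts.append(a)
    return acts


def forward(model: MLPModel, x) -> float:
    """Evaluate o(x) for a single input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.layer_sizes[0],):
        raise ValueError(f"expected input of length {model.layer_sizes[0]}, got {x.shape}")
    return float(_forward_pass(model, x[None, :])[-1][0, 0])


def predict_batch(model: MLPModel, X) -> np.ndarray:
    """Evaluate o(x) for a batch of rows."""
    X = np.asarray(X, dtype=float)
    return _forward_pass(model, X)[-1][:, 0]


def batch_error(model: MLPModel, X, Y) -> float:
    """Sum-of-squares error E = ½ Σ (o − y)² over the batch."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X rows must match Y length")
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    resid = predict_batch(model, X) - Y
    return 0.5 * float(resid @ resid)


def gradient(model: MLPModel, X, Y):
    """Analytic ∂E/∂w by backpropagation.

    Returns ``(weight_grads, intercept_grads)`` shaped like the model's
    weights and intercepts.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    acts = _forward_pass(model, X)
    # output layer is linear: delta = (o - y)
    delta = acts[-1] - Y[:, None]
    w_grads = [None] * len(model.weights)
    b_grads = [None] * len(model.weights)
    for k in range(len(model.weights) - 1, -1, -1):
        w_grads[k] = delta.T @ acts[k]
        b_grads[k] = delta.sum(axis=0)
        if k > 0:
            a = acts[k]  # logistic activations of layer k
            delta = (delta @ model.weights[k]) * a * (1.0 - a)
    return w_grads, b_grads


def train_rprop_plus(model: MLPModel, X, Y, config: RpropConfig | None = None):
    """Train in place-copy with Rprop+ (weight backtracking); returns (model, trace).

    Per weight: on a stable gradient sign the step Δ grows by eta_plus
    and the weight moves by −sign(g)·Δ; on a sign flip Δ shrinks by
    eta_minus, the previous update is reverted and the stored gradient is
    zeroed; with a zero stored gradient the weight simply moves by
    −sign(g)·Δ.  Stops when max|∂E/∂w| < threshold.
    """
    cfg = config or RpropConfig()
    model = model.copy()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("training data must be finite")

    params = model.weights + model.intercepts  # views; updated in place
    deltas = [np.full_like(p, cfg.delta_init) for p in params]
    prev_grad = [np.zeros_like(p) for p in params]
    prev_step = [np.zeros_like(p) for p in params]

    max_abs_grad = np.inf
    steps = 0
    for steps in range(1, cfg.max_steps + 1):
        w_g, b_g = gradient(model, X, Y)
        grads = w_g + b_g
        max_abs_grad = max(float(np.max(np.abs(g))) if g.size else 0.0 for g in grads)
        if not np.isfinite(max_abs_grad):
            raise FloatingPointError(f"non-finite gradient at step {steps}")
        if max_abs_grad < cfg.threshold:
            steps -= 1  # no update taken this iteration
            break
        for p, d, g, pg, ps in zip(params, deltas, grads, prev_grad, prev_step):
            sign_prod = pg * g
            grown = sign_prod > 0
            flipped = sign_prod < 0
            d[grown] = np.minimum(d[grown] * cfg.eta_plus, cfg.delta_max)
            d[flipped] = np.maximum(d[flipped] * cfg.eta_minus, cfg.delta_min)
            # on a sign flip the previous change is reverted (backtracking)
            change = np.where(flipped, -ps, -np.sign(g) * d)
            p += change
            ps[...] = change
            pg[...] = np.where(flipped, 0.0, g)
    else:
        steps = cfg.max_steps

    if cfg.max_steps == 0:
        steps = 0
        max_abs_grad = float(
            max(np.max(np.abs(g)) for g in sum(gradient(model, X, Y), []))
        )

    err = batch_error(model, X, Y)
    if not np.isfinite(err):
        raise FloatingPointError(f"non-finite error after step {steps}")
    trace = TrainTrace(
        final_error=err,
        reached_threshold=max_abs_grad,
        steps=steps,
        converged=bool(max_abs_grad < cfg.threshold),
    )
    return model, trace


class RpropMLPRegressor(RegressorMixin, BaseEstimator):
    """scikit-learn estimator interface to the Rprop+ MLP.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Sizes of the logistic hidden layers; ``()`` gives a single linear
        neuron.
    eta_plus, eta_minus, delta_init, delta_min, delta_max : float
        Rprop+ step-size schedule (Riedmiller–Braun defaults).
    threshold : float
        Stopping criterion on the largest absolute partial derivative.
    max_steps : int
        Iteration cap.
    random_state : int
        Seed for the standard-normal weight initialisation.

    Attributes
    ----------
    model_ : MLPModel
        Trained network.
    trace_ : TrainTrace
        Final error (½-sum-of-squares convention), the gradient bound
        reached, the number of steps and the convergence flag.
    """

    def __init__(
        self,
        hidden_layer_sizes=(20, 15, 5),
        eta_plus=1.2,
        eta_minus=0.5,
        delta_init=0.1,
        delta_min=1e-6,
        delta_max=50.0,
        threshold=0.01,
        max_steps=100_000,
        random_state=0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.eta_plus = eta_plus
        self.eta_minus = eta_minus
        self.delta_init = delta_init
        self.delta_min = delta_min
        self.delta_max = delta_max
        self.threshold = threshold
        self.max_steps = max_steps
        self.random_state = random_state

    def _config(self) -> RpropConfig:
        return RpropConfig(
            eta_plus=self.eta_plus,
            eta_minus=self.eta_minus,
            delta_init=self.delta_init,
            delta_min=self.delta_min,
            delta_max=self.delta_max,
            threshold=self.threshold,
            max_steps=self.max_steps,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        sizes = [X.shape[1], *self.hidden_layer_sizes, 1]
        model = init_mlp(sizes, seed=self.random_state)
        self.model_, self.trace_ = train_rprop_plus(model, X, y, self._config())
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        return predict_batch(self.model_, X)
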