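"""Feed-forward glucose forecasters and their two training regimes.

The predictor is a small fully connected regression network (single output
node = future glucose in standardized units).  Two regimes are supported:

* **software** — the benchmark configuration: SELU activations, Adam,
  mini-batches of 1500, up to 2500 epochs with early stopping (patience 100),
  unconstrained float weights.
* **hardware** — the neuromorphic-feasible configuration: ReLU activations,
  plain per-sample gradient descent (batch size 1, no optimizer moments),
  10 epochs with no early stopping, and every weight and bias confined to a
  bounded, discrete :class:`~gluconet.device.WeightSpace`.  After each ideal
  update the parameter is rounded to the nearest allowed state of the ladder
  matching the update direction (set if the parameter would increase, reset
  if it would decrease); a zero gradient leaves it untouched.

Nets this small (11 to ~25k parameters) need no autodiff framework;
forward and backward passes are explicit numpy.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .device import WeightSpace, nearest_state
from .evaluation import ForecastResult
from .preprocessing import SampleSet

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "Network",
    "GlucoseMLPRegressor",
    "count_parameters",
    "init_network",
    "sgd_step",
    "search_learning_rate",
    "predict_series",
]

_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772

SOFTWARE_DEFAULTS = {
    "activation": "SELU",
    "batch_size": 1500,
    "max_epochs": 2500,
    "patience": 100,
    "lr_search_window": (1e-4, 1e-2),
}
HARDWARE_DEFAULTS = {
    "activation": "ReLU",
    "batch_size": 1,
    "max_epochs": 10,
    "patience": None,
    "lr_search_window": (1e-5, 1e-1),
}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of a fully connected forecaster."""

    input_nodes: int
    hidden_sizes: tuple[int, ...]
    output_nodes: int = 1
    activation: Literal["SELU", "ReLU"] = "SELU"

    def __post_init__(self) -> None:
        sizes = (self.input_nodes, *self.hidden_sizes, self.output_nodes)
        if any(s < 1 for s in sizes):
            raise ValueError("all layer sizes must be >= 1")
        if self.output_nodes != 1:
            raise ValueError("the forecaster has a single regression output")
        if self.activation not in ("SELU", "ReLU"):
            raise ValueError("activation must be 'SELU' or 'ReLU'")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_nodes, *self.hidden_sizes, self.output_nodes)


@dataclass(frozen=True)
class TrainConfig:
    """Training regime; unset fields take the mode's defaults."""

    mode: Literal["software", "hardware"] = "software"
    learning_rate: float = 1e-3
    lr_search_window: tuple[float, float] | None = None
    batch_size: int | None = None
    max_epochs: int | None = None
    early_stopping_patience: int | None = None
    seed: int = 0
    weight_space: WeightSpace | None = None
    fixed_init: bool = False
    quantize: bool = True   # False: hardware loop with continuous weights

    def __post_init__(self) -> None:
        if self.mode not in ("software", "hardware"):
            raise ValueError("mode must be 'software' or 'hardware'")
        if self.mode == "hardware" and self.quantize and self.weight_space is None:
            raise ValueError("hardware mode requires a weight_space")

    def resolved(self, name: str):
        defaults = SOFTWARE_DEFAULTS if self.mode == "software" else HARDWARE_DEFAULTS
        value = getattr(self, name if name != "patience" else
                        "early_stopping_patience")
        return defaults[name] if value is None else value


def count_parameters(spec: ModelSpec) -> int:
    """Total number of weights and biases of the fully connected network."""
    sizes = spec.layer_sizes
    return int(sum((sizes[i] + 1) * sizes[i + 1] for i in range(len(sizes) - 1)))


@dataclass
class Network:
    """Layer parameters of a forecaster (standardized-unit weights)."""

    weights: list[np.ndarray]   # each (fan_out, fan_in)
    biases: list[np.ndarray]    # each (fan_out,)
    spec: ModelSpec

    def copy(self) -> "Network":
        return Network([w.copy() for w in self.weights],
                       [b.copy() for b in self.biases], self.spec)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Predictions (standardized units) for inputs of shape (n, input_nodes)."""
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        a = np.atleast_2d(x)
        if a.shape[1] != self.spec.input_nodes:
            raise ValueError(
                f"expected {self.spec.input_nodes} input nodes, got {a.shape[1]}")
        act = _activation(self.spec.activation)
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = act(a @ w.T + b)
        out = (a @ self.weights[-1].T + self.biases[-1])[:, 0]
        return float(out[0]) if squeeze else out

    def all_parameters(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights]
                              + [b.ravel() for b in self.biases])

    def to_json(self, destination: str | Path | IO[str]) -> None:
        payload = {
            "spec": {"input_nodes": self.spec.input_nodes,
                     "hidden_sizes": list(self.spec.hidden_sizes),
                     "activation": self.spec.activation},
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        if hasattr(destination, "write"):
            json.dump(payload, destination)
        else:
            Path(destination).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, source: str | Path | IO[str]) -> "Network":
        data = json.load(source) if hasattr(source, "read") else json.loads(
            Path(source).read_text())
        spec = ModelSpec(data["spec"]["input_nodes"],
                         tuple(data["spec"]["hidden_sizes"]),
                         activation=data["spec"]["activation"])
        return cls([np.array(w) for w in data["weights"]],
                   [np.array(b) for b in data["biases"]], spec)


def _activation(name: str):
    if name == "ReLU":
        return lambda z: np.maximum(z, 0.0)
    return lambda z: _SELU_SCALE * np.where(
        z > 0, z, _SELU_ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0))


def _activation_grad(name: str):
    if name == "ReLU":
        return lambda z: (z > 0).astype(float)
    return lambda z: _SELU_SCALE * np.where(
        z > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(z, 0.0)))


def _fixed_seed(hidden_sizes: tuple[int, ...], input_nodes: int) -> int:
    # packaged deterministic initialization, independent of the user seed
    key = f"gluconet-init:{input_nodes}:{hidden_sizes}"
    return zlib.crc32(key.encode()) % (2**31)


def init_network(spec: ModelSpec, config: TrainConfig) -> Network:
    """Seeded fan-in-scaled initialization; hardware parameters snap to states.

    Weights draw from N(0, 1/fan_in) (LeCun scaling, the convention matching
    SELU); biases start at zero.  In hardware mode every parameter is then
    rounded to the nearest state of the set selection, which also clips it to
    the bounds.  ``fixed_init`` replaces the user seed with a packaged
    deterministic one keyed by the architecture.
    """
    seed = _fixed_seed(spec.hidden_sizes, spec.input_nodes) \
        if config.fixed_init else config.seed
    rng = np.random.default_rng(seed)
    sizes = spec.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in),
                                  size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    net = Network(weights, biases, spec)
    if config.mode == "hardware" and config.quantize:
        ws = config.weight_space
        net.weights = [nearest_state(w, "set", ws) for w in net.weights]
        net.biases = [nearest_state(b, "set", ws) for b in net.biases]
    return net


def _backward(net: Network, x: np.ndarray, y: np.ndarray
              ) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Gradients of mean squared error over the batch; returns (gW, gb, loss).

    Overflow is not trapped here: callers check gradient finiteness and
    raise FloatingPointError on divergence.
    """
    act = _activation(net.spec.activation)
    act_grad = _activation_grad(net.spec.activation)
    a = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n = a.shape[0]

    activations = [a]
    zs = []
    for w, b in zip(net.weights[:-1], net.biases[:-1]):
        z = activations[-1] @ w.T + b
        zs.append(z)
        activations.append(act(z))
    out = (activations[-1] @ net.weights[-1].T + net.biases[-1])[:, 0]
    resid = out - y
    loss = float(np.mean(resid**2))

    delta = (2.0 / n) * resid[:, None]          # (n, 1) at the linear output
    g_w = [np.empty(0)] * len(net.weights)
    g_b = [np.empty(0)] * len(net.biases)
    g_w[-1] = delta.T @ activations[-1]
    g_b[-1] = delta.sum(axis=0)
    for layer in range(len(net.weights) - 2, -1, -1):
        delta = (delta @ net.weights[layer + 1]) * act_grad(zs[layer])
        g_w[layer] = delta.T @ activations[layer]
        g_b[layer] = delta.sum(axis=0)
    return g_w, g_b, loss


def _quantized_update(value: np.ndarray, grad: np.ndarray, lr: float,
                      ws: WeightSpace) -> np.ndarray:
    """One hardware parameter update: ideal step, then direction-wise rounding."""
    ideal = value - lr * grad
    out = value.copy()
    inc = ideal > value
    dec = ideal < value
    if inc.any():
        out[inc] = nearest_state(ideal[inc], "set", ws)
    if dec.any():
        out[dec] = nearest_state(ideal[dec], "reset", ws)
    return out


def sgd_step(net: Network, x: np.ndarray, y: float | np.ndarray,
             learning_rate: float,
             weight_space: WeightSpace | None = None) -> Network:
    """One gradient step on a sample (or mini-batch mean) of squared error.

    Without a weight space this is the plain update ``p - lr * grad``.  With
    one, each parameter's ideal update is rounded via the direction-dependent
    nearest-state quantizer; zero-gradient parameters are untouched (no
    device pulse).  Returns a new network.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        g_w, g_b, _ = _backward(net, x, y)
    if not all(np.isfinite(g).all() for g in (*g_w, *g_b)):
        raise FloatingPointError("non-finite gradients; aborting step")
    new = net.copy()
    if weight_space is None:
        new.weights = [w - learning_rate * g for w, g in zip(net.weights, g_w)]
        new.biases = [b - learning_rate * g for b, g in zip(net.biases, g_b)]
    else:
        new.weights = [_quantized_update(w, g, learning_rate, weight_space)
                       for w, g in zip(net.weights, g_w)]
        new.biases = [_quantized_update(b, g, learning_rate, weight_space)
                      for b, g in zip(net.biases, g_b)]
    return new


class GlucoseMLPRegressor(RegressorMixin, BaseEstimator):
    """Feed-forward glucose forecaster, software or hardware training regime.

    Parameters left ``None`` resolve to the regime defaults (see module
    docstring).  Inputs and targets are expected in standardized units; use
    :func:`predict_series` to get forecasts back in mg/dL.

    Parameters
    ----------
    hidden_sizes : tuple of int
        Hidden layer widths, e.g. ``(128, 64, 32, 16)`` or ``(9, 6)``.
    mode : {"software", "hardware"}
        Training regime.
    activation : {"SELU", "ReLU"} or None
        Override of the regime's activation.
    learning_rate : float
        Step size (Adam in software mode, plain SGD in hardware mode).
    weight_space : WeightSpace or None
        Required in hardware mode; every weight and bias is confined to it.
    quantize : bool
        Hardware mode only.  ``False`` runs the identical per-sample SGD
        loop (same initialization and sample order) with continuous weights
        — the unquantized twin used to isolate the cost of discrete states.
    fixed_init : bool
        Use the packaged deterministic initialization for this architecture
        instead of ``random_state`` (used for the smallest hardware models,
        whose convergence is initialization-sensitive).
    random_state : int
        Seed for initialization and epoch shuffling.

    Attributes
    ----------
    network_ : Network
        Best-validation snapshot of the trained parameters.
    history_ : pandas.DataFrame
        Per-epoch training loss and validation RMSE (standardized units).
    best_epoch_ : int
        Epoch (1-based) of the returned snapshot.
    n_iter_ : int
        Epochs actually run.
    """

    def __init__(self, hidden_sizes: tuple[int, ...] = (128, 64, 32, 16),
                 mode: str = "software", activation: str | None = None,
                 learning_rate: float = 1e-3, batch_size: int | None = None,
                 max_epochs: int | None = None, patience: int | None = None,
                 weight_space: WeightSpace | None = None,
                 fixed_init: bool = False, quantize: bool = True,
                 random_state: int = 0):
        self.hidden_sizes = hidden_sizes
        self.mode = mode
        self.activation = activation
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.weight_space = weight_space
        self.fixed_init = fixed_init
        self.quantize = quantize
        self.random_state = random_state

    # -- configuration ----------------------------------------------------
    def _config(self) -> TrainConfig:
        return TrainConfig(
            mode=self.mode, learning_rate=self.learning_rate,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            early_stopping_patience=self.patience, seed=self.random_state,
            weight_space=self.weight_space, fixed_init=self.fixed_init,
            quantize=self.quantize,
        )

    def _spec(self, n_features: int) -> ModelSpec:
        defaults = SOFTWARE_DEFAULTS if self.mode == "software" else HARDWARE_DEFAULTS
        activation = self.activation or defaults["activation"]
        return ModelSpec(n_features, tuple(self.hidden_sizes),
                         activation=activation)

    # -- training ---------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train and keep the best-validation snapshot.

        Software mode: Adam on mini-batches, early stopping on validation
        RMSE.  Hardware mode: fixed 10-epoch budget of quantized per-sample
        updates in a seeded shuffle order, snapshot at the best epoch end.
        Without a validation set the training loss drives both.
        """
        X, y = check_X_y(X, y, y_numeric=True)
        if len(y) == 0:
            raise ValueError("empty training set")
        if X_val is not None:
            X_val, y_val = check_X_y(X_val, y_val, y_numeric=True)
            if len(y_val) == 0:
                raise ValueError("empty validation set")
        config = self._config()
        spec = self._spec(X.shape[1])
        net = init_network(spec, config)
        if self.mode == "hardware":
            net, history, best_epoch = self._fit_hardware(
                net, X, y, X_val, y_val, config)
        else:
            net, history, best_epoch = self._fit_software(
                net, X, y, X_val, y_val, config)
        self.network_ = net
        self.spec_ = spec
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_iter_ = len(history)
        self.n_features_in_ = X.shape[1]
        return self

    def _validation_rmse(self, net: Network, X_val, y_val, X, y) -> float:
        if X_val is None:
            xv, yv = X, y
        else:
            xv, yv = X_val, y_val
        return float(np.sqrt(np.mean((net.forward(xv) - yv) ** 2)))

    def _fit_software(self, net, X, y, X_val, y_val, config):
        batch = int(config.resolved("batch_size"))
        epochs = int(config.resolved("max_epochs"))
        patience = config.resolved("patience")
        lr = config.learning_rate
        rng = np.random.default_rng(config.seed)
        n = len(y)

        # Adam state
        m_w = [np.zeros_like(w) for w in net.weights]
        v_w = [np.zeros_like(w) for w in net.weights]
        m_b = [np.zeros_like(b) for b in net.biases]
        v_b = [np.zeros_like(b) for b in net.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        rows = []
        best = (np.inf, 0, net.copy())
        since_best = 0
        for epoch in range(1, epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                g_w, g_b, loss = _backward(net, X[idx], y[idx])
                if not all(np.isfinite(g).all() for g in (*g_w, *g_b)):
                    raise FloatingPointError("non-finite gradients during fit")
                step += 1
                for i in range(len(net.weights)):
                    for g, p, m, v in ((g_w[i], net.weights[i], m_w[i], v_w[i]),
                                       (g_b[i], net.biases[i], m_b[i], v_b[i])):
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g**2
                        m_hat = m / (1 - beta1**step)
                        v_hat = v / (1 - beta2**step)
                        p -= lr * m_hat / (np.sqrt(v_hat) + eps)
                epoch_loss += loss
                n_batches += 1
            val = self._validation_rmse(net, X_val, y_val, X, y)
            rows.append((epoch, epoch_loss / max(n_batches, 1), val))
            if val < best[0]:
                best = (val, epoch, net.copy())
                since_best = 0
            else:
                since_best += 1
            if patience is not None and since_best > patience:
                break
        history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_rmse"])
        return best[2], history, best[1]

    def _fit_hardware(self, net, X, y, X_val, y_val, config):
        ws = config.weight_space
        quantize = config.quantize and ws is not None
        epochs = int(config.resolved("max_epochs"))
        lr = config.learning_rate
        rng = np.random.default_rng(config.seed)
        n = len(y)
        act = _activation(net.spec.activation)
        act_grad = _activation_grad(net.spec.activation)
        n_layers = len(net.weights)
        weights = [w.copy() for w in net.weights]
        biases = [b.copy() for b in net.biases]

        rows = []
        best = (np.inf, 0, net.copy())
        for epoch in range(1, epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for i in order:
                # forward, single sample (1-D throughout: ~2x faster)
                a = X[i]
                acts = [a]
                zs = []
                for li in range(n_layers - 1):
                    z = weights[li] @ acts[-1] + biases[li]
                    zs.append(z)
                    acts.append(act(z))
                out = float((weights[-1] @ acts[-1] + biases[-1])[0])
                resid = out - y[i]
                epoch_loss += resid * resid
                delta = np.array([2.0 * resid])
                for li in range(n_layers - 1, -1, -1):
                    g_w = np.outer(delta, acts[li])
                    g_b = delta
                    if li > 0:
                        delta = (delta @ weights[li]) * act_grad(zs[li - 1])
                    if quantize:
                        weights[li] = _quantized_update(weights[li], g_w, lr, ws)
                        biases[li] = _quantized_update(biases[li], g_b, lr, ws)
                    else:
                        weights[li] = weights[li] - lr * g_w
                        biases[li] = biases[li] - lr * g_b
            snapshot = Network([w.copy() for w in weights],
                               [b.copy() for b in biases], net.spec)
            val = self._validation_rmse(snapshot, X_val, y_val, X, y)
            rows.append((epoch, epoch_loss / n, val))
            if val < best[0]:
                best = (val, epoch, snapshot)
        history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_rmse"])
        return best[2], history, best[1]

    # -- inference --------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Predictions in standardized units."""
        check_is_fitted(self, "network_")
        X = check_array(X)
        return np.atleast_1d(self.network_.forward(X))


def search_learning_rate(estimator: GlucoseMLPRegressor,
                         X, y, X_val=None, y_val=None,
                         window: tuple[float, float] | None = None,
                         n_points: int | None = None,
                         points_per_decade: int = 5
                         ) -> tuple[float, GlucoseMLPRegressor, pd.DataFrame]:
    """Logarithmic learning-rate search; returns (best rate, fitted model, table).

    Candidates are log-spaced over ``window`` (default: the regime's search
    window, [1e-4, 1e-2] software / [1e-5, 1e-1] hardware) with
    ``points_per_decade`` resolution unless ``n_points`` fixes the grid size.
    The candidate minimizing validation RMSE wins.
    """
    if window is None:
        defaults = SOFTWARE_DEFAULTS if estimator.mode == "software" \
            else HARDWARE_DEFAULTS
        window = defaults["lr_search_window"]
    lo, hi = window
    if not 0 < lo <= hi:
        raise ValueError("invalid learning-rate window")
    if lo == hi:
        grid = np.array([lo])
    else:
        if n_points is None:
            decades = np.log10(hi) - np.log10(lo)
            n_points = int(round(points_per_decade * decades)) + 1
        if n_points < 1:
            raise ValueError("empty learning-rate grid")
        grid = np.logspace(np.log10(lo), np.log10(hi), n_points)

    best: tuple[float, float, GlucoseMLPRegressor | None] = (np.inf, np.nan, None)
    rows = []
    for lr in grid:
        model = GlucoseMLPRegressor(**{**estimator.get_params(),
                                       "learning_rate": float(lr)})
        model.fit(X, y, X_val=X_val, y_val=y_val)
        val = model._validation_rmse(model.network_, X_val, y_val, X, y)
        rows.append((float(lr), val))
        if val < best[0]:
            best = (val, float(lr), model)
    table = pd.DataFrame(rows, columns=["learning_rate", "val_rmse"])
    return best[1], best[2], table


def predict_series(model: GlucoseMLPRegressor | Network,
                   samples: SampleSet) -> ForecastResult:
    """Forecast a sample set and return an mg/dL :class:`ForecastResult`.

    The sample set must be standardized with the training scaling; both
    predictions and references are inverse-transformed back to mg/dL and
    consecutive-sample rates attached at the set's prediction frequency.
    Evaluate one patient at a time: a pooled multi-patient set interleaves
    timestamps, so its rate series would be flagged undefined (or, worse,
    cross patient boundaries).
    """
    if not samples.standardized or samples.scaling is None:
        raise ValueError("samples must be standardized with training scaling")
    net = model.network_ if isinstance(model, GlucoseMLPRegressor) else model
    pred_std = np.atleast_1d(net.forward(samples.inputs))
    scaling = samples.scaling
    predicted = scaling.inverse_targets(pred_std)
    reference = scaling.inverse_targets(samples.targets)
    return ForecastResult(
        times=samples.timestamps,
        reference_glucose=reference,
        predicted_glucose=predicted,
        step_minutes=float(samples.config.prediction_frequency_minutes),
    )
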