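"""From-scratch three-layer sigmoid network trained by online backpropagation.

The network is the classical fully connected perceptron with one hidden
layer: input units ``x_i``, hidden units ``y_j = f(X_j)`` and output units
``z_k = f(Y_k)``, where ``f`` is the logistic sigmoid and each hidden/output
unit carries a bias weight.  Training is plain online (per-sample) gradient
descent on the sum-squared error

    E = 1/2 * sum_samples sum_k (t_k - z_k)**2,

with optional momentum and per-epoch random shuffling of the training
patterns.  Training stops as soon as the overall error drops below a fixed
limit (0.1 by default) or a safety cap on epochs is reached.

Everything here is deliberately written out rather than delegated to an ML
library: the training rule itself is the object of study.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "NetTopology",
    "NetParameters",
    "ForwardTrace",
    "TrainingConfig",
    "LabeledSample",
    "TrainingReport",
    "WeightDeltas",
    "sigmoid",
    "sigmoid_prime",
    "forward",
    "forward_batch",
    "network_error",
    "error_gradients",
    "backprop_step",
    "train",
    "save_model",
    "load_model",
]

# Sigmoid outputs are clipped to the largest representable open subinterval
# of (0, 1) so that extreme pre-activations saturate instead of collapsing
# to exactly 0 or 1 (which would zero the derivative f*(1-f) permanently).
_SIG_LO = 5e-324
_SIG_HI = float(np.nextafter(1.0, 0.0))


@dataclass(frozen=True)
class NetTopology:
    """Unit counts of the three layers (input, hidden, output)."""

    n_input: int
    n_hidden: int
    n_output: int

    def __post_init__(self) -> None:
        for name in ("n_input", "n_hidden", "n_output"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_input, self.n_hidden, self.n_output)


@dataclass
class NetParameters:
    """All connection weights and bias weights of a fully connected net.

    ``w_ih[i, j]`` is the weight from input unit ``i`` to hidden unit ``j``;
    ``w_ho[j, k]`` from hidden unit ``j`` to output unit ``k``.  ``b_h`` and
    ``b_o`` are the bias weights of the hidden and output units.
    """

    topology: NetTopology
    w_ih: np.ndarray
    w_ho: np.ndarray
    b_h: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        I, J, K = self.topology.as_tuple()
        self.w_ih = np.asarray(self.w_ih, dtype=float)
        self.w_ho = np.asarray(self.w_ho, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        self.b_o = np.asarray(self.b_o, dtype=float)
        expected = {
            "w_ih": (I, J),
            "w_ho": (J, K),
            "b_h": (J,),
            "b_o": (K,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape} for "
                    f"topology {self.topology.as_tuple()}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    @classmethod
    def zeros(cls, topology: NetTopology) -> "NetParameters":
        I, J, K = topology.as_tuple()
        return cls(topology, np.zeros((I, J)), np.zeros((J, K)), np.zeros(J), np.zeros(K))

    @classmethod
    def random(
        cls, topology: NetTopology, rng: np.random.Generator, scale: float = 0.5
    ) -> "NetParameters":
        """Uniform initialization on [-scale, scale] from the given generator."""
        I, J, K = topology.as_tuple()
        return cls(
            topology,
            rng.uniform(-scale, scale, size=(I, J)),
            rng.uniform(-scale, scale, size=(J, K)),
            rng.uniform(-scale, scale, size=J),
            rng.uniform(-scale, scale, size=K),
        )

    def copy(self) -> "NetParameters":
        return NetParameters(
            self.topology, self.w_ih.copy(), self.w_ho.copy(), self.b_h.copy(), self.b_o.copy()
        )


@dataclass
class ForwardTrace:
    """Intermediate quantities of one forward pass (needed by backprop)."""

    x: np.ndarray  # input vector
    X: np.ndarray  # hidden pre-activations
    y: np.ndarray  # hidden activations
    Y: np.ndarray  # output pre-activations
    z: np.ndarray  # output activations


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of online backpropagation training.

    Defaults follow the study conditions: learning rate 0.1, momentum 0,
    stop when the whole-set error falls below 0.1, patterns reshuffled every
    epoch.  ``error_scope`` selects whether the stopping error is the sum
    over the whole presented set (``"total"``, default) or the worst
    per-sample error (``"max_per_sample"``).
    """

    alpha: float = 0.1
    eta: float = 0.0
    e_limit: float = 0.1
    max_epochs: int = 50_000
    shuffle_each_epoch: bool = True
    rng_seed: int = 0
    init_scale: float = 0.5
    error_scope: str = "total"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 <= self.eta < 1.0):
            raise ValueError(f"eta must be in [0, 1), got {self.eta}")
        if self.e_limit < 0:
            raise ValueError(f"e_limit must be nonnegative, got {self.e_limit}")
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be positive, got {self.max_epochs}")
        if self.error_scope not in ("total", "max_per_sample"):
            raise ValueError(f"unknown error_scope {self.error_scope!r}")


@dataclass(frozen=True)
class LabeledSample:
    """One training example: an input vector and a target vector in [0,1]^K."""

    input: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "input", np.asarray(self.input, dtype=float))
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
        if self.input.ndim != 1 or self.target.ndim != 1:
            raise ValueError("input and target must be 1-D vectors")


@dataclass
class TrainingReport:
    epochs_run: int
    error_history: list[float]
    converged: bool


@dataclass
class WeightDeltas:
    """Per-weight change record; carries the momentum state between steps."""

    dw_ih: np.ndarray
    dw_ho: np.ndarray
    db_h: np.ndarray
    db_o: np.ndarray

    @classmethod
    def zeros(cls, topology: NetTopology) -> "WeightDeltas":
        I, J, K = topology.as_tuple()
        return cls(np.zeros((I, J)), np.zeros((J, K)), np.zeros(J), np.zeros(K))


def sigmoid(x):
    """Logistic sigmoid 1/(1+exp(-x)), saturating strictly inside (0, 1)."""
    return np.clip(expit(x), _SIG_LO, _SIG_HI)


def sigmoid_prime(activation):
    """Derivative f' = f*(1-f), expressed in terms of the activation f."""
    activation = np.asarray(activation)
    return activation * (1.0 - activation)


def forward(params: NetParameters, input: Sequence[float]) -> ForwardTrace:
    """One forward pass; returns all intermediate layer values."""
    x = np.asarray(input, dtype=float)
    I, J, K = params.topology.as_tuple()
    if x.shape != (I,):
        raise ValueError(f"input has shape {x.shape}, expected ({I},)")
    X = params.b_h + x @ params.w_ih
    y = sigmoid(X)
    Y = params.b_o + y @ params.w_ho
    z = sigmoid(Y)
    return ForwardTrace(x=x, X=X, y=y, Y=Y, z=z)


def forward_batch(params: NetParameters, inputs: np.ndarray) -> np.ndarray:
    """Vectorized forward pass over rows of ``inputs``; returns outputs only."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[1] != params.topology.n_input:
        raise ValueError(
            f"inputs must be (m, {params.topology.n_input}), got {inputs.shape}"
        )
    y = sigmoid(inputs @ params.w_ih + params.b_h)
    return sigmoid(y @ params.w_ho + params.b_o)


def network_error(targets, outputs) -> float:
    """Overall sum-squared error E = 1/2 sum_samples sum_k (t_k - z_k)^2."""
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    Z = np.atleast_2d(np.asarray(outputs, dtype=float))
    if T.shape != Z.shape:
        raise ValueError(f"targets shape {T.shape} != outputs shape {Z.shape}")
    return 0.5 * float(np.sum((T - Z) ** 2))


def _sample_gradients(params: NetParameters, x: np.ndarray, t: np.ndarray):
    """Backprop gradients of E for one sample.

    Returns (g_w_ih, g_w_ho, g_b_h, g_b_o, trace) where each g is dE/dw
    (the *ascent* direction; the learning step subtracts alpha times it).
    """
    trace = forward(params, x)
    delta_k = (t - trace.z) * sigmoid_prime(trace.z)          # dE/dY_k = -delta_k
    Delta_j = sigmoid_prime(trace.y) * (params.w_ho @ delta_k)  # dE/dX_j = -Delta_j
    g_w_ho = -np.outer(trace.y, delta_k)
    g_b_o = -delta_k
    g_w_ih = -np.outer(trace.x, Delta_j)
    g_b_h = -Delta_j
    return g_w_ih, g_w_ho, g_b_h, g_b_o, trace


def error_gradients(params: NetParameters, samples: Sequence[LabeledSample]) -> WeightDeltas:
    """Analytic gradient of the whole-set error E with respect to every weight."""
    acc = WeightDeltas.zeros(params.topology)
    for s in samples:
        if s.target.shape != (params.topology.n_output,):
            raise ValueError("target dimension does not match topology")
        g_w_ih, g_w_ho, g_b_h, g_b_o, _ = _sample_gradients(params, s.input, s.target)
        acc.dw_ih += g_w_ih
        acc.dw_ho += g_w_ho
        acc.db_h += g_b_h
        acc.db_o += g_b_o
    return acc


def backprop_step(
    params: NetParameters,
    sample: LabeledSample,
    config: TrainingConfig,
    prev_delta: WeightDeltas | None = None,
) -> tuple[NetParameters, WeightDeltas]:
    """One online weight update on a single sample.

    The applied change is ``alpha * gradient-descent term + eta * previous
    change``; the returned record is the change actually applied, to be fed
    back in as ``prev_delta`` on the next call when momentum is used.
    """
    if sample.target.shape != (params.topology.n_output,):
        raise ValueError("target dimension does not match topology")
    g_w_ih, g_w_ho, g_b_h, g_b_o, _ = _sample_gradients(params, sample.input, sample.target)
    a, eta = config.alpha, config.eta
    if prev_delta is None:
        prev_delta = WeightDeltas.zeros(params.topology)
    delta = WeightDeltas(
        dw_ih=-a * g_w_ih + eta * prev_delta.dw_ih,
        dw_ho=-a * g_w_ho + eta * prev_delta.dw_ho,
        db_h=-a * g_b_h + eta * prev_delta.db_h,
        db_o=-a * g_b_o + eta * prev_delta.db_o,
    )
    new = NetParameters(
        params.topology,
        params.w_ih + delta.dw_ih,
        params.w_ho + delta.dw_ho,
        params.b_h + delta.db_h,
        params.b_o + delta.db_o,
    )
    return new, delta


def _epoch_error(params: NetParameters, X: np.ndarray, T: np.ndarray, scope: str) -> float:
    Z = forward_batch(params, X)
    per_sample = 0.5 * np.sum((T - Z) ** 2, axis=1)
    if scope == "max_per_sample":
        return float(per_sample.max())
    return float(per_sample.sum())


def train(
    topology: NetTopology,
    samples: Sequence[LabeledSample],
    config: TrainingConfig | None = None,
) -> tuple[NetParameters, TrainingReport]:
    """Online backpropagation until the overall error drops below the limit.

    Weights start uniform on [-init_scale, init_scale] from the seeded
    generator; every epoch presents each sample once, in a fresh random
    order when shuffling is on.  The overall error is evaluated on the
    whole set after each epoch and compared against ``e_limit``.
    """
    if config is None:
        config = TrainingConfig()
    samples = list(samples)
    if not samples:
        raise ValueError("cannot train on an empty sample list")
    I, J, K = topology.as_tuple()
    for s in samples:
        if s.input.shape != (I,) or s.target.shape != (K,):
            raise ValueError(
                f"sample shapes {s.input.shape}/{s.target.shape} do not match "
                f"topology {(I, J, K)}"
            )
    rng = np.random.default_rng(config.rng_seed)
    params = NetParameters.random(topology, rng, config.init_scale)
    X = np.stack([s.input for s in samples])
    T = np.stack([s.target for s in samples])
    n = len(samples)

    # Hot loop: operate on the arrays directly instead of going through the
    # functional backprop_step (which copies every parameter array).
    w_ih, w_ho, b_h, b_o = params.w_ih, params.w_ho, params.b_h, params.b_o
    d_w_ih = np.zeros_like(w_ih)
    d_w_ho = np.zeros_like(w_ho)
    d_b_h = np.zeros_like(b_h)
    d_b_o = np.zeros_like(b_o)
    a, eta = config.alpha, config.eta
    use_momentum = eta != 0.0

    history: list[float] = []
    converged = False
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        for idx in order:
            x = X[idx]
            t = T[idx]
            y = sigmoid(b_h + x @ w_ih)
            z = sigmoid(b_o + y @ w_ho)
            delta_k = (t - z) * (z * (1.0 - z))
            Delta_j = (y * (1.0 - y)) * (w_ho @ delta_k)
            if use_momentum:
                d_w_ho *= eta
                d_w_ho += a * np.outer(y, delta_k)
                d_b_o *= eta
                d_b_o += a * delta_k
                d_w_ih *= eta
                d_w_ih += a * np.outer(x, Delta_j)
                d_b_h *= eta
                d_b_h += a * Delta_j
                w_ho += d_w_ho
                b_o += d_b_o
                w_ih += d_w_ih
                b_h += d_b_h
            else:
                w_ho += a * np.outer(y, delta_k)
                b_o += a * delta_k
                w_ih += a * np.outer(x, Delta_j)
                b_h += a * Delta_j
        E = _epoch_error(params, X, T, config.error_scope)
        history.append(E)
        if E < config.e_limit:
            converged = True
            break
    report = TrainingReport(epochs_run=len(history), error_history=history, converged=converged)
    return params, report


# ---------------------------------------------------------------------------
# Model persistence: one JSON document with topology, flat row-major weight
# arrays, and (optionally) the training config and seed that produced them.
# ---------------------------------------------------------------------------


def save_model(
    path: str | Path,
    params: NetParameters,
    config: TrainingConfig | None = None,
) -> None:
    doc = {
        "topology": {
            "n_input": params.topology.n_input,
            "n_hidden": params.topology.n_hidden,
            "n_output": params.topology.n_output,
        },
        "w_ih": params.w_ih.ravel(order="C").tolist(),
        "w_ho": params.w_ho.ravel(order="C").tolist(),
        "b_h": params.b_h.tolist(),
        "b_o": params.b_o.tolist(),
    }
    if config is not None:
        doc["config"] = asdict(config)
        doc["seed"] = config.rng_seed
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> NetParameters:
    doc = json.loads(Path(path).read_text())
    try:
        topo = NetTopology(**doc["topology"])
    except KeyError as exc:
        raise ValueError(f"model file missing field: {exc}") from exc
    I, J, K = topo.as_tuple()
    for name, length in (("w_ih", I * J), ("w_ho", J * K), ("b_h", J), ("b_o", K)):
        if name not in doc:
            raise ValueError(f"model file missing field: {name}")
        if len(doc[name]) != length:
            raise ValueError(
                f"{name} has {len(doc[name])} entries, expected {length} for "
                f"topology {topo.as_tuple()}"
            )
    return NetParameters(
        topo,
        np.asarray(doc["w_ih"], dtype=float).reshape(I, J),
        np.asarray(doc["w_ho"], dtype=float).reshape(J, K),
        np.asarray(doc["b_h"], dtype=float),
        np.asarray(doc["b_o"], dtype=float),
    )
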