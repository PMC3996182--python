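"""Feed-forward network substrate: representation, forward pass, loss,
gradient and residual Jacobian.

The networks are small fully connected multilayer perceptrons: tanh hidden
units, and either an identity output (regression head for frequency, tidal
volume and FiO2) or a logistic output (classification head for the
pressure-/volume-support mode).  Everything the trainers need — flattened
parameter vectors, the sum-of-squared-error loss, its exact gradient, and the
Jacobian of the residual vector — lives here so the six training algorithms
share one numerical substrate.

Parameter flattening is layer-major, weights before the layer's biases:
[W1.ravel(), b1, W2.ravel(), b2, ...].  Residuals are flattened sample-major
(sample index varies slowest, output index fastest), and Jacobian rows follow
the same order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

ACTIVATIONS = ("tanh", "identity", "logistic")


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(z)
    if name == "identity":
        return z
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {name!r}")


def _act_deriv(name: str, a: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation value a = act(z)
    if name == "tanh":
        return 1.0 - a * a
    if name == "identity":
        return np.ones_like(a)
    if name == "logistic":
        return a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


@dataclass(frozen=True)
class MLPModel:
    """Immutable MLP: per-layer weight matrices (out x in) and bias vectors."""

    layer_sizes: tuple[int, ...]
    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]
    hidden_activation: str = "tanh"
    output_activation: str = "identity"
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.hidden_activation!r}")
        if self.output_activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.output_activation!r}")
        expected = list(zip(self.layer_sizes[1:], self.layer_sizes[:-1]))
        for W, b, (n_out, n_in) in zip(self.weights, self.biases, expected):
            if W.shape != (n_out, n_in) or b.shape != (n_out,):
                raise ValueError("weight/bias shapes inconsistent with layer_sizes")
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError("parameters must be finite")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]

    @property
    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    def activation_for_layer(self, layer: int) -> str:
        last = len(self.weights) - 1
        return self.output_activation if layer == last else self.hidden_activation


def parameter_count(layer_sizes: Sequence[int]) -> int:
    """Number of weights plus biases for the given layer widths."""
    return sum(
        n_in * n_out + n_out for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:])
    )


def init_mlp(
    layer_sizes: Sequence[int],
    seed: int,
    hidden_activation: str = "tanh",
    output_activation: str = "identity",
) -> MLPModel:
    """Seeded uniform initialization on [-0.5, 0.5]; same seed, same model."""
    sizes = tuple(int(s) for s in layer_sizes)
    rng = np.random.default_rng(seed)
    weights = []
    biases = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(n_out, n_in)))
        biases.append(rng.uniform(-0.5, 0.5, size=n_out))
    return MLPModel(
        layer_sizes=sizes,
        weights=tuple(weights),
        biases=tuple(biases),
        hidden_activation=hidden_activation,
        output_activation=output_activation,
        seed=seed,
    )


def flatten(model: MLPModel) -> np.ndarray:
    """Layer-major [W, b] parameter vector."""
    parts = []
    for W, b in zip(model.weights, model.biases):
        parts.append(W.ravel())
        parts.append(b)
    return np.concatenate(parts)


def unflatten(model: MLPModel, theta: np.ndarray) -> MLPModel:
    """Model with the same architecture carrying the given parameter vector."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.n_parameters,):
        raise ValueError(
            f"expected parameter vector of length {model.n_parameters}, got {theta.shape}"
        )
    weights = []
    biases = []
    pos = 0
    for W, b in zip(model.weights, model.biases):
        weights.append(theta[pos : pos + W.size].reshape(W.shape).copy())
        pos += W.size
        biases.append(theta[pos : pos + b.size].copy())
        pos += b.size
    return replace(model, weights=tuple(weights), biases=tuple(biases))


def _forward_all(model: MLPModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer, input included; X is (n, n_inputs)."""
    activations = [X]
    a = X
    for layer, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W.T + b
        a = _act(model.activation_for_layer(layer), z)
        activations.append(a)
    return activations


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Network output for a single feature vector or a (n, d) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != model.n_inputs:
        raise ValueError(
            f"expected {model.n_inputs} inputs, got {X.shape[1]}"
        )
    out = _forward_all(model, X)[-1]
    return out[0] if single else out


def residuals(model: MLPModel, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Flattened prediction errors (yhat - y), sample-major."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if Y.shape[1] != model.n_outputs:
        raise ValueError(f"expected {model.n_outputs} target columns, got {Y.shape[1]}")
    return (forward(model, X) - Y).ravel()


def sse_loss(model: MLPModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Half the sum of squared residuals over all samples and outputs."""
    r = residuals(model, X, Y)
    return 0.5 * float(r @ r)


def gradient(model: MLPModel, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact gradient of :func:`sse_loss` w.r.t. the flat parameter vector.

    Standard backpropagation with the residual as the output delta.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    acts = _forward_all(model, X)
    delta = (acts[-1] - Y) * _act_deriv(model.output_activation, acts[-1])
    grads_W: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * len(model.biases)  # type: ignore[list-item]
    for layer in range(len(model.weights) - 1, -1, -1):
        grads_W[layer] = delta.T @ acts[layer]
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            act_name = model.activation_for_layer(layer - 1)
            delta = (delta @ model.weights[layer]) * _act_deriv(act_name, acts[layer])
    parts = []
    for gW, gb in zip(grads_W, grads_b):
        parts.append(gW.ravel())
        parts.append(gb)
    return np.concatenate(parts)


def jacobian(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Jacobian of the flattened residual vector w.r.t. the parameters.

    Shape (n_samples * n_outputs, n_parameters); rows are sample-major to
    match :func:`residuals`.  Satisfies J.T @ r == gradient.
    """
    X = np.asarray(X, dtype=float)
    n, _ = X.shape
    m = model.n_outputs
    acts = _forward_all(model, X)
    n_layers = len(model.weights)

    # deltas[layer] has shape (n, m, layer_width): d out_k / d z_layer
    out_deriv = _act_deriv(model.output_activation, acts[-1])  # (n, m)
    delta = np.zeros((n, m, m))
    idx = np.arange(m)
    delta[:, idx, idx] = out_deriv

    J = np.empty((n * m, model.n_parameters))
    # fill per layer, walking backwards
    col_offsets = []
    pos = 0
    for W, b in zip(model.weights, model.biases):
        col_offsets.append((pos, pos + W.size, pos + W.size + b.size))
        pos += W.size + b.size

    for layer in range(n_layers - 1, -1, -1):
        a_prev = acts[layer]  # (n, n_in)
        w_start, b_start, b_end = col_offsets[layer]
        # dr/dW = delta x a_prev  -> (n, m, n_out, n_in)
        block = np.einsum("nko,ni->nkoi", delta, a_prev)
        J[:, w_start:b_start] = block.reshape(n * m, -1)
        J[:, b_start:b_end] = delta.reshape(n * m, -1)
        if layer > 0:
            act_name = model.activation_for_layer(layer - 1)
            deriv = _act_deriv(act_name, acts[layer])  # (n, n_in of this layer)
            delta = np.einsum("nko,oi->nki", delta, model.weights[layer]) * deriv[
                :, None, :
            ]
    return J


def to_json(model: MLPModel) -> str:
    """Bit-exact JSON serialization (floats via repr round-trip)."""
    payload = {
        "layer_sizes": list(model.layer_sizes),
        "hidden_activation": model.hidden_activation,
        "output_activation": model.output_activation,
        "seed": model.seed,
        "parameters": flatten(model).tolist(),
    }
    return json.dumps(payload)


def from_json(text: str) -> MLPModel:
    payload = json.loads(text)
    sizes = tuple(payload["layer_sizes"])
    template = init_mlp(
        sizes,
        seed=0,
        hidden_activation=payload["hidden_activation"],
        output_activation=payload["output_activation"],
    )
    model = unflatten(template, np.asarray(payload["parameters"], dtype=float))
    return replace(model, seed=payload["seed"])
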