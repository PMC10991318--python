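"""Attention-weighted two-layer GRU classifier for tabular records.

Tabular-to-sequence convention: each of the ``d`` input features is one time
step carrying a scalar value.  A one-parameter attention scorer assigns each
feature a relevance ``e_t = tanh(w_a * x_t + b_a)``; the softmax of the
scores gives attention weights ``alpha`` summing to 1, and the weighted
scalar sequence ``alpha_t * x_t`` is consumed stepwise by GRU layer 1, whose
hidden state feeds GRU layer 2.  The final hidden state passes through a
fully connected layer and a sigmoid to a class-1 probability.

GRU cell (reset gate j, update gate v, candidate state lam, ``*`` elementwise)::

    j_t   = sigmoid(W_j [h_prev, x_t] + b_j)
    v_t   = sigmoid(W_v [h_prev, x_t] + b_v)
    lam_t = tanh(W_h [(h_prev * j_t), x_t] + b_h)
    h_t   = (1 - v_t) * lam_t + v_t * h_prev

Note the blend direction: the update gate v multiplies the *previous* state
(some textbooks use the transpose convention).  All parameters flatten to a
single real vector so a derivative-free optimizer can train the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "AttGRUConfig",
    "AttGRUParams",
    "FitnessSpec",
    "attention_weights",
    "weighted_input",
    "gru_cell",
    "forward",
    "forward_batch",
    "mape",
    "fitness",
    "param_count",
    "softmax",
    "flatten",
    "unflatten",
    "zero_params",
]


@dataclass(frozen=True)
class AttGRUConfig:
    """Topology: input width and hidden units of the two GRU layers."""

    n_features_in: int
    hidden_units: tuple[int, int] = (8, 8)
    batch_size: int = 4096  # evaluation chunking only; no effect on results

    def __post_init__(self) -> None:
        if self.n_features_in < 1:
            raise ValueError("n_features_in must be >= 1")
        if any(h < 1 for h in self.hidden_units):
            raise ValueError("hidden_units must be >= 1")


@dataclass
class LayerParams:
    """One GRU layer's gate weights; W_* have shape (h, h + in_dim)."""

    W_j: np.ndarray
    b_j: np.ndarray
    W_v: np.ndarray
    b_v: np.ndarray
    W_h: np.ndarray
    b_h: np.ndarray


@dataclass
class AttGRUParams:
    """All weights: attention scorer, two GRU layers, output layer."""

    w_a: float
    b_a: float
    layers: list[LayerParams]
    w_out: np.ndarray
    b_out: float


@dataclass(frozen=True)
class FitnessSpec:
    """Training objective: mean absolute percentage error by default, with
    cross-entropy and 0/1 error-rate alternatives (MAPE against 0-labels is
    epsilon-guarded and therefore dominated by the healthy class)."""

    kind: str = "mape"
    epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if self.kind not in ("mape", "cross_entropy", "error_rate"):
            raise ValueError(f"unknown fitness kind {self.kind!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def softmax(scores: np.ndarray) -> np.ndarray:
    """Softmax along the last axis with max-subtraction for stability.

    Invariant under adding a constant to all scores; rows sum to 1.
    """
    e = np.asarray(scores, dtype=float)
    e = e - e.max(axis=-1, keepdims=True)
    w = np.exp(e)
    return w / w.sum(axis=-1, keepdims=True)


def attention_weights(x_sequence: np.ndarray, params: AttGRUParams) -> np.ndarray:
    """Softmax attention over the feature sequence (rows if 2-D).

    Relevance scores are ``tanh(w_a * x + b_a)`` (a one-parameter scorer);
    the resulting weights sum to 1 along the last axis.
    """
    x = np.asarray(x_sequence, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("attention input contains non-finite values")
    return softmax(np.tanh(params.w_a * x + params.b_a))


def weighted_input(x_sequence: np.ndarray, alpha: np.ndarray) -> float:
    """Attention-weighted sum mu = sum_t alpha_t x_t (scalar summary).

    The per-step sequence the GRU actually consumes is the elementwise
    products ``alpha_t * x_t``; this function exposes their sum.
    """
    x = np.asarray(x_sequence, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape:
        raise ValueError("x_sequence and alpha must have equal length")
    return float(np.sum(alpha * x, axis=-1))


def gru_cell(x_t: np.ndarray, h_prev: np.ndarray, layer: LayerParams) -> np.ndarray:
    """One GRU step; accepts (h,) vectors or (B, h) batches."""
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.asarray(h_prev, dtype=float)
    squeeze = h_prev.ndim == 1
    if squeeze:
        h_prev = h_prev[None, :]
        x_t = x_t[None, :] if x_t.ndim == 1 else x_t
    if not (np.isfinite(x_t).all() and np.isfinite(h_prev).all()):
        raise ValueError("gru_cell received non-finite inputs")
    z = np.concatenate([h_prev, x_t], axis=1)  # (B, h + in)
    j = _sigmoid(z @ layer.W_j.T + layer.b_j)
    v = _sigmoid(z @ layer.W_v.T + layer.b_v)
    zc = np.concatenate([h_prev * j, x_t], axis=1)
    lam = np.tanh(zc @ layer.W_h.T + layer.b_h)
    h_t = (1.0 - v) * lam + v * h_prev
    return h_t[0] if squeeze else h_t


def forward_batch(
    X: np.ndarray, params: AttGRUParams, config: AttGRUConfig
) -> np.ndarray:
    """Class-1 probabilities for a (n, d) feature matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != config.n_features_in:
        raise ValueError(
            f"input has {X.shape[1]} features, config expects {config.n_features_in}"
        )
    # pre-split each gate matrix into its h_prev and x_t blocks so the step
    # loop is pure matmuls (identical arithmetic to gru_cell, just faster)
    splits = []
    for layer, (in_dim, h) in zip(params.layers, _layer_dims(config)):
        splits.append(tuple(
            (W[:, :h].T.copy(), W[:, h:].T.copy(), b)
            for W, b in ((layer.W_j, layer.b_j), (layer.W_v, layer.b_v),
                         (layer.W_h, layer.b_h))
        ))

    def cell(x_t, h_prev, gates):
        (Wjh, Wjx, bj), (Wvh, Wvx, bv), (Whh, Whx, bh) = gates
        j = _sigmoid(h_prev @ Wjh + x_t @ Wjx + bj)
        v = _sigmoid(h_prev @ Wvh + x_t @ Wvx + bv)
        lam = np.tanh((h_prev * j) @ Whh + x_t @ Whx + bh)
        return (1.0 - v) * lam + v * h_prev

    out = np.empty(X.shape[0])
    for start in range(0, X.shape[0], config.batch_size):
        chunk = X[start:start + config.batch_size]
        alpha = attention_weights(chunk, params)
        seq = alpha * chunk  # (B, d) attention-weighted scalar sequence
        B = chunk.shape[0]
        h1 = np.zeros((B, config.hidden_units[0]))
        h2 = np.zeros((B, config.hidden_units[1]))
        for t in range(config.n_features_in):
            h1 = cell(seq[:, t:t + 1], h1, splits[0])
            h2 = cell(h1, h2, splits[1])
        logits = h2 @ params.w_out + params.b_out
        out[start:start + config.batch_size] = _sigmoid(logits)
    return out


def forward(x: np.ndarray, params: AttGRUParams, config: AttGRUConfig) -> float:
    """Class-1 probability for one feature vector."""
    return float(forward_batch(np.asarray(x, dtype=float)[None, :], params, config)[0])


def mape(E: np.ndarray, e: np.ndarray, epsilon: float = 1e-7) -> float:
    """Mean absolute percentage error (1/N) sum |E_i - e_i| / max(|e_i|, eps)."""
    E = np.asarray(E, dtype=float)
    e = np.asarray(e, dtype=float)
    if E.size == 0:
        raise ValueError("empty data")
    return float(np.mean(np.abs(E - e) / np.maximum(np.abs(e), epsilon)))


def fitness(
    param_vector: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: AttGRUConfig,
    spec: FitnessSpec = FitnessSpec(),
) -> float:
    """Training loss of the network encoded by ``param_vector`` (lower = better)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty data")
    params = unflatten(param_vector, config)
    E = forward_batch(X, params, config)
    if spec.kind == "mape":
        return mape(E, y, spec.epsilon)
    if spec.kind == "cross_entropy":
        p = np.clip(E, spec.epsilon, 1.0 - spec.epsilon)
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    return float(np.mean((E >= 0.5).astype(float) != y))


# ---------------------------------------------------------------------------
# Parameter vector layout (stable, documented):
#   [w_a, b_a,
#    per layer l (input width i_l, hidden h_l):
#        W_j (h_l x (h_l + i_l)) row-major, b_j (h_l),
#        W_v ..., b_v, W_h ..., b_h,
#    w_out (h_last), b_out]
# ---------------------------------------------------------------------------

def _layer_dims(config: AttGRUConfig) -> list[tuple[int, int]]:
    return [(1, config.hidden_units[0]),
            (config.hidden_units[0], config.hidden_units[1])]


def param_count(config: AttGRUConfig) -> int:
    """Total number of real parameters for a given topology."""
    count = 2  # attention scorer
    for in_dim, h in _layer_dims(config):
        count += 3 * (h * (h + in_dim) + h)
    count += config.hidden_units[1] + 1  # output layer
    return count


def flatten(params: AttGRUParams) -> np.ndarray:
    parts = [np.array([params.w_a, params.b_a])]
    for layer in params.layers:
        for W, b in ((layer.W_j, layer.b_j), (layer.W_v, layer.b_v),
                     (layer.W_h, layer.b_h)):
            parts.append(W.ravel())
            parts.append(b)
    parts.append(params.w_out)
    parts.append(np.array([params.b_out]))
    return np.concatenate(parts)


def unflatten(vector: np.ndarray, config: AttGRUConfig) -> AttGRUParams:
    vector = np.asarray(vector, dtype=float)
    expected = param_count(config)
    if vector.shape != (expected,):
        raise ValueError(
            f"parameter vector has length {vector.size}, expected {expected}"
        )
    pos = 0

    def take(n: int) -> np.ndarray:
        nonlocal pos
        chunk = vector[pos:pos + n]
        pos += n
        return chunk

    w_a, b_a = take(1)[0], take(1)[0]
    layers = []
    for in_dim, h in _layer_dims(config):
        mats = {}
        for name in ("j", "v", "h"):
            mats[f"W_{name}"] = take(h * (h + in_dim)).reshape(h, h + in_dim)
            mats[f"b_{name}"] = take(h)
        layers.append(LayerParams(**mats))
    w_out = take(config.hidden_units[1])
    b_out = take(1)[0]
    return AttGRUParams(w_a=w_a, b_a=b_a, layers=layers, w_out=w_out, b_out=b_out)


def zero_params(config: AttGRUConfig) -> AttGRUParams:
    """All-zero network: outputs exactly 0.5 for every input."""
    return unflatten(np.zeros(param_count(config)), config)
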