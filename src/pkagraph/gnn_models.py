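"""The three graph-network regressors: GCN, GIN and GATv2.

Each architecture is a three-stage network — input layer, one hidden
layer, output stage — operating on a residue graph's N x 26 node-feature
matrix and its binary adjacency with self-loops, ending in a global
pooling that yields one scalar pKa prediction per graph.

Layer semantics (all authored here, on the package's own autodiff
engine):

* GCN: symmetric degree-normalized convolution over the closed
  neighborhood, ``h_i' = relu( sum_j W h_j / sqrt(d_i d_j) )`` with the
  degree counting the self-loop.
* GIN: ``h_i' = MLP( (1 + eps) h_i + sum_{j in N(i)} h_j )`` over the
  open neighborhood, with a learnable scalar eps and a two-layer MLP.
* GATv2: per-head attention ``alpha_ij ∝ exp(a^T LeakyReLU(W_s h_i +
  W_t h_j))`` normalized over the closed neighborhood, heads
  concatenated.

The functional ops (``gcn_layer`` and friends) take plain NumPy arrays
and are the reference surface used by the equation-oracle tests; the
``Var``-based internals (same code path) power training and the
explainer.  All ops broadcast over an optional leading batch axis, so a
stack of equally sized graphs evaluates in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from ._autodiff import Var, as_var, concat
from .graph_builder import N_FEATURES, ResidueGraph

__all__ = [
    "ModelConfig",
    "gcn_layer",
    "gin_layer",
    "gat_attention",
    "gat_layer",
    "global_pool",
    "model_forward",
    "init_parameters",
    "forward_var",
    "LEAKY_SLOPE",
]

LEAKY_SLOPE = 0.2  # LeakyReLU negative slope in the attention scoring

Architecture = Literal["GCN", "GIN", "GAT"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture choice plus every tunable training hyperparameter."""

    architecture: Architecture = "GCN"
    hidden_channels: int = 32
    dropout_rate: float = 0.3
    n_heads: int = 4  # GAT only
    pooling: Literal["mean", "add"] = "mean"  # GIN only; GCN/GAT use mean
    loss: Literal["smooth_l1", "l1", "mse"] = "smooth_l1"
    learning_rate: float = 0.006
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_channels < 1:
            raise ValueError("hidden_channels must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if self.architecture not in ("GCN", "GIN", "GAT"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.pooling not in ("mean", "add"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# Var-level layer implementations (support (N,d) or batched (B,N,d) inputs)
# ---------------------------------------------------------------------------

def _swap_last(v: Var) -> Var:
    axes = list(range(len(v.shape)))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return v.transpose(*axes)


def _gcn_layer_v(H: Var, A: Var, W: Var, activation: bool = True) -> Var:
    if H.shape[-1] != W.shape[0]:
        raise ValueError(
            f"feature width {H.shape[-1]} does not match W rows {W.shape[0]}"
        )
    if A.shape[-1] != H.shape[-2]:
        raise ValueError("adjacency size does not match node count")
    deg = A.sum(axis=-1, keepdims=True)  # closed-neighborhood degree
    inv_sqrt = deg ** -0.5
    norm = A * (inv_sqrt * _swap_last(inv_sqrt))
    out = norm @ (H @ W)
    return out.relu() if activation else out


def _gin_layer_v(
    H: Var, A: Var, eps: Var, W1: Var, b1: Var, W2: Var, b2: Var
) -> Var:
    if H.shape[-1] != W1.shape[0]:
        raise ValueError("feature width does not match MLP input size")
    n = A.shape[-1]
    eye = np.eye(n)
    open_adj = A * (1.0 - eye)  # self handled by the (1 + eps) term
    agg = H * (1.0 + eps) + open_adj @ H
    hidden = (agg @ W1 + b1).relu()
    return hidden @ W2 + b2


def _gat_attention_v(H: Var, A: Var, Ws: Var, Wt: Var, a: Var) -> Var:
    """Per-head attention matrix; rows sum to 1 over the closed neighborhood."""
    S = H @ Ws  # query transform of the central node
    T = H @ Wt  # key transform of the neighbors
    n, d = H.shape[-2], Ws.shape[-1]
    batch = H.shape[:-2]
    S_exp = S.reshape(*batch, n, 1, d)
    T_exp = T.reshape(*batch, 1, n, d)
    scores = (S_exp + T_exp).leaky_relu(LEAKY_SLOPE) @ a.reshape(d, 1)
    scores = scores.reshape(*batch, n, n)
    # subtract a detached row max before exponentiation (overflow guard;
    # softmax is invariant to the shift)
    shift = scores.value.max(axis=-1, keepdims=True)
    weights = (scores - shift).exp() * A
    return weights / weights.sum(axis=-1, keepdims=True)


def _gat_layer_v(
    H: Var, A: Var, heads: list[tuple[Var, Var, Var]]
) -> Var:
    n = A.shape[-1]
    eye = np.eye(n)
    outputs = []
    for Ws, Wt, a in heads:
        alpha = _gat_attention_v(H, A, Ws, Wt, a)
        self_part = (alpha * eye) @ (H @ Ws)
        neigh_part = (alpha * (1.0 - eye)) @ (H @ Wt)
        outputs.append(self_part + neigh_part)
    return outputs[0] if len(outputs) == 1 else concat(outputs, axis=-1)


def _pool_v(H: Var, mode: str) -> Var:
    if H.shape[-2] < 1:
        raise ValueError("cannot pool an empty graph")
    if mode == "mean":
        return H.mean(axis=-2)
    if mode == "add":
        return H.sum(axis=-2)
    raise ValueError(f"unknown pooling mode {mode!r}")


# ---------------------------------------------------------------------------
# Functional (NumPy in / NumPy out) surface
# ---------------------------------------------------------------------------

def gcn_layer(
    H: np.ndarray, A: np.ndarray, W: np.ndarray, activation: bool = True
) -> np.ndarray:
    """Degree-normalized graph convolution with ReLU (one GCN layer)."""
    return _gcn_layer_v(as_var(H), as_var(A), as_var(W), activation).value


def gin_layer(
    H: np.ndarray,
    A: np.ndarray,
    eps: float,
    mlp: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray:
    """GIN aggregation followed by an arbitrary MLP callable."""
    H = np.asarray(H, dtype=float)
    A = np.asarray(A, dtype=float)
    if A.shape[-1] != H.shape[-2]:
        raise ValueError("adjacency size does not match node count")
    eye = np.eye(A.shape[-1])
    agg = (1.0 + eps) * H + (A * (1.0 - eye)) @ H
    return mlp(agg)


def gat_attention(
    H: np.ndarray, A: np.ndarray, Ws: np.ndarray, Wt: np.ndarray, a: np.ndarray
) -> np.ndarray:
    """Single-head GATv2 attention coefficients (rows sum to 1 on support)."""
    return _gat_attention_v(
        as_var(H), as_var(A), as_var(Ws), as_var(Wt), as_var(a)
    ).value


def gat_layer(
    H: np.ndarray,
    A: np.ndarray,
    head_params: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Multi-head GATv2 layer; heads concatenated in index order."""
    heads = [(as_var(Ws), as_var(Wt), as_var(a)) for Ws, Wt, a in head_params]
    return _gat_layer_v(as_var(H), as_var(A), heads).value


def global_pool(H: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Permutation-invariant graph readout: column means or sums."""
    return _pool_v(as_var(H), mode).value


# ---------------------------------------------------------------------------
# Parameters and full forward pass
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_parameters(
    config: ModelConfig, n_features: int = N_FEATURES
) -> dict[str, np.ndarray]:
    """Seeded Glorot-style initialization for the configured architecture."""
    rng = np.random.default_rng(config.seed)
    h = config.hidden_channels
    p: dict[str, np.ndarray] = {}
    if config.architecture == "GCN":
        p["W1"] = _glorot(rng, n_features, h)
        p["W2"] = _glorot(rng, h, 1)
    elif config.architecture == "GIN":
        p["eps"] = np.zeros(())
        p["mlp_W1"] = _glorot(rng, n_features, h)
        p["mlp_b1"] = np.zeros(h)
        p["mlp_W2"] = _glorot(rng, h, h)
        p["mlp_b2"] = np.zeros(h)
        p["out_W"] = _glorot(rng, h, 1)
        p["out_b"] = np.zeros(1)
    else:  # GAT
        for m in range(config.n_heads):
            p[f"Ws1_{m}"] = _glorot(rng, n_features, h)
            p[f"Wt1_{m}"] = _glorot(rng, n_features, h)
            p[f"a1_{m}"] = rng.uniform(
                -np.sqrt(6.0 / (h + 1)), np.sqrt(6.0 / (h + 1)), size=h
            )
        wide = config.n_heads * h
        p["Ws2"] = _glorot(rng, wide, 1)
        p["Wt2"] = _glorot(rng, wide, 1)
        p["a2"] = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=1)
    return p


def forward_var(
    X: Var,
    A: Var,
    config: ModelConfig,
    params: dict[str, Var],
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Var:
    """Full forward pass to per-graph predictions; autodiff-capable.

    X is (N, F) or (B, N, F) with matching adjacency.  Dropout is active
    only when ``training`` is set (requires ``rng``); evaluation is
    deterministic given the parameters.
    """
    if X.shape[-1] != N_FEATURES:
        raise ValueError(
            f"expected {N_FEATURES} node features, got {X.shape[-1]}"
        )

    def dropout(v: Var) -> Var:
        if not training or config.dropout_rate == 0.0:
            return v
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - config.dropout_rate
        mask = rng.binomial(1, keep, size=v.shape) / keep
        return v * mask

    arch = config.architecture
    if arch == "GCN":
        h = _gcn_layer_v(X, A, params["W1"], activation=True)
        h = dropout(h)
        h = _gcn_layer_v(h, A, params["W2"], activation=False)
        out = _pool_v(h, "mean")
    elif arch == "GIN":
        h = _gin_layer_v(
            X, A, params["eps"], params["mlp_W1"], params["mlp_b1"],
            params["mlp_W2"], params["mlp_b2"],
        ).relu()
        h = dropout(h)
        pooled = _pool_v(h, config.pooling)
        out = pooled @ params["out_W"] + params["out_b"]
    else:  # GAT
        heads = [
            (params[f"Ws1_{m}"], params[f"Wt1_{m}"], params[f"a1_{m}"])
            for m in range(config.n_heads)
        ]
        h = _gat_layer_v(X, A, heads).relu()
        h = dropout(h)
        h = _gat_layer_v(h, A, [(params["Ws2"], params["Wt2"], params["a2"])])
        out = _pool_v(h, "mean")
    # out has trailing singleton feature axis -> per-graph scalar(s)
    return out.reshape(*out.shape[:-1]) if out.shape[-1] == 1 else out


def model_forward(
    graph: ResidueGraph,
    config: ModelConfig,
    params: dict[str, np.ndarray],
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Predict one graph's pKa.  Deterministic when ``training`` is False."""
    pvars = {k: as_var(v) for k, v in params.items()}
    out = forward_var(
        as_var(graph.node_features),
        as_var(graph.adjacency.astype(float)),
        config,
        pvars,
        training=training,
        rng=rng,
    )
    return float(out.value)
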