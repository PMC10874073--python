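"""Graph learning-convolutional network (GLCN) core.

A GLCN layer replaces the fixed molecular/contact-map adjacency with a
learned row-stochastic *soft adjacency matrix* and propagates node
features through it:

1. graph learning:   ``e_ij = LeakyReLU(w . |v_i - v_j|)``,
   ``A_i = softmax(e_i)`` so every row of ``A`` sums to one and is
   nonnegative;
2. regularizer:      ``L_GL = (1/N^2) sum_ij exp(A_ij + eta * ||v_i - v_j||^2)
   + gamma * ||A||_F^2`` — penalizes large weights between distant nodes
   and is added to the training objective so the graph-learning weights
   do not collapse to zero;
3. pairwise hidden features: ``h_ij = relu(W_vih v_i + W_vjh v_j + b)``;
4. graph convolution: ``v_i' = relu((sum_j A_ij h_ij) W)`` — row i of the
   soft adjacency forms convex-combination weights over the hidden
   vectors of node i.

The soft adjacency is learned over *all* node pairs of a graph (dense);
the fixed bond/contact adjacency is kept in the data model and can be
applied as a mask for ablation (``graph_learning(..., allowed=...)``).

All operations accept an optional leading batch axis and a node-validity
``mask`` so mixed-size graphs can be padded into one batch; padded
positions are excluded from the softmax, the regularizer and pooling, and
batched outputs match per-graph execution to tight tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _k
from .autodiff import Tensor, as_tensor

__all__ = [
    "GLConfig",
    "GLCNLayerParams",
    "GLCNParams",
    "init_glcn_params",
    "graph_learning",
    "graph_learning_loss",
    "pairwise_hidden",
    "graph_conv",
    "glcn_forward",
    "global_pool",
    "glorot",
]

_NEG_BIG = 1e30  # additive mask value: exp(-1e30) underflows to exactly 0


@dataclass
class GLConfig:
    """Hyperparameters of one GLCN branch.

    ``d_model`` is the embedding width, ``n_layers`` the number of stacked
    (graph-learning, graph-convolution) blocks, ``eta`` the node-distance
    balance in the regularizer, ``gamma`` the Frobenius trade-off,
    ``leaky_slope`` the negative slope of the LeakyReLU used in graph
    learning, and ``pool`` the graph-level readout.
    """

    d_model: int = 128
    n_layers: int = 2
    eta: float = 1.0
    gamma: float = 1.0
    leaky_slope: float = 0.01
    pool: str = "max"

    def __post_init__(self):
        if self.d_model < 1 or self.n_layers < 1:
            raise ValueError("d_model and n_layers must be >= 1")
        if self.eta < 0 or self.gamma < 0:
            raise ValueError("eta and gamma must be nonnegative")
        if self.pool not in ("max", "mean"):
            raise ValueError(f"pool must be 'max' or 'mean', got {self.pool!r}")


@dataclass
class GLCNLayerParams:
    """Learnable tensors of one layer: w (graph learning), W_vih / W_vjh / b
    (pairwise hidden features), W (convolution)."""

    w: Tensor
    W_vih: Tensor
    W_vjh: Tensor
    b: Tensor
    W: Tensor

    def named(self, prefix: str) -> dict[str, Tensor]:
        return {
            f"{prefix}.w": self.w,
            f"{prefix}.W_vih": self.W_vih,
            f"{prefix}.W_vjh": self.W_vjh,
            f"{prefix}.b": self.b,
            f"{prefix}.W": self.W,
        }


@dataclass
class GLCNParams:
    """Input projection plus the per-layer parameter stacks of one branch."""

    W_in: Tensor
    b_in: Tensor
    layers: list[GLCNLayerParams] = field(default_factory=list)

    def named(self, prefix: str) -> dict[str, Tensor]:
        out = {f"{prefix}.W_in": self.W_in, f"{prefix}.b_in": self.b_in}
        for i, layer in enumerate(self.layers):
            out.update(layer.named(f"{prefix}.layer{i}"))
        return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    """Uniform Glorot-style initialization, seed-controlled."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def init_glcn_params(in_dim: int, config: GLConfig, rng: np.random.Generator) -> GLCNParams:
    d = config.d_model
    params = GLCNParams(
        W_in=glorot(rng, in_dim, d, (in_dim, d)),
        b_in=Tensor(np.zeros(d), requires_grad=True),
    )
    for _ in range(config.n_layers):
        params.layers.append(
            GLCNLayerParams(
                w=glorot(rng, d, 1, (d,)),
                W_vih=glorot(rng, d, d, (d, d)),
                W_vjh=glorot(rng, d, d, (d, d)),
                b=Tensor(np.zeros(d), requires_grad=True),
                W=glorot(rng, d, d, (d, d)),
            )
        )
    return params


# ---------------------------------------------------------------------------
# shape helpers


def _check_nodes(V: Tensor) -> int:
    if V.ndim < 2:
        raise ValueError(f"node matrix must be at least 2-D, got shape {V.shape}")
    n = V.shape[-2]
    if n == 0:
        raise ValueError("graph has no nodes")
    return n


def _pair_views(V: Tensor) -> tuple[Tensor, Tensor]:
    """Reshape (..., N, d) into broadcastable (..., N, 1, d) / (..., 1, N, d)."""
    *lead, n, d = V.shape
    vi = V.reshape(*lead, n, 1, d)
    vj = V.reshape(*lead, 1, n, d)
    return vi, vj


def _mask_arrays(mask, n: int):
    """Return (row, col, pair) float masks shaped for (..., N, N) tensors."""
    m = np.asarray(mask, dtype=np.float64)
    if m.shape[-1] != n:
        raise ValueError(f"mask last axis {m.shape[-1]} != node count {n}")
    col = np.expand_dims(m, -2)  # (..., 1, N)
    row = np.expand_dims(m, -1)  # (..., N, 1)
    return row, col, row * col


# ---------------------------------------------------------------------------
# fused pairwise kernels
#
# The (N, N, d) intermediates of graph learning and pairwise convolution
# dominate memory and memory traffic.  These custom tape nodes call the
# compiled loops in ``_kernels`` so nothing larger than N x N is ever
# materialized.  Each is verified against the composed reference
# operations in the test suite.


def _abs_dist_dot(V: Tensor, w: Tensor) -> Tensor:
    """e_raw[..., i, j] = sum_d w_d |V_i,d - V_j,d| via the compiled kernel."""
    Vd, wd = V.data, w.data
    *lead, n, d = Vd.shape
    V3 = np.ascontiguousarray(Vd.reshape(-1, n, d))
    w1 = np.ascontiguousarray(wd)
    out_data = _k.abs_dist_dot_fwd(V3, w1).reshape(*lead, n, n)

    def backward(g: np.ndarray) -> None:
        gV, gw = _k.abs_dist_dot_bwd(V3, w1, np.ascontiguousarray(g.reshape(-1, n, n)))
        if V.requires_grad:
            V._accumulate(gV.reshape(Vd.shape))
        if w.requires_grad:
            w._accumulate(gw)

    return Tensor._from_op(out_data, (V, w), backward)


def _pairwise_sqdist(V: Tensor) -> Tensor:
    """d2[..., i, j] = ||V_i - V_j||^2 without retaining the diff tensor."""
    Vd = V.data
    sq = (Vd**2).sum(axis=-1)
    gram = Vd @ np.swapaxes(Vd, -1, -2)
    out_data = np.expand_dims(sq, -1) + np.expand_dims(sq, -2) - 2.0 * gram
    np.maximum(out_data, 0.0, out=out_data)  # clip fp negatives

    def backward(g: np.ndarray) -> None:
        if not V.requires_grad:
            return
        gs = g + np.swapaxes(g, -1, -2)  # symmetrize the pair gradient
        row = gs.sum(axis=-1)  # (..., N)
        V._accumulate(2.0 * (row[..., None] * Vd - gs @ Vd))

    return Tensor._from_op(out_data, (V,), backward)


def _fused_pair_conv(A: Tensor, P: Tensor, Qb: Tensor) -> Tensor:
    """M[..., i, :] = sum_j A_ij relu(P_i + Qb_j) without tape bloat.

    The hidden stack H = relu(P_i + Qb_j) is computed once, kept for
    backward, and overwritten in place there; the tape never holds more
    than one (..., N, N, d) buffer per layer.
    """
    Ad, Pd, Qd = A.data, P.data, Qb.data
    *lead, n, d = Pd.shape
    A3 = np.ascontiguousarray(Ad.reshape(-1, n, n))
    P3 = np.ascontiguousarray(Pd.reshape(-1, n, d))
    Q3 = np.ascontiguousarray(Qd.reshape(-1, n, d))
    out_data = _k.pair_conv_fwd(A3, P3, Q3).reshape(*lead, n, d)

    def backward(g: np.ndarray) -> None:
        gA, gP, gQ = _k.pair_conv_bwd(A3, P3, Q3, np.ascontiguousarray(g.reshape(-1, n, d)))
        if A.requires_grad:
            A._accumulate(gA.reshape(Ad.shape))
        if P.requires_grad:
            P._accumulate(gP.reshape(Pd.shape))
        if Qb.requires_grad:
            Qb._accumulate(gQ.reshape(Qd.shape))

    return Tensor._from_op(out_data, (A, P, Qb), backward)


# ---------------------------------------------------------------------------
# core operations


def graph_learning(
    V,
    w,
    leaky_slope: float = 0.01,
    mask=None,
    allowed=None,
) -> Tensor:
    """Learn the soft adjacency matrix from node features.

    ``e_ij = LeakyReLU(w . |v_i - v_j|)`` followed by a row-wise softmax,
    yielding a matrix whose rows are nonnegative and sum to one.

    Parameters
    ----------
    V : (..., N, d) node features.
    w : (d,) graph-learning weight vector, shared across nodes.
    mask : optional (..., N) validity indicator for padded batches; invalid
        columns are excluded from each softmax and invalid rows come out
        all-zero.
    allowed : optional (..., N, N) binary matrix restricting the softmax
        support to a fixed adjacency (ablation switch); by default the
        support is all node pairs.
    """
    V = as_tensor(V)
    w = as_tensor(w)
    n = _check_nodes(V)
    if w.shape != (V.shape[-1],):
        raise ValueError(f"w must have shape ({V.shape[-1]},), got {w.shape}")
    e = _abs_dist_dot(V, w).leaky_relu(leaky_slope)  # (..., N, N)

    bias = np.zeros(e.shape)
    if allowed is not None:
        bias = bias - _NEG_BIG * (1.0 - np.asarray(allowed, dtype=np.float64))
    if mask is not None:
        _, col, _ = _mask_arrays(mask, n)
        bias = bias - _NEG_BIG * (1.0 - col)
    e = e + Tensor(bias)

    shift = Tensor(e.data.max(axis=-1, keepdims=True))  # detached, grad-free
    num = (e - shift).exp()
    if mask is not None:
        row, _, pair = _mask_arrays(mask, n)
        num = num * Tensor(pair)  # zero both padded rows and padded columns
        denom = num.sum(axis=-1, keepdims=True) + Tensor(1.0 - row)
    else:
        denom = num.sum(axis=-1, keepdims=True)
    return num / denom


def graph_learning_loss(A, V, eta: float = 1.0, gamma: float = 1.0, mask=None) -> Tensor:
    """Regularizer of the learned soft adjacency.

    ``(1/N^2) sum_ij exp(A_ij + eta * ||v_i - v_j||^2_2) + gamma * ||A||_F^2``

    Returns a scalar for unbatched input, else one loss per graph with
    ``N`` the per-graph valid node count.  Differentiable in both ``A``
    and ``V``.
    """
    A = as_tensor(A)
    V = as_tensor(V)
    n = _check_nodes(V)
    if A.shape[-2:] != (n, n) or A.shape[:-2] != V.shape[:-2]:
        raise ValueError(f"adjacency shape {A.shape} inconsistent with nodes {V.shape}")
    d2 = _pairwise_sqdist(V)  # (..., N, N)
    exponent = A + eta * d2
    if mask is None:
        n_eff = float(n)
        term = exponent.exp().sum(axis=-1).sum(axis=-1)
    else:
        _, _, pair = _mask_arrays(mask, n)
        pair_t = Tensor(pair)
        # mask inside the exponent first so padded distances cannot overflow
        term = ((exponent * pair_t).exp() * pair_t).sum(axis=-1).sum(axis=-1)
        n_eff = np.asarray(mask, dtype=np.float64).sum(axis=-1)
    frob = A.square().sum(axis=-1).sum(axis=-1)
    return term * (1.0 / n_eff**2) + gamma * frob


def pairwise_hidden(V, params: GLCNLayerParams) -> Tensor:
    """Hidden features for every ordered node pair.

    ``h_ij = relu(W_vih v_i + W_vjh v_j + b)`` returned as an
    (..., N, N, d) stack.
    """
    V = as_tensor(V)
    n = _check_nodes(V)
    d = V.shape[-1]
    if params.W_vih.shape != (d, d) or params.W_vjh.shape != (d, d):
        raise ValueError("weight matrices must be (d, d) matching node width")
    P = V @ params.W_vih.swapaxes(-1, -2)  # rows: (W_vih v_i)^T
    Q = V @ params.W_vjh.swapaxes(-1, -2)
    *lead, _, _ = V.shape
    pi = P.reshape(*lead, n, 1, d)
    qj = Q.reshape(*lead, 1, n, d)
    return (pi + qj + params.b).relu()


def graph_conv(A, H, W) -> Tensor:
    """Aggregate pairwise hidden features under the soft adjacency.

    ``v_i' = relu((sum_j A_ij h_ij) W)``: row i of ``A`` weights the N
    hidden vectors of node i before the shared linear map.
    """
    A = as_tensor(A)
    H = as_tensor(H)
    W = as_tensor(W)
    if H.ndim < 3 or A.shape != H.shape[:-1]:
        raise ValueError(f"adjacency {A.shape} inconsistent with hidden {H.shape}")
    d = H.shape[-1]
    if W.shape != (d, d):
        raise ValueError(f"W must be ({d}, {d}), got {W.shape}")
    *lead, n, _, _ = H.shape
    weighted = (A.reshape(*lead, n, n, 1) * H).sum(axis=-2)  # (..., N, d)
    return (weighted @ W).relu()


def glcn_forward(
    X,
    params: GLCNParams,
    config: GLConfig,
    mask=None,
) -> tuple[Tensor, Tensor]:
    """Run the full branch: input projection, then stacked GLCN layers.

    Returns the final node embeddings (..., N, d_model) and the
    graph-learning loss summed over layers (scalar, or per-graph vector
    for batched input).  The fixed input adjacency is not consumed here:
    the soft adjacency is learned over all pairs.
    """
    X = as_tensor(X)
    if X.shape[-1] != params.W_in.shape[0]:
        raise ValueError(
            f"input feature width {X.shape[-1]} != projection rows {params.W_in.shape[0]}"
        )
    V = X @ params.W_in + params.b_in
    gl_total: Tensor | None = None
    for layer in params.layers:
        A = graph_learning(V, layer.w, config.leaky_slope, mask=mask)
        loss = graph_learning_loss(A, V, config.eta, config.gamma, mask=mask)
        gl_total = loss if gl_total is None else gl_total + loss
        # fused equivalent of graph_conv(A, pairwise_hidden(V, layer), W):
        # the bias folds into the j-side projection, and the N x N x d
        # hidden stack is never retained
        P = V @ layer.W_vih.swapaxes(-1, -2)
        Qb = V @ layer.W_vjh.swapaxes(-1, -2) + layer.b
        V = (_fused_pair_conv(A, P, Qb) @ layer.W).relu()
    assert gl_total is not None
    return V, gl_total


def global_pool(V, mode: str = "max", mask=None) -> Tensor:
    """Graph-level readout: coordinatewise max (default) or mean over nodes."""
    V = as_tensor(V)
    n = _check_nodes(V)
    if mode not in ("max", "mean"):
        raise ValueError(f"unknown pooling mode {mode!r}")
    if mask is None:
        if mode == "max":
            return V.amax(axis=-2)
        return V.mean(axis=-2)
    m = np.asarray(mask, dtype=np.float64)
    if np.any(m.sum(axis=-1) < 1):
        raise ValueError("every graph in the batch must have at least one node")
    m_col = np.expand_dims(m, -1)  # (..., N, 1)
    if mode == "max":
        neg = Tensor(-_NEG_BIG * (1.0 - m_col))
        return (V + neg).amax(axis=-2)
    total = (V * Tensor(m_col)).sum(axis=-2)
    return total * Tensor(1.0 / m.sum(axis=-1, keepdims=True))
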