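"""Compiled inner loops for the pairwise GLCN operations.

The graph-learning distance statistic and the pairwise convolution touch
every (node i, node j, channel) triple; materializing those N x N x d
stacks in numpy is memory-bound.  These numba kernels fuse the loops so
nothing larger than N x N is ever allocated.  They are pure functions of
their inputs and are verified against the composed numpy reference
operations in the test suite.

All arrays are C-contiguous float64 with an explicit leading batch axis.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def abs_dist_dot_fwd(V: np.ndarray, w: np.ndarray) -> np.ndarray:
    """e[b, i, j] = sum_k w[k] * |V[b, i, k] - V[b, j, k]| (symmetric)."""
    B, n, d = V.shape
    out = np.zeros((B, n, n))
    for b in range(B):
        for i in range(n):
            for j in range(i + 1, n):
                s = 0.0
                for k in range(d):
                    s += w[k] * abs(V[b, i, k] - V[b, j, k])
                out[b, i, j] = s
                out[b, j, i] = s
    return out


@njit(cache=False)
def abs_dist_dot_bwd(
    V: np.ndarray, w: np.ndarray, ge: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of abs_dist_dot_fwd w.r.t. V and w given d(out) = ge."""
    B, n, d = V.shape
    gV = np.zeros((B, n, d))
    gw = np.zeros(d)
    for b in range(B):
        for i in range(n):
            for j in range(n):
                g = ge[b, i, j]
                if g == 0.0 or i == j:
                    continue
                for k in range(d):
                    diff = V[b, i, k] - V[b, j, k]
                    sgn = 1.0 if diff > 0.0 else (-1.0 if diff < 0.0 else 0.0)
                    gw[k] += g * sgn * diff
                    t = g * w[k] * sgn
                    gV[b, i, k] += t
                    gV[b, j, k] -= t
    return gV, gw


@njit(cache=False)
def pair_conv_fwd(A: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """out[b, i, :] = sum_j A[b, i, j] * relu(P[b, i, :] + Q[b, j, :])."""
    B, n, d = P.shape
    out = np.zeros((B, n, d))
    for b in range(B):
        for i in range(n):
            for j in range(n):
                a = A[b, i, j]
                if a == 0.0:
                    continue
                for k in range(d):
                    pre = P[b, i, k] + Q[b, j, k]
                    if pre > 0.0:
                        out[b, i, k] += a * pre
    return out


@njit(cache=False)
def pair_conv_bwd(
    A: np.ndarray, P: np.ndarray, Q: np.ndarray, gout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of pair_conv_fwd w.r.t. A, P and Q."""
    B, n, d = P.shape
    gA = np.zeros((B, n, n))
    gP = np.zeros((B, n, d))
    gQ = np.zeros((B, n, d))
    for b in range(B):
        for i in range(n):
            for j in range(n):
                a = A[b, i, j]
                s = 0.0
                for k in range(d):
                    pre = P[b, i, k] + Q[b, j, k]
                    if pre > 0.0:
                        g = gout[b, i, k]
                        s += g * pre
                        t = a * g
                        gP[b, i, k] += t
                        gQ[b, j, k] += t
                gA[b, i, j] = s
    return gA, gP, gQ
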