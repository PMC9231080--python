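"""Fused numerical kernels for the network's bandwidth-bound steps.

The convolutions are BLAS matrix products; what remains (batch-norm
backward, 2x2 max pooling, the SGD/Nesterov parameter update) is
memory-bandwidth bound in pure NumPy because each expression walks the
arrays several times.  These numba kernels fuse each step into one or two
passes.  All array arguments are float32, channels-last and C-contiguous.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sgd_nesterov_step", "bn_backward", "maxpool2x2_forward", "maxpool2x2_backward"]


@njit(cache=True, fastmath=True)
def sgd_nesterov_step(p, v, g, lr, mu):
    """v <- mu*v - lr*g;  p <- p + mu*v - lr*g   (flattened views)."""
    for i in range(p.size):
        vn = mu * v[i] - lr * g[i]
        v[i] = vn
        p[i] += mu * vn - lr * g[i]


@njit(cache=True, fastmath=True)
def sgd_momentum_step(p, v, g, lr, mu):
    for i in range(p.size):
        vn = mu * v[i] - lr * g[i]
        v[i] = vn
        p[i] += vn


@njit(cache=True, fastmath=True)
def bn_backward(x2, g2, mean, inv, gamma):
    """Training-mode batch-norm gradient for x flattened to (M, C).

    Returns (dx, dgamma, dbeta); two passes over the data.
    """
    m, c = x2.shape
    s1 = np.zeros(c, dtype=x2.dtype)  # sum g*xhat
    s2 = np.zeros(c, dtype=x2.dtype)  # sum g
    for i in range(m):
        for j in range(c):
            xh = (x2[i, j] - mean[j]) * inv[j]
            s1[j] += g2[i, j] * xh
            s2[j] += g2[i, j]
    dx = np.empty_like(x2)
    for i in range(m):
        for j in range(c):
            xh = (x2[i, j] - mean[j]) * inv[j]
            dx[i, j] = (
                inv[j] * gamma[j] * (g2[i, j] - s2[j] / m - xh * s1[j] / m)
            )
    return dx, s1, s2


@njit(cache=True, fastmath=True)
def maxpool2x2_forward(x):
    """x (B, H, W, C) -> (out (B, H/2, W/2, C), idx of argmax in {0..3});
    ties resolve to the first element in row-major window order."""
    b, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    out = np.empty((b, h2, w2, c), dtype=x.dtype)
    idx = np.empty((b, h2, w2, c), dtype=np.uint8)
    for n in range(b):
        for i in range(h2):
            for j in range(w2):
                for k in range(c):
                    best = x[n, 2 * i, 2 * j, k]
                    arg = 0
                    v = x[n, 2 * i, 2 * j + 1, k]
                    if v > best:
                        best, arg = v, 1
                    v = x[n, 2 * i + 1, 2 * j, k]
                    if v > best:
                        best, arg = v, 2
                    v = x[n, 2 * i + 1, 2 * j + 1, k]
                    if v > best:
                        best, arg = v, 3
                    out[n, i, j, k] = best
                    idx[n, i, j, k] = arg
    return out, idx


@njit(cache=True, fastmath=True)
def maxpool2x2_backward(g, idx, h, w):
    b, h2, w2, c = g.shape
    dx = np.zeros((b, h, w, c), dtype=g.dtype)
    for n in range(b):
        for i in range(h2):
            for j in range(w2):
                for k in range(c):
                    a = idx[n, i, j, k]
                    dx[n, 2 * i + a // 2, 2 * j + a % 2, k] = g[n, i, j, k]
    return dx


@njit(cache=True, fastmath=True)
def im2col3x3(xp, cols):
    """Gather 3x3 same-padded patches: xp (B, H+2, W+2, C) into
    cols (B, H, W, 9*C), patch-major then channel."""
    b, hp, wp, c = xp.shape
    h, w = hp - 2, wp - 2
    for n in range(b):
        for i in range(h):
            for j in range(w):
                s = 0
                for di in range(3):
                    for dj in range(3):
                        for k in range(c):
                            cols[n, i, j, s + k] = xp[n, i + di, j + dj, k]
                        s += c
    return cols


@njit(cache=True, fastmath=True)
def col2im3x3(dcols, dxp):
    """Scatter-add the adjoint of im2col3x3: dcols (B, H, W, 9*C) into
    dxp (B, H+2, W+2, C)."""
    b, h, w, _ = dcols.shape
    c = dxp.shape[3]
    for n in range(b):
        for i in range(h):
            for j in range(w):
                s = 0
                for di in range(3):
                    for dj in range(3):
                        for k in range(c):
                            dxp[n, i + di, j + dj, k] += dcols[n, i, j, s + k]
                        s += c
    return dxp
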