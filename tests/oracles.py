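"""Naive loop-based reference implementations used as independent oracles.

Everything here is written with explicit Python loops over scalar indices,
deliberately sharing no code with the package's vectorised/autograd paths.
"""

from __future__ import annotations

import numpy as np


def naive_z_pool(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    out = np.zeros((n, 2, h, w), dtype=np.float64)
    for b in range(n):
        for i in range(h):
            for j in range(w):
                vals = [x[b, ch, i, j] for ch in range(c)]
                out[b, 0, i, j] = max(vals)
                out[b, 1, i, j] = sum(vals) / c
    return out


def naive_conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
                 stride: int = 1, pad: int = 0) -> np.ndarray:
    n, cin, h, wid = x.shape
    cout, _, kh, kw = w.shape
    xp = np.zeros((n, cin, h + 2 * pad, wid + 2 * pad), dtype=np.float64)
    xp[:, :, pad:pad + h, pad:pad + wid] = x
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wid + 2 * pad - kw) // stride + 1
    out = np.zeros((n, cout, ho, wo), dtype=np.float64)
    for bi in range(n):
        for co in range(cout):
            for oi in range(ho):
                for oj in range(wo):
                    acc = 0.0
                    for ci in range(cin):
                        for ki in range(kh):
                            for kj in range(kw):
                                acc += xp[bi, ci, oi * stride + ki,
                                          oj * stride + kj] * w[co, ci, ki, kj]
                    out[bi, co, oi, oj] = acc + (0.0 if b is None else b[co])
    return out


def naive_sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def naive_triplet(x: np.ndarray, convs: list[tuple[np.ndarray, np.ndarray]],
                  pad: int) -> np.ndarray:
    """convs = [(w_h, b_h), (w_w, b_w), (w_c, b_c)] for the three branches."""
    perms = [(0, 3, 2, 1), (0, 2, 1, 3), None]
    branches = []
    for (w, b), perm in zip(convs, perms):
        t = x if perm is None else x.transpose(perm)
        gate = naive_sigmoid(naive_conv2d(naive_z_pool(t), w, b, pad=pad))
        y = t * gate
        branches.append(y if perm is None else y.transpose(perm))
    return (branches[0] + branches[1] + branches[2]) / 3.0


def naive_channel_gate(x: np.ndarray, w1: np.ndarray, b1: np.ndarray,
                       w2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """sigma(W2 relu(W1 gap + b1) + b2 + W2 relu(W1 gmp + b1) + b2).

    Weight layout matches rtcb.nn.Linear: y = x @ W + b.
    """
    n, c, h, w = x.shape
    gap = x.mean(axis=(2, 3))
    gmp = x.max(axis=(2, 3))
    def mlp(v):
        return np.maximum(v @ w1 + b1, 0.0) @ w2 + b2
    return naive_sigmoid(mlp(gap) + mlp(gmp))


def naive_partial_conv(x: np.ndarray, w: np.ndarray, c_p: int,
                       pad: int) -> np.ndarray:
    head = naive_conv2d(x[:, :c_p], w, None, pad=pad)
    return np.concatenate([head, x[:, c_p:]], axis=1)
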