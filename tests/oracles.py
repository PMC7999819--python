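"""Independent scalar-loop reference implementations of the attention blocks.

These deliberately avoid the package's autodiff ops: every computation is an
explicit per-pixel / per-channel python loop over float64 numpy scalars, so
they serve as independent oracles for the vectorized implementations.
"""

import numpy as np

BN_EPS = 1e-5


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def conv1x1_loop(x, weight, bias=None):
    """x (N,C,H,W), weight (Cout,Cin,1,1) -> (N,Cout,H,W), explicit loops."""
    n, c, h, w = x.shape
    cout = weight.shape[0]
    out = np.zeros((n, cout, h, w))
    for b in range(n):
        for o in range(cout):
            for i in range(h):
                for j in range(w):
                    acc = 0.0
                    for ci in range(c):
                        acc += weight[o, ci, 0, 0] * x[b, ci, i, j]
                    if bias is not None:
                        acc += bias[o]
                    out[b, o, i, j] = acc
    return out


def conv3x3_loop(x, weight, bias=None):
    """3x3 cross-correlation with zero padding 1, explicit loops."""
    n, c, h, w = x.shape
    cout = weight.shape[0]
    out = np.zeros((n, cout, h, w))
    for b in range(n):
        for o in range(cout):
            for i in range(h):
                for j in range(w):
                    acc = 0.0 if bias is None else float(bias[o])
                    for ci in range(c):
                        for di in range(3):
                            for dj in range(3):
                                ii, jj = i + di - 1, j + dj - 1
                                if 0 <= ii < h and 0 <= jj < w:
                                    acc += weight[o, ci, di, dj] * x[b, ci, ii, jj]
                    out[b, o, i, j] = acc
    return out


def conv_transpose2x2_loop(x, weight, bias=None):
    """2x2 stride-2 transpose convolution, explicit loops.

    weight (Cin, Cout, 2, 2); output (N, Cout, 2H, 2W).
    """
    n, cin, h, w = x.shape
    cout = weight.shape[1]
    out = np.zeros((n, cout, 2 * h, 2 * w))
    for b in range(n):
        for ci in range(cin):
            for o in range(cout):
                for i in range(h):
                    for j in range(w):
                        for di in range(2):
                            for dj in range(2):
                                out[b, o, 2 * i + di, 2 * j + dj] += (
                                    weight[ci, o, di, dj] * x[b, ci, i, j])
    if bias is not None:
        for o in range(cout):
            out[:, o] += bias[o]
    return out


def bn_eval_loop(x, gamma, beta, running_mean, running_var, eps=BN_EPS):
    """Eval-mode batch norm with the given statistics, per element."""
    out = np.zeros_like(x, dtype=np.float64)
    n, c, h, w = x.shape
    for b in range(n):
        for ci in range(c):
            inv = 1.0 / np.sqrt(running_var[ci] + eps)
            for i in range(h):
                for j in range(w):
                    out[b, ci, i, j] = gamma[ci] * (x[b, ci, i, j] - running_mean[ci]) * inv + beta[ci]
    return out


def attention_gate_loop(x, g, wx, wg, bg, psi, bpsi):
    """Per-pixel additive attention: alpha and gated skip features.

    wx (F_int, F_l, 1, 1), wg (F_int, F_g, 1, 1), psi (1, F_int, 1, 1).
    """
    n, fl, h, w = x.shape
    f_int = wx.shape[0]
    alpha = np.zeros((n, 1, h, w))
    for b in range(n):
        for i in range(h):
            for j in range(w):
                q = 0.0
                for f in range(f_int):
                    pre = bg[f]
                    for c in range(fl):
                        pre += wx[f, c, 0, 0] * x[b, c, i, j]
                    for c in range(g.shape[1]):
                        pre += wg[f, c, 0, 0] * g[b, c, i, j]
                    q += psi[0, f, 0, 0] * max(pre, 0.0)
                alpha[b, 0, i, j] = sigmoid(q + bpsi[0])
    gated = x * alpha
    return gated, alpha


def spatial_attention_loop(x, w1, b1, gamma, beta, rmean, rvar, w2, b2):
    """Conv1x1 -> eval BN -> ReLU -> conv1x1 -> sigmoid -> channel stacking."""
    t = conv1x1_loop(x, w1, b1)
    t = bn_eval_loop(t, gamma, beta, rmean, rvar)
    t = np.maximum(t, 0.0)
    mask = sigmoid(conv1x1_loop(t, w2, b2))  # (N,1,H,W)
    return np.repeat(mask, x.shape[1], axis=1)


def channel_squeeze_loop(y):
    """Explicit double-sum global average pooling: (N,F,H,W) -> (N,F)."""
    n, f, h, w = y.shape
    s = np.zeros((n, f))
    for b in range(n):
        for c in range(f):
            acc = 0.0
            for m in range(h):
                for nn in range(w):
                    acc += y[b, c, m, nn]
            s[b, c] = acc / (h * w)
    return s


def channel_excite_loop(z, w1, b1, w2, b2):
    """sigmoid(S2 relu(S1 z)) with dense matrix-vector loops; w (in, out)."""
    n, f = z.shape
    hidden = w1.shape[1]
    cs = np.zeros((n, f))
    for b in range(n):
        hid = np.zeros(hidden)
        for o in range(hidden):
            acc = b1[o]
            for i in range(f):
                acc += z[b, i] * w1[i, o]
            hid[o] = max(acc, 0.0)
        for o in range(f):
            acc = b2[o]
            for i in range(hidden):
                acc += hid[i] * w2[i, o]
            cs[b, o] = sigmoid(acc)
    return cs


def fuse_loop(fc, fs):
    out = np.zeros_like(fc)
    it = np.nditer(fc, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = fc[idx] * (fs[idx] + 1.0)
    return out
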