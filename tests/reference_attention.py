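"""Independent loop-based reference for every attention mechanism.

Deliberately naive: explicit Python loops, explicit softmax, no shared code
with the package (only numpy arrays as containers).  Used as the oracle the
vectorised implementations must match on small instances.
"""

import math

import numpy as np


def mm(a, b):
    """Loop matrix product."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = np.zeros((a.shape[0], b.shape[1]))
    for i in range(a.shape[0]):
        for j in range(b.shape[1]):
            s = 0.0
            for k in range(a.shape[1]):
                s += a[i, k] * b[k, j]
            out[i, j] = s
    return out


def softmax_row(row):
    m = max(row)
    e = [math.exp(v - m) for v in row]
    z = sum(e)
    return [v / z for v in e]


def sdpa(Q, K, V):
    """Scaled dot-product attention for one head, loops only."""
    T, dk = Q.shape
    Tk = K.shape[0]
    W = np.zeros((T, Tk))
    for t in range(T):
        scores = [sum(Q[t, d] * K[j, d] for d in range(dk)) / math.sqrt(dk) for j in range(Tk)]
        W[t] = softmax_row(scores)
    out = np.zeros((T, V.shape[1]))
    for t in range(T):
        for d in range(V.shape[1]):
            out[t, d] = sum(W[t, j] * V[j, d] for j in range(Tk))
    return out, W


def split(M, num_heads):
    d = M.shape[1] // num_heads
    return [M[:, h * d : (h + 1) * d] for h in range(num_heads)]


def heads_attend(Q, K, V, num_heads):
    outs, weights = [], []
    for qh, kh, vh in zip(split(Q, num_heads), split(K, num_heads), split(V, num_heads)):
        o, w = sdpa(qh, kh, vh)
        outs.append(o)
        weights.append(w)
    return np.concatenate(outs, axis=1), np.stack(weights)


def ref_mha(H, p, num_heads):
    Q, K, V = mm(H, p.w_q), mm(H, p.w_k), mm(H, p.w_v)
    concat, W = heads_attend(Q, K, V, num_heads)
    return mm(concat, p.w_o), W


def ref_hierarchical(H, params, num_heads):
    out, W = ref_mha(H, params[0], num_heads)
    K1, V1 = mm(H, params[0].w_k), mm(H, params[0].w_v)
    for p in params[1:]:
        Q = mm(out, p.w_q)
        concat, W = heads_attend(Q, K1, V1, num_heads)
        out = mm(concat, p.w_o)
    return out, W


def ref_cross(H, K_ext, V_ext, p, num_heads, add_self=False):
    Q = mm(H, p.w_q)
    concat, W = heads_attend(Q, np.asarray(K_ext, float), np.asarray(V_ext, float), num_heads)
    out = mm(concat, p.w_o)
    if add_self:
        out = out + ref_mha(H, p, num_heads)[0]
    return out, W


def ref_feature_enhanced(H, F, params, num_heads):
    out = np.asarray(H, dtype=float)
    W = None
    for p in params:
        f_prime = mm(F, p.w_f)
        Q = mm(out, p.w_q) + f_prime
        K = mm(out, p.w_k) + f_prime
        V = mm(out, p.w_v) + f_prime
        concat, W = heads_attend(Q, K, V, num_heads)
        out = mm(concat, p.w_o)
    return out, W
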