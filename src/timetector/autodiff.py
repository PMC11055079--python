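"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in :mod:`timetector.model` is small (hidden width 64, windows of
24 steps) and trains on a single CPU, so rather than depending on a deep
learning framework the package carries a compact tape-based autodiff engine:
a :class:`Tensor` wraps an ``ndarray`` and records a closure that propagates
the upstream gradient to its parents.  Only the operations the model needs
are implemented.  Recurrent layers get a fused :func:`lstm` primitive with a
hand-written backward pass — the sequential loop would otherwise dominate
the tape with thousands of tiny nodes.

The default working dtype is float32 — the conventional precision for this
class of model, and twice the throughput of float64 on the training loop —
but float64 inputs are preserved, so analysis code that wants full precision
(e.g. checking an attention identity) simply passes float64 arrays.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32

__all__ = ["Tensor", "DTYPE", "astensor", "concat", "stack", "lstm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(DTYPE)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray, own: bool = False) -> None:
        """Add ``g`` into the gradient; ``own=True`` promises ``g`` is a
        freshly allocated array this node may keep without copying."""
        dt = self.data.dtype
        if self.grad is None:
            if g.dtype != dt:
                self.grad = g.astype(dt)
            else:
                self.grad = g if own else g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, expanded = stack_.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            # plain python scalars stay weakly typed: no dtype promotion
            # (float() also strips strongly-typed numpy scalars)
            other = float(other)
            out = Tensor(self.data + other, parents=(self,))
            if out.requires_grad:
                out._backward = lambda g, a=self: a._accum(g)
            return out
        other = astensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g, b.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g, own=True)
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        other = astensor(other)
        out = Tensor(self.data - other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(-g, b.data.shape))
            out._backward = bwd
        return out

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return astensor(other) - self

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            other = float(other)
            out = Tensor(self.data * other, parents=(self,))
            if out.requires_grad:
                out._backward = lambda g, a=self, s=other: a._accum(g * s, own=True)
            return out
        other = astensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g * b.data, a.data.shape), own=True)
                if b.requires_grad:
                    b._accum(_unbroadcast(g * a.data, b.data.shape), own=True)
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = astensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g / b.data, a.data.shape), own=True)
                if b.requires_grad:
                    b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape), own=True)
            out._backward = bwd
        return out

    def __matmul__(self, other):
        other = astensor(other)
        a_d, b_d = self.data, other.data
        # (..., T, p) @ (p, q): collapse the leading axes into one GEMM
        # instead of letting numpy loop small per-batch products
        if a_d.ndim > 2 and b_d.ndim == 2:
            lead = a_d.shape[:-1]
            y = (a_d.reshape(-1, a_d.shape[-1]) @ b_d).reshape(*lead, b_d.shape[1])
            out = Tensor(y, parents=(self, other))
            if out.requires_grad:
                def bwd(g, a=self, b=other):
                    g2 = g.reshape(-1, g.shape[-1])
                    if a.requires_grad:
                        a._accum((g2 @ b.data.T).reshape(a.data.shape), own=True)
                    if b.requires_grad:
                        b._accum(a.data.reshape(-1, a.data.shape[-1]).T @ g2, own=True)
                out._backward = bwd
            return out
        out = Tensor(a_d @ b_d, parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.data.shape), own=True)
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.data.shape), own=True)
            out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            def bwd(g, a=self, idx=idx):
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full, own=True)
            out._backward = bwd
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    def swapaxes(self, ax1: int, ax2: int):
        out = Tensor(np.swapaxes(self.data, ax1, ax2), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(np.swapaxes(g, ax1, ax2))
        return out

    def repeat_steps(self, length: int):
        """Tile a (N, D) tensor into (N, length, D) — the Repeat layer."""
        out = Tensor(
            np.broadcast_to(self.data[:, None, :], (self.data.shape[0], length, self.data.shape[1])).copy(),
            parents=(self,),
        )
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.sum(axis=1), own=True)
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def bwd(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy(), own=True)
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * (1.0 - y * y), own=True)
        return out

    def sigmoid(self):
        y = _sigmoid(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * y * (1.0 - y), own=True)
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * (a.data > 0), own=True)
        return out

    def square(self):
        out = Tensor(self.data * self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * 2.0 * a.data, own=True)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * 0.5 / y, own=True)
        return out

    def softmax(self):
        """Row softmax over the last axis (fused forward/backward)."""
        x = self.data
        m = x.max(axis=-1, keepdims=True)
        e = np.exp(x - m)
        y = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            def bwd(g, a=self, y=y):
                dot = (g * y).sum(axis=-1, keepdims=True)
                a._accum(y * (g - dot), own=True)
            out._backward = bwd
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # direct formula; exp overflow saturates harmlessly to 0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bwd(g, ts=tensors, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bwd
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        def bwd(g, ts=tensors, axis=axis):
            for i, t in enumerate(ts):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis), own=True)
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Fused LSTM primitive
# ---------------------------------------------------------------------------

# The sequential time loop is the one place where numpy dispatch overhead
# dominates the arithmetic; a numba-compiled kernel removes it when numba
# is available.  The numpy loop below remains the reference/fallback path.
try:
    from numba import njit as _njit

    @_njit(cache=False)
    def _lstm_fwd_jit(xw, w_h, H, ci, cf, co, cg, cc, ctc):  # pragma: no cover
        N, T, D4 = xw.shape
        D = D4 // 4
        h = np.zeros((N, D), dtype=xw.dtype)
        c = np.zeros((N, D), dtype=xw.dtype)
        for t in range(T):
            a = xw[:, t] + np.dot(h, w_h)
            for n in range(N):
                for d in range(D):
                    i = 1.0 / (1.0 + np.exp(-a[n, d]))
                    f = 1.0 / (1.0 + np.exp(-a[n, D + d]))
                    o = 1.0 / (1.0 + np.exp(-a[n, 2 * D + d]))
                    g = np.tanh(a[n, 3 * D + d])
                    cp = c[n, d]
                    cn = f * cp + i * g
                    tc = np.tanh(cn)
                    ci[n, t, d] = i
                    cf[n, t, d] = f
                    co[n, t, d] = o
                    cg[n, t, d] = g
                    cc[n, t, d] = cp
                    ctc[n, t, d] = tc
                    c[n, d] = cn
                    hn = o * tc
                    h[n, d] = hn
                    H[n, t, d] = hn

    @_njit(cache=False)
    def _lstm_bwd_jit(gH, w_hT, ci, cf, co, cg, cc, ctc, dA):  # pragma: no cover
        N, T, D = ci.shape
        dh_next = np.zeros((N, D), dtype=gH.dtype)
        dc_next = np.zeros((N, D), dtype=gH.dtype)
        for t in range(T - 1, -1, -1):
            for n in range(N):
                for d in range(D):
                    i = ci[n, t, d]
                    f = cf[n, t, d]
                    o = co[n, t, d]
                    g = cg[n, t, d]
                    tc = ctc[n, t, d]
                    dh = gH[n, t, d] + dh_next[n, d]
                    do = dh * tc
                    dc = dh * o * (1.0 - tc * tc) + dc_next[n, d]
                    dc_next[n, d] = dc * f
                    dA[t, n, d] = dc * g * i * (1.0 - i)
                    dA[t, n, D + d] = dc * cc[n, t, d] * f * (1.0 - f)
                    dA[t, n, 2 * D + d] = do * o * (1.0 - o)
                    dA[t, n, 3 * D + d] = dc * i * (1.0 - g * g)
            dh_next = np.dot(dA[t], w_hT)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def lstm(x: Tensor, w_x: Tensor, w_h: Tensor, b: Tensor) -> Tensor:
    """Run a standard gated LSTM layer over a (N, T, D_in) sequence.

    Gate order in the stacked weight matrices is (input, forget, output,
    candidate) — the three sigmoid gates first so they share one call; the
    cell follows the classic formulation

        i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)
        f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)
        g_t = tanh  (W_c [h_{t-1}, x_t] + b_c)
        c_t = f_t * c_{t-1} + i_t * g_t
        o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)
        h_t = o_t * tanh(c_t)

    with zero initial state.  Returns the full hidden sequence (N, T, D).
    The input projection ``x @ w_x`` is hoisted out of the time loop into a
    single GEMM, and the whole layer is one tape node with a hand-written
    backward pass.
    """
    N, T, _ = x.data.shape
    D = w_h.data.shape[0]
    xw = x.data.reshape(N * T, x.data.shape[2]) @ w_x.data + b.data  # (N*T, 4D)
    xw = xw.reshape(N, T, 4 * D)
    dt = xw.dtype
    h = np.zeros((N, D), dtype=dt)
    c = np.zeros((N, D), dtype=dt)
    H = np.empty((N, T, D), dtype=dt)
    cache_i = np.empty((N, T, D), dtype=dt)
    cache_f = np.empty((N, T, D), dtype=dt)
    cache_g = np.empty((N, T, D), dtype=dt)
    cache_o = np.empty((N, T, D), dtype=dt)
    cache_c = np.empty((N, T, D), dtype=dt)
    cache_tc = np.empty((N, T, D), dtype=dt)
    if _HAVE_NUMBA:
        _lstm_fwd_jit(xw, w_h.data, H, cache_i, cache_f, cache_o, cache_g, cache_c, cache_tc)
    else:
        for t in range(T):
            a = xw[:, t] + h @ w_h.data
            gates = _sigmoid(a[:, : 3 * D])
            i = gates[:, :D]
            f = gates[:, D : 2 * D]
            o = gates[:, 2 * D :]
            g = np.tanh(a[:, 3 * D :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            H[:, t] = h
            cache_i[:, t] = i
            cache_f[:, t] = f
            cache_g[:, t] = g
            cache_o[:, t] = o
            cache_c[:, t] = c_prev
            cache_tc[:, t] = tc

    out = Tensor(H, parents=(x, w_x, w_h, b))
    if out.requires_grad:
        def bwd(gH):
            w_h_T = np.ascontiguousarray(w_h.data.T)
            dWh = np.zeros_like(w_h.data)
            if _HAVE_NUMBA:
                # time-major buffer keeps the per-step GEMM contiguous
                dA_tm = np.empty((T, N, 4 * D), dtype=dt)
                _lstm_bwd_jit(np.ascontiguousarray(gH), w_h_T, cache_i, cache_f,
                              cache_o, cache_g, cache_c, cache_tc, dA_tm)
                dA = np.ascontiguousarray(dA_tm.swapaxes(0, 1))
            else:
                dA = np.empty((N, T, 4 * D), dtype=dt)
                dh_next = np.zeros((N, D), dtype=dt)
                dc_next = np.zeros((N, D), dtype=dt)
                for t in range(T - 1, -1, -1):
                    i, f, g, o = cache_i[:, t], cache_f[:, t], cache_g[:, t], cache_o[:, t]
                    tc = cache_tc[:, t]
                    dh = gH[:, t] + dh_next
                    do = dh * tc
                    dc = dh * o * (1.0 - tc * tc) + dc_next
                    di = dc * g
                    dg = dc * i
                    df = dc * cache_c[:, t]
                    dc_next = dc * f
                    da = dA[:, t]
                    da[:, :D] = di * i * (1.0 - i)
                    da[:, D : 2 * D] = df * f * (1.0 - f)
                    da[:, 2 * D : 3 * D] = do * o * (1.0 - o)
                    da[:, 3 * D :] = dg * (1.0 - g * g)
                    dh_next = da @ w_h_T
            dA_flat = dA.reshape(N * T, 4 * D)
            if x.requires_grad:
                x._accum((dA_flat @ w_x.data.T).reshape(x.data.shape), own=True)
            if w_x.requires_grad:
                w_x._accum(x.data.reshape(N * T, -1).T @ dA_flat, own=True)
            if w_h.requires_grad:
                # dWh = sum_t h_{t-1}^T da_t, batched into one GEMM
                if T > 1:
                    dWh = H[:, : T - 1].reshape(-1, D).T @ dA[:, 1:].reshape(-1, 4 * D)
                w_h._accum(dWh, own=True)
            if b.requires_grad:
                b._accum(dA_flat.sum(axis=0), own=True)
        out._backward = bwd
    return out
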