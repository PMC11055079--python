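"""Four multi-head attention mechanisms over an encoder hidden sequence.

Given hidden states H = [h_1 ... h_T] (width ``d_model``), queries, keys and
values are linear projections Q = H W_Q, K = H W_K, V = H W_V, split into
``num_heads`` subspaces of depth D_k = d_model / num_heads.  Each head
computes scaled dot-product attention softmax(Q K^T / sqrt(D_k)) V; heads
are concatenated and re-projected by W_O.  On top of that single mechanism
the module provides:

* hierarchical attention — stacked layers where each layer's output becomes
  the next layer's query source while keys and values stay those of the
  first layer;
* cross attention — keys and values come from an external sequence (used
  here with projections of the encoder output itself), optionally summed
  with the standard self-attention output;
* feature-enhanced attention — an auxiliary feature matrix F is projected
  by W_F and added to Q, K and V before scoring; stacked blocks re-add the
  projected features at every layer.

The four outputs are fused by feature-axis concatenation in the fixed order
(MHA, hierarchical, cross, feature-enhanced).  No positional encoding,
dropout or masking is applied anywhere; self-attention is therefore
permutation-equivariant over timesteps.

All functions accept either plain arrays (shape (T, d_model) or batched
(N, T, d_model)) or autodiff :class:`~timetector.autodiff.Tensor` inputs;
the return type follows the input, so the same code path serves both the
public API and the trainable model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import DTYPE, Tensor, astensor, concat

__all__ = [
    "AttentionSpec",
    "AttentionParams",
    "AttentionOutput",
    "project_qkv",
    "split_heads",
    "combine_heads",
    "scaled_dot_attention",
    "multi_head_attention",
    "hierarchical_mha",
    "cross_mha",
    "feature_enhanced_mha",
    "fuse",
]


@dataclass(frozen=True)
class AttentionSpec:
    """Width/head/layer geometry of one attention mechanism."""

    d_model: int = 64
    num_heads: int = 8
    num_layers: int = 0  # 0 means a single application, no stacking

    def __post_init__(self):
        if self.d_model < 1 or self.num_heads < 1 or self.num_layers < 0:
            raise ValueError("d_model, num_heads must be positive; num_layers non-negative")
        if self.d_model % self.num_heads != 0:
            raise ValueError(f"num_heads={self.num_heads} must divide d_model={self.d_model}")

    @property
    def head_depth(self) -> int:
        """D_k = d_model / num_heads (64/8 = 8 at the defaults)."""
        return self.d_model // self.num_heads

    @property
    def effective_layers(self) -> int:
        return max(1, self.num_layers)


@dataclass
class AttentionParams:
    """Trainable projections of one attention layer.

    ``w_f`` is only present for the feature-enhanced variant.  Entries may
    be plain arrays (inference/analysis) or Tensors (training).
    """

    w_q: object
    w_k: object
    w_v: object
    w_o: object
    w_f: object | None = None

    @classmethod
    def init(cls, spec: AttentionSpec, rng: np.random.Generator, d_f: int | None = None) -> "AttentionParams":
        d = spec.d_model

        def glorot(n_in, n_out):
            lim = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-lim, lim, size=(n_in, n_out)).astype(DTYPE)

        return cls(
            w_q=glorot(d, d),
            w_k=glorot(d, d),
            w_v=glorot(d, d),
            w_o=glorot(d, d),
            w_f=glorot(d_f, d) if d_f is not None else None,
        )


@dataclass
class AttentionOutput:
    """Attended sequence plus the (final-layer) per-head weight matrices."""

    values: np.ndarray  # (..., T, d_model)
    weights: np.ndarray  # (..., num_heads, T, T); rows are query positions


def _is_tensor_in(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _ret(x: Tensor, tensor_mode: bool):
    return x if tensor_mode else x.data


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def project_qkv(H, params: AttentionParams):
    """Q = H W_Q, K = H W_K, V = H W_V (plain matrix products)."""
    tensor_mode = _is_tensor_in(H)
    Ht = astensor(H)
    wq, wk, wv = astensor(params.w_q), astensor(params.w_k), astensor(params.w_v)
    if Ht.shape[-1] != wq.shape[0]:
        raise ValueError(f"H has width {Ht.shape[-1]}, projections expect {wq.shape[0]}")
    return tuple(_ret(Ht @ w, tensor_mode) for w in (wq, wk, wv))


def split_heads(M, num_heads: int):
    """(..., T, d_model) -> (..., num_heads, T, D_k) by contiguous partition."""
    tensor_mode = _is_tensor_in(M)
    Mt = astensor(M)
    *lead, T, d = Mt.shape
    if d % num_heads != 0:
        raise ValueError(f"num_heads={num_heads} must divide the model width {d}")
    out = Mt.reshape(*lead, T, num_heads, d // num_heads).swapaxes(-3, -2)
    return _ret(out, tensor_mode)


def combine_heads(M):
    """Inverse of :func:`split_heads`: (..., H, T, D_k) -> (..., T, H*D_k)."""
    tensor_mode = _is_tensor_in(M)
    Mt = astensor(M)
    *lead, h, T, dk = Mt.shape
    out = Mt.swapaxes(-3, -2).reshape(*lead, T, h * dk)
    return _ret(out, tensor_mode)


def scaled_dot_attention(Q_h, K_h, V_h):
    """One head: weights = row-softmax(Q K^T / sqrt(D_k)); output = weights V."""
    tensor_mode = _is_tensor_in(Q_h, K_h, V_h)
    q, k, v = astensor(Q_h), astensor(K_h), astensor(V_h)
    if not (q.requires_grad or k.requires_grad or v.requires_grad):
        # training tensors are validated at the loss; check analysis inputs here
        for t in (q, k, v):
            if not np.all(np.isfinite(t.data)):
                raise ValueError("attention inputs must be finite")
    dk = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
    weights = scores.softmax()
    out = weights @ v
    return _ret(out, tensor_mode), _ret(weights, tensor_mode)


def _attend(q_in: Tensor, k_in: Tensor, v_in: Tensor, params: AttentionParams,
            spec: AttentionSpec, project_kv: bool = True, f_prime: Tensor | None = None,
            precomputed_kv: tuple[Tensor, Tensor] | None = None):
    """Shared core: project, add optional feature shift, split, attend, merge."""
    q = q_in @ astensor(params.w_q)
    if precomputed_kv is not None:
        k, v = precomputed_kv
    elif project_kv:
        k = k_in @ astensor(params.w_k)
        v = v_in @ astensor(params.w_v)
    else:
        k, v = k_in, v_in
    if f_prime is not None:
        q = q + f_prime
        k = k + f_prime
        v = v + f_prime
    qh = split_heads(q, spec.num_heads)
    kh = split_heads(k, spec.num_heads)
    vh = split_heads(v, spec.num_heads)
    out_h, weights = scaled_dot_attention(qh, kh, vh)
    out = combine_heads(out_h) @ astensor(params.w_o)
    return out, weights, (k, v)


# ---------------------------------------------------------------------------
# Mechanisms
# ---------------------------------------------------------------------------

def multi_head_attention(H, params: AttentionParams, spec: AttentionSpec) -> AttentionOutput:
    """Standard self-attention: heads over projected Q/K/V, concat, W_O."""
    tensor_mode = _is_tensor_in(H)
    Ht = astensor(H)
    out, w, _ = _attend(Ht, Ht, Ht, params, spec)
    return AttentionOutput(_ret(out, tensor_mode), _ret(w, tensor_mode))


def hierarchical_mha(H, params_per_layer, spec: AttentionSpec) -> AttentionOutput:
    """Stacked attention: layer 1 projects Q, K, V from H; every later layer
    draws its query from the previous layer's output while K and V stay
    those of layer 1."""
    if isinstance(params_per_layer, AttentionParams):
        params_per_layer = [params_per_layer]
    if len(params_per_layer) == 0:
        raise ValueError("at least one layer of parameters is required")
    tensor_mode = _is_tensor_in(H)
    x = astensor(H)
    out, w, kv = _attend(x, x, x, params_per_layer[0], spec)
    for params in params_per_layer[1:]:
        out, w, _ = _attend(out, x, x, params, spec, precomputed_kv=kv)
    return AttentionOutput(_ret(out, tensor_mode), _ret(w, tensor_mode))


def cross_mha(H, K_external, V_external, params: AttentionParams, spec: AttentionSpec,
              add_self: bool = False) -> AttentionOutput:
    """Queries from H; keys/values are the external sequences themselves
    (already at model width, split into heads without re-projection).  With
    ``add_self`` the standard self-attention output (same parameters) is
    added elementwise."""
    tensor_mode = _is_tensor_in(H, K_external, V_external)
    Ht, Kt, Vt = astensor(H), astensor(K_external), astensor(V_external)
    if Kt.shape[-1] != spec.d_model or Vt.shape[-1] != spec.d_model:
        raise ValueError("external keys/values must have depth d_model")
    out, w, _ = _attend(Ht, Kt, Vt, params, spec, project_kv=False)
    if add_self:
        self_out, _, _ = _attend(Ht, Ht, Ht, params, spec)
        out = out + self_out
    return AttentionOutput(_ret(out, tensor_mode), _ret(w, tensor_mode))


def feature_enhanced_mha(H, F, params_per_layer, spec: AttentionSpec) -> AttentionOutput:
    """Attention with an additive projected feature shift: F' = F W_F and
    Q' = Q + F', K' = K + F', V' = V + F'.  With several layers, each block
    feeds the next and re-adds its own projection of the same F."""
    if isinstance(params_per_layer, AttentionParams):
        params_per_layer = [params_per_layer]
    if len(params_per_layer) == 0:
        raise ValueError("at least one layer of parameters is required")
    tensor_mode = _is_tensor_in(H, F)
    x = astensor(H)
    Ft = astensor(F)
    if Ft.shape[-2] != x.shape[-2]:
        raise ValueError("F must have one row per timestep of H")
    out, w = x, None
    for params in params_per_layer:
        if params.w_f is None:
            raise ValueError("feature-enhanced attention requires w_f in every layer")
        w_f = astensor(params.w_f)
        if Ft.shape[-1] != w_f.shape[0]:
            raise ValueError(f"W_F expects feature depth {w_f.shape[0]}, got {Ft.shape[-1]}")
        f_prime = Ft @ w_f
        out, w, _ = _attend(out, out, out, params, spec, f_prime=f_prime)
    return AttentionOutput(_ret(out, tensor_mode), _ret(w, tensor_mode))


def fuse(outputs) -> np.ndarray:
    """Concatenate mechanism outputs along the feature axis in the fixed
    order (MHA, hierarchical, cross, feature-enhanced)."""
    vals = [o.values if isinstance(o, AttentionOutput) else o for o in outputs]
    tensor_mode = _is_tensor_in(*vals)
    ts = [astensor(v) for v in vals]
    T0 = ts[0].shape[-2]
    if any(t.shape[-2] != T0 for t in ts):
        raise ValueError("all attention outputs must share the same sequence length")
    return _ret(concat(ts, axis=-1), tensor_mode)
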