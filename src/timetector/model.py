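"""The twin-branch shared-LSTM autoencoder with quadruple attention.

Architecture (one forward pass over a corrupted window X_noisy of shape
(N, L, F)):

1. a stacked shared LSTM encoder produces the hidden sequence H (N, L, 64);
2. four attention mechanisms (standard, hierarchical, cross with externally
   projected keys/values, feature-enhanced) refine H in parallel and their
   outputs are concatenated into a (N, L, 256) tensor;
3. a second shared LSTM encoder summarises the fused sequence; its final
   hidden state H_E (N, 64) feeds both branches;
4. reconstruction branch: H_E repeated L times -> LSTM decoder -> a
   per-timestep linear map back to F features;
5. prediction branch: relu dense -> linear dense -> future block (N, H, F).

Training minimises  w_rec * MSE(X, X_rec) + w_pred * MSE(X_future, Y_pred)
(weights 1.0 / 0.5) plus an L2 penalty on the recurrent kernels, with Adam,
mini-batches, early stopping on validation loss, and a feedback log that
records per-epoch, per-feature, per-branch mean errors.  Inputs are the
noise-corrupted copies while targets stay clean: the denoising-autoencoder
objective.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import attention as att
from .autodiff import DTYPE, Tensor, lstm
from .preprocess import WindowedDataset

__all__ = [
    "TTTBADConfig",
    "BranchOutputs",
    "FeedbackLog",
    "TTTBAD",
    "composite_loss",
    "train",
    "save",
    "load",
]


@dataclass
class TTTBADConfig:
    """Hyperparameters; defaults follow the published configuration
    (d_model 64, 8 heads, 4 hierarchical / feature-enhanced layers, loss
    weights 1.0/0.5, Adam + MSE, batch 32, up to 20 epochs, early-stopping
    patience 4, DAE noise sd 0.1, L2 0.001)."""

    features: int = 5
    window_length: int = 24
    horizon: int = 1
    d_model: int = 64
    num_heads: int = 8
    encoder_layers: int = 2
    hier_layers: int = 4
    fe_layers: int = 4
    cross_add_self: bool = True
    w_rec: float = 1.0
    w_pred: float = 0.5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 4
    noise_sd: float = 0.1
    l2: float = 0.001
    loss_reduction: str = "mse"  # or "sum_norm"
    seed: int = 0

    def __post_init__(self):
        if self.w_rec <= 0 or self.w_pred <= 0:
            raise ValueError("loss weights must be positive")
        if min(self.features, self.window_length, self.horizon) < 1:
            raise ValueError("features, window_length and horizon must be positive")
        if self.loss_reduction not in ("mse", "sum_norm"):
            raise ValueError("loss_reduction must be 'mse' or 'sum_norm'")


@dataclass
class BranchOutputs:
    """Forward-pass results of the two branches."""

    X_rec: np.ndarray  # (N, L, F)
    Y_pred: np.ndarray  # (N, H, F)


@dataclass
class FeedbackLog:
    """Per-epoch training diagnostics: one record per (epoch, branch,
    feature) mean error, plus the epoch-level loss trajectory."""

    records: list = field(default_factory=list)
    epochs: list = field(default_factory=list)

    def add_epoch(self, epoch: int, train_loss: float, val_loss: float, l2_penalty: float):
        self.epochs.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "l2_penalty": l2_penalty}
        )

    def add_feature_errors(self, epoch: int, branch: str, feature_names, errors):
        for name, err in zip(feature_names, errors):
            self.records.append({"epoch": epoch, "branch": branch, "feature": name, "error": float(err)})

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _branch_loss(diff: Tensor, reduction: str) -> Tensor:
    if reduction == "mse":
        return diff.square().mean()
    # summed unsquared L2 norms over the feature axis
    return (diff.square().sum(axis=-1) + 1e-12).sqrt().sum()


def composite_loss(
    X, X_rec, X_future, Y_pred, w_rec: float = 1.0, w_pred: float = 0.5, reduction: str = "mse"
):
    """total = w_rec * L_rec + w_pred * L_pred.

    With the default ``mse`` reduction each branch loss is the mean of
    squared elementwise differences over its whole tensor; ``sum_norm``
    instead sums unsquared per-timestep L2 norms.  Returns
    ``(total, L_rec, L_pred)`` as floats.
    """
    X, X_rec = np.asarray(X, dtype=float), np.asarray(X_rec, dtype=float)
    X_future, Y_pred = np.asarray(X_future, dtype=float), np.asarray(Y_pred, dtype=float)
    if X.shape != X_rec.shape or X_future.shape != Y_pred.shape:
        raise ValueError("shape mismatch between targets and outputs")
    l_rec = float(_branch_loss(Tensor(X - X_rec), reduction).data)
    l_pred = float(_branch_loss(Tensor(X_future - Y_pred), reduction).data)
    return w_rec * l_rec + w_pred * l_pred, l_rec, l_pred


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _glorot(rng, n_in, n_out):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out)).astype(DTYPE)


class TTTBAD:
    """Trainable twin-branch detector network."""

    def __init__(self, config: TTTBADConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
        d, F, L, H = config.d_model, config.features, config.window_length, config.horizon
        self.params: dict[str, Tensor] = {}

        def par(name, arr):
            t = Tensor(arr, requires_grad=True)
            self.params[name] = t
            return t

        def lstm_params(prefix, d_in, d_hid):
            wx = par(f"{prefix}_wx", _glorot(rng, d_in, 4 * d_hid))
            wh = par(f"{prefix}_wh", _glorot(rng, d_hid, 4 * d_hid))
            b = np.zeros(4 * d_hid, dtype=DTYPE)
            b[d_hid : 2 * d_hid] = 1.0  # forget-gate bias starts open
            return wx, wh, par(f"{prefix}_b", b)

        # first shared encoder (stacked)
        self.enc1 = []
        d_in = F
        for i in range(config.encoder_layers):
            self.enc1.append(lstm_params(f"enc1_{i}", d_in, d))
            d_in = d

        def att_params(prefix, with_f=False):
            p = att.AttentionParams(
                w_q=par(f"{prefix}_wq", _glorot(rng, d, d)),
                w_k=par(f"{prefix}_wk", _glorot(rng, d, d)),
                w_v=par(f"{prefix}_wv", _glorot(rng, d, d)),
                w_o=par(f"{prefix}_wo", _glorot(rng, d, d)),
                w_f=par(f"{prefix}_wf", _glorot(rng, d, d)) if with_f else None,
            )
            return p

        self.spec_single = att.AttentionSpec(d, config.num_heads, 0)
        self.spec_hier = att.AttentionSpec(d, config.num_heads, config.hier_layers)
        self.spec_fe = att.AttentionSpec(d, config.num_heads, config.fe_layers)
        self.att_mha = att_params("mha")
        self.att_hier = [att_params(f"hier{i}") for i in range(self.spec_hier.effective_layers)]
        self.att_cross = att_params("cross")
        self.w_ke = par("cross_wke", _glorot(rng, d, d))
        self.w_ve = par("cross_wve", _glorot(rng, d, d))
        self.att_fe = [att_params(f"fe{i}", with_f=True) for i in range(self.spec_fe.effective_layers)]
        self.w_feat = par("fe_wfeat", _glorot(rng, d, d))

        # second shared encoder over the fused (4*d)-wide sequence
        self.enc2 = lstm_params("enc2", 4 * d, d)
        # reconstruction branch
        self.dec = lstm_params("dec", d, d)
        self.w_rec_out = par("rec_w", _glorot(rng, d, F))
        self.b_rec_out = par("rec_b", np.zeros(F, dtype=DTYPE))
        # prediction branch
        self.w_pred1 = par("pred_w1", _glorot(rng, d, d))
        self.b_pred1 = par("pred_b1", np.zeros(d, dtype=DTYPE))
        self.w_pred2 = par("pred_w2", _glorot(rng, d, H * F))
        self.b_pred2 = par("pred_b2", np.zeros(H * F, dtype=DTYPE))

    # -- forward -------------------------------------------------------
    def _encode_t(self, X: Tensor) -> Tensor:
        h = X
        for wx, wh, b in self.enc1:
            h = lstm(h, wx, wh, b)
        return h

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Hidden-state sequence of the first shared encoder: (N, L, d_model)."""
        X = self._check_input(X)
        return self._encode_t(Tensor(X)).data

    def _forward_t(self, X: Tensor) -> tuple[Tensor, Tensor]:
        cfg = self.config
        H1 = self._encode_t(X)
        out_mha = att.multi_head_attention(H1, self.att_mha, self.spec_single)
        out_hier = att.hierarchical_mha(H1, self.att_hier, self.spec_hier)
        k_ext = H1 @ self.w_ke
        v_ext = H1 @ self.w_ve
        out_cross = att.cross_mha(
            H1, k_ext, v_ext, self.att_cross, self.spec_single, add_self=cfg.cross_add_self
        )
        feats = H1 @ self.w_feat
        out_fe = att.feature_enhanced_mha(H1, feats, self.att_fe, self.spec_fe)
        fused = att.fuse([out_mha, out_hier, out_cross, out_fe])
        H2 = lstm(fused, *self.enc2)
        He = H2[:, -1]
        # reconstruction branch
        Hrp = He.repeat_steps(cfg.window_length)
        Hd = lstm(Hrp, *self.dec)
        x_rec = Hd @ self.w_rec_out + self.b_rec_out
        # prediction branch
        hp = (He @ self.w_pred1 + self.b_pred1).relu()
        y_flat = hp @ self.w_pred2 + self.b_pred2
        n = X.shape[0]
        y_pred = y_flat.reshape(n, cfg.horizon, cfg.features)
        return x_rec, y_pred

    def _check_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=DTYPE)
        if X.ndim != 3 or X.shape[1] != self.config.window_length or X.shape[2] != self.config.features:
            raise ValueError(
                f"expected input (N, {self.config.window_length}, {self.config.features}), got {X.shape}"
            )
        return X

    def forward(self, X: np.ndarray) -> BranchOutputs:
        """Deterministic inference pass (no corruption applied here)."""
        X = self._check_input(X)
        x_rec, y_pred = self._forward_t(Tensor(X))
        if not (np.all(np.isfinite(x_rec.data)) and np.all(np.isfinite(y_pred.data))):
            raise FloatingPointError("non-finite activations in forward pass")
        return BranchOutputs(x_rec.data.astype(float), y_pred.data.astype(float))

    def forward_batched(self, X: np.ndarray, batch_size: int = 256) -> BranchOutputs:
        """Memory-bounded forward over many windows."""
        X = self._check_input(X)
        if X.shape[0] == 0:
            return self.forward(X)
        recs, preds = [], []
        for i in range(0, X.shape[0], batch_size):
            out = self.forward(X[i : i + batch_size])
            recs.append(out.X_rec)
            preds.append(out.Y_pred)
        return BranchOutputs(np.concatenate(recs), np.concatenate(preds))

    # -- persistence ----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state(self, arrays: dict[str, np.ndarray]):
        for k, t in self.params.items():
            if k not in arrays:
                raise ValueError(f"missing parameter {k!r} in state")
            if arrays[k].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k!r}: {arrays[k].shape} vs {t.data.shape}")
            t.data = arrays[k].astype(DTYPE).copy()


def save(model: TTTBAD, path) -> None:
    """Write weights + config to a single .npz archive."""
    np.savez(path, __config__=json.dumps(asdict(model.config)), **model.state_arrays())


def load(path, features: int | None = None) -> TTTBAD:
    """Rebuild a model from :func:`save`; ``features`` cross-checks the
    expected channel count and raises on mismatch."""
    with np.load(path, allow_pickle=False) as archive:
        config = TTTBADConfig(**json.loads(str(archive["__config__"])))
        if features is not None and features != config.features:
            raise ValueError(f"checkpoint was trained on {config.features} features, expected {features}")
        model = TTTBAD(config)
        model.load_state({k: archive[k] for k in archive.files if k != "__config__"})
    return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _l2_penalty(model: TTTBAD) -> Tensor:
    """L2 on recurrent-layer kernels (both input and recurrent matrices)."""
    total = None
    for name, t in model.params.items():
        if name.endswith(("_wx", "_wh")):
            term = t.square().sum()
            total = term if total is None else total + term
    return total * model.config.l2


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def _eval_loss(model: TTTBAD, ds: WindowedDataset, batch_size: int = 256) -> float:
    """Validation objective: weighted branch losses on clean inputs."""
    cfg = model.config
    total, n = 0.0, 0
    for i in range(0, ds.n_windows, batch_size):
        xb = ds.X[i : i + batch_size].astype(DTYPE)
        yb = ds.Y_future[i : i + batch_size].astype(DTYPE)
        x_rec, y_pred = model._forward_t(Tensor(xb))
        rec = float(np.mean((x_rec.data - xb) ** 2))
        pred = float(np.mean((y_pred.data - yb) ** 2))
        total += (cfg.w_rec * rec + cfg.w_pred * pred) * xb.shape[0]
        n += xb.shape[0]
    return total / max(n, 1)


def train(
    model: TTTBAD,
    train_ds: WindowedDataset,
    val_ds: WindowedDataset | None = None,
    config: TTTBADConfig | None = None,
) -> tuple[TTTBAD, FeedbackLog]:
    """Mini-batch Adam training of the denoising multi-task objective.

    Inputs are the corrupted copies in ``train_ds`` (``X_noisy``; the clean
    ``X`` if no corruption was attached), targets are the clean windows and
    future blocks.  Stops at ``max_epochs`` or when validation loss has not
    improved for ``patience`` consecutive epochs; the best-validation
    weights are restored.  Fully deterministic given the config seed.
    """
    cfg = config or model.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    opt = _Adam(model.params, cfg.learning_rate)
    log = FeedbackLog()
    X_in = train_ds.inputs().astype(DTYPE)
    X_clean = train_ds.X.astype(DTYPE)
    Y = train_ds.Y_future.astype(DTYPE)
    N = X_in.shape[0]
    F = cfg.features
    names = train_ds.feature_names

    best_val = np.inf
    best_state = model.state_arrays()
    stale = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(N)
        epoch_loss = 0.0
        seen = 0
        rec_feat = np.zeros(F)
        pred_feat = np.zeros(F)
        l2_value = 0.0
        for i in range(0, N, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb_in = Tensor(X_in[idx])
            xb = X_clean[idx]
            yb = Y[idx]
            x_rec, y_pred = model._forward_t(xb_in)
            loss = (
                cfg.w_rec * _branch_loss(x_rec - Tensor(xb), cfg.loss_reduction)
                + cfg.w_pred * _branch_loss(y_pred - Tensor(yb), cfg.loss_reduction)
            )
            l2_term = _l2_penalty(model)
            objective = loss + l2_term
            value = float(objective.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={value}; "
                    "try a lower learning rate or noise level"
                )
            opt.zero_grad()
            objective.backward()
            opt.step()
            b = len(idx)
            epoch_loss += float(loss.data) * b
            l2_value = float(l2_term.data)
            seen += b
            rec_feat += ((x_rec.data - xb) ** 2).mean(axis=(0, 1)) * b
            pred_feat += ((y_pred.data - yb) ** 2).mean(axis=(0, 1)) * b
        train_loss = epoch_loss / max(seen, 1)
        log.add_feature_errors(epoch, "reconstruction", names, rec_feat / max(seen, 1))
        log.add_feature_errors(epoch, "prediction", names, pred_feat / max(seen, 1))

        val_loss = _eval_loss(model, val_ds) if val_ds is not None else train_loss
        log.add_epoch(epoch, train_loss, val_loss, l2_value)

        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_arrays()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_state(best_state)
    return model, log
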