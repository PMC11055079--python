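"""Normalisation, chronological splitting, windowing and DAE corruption.

The training recipe is: fit a min–max scaler on the chronologically first
80% of the series, scale everything with it (validation/test values may
fall outside [0, 1] and are deliberately not clipped), cut each split into
sliding windows of 24 steps plus a short future-target block, and corrupt a
copy of the training inputs with additive Gaussian noise (sd 0.1 in scaled
units) — the denoising-autoencoder objective reconstructs the clean window
from the corrupted one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .simulate import SensorFrame

__all__ = [
    "ScalerParams",
    "WindowedDataset",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "chronological_split",
    "make_windows",
    "corrupt",
    "with_corruption",
]


@dataclass
class ScalerParams:
    """Per-feature min/max fitted on the training split only."""

    feature_names: tuple[str, ...]
    data_min: np.ndarray
    data_max: np.ndarray
    feature_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.data_min = np.asarray(self.data_min, dtype=float)
        self.data_max = np.asarray(self.data_max, dtype=float)
        if np.any(self.data_max < self.data_min):
            raise ValueError("data_max must be >= data_min per feature")

    @property
    def _denom(self) -> np.ndarray:
        d = self.data_max - self.data_min
        # constant training column: map to the low end of the range
        return np.where(d == 0.0, 1.0, d)


def fit_scaler(train_frame: SensorFrame, feature_range: tuple[float, float] = (0.0, 1.0)) -> ScalerParams:
    if train_frame.n_rows == 0:
        raise ValueError("cannot fit a scaler on an empty frame")
    return ScalerParams(
        train_frame.feature_names,
        train_frame.values.min(axis=0),
        train_frame.values.max(axis=0),
        feature_range,
    )


def _check_names(names, params: ScalerParams):
    if tuple(names) != tuple(params.feature_names):
        raise ValueError(f"feature names {tuple(names)} do not match scaler {params.feature_names}")


def apply_scaler(frame: SensorFrame, params: ScalerParams) -> SensorFrame:
    _check_names(frame.feature_names, params)
    lo, hi = params.feature_range
    scaled = lo + (frame.values - params.data_min) / params._denom * (hi - lo)
    return SensorFrame(frame.timestamps, scaled, frame.feature_names)


def invert_scaler(frame_or_values, params: ScalerParams):
    """Map scaled values back to original units.

    Accepts a :class:`SensorFrame` (returns one) or a plain array whose last
    axis is the feature axis (returns an array).
    """
    lo, hi = params.feature_range
    if isinstance(frame_or_values, SensorFrame):
        _check_names(frame_or_values.feature_names, params)
        raw = (frame_or_values.values - lo) / (hi - lo) * params._denom + params.data_min
        return SensorFrame(frame_or_values.timestamps, raw, frame_or_values.feature_names)
    values = np.asarray(frame_or_values, dtype=float)
    if values.shape[-1] != len(params.feature_names):
        raise ValueError("last axis must equal the number of scaler features")
    return (values - lo) / (hi - lo) * params._denom + params.data_min


def scaler_to_json(params: ScalerParams, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "feature_names": list(params.feature_names),
                "data_min": params.data_min.tolist(),
                "data_max": params.data_max.tolist(),
                "feature_range": list(params.feature_range),
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def scaler_from_json(path) -> ScalerParams:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return ScalerParams(
        tuple(d["feature_names"]),
        np.asarray(d["data_min"]),
        np.asarray(d["data_max"]),
        tuple(d["feature_range"]),
    )


def chronological_split(
    frame: SensorFrame, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> tuple[SensorFrame, SensorFrame, SensorFrame]:
    """Contiguous, order-preserving train/val/test segments.

    Sizes are floor(f*T) for train and validation; remainder rows go to the
    test segment, so the three parts always concatenate back to the input.
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    T = frame.n_rows
    n_train = int(np.floor(fractions[0] * T))
    n_val = int(np.floor(fractions[1] * T))
    return (
        frame.slice_rows(0, n_train),
        frame.slice_rows(n_train, n_train + n_val),
        frame.slice_rows(n_train + n_val, T),
    )


@dataclass
class WindowedDataset:
    """Sliding windows of a (scaled) split: clean inputs ``X``, optional
    corrupted copies ``X_noisy`` and future targets ``Y_future``.

    ``start_indices[i]`` is the source row of the first timestep of window
    i, so window i covers rows [s, s+L) and its target rows [s+L, s+L+H).
    """

    X: np.ndarray
    Y_future: np.ndarray
    window_length: int
    horizon: int
    stride: int
    feature_names: tuple[str, ...]
    start_indices: np.ndarray
    split: str = ""
    X_noisy: np.ndarray | None = None
    timestamps: object = None  # source DatetimeIndex, if known

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def n_source_rows(self) -> int:
        return int(self.start_indices[-1]) + self.window_length + self.horizon if self.n_windows else 0

    def inputs(self) -> np.ndarray:
        """Training inputs: the corrupted copy when present, else clean."""
        return self.X_noisy if self.X_noisy is not None else self.X


def make_windows(
    frame: SensorFrame, window_length: int = 24, horizon: int = 1, stride: int = 1, split: str = ""
) -> WindowedDataset:
    """Cut a frame into N = floor((T-L-H)/stride)+1 ordered sliding windows."""
    if window_length < 1 or horizon < 0 or stride < 1:
        raise ValueError("window_length >= 1, horizon >= 0, stride >= 1 required")
    T = frame.n_rows
    if T < window_length + horizon:
        raise ValueError(f"series of length {T} is shorter than window+horizon={window_length + horizon}")
    starts = np.arange(0, T - window_length - horizon + 1, stride)
    x = frame.values
    X = np.stack([x[s : s + window_length] for s in starts])
    Y = np.stack([x[s + window_length : s + window_length + horizon] for s in starts])
    return WindowedDataset(
        X=X,
        Y_future=Y,
        window_length=window_length,
        horizon=horizon,
        stride=stride,
        feature_names=frame.feature_names,
        start_indices=starts,
        split=split,
        timestamps=frame.timestamps,
    )


def corrupt(X: np.ndarray, noise_sd: float = 0.1, seed: int = 0) -> np.ndarray:
    """Additive i.i.d. Gaussian corruption (in scaled units): x_tilde = x + noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    X = np.asarray(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if noise_sd == 0.0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X + rng.normal(0.0, noise_sd, size=X.shape)


def with_corruption(ds: WindowedDataset, noise_sd: float = 0.1, seed: int = 0) -> WindowedDataset:
    """Return a copy of the dataset with ``X_noisy`` attached; ``X`` and
    ``Y_future`` stay clean (they are the denoising targets)."""
    return replace(ds, X_noisy=corrupt(ds.X, noise_sd, seed))
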