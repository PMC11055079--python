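"""From model outputs to errors, dynamic thresholds, flags and forecasts.

The anomaly score of a timestep is its squared reconstruction error
(averaged over every sliding window that covers it).  The cutoff is the
dynamic threshold

    threshold_t = rolling_mean_t + k * rolling_std_t

computed per feature over a trailing window of w error values (population
standard deviation).  A sample is flagged when its error strictly exceeds
the threshold.  Defaults w = 288 (one day at 5-minute cadence) and k = 3
are package choices — they are configuration keys and are recorded in every
report.  Positions before the first full rolling window reuse the first
defined threshold instead of going unscored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TTTBAD
from .preprocess import ScalerParams, WindowedDataset, invert_scaler

__all__ = [
    "ErrorSeries",
    "ThresholdConfig",
    "ThresholdSeries",
    "AnomalyMask",
    "Forecasts",
    "reconstruction_errors",
    "dynamic_threshold",
    "flag_anomalies",
    "predict_future",
]


@dataclass
class ThresholdConfig:
    window: int = 288
    k: float = 3.0


@dataclass
class ErrorSeries:
    """Per-timestep, per-feature squared reconstruction error (scaled units).

    ``offset`` is the source row (within the split the windows came from)
    of the first error entry; overlapping windows covering the same row were
    averaged.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    offset: int = 0
    timestamps: object = None

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass
class ThresholdSeries:
    rolling_mean: np.ndarray
    rolling_std: np.ndarray
    threshold: np.ndarray
    window: int
    k: float
    feature_names: tuple[str, ...]


@dataclass
class AnomalyMask:
    flags: np.ndarray  # boolean, same shape as the error series
    feature_names: tuple[str, ...]

    @property
    def percentages(self) -> np.ndarray:
        """Per-feature share of flagged timesteps, in percent."""
        return 100.0 * self.flags.mean(axis=0)


@dataclass
class Forecasts:
    """Prediction-branch output mapped back to physical units."""

    values: np.ndarray  # (N, H, F), original units
    target_indices: np.ndarray  # (N, H) source rows the forecasts refer to
    feature_names: tuple[str, ...]
    timestamps: object = None

    def to_dataframe(self, actuals: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        n, h, f = self.values.shape
        for i in range(n):
            for j in range(h):
                for c, name in enumerate(self.feature_names):
                    row = {
                        "target_index": int(self.target_indices[i, j]),
                        "feature": name,
                        "predicted": self.values[i, j, c],
                    }
                    if self.timestamps is not None:
                        row["timestamp"] = self.timestamps[self.target_indices[i, j]]
                    if actuals is not None:
                        row["actual"] = actuals[i, j, c]
                    rows.append(row)
        return pd.DataFrame(rows)


def reconstruct_series(model: TTTBAD, ds: WindowedDataset, batch_size: int = 256):
    """Average the per-window reconstructions into one (T_cov, F) series.

    Returns ``(values, offset)`` where ``offset`` is the first covered
    source row.
    """
    out = model.forward_batched(ds.X, batch_size=batch_size)
    L = ds.window_length
    starts = np.asarray(ds.start_indices)
    lo = int(starts.min())
    hi = int(starts.max()) + L
    sums = np.zeros((hi - lo, ds.X.shape[2]))
    counts = np.zeros(hi - lo)
    for j in range(L):
        np.add.at(sums, starts - lo + j, out.X_rec[:, j])
        np.add.at(counts, starts - lo + j, 1.0)
    return sums / counts[:, None], lo


def reconstruction_errors(model: TTTBAD, ds: WindowedDataset, batch_size: int = 256) -> ErrorSeries:
    """Squared error (x - x_hat)^2 per cell, averaged over the sliding
    windows covering each source row.  Inference runs on the clean windows."""
    out = model.forward_batched(ds.X, batch_size=batch_size)
    err = (ds.X - out.X_rec) ** 2  # (N, L, F)
    L = ds.window_length
    starts = np.asarray(ds.start_indices)
    lo = int(starts.min())
    hi = int(starts.max()) + L
    sums = np.zeros((hi - lo, err.shape[2]))
    counts = np.zeros(hi - lo)
    for j in range(L):
        np.add.at(sums, starts - lo + j, err[:, j])
        np.add.at(counts, starts - lo + j, 1.0)
    values = sums / counts[:, None]
    ts = None
    if ds.timestamps is not None:
        ts = ds.timestamps[lo:hi]
    return ErrorSeries(values, ds.feature_names, offset=lo, timestamps=ts)


def dynamic_threshold(errors: ErrorSeries, window: int = 288, k: float = 3.0) -> ThresholdSeries:
    """Trailing rolling mean + k * rolling population std, per feature.

    The first window-1 positions carry the first defined threshold so every
    scored timestep has a cutoff.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if k < 0:
        raise ValueError("k must be >= 0")
    T = errors.n_rows
    if T < window:
        raise ValueError(f"series of length {T} is shorter than the rolling window {window}")
    df = pd.DataFrame(errors.values)
    mean = df.rolling(window).mean().to_numpy()
    std = df.rolling(window).std(ddof=0).to_numpy()
    thr = mean + k * std
    first = window - 1
    mean[:first] = mean[first]
    std[:first] = std[first]
    thr[:first] = thr[first]
    return ThresholdSeries(mean, std, thr, window, k, errors.feature_names)


def flag_anomalies(errors: ErrorSeries, thresholds: ThresholdSeries) -> AnomalyMask:
    """Flag where error strictly exceeds its dynamic threshold."""
    if errors.values.shape != thresholds.threshold.shape:
        raise ValueError("errors and thresholds are misaligned")
    return AnomalyMask(errors.values > thresholds.threshold, errors.feature_names)


def predict_future(model: TTTBAD, ds: WindowedDataset, scaler: ScalerParams,
                   batch_size: int = 256) -> Forecasts:
    """Prediction-branch forecasts, inverse-scaled to original units and
    aligned H steps beyond each window's end."""
    if tuple(scaler.feature_names) != tuple(ds.feature_names):
        raise ValueError("scaler features do not match the dataset")
    out = model.forward_batched(ds.X, batch_size=batch_size)
    values = invert_scaler(out.Y_pred, scaler)
    starts = np.asarray(ds.start_indices)
    h = ds.horizon
    targets = starts[:, None] + ds.window_length + np.arange(h)[None, :]
    return Forecasts(values, targets, ds.feature_names, timestamps=ds.timestamps)
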