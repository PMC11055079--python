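"""Synthetic barn-environment sensor series with labelled anomalies.

The detector was designed around two proprietary pig-barn data streams — an
indoor set (temperature, humidity, CO2, NH3, H2S) and an outdoor weather
station (temperature, humidity, solar irradiance, daily accumulated solar) —
sampled every 5 minutes.  This module generates series with the same
structure so the whole pipeline is testable: a diurnal sinusoid plus an
AR(1) Gaussian residual per feature, an explicit negative linear coupling
from temperature onto humidity, a daylight-only solar curve whose within-day
cumulative sum gives the characteristic step-like accumulated-solar series,
and four kinds of injected, cell-labelled anomalies.

Anomaly magnitudes are expressed in units of each feature's clean residual
standard deviation (the spread left after removing the mean daily cycle), so
an "8 sigma spike" means the same difficulty on every channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PROFILES",
    "SimConfig",
    "SensorFrame",
    "AnomalyEvent",
    "generate_barn_series",
    "inject_anomalies",
    "random_spike_events",
    "residual_sigma",
    "write_dataset",
    "read_dataset",
]

PROFILES: dict[str, tuple[str, ...]] = {
    "indoor": ("temperature", "humidity", "co2", "nh3", "h2s"),
    "outdoor": ("temperature", "humidity", "solar", "accumulated_solar"),
}

# Non-negative physical quantities are clipped at zero.
_GAS_FLOOR = ("co2", "nh3", "h2s", "solar", "accumulated_solar")

# Typical levels for a fattening barn / adjacent weather station.  Units:
# temperature degC, humidity %RH, co2 ppm, nh3 ppm, h2s ppm, solar W/m2.
_DEFAULTS = {
    "indoor": {
        "base": {"temperature": 22.0, "humidity": 65.0, "co2": 800.0, "nh3": 12.0, "h2s": 0.6},
        "amplitude": {"temperature": 3.0, "humidity": 0.0, "co2": 150.0, "nh3": 3.0, "h2s": 0.15},
        "noise": {"temperature": 0.15, "humidity": 0.4, "co2": 7.5, "nh3": 0.15, "h2s": 0.01},
    },
    "outdoor": {
        "base": {"temperature": 15.0, "humidity": 70.0, "solar": 0.0, "accumulated_solar": 0.0},
        "amplitude": {"temperature": 8.0, "humidity": 0.0, "solar": 800.0, "accumulated_solar": 0.0},
        "noise": {"temperature": 0.4, "humidity": 0.8, "solar": 20.0, "accumulated_solar": 0.0},
    },
}


@dataclass
class SensorFrame:
    """A timestamped T x F block of sensor readings."""

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x F matrix")
        if len(self.timestamps) != self.values.shape[0]:
            raise ValueError("timestamps and values disagree on T")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names and values disagree on F")
        self.feature_names = tuple(self.feature_names)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.timestamps, columns=list(self.feature_names))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SensorFrame":
        return cls(pd.DatetimeIndex(df.index), df.to_numpy(dtype=float), tuple(df.columns))

    def copy(self) -> "SensorFrame":
        return SensorFrame(self.timestamps, self.values.copy(), self.feature_names)

    def slice_rows(self, start: int, stop: int) -> "SensorFrame":
        return SensorFrame(self.timestamps[start:stop], self.values[start:stop].copy(), self.feature_names)


@dataclass
class AnomalyEvent:
    """One injected fault: where, how long, what shape, how big.

    ``magnitude`` is in units of the feature's clean residual standard
    deviation.  ``stuck_at`` ignores magnitude; ``noise_burst`` interprets it
    as the factor by which the local noise sd is multiplied (must be >= 1).
    """

    kind: str
    feature: str
    start_index: int
    length: int = 1
    magnitude: float = 8.0

    KINDS = ("spike", "level_shift", "stuck_at", "noise_burst")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}; expected one of {self.KINDS}")
        if self.start_index < 0 or self.length < 1:
            raise ValueError("start_index must be >= 0 and length >= 1")


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the smooth, strongly diurnal
    character of real barn data (innovation sd ~5% of the diurnal swing)."""

    profile: str = "indoor"
    n_days: int = 30
    step_minutes: int = 5
    seed: int = 0
    base_levels: dict[str, float] = field(default_factory=dict)
    diurnal_amplitude: dict[str, float] = field(default_factory=dict)
    ar_coefficient: float = 0.8
    noise_sd: dict[str, float] = field(default_factory=dict)
    temp_humidity_coupling: float = -2.5
    anomaly_spec: list[AnomalyEvent] = field(default_factory=list)
    start: str = "2023-01-01"

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; expected one of {tuple(PROFILES)}")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.step_minutes < 1 or 1440 % self.step_minutes != 0:
            raise ValueError("step_minutes must be positive and divide 1440")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.temp_humidity_coupling > 0:
            raise ValueError("temp_humidity_coupling must be <= 0")
        defaults = _DEFAULTS[self.profile]
        self.base_levels = {**defaults["base"], **self.base_levels}
        self.diurnal_amplitude = {**defaults["amplitude"], **self.diurnal_amplitude}
        self.noise_sd = {**defaults["noise"], **self.noise_sd}
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{name!r}] must be >= 0")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return PROFILES[self.profile]

    @property
    def steps_per_day(self) -> int:
        return 1440 // self.step_minutes

    @property
    def n_rows(self) -> int:
        return self.n_days * self.steps_per_day


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) residual with innovation sd ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(max(1.0 - phi * phi, 1e-12))
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def generate_barn_series(config: SimConfig) -> SensorFrame:
    """Generate a clean (anomaly-free) multivariate barn series.

    Per feature: base level + 24 h sinusoid (afternoon peak) + AR(1)
    residual.  Humidity has no sinusoid of its own by default: its diurnal
    swing enters through the negative linear coupling to the temperature
    anomaly.  Outdoor solar is zero at night, a half-sine between 06:00 and
    18:00 during the day, and ``accumulated_solar`` is its running
    within-day cumulative sum, resetting at each day boundary.  Output is
    deterministic given the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    T = config.n_rows
    timestamps = pd.date_range(config.start, periods=T, freq=f"{config.step_minutes}min")
    hours = (timestamps.hour + timestamps.minute / 60.0).to_numpy()
    diurnal = np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)  # peaks at 15:00

    names = config.feature_names
    cols: dict[str, np.ndarray] = {}

    temp_anom = (
        config.diurnal_amplitude["temperature"] * diurnal
        + _ar1(rng, T, config.ar_coefficient, config.noise_sd["temperature"])
    )
    cols["temperature"] = config.base_levels["temperature"] + temp_anom

    cols["humidity"] = (
        config.base_levels["humidity"]
        + config.diurnal_amplitude["humidity"] * diurnal
        + config.temp_humidity_coupling * temp_anom
        + _ar1(rng, T, config.ar_coefficient, config.noise_sd["humidity"])
    )

    for gas in ("co2", "nh3", "h2s"):
        if gas in names:
            cols[gas] = (
                config.base_levels[gas]
                + config.diurnal_amplitude[gas] * diurnal
                + _ar1(rng, T, config.ar_coefficient, config.noise_sd[gas])
            )

    if "solar" in names:
        daylight = np.clip(np.sin(np.pi * (hours - 6.0) / 12.0), 0.0, None)
        solar = config.diurnal_amplitude["solar"] * daylight
        day_mask = daylight > 0.0
        solar[day_mask] += _ar1(rng, int(day_mask.sum()), config.ar_coefficient, config.noise_sd["solar"])
        solar = np.clip(solar, 0.0, None)
        solar[~day_mask] = 0.0
        cols["solar"] = solar
        day_id = np.arange(T) // config.steps_per_day
        acc = np.empty(T)
        for d in np.unique(day_id):
            m = day_id == d
            acc[m] = np.cumsum(solar[m])
        cols["accumulated_solar"] = acc

    values = np.column_stack([cols[n] for n in names])
    floor = [i for i, n in enumerate(names) if n in _GAS_FLOOR]
    values[:, floor] = np.clip(values[:, floor], 0.0, None)
    return SensorFrame(timestamps, values, names)


def residual_sigma(frame: SensorFrame, steps_per_day: int | None = None) -> np.ndarray:
    """Per-feature sd of the residual after removing the mean daily cycle.

    With fewer than two full days the daily cycle cannot be averaged out and
    the estimator falls back to sd(first difference)/sqrt(2).
    """
    x = frame.values
    T = x.shape[0]
    if steps_per_day is None:
        step = (frame.timestamps[1] - frame.timestamps[0]) if T > 1 else pd.Timedelta(minutes=5)
        steps_per_day = max(int(pd.Timedelta(days=1) / step), 1)
    if T >= 2 * steps_per_day:
        tod = np.arange(T) % steps_per_day
        resid = np.empty_like(x)
        for s in range(steps_per_day):
            m = tod == s
            resid[m] = x[m] - x[m].mean(axis=0)
        return resid.std(axis=0)
    if T < 2:
        return np.zeros(x.shape[1])
    return np.diff(x, axis=0).std(axis=0) / np.sqrt(2.0)


def inject_anomalies(
    frame: SensorFrame,
    events: list[AnomalyEvent],
    seed: int = 0,
) -> tuple[SensorFrame, np.ndarray]:
    """Apply anomaly events to a copy of ``frame``; return it with a cell mask.

    The boolean LabelMask has the same shape as ``frame.values`` and is True
    on every cell covered by an event; all other cells stay bit-identical to
    the input.  Spikes and level shifts add ``magnitude * sigma_hat`` (the
    clean residual sd of that feature); ``stuck_at`` freezes the value found
    at the event start; ``noise_burst`` adds Gaussian noise so the local sd
    is multiplied by ``magnitude``.
    """
    rng = np.random.default_rng(seed)
    out = frame.copy()
    mask = np.zeros(out.values.shape, dtype=bool)
    if not events:
        return out, mask
    sigma = residual_sigma(frame)
    name_to_col = {n: i for i, n in enumerate(frame.feature_names)}
    T = out.n_rows
    for ev in events:
        if ev.feature not in name_to_col:
            raise ValueError(f"unknown feature {ev.feature!r}")
        if ev.start_index + ev.length > T:
            raise ValueError(f"event out of bounds: start={ev.start_index} length={ev.length} T={T}")
        col = name_to_col[ev.feature]
        sl = slice(ev.start_index, ev.start_index + ev.length)
        s = sigma[col]
        if ev.kind in ("spike", "level_shift"):
            out.values[sl, col] += ev.magnitude * s
        elif ev.kind == "stuck_at":
            out.values[sl, col] = out.values[ev.start_index, col]
        elif ev.kind == "noise_burst":
            if ev.magnitude < 1.0:
                raise ValueError("noise_burst magnitude must be >= 1 (a noise-sd multiplier)")
            extra = s * np.sqrt(ev.magnitude**2 - 1.0)
            out.values[sl, col] += rng.normal(0.0, extra, size=ev.length)
        mask[sl, col] = True
    return out, mask


def random_spike_events(
    frame: SensorFrame,
    rate: float,
    magnitude: float = 8.0,
    seed: int = 0,
    start: int = 0,
    stop: int | None = None,
    sign: str = "both",
) -> list[AnomalyEvent]:
    """Draw independent single-sample spikes at the given per-cell rate.

    ``start``/``stop`` restrict the affected row range (e.g. the test
    segment).  With ``sign='both'`` each spike points up or down with equal
    probability.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    stop = frame.n_rows if stop is None else stop
    events: list[AnomalyEvent] = []
    for name in frame.feature_names:
        hits = start + np.nonzero(rng.random(stop - start) < rate)[0]
        for idx in hits:
            m = magnitude if (sign != "both" or rng.random() < 0.5) else -magnitude
            events.append(AnomalyEvent("spike", name, int(idx), 1, m))
    return events


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


def write_dataset(frame: SensorFrame, mask: np.ndarray | None, path) -> dict[str, Path]:
    """Write ``values.csv`` (timestamp + features) and, if a mask is given,
    ``labels.csv`` with the same layout and 0/1 entries.  Values round-trip
    bit-identically through :func:`read_dataset`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {}
    df = frame.to_dataframe()
    df.index.name = "timestamp"
    values_path = path / "values.csv"
    df.to_csv(values_path, date_format=_TS_FORMAT)
    files["values"] = values_path
    if mask is not None:
        if mask.shape != frame.values.shape:
            raise ValueError("mask shape must match frame values")
        ldf = pd.DataFrame(mask.astype(int), index=df.index, columns=df.columns)
        labels_path = path / "labels.csv"
        ldf.to_csv(labels_path, date_format=_TS_FORMAT)
        files["labels"] = labels_path
    return files


def read_dataset(path) -> tuple[SensorFrame, np.ndarray | None]:
    """Read a dataset written by :func:`write_dataset` (labels optional)."""
    path = Path(path)
    values_path = path / "values.csv" if path.is_dir() else path
    df = pd.read_csv(values_path, index_col="timestamp", parse_dates=True, float_precision="round_trip")
    frame = SensorFrame.from_dataframe(df)
    mask = None
    labels_path = values_path.parent / "labels.csv"
    if labels_path.exists():
        ldf = pd.read_csv(labels_path, index_col="timestamp", parse_dates=True)
        mask = ldf.to_numpy(dtype=int).astype(bool)
    return frame, mask
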