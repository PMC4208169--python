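"""Windowing and feature extraction for the inertial classifier.

Unified sensor streams are cut into fixed-length windows (default 2 s with a
1 s hop, i.e. 50% overlap — 100 accelerometer samples at the nominal 50 Hz)
and each window is reduced to an ordered vector of continuous features:

======================  =========================================
``accel_mean_{x,y,z}``  per-axis accelerometer mean (m/s^2)
``accel_std_{x,y,z}``   per-axis accelerometer population std
``accel_mag_mean``      mean of the acceleration magnitude
``accel_mag_std``       population std of the magnitude
``gyro_std_{x,y,z}``    per-axis gyroscope population std (rad/s)
``proximity_mean``      mean raw proximity reading (cm)
======================  =========================================

Twelve features with the default configuration; standard deviations divide
by N (population convention), matching the streaming trainer's
``sigma2 = v - mu**2``.  GPS is never placed in the feature vector: it is
summarized per window (mean speed, last fix, fix quality) and handed to the
hierarchical router, which owns all location and speed decisions.  Missing
gyroscope/proximity channels are imputed as zeros and flagged, so
accelerometer-only logs remain classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .sensor_io import SensorLog

DEFAULT_WINDOW_S = 2.0
DEFAULT_HOP_S = 1.0

#: tolerance absorbing float accumulation when counting windows
_TIME_EPS = 1e-9


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing lengths and feature-channel toggles."""

    window_s: float = DEFAULT_WINDOW_S
    hop_s: float = DEFAULT_HOP_S
    use_gyroscope: bool = True
    use_proximity: bool = True

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError("window_s must be > 0")
        if not (0 < self.hop_s <= self.window_s):
            raise ValueError("hop_s must satisfy 0 < hop_s <= window_s")

    def feature_names(self) -> tuple:
        names = [
            "accel_mean_x", "accel_mean_y", "accel_mean_z",
            "accel_std_x", "accel_std_y", "accel_std_z",
            "accel_mag_mean", "accel_mag_std",
        ]
        if self.use_gyroscope:
            names += ["gyro_std_x", "gyro_std_y", "gyro_std_z"]
        if self.use_proximity:
            names += ["proximity_mean"]
        return tuple(names)

    def to_dict(self) -> dict:
        return {
            "window_s": self.window_s,
            "hop_s": self.hop_s,
            "use_gyroscope": self.use_gyroscope,
            "use_proximity": self.use_proximity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**d)


@dataclass(frozen=True)
class GpsSummary:
    """Per-window GPS digest consumed by the hierarchical router."""

    mean_speed_kmh: float
    last_lat: float
    last_lon: float
    min_fix_quality: float
    max_fix_quality: float
    n_fixes: int


@dataclass
class SensorWindow:
    """A fixed-duration aligned slice of every sensor stream."""

    start_time: float
    end_time: float
    accelerometer: np.ndarray
    gyroscope: np.ndarray
    proximity: np.ndarray
    gps_summary: Optional[GpsSummary]
    degenerate: bool  # no accelerometer samples in the window


@dataclass(frozen=True)
class FeatureVector:
    """Ordered continuous attributes F_1..F_n fed to the classifier."""

    values: np.ndarray
    names: tuple
    imputed: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size != len(self.names):
            raise ValueError("values and names must have equal length")


def _slice(stream: np.ndarray, start: float, end: float) -> np.ndarray:
    """Samples with timestamp in the half-open interval [start, end)."""
    if stream.shape[0] == 0:
        return stream
    lo = np.searchsorted(stream[:, 0], start, side="left")
    hi = np.searchsorted(stream[:, 0], end, side="left")
    return stream[lo:hi]


def _gps_summary(gps: np.ndarray) -> Optional[GpsSummary]:
    if gps.shape[0] == 0:
        return None
    return GpsSummary(
        mean_speed_kmh=float(gps[:, 3].mean()),
        last_lat=float(gps[-1, 1]),
        last_lon=float(gps[-1, 2]),
        min_fix_quality=float(gps[:, 4].min()),
        max_fix_quality=float(gps[:, 4].max()),
        n_fixes=int(gps.shape[0]),
    )


def segment_windows(
    log: SensorLog,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
) -> list[SensorWindow]:
    """Tile the log's time span with fixed windows at stride ``hop_s``.

    Window starts are ``first_ts + k * hop_s``; a trailing partial window is
    dropped, so a span of length T yields ``floor((T - window_s)/hop_s) + 1``
    windows (zero when T < window_s).  An empty log yields an empty list.
    """
    if not window_s > 0:
        raise ValueError("window_s must be > 0")
    if not (0 < hop_s <= window_s):
        raise ValueError("hop_s must satisfy 0 < hop_s <= window_s")
    span = log.time_span()
    if span is None:
        return []
    first, last = span
    total = last - first
    if total + _TIME_EPS < window_s:
        return []
    n_windows = int(np.floor((total - window_s) / hop_s + _TIME_EPS)) + 1
    out = []
    for k in range(n_windows):
        s = first + k * hop_s
        e = s + window_s
        accel = _slice(log.accelerometer, s, e)
        out.append(
            SensorWindow(
                start_time=s,
                end_time=e,
                accelerometer=accel,
                gyroscope=_slice(log.gyroscope, s, e),
                proximity=_slice(log.proximity, s, e),
                gps_summary=_gps_summary(_slice(log.gps, s, e)),
                degenerate=accel.shape[0] == 0,
            )
        )
    return out


def extract_features(window: SensorWindow, config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Reduce one non-degenerate window to its ordered feature vector.

    Deterministic and order-fixed for a fixed configuration; constant
    signals yield zero standard deviations.  NaNs anywhere in the used
    channels reject the window with a diagnostic.
    """
    if window.degenerate:
        raise ValueError(
            f"degenerate window at t={window.start_time}: no accelerometer samples"
        )
    acc = window.accelerometer[:, 1:4]
    if not np.all(np.isfinite(acc)):
        raise ValueError(f"non-finite accelerometer sample in window at t={window.start_time}")
    mag = np.linalg.norm(acc, axis=1)
    values = [
        *acc.mean(axis=0),
        *acc.std(axis=0),  # population std (ddof=0)
        mag.mean(),
        mag.std(),
    ]
    imputed = []
    if config.use_gyroscope:
        gyro = window.gyroscope[:, 1:4]
        if gyro.shape[0] == 0:
            imputed.append("gyroscope")
            values += [0.0, 0.0, 0.0]
        else:
            if not np.all(np.isfinite(gyro)):
                raise ValueError(
                    f"non-finite gyroscope sample in window at t={window.start_time}"
                )
            values += list(gyro.std(axis=0))
    if config.use_proximity:
        prox = window.proximity[:, 1]
        if prox.shape[0] == 0:
            imputed.append("proximity")
            values.append(0.0)
        else:
            if not np.all(np.isfinite(prox)):
                raise ValueError(
                    f"non-finite proximity sample in window at t={window.start_time}"
                )
            values.append(prox.mean())
    return FeatureVector(
        values=np.asarray(values, dtype=float),
        names=config.feature_names(),
        imputed=tuple(imputed),
    )


def log_to_features(
    log: SensorLog, config: FeatureConfig = FeatureConfig()
) -> list[tuple[SensorWindow, FeatureVector]]:
    """Segment a log and extract features, skipping degenerate windows."""
    out = []
    for w in segment_windows(log, config.window_s, config.hop_s):
        if w.degenerate:
            continue
        out.append((w, extract_features(w, config)))
    return out
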