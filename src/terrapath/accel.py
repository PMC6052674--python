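"""Tri-axial acceleration bursts and overall dynamic body acceleration (ODBA).

ODBA is the standard biologging proxy for the intensity of activity:
per axis, the static (gravitational) component is estimated by a
running mean and removed; the absolute dynamic residuals of the three
axes are summed per sample and averaged over the burst, yielding one
non-negative scalar (units g) per burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AccBurst",
    "Calibration",
    "apply_calibration",
    "compute_odba",
    "odba_records",
    "hourly_mean_odba",
    "bin_by_temperature",
]


@dataclass(frozen=True)
class Calibration:
    """Per-axis affine correction: corrected = (raw - offset) * gain."""

    offset: np.ndarray  # shape (3,), g
    gain: np.ndarray  # shape (3,), dimensionless, all non-zero

    def __post_init__(self):
        offset = np.asarray(self.offset, dtype=float).reshape(3)
        gain = np.asarray(self.gain, dtype=float).reshape(3)
        if np.any(gain == 0.0):
            raise ValueError("calibration gains must be non-zero")
        object.__setattr__(self, "offset", offset)
        object.__setattr__(self, "gain", gain)


@dataclass(frozen=True)
class AccBurst:
    """One fixed-duration tri-axial accelerometer recording (units g)."""

    individual: str
    timestamp: pd.Timestamp
    samples: np.ndarray  # shape (n, 3)
    rate: float  # Hz
    calibration: Calibration | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.rate


def apply_calibration(burst: AccBurst) -> AccBurst:
    """Apply the device-specific affine calibration to a burst.

    Raises if the burst carries no calibration, naming the device.
    """
    if burst.calibration is None:
        raise ValueError(f"no calibration available for device of {burst.individual!r}")
    cal = burst.calibration
    corrected = (burst.samples - cal.offset) * cal.gain
    return replace(burst, samples=corrected)


def _running_mean(x: np.ndarray, w: int) -> np.ndarray:
    """Centred running mean over a window of `w` samples, truncated at the
    edges (the mean is taken over the samples that fall inside the array)."""
    n = x.shape[0]
    c = np.concatenate([np.zeros((1,) + x.shape[1:]), np.cumsum(x, axis=0)])
    i = np.arange(n)
    lo = np.clip(i - (w - 1) // 2, 0, n)
    hi = np.clip(i + w // 2 + 1, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)[:, None]


def compute_odba(burst: AccBurst, window: float | None = None) -> float:
    """Overall dynamic body acceleration of one burst, in g.

    Parameters
    ----------
    window : seconds, or None
        Length of the centred running mean used to estimate the static
        (gravitational) component per axis.  ``None`` (the default) uses
        the full-burst mean, the usual choice for short fixed bursts.
    """
    s = burst.samples
    if s.shape[0] == 0:
        raise ValueError("empty burst")
    if window is None or window >= burst.duration:
        static = s.mean(axis=0, keepdims=True)
    else:
        w = int(round(window * burst.rate))
        if w < 2:
            raise ValueError("window must span at least 2 samples")
        static = _running_mean(s, w)
    dyn = s - static
    return float(np.abs(dyn).sum(axis=1).mean())


def odba_records(
    bursts: Iterable[AccBurst],
    body_temps: pd.DataFrame | None = None,
    window: float | None = None,
    temp_tolerance: pd.Timedelta = pd.Timedelta(seconds=150),
) -> pd.DataFrame:
    """Per-burst ODBA table: individual, timestamp, odba, body_temp, hour.

    Body temperature (a 5-min logger series with columns individual,
    timestamp, body_temp_c) is joined by the nearest reading within
    ``temp_tolerance`` of the burst start; bursts with no reading in
    range carry a missing temperature.
    """
    rows = [
        (b.individual, b.timestamp, compute_odba(b, window=window))
        for b in bursts
    ]
    out = pd.DataFrame(rows, columns=["individual", "timestamp", "odba"])
    out = out.sort_values(["individual", "timestamp"]).reset_index(drop=True)
    if body_temps is not None and len(body_temps):
        bt = body_temps.rename(columns={"body_temp_c": "body_temp"})
        bt = bt[["individual", "timestamp", "body_temp"]].copy()
        bt["timestamp"] = pd.to_datetime(bt["timestamp"])
        bt = bt.sort_values("timestamp")
        out = out.sort_values("timestamp", kind="stable")
        out = pd.merge_asof(
            out,
            bt,
            on="timestamp",
            by="individual",
            direction="nearest",
            tolerance=temp_tolerance,
        )
        out = out.sort_values(["individual", "timestamp"]).reset_index(drop=True)
    else:
        out["body_temp"] = np.nan
    out["hour"] = out["timestamp"].dt.hour
    return out


def hourly_mean_odba(records: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean ODBA per individual x date x hour.

    Hours with no bursts are absent from the output.
    """
    df = records.copy()
    df["date"] = df["timestamp"].dt.date
    grouped = (
        df.groupby(["individual", "date", "hour"], sort=True)["odba"]
        .agg(mean_odba="mean", n_bursts="size")
        .reset_index()
    )
    return grouped


def bin_by_temperature(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ODBA (+/- SE) at each whole degree C of body temperature.

    The bin label is the nearest whole degree, floor(t + 0.5).  The SE of
    a single-observation bin is 0 by convention.  Raises if no record
    carries a body temperature.
    """
    df = records.dropna(subset=["body_temp"])
    if df.empty:
        raise ValueError("no records carry a body temperature")
    bins = np.floor(df["body_temp"].to_numpy() + 0.5).astype(int)
    g = df.assign(temp_bin=bins).groupby("temp_bin")["odba"]
    out = g.agg(mean_odba="mean", sd="std", n="size").reset_index()
    out["se_odba"] = np.where(out["n"] > 1, out["sd"] / np.sqrt(out["n"]), 0.0)
    return out[["temp_bin", "mean_odba", "se_odba", "n"]]
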