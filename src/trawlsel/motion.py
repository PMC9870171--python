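"""Codend-motion characterisation from 1-Hz sensor records.

A depth logger on the codend side panel records depth every second; a
tri-axial accelerometer records acceleration along X (anterior-posterior),
Y (port-starboard) and Z (top-bottom).  The codend's vertical oscillation
is summarised by

* peak-to-peak amplitude — vertical excursion between an adjacent valley
  and peak of the depth trace,
* amplitude ratio — peak-to-peak amplitude divided by the side-panel
  length (default 99.6 cm),
* period — time between successive depth peaks,
* total acceleration TA = sqrt(X^2 + Y^2 + Z^2).

At sea the seabed depth drifts continuously, so oscillation statistics
are taken only on stable segments where depth varies by at most 0.5 m,
after trimming the first and last minute of the haul.

Peak detection defaults (`min_prominence` = 0.02 m, `min_separation` =
2 s) reflect the logger resolution and the shortest credible oscillation;
both are exposed.  On a plateau of equal extreme readings the extremum
time is the midpoint of the plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import linregress

__all__ = [
    "SensorSeries",
    "OscillationSummary",
    "DEFAULT_PANEL_LENGTH_CM",
    "total_acceleration",
    "detect_extrema",
    "amplitude_ratio",
    "periods",
    "stable_segments",
    "trim_haul",
    "ols_trend",
    "summarize_values",
]

DEFAULT_PANEL_LENGTH_CM = 99.6
DEFAULT_MIN_PROMINENCE = 0.02  # m, about the logger resolution
DEFAULT_MIN_SEPARATION = 2.0  # s
DEFAULT_MAX_RANGE = 0.5  # m, stable-depth cap
DEFAULT_MIN_DURATION = 30.0  # s, long enough for >= 2 oscillations
SEA_TRIM_S = 60.0
FLUME_TRIM_S = 300.0


@dataclass
class SensorSeries:
    """A 1-Hz scalar time series (depth in m, or one derived channel)."""

    t: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have the same shape")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_csv(cls, path, t_col: str = "t_s", value_col: str = "depth_m"):
        df = pd.read_csv(path)
        return cls(df[t_col].to_numpy(), df[value_col].to_numpy())


@dataclass
class OscillationSummary:
    """Alternating depth extrema and the oscillation statistics they imply."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    valley_times: np.ndarray
    valley_values: np.ndarray
    panel_length_cm: float = DEFAULT_PANEL_LENGTH_CM

    @property
    def peak_to_peak_amplitudes_cm(self) -> np.ndarray:
        """Vertical excursion (cm) of each adjacent valley/peak pair."""
        events = sorted(
            [(t, v, "p") for t, v in zip(self.peak_times, self.peak_values)]
            + [(t, v, "v") for t, v in zip(self.valley_times, self.valley_values)]
        )
        exc = [
            abs(b[1] - a[1]) * 100.0
            for a, b in zip(events, events[1:])
            if a[2] != b[2]
        ]
        return np.array([e for e in exc if e > 0.0])


def total_acceleration(x, y, z) -> np.ndarray:
    """Total acceleration TA = sqrt(X^2 + Y^2 + Z^2) per sample (m s^-2)."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    ta = np.sqrt(x * x + y * y + z * z)
    if np.any(~np.isfinite(ta)):
        warnings.warn("non-finite samples in total acceleration", RuntimeWarning)
    return ta


def _extrema_one_sign(
    values: np.ndarray, t: np.ndarray, min_prominence: float, min_distance: int
):
    idx, props = find_peaks(
        values,
        prominence=min_prominence,
        distance=max(min_distance, 1),
        plateau_size=(1, None),
    )
    times = np.empty(idx.size)
    for k, (le, re_) in enumerate(zip(props["left_edges"], props["right_edges"])):
        times[k] = 0.5 * (t[le] + t[re_])  # plateau midpoint rule
    return times, values[idx]


def detect_extrema(
    series: SensorSeries,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    panel_length_cm: float = DEFAULT_PANEL_LENGTH_CM,
) -> OscillationSummary:
    """Alternating local maxima (peaks) and minima (valleys) of a depth trace.

    Peaks and valleys must clear ``min_prominence`` (m) and be at least
    ``min_separation`` (s) apart within their own kind.  Alternation is
    enforced: between two peaks only the deepest valley survives, and
    between two valleys only the highest peak.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 samples to detect extrema")
    dt = float(np.median(np.diff(series.t)))
    dist = int(round(min_separation / dt))
    pt, pv = _extrema_one_sign(series.values, series.t, min_prominence, dist)
    vt, vv = _extrema_one_sign(-series.values, series.t, min_prominence, dist)
    vv = -vv

    events = sorted(
        [(t_, v_, "p") for t_, v_ in zip(pt, pv)]
        + [(t_, v_, "v") for t_, v_ in zip(vt, vv)]
    )
    kept: list[tuple[float, float, str]] = []
    for ev in events:
        if kept and kept[-1][2] == ev[2]:
            prev = kept[-1]
            if ev[2] == "p":
                keep_new = ev[1] > prev[1]  # higher peak wins
            else:
                keep_new = ev[1] < prev[1]  # deeper valley wins
            if keep_new:
                kept[-1] = ev
        else:
            kept.append(ev)
    peaks = [(t_, v_) for t_, v_, kind in kept if kind == "p"]
    valleys = [(t_, v_) for t_, v_, kind in kept if kind == "v"]
    return OscillationSummary(
        peak_times=np.array([p[0] for p in peaks]),
        peak_values=np.array([p[1] for p in peaks]),
        valley_times=np.array([v[0] for v in valleys]),
        valley_values=np.array([v[1] for v in valleys]),
        panel_length_cm=panel_length_cm,
    )


def amplitude_ratio(summary: OscillationSummary) -> np.ndarray:
    """Peak-to-peak amplitudes divided by the side-panel length."""
    if not (summary.panel_length_cm > 0):
        raise ValueError("panel length must be positive")
    return summary.peak_to_peak_amplitudes_cm / summary.panel_length_cm


def periods(summary: OscillationSummary) -> np.ndarray:
    """Per-oscillation durations: successive peak-time differences (s)."""
    return np.diff(summary.peak_times)


def trim_haul(
    series: SensorSeries,
    lead_s: float = SEA_TRIM_S,
    tail_s: float = SEA_TRIM_S,
) -> SensorSeries:
    """Drop the settling lead-in and haul-back tail of a record.

    Defaults drop one minute at each end (sea protocol); use
    ``lead_s=FLUME_TRIM_S, tail_s=0`` for the flume protocol, which
    discards the first five minutes of each flow-velocity run.
    """
    t0, t1 = series.t[0] + lead_s, series.t[-1] - tail_s
    keep = (series.t >= t0) & (series.t <= t1)
    if not keep.any():
        warnings.warn("trim removed the entire series", RuntimeWarning)
        return SensorSeries(np.empty(0), np.empty(0))
    return SensorSeries(series.t[keep], series.values[keep])


def stable_segments(
    depth: SensorSeries,
    max_range: float = DEFAULT_MAX_RANGE,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> list[SensorSeries]:
    """Maximal stable-depth subsamples of a (trimmed) depth trace.

    Greedy left-to-right: from the current start, extend the window while
    its depth range stays within ``max_range`` (m); emit it if it lasts at
    least ``min_duration`` (s), then continue after it.
    """
    segments: list[SensorSeries] = []
    t, v = depth.t, depth.values
    n = len(depth)
    i = 0
    while i < n:
        lo = hi = v[i]
        j = i + 1
        while j < n:
            lo, hi = min(lo, v[j]), max(hi, v[j])
            if hi - lo > max_range:
                break
            j += 1
        # window [i, j) is maximal from i
        if j - i >= 2 and t[j - 1] - t[i] >= min_duration:
            segments.append(SensorSeries(t[i:j], v[i:j]))
            i = j
        else:
            i += 1
    return segments


def ols_trend(x, y):
    """Ordinary least-squares trend of a response against flow velocity.

    Returns the scipy ``linregress`` result (slope, intercept, rvalue,
    pvalue, stderr).  Requires >= 3 points and non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a trend")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    return linregress(x, y)


def summarize_values(values) -> dict:
    """Mean, sample SD, SEM and range of a set of measurements."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    sd = float(arr.std(ddof=1)) if n > 1 else None
    return {
        "n": int(n),
        "mean": float(arr.mean()),
        "sd": sd,
        "sem": (sd / np.sqrt(n)) if sd is not None else None,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }
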