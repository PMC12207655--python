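"""Depth-stream processing: outlier repair, zero-offset correction, dives.

Time-depth recorders drift slowly (pressure-sensor offset), so raw depth is
corrected by subtracting a rolling low quantile — the zero-offset correction
(ZOC) — before dives are detected against a fixed threshold.  Petrel dives
are rare and shallow, so the default pipeline is: repair isolated >15 m
spikes by linear interpolation, subtract the rolling 10-min 10th percentile,
clip negatives to zero, then call any run of samples at or above 0.5 m a
dive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrace",
    "DiveEvent",
    "repair_outliers",
    "zero_offset_correct",
    "detect_dives",
    "depth_histogram",
    "dive_pitch_profile",
]


@dataclass
class DepthTrace:
    """1 Hz depth stream (metres, positive down) for one deployment."""

    start: pd.Timestamp
    depth: np.ndarray
    rate: float = 1.0

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if len(self.depth) == 0:
            raise ValueError("empty depth trace")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def times(self) -> pd.DatetimeIndex:
        step = pd.to_timedelta(1.0 / self.rate, unit="s")
        return pd.DatetimeIndex(self.start + step * np.arange(len(self)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "depth_m": self.depth})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate: float = 1.0) -> "DepthTrace":
        return cls(
            start=pd.Timestamp(df["timestamp"].iloc[0]),
            depth=df["depth_m"].to_numpy(),
            rate=rate,
        )


@dataclass
class DiveEvent:
    """A maximal run of consecutive samples at or above the dive threshold."""

    start: pd.Timestamp
    duration_s: float
    max_depth_m: float
    mean_depth_m: float


def repair_outliers(trace: DepthTrace, max_plausible: float = 15.0):
    """Replace implausible depth spikes by linear interpolation.

    Samples exceeding ``max_plausible`` metres (isolated events that would
    imply vertical speeds far beyond a surface-feeding bird) are treated as
    sensor anomalies.  Returns ``(repaired_trace, outlier_count)``.
    Leading/trailing outliers take the nearest valid value.
    """
    depth = trace.depth
    bad = depth > max_plausible
    count = int(bad.sum())
    if count == 0:
        return trace, 0
    if bad.all():
        raise ValueError("all samples are outliers; nothing to interpolate from")
    s = pd.Series(np.where(bad, np.nan, depth))
    s = s.interpolate(method="linear", limit_direction="both")
    return DepthTrace(start=trace.start, depth=s.to_numpy(), rate=trace.rate), count


def zero_offset_correct(
    trace: DepthTrace, window: float = 10.0, quantile: float = 0.10
):
    """Subtract the rolling low-quantile depth (sensor drift) from the trace.

    ``window`` is in minutes; the window is centred and truncated at the
    edges, and the quantile uses linear interpolation between order
    statistics.  Corrected values below 0 m are fixed at 0 m.  Returns
    ``(corrected_trace, zoc_series)``.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if len(trace) <= 2:
        raise ValueError("trace too short for zero-offset correction")
    n_samples = max(int(round(window * 60 * trace.rate)), 1)
    zoc = (
        pd.Series(trace.depth)
        .rolling(window=n_samples, center=True, min_periods=1)
        .quantile(quantile, interpolation="linear")
        .to_numpy()
    )
    corrected = np.maximum(trace.depth - zoc, 0.0)
    return DepthTrace(start=trace.start, depth=corrected, rate=trace.rate), zoc


def detect_dives(corrected: DepthTrace, threshold: float = 0.5) -> list[DiveEvent]:
    """Find dives: maximal runs of consecutive samples with depth ≥ threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    depth = corrected.depth
    submerged = depth >= threshold
    if not submerged.any():
        return []
    edges = np.diff(submerged.astype(int))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1
    if submerged[0]:
        starts = np.r_[0, starts]
    if submerged[-1]:
        ends = np.r_[ends, len(depth)]
    times = corrected.times
    events = []
    for i0, i1 in zip(starts, ends):
        run = depth[i0:i1]
        events.append(
            DiveEvent(
                start=times[i0],
                duration_s=(i1 - i0) / corrected.rate,
                max_depth_m=float(run.max()),
                mean_depth_m=float(run.mean()),
            )
        )
    return events


def depth_histogram(corrected: DepthTrace, bin_width: float = 0.1) -> pd.DataFrame:
    """Depth occupancy in half-open bins [k·w, (k+1)·w); percentages sum to 100."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    depth = corrected.depth
    idx = np.floor(depth / bin_width).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {
            "bin_lower_m": np.arange(n_bins) * bin_width,
            "bin_upper_m": (np.arange(n_bins) + 1) * bin_width,
            "count": counts,
            "percent": 100.0 * counts / counts.sum(),
        }
    )


def dive_pitch_profile(
    dive: DiveEvent,
    pitch: pd.Series,
    pad: float = 5.0,
    excursion_deg: float = 20.0,
):
    """Summarise the pitch profile around a dive.

    Surface-feeding birds show a characteristic dip-and-recover (sigmoidal)
    pitch pattern through brief dives.  Looks at ``pitch`` (a time-indexed
    series in degrees) over the dive padded by ``pad`` seconds on each side
    and reports ``(min_pitch, max_pitch, dip_flag)`` where the flag is True
    when pitch drops below ``-excursion_deg`` and recovers above it within
    the window.
    """
    lo = dive.start - pd.to_timedelta(pad, unit="s")
    hi = dive.start + pd.to_timedelta(dive.duration_s + pad, unit="s")
    win = pitch.loc[lo:hi]
    if len(win) == 0:
        raise ValueError("pitch series does not cover the dive window")
    vals = win.to_numpy(dtype=float)
    pmin, pmax = float(np.nanmin(vals)), float(np.nanmax(vals))
    below = np.where(vals < -excursion_deg)[0]
    dip = bool(len(below) and np.any(vals[below[-1] :] > -excursion_deg))
    return pmin, pmax, dip
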