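"""Per-sample metrics derived from tri-axial acceleration.

Raw acceleration on each axis (surge = forward-back, sway = left-right,
heave = up-down, in units of g) is split into a *static* component — the
orientation of the gravity vector, estimated as a centred 1-s moving mean —
and a *dynamic* component (raw minus static) carrying body movement.  From
these we derive body pitch and roll, the vectorial static and dynamic body
accelerations (VeSBA, VeDBA), and per-sample wingbeat flags.

VeSBA is close to 1 g when the bird is stationary or moving linearly and
exceeds it in banked turns; VeDBA is the standard proxy for movement
intensity.  Wingbeats are prominent peaks in heave acceleration occurring in
rapid succession (flapping at ≥ 4 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

__all__ = [
    "AccelTrace",
    "decompose",
    "body_angles",
    "vedba_vesba",
    "detect_wingbeats",
    "compute_metrics",
]


@dataclass
class AccelTrace:
    """A uniformly sampled tri-axial acceleration stream for one deployment.

    Attributes
    ----------
    start : pandas.Timestamp
        UTC time of the first sample.
    rate : float
        Sampling rate in Hz (nominally 25).
    surge, sway, heave : ndarray
        Acceleration in g.
    temperature : ndarray, optional
        Logger temperature in °C, same length as the axes.
    """

    start: pd.Timestamp
    rate: float
    surge: np.ndarray
    sway: np.ndarray
    heave: np.ndarray
    temperature: np.ndarray | None = None

    def __post_init__(self):
        self.surge = np.asarray(self.surge, dtype=float)
        self.sway = np.asarray(self.sway, dtype=float)
        self.heave = np.asarray(self.heave, dtype=float)
        n = len(self.surge)
        if not (len(self.sway) == len(self.heave) == n):
            raise ValueError("axis arrays must have equal length")
        if n == 0:
            raise ValueError("empty trace")
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
            if len(self.temperature) != n:
                raise ValueError("temperature length mismatch")
        for name in ("surge", "sway", "heave"):
            if np.nanmax(np.abs(getattr(self, name))) >= 16:
                raise ValueError(f"{name} exceeds the 16 g sensor range")

    def __len__(self) -> int:
        return len(self.surge)

    @property
    def times(self) -> pd.DatetimeIndex:
        step = pd.to_timedelta(1.0 / self.rate, unit="s")
        return pd.DatetimeIndex(self.start + step * np.arange(len(self)))

    @property
    def duration(self) -> float:
        return len(self) / self.rate

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "timestamp": self.times,
            "ax_g": self.surge,
            "ay_g": self.sway,
            "az_g": self.heave,
        }
        if self.temperature is not None:
            cols["temp_c"] = self.temperature
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate: float = 25.0) -> "AccelTrace":
        temp = df["temp_c"].to_numpy() if "temp_c" in df else None
        return cls(
            start=pd.Timestamp(df["timestamp"].iloc[0]),
            rate=rate,
            surge=df["ax_g"].to_numpy(),
            sway=df["ay_g"].to_numpy(),
            heave=df["az_g"].to_numpy(),
            temperature=temp,
        )


def _moving_mean(x: np.ndarray, n_samples: int) -> np.ndarray:
    # centred window, truncated (not dropped) at the edges so output length
    # equals input length
    return (
        pd.Series(x)
        .rolling(window=n_samples, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def decompose(trace: AccelTrace, window: float = 1.0):
    """Split each axis into static (centred moving mean) and dynamic parts.

    Returns ``(static, dynamic)``, each a dict with keys ``surge``, ``sway``,
    ``heave``.  Edge samples use shrunken windows, so
    ``static + dynamic == raw`` exactly at every sample.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_samples = max(int(round(window * trace.rate)), 1)
    static, dynamic = {}, {}
    for axis in ("surge", "sway", "heave"):
        raw = getattr(trace, axis)
        s = _moving_mean(raw, n_samples)
        static[axis] = s
        dynamic[axis] = raw - s
    return static, dynamic


def body_angles(static_surge, static_sway, static_heave):
    """Body pitch and roll in degrees from the static (gravity) components.

    pitch = atan2(s_surge, sqrt(s_sway² + s_heave²)),
    roll  = atan2(s_sway, s_heave); both in (-180, 180].  An all-zero static
    vector yields NaN (undefined posture), not an exception.
    """
    sx = np.asarray(static_surge, dtype=float)
    sy = np.asarray(static_sway, dtype=float)
    sz = np.asarray(static_heave, dtype=float)
    norm = np.sqrt(sx**2 + sy**2 + sz**2)
    with np.errstate(invalid="ignore"):
        pitch = np.degrees(np.arctan2(sx, np.hypot(sy, sz)))
        roll = np.degrees(np.arctan2(sy, sz))
    undefined = norm == 0
    if np.any(undefined):
        pitch = np.where(undefined, np.nan, pitch)
        roll = np.where(undefined, np.nan, roll)
    return pitch, roll


def vedba_vesba(dynamic: dict, static: dict):
    """Vectorial dynamic and static body acceleration (both ≥ 0, in g)."""
    vedba = np.sqrt(
        dynamic["surge"] ** 2 + dynamic["sway"] ** 2 + dynamic["heave"] ** 2
    )
    vesba = np.sqrt(static["surge"] ** 2 + static["sway"] ** 2 + static["heave"] ** 2)
    return vedba, vesba


@dataclass
class WingbeatResult:
    """Per-sample wingbeat flags plus the retained peak bouts."""

    flags: np.ndarray
    bouts: list = field(default_factory=list)

    @property
    def n_beats(self) -> int:
        return int(sum(len(b) for b in self.bouts))


def detect_wingbeats(
    heave,
    rate: float = 25.0,
    amp_threshold: float = 1.0,
    min_rate: float = 4.0,
    min_successive: int = 2,
    criterion: str = "prominence",
) -> WingbeatResult:
    """Flag wingbeats: heave peaks with amplitude > 1 g in rapid succession.

    Candidate peaks are local maxima of heave whose amplitude exceeds
    ``amp_threshold``.  Amplitude is measured by default as peak *prominence*
    (height above the surrounding signal): stationary heave sits at the 1 g
    gravity baseline, so a raw-value criterion would flag every supra-1 g
    excursion — including the slow un-flapped oscillations of dynamic
    soaring — as beats.  ``criterion="height"`` switches to the raw heave
    value at the maximum.

    Successive candidates separated by at most ``1/min_rate`` seconds (i.e.
    flapping at ≥ ``min_rate`` Hz) chain into bouts; only bouts of at least
    ``min_successive`` peaks are kept, and each retained peak flags one
    wingbeat sample.
    """
    heave = np.asarray(heave, dtype=float)
    if rate < 2 * min_rate:
        raise ValueError("sampling rate below Nyquist for the requested min_rate")
    flags = np.zeros(len(heave), dtype=bool)
    if len(heave) < 3:
        return WingbeatResult(flags=flags)
    peaks, _ = find_peaks(heave)
    if len(peaks) == 0:
        return WingbeatResult(flags=flags)
    if criterion == "prominence":
        amp = peak_prominences(heave, peaks)[0]
    elif criterion == "height":
        amp = heave[peaks]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    peaks = peaks[amp > amp_threshold]
    max_gap = rate / min_rate  # samples
    bouts: list[np.ndarray] = []
    if len(peaks):
        breaks = np.where(np.diff(peaks) > max_gap)[0] + 1
        for bout in np.split(peaks, breaks):
            if len(bout) >= min_successive:
                bouts.append(bout)
                flags[bout] = True
    return WingbeatResult(flags=flags, bouts=bouts)


def compute_metrics(
    trace: AccelTrace,
    window: float = 1.0,
    amp_threshold: float = 1.0,
    min_rate: float = 4.0,
    min_successive: int = 2,
    wingbeat_criterion: str = "prominence",
) -> pd.DataFrame:
    """Compute the full per-sample metric table for a trace.

    Returns a DataFrame indexed by timestamp with columns: the three raw
    axes, static_*/dyn_* components, ``pitch``, ``roll``, ``vedba``,
    ``vesba``, boolean ``wingbeat`` and ``temp_c``.
    """
    static, dynamic = decompose(trace, window=window)
    pitch, roll = body_angles(static["surge"], static["sway"], static["heave"])
    vedba, vesba = vedba_vesba(dynamic, static)
    wb = detect_wingbeats(
        trace.heave,
        rate=trace.rate,
        amp_threshold=amp_threshold,
        min_rate=min_rate,
        min_successive=min_successive,
        criterion=wingbeat_criterion,
    )
    temp = (
        trace.temperature
        if trace.temperature is not None
        else np.full(len(trace), np.nan)
    )
    return pd.DataFrame(
        {
            "surge": trace.surge,
            "sway": trace.sway,
            "heave": trace.heave,
            "static_surge": static["surge"],
            "static_sway": static["sway"],
            "static_heave": static["heave"],
            "dyn_surge": dynamic["surge"],
            "dyn_sway": dynamic["sway"],
            "dyn_heave": dynamic["heave"],
            "pitch": pitch,
            "roll": roll,
            "vedba": vedba,
            "vesba": vesba,
            "wingbeat": wb.flags,
            "temp_c": temp,
        },
        index=trace.times,
    )
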