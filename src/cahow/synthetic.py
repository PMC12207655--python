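"""Synthetic logger deployments with the statistical structure of the field data.

Generates the three raw streams a multi-sensor biologger produces —
25 Hz tri-axial acceleration with temperature, 1 Hz depth, and periodic GPS
fixes — plus the ground-truth behaviour sequence, so that every downstream
stage (signal metrics, dive detection, classification, diel models, trip
segmentation) can be exercised and validated without field data.

Each of the nine behaviour classes has a parameterised acceleration
*signature* (baseline orientation, noise floor, slow posture wander,
periodic components, wingbeat bouts, temperature) whose defaults are tuned
so that the generated signal reproduces the qualitative movement criteria
that define the class in the ethogram: e.g. burrow-still is nearly
motionless at high temperature; dynamic soaring shows slow supra-1.5 g
VeSBA oscillations without wingbeats; flap-glide adds regular bouts of
>2 g heave peaks at flapping frequency.

Behaviour switching at sea is a first-order Markov chain whose transition
weights are tilted by the solar elevation, emulating the diel activity
shifts the analysis is designed to detect.  GPS tracks are out-and-back
correlated random walks from the colony; depth traces combine bounded
sensor drift, measurement noise and scheduled shallow dive excursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._utils import spawn_rng
from .dive import DepthTrace
from .signal_metrics import AccelTrace
from .solar import sun_angle
from .taxonomy import AT_SEA_CLASSES, ALL_CLASSES, BehaviourClass
from .trips import EARTH_RADIUS_KM, COLONY_LONLAT, GpsTrack

__all__ = [
    "ClassSignature",
    "DEFAULT_SIGNATURES",
    "DielGenerator",
    "gen_accel",
    "gen_depth",
    "gen_diel_sequence",
    "gen_track",
    "gen_training_segments",
    "DeploymentConfig",
    "gen_logger_dataset",
]


# ------------------------------------------------------------ acceleration

@dataclass(frozen=True)
class ClassSignature:
    """Generative parameters for one behaviour class's acceleration signal.

    All accelerations in g, frequencies in Hz, angles in degrees,
    temperature in °C.

    The static signal is a gravity vector rotated by slowly wandering
    posture angles (``posture_sd`` degrees of smooth pitch/roll wander on a
    ``posture_tau``-second time-scale) and scaled by a load factor
    ``1 + Σ amp·sin(2π f t)`` from ``load_osc`` — banked dynamic-soaring
    turns raise VeSBA above 1 g without ever collapsing the static vector.
    ``oscillations`` add (axis, frequency, amplitude) periodic components;
    ``wingbeat`` is (bouts/min, bout length s, flap frequency, amplitude) or
    None; ``noise_tau`` low-passes the white noise floor (seconds; 0 keeps
    it white); ``burst_sd`` adds intermittent high-activity noise.
    """

    baseline: tuple = (0.0, 0.0, 0.0)
    noise_sd: tuple = (0.01, 0.01, 0.01)
    noise_tau: float = 0.0
    posture_sd: tuple = (0.0, 0.0)  # pitch, roll wander (degrees)
    posture_tau: float = 2.0
    load_osc: tuple = ()  # (freq_hz, amp) multiplicative on gravity
    oscillations: tuple = ()  # (axis index, freq_hz, amp_g)
    wingbeat: tuple | None = None  # (bouts_per_min, bout_len_s, freq_hz, amp_g)
    burst_sd: float = 0.0
    burst_frac: float = 0.25
    temp_mean: float = 18.0
    temp_sd: float = 0.3


# Defaults hand-tuned so each class satisfies its ethogram criteria when run
# through cahow.signal_metrics (checked by the signature-fidelity tests).
# Burrow temperature defaults to 28 °C vs 18 °C at sea.
DEFAULT_SIGNATURES: dict[BehaviourClass, ClassSignature] = {
    BehaviourClass.BURROW_STILL: ClassSignature(
        noise_sd=(0.005, 0.005, 0.005), temp_mean=28.0, temp_sd=0.15
    ),
    BehaviourClass.BURROW_STIRRING: ClassSignature(
        noise_sd=(0.03, 0.03, 0.03), posture_sd=(2.0, 2.0),
        temp_mean=28.0, temp_sd=0.15,
    ),
    BehaviourClass.BURROW_ACTIVE: ClassSignature(
        noise_sd=(0.12, 0.12, 0.12), posture_sd=(8.0, 8.0), posture_tau=3.0,
        burst_sd=0.4, temp_mean=28.0, temp_sd=0.15,
    ),
    BehaviourClass.WATER_INACTIVE: ClassSignature(
        noise_sd=(0.02, 0.02, 0.02), posture_sd=(1.0, 1.0),
        oscillations=((2, 0.12, 0.03),),  # gentle swell in heave
    ),
    BehaviourClass.WATER_ACTIVE: ClassSignature(
        noise_sd=(0.12, 0.12, 0.12), posture_sd=(8.0, 7.0), posture_tau=2.0,
    ),
    BehaviourClass.WATER_INTENSIVE: ClassSignature(
        noise_sd=(0.7, 0.6, 0.65), posture_sd=(20.0, 18.0), posture_tau=1.5,
    ),
    BehaviourClass.FLYING_DYNAMIC_SOARING: ClassSignature(
        noise_sd=(0.18, 0.18, 0.2), noise_tau=0.12,
        posture_sd=(8.0, 12.0), load_osc=((0.15, 0.68),),
        oscillations=((2, 1.2, 0.55),),
    ),
    BehaviourClass.FLYING_FLAP_GLIDE: ClassSignature(
        noise_sd=(0.16, 0.16, 0.18), noise_tau=0.12,
        posture_sd=(6.0, 8.0), load_osc=((0.18, 0.6),),
        oscillations=((2, 1.2, 0.4),),
        wingbeat=(12.0, 1.5, 6.0, 1.5),
    ),
    BehaviourClass.FLYING_INTENSIVE: ClassSignature(
        noise_sd=(0.28, 0.25, 0.25), noise_tau=0.1,
        posture_sd=(12.0, 15.0), posture_tau=1.0, load_osc=((0.2, 0.6),),
        oscillations=((2, 1.2, 0.3),),
        wingbeat=(6.0, 6.0, 7.0, 2.3),
    ),
}


def _smooth_noise(rng, n, sd, tau, rate):
    """Band-limited Gaussian noise with target standard deviation."""
    x = rng.normal(0.0, 1.0, n)
    if tau > 0 and n > 3:
        x = gaussian_filter1d(x, sigma=max(tau * rate, 1e-6), mode="nearest")
        s = x.std()
        if s > 0:
            x = x / s
    return sd * x


def gen_accel(
    cls: BehaviourClass | str,
    sig: ClassSignature | None = None,
    duration: float = 15.0,
    rate: float = 25.0,
    seed: int = 0,
    start: pd.Timestamp | str = "2023-02-01 00:00:00",
) -> AccelTrace:
    """Generate a tri-axial acceleration trace for one behaviour class."""
    cls = BehaviourClass(cls)
    if duration < 1.0 / rate or rate <= 0:
        raise ValueError("duration and rate must be positive")
    sig = sig if sig is not None else DEFAULT_SIGNATURES[cls]
    rng = spawn_rng(seed, "accel")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    # gravity vector under wandering posture and oscillating load factor
    pitch = np.radians(_smooth_noise(rng, n, sig.posture_sd[0], sig.posture_tau, rate))
    roll = np.radians(_smooth_noise(rng, n, sig.posture_sd[1], sig.posture_tau, rate))
    load = np.ones(n)
    for freq, amp in sig.load_osc:
        load = load + amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    gravity = [
        load * np.sin(pitch),
        load * np.cos(pitch) * np.sin(roll),
        load * np.cos(pitch) * np.cos(roll),
    ]
    axes = []
    for ax in range(3):
        x = gravity[ax] + sig.baseline[ax]
        x += _smooth_noise(rng, n, sig.noise_sd[ax], sig.noise_tau, rate)
        axes.append(x)
    for ax, freq, amp in sig.oscillations:
        phase = rng.uniform(0, 2 * np.pi)
        axes[ax] = axes[ax] + amp * np.sin(2 * np.pi * freq * t + phase)
    if sig.burst_sd > 0:
        env = _smooth_noise(rng, n, 1.0, sig.posture_tau, rate)
        thresh = np.quantile(env, 1.0 - sig.burst_frac)
        mask = env > thresh
        for ax in range(3):
            axes[ax] = axes[ax] + np.where(mask, rng.normal(0, sig.burst_sd, n), 0.0)
    if sig.wingbeat is not None:
        bout_rate, bout_len, freq, amp = sig.wingbeat
        gap = 60.0 / bout_rate
        t0 = rng.uniform(0, gap * 0.5)
        while t0 < duration:
            i0 = int(t0 * rate)
            i1 = min(int((t0 + bout_len) * rate), n)
            tb = t[i0:i1] - t0
            axes[2][i0:i1] += amp * np.sin(2 * np.pi * freq * tb)
            t0 += gap * rng.uniform(0.8, 1.2)
    temp = sig.temp_mean + _smooth_noise(rng, n, sig.temp_sd, 5.0, rate)
    return AccelTrace(
        start=pd.Timestamp(start), rate=rate,
        surge=axes[0], sway=axes[1], heave=axes[2], temperature=temp,
    )


# ------------------------------------------------------------------- depth

def gen_depth(
    dives: list[tuple[float, float, float]],
    total_duration: float,
    drift_max: float = 0.3,
    noise_sd: float = 0.005,
    drift_tau: float = 1800.0,
    seed: int = 0,
    start: pd.Timestamp | str = "2023-02-01 00:00:00",
) -> DepthTrace:
    """Generate a 1 Hz depth trace: bounded drift + scheduled dives + noise.

    ``dives`` is a list of ``(start_s, max_depth_m, duration_s)``.  Each
    dive is a smooth excursion whose deepest sample equals ``max_depth_m``
    and which keeps all its samples above roughly 60% of that maximum, so
    scheduled dives are recoverable by the detection pipeline.  Drift is a
    smoothed random walk confined to [0, drift_max] with correlation
    time-scale ``drift_tau`` seconds — slow relative to the ZOC window, so
    the rolling-percentile correction can follow it.
    """
    if drift_max < 0:
        raise ValueError("drift_max must be >= 0")
    n = int(round(total_duration))
    rng = spawn_rng(seed, "depth")
    if drift_max > 0 and n > 10:
        w = gaussian_filter1d(rng.normal(0, 1, n), sigma=drift_tau, mode="nearest")
        lo, hi = w.min(), w.max()
        drift = (w - lo) / (hi - lo) * drift_max if hi > lo else np.zeros(n)
    else:
        drift = np.zeros(n)
    depth = drift + (rng.normal(0, noise_sd, n) if noise_sd > 0 else 0.0)
    occupied = np.zeros(n, dtype=bool)
    for t0, max_depth, dur in sorted(dives):
        i0, i1 = int(round(t0)), int(round(t0)) + int(round(dur))
        if i0 < 0 or i1 > n:
            raise ValueError("scheduled dive falls outside the trace")
        if occupied[i0:i1].any():
            raise ValueError("overlapping scheduled dives")
        occupied[i0:i1] = True
        k = i1 - i0
        shape = np.sin(np.pi * (np.arange(k) + 1) / (k + 1))
        depth[i0:i1] += max_depth * shape / shape.max()
    return DepthTrace(start=pd.Timestamp(start), depth=depth)


# ---------------------------------------------------------- diel behaviour

@dataclass
class DielGenerator:
    """Markov behaviour generator over the six at-sea classes.

    ``transition`` is the row-stochastic base matrix (mean dwell controls
    bout lengths); ``sun_mod`` tilts the per-step destination weights by
    ``exp(sun_mod[j] * sun_angle)``, so positive coefficients make a class
    more likely at high sun (daytime) and negative ones favour it at night.
    ``precision`` is the beta precision used when proportions are simulated
    directly from the regression model.
    """

    classes: tuple = AT_SEA_CLASSES
    transition: np.ndarray | None = None
    sun_mod: tuple = (0.9, 0.8, 0.5, -0.2, -0.6, 0.0)
    precision: float = 10.0
    switch_rate: float = 0.02  # per-second probability of leaving a bout
    # stationary occupancy matching the observed at-sea activity budget
    occupancy: tuple = (0.062, 0.092, 0.045, 0.529, 0.276, 0.009)

    def __post_init__(self):
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        self._jump_to_tilted_occupancy = self.transition is None
        if self.transition is None:
            pi = np.asarray(self.occupancy, dtype=float)
            pi = pi / pi.sum()
            k = len(self.classes)
            self.transition = (1 - self.switch_rate) * np.eye(k) + (
                self.switch_rate * np.tile(pi, (k, 1))
            )
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (len(self.classes), len(self.classes)):
            raise ValueError("transition matrix shape mismatch")
        if np.any(self.transition < 0) or not np.allclose(
            self.transition.sum(axis=1), 1.0
        ):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")


def gen_diel_sequence(
    gen: DielGenerator,
    start: pd.Timestamp | str,
    duration_h: float,
    colony_lonlat=COLONY_LONLAT,
    seed: int = 0,
) -> pd.Series:
    """Per-second at-sea class labels whose occupancy tracks the sun angle."""
    start = pd.Timestamp(start)
    n = int(round(duration_h * 3600))
    lon, lat = colony_lonlat
    # sun angle per minute, held constant within the minute
    minutes = pd.date_range(start, periods=int(np.ceil(n / 60)), freq="min")
    sun_min = sun_angle(lat, lon, minutes + pd.Timedelta(seconds=30))
    sun = np.repeat(sun_min, 60)[:n]
    mod = np.asarray(gen.sun_mod, dtype=float)
    k = len(gen.classes)
    rng = spawn_rng(seed, "diel")
    # per-minute cumulative transition rows (weights tilted by sun angle)
    labels = np.empty(n, dtype=np.int64)
    state = int(rng.integers(0, k))
    u = rng.random(n)
    cum = None
    pi0 = np.asarray(gen.occupancy, dtype=float)
    pi0 = pi0 / pi0.sum()
    for i in range(n):
        if i % 60 == 0:
            tilt = np.exp(mod * sun[i])
            if gen._jump_to_tilted_occupancy:
                # jump-to-stationary chain: tilting the target distribution
                # keeps the realised occupancy equal to the tilted occupancy
                pi_t = pi0 * tilt
                pi_t /= pi_t.sum()
                W = (1 - gen.switch_rate) * np.eye(k) + gen.switch_rate * np.tile(
                    pi_t, (k, 1)
                )
            else:
                W = gen.transition * tilt[None, :]
                W /= W.sum(axis=1, keepdims=True)
            cum = np.cumsum(W, axis=1)
        state = int(np.searchsorted(cum[state], u[i]))
        labels[i] = state
    values = [gen.classes[s].value for s in labels]
    index = pd.date_range(start, periods=n, freq="s")
    return pd.Series(values, index=index, name="behaviour")


# --------------------------------------------------------------------- GPS

def _destination(lon0, lat0, bearing_rad, dist_km):
    """Point at great-circle distance ``dist_km`` along ``bearing`` (exact)."""
    d = dist_km / EARTH_RADIUS_KM
    lat0, lon0 = np.radians(lat0), np.radians(lon0)
    lat = np.arcsin(
        np.sin(lat0) * np.cos(d) + np.cos(lat0) * np.sin(d) * np.cos(bearing_rad)
    )
    lon = lon0 + np.arctan2(
        np.sin(bearing_rad) * np.sin(d) * np.cos(lat0),
        np.cos(d) - np.sin(lat0) * np.sin(lat),
    )
    return np.degrees(lon), np.degrees(lat)


def gen_track(
    colony=COLONY_LONLAT,
    trip_duration: float = 10.0,
    max_range: float = 1200.0,
    fix_interval: float = 60.0,
    seed: int = 0,
    start: pd.Timestamp | str = "2023-02-01 00:00:00",
    bird: str = "SYN1",
    truncate_fraction: float | None = None,
) -> GpsTrack:
    """Out-and-back foraging track as a correlated random walk.

    The distance-from-colony profile rises smoothly to ``max_range`` km at
    mid-trip and returns, with small correlated wiggle; the bearing drifts
    slowly around a random outbound direction.  The track is book-ended by
    fixes at the colony.  ``truncate_fraction`` keeps only the first part of
    the track (emulating a logger failing mid-trip), which yields an
    incomplete trip downstream.
    """
    if trip_duration <= 0:
        raise ValueError("trip duration must be positive")
    if max_range <= 1.0:
        raise ValueError("max_range must exceed the 1 km colony exclusion")
    rng = spawn_rng(seed, "track")
    n = int(round(trip_duration * 24 * 60 / fix_interval)) + 1
    u = np.linspace(0.0, 1.0, n)
    radial = max_range * np.sin(np.pi * u)
    wiggle = _smooth_noise(rng, n, 0.015 * max_range, 3.0, 1.0)
    radial = np.clip(radial + wiggle, 0.0, None)
    radial[0] = radial[-1] = 0.0
    # the smooth profile peaks within wiggle of max_range; pin the apex
    radial[np.argmax(radial)] = max_range
    bearing = np.radians(rng.uniform(0, 360)) + _smooth_noise(rng, n, 0.15, 5.0, 1.0)
    lon, lat = _destination(colony[0], colony[1], bearing, radial)
    times = pd.date_range(
        pd.Timestamp(start), periods=n, freq=pd.Timedelta(minutes=fix_interval)
    )
    fixes = pd.DataFrame({"timestamp": times, "lon": lon, "lat": lat})
    if truncate_fraction is not None:
        fixes = fixes.iloc[: max(int(n * truncate_fraction), 2)].reset_index(drop=True)
    return GpsTrack(bird=bird, fixes=fixes)


# ------------------------------------------------------- full deployments

def gen_training_segments(
    n_per_bird: int = 400,
    n_birds: int = 11,
    seed: int = 0,
    classes: tuple = ALL_CLASSES,
    signatures: dict | None = None,
    rate: float = 25.0,
):
    """Balanced labelled 15-s segments emulating a manual training set.

    For each of ``n_birds`` birds, generates ``n_per_bird`` single-class
    15-s traces (classes assigned round-robin, so the set is as balanced as
    the counts allow), computes per-sample metrics and the 36 segment
    features.  Returns a feature table with ``bird`` and ``label`` columns.
    """
    from .classify import features_table
    from .signal_metrics import compute_metrics

    signatures = signatures or DEFAULT_SIGNATURES
    rows = []
    base = pd.Timestamp("2023-02-01 00:00:00")
    base_seed = int(spawn_rng(seed, "labels").integers(0, 2**31 - 1))
    counter = 0
    for b in range(n_birds):
        for i in range(n_per_bird):
            cls = classes[(b * n_per_bird + i) % len(classes)]
            trace = gen_accel(
                cls, signatures.get(cls), duration=15.0, rate=rate,
                seed=(base_seed + counter) % (2**31 - 1),
                start=base + pd.Timedelta(seconds=15 * counter),
            )
            metrics = compute_metrics(trace)
            rows.append((f"B{b:02d}", cls.value, metrics))
            counter += 1
    segs = [m for _, _, m in rows]
    table = features_table(
        segs,
        labels=[lab for _, lab, _ in rows],
        bird=[bd for bd, _, _ in rows],
    )
    return table


@dataclass
class DeploymentConfig:
    """Configuration for a full synthetic deployment."""

    bird: str = "SYN1"
    start: str = "2023-02-01 00:00:00"
    burrow_h: float = 2.0  # burrow time before and after the trip
    at_sea_h: float = 20.0
    block_s: int = 15  # behaviour changes only at block boundaries
    dives: tuple | None = None  # default: two shallow dives mid-trip
    drift_max: float = 0.3
    depth_noise_sd: float = 0.005
    max_range_km: float = 1200.0
    fix_interval_min: float = 60.0
    colony: tuple = COLONY_LONLAT
    diel: DielGenerator = field(default_factory=DielGenerator)
    signatures: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURES))
    seed: int = 0

    def __post_init__(self):
        if self.burrow_h < 0 or self.at_sea_h <= 0:
            raise ValueError("inconsistent date ranges")
        if self.dives is None:
            sea_s = self.at_sea_h * 3600
            self.dives = ((0.35 * sea_s, 0.59, 1.0), (0.65 * sea_s, 1.57, 4.0))
        for t0, _, dur in self.dives:
            if t0 < 0 or t0 + dur > self.at_sea_h * 3600:
                raise ValueError("inconsistent date ranges: dive outside trip")


@dataclass
class Deployment:
    """One synthetic deployment: aligned streams plus ground-truth labels."""

    accel: AccelTrace
    depth: DepthTrace
    track: GpsTrack
    labels: pd.DataFrame  # start, end, class — partitions the accel timeline


def _burrow_blocks(n_blocks: int, rng) -> list[str]:
    # mostly still, occasional stirring/active interludes
    probs = [0.75, 0.18, 0.07]
    choices = [
        BehaviourClass.BURROW_STILL.value,
        BehaviourClass.BURROW_STIRRING.value,
        BehaviourClass.BURROW_ACTIVE.value,
    ]
    return [choices[rng.choice(3, p=probs)] for _ in range(n_blocks)]


def gen_logger_dataset(config: DeploymentConfig, outdir=None) -> Deployment:
    """Generate one full deployment and optionally write the CSV layout.

    The behaviour timeline is burrow → at sea (diel Markov) → burrow,
    quantised to ``block_s``-second blocks so ground-truth labels align with
    classification segments; the accelerometer trace is synthesised per
    block run, the depth trace covers the at-sea period with the scheduled
    dives, and the GPS track is an out-and-back trip spanning it.
    """
    rng = spawn_rng(config.seed, "labels")
    start = pd.Timestamp(config.start)
    blk = config.block_s
    n_burrow = int(config.burrow_h * 3600 / blk)
    n_sea = int(config.at_sea_h * 3600 / blk)
    sea_start = start + pd.Timedelta(seconds=n_burrow * blk)
    diel_fine = gen_diel_sequence(
        config.diel, sea_start, n_sea * blk / 3600.0,
        colony_lonlat=config.colony, seed=config.seed,
    )
    # modal label per block
    sea_blocks = [
        diel_fine.iloc[i * blk : (i + 1) * blk].mode().iloc[0] for i in range(n_sea)
    ]
    blocks = (
        _burrow_blocks(n_burrow, rng) + sea_blocks + _burrow_blocks(n_burrow, rng)
    )
    # merge consecutive equal labels into runs, generate accel per run
    traces, label_rows = [], []
    t_cursor = start
    i = 0
    while i < len(blocks):
        j = i
        while j < len(blocks) and blocks[j] == blocks[i]:
            j += 1
        run_s = (j - i) * blk
        cls = BehaviourClass(blocks[i])
        traces.append(
            gen_accel(
                cls, config.signatures.get(cls), duration=run_s,
                seed=int(rng.integers(0, 2**31 - 1)), start=t_cursor,
            )
        )
        label_rows.append(
            {
                "start": t_cursor,
                "end": t_cursor + pd.Timedelta(seconds=run_s),
                "class": cls.value,
            }
        )
        t_cursor += pd.Timedelta(seconds=run_s)
        i = j
    accel = AccelTrace(
        start=start,
        rate=traces[0].rate,
        surge=np.concatenate([tr.surge for tr in traces]),
        sway=np.concatenate([tr.sway for tr in traces]),
        heave=np.concatenate([tr.heave for tr in traces]),
        temperature=np.concatenate([tr.temperature for tr in traces]),
    )
    depth = gen_depth(
        list(config.dives), total_duration=n_sea * blk,
        drift_max=config.drift_max, noise_sd=config.depth_noise_sd,
        seed=config.seed, start=sea_start,
    )
    track = gen_track(
        colony=config.colony, trip_duration=n_sea * blk / 86400.0,
        max_range=config.max_range_km, fix_interval=config.fix_interval_min,
        seed=config.seed, start=sea_start, bird=config.bird,
    )
    labels = pd.DataFrame(label_rows)
    dep = Deployment(accel=accel, depth=depth, track=track, labels=labels)
    if outdir is not None:
        from . import io as cio

        cio.write_deployment(dep, outdir)
    return dep
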