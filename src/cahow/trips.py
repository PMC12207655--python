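"""Central-place foraging trip segmentation and summaries from GPS tracks.

A foraging trip is the period between a bird's departure from and return to
the breeding colony, with fixes inside a 1 km exclusion radius around the
colony discarded (these are on land or rafting birds).  A trip is *complete*
when it is bracketed by within-radius fixes on both sides; trips lasting at
least two days are flagged *long*, separating multi-day foraging excursions
from brief near-colony loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GpsTrack",
    "Trip",
    "great_circle_km",
    "segment_trips",
    "classify_long",
    "trip_summary",
    "exclusion_filter",
]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

#: Nonsuch Island colony, 32°20' N 64°40' W, in decimal degrees (lon, lat).
COLONY_LONLAT = (-64.6667, 32.3333)


@dataclass
class GpsTrack:
    """Time-ordered GPS fixes for one bird."""

    bird: str
    fixes: pd.DataFrame  # columns: timestamp, lon, lat

    def __post_init__(self):
        t = pd.to_datetime(self.fixes["timestamp"])
        if not t.is_monotonic_increasing or t.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        lat = self.fixes["lat"]
        lon = self.fixes["lon"]
        if (lat.abs() > 90).any() or (lon.abs() > 180).any():
            raise ValueError("coordinates outside WGS84 bounds")


@dataclass
class Trip:
    """One departure-return excursion from the colony."""

    bird: str
    start: pd.Timestamp
    end: pd.Timestamp
    duration_days: float
    max_distance_km: float
    complete: bool
    long: bool = False


def great_circle_km(a, b) -> float:
    """Haversine distance in km between (lon, lat) points, degrees."""
    lon1, lat1 = np.radians(np.asarray(a, dtype=float))
    lon2, lat2 = np.radians(np.asarray(b, dtype=float))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def _distances_km(track: GpsTrack, colony) -> np.ndarray:
    lon0, lat0 = np.radians(np.asarray(colony, dtype=float))
    lon = np.radians(track.fixes["lon"].to_numpy(dtype=float))
    lat = np.radians(track.fixes["lat"].to_numpy(dtype=float))
    h = (
        np.sin((lat - lat0) / 2) ** 2
        + np.cos(lat0) * np.cos(lat) * np.sin((lon - lon0) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def segment_trips(
    track: GpsTrack, colony=COLONY_LONLAT, exclusion: float = 1.0
) -> list[Trip]:
    """Split a track into trips: maximal runs of fixes beyond the exclusion.

    A trip is complete iff both the preceding and following fix lie within
    the exclusion radius; trips truncated by the start or end of the track
    are incomplete.  Start/end times are the first/last at-sea fix.
    """
    if len(track.fixes) < 2:
        raise ValueError("need at least 2 fixes")
    dist = _distances_km(track, colony)
    away = dist > exclusion
    if not away.any():
        return []
    t = pd.to_datetime(track.fixes["timestamp"]).to_numpy()
    edges = np.diff(away.astype(int))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1
    if away[0]:
        starts = np.r_[0, starts]
    if away[-1]:
        ends = np.r_[ends, len(away)]
    trips = []
    for i0, i1 in zip(starts, ends):
        t0, t1 = pd.Timestamp(t[i0]), pd.Timestamp(t[i1 - 1])
        trips.append(
            Trip(
                bird=track.bird,
                start=t0,
                end=t1,
                duration_days=(t1 - t0) / pd.Timedelta(days=1),
                max_distance_km=float(dist[i0:i1].max()),
                complete=bool(i0 > 0 and i1 < len(away)),
            )
        )
    return trips


def classify_long(trips: list[Trip], min_duration: float = 2.0) -> list[Trip]:
    """Set the ``long`` flag: trips of at least ``min_duration`` days."""
    for trip in trips:
        trip.long = trip.duration_days >= min_duration
    return trips


def trip_summary(trips: list[Trip]) -> pd.DataFrame:
    """Mean ± sample SD of duration (days) and maximum distance (km).

    Intended for complete long trips; with fewer than two trips the SD is
    undefined and reported as NaN.
    """
    if len(trips) == 0:
        raise ValueError("no trips to summarise")
    dur = np.array([t.duration_days for t in trips], dtype=float)
    dist = np.array([t.max_distance_km for t in trips], dtype=float)
    sd = (lambda x: float(np.std(x, ddof=1))) if len(trips) > 1 else (lambda x: np.nan)
    return pd.DataFrame(
        {
            "n": len(trips),
            "duration_mean_days": dur.mean(),
            "duration_sd_days": sd(dur),
            "max_distance_mean_km": dist.mean(),
            "max_distance_sd_km": sd(dist),
        },
        index=[0],
    )


def exclusion_filter(track: GpsTrack, colony=COLONY_LONLAT, radius: float = 50.0):
    """Drop fixes within ``radius`` km of the colony (distribution analyses).

    Returns ``(filtered_track, n_removed)``.  Only distant fixes reflect
    unequivocal foraging, so space-use estimates exclude the colony's
    surroundings.
    """
    dist = _distances_km(track, colony)
    keep = dist >= radius if radius > 0 else np.ones(len(dist), dtype=bool)
    removed = int((~keep).sum())
    fixes = track.fixes.loc[keep].reset_index(drop=True)
    return GpsTrack(bird=track.bird, fixes=fixes), removed
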