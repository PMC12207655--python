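"""Published foraging-trip metrics for Bermuda petrels, Nonsuch Island 2023.

The eight complete incubation foraging trips recorded by tail-mounted GPS
loggers (one fix per hour) on seven birds.  Durations are in days and
maximum distances from the colony in km, as printed in the deposited study
summary.  Seven trips are multi-day ("long"); one 1.9-day excursion is the
single short complete trip.

These records serve as a worked example for :func:`cahow.trips.trip_summary`
and as the desk-scale reference inputs of the acceptance checks.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["complete_trips"]

_COMPLETE_TRIPS = [
    # bird, trip, duration_days, max_distance_km
    ("E0487", 1, 9.2, 1493.0),
    ("E0243", 1, 12.5, 1503.0),
    ("E0161", 1, 9.8, 1100.0),
    ("E0801", 1, 1.9, 232.0),
    ("E0801", 2, 12.7, 1433.0),
    ("E0363", 1, 13.9, 1003.0),
    ("E0484", 1, 5.9, 675.0),
    ("E0552", 1, 7.9, 1241.0),
]


def complete_trips(long_only: bool = False, min_duration: float = 2.0) -> pd.DataFrame:
    """The complete GPS-recorded foraging trips (optionally long trips only)."""
    df = pd.DataFrame(
        _COMPLETE_TRIPS, columns=["bird", "trip", "duration_days", "max_distance_km"]
    )
    if long_only:
        df = df[df["duration_days"] >= min_duration].reset_index(drop=True)
    return df
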