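"""Solar elevation from time and place (NOAA low-precision ephemeris).

Implements the standard NOAA solar-position geometry (Meeus-style series for
solar longitude, declination and the equation of time) to compute the
*geometric* elevation of the sun — positive by day, negative at night, zero
at sunrise/sunset — accurate to a few hundredths of a degree over
1950-2050.  Atmospheric refraction is not applied; the diel analysis only
needs the sign and smooth magnitude of the sun angle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["sun_angle", "solar_declination_eot"]


def _julian_century(times: pd.DatetimeIndex) -> np.ndarray:
    # days since J2000.0 epoch (2000-01-01 12:00 UTC)
    epoch = pd.Timestamp("2000-01-01 12:00:00")
    days = (times - epoch) / pd.Timedelta(days=1)
    return np.asarray(days, dtype=float) / 36525.0


def solar_declination_eot(times: pd.DatetimeIndex):
    """Solar declination (radians) and equation of time (minutes)."""
    T = _julian_century(times)
    L0 = np.remainder(280.46646 + T * (36000.76983 + T * 0.0003032), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = np.radians(M)
    C = (
        np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + np.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = np.radians(125.04 - 1934.136 * T)
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(eps) * np.sin(np.radians(app_long)))
    y = np.tan(eps / 2.0) ** 2
    L0r = np.radians(L0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(Mr)
        + 4.0 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y**2 * np.sin(4 * L0r)
        - 1.25 * e**2 * np.sin(2 * Mr)
    )
    return decl, eot


def sun_angle(lat: float, lon: float, times) -> np.ndarray:
    """Geometric solar elevation in radians at (lat, lon) for UTC times.

    ``times`` may be a single timestamp, a sequence, or a DatetimeIndex.
    Scalar input returns a scalar.
    """
    if np.abs(lat) > 90 or np.abs(lon) > 180:
        raise ValueError("invalid coordinates")
    scalar = np.isscalar(times) or isinstance(times, (str, pd.Timestamp))
    idx = pd.DatetimeIndex([times] if scalar else pd.to_datetime(times))
    decl, eot = solar_declination_eot(idx)
    minutes = (
        idx.hour.to_numpy() * 60.0
        + idx.minute.to_numpy()
        + idx.second.to_numpy() / 60.0
        + idx.microsecond.to_numpy() / 6e7
    )
    tst = np.remainder(minutes + eot + 4.0 * lon, 1440.0)
    hour_angle = np.radians(tst / 4.0 - 180.0)
    latr = np.radians(lat)
    elev = np.arcsin(
        np.sin(latr) * np.sin(decl)
        + np.cos(latr) * np.cos(decl) * np.cos(hour_angle)
    )
    return float(elev[0]) if scalar else elev
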