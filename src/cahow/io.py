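"""CSV layouts for logger streams and pipeline outputs.

All files are comma-separated UTF-8 with a header row and ISO-8601 UTC
timestamps.  Pipeline outputs carry a leading ``#`` comment line naming the
package version and the configuration hash that produced them; the readers
skip such lines.

Layouts:

- accelerometer: ``timestamp, ax_g, ay_g, az_g, temp_c`` (25 Hz)
- depth:         ``timestamp, depth_m`` (1 Hz)
- GPS:           ``timestamp, lon, lat``
- labels:        ``start, end, class``
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .dive import DepthTrace
from .signal_metrics import AccelTrace
from .trips import GpsTrack

TIME_FMT = "%Y-%m-%dT%H:%M:%S.%f"


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_line(meta: str | None) -> str:
    from . import __version__

    tag = f"# cahow {__version__}"
    return tag + (f" {meta}" if meta else "") + "\n"


def write_csv(df: pd.DataFrame, path, meta: str | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_line(meta))
        df.to_csv(fh, index=False, date_format=TIME_FMT, float_format="%.6f")


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_accel(trace: AccelTrace, path, meta=None):
    write_csv(trace.to_frame(), path, meta)


def read_accel(path, rate: float = 25.0) -> AccelTrace:
    df = read_csv(path, parse_dates=["timestamp"])
    return AccelTrace.from_frame(df, rate=rate)


def write_depth(trace: DepthTrace, path, meta=None):
    write_csv(trace.to_frame(), path, meta)


def read_depth(path, rate: float = 1.0) -> DepthTrace:
    df = read_csv(path, parse_dates=["timestamp"])
    return DepthTrace.from_frame(df, rate=rate)


def write_gps(track: GpsTrack, path, meta=None):
    write_csv(track.fixes, path, meta)


def read_gps(path, bird: str = "bird") -> GpsTrack:
    df = read_csv(path, parse_dates=["timestamp"])
    return GpsTrack(bird=bird, fixes=df)


def write_labels(labels: pd.DataFrame, path, meta=None):
    write_csv(labels, path, meta)


def read_labels(path) -> pd.DataFrame:
    return read_csv(path, parse_dates=["start", "end"])


def write_deployment(dep, outdir, meta=None):
    """Write one deployment to the standard four-file layout."""
    outdir = Path(outdir)
    write_accel(dep.accel, outdir / "accel.csv", meta)
    write_depth(dep.depth, outdir / "depth.csv", meta)
    write_gps(dep.track, outdir / "gps.csv", meta)
    write_labels(dep.labels, outdir / "labels.csv", meta)


def read_deployment(outdir, bird: str = "bird"):
    from .synthetic import Deployment

    outdir = Path(outdir)
    return Deployment(
        accel=read_accel(outdir / "accel.csv"),
        depth=read_depth(outdir / "depth.csv"),
        track=read_gps(outdir / "gps.csv", bird=bird),
        labels=read_labels(outdir / "labels.csv"),
    )
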