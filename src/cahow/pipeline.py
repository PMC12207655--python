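"""End-to-end orchestration of the biologging analysis stages.

``run_all`` takes a :class:`PipelineConfig`, reads the raw CSV streams,
and produces every analysis product — per-sample metrics, 15-s segment
features, behaviour predictions, dive events, hourly diel budgets and
zero-inflated beta fits, and foraging-trip tables — together with a run
manifest recording versions, seeds, parameters and per-stage timings.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .classify import (
    ClassifierConfig,
    features_table,
    segment,
    train_classifier,
)
from .diel import fit_zib, hourly_budget
from .dive import detect_dives, depth_histogram, repair_outliers, zero_offset_correct
from .taxonomy import AT_SEA_CLASSES, collapse_modes
from .trips import COLONY_LONLAT, classify_long, segment_trips, trip_summary

logger = logging.getLogger("cahow")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Paths plus every stage parameter (defaults are the study's)."""

    accel_path: str | None = None
    depth_path: str | None = None
    gps_path: str | None = None
    labels_path: str | None = None
    outdir: str = "cahow_out"
    bird: str = "bird"
    colony: tuple = COLONY_LONLAT
    accel_rate: float = 25.0
    static_window_s: float = 1.0
    wingbeat_amp_g: float = 1.0
    wingbeat_min_rate_hz: float = 4.0
    wingbeat_min_successive: int = 2
    depth_outlier_m: float = 15.0
    zoc_window_min: float = 10.0
    zoc_quantile: float = 0.10
    dive_threshold_m: float = 0.5
    depth_bin_m: float = 0.1
    segment_length_s: float = 15.0
    trip_exclusion_km: float = 1.0
    long_trip_days: float = 2.0
    min_at_sea_fraction: float = 0.5
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def validate(self):
        if not 0 < self.zoc_quantile < 1:
            raise ValueError("zoc_quantile must be in (0, 1)")
        for name in ("accel_path", "depth_path", "gps_path", "labels_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")
        return self


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_all(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the manifest dict.

    Stages whose inputs are absent are skipped with a warning; degenerate
    inputs (e.g. burrow-only accelerometer data) produce empty outputs
    rather than errors.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = _to_plain(asdict(config))
    # the hash characterises the analysis parameters, not where output lands
    chash = cio.config_hash({k: v for k, v in cfg_dict.items() if k != "outdir"})
    meta = f"config={chash}"
    manifest: dict = {
        "config": cfg_dict,
        "config_hash": chash,
        "outputs": [],
        "timings_s": {},
        "warnings": [],
    }
    from . import __version__

    manifest["version"] = __version__

    def warn(msg):
        logger.warning(msg)
        manifest["warnings"].append(msg)

    def emit(df, name):
        path = outdir / name
        cio.write_csv(df, path, meta)
        manifest["outputs"].append(str(path))

    metrics = None
    if config.accel_path:
        t0 = time.perf_counter()
        from .signal_metrics import compute_metrics

        trace = cio.read_accel(config.accel_path, rate=config.accel_rate)
        metrics = compute_metrics(
            trace,
            window=config.static_window_s,
            amp_threshold=config.wingbeat_amp_g,
            min_rate=config.wingbeat_min_rate_hz,
            min_successive=config.wingbeat_min_successive,
        )
        emit(metrics.reset_index(names="timestamp"), "metrics.csv")
        manifest["timings_s"]["metrics"] = time.perf_counter() - t0

    if config.depth_path:
        t0 = time.perf_counter()
        depth = cio.read_depth(config.depth_path)
        repaired, n_out = repair_outliers(depth, config.depth_outlier_m)
        corrected, zoc = zero_offset_correct(
            repaired, window=config.zoc_window_min, quantile=config.zoc_quantile
        )
        dives = detect_dives(corrected, threshold=config.dive_threshold_m)
        emit(
            pd.DataFrame(
                [
                    {
                        "start": d.start,
                        "duration_s": d.duration_s,
                        "max_depth_m": d.max_depth_m,
                        "mean_depth_m": d.mean_depth_m,
                    }
                    for d in dives
                ],
                columns=["start", "duration_s", "max_depth_m", "mean_depth_m"],
            ),
            "dives.csv",
        )
        emit(depth_histogram(corrected, config.depth_bin_m), "depth_histogram.csv")
        manifest["dive_stats"] = {
            "n_outliers_repaired": n_out,
            "n_dives": len(dives),
            "max_depth_m": max((d.max_depth_m for d in dives), default=0.0),
            "max_zoc_m": float(np.max(zoc)),
        }
        manifest["timings_s"]["dives"] = time.perf_counter() - t0

    predictions = None
    if metrics is not None and config.labels_path:
        t0 = time.perf_counter()
        labels = cio.read_labels(config.labels_path)
        segs = segment(metrics, config.segment_length_s, config.accel_rate)
        seg_labels = []
        for seg_df in segs:
            t_mid = seg_df.index[len(seg_df) // 2]
            hit = labels[(labels["start"] <= t_mid) & (labels["end"] > t_mid)]
            seg_labels.append(hit["class"].iloc[0] if len(hit) else None)
        keep = [i for i, lab in enumerate(seg_labels) if lab is not None]
        feats = features_table(
            [segs[i] for i in keep],
            labels=[seg_labels[i] for i in keep],
            bird=config.bird,
        )
        emit(feats, "segment_features.csv")
        # classes too rare to stratify and cross-validate cannot be trained on
        min_count = max(4, config.classifier.cv_folds)
        counts = feats["label"].value_counts()
        rare = counts[counts < min_count].index.tolist()
        if rare:
            warn(f"dropping rare behaviour classes from training: {rare}")
            feats = feats[~feats["label"].isin(rare)].reset_index(drop=True)
        if feats["label"].nunique() < 2:
            warn("fewer than 2 behaviour classes; classifier stage skipped")
        else:
            result = train_classifier(feats, config.classifier)
            feat_cols = [
                c for c in feats.columns if c not in ("label", "bird", "start")
            ]
            pred = result.model.predict(feats[feat_cols])
            predictions = pd.DataFrame(
                {
                    "start": feats["start"],
                    "label": feats["label"],
                    "predicted": pred,
                    "predicted_mode": collapse_modes(pred),
                }
            )
            emit(predictions, "predictions.csv")
            report = result.report.to_json_dict()
            report["selected_features"] = result.model.selected_features_
            (outdir / "classifier_report.json").write_text(
                json.dumps(_to_plain(report), indent=2)
            )
            manifest["outputs"].append(str(outdir / "classifier_report.json"))
        manifest["timings_s"]["classifier"] = time.perf_counter() - t0

    if predictions is not None:
        t0 = time.perf_counter()
        at_sea = predictions[
            [collapse_modes(p) != "burrow" for p in predictions["predicted"]]
        ]
        if len(at_sea) == 0:
            warn("no at-sea behaviour predicted; diel stage emits empty outputs")
            emit(pd.DataFrame(), "budgets.csv")
        else:
            per_second = (
                predictions.set_index("start")["predicted"]
                .resample("1s").ffill().dropna()
            )
            budgets = hourly_budget(
                per_second,
                colony_lonlat=config.colony,
                bird=config.bird,
                min_at_sea=config.min_at_sea_fraction,
            )
            emit(budgets, "budgets.csv")
            fits = []
            for cls in AT_SEA_CLASSES:
                if len(budgets) < 30:
                    warn("too few hourly budgets for diel model fits")
                    break
                fit = fit_zib(
                    budgets["sun_angle_rad"].to_numpy(),
                    budgets[cls.value].to_numpy(),
                )
                s = fit.summary_.copy()
                s.insert(0, "behaviour", cls.value)
                s["converged"] = fit.converged_
                fits.append(s)
            if fits:
                emit(pd.concat(fits, ignore_index=True), "diel_fits.csv")
        manifest["timings_s"]["diel"] = time.perf_counter() - t0

    if config.gps_path:
        t0 = time.perf_counter()
        track = cio.read_gps(config.gps_path, bird=config.bird)
        trips = classify_long(
            segment_trips(track, config.colony, config.trip_exclusion_km),
            config.long_trip_days,
        )
        trip_df = pd.DataFrame(
            [
                {
                    "bird": t.bird,
                    "start": t.start,
                    "end": t.end,
                    "duration_days": t.duration_days,
                    "max_distance_km": t.max_distance_km,
                    "complete": t.complete,
                    "long": t.long,
                }
                for t in trips
            ]
        )
        emit(trip_df, "trips.csv")
        full = [t for t in trips if t.complete and t.long]
        if len(full) >= 2:
            emit(trip_summary(full), "trip_summary.csv")
        else:
            warn("fewer than 2 complete long trips; no trip summary")
        manifest["timings_s"]["trips"] = time.perf_counter() - t0

    (outdir / "manifest.json").write_text(json.dumps(_to_plain(manifest), indent=2))
    return manifest
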