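"""Synthetic generator fidelity, determinism and round-trips."""

import numpy as np
import pandas as pd
import pytest

from cahow import io as cio
from cahow.dive import detect_dives, repair_outliers, zero_offset_correct
from cahow.signal_metrics import compute_metrics, detect_wingbeats
from cahow.synthetic import (
    DEFAULT_SIGNATURES,
    DeploymentConfig,
    DielGenerator,
    gen_accel,
    gen_depth,
    gen_diel_sequence,
    gen_logger_dataset,
    gen_track,
    gen_training_segments,
)
from cahow.taxonomy import AT_SEA_CLASSES, BehaviourClass, collapse_modes
from cahow.trips import segment_trips


class TestGenAccel:
    def test_burrow_still_nearly_motionless(self):
        tr = gen_accel("burrow-still", duration=15, seed=1)
        m = compute_metrics(tr)
        assert m.vedba.mean() < 0.05
        q75, q25 = np.percentile(tr.heave, [75, 25])
        assert q75 - q25 < 0.05

    def test_flap_glide_has_regular_wingbeat_bouts(self):
        tr = gen_accel("flying-flap-glide", duration=60, seed=1)
        res = detect_wingbeats(tr.heave, rate=25)
        bouts3 = [b for b in res.bouts if len(b) >= 3]
        assert len(bouts3) >= 4

    def test_water_inactive_low_activity(self):
        m = compute_metrics(gen_accel("water-inactive", duration=15, seed=2))
        assert m.vedba.mean() < 0.1
        assert np.all((m.vesba > 0.9) & (m.vesba < 1.1))

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            gen_accel("swimming-backwards", duration=15, seed=1)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            gen_accel("burrow-still", duration=0, seed=1)

    def test_determinism(self):
        a = gen_accel("flying-intensive", duration=15, seed=9)
        b = gen_accel("flying-intensive", duration=15, seed=9)
        assert np.array_equal(a.heave, b.heave)
        assert np.array_equal(a.temperature, b.temperature)

    @pytest.mark.parametrize("cls", list(BehaviourClass), ids=lambda c: c.value)
    def test_signature_fidelity(self, cls):
        """At least 95% of 15-s windows satisfy the class's defining criteria."""
        checks = {
            BehaviourClass.BURROW_STILL: lambda m, wb: m.vedba.mean() < 0.05,
            BehaviourClass.BURROW_STIRRING: lambda m, wb: (
                m.vedba.max() < 1.0 and 0.02 < m.vedba.mean() < 0.3
            ),
            BehaviourClass.BURROW_ACTIVE: lambda m, wb: (
                m.vedba.max() > 1.0
                and max(m.pitch.max() - m.pitch.min(),
                        m.roll.max() - m.roll.min()) > 10
            ),
            BehaviourClass.WATER_INACTIVE: lambda m, wb: (
                m.vedba.mean() < 0.1 and m.vesba.max() < 1.1
            ),
            BehaviourClass.WATER_ACTIVE: lambda m, wb: (
                0.1 < m.vedba.mean() < 1.0
                and 10 < m.pitch.max() - m.pitch.min() < 60
            ),
            BehaviourClass.WATER_INTENSIVE: lambda m, wb: (
                m.vedba.mean() > 0.9 and m.vedba.max() > 2.0
                and m.vesba.max() < 1.5
            ),
            BehaviourClass.FLYING_DYNAMIC_SOARING: lambda m, wb: (
                m.vesba.max() > 1.5 and m.heave.max() > 2.0 and wb.n_beats == 0
            ),
            BehaviourClass.FLYING_FLAP_GLIDE: lambda m, wb: (
                m.vesba.max() > 1.5
                and any(len(b) >= 3 for b in wb.bouts)
            ),
            BehaviourClass.FLYING_INTENSIVE: lambda m, wb: (
                m.heave.max() > 3.0 and wb.n_beats > 10
            ),
        }
        ok = 0
        n_win = 40
        for seed in range(n_win):
            tr = gen_accel(cls, duration=15, seed=seed)
            m = compute_metrics(tr)
            wb = detect_wingbeats(tr.heave, rate=25)
            ok += bool(checks[cls](m, wb))
        assert ok / n_win >= 0.95


class TestGenDepth:
    def test_no_dives_means_no_events(self):
        tr = gen_depth([], 3600, drift_max=0.3, noise_sd=0.005, seed=1)
        corrected, _ = zero_offset_correct(repair_outliers(tr)[0])
        assert detect_dives(corrected) == []

    def test_single_dive_recovered_end_to_end(self):
        tr = gen_depth([(1800, 1.5, 4)], 3600, drift_max=0.3,
                       noise_sd=0.005, seed=1)
        corrected, _ = zero_offset_correct(repair_outliers(tr)[0])
        events = detect_dives(corrected)
        assert len(events) == 1
        assert events[0].max_depth_m == pytest.approx(1.5, abs=0.1)
        assert abs(events[0].duration_s - 4) <= 1

    def test_sub_threshold_dive_not_detected(self):
        tr = gen_depth([(1800, 0.6, 2), (5400, 0.4, 2)], 7200,
                       drift_max=0.0, noise_sd=0.0, seed=3)
        events = detect_dives(tr)
        assert len(events) == 1
        assert events[0].max_depth_m == pytest.approx(0.6, abs=0.01)

    def test_overlapping_dives_rejected(self):
        with pytest.raises(ValueError):
            gen_depth([(100, 1.0, 10), (105, 1.0, 10)], 3600, seed=1)

    def test_dive_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            gen_depth([(3599, 1.0, 10)], 3600, seed=1)


class TestGenDielSequence:
    def test_null_generator_has_no_sun_trend(self):
        gen = DielGenerator(sun_mod=(0.0,) * 6)
        seq = gen_diel_sequence(gen, "2023-02-01", 48, seed=1)
        from cahow.diel import hourly_budget

        budgets = hourly_budget(seq, min_at_sea=0.0)
        x = budgets["sun_angle_rad"].to_numpy()
        y = budgets["flying-dynamic-soaring"].to_numpy()
        slope, resid = np.polyfit(x, y, 1)[0], None
        se = np.std(y) / (np.std(x) * np.sqrt(len(x)))
        assert abs(slope) < 3 * se + 0.05

    def test_night_flight_bias_by_construction(self):
        seq = gen_diel_sequence(DielGenerator(), "2023-02-01", 48, seed=2)
        from cahow.solar import sun_angle
        from cahow.trips import COLONY_LONLAT

        sun = sun_angle(COLONY_LONLAT[1], COLONY_LONLAT[0], seq.index[::60])
        sun_by_sec = np.repeat(sun, 60)[: len(seq)]
        flying = np.array([collapse_modes(v) == "flying" for v in seq.to_numpy()])
        night_frac = flying[sun_by_sec < 0].mean()
        day_frac = flying[sun_by_sec > 0].mean()
        assert night_frac > day_frac

    def test_sequence_reproducible(self):
        a = gen_diel_sequence(DielGenerator(), "2023-02-01", 6, seed=5)
        b = gen_diel_sequence(DielGenerator(), "2023-02-01", 6, seed=5)
        assert a.equals(b)

    def test_invalid_transition_matrix_rejected(self):
        with pytest.raises(ValueError):
            DielGenerator(transition=np.ones((6, 6)))


class TestGenTrack:
    def test_round_trip_geometry(self):
        track = gen_track(trip_duration=10, max_range=1200, fix_interval=60, seed=1)
        trips = segment_trips(track)
        assert len(trips) == 1 and trips[0].complete
        assert trips[0].max_distance_km == pytest.approx(1200, rel=0.1)

    def test_tiny_range_never_leaves_exclusion(self):
        track = gen_track(trip_duration=0.5, max_range=1.01, fix_interval=60, seed=1)
        # clip wiggle may push a fix past 1 km; allow only sub-km excursions
        assert all(not t.complete or t.max_distance_km < 5
                   for t in segment_trips(track))

    def test_range_below_exclusion_rejected(self):
        with pytest.raises(ValueError):
            gen_track(max_range=0.5, seed=1)


@pytest.fixture(scope="module")
def small_config():
    return DeploymentConfig(
        burrow_h=0.25, at_sea_h=1.0,
        dives=((600.0, 0.8, 2.0),), max_range_km=100.0,
        fix_interval_min=10.0, seed=7,
    )


class TestDeployment:
    def test_files_round_trip(self, small_config, tmp_path_factory):
        outdir = tmp_path_factory.mktemp("dep")
        dep = gen_logger_dataset(small_config, outdir=outdir)
        back = cio.read_deployment(outdir)
        assert np.allclose(back.accel.heave, dep.accel.heave, atol=1e-6)
        assert np.allclose(back.depth.depth, dep.depth.depth, atol=1e-6)
        assert len(back.track.fixes) == len(dep.track.fixes)
        assert back.labels["class"].tolist() == dep.labels["class"].tolist()

    def test_byte_identical_reruns(self, small_config, tmp_path_factory):
        d1 = tmp_path_factory.mktemp("a")
        d2 = tmp_path_factory.mktemp("b")
        gen_logger_dataset(small_config, outdir=d1)
        gen_logger_dataset(small_config, outdir=d2)
        for name in ("accel.csv", "depth.csv", "gps.csv", "labels.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_labels_partition_timeline(self, small_config):
        dep = gen_logger_dataset(small_config)
        labs = dep.labels
        assert labs["start"].iloc[0] == dep.accel.start
        # contiguous, no gaps or overlaps
        assert (labs["end"].iloc[:-1].to_numpy()
                == labs["start"].iloc[1:].to_numpy()).all()
        total = (labs["end"].iloc[-1] - labs["start"].iloc[0]).total_seconds()
        assert total == pytest.approx(len(dep.accel) / dep.accel.rate)

    def test_training_set_size_matches_study_design(self):
        table = gen_training_segments(n_per_bird=400, n_birds=11, seed=7)
        assert len(table) == 4400
        assert table["bird"].nunique() == 11
        counts = table["label"].value_counts()
        assert counts.max() - counts.min() <= 9  # balanced up to rounding
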