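"""Synthetic generator: base signals, degradation operators, cohort assembly."""

import numpy as np
import pytest

from sensorqc import completeness, consistency, correctness
from sensorqc.sensor_records import SensorRecord
from sensorqc.synth import (
    ANDROID_PROFILE,
    IOS_PROFILE,
    DeviceProfile,
    GenConfig,
    SensorProfile,
    degrade_missingness,
    generate_base_signal,
    generate_cohort,
    inject_anomalies,
    inject_noise,
    simulate_cohort,
)

from conftest import grid_record


def _signal_record(n=1000, seed=0, interval=20.0):
    x = generate_base_signal(n, 3, seed)
    return SensorRecord(
        "r", "p", "android", "gyroscope", np.arange(n) * interval, x
    )


class TestBaseSignal:
    def test_zero_length(self):
        assert generate_base_signal(0, 3, 0).shape == (0, 3)

    def test_determinism(self):
        np.testing.assert_array_equal(
            generate_base_signal(200, 2, 42), generate_base_signal(200, 2, 42)
        )

    def test_nonzero_mean_absolute_value(self):
        for seed in range(100):
            x = generate_base_signal(10, 1, seed)
            assert np.abs(x).mean() > 0


class TestInjectNoise:
    def test_zero_db_target(self):
        rec = inject_noise(_signal_record(2000), 0.0, seed=1)
        # 0 dB means MAV ~ sigma on the record scale
        assert correctness.snr_db(rec) == pytest.approx(0.0, abs=0.1)

    @pytest.mark.parametrize("target", [-3.0, -7.63, -13.2])
    def test_heavy_tail_targets_at_rl2000(self, target):
        rec = inject_noise(_signal_record(2000), target, seed=2)
        assert correctness.snr_db(rec) == pytest.approx(target, abs=1.0)

    def test_target_above_clean_snr_leaves_record(self):
        base = _signal_record(500)
        out = inject_noise(base, 500.0, seed=0)
        np.testing.assert_array_equal(out.channels, base.channels)

    def test_non_finite_target_raises(self):
        with pytest.raises(ValueError):
            inject_noise(_signal_record(100), np.nan, seed=0)


class TestDegradeMissingness:
    def test_zero_target_unchanged(self):
        rec = grid_record(100)
        out = degrade_missingness(rec, 0.0, seed=0)
        np.testing.assert_array_equal(out.timestamps, rec.timestamps)

    def test_alternate_deletion_oracle(self):
        # keep every other point of a regular grid plus the endpoint: with
        # the base interval known, brute-force slot counting gives MDR ~ 0.5
        # at large RL.  (The surviving points form a new regular grid, so
        # the data-driven modal interval cannot see this pattern — which is
        # exactly why the cohort generator deletes in runs, not alternately.)
        n = 400
        keep = np.zeros(n, dtype=bool)
        keep[::2] = True
        keep[-1] = True
        ts = np.flatnonzero(keep) * 10.0
        rec = grid_record(n).copy(timestamps=ts, channels=np.ones((ts.size, 1)))
        got, mpc, tpc = completeness.mdr(rec, sampling_interval=10.0)
        assert mpc == int((~keep).sum())
        assert got == pytest.approx(mpc / n)

    @pytest.mark.parametrize("target", [0.1, 0.4, 0.99])
    def test_computed_mdr_recovers_target(self, target):
        rec = grid_record(5000)
        out = degrade_missingness(rec, target, seed=3)
        got, _, _ = completeness.mdr(out)
        assert got == pytest.approx(target, abs=0.01)

    def test_surviving_timestamps_unchanged(self):
        rec = grid_record(500)
        out = degrade_missingness(rec, 0.3, seed=1)
        assert np.isin(out.timestamps, rec.timestamps).all()
        assert out.timestamps[0] == rec.timestamps[0]
        assert out.timestamps[-1] == rec.timestamps[-1]

    def test_target_one_raises(self):
        with pytest.raises(ValueError):
            degrade_missingness(grid_record(100), 1.0, seed=0)


class TestInjectAnomalies:
    def test_zero_target_empty_mask(self):
        rec = _signal_record(200)
        out, mask = inject_anomalies(rec, 0.0, seed=0)
        assert not mask.any()
        np.testing.assert_array_equal(out.channels, rec.channels)

    def test_expected_spike_count(self):
        # Bernoulli(0.02) over 100 points -> 2 expected
        counts = [
            inject_anomalies(_signal_record(100, seed=s), 0.02, seed=s)[1].sum()
            for s in range(300)
        ]
        assert np.mean(counts) == pytest.approx(2.0, abs=0.3)

    def test_detector_recall_on_large_spikes(self):
        """Ground-truth recall >= 0.8 for spike_scale >= 8 at calibration
        densities, averaged over seeded records."""
        recalls = []
        cases = [(0.01, 8.0), (0.01, 10.0), (0.02, 10.0), (0.02, 12.0)]
        per_case = 6
        for target, scale in cases:
            for s in range(per_case):
                base = inject_noise(_signal_record(1000, seed=100 + s), 0.0, 200 + s)
                rec, mask = inject_anomalies(base, target, scale, 300 + s)
                if not mask.any():
                    continue
                ds = correctness.anomaly_scores(rec, rounds=8, seed=400 + s)
                flagged = ds > ds.mean() + 3 * ds.std()
                recalls.append(flagged[mask].mean())
        assert np.mean(recalls) >= 0.8

    def test_apd_tracks_target(self):
        """|APD - target| <= 0.5 * target averaged over seeded records."""
        for target in (0.01, 0.02):
            apds = []
            for s in range(10):
                base = inject_noise(_signal_record(1000, seed=500 + s), 0.0, 600 + s)
                rec, _ = inject_anomalies(base, target, 10.0, 700 + s)
                ds = correctness.anomaly_scores(rec, rounds=8, seed=800 + s)
                apds.append(correctness.apd(rec, ds)[0])
            assert abs(np.mean(apds) - target) <= 0.5 * target


def _uniform_profile(**kw):
    prof = SensorProfile(
        base_interval_ms=20.0, mean_record_length=300, n_channels=3, **kw
    )
    return DeviceProfile(name="x", sensors={"accelerometer": prof})


class TestCohortGeneration:
    def test_seed_reproducibility_on_disk(self, tmp_path):
        cfg = GenConfig(
            n_participants=2, seed=9, sensors=("accelerometer",), records_per_participant=3
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(ANDROID_PROFILE, IOS_PROFILE, cfg, d1)
        generate_cohort(ANDROID_PROFILE, IOS_PROFILE, cfg, d2)
        assert (d1 / "manifest.jsonl").read_bytes() == (d2 / "manifest.jsonl").read_bytes()
        for f in sorted(d1.rglob("*.csv")):
            assert f.read_bytes() == (d2 / f.relative_to(d1)).read_bytes()

    def test_degenerate_rate_drives_irlr(self):
        prof = _uniform_profile(degenerate_record_rate=0.2)
        cfg = GenConfig(
            n_participants=10, seed=4, sensors=("accelerometer",), records_per_participant=20
        )
        cohort, _ = simulate_cohort(prof, prof, cfg)
        vals = [completeness.irlr(rs) for rs in cohort.values()]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.05)

    def test_zero_dispersion_gives_perfect_consistency(self):
        prof = _uniform_profile()
        cfg = GenConfig(
            n_participants=3, seed=4, sensors=("accelerometer",), records_per_participant=5
        )
        cohort, _ = simulate_cohort(prof, prof, cfg)
        for rs in cohort.values():
            assert consistency.rlc(rs) == 1.0
            assert all(consistency.src(r) == 1.0 for r in rs)

    def test_consistency_knobs_monotone(self):
        """A ladder of dispersion values strictly decreases the matching score."""
        cfg = GenConfig(
            n_participants=4, seed=7, sensors=("accelerometer",), records_per_participant=12
        )
        for knob, metric in (
            ("record_length_cv", "rlc"),
            ("range_cv", "vrc"),
            ("interval_jitter_cv", "src"),
        ):
            medians = []
            for level in (0.0, 0.1, 0.25, 0.5, 1.0):
                prof = _uniform_profile(**{knob: level})
                cohort, _ = simulate_cohort(prof, prof, cfg)
                vals = []
                for rs in cohort.values():
                    if metric == "rlc":
                        vals.append(consistency.rlc(rs))
                    elif metric == "vrc":
                        vals.append(consistency.vrc(rs))
                    else:
                        vals.append(np.median([consistency.src(r) for r in rs]))
                medians.append(np.median(vals))
            assert all(a > b for a, b in zip(medians, medians[1:])), (knob, medians)

    def test_channel_drop_rate_drives_scr(self):
        prof = _uniform_profile(channel_drop_rate=0.3)
        cfg = GenConfig(
            n_participants=6, seed=2, sensors=("accelerometer",), records_per_participant=20
        )
        cohort, _ = simulate_cohort(prof, prof, cfg)
        sccs = [r.n_channels for rs in cohort.values() for r in rs]
        frac_dropped = np.mean(np.array(sccs) == 2)
        assert frac_dropped == pytest.approx(0.3, abs=0.08)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            SensorProfile(target_mdr=1.5)
        with pytest.raises(ValueError):
            SensorProfile(base_interval_ms=0.0)
        with pytest.raises(ValueError):
            GenConfig(n_participants=0)
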