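"""Participant aggregation, normalization and the nonparametric statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sensorqc import cohort
from sensorqc.sensor_records import RecordSet

from conftest import grid_record, make_record


def _perfect_set(n_records=4, participant="p", device="android"):
    recs = []
    for i in range(n_records):
        ts = np.arange(60) * 10.0
        x = np.column_stack([np.sin(ts / 30), np.cos(ts / 30), ts / 600.0])
        recs.append(
            make_record(
                ts, x, record_id=f"r{i}", participant_id=participant, device_type=device
            )
        )
    return RecordSet(recs)


class TestSummarize:
    def test_perfect_records(self):
        row = cohort.summarize_participant(_perfect_set())
        assert row["irlr"] == 1.0
        assert row["scr"] == 1.0
        assert row["mdr"] == 0.0
        assert row["apd"] == 0.0
        assert row["rlc"] == 1.0
        assert row["src"] == 1.0
        assert row["vrc"] == 1.0

    def test_single_record_consistency_rules(self):
        rs = RecordSet([_perfect_set(1)[0]])
        row = cohort.summarize_participant(rs)
        assert row["rlc"] == 1.0 and row["vrc"] == 1.0
        assert row["src"] == 1.0  # intra-record, computed not defaulted

    def test_median_aggregation_of_mdr(self):
        # per-record MDRs {0.2, 0.4, 0.6}: gaps engineered per record
        recs = []
        for i, n_miss in enumerate((25, 67, 150)):
            n = 100
            ts = np.concatenate([np.arange(n) * 10.0, [(n + n_miss) * 10.0]])
            recs.append(make_record(ts, np.ones((ts.size, 1)), record_id=f"r{i}"))
        rs = RecordSet(recs)
        expected = np.median(
            [n_miss / (101 + n_miss) for n_miss in (25, 67, 150)]
        )
        row = cohort.summarize_participant(rs)
        assert row["mdr"] == pytest.approx(expected)

    def test_mean_aggregate_option(self):
        rs = _perfect_set()
        row = cohort.summarize_participant(rs, aggregate="mean")
        assert row["mdr"] == 0.0


def _toy_table():
    rng = np.random.default_rng(5)
    rows = []
    for dev, shift in (("android", 0.0), ("ios", 0.5)):
        for i in range(15):
            rows.append(
                {
                    "participant_id": f"{dev}{i}",
                    "device_type": dev,
                    "sensor_type": "accelerometer",
                    **{m: float(rng.random() + shift) for m in cohort.DQM_COLUMNS},
                }
            )
    return pd.DataFrame(rows)


class TestNormalize:
    def test_two_point_column(self):
        t = _toy_table().iloc[:2].copy()
        t.loc[:, "mdr"] = [0.2, 0.7]
        out = cohort.minmax_normalize(t)
        assert sorted(out["mdr"]) == [0.0, 1.0]

    def test_constant_column_all_zero(self):
        t = _toy_table()
        t["vrc"] = 0.42
        assert (cohort.minmax_normalize(t)["vrc"] == 0.0).all()

    def test_snr_column_unchanged(self):
        t = _toy_table()
        out = cohort.minmax_normalize(t)
        np.testing.assert_array_equal(out["snr_db"], t["snr_db"])

    def test_idempotent(self):
        t = _toy_table()
        once = cohort.minmax_normalize(t)
        twice = cohort.minmax_normalize(once)
        pd.testing.assert_frame_equal(once, twice)


class TestCompareDevices:
    def test_identical_groups_p_near_one(self):
        t = _toy_table()
        t["mdr"] = list(range(15)) * 2
        r = cohort.compare_devices(t, "mdr")
        assert r.p > 0.9

    def test_separated_groups_exact_oracle(self):
        # {1,2,3} vs {4,5,6}: full enumeration of rank assignments gives
        # two-sided p = 0.1 (scipy exact is the oracle); the asymptotic
        # tie-corrected approximation must agree to within its usual error
        exact = stats.mannwhitneyu([1, 2, 3], [4, 5, 6], method="exact").pvalue
        assert exact == pytest.approx(0.1)
        t = _toy_table().iloc[:6].copy()
        t["device_type"] = ["android"] * 3 + ["ios"] * 3
        t["mdr"] = [1, 2, 3, 4, 5, 6]
        r = cohort.compare_devices(t, "mdr")
        assert r.statistic == 0.0
        assert r.p == pytest.approx(exact, abs=0.05)
        assert r.group_stats["android"]["median"] == 2.0

    def test_small_group_raises(self):
        t = _toy_table().iloc[:3]
        with pytest.raises(ValueError):
            cohort.compare_devices(t, "mdr")


class TestCovariateAssociation:
    def test_two_level_covariate_reduces_to_mannwhitney(self):
        t = _toy_table()
        t["group"] = ["a"] * 15 + ["b"] * 15
        res = cohort.covariate_association(t, "group", metrics=("mdr",))[0]
        mw = stats.mannwhitneyu(
            t.loc[t.group == "a", "mdr"],
            t.loc[t.group == "b", "mdr"],
            alternative="two-sided",
            method="asymptotic",
            use_continuity=False,
        )
        assert res.p == pytest.approx(mw.pvalue, rel=1e-6)

    def test_effect_size_is_h_over_n_minus_one(self):
        t = _toy_table()
        t["group"] = (["a", "b", "c"] * 10)[:30]
        res = cohort.covariate_association(t, "group", metrics=("mdr",))[0]
        assert res.effect_size == pytest.approx(res.statistic / 29)

    def test_single_level_raises(self):
        t = _toy_table()
        t["group"] = "only"
        with pytest.raises(ValueError):
            cohort.covariate_association(t, "group", metrics=("mdr",))

    def test_null_false_positive_rate_controlled(self):
        """Under an independent covariate, the BH-corrected omnibus q<0.05
        rate stays near or below nominal (Monte-Carlo tolerance)."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 300
        for _ in range(reps):
            t = pd.DataFrame(
                {
                    "m1": rng.random(36),
                    "m2": rng.random(36),
                    "group": np.repeat(["a", "b", "c"], 12),
                }
            )
            res = cohort.covariate_association(t, "group", metrics=("m1", "m2"))
            hits += any(r.q < 0.05 for r in res)
        assert hits / reps <= 0.05 + 0.03

    def test_dunn_matches_pairwise_rank_formula(self):
        # 3 balanced groups, no ties: z_ij = (Ri - Rj)/sqrt(N(N+1)/12 * 2/n)
        rng = np.random.default_rng(2)
        groups = [rng.normal(loc, 1.0, 10) for loc in (0.0, 0.5, 2.0)]
        ps = cohort.dunn_test(groups)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        means = [ranks[i * 10 : (i + 1) * 10].mean() for i in range(3)]
        n = 30
        se = np.sqrt(n * (n + 1) / 12 * (2 / 10))
        expected = [
            2 * stats.norm.sf(abs((means[i] - means[j]) / se))
            for i, j in ((0, 1), (0, 2), (1, 2))
        ]
        np.testing.assert_allclose(ps, expected, rtol=1e-10)
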