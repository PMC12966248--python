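import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from infantwear import (
    ChildRecord,
    ConfigurationError,
    DaySummary,
    NightSummary,
    SimProfile,
    UsabilityRules,
    compare_devices,
    precision_halfwidth,
    reliability_table,
    simulate_accel,
    simulate_cohort,
    simulate_rr_stream,
    threshold_sensitivity,
    usable_units,
    wilcoxon_signed_rank,
)


def night(hours, period=float("nan")):
    return NightSummary(None, hours * 3600.0, 0, 1.0, 25.0, 2.0,
                        ultradian_period_min=period)


def day(attached_hours, hr=float("nan"), hrv=float("nan")):
    return DaySummary(0, mean_hr_bpm=hr, mean_hrv_ms=hrv, attached_hours=attached_hours)


class TestUsableUnits:
    def test_all_nights_usable(self):
        record = ChildRecord("c", [], [night(8.0)] * 7)
        nappa, hr, denom = usable_units(record)
        assert nappa == 7 and denom == 7
        assert nappa / denom == 1.0

    def test_no_recordings(self):
        record = ChildRecord("c")
        assert usable_units(record)[:2] == (0, 0)

    def test_boundary_day_below_threshold(self):
        record = ChildRecord("c", [day(5.9)], [])
        assert usable_units(record)[1] == 0
        record = ChildRecord("c", [day(6.0)], [])
        assert usable_units(record)[1] == 1

    def test_monotone_in_rules(self):
        """Relaxing a rule never decreases a usable count."""
        record = ChildRecord(
            "c",
            [day(h) for h in (2.0, 5.0, 6.5, 9.0)],
            [night(h) for h in (3.0, 6.5, 8.0)],
        )
        prev_days, prev_nights = -1, -1
        for thr in (10.0, 6.0, 4.0, 1.0):
            rules = UsabilityRules(min_attached_hours=thr, min_night_hours=thr)
            nights, days, _ = usable_units(record, rules)
            assert days >= prev_days and nights >= prev_nights
            prev_days, prev_nights = days, nights


class TestReliabilityTable:
    def test_two_unit_oracle(self):
        # hand formula: mean 123, sample SD 4.2426, CV = 100*4.2426/123 = 3.449%
        record = ChildRecord("c", [day(8, hr=120.0), day(8, hr=126.0)], [])
        row = reliability_table(record)[0]
        assert row.metric == "HR"
        assert row.mean == pytest.approx(123.0)
        assert row.cv_percent == pytest.approx(3.449, abs=0.01)
        lo, hi = row.ci95
        assert lo <= row.mean <= hi

    def test_single_unit_undefined_ci_cv(self):
        record = ChildRecord("c", [day(8, hr=127.0)], [])
        row = reliability_table(record)[0]
        assert row.mean == pytest.approx(127.0)
        assert row.n_units == 1
        assert np.isnan(row.cv_percent)
        assert np.isnan(row.ci95[0])

    def test_identical_units_zero_cv(self):
        record = ChildRecord("c", [day(8, hr=120.0)] * 3, [])
        assert reliability_table(record)[0].cv_percent == pytest.approx(0.0)

    def test_cv_scale_invariant(self):
        values = [110.0, 120.0, 135.0]
        r1 = ChildRecord("c", [day(8, hr=v) for v in values], [])
        r2 = ChildRecord("c", [day(8, hr=3.7 * v) for v in values], [])
        cv1 = reliability_table(r1)[0].cv_percent
        cv2 = reliability_table(r2)[0].cv_percent
        assert cv1 == pytest.approx(cv2)

    def test_ultradian_rows_use_nights(self):
        record = ChildRecord("c", [], [night(8, period=80.0), night(8, period=90.0)])
        row = reliability_table(record)[2]
        assert row.metric == "ultradian_period"
        assert row.mean == pytest.approx(85.0)
        assert row.n_units == 2


class TestSignedRank:
    def test_all_positive_diffs_give_zero(self):
        t_stat, _, n = wilcoxon_signed_rank(np.array([1, 2, 3]) / 7.0)
        assert t_stat == 0.0 and n == 3

    def test_all_zero_diffs_undefined(self):
        t_stat, p, n = wilcoxon_signed_rank([0.0, 0.0])
        assert np.isnan(t_stat) and n == 0

    def test_matches_brute_force_enumeration(self):
        """Exact p agrees with 2^n enumeration for n <= 8, both tie modes."""
        rng = np.random.default_rng(3)
        for trial in range(10):
            n = int(rng.integers(2, 9))
            diffs = rng.choice([-3, -2, -1, 1, 2, 3], size=n) / 7.0
            for method in ("ordinal", "average"):
                t_stat, p, n_nz = wilcoxon_signed_rank(diffs, method)
                d = diffs[diffs != 0]
                ranks = rankdata(np.abs(d), method=method)
                count = sum(
                    sum(r for r, s in zip(ranks, signs) if s) <= t_stat + 1e-9
                    for signs in itertools.product([0, 1], repeat=len(d))
                )
                expected = min(1.0, 2.0 * count / 2 ** len(d))
                assert p == pytest.approx(expected), (diffs, method)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=8))
    def test_property_t_bounds(self, diffs):
        t_stat, p, n = wilcoxon_signed_rank(np.array(diffs, dtype=float))
        if n == 0:
            assert np.isnan(t_stat)
        else:
            assert 0 <= t_stat <= n * (n + 1) / 4
            assert 0 < p <= 1


class TestCompareDevices:
    PAIRS = [(1, 2), (3, 5), (0, 0), (5, 3), (2, 0), (2, 0), (7, 1)]

    def test_reference_cohort_ordinal(self):
        cohort = simulate_cohort(7, self.PAIRS, seed=1)
        result = compare_devices(cohort, tie_method="ordinal")
        assert result.statistic_t == 3.0
        assert result.p_value == pytest.approx(0.15625)
        assert result.n_nonzero == 6

    def test_reference_cohort_average_ties(self):
        cohort = simulate_cohort(7, self.PAIRS, seed=1)
        result = compare_devices(cohort, tie_method="average")
        assert result.statistic_t == 4.5

    def test_identical_proportions_undefined(self):
        cohort = simulate_cohort(2, [(3, 3), (5, 5)], seed=0)
        result = compare_devices(cohort)
        assert np.isnan(result.statistic_t)
        assert result.reason == "all_differences_zero"

    def test_diff_column_is_proportion_difference(self):
        cohort = simulate_cohort(2, [(7, 0), (0, 7)], seed=0)
        result = compare_devices(cohort)
        np.testing.assert_allclose(result.per_child["diff"], [1.0, -1.0])


class TestPrecisionHalfwidth:
    def test_closed_form_n100(self):
        assert precision_halfwidth(0.5, 100) == pytest.approx(0.098, abs=0.0005)

    def test_degenerate_p(self):
        assert precision_halfwidth(0.0, 50) == 0.0

    def test_n28_gives_185(self):
        assert precision_halfwidth(0.5, 28) == pytest.approx(0.185, abs=0.0005)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            precision_halfwidth(1.5, 10)
        with pytest.raises(ValueError):
            precision_halfwidth(0.5, 0)


@pytest.fixture(scope="module")
def sensitivity_streams():
    profile = SimProfile(
        duration_s=3 * 600,
        baseline_hr_bpm=120,
        hr_jitter_ms=15,
        artefact_fraction=0.05,
        detach_windows=((600.0, 1200.0),),
        movement_schedule=(
            (0.0, 600.0, "still"),
            (600.0, 1200.0, "moving"),
            (1200.0, 1800.0, "still"),
        ),
        seed=0,
    )
    return simulate_rr_stream(profile), simulate_accel(profile)


class TestThresholdSensitivity:
    def test_single_point_equals_direct_run(self, sensitivity_streams, cfg):
        rr, accel = sensitivity_streams
        table = threshold_sensitivity(rr, accel, {"movement_sd_threshold_mg": [13.0]}, cfg)
        assert len(table) == 1
        from infantwear import classify_wear, wear_summary

        states = classify_wear(rr, accel, cfg)
        summary = wear_summary(states, rr, cfg)
        assert table.loc[0, "wear_attached_h"] == pytest.approx(summary.attached_hours)

    def test_detached_time_monotone_in_threshold(self, sensitivity_streams, cfg):
        rr, accel = sensitivity_streams
        table = threshold_sensitivity(
            rr, accel, {"movement_sd_threshold_mg": [10.0, 13.0, 16.0]}, cfg
        )
        detached = table["wear_detached_h"].to_numpy()
        assert np.all(np.diff(detached) <= 0)

    def test_empty_grid_rejected(self, sensitivity_streams, cfg):
        rr, accel = sensitivity_streams
        with pytest.raises(ConfigurationError):
            threshold_sensitivity(rr, accel, {}, cfg)
        with pytest.raises(ConfigurationError):
            threshold_sensitivity(rr, accel, {"window_s": []}, cfg)
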