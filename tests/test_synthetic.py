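import numpy as np
import pytest

from infantwear import (
    ConfigurationError,
    RespProfile,
    SimProfile,
    classify_wear,
    expected_wear_states,
    filter_physiological,
    quality_mask,
    simulate_accel,
    simulate_cohort,
    simulate_respiration_night,
    simulate_rr_stream,
    ultradian_cycle,
    usable_units,
    vector_magnitude_sd,
)
from infantwear.io import write_rr


class TestSimulateRR:
    def test_clean_stream_is_closed_form(self):
        """120 bpm for 60 s with no jitter: 120 intervals of exactly 500 ms."""
        rr = simulate_rr_stream(SimProfile(duration_s=60, baseline_hr_bpm=120,
                                           hr_jitter_ms=0, seed=0))
        assert len(rr) == 120
        np.testing.assert_allclose(rr.rr_ms, 500.0, atol=1e-9)

    def test_mean_interval_matches_baseline(self):
        # oracle: recompute the mean over the emitted stream; 60000/130 = 461.5 ms
        rr = simulate_rr_stream(SimProfile(duration_s=3600, baseline_hr_bpm=130,
                                           hr_jitter_ms=20, seed=7))
        assert abs(rr.rr_ms.mean() - 461.5) / 461.5 < 0.01

    def test_all_artefacts_fall_outside_physiological_range(self, cfg):
        rr = simulate_rr_stream(SimProfile(duration_s=120, baseline_hr_bpm=120,
                                           hr_jitter_ms=0, artefact_fraction=1.0, seed=1))
        kept, outside = filter_physiological(rr, cfg)
        assert len(kept) == 0
        assert outside.sum() == len(rr)

    def test_no_beats_inside_detach_windows(self):
        profile = SimProfile(duration_s=1800, baseline_hr_bpm=120, hr_jitter_ms=10,
                             detach_windows=((600.0, 1200.0),), seed=3)
        rr = simulate_rr_stream(profile)
        assert not np.any((rr.t_s >= 600.0) & (rr.t_s < 1200.0))

    def test_conservation_of_time(self):
        """Between-beat intervals sum to last beat time minus first beat time."""
        rr = simulate_rr_stream(SimProfile(duration_s=600, baseline_hr_bpm=110,
                                           hr_jitter_ms=25, artefact_fraction=0.05,
                                           detach_windows=((200.0, 300.0),), seed=5))
        assert np.isclose(rr.rr_ms[1:].sum() / 1000.0, rr.t_s[-1] - rr.t_s[0], atol=1e-6)

    def test_determinism_byte_identical(self, tmp_path):
        profile = SimProfile(duration_s=300, baseline_hr_bpm=125, hr_jitter_ms=15,
                             artefact_fraction=0.1, seed=11)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_rr(simulate_rr_stream(profile), p1)
        write_rr(simulate_rr_stream(profile), p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duration_s": -1},
            {"duration_s": 60, "baseline_hr_bpm": 0},
            {"duration_s": 60, "artefact_fraction": 1.5},
            {"duration_s": 60, "detach_windows": ((10.0, 70.0),)},
            {"duration_s": 60, "nap_windows": ((0.0, 30.0, 1.0), (20.0, 50.0, 1.0))},
        ],
    )
    def test_invalid_profiles_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimProfile(**kwargs)


class TestSimulateAccel:
    def test_off_body_stays_below_threshold(self, cfg):
        profile = SimProfile(duration_s=1200,
                             movement_schedule=((0.0, 1200.0, "off_body"),), seed=0)
        accel = simulate_accel(profile)
        for t0 in (0.0, 600.0):
            assert vector_magnitude_sd(accel, t0, t0 + 600.0) < cfg.movement_sd_threshold_mg

    def test_moving_exceeds_threshold(self, cfg):
        profile = SimProfile(duration_s=1200,
                             movement_schedule=((0.0, 1200.0, "moving"),), seed=0)
        accel = simulate_accel(profile)
        for t0 in (0.0, 600.0):
            assert vector_magnitude_sd(accel, t0, t0 + 600.0) > cfg.movement_sd_threshold_mg

    def test_unknown_state_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown movement state"):
            SimProfile(duration_s=60, movement_schedule=((0.0, 60.0, "floating"),))

    def test_schedule_must_cover_duration(self):
        profile = SimProfile(duration_s=120, movement_schedule=((0.0, 60.0, "still"),))
        with pytest.raises(ConfigurationError, match="cover"):
            simulate_accel(profile)

    def test_classify_recovers_mixed_schedule(self, cfg):
        """Window-level wear-state recovery against the generating schedule."""
        profile = SimProfile(
            duration_s=6 * 600,
            baseline_hr_bpm=125,
            hr_jitter_ms=15,
            detach_windows=((600.0, 1800.0), (2400.0, 3000.0)),
            movement_schedule=(
                (0.0, 600.0, "still"),
                (600.0, 1200.0, "moving"),    # detached
                (1200.0, 1800.0, "off_body"),  # not worn
                (1800.0, 2400.0, "moving"),
                (2400.0, 3000.0, "off_body"),  # not worn
                (3000.0, 3600.0, "still"),
            ),
            seed=21,
        )
        rr = simulate_rr_stream(profile, cfg)
        accel = simulate_accel(profile)
        got = classify_wear(rr, accel, cfg, duration_s=profile.duration_s)
        truth = expected_wear_states(profile, cfg)
        assert np.mean(got.states == truth.states) >= 0.95


class TestSimulateRespiration:
    def test_degenerate_sinusoid_is_constant(self):
        night = simulate_respiration_night(
            RespProfile(duration_s=3600, base_rate_bpm=25, ultradian_amplitude_bpm=0,
                        noise_sd_bpm=0, seed=0)
        )
        np.testing.assert_allclose(night.resp_rate_bpm, 25.0)

    def test_ultradian_recovery_of_injected_period(self, cfg):
        night = simulate_respiration_night(
            RespProfile(duration_s=8 * 3600, ultradian_period_min=65,
                        ultradian_amplitude_bpm=2, noise_sd_bpm=1, seed=4)
        )
        result = ultradian_cycle(night, cfg)
        assert result.defined
        assert abs(result.period_min - 65.0) <= 5.0

    def test_dropout_fraction_controls_quality_mask(self, cfg):
        night = simulate_respiration_night(
            RespProfile(duration_s=8 * 3600, dropout_fraction=0.5, seed=9)
        )
        frac = quality_mask(night, cfg).mean()
        # binomial oracle: 960 samples at p=0.5, 4-sigma band
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / len(night))

    def test_positions_piecewise_constant(self):
        night = simulate_respiration_night(
            RespProfile(duration_s=3600, position_changes=((1800.0, "prone"),), seed=0)
        )
        assert set(night.position[night.t_s < 1800]) == {"supine"}
        assert set(night.position[night.t_s >= 1800]) == {"prone"}

    def test_invalid_period_rejected(self):
        with pytest.raises(ConfigurationError):
            RespProfile(duration_s=3600, ultradian_period_min=20)

    def test_determinism(self):
        p = RespProfile(duration_s=3600, dropout_fraction=0.3, seed=13)
        a, b = simulate_respiration_night(p), simulate_respiration_night(p)
        np.testing.assert_array_equal(a.resp_rate_bpm, b.resp_rate_bpm)
        np.testing.assert_array_equal(a.autocorr, b.autocorr)


class TestSimulateCohort:
    def test_requested_counts_recovered(self):
        cohort = simulate_cohort(1, [(7, 1)], seed=0)
        nappa, hr, denom = usable_units(cohort.children[0])
        assert (nappa, hr, denom) == (7, 1, 7)
        assert nappa / denom == 1.0
        assert round(hr / denom, 2) == 0.14

    def test_empty_cohort(self):
        cohort = simulate_cohort(0, [], seed=0)
        assert len(cohort) == 0

    def test_infeasible_request_rejected(self):
        with pytest.raises(ConfigurationError, match="exceed"):
            simulate_cohort(1, [(8, 0)], seed=0)

    def test_counts_match_for_all_pairs(self):
        pairs = [(1, 2), (3, 5), (0, 0), (5, 3), (2, 0), (2, 0), (7, 1)]
        cohort = simulate_cohort(7, pairs, seed=42)
        got = [usable_units(c)[:2] for c in cohort.children]
        assert got == pairs


class TestInjectedTruthRecovery:
    """Cross-seed recovery invariants for the generators."""

    def test_ultradian_period_median_error_under_10pct(self, cfg):
        errors = []
        for seed in range(20):
            night = simulate_respiration_night(
                RespProfile(duration_s=8 * 3600, ultradian_period_min=65,
                            ultradian_amplitude_bpm=2, noise_sd_bpm=1, seed=seed)
            )
            res = ultradian_cycle(night, cfg)
            errors.append(abs(res.period_min - 65.0) / 65.0 if res.defined else 1.0)
        assert np.median(errors) < 0.10

    def test_wear_state_accuracy_across_seeds(self, cfg):
        accs = []
        for seed in range(20):
            profile = SimProfile(
                duration_s=4 * 600,
                detach_windows=((600.0, 1200.0), (1800.0, 2400.0)),
                movement_schedule=(
                    (0.0, 600.0, "still"),
                    (600.0, 1200.0, "moving"),
                    (1200.0, 1800.0, "still"),
                    (1800.0, 2400.0, "off_body"),
                ),
                seed=seed,
            )
            rr = simulate_rr_stream(profile, cfg)
            accel = simulate_accel(profile)
            got = classify_wear(rr, accel, cfg, duration_s=profile.duration_s)
            truth = expected_wear_states(profile, cfg)
            accs.append(np.mean(got.states == truth.states))
        assert np.mean(accs) >= 0.95
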