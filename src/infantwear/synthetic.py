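"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The source study deposits no machine-readable recordings, so every
downstream stage is exercised against generated streams: R-R interval
sequences with artefact beats and detachment gaps, tri-axial accelerometry
straddling the 13 mg movement threshold, nightly respiration series with an
embedded 30-120-min oscillation and quality dropout, and cohorts with
requested usable-unit counts. All distributional choices are stand-ins;
none is a claim about the real recordings.

Every generator draws from ``numpy.random.default_rng`` seeded per profile
(plus a fixed per-stream key), so identical profiles give byte-identical
serialised output and the generators share no global state.

Detachment gaps are represented the way a Holter R-R export shows them:
the first beat after a gap carries one long interval spanning it, so beat
times remain exact cumulative sums of the emitted intervals and the long
interval is removed by the physiological-range filter downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig, UsabilityRules
from .errors import ConfigurationError
from .respiration import NightSummary
from .reliability import ChildRecord, DaySummary, StudyCohort
from .series import AccelSeries, RespirationNight, RRSeries
from .wear import WearStateSeries

__all__ = [
    "SimProfile",
    "RespProfile",
    "ARTEFACT_MAX_MS",
    "MOVEMENT_STATES",
    "simulate_rr_stream",
    "simulate_accel",
    "simulate_respiration_night",
    "simulate_cohort",
    "expected_wear_states",
    "minute_hr_sd_bpm",
]

#: upper bound of the artefact interval draw (ms); artefacts come from
#: (0, physio_lower) | (physio_upper, ARTEFACT_MAX_MS) so they are
#: unambiguously non-physiological
ARTEFACT_MAX_MS = 3000.0

MOVEMENT_STATES = ("moving", "still", "off_body")

#: per-axis noise SD (mg) by movement state; moving clears the 13 mg
#: vector-magnitude-SD threshold, the others sit well below it
_STATE_NOISE_SD_MG = {"moving": 50.0, "still": 2.0, "off_body": 0.5}

_GRAVITY_MG = 1000.0
_NAP_RAMP_S = 300.0
_RESP_CADENCE_S = 30.0


def _check_windows(windows, duration_s, what: str) -> None:
    prev_end = None
    for win in sorted(windows, key=lambda w: w[0]):
        start, end = win[0], win[1]
        if not 0 <= start < end <= duration_s:
            raise ConfigurationError(
                f"{what} window ({start}, {end}) outside [0, {duration_s}]"
            )
        if prev_end is not None and start < prev_end:
            raise ConfigurationError(f"{what} windows overlap at {start}")
        prev_end = end


@dataclass(frozen=True)
class SimProfile:
    """Recipe for one synthetic heart-rate-monitor wear period."""

    duration_s: float
    baseline_hr_bpm: float = 125.0
    hr_jitter_ms: float = 15.0
    artefact_fraction: float = 0.0
    nap_windows: tuple = ()  # (start_s, end_s, hr_dip_sd)
    detach_windows: tuple = ()  # (start_s, end_s)
    movement_schedule: tuple = ()  # (start_s, end_s, state)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.baseline_hr_bpm <= 0:
            raise ConfigurationError("baseline_hr_bpm must be > 0")
        if not 0.0 <= self.artefact_fraction <= 1.0:
            raise ConfigurationError("artefact_fraction must lie in [0, 1]")
        if self.hr_jitter_ms < 0:
            raise ConfigurationError("hr_jitter_ms must be >= 0")
        _check_windows(self.nap_windows, self.duration_s, "nap")
        _check_windows(self.detach_windows, self.duration_s, "detach")
        _check_windows(self.movement_schedule, self.duration_s, "movement")
        for _, _, state in self.movement_schedule:
            if state not in MOVEMENT_STATES:
                raise ConfigurationError(f"unknown movement state {state!r}")


@dataclass(frozen=True)
class RespProfile:
    """Recipe for one synthetic respiration night."""

    duration_s: float
    base_rate_bpm: float = 25.0
    ultradian_period_min: float = 65.0  # 0 disables the injected cycle
    ultradian_amplitude_bpm: float = 2.0
    noise_sd_bpm: float = 1.0
    dropout_fraction: float = 0.0
    position_changes: tuple = ()  # (time_s, position)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.base_rate_bpm <= 0:
            raise ConfigurationError("base_rate_bpm must be > 0")
        if self.ultradian_period_min != 0 and not 30 <= self.ultradian_period_min <= 120:
            raise ConfigurationError(
                "ultradian_period_min must be 0 (disabled) or within [30, 120]"
            )
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ConfigurationError("dropout_fraction must lie in [0, 1]")


def minute_hr_sd_bpm(profile: SimProfile) -> float:
    """SD of the minute-averaged heart rate implied by the interval jitter.

    Nap dips are expressed as multiples of this scale.
    """
    beats_per_min = max(profile.baseline_hr_bpm, 1.0)
    return (
        profile.baseline_hr_bpm**2
        * profile.hr_jitter_ms
        / 60000.0
        / math.sqrt(beats_per_min)
    )


def _nap_dip_bpm(profile: SimProfile, t: float) -> float:
    """Smooth HR reduction (bpm) at time t from the scheduled naps."""
    scale = minute_hr_sd_bpm(profile)
    dip = 0.0
    for start, end, dip_sd in profile.nap_windows:
        if not start <= t < end:
            continue
        ramp = min(_NAP_RAMP_S, (end - start) / 2.0)
        shape = min(1.0, (t - start) / ramp, (end - t) / ramp)
        dip += dip_sd * scale * max(0.0, shape)
    return dip


def _draw_artefact_ms(rng: np.random.Generator, cfg: AnalysisConfig) -> float:
    """Uniform draw from (0, lower) | (upper, ARTEFACT_MAX_MS)."""
    low_len = cfg.rr_physio_lower_ms
    high_len = ARTEFACT_MAX_MS - cfg.rr_physio_upper_ms
    u = rng.uniform(0.0, low_len + high_len)
    if u < low_len:
        return max(u, 1e-3)
    return cfg.rr_physio_upper_ms + (u - low_len)


def simulate_rr_stream(
    profile: SimProfile, cfg: AnalysisConfig | None = None
) -> RRSeries:
    """Generate a beat-by-beat R-R stream for the profile.

    Clean intervals are 60000/HR(t) plus Gaussian jitter; a configured
    fraction is replaced with out-of-range artefacts; beats never land
    inside detach windows (the next beat's interval spans the gap).
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng([profile.seed, 1])
    detach = sorted((s, e) for s, e in profile.detach_windows)

    def gap_end(t: float) -> float | None:
        for s, e in detach:
            if s <= t < e:
                return e
        return None

    t_list: list[float] = []
    rr_list: list[float] = []
    t_prev = 0.0
    eps = 1e-9
    while t_prev < profile.duration_s - eps:
        hr = profile.baseline_hr_bpm - _nap_dip_bpm(profile, t_prev)
        rr = 60000.0 / max(hr, 1.0) + profile.hr_jitter_ms * rng.standard_normal()
        rr = max(rr, 1.0)
        if profile.artefact_fraction and rng.random() < profile.artefact_fraction:
            rr = _draw_artefact_ms(rng, cfg)
        t_next = t_prev + rr / 1000.0
        while (end := gap_end(t_next)) is not None:
            hr = profile.baseline_hr_bpm - _nap_dip_bpm(profile, end)
            step = 60000.0 / max(hr, 1.0) + profile.hr_jitter_ms * rng.standard_normal()
            t_next = end + max(step, 1.0) / 1000.0
        if t_next > profile.duration_s + eps:
            break
        t_list.append(t_next)
        rr_list.append((t_next - t_prev) * 1000.0)
        t_prev = t_next
    return RRSeries(np.array(t_list), np.array(rr_list), start_time=None).validate()


def simulate_accel(
    profile: SimProfile, sample_rate_hz: float = 25.0
) -> AccelSeries:
    """Generate tri-axial accelerometry following the movement schedule.

    Gravity sits on the z-axis; each scheduled state sets the per-axis
    noise SD so that 'moving' windows exceed the 13 mg vector-magnitude-SD
    threshold and 'still'/'off_body' windows stay below it.
    """
    if not profile.movement_schedule:
        raise ConfigurationError("movement_schedule must cover [0, duration_s)")
    schedule = sorted(profile.movement_schedule, key=lambda w: w[0])
    covered = schedule[0][0] == 0 and all(
        a[1] == b[0] for a, b in zip(schedule, schedule[1:])
    )
    if not covered or schedule[-1][1] < profile.duration_s:
        raise ConfigurationError("movement_schedule must cover [0, duration_s)")

    rng = np.random.default_rng([profile.seed, 2])
    n = int(round(profile.duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    sd = np.empty(n)
    for start, end, state in schedule:
        sel = (t >= start) & (t < end)
        sd[sel] = _STATE_NOISE_SD_MG[state]
    samples = rng.standard_normal((n, 3)) * sd[:, None]
    samples[:, 2] += _GRAVITY_MG
    return AccelSeries(samples, sample_rate_hz, start_time=None).validate()


def simulate_respiration_night(
    profile: RespProfile, cfg: AnalysisConfig | None = None
) -> RespirationNight:
    """Generate one night: sinusoid-plus-noise rate, dropout and positions."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng([profile.seed, 3])
    t = np.arange(0.0, profile.duration_s, _RESP_CADENCE_S)
    rate = np.full(t.size, profile.base_rate_bpm)
    if profile.ultradian_period_min:
        rate = rate + profile.ultradian_amplitude_bpm * np.sin(
            2 * np.pi * t / (profile.ultradian_period_min * 60.0)
        )
    if profile.noise_sd_bpm:
        rate = rate + profile.noise_sd_bpm * rng.standard_normal(t.size)
    rate = np.clip(rate, 0.0, None)

    thr = cfg.autocorr_threshold
    dropout = rng.random(t.size) < profile.dropout_fraction
    autocorr = rng.uniform(np.nextafter(thr, 2.0), 1.0, size=t.size)
    autocorr[dropout] = rng.uniform(-1.0, thr, size=int(dropout.sum()))

    position = np.full(t.size, "supine", dtype=object)
    for change_t, pos in sorted(profile.position_changes):
        position[t >= change_t] = pos
    return RespirationNight(
        t, rate, autocorr, position, start_time=None, night_id=None
    ).validate()


def expected_wear_states(
    profile: SimProfile, cfg: AnalysisConfig | None = None
) -> WearStateSeries:
    """Ground-truth window labels implied by a profile's schedules.

    A window wholly inside a detach gap has no heartbeat: it is
    worn_detached when its dominant movement state is 'moving', not_worn
    otherwise. Any window with beat-bearing time is worn_attached.
    """
    cfg = cfg or AnalysisConfig()
    n_win = int(np.ceil(profile.duration_s / cfg.window_s))
    starts = np.arange(n_win) * cfg.window_s
    states = np.full(n_win, "worn_attached", dtype=object)
    for w, t0 in enumerate(starts):
        t1 = min(t0 + cfg.window_s, profile.duration_s)
        in_gap = any(s <= t0 and t1 <= e for s, e in profile.detach_windows)
        if not in_gap:
            continue
        overlap = {state: 0.0 for state in MOVEMENT_STATES}
        for s, e, state in profile.movement_schedule:
            overlap[state] += max(0.0, min(e, t1) - max(s, t0))
        dominant = max(overlap, key=overlap.get)
        states[w] = "worn_detached" if dominant == "moving" else "not_worn"
    return WearStateSeries(starts, states, cfg.window_s)


def simulate_cohort(
    n_children: int,
    per_child_success: list[tuple[int, int]],
    seed: int = 0,
    rules: UsabilityRules | None = None,
) -> StudyCohort:
    """Build a cohort whose usable-unit counts match the request.

    ``per_child_success[i] = (nappa_nights, hr_days)`` gives the number of
    usable units each child should contribute over the study window; the
    generated day/night summaries pass or fail the usability rules
    accordingly.
    """
    rules = rules or UsabilityRules()
    if n_children != len(per_child_success):
        raise ConfigurationError("per_child_success must list one pair per child")
    children: list[ChildRecord] = []
    for i, (nn, hd) in enumerate(per_child_success):
        if not 0 <= nn <= rules.study_days or not 0 <= hd <= rules.study_days:
            raise ConfigurationError(
                f"child {i}: requested usable units ({nn}, {hd}) exceed the "
                f"{rules.study_days}-day study window"
            )
        rng = np.random.default_rng([seed, 4, i])
        days = []
        for d in range(rules.study_days):
            if d < hd:
                days.append(
                    DaySummary(
                        day_index=d,
                        mean_hr_bpm=float(rng.normal(125.0, 4.0)),
                        mean_hrv_ms=float(rng.normal(35.0, 4.0)),
                        attached_hours=float(
                            rng.uniform(rules.min_attached_hours + 0.5, 14.0)
                        ),
                    )
                )
            else:
                days.append(
                    DaySummary(
                        day_index=d,
                        attached_hours=float(
                            rng.uniform(0.0, max(rules.min_attached_hours - 1.0, 0.0))
                        ),
                    )
                )
        nights = [
            NightSummary(
                night_id=f"C{i + 1:03d}-N{k + 1}",
                recording_duration_s=float(
                    rng.uniform(rules.min_night_hours + 1.0, 12.0) * 3600.0
                ),
                n_samples=960,
                prop_above_autocorr=float(rng.uniform(0.3, 0.6)),
                mean_resp_rate_bpm=float(rng.normal(25.0, 2.0)),
                resp_rate_variance=float(rng.uniform(1.0, 4.0)),
                ultradian_period_min=float(rng.uniform(40.0, 110.0)),
            )
            for k in range(nn)
        ]
        if nn < rules.study_days:
            # one short, unusable night so the duration rule is exercised
            nights.append(
                NightSummary(
                    night_id=f"C{i + 1:03d}-Nshort",
                    recording_duration_s=max(rules.min_night_hours - 4.0, 0.5) * 3600.0,
                    n_samples=240,
                    prop_above_autocorr=0.2,
                    mean_resp_rate_bpm=float(rng.normal(25.0, 2.0)),
                    resp_rate_variance=float(rng.uniform(1.0, 4.0)),
                )
            )
        children.append(ChildRecord(child_id=f"C{i + 1:03d}", hr_days=days, nappa_nights=nights))
    return StudyCohort(children, study_days=rules.study_days)
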