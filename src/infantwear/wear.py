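"""Wear-state classification from joint ECG and accelerometry evidence.

Per 10-min window: any physiological R-R interval means the device was worn
and attached; otherwise persistent movement (SD of the acceleration vector
magnitude above 13 mg over the window) means worn but detached; otherwise
not worn. The vector-magnitude SD uses the population formula (ddof=0) —
it characterises the window itself rather than estimating a wider
population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import ValidationError
from .series import WEAR_STATES, AccelSeries, RRSeries

__all__ = ["WearStateSeries", "WearSummary", "vector_magnitude_sd", "classify_wear", "wear_summary"]

logger = logging.getLogger(__name__)


@dataclass
class WearStateSeries:
    """Contiguous half-open windows, each labelled with one wear state."""

    window_starts_s: np.ndarray
    states: np.ndarray  # values in WEAR_STATES
    window_s: float

    def __len__(self) -> int:
        return self.window_starts_s.size

    def mask(self, state: str) -> np.ndarray:
        if state not in WEAR_STATES:
            raise ValidationError(f"unknown wear state {state!r}")
        return self.states == state

    def duration_s(self, state: str) -> float:
        return float(self.mask(state).sum() * self.window_s)


@dataclass
class WearSummary:
    n_wear_periods: int
    total_wear_s: float
    wear_attached_s: float
    wear_detached_s: float
    n_accidental_detachments: int
    error_rate_per_min: float  # NaN when there is no attached time

    @property
    def total_wear_hours(self) -> float:
        return self.total_wear_s / 3600.0

    @property
    def attached_hours(self) -> float:
        return self.wear_attached_s / 3600.0


def vector_magnitude_sd(accel: AccelSeries, t0: float, t1: float) -> float:
    """Population SD of sqrt(ax^2+ay^2+az^2) over samples in [t0, t1).

    Returns NaN when no sample falls in the window.
    """
    if t1 <= t0:
        raise ValidationError("window must satisfy t0 < t1")
    i0 = max(0, int(np.ceil(t0 * accel.sample_rate_hz)))
    i1 = min(len(accel), int(np.ceil(t1 * accel.sample_rate_hz)))
    if i1 <= i0:
        return float("nan")
    vm = np.sqrt(np.sum(accel.samples_mg[i0:i1] ** 2, axis=1))
    return float(np.std(vm))


def classify_wear(
    rr: RRSeries,
    accel: AccelSeries,
    cfg: AnalysisConfig | None = None,
    duration_s: float | None = None,
) -> WearStateSeries:
    """Label each window worn_attached / worn_detached / not_worn.

    Heartbeat evidence (>= 1 interval inside the physiological range, the
    weakest faithful reading of "a detectable heartbeat") wins over
    movement. Windows lacking both heartbeat and accelerometry are marked
    not_worn with a data-gap warning.
    """
    cfg = cfg or AnalysisConfig()
    if duration_s is None:
        duration_s = max(rr.duration_s, accel.duration_s)
    n_win = int(np.ceil(duration_s / cfg.window_s)) if duration_s > 0 else 0
    starts = np.arange(n_win) * cfg.window_s
    states = np.full(n_win, "not_worn", dtype=object)

    physio = (rr.rr_ms >= cfg.rr_physio_lower_ms) & (rr.rr_ms <= cfg.rr_physio_upper_ms)
    beat_idx = np.floor(rr.t_s[physio] / cfg.window_s).astype(int)
    beat_idx = beat_idx[(beat_idx >= 0) & (beat_idx < n_win)]
    has_beat = np.zeros(n_win, dtype=bool)
    has_beat[beat_idx] = True

    for w in range(n_win):
        if has_beat[w]:
            states[w] = "worn_attached"
            continue
        sd = vector_magnitude_sd(accel, starts[w], starts[w] + cfg.window_s)
        if np.isnan(sd):
            logger.warning(
                "window starting %.0f s: no heartbeat and no accelerometry; "
                "marking not_worn",
                starts[w],
            )
        elif sd > cfg.movement_sd_threshold_mg:
            states[w] = "worn_detached"
    return WearStateSeries(starts, states, cfg.window_s)


def wear_summary(
    states: WearStateSeries, rr: RRSeries, cfg: AnalysisConfig | None = None
) -> WearSummary:
    """Roll wear states and artefact load up into one summary.

    Wear periods are maximal runs of windows that are not not_worn;
    accidental detachments are worn_attached -> worn_detached transitions;
    the error rate is the count of non-physiological intervals landing in
    attached windows divided by attached minutes.
    """
    cfg = cfg or AnalysisConfig()
    worn = states.states != "not_worn"
    n_periods = int(np.sum(worn & ~np.concatenate(([False], worn[:-1]))))
    attached = states.mask("worn_attached")
    detached = states.mask("worn_detached")
    n_detach = int(np.sum(attached[:-1] & detached[1:]))

    attached_s = states.duration_s("worn_attached")
    detached_s = states.duration_s("worn_detached")
    nonphysio = (rr.rr_ms < cfg.rr_physio_lower_ms) | (rr.rr_ms > cfg.rr_physio_upper_ms)
    idx = np.floor(rr.t_s[nonphysio] / states.window_s).astype(int)
    idx = idx[(idx >= 0) & (idx < len(states))]
    n_errors = int(np.sum(attached[idx]))
    attached_min = attached_s / 60.0
    rate = n_errors / attached_min if attached_min > 0 else float("nan")
    return WearSummary(
        n_wear_periods=n_periods,
        total_wear_s=attached_s + detached_s,
        wear_attached_s=attached_s,
        wear_detached_s=detached_s,
        n_accidental_detachments=n_detach,
        error_rate_per_min=rate,
    )
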