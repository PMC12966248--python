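"""Analysis thresholds and usability rules.

All quality gates used by the pipeline live in :class:`AnalysisConfig` so a
sensitivity sweep can vary any of them in one place. Defaults follow the
study protocol this package implements: 13 mg persistent-movement threshold
on the SD of the accelerometer vector magnitude, 10-min analysis windows,
150 non-physiological intervals per window as the artefact flag, 25/50/100
interval-count gates for HR minutes and HR/HRV window coverage, and a 0.35
autocorrelation threshold for respiration quality.

The physiological R-R range default of [250, 1000] ms (240-60 bpm) is a
configuration value, not a measured constant; revisit it for populations
outside infancy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

from .errors import ConfigurationError

__all__ = ["AnalysisConfig", "UsabilityRules"]


@dataclass(frozen=True)
class AnalysisConfig:
    movement_sd_threshold_mg: float = 13.0
    window_s: float = 600.0
    nonphysio_limit_per_window: int = 150
    rr_physio_lower_ms: float = 250.0
    rr_physio_upper_ms: float = 1000.0
    min_intervals_hr_coverage: int = 50
    min_intervals_hrv_window: int = 100
    min_intervals_hr_minute: int = 25
    autocorr_threshold: float = 0.35
    ultradian_period_band_min: tuple[float, float] = (30.0, 120.0)
    #: order of the Butterworth section used for the ultradian band-pass
    bandpass_order: int = 2
    #: peak prominence threshold, in units of the band-passed signal SD
    peak_prominence_sd: float = 0.5
    #: minimum fraction of variance the band-passed component must carry
    #: for a period to be reported (rejects noise-only nights)
    min_band_variance_ratio: float = 0.15
    #: respiration gaps up to this length are bridged by interpolation
    max_gap_bridge_s: float = 600.0
    #: minimum interval count for a 2-min HRV sub-segment SD
    min_subsegment_intervals: int = 2

    def __post_init__(self) -> None:
        positive = (
            "movement_sd_threshold_mg",
            "window_s",
            "nonphysio_limit_per_window",
            "rr_physio_lower_ms",
            "rr_physio_upper_ms",
            "min_intervals_hr_coverage",
            "min_intervals_hrv_window",
            "min_intervals_hr_minute",
            "autocorr_threshold",
            "bandpass_order",
            "peak_prominence_sd",
            "max_gap_bridge_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.rr_physio_lower_ms >= self.rr_physio_upper_ms:
            raise ConfigurationError(
                "rr_physio_lower_ms must be below rr_physio_upper_ms"
            )
        lo, hi = self.ultradian_period_band_min
        if not 0 < lo < hi:
            raise ConfigurationError("ultradian band must satisfy 0 < lower < upper")

    def replace(self, **changes: Any) -> "AnalysisConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class UsabilityRules:
    """What counts as a usable heart-rate day or respiration night.

    The source study reports usable-unit counts without printing the rule
    that produced them; these defaults (>= 6 h attached wear per day,
    >= 6 h recorded per night, 7-day study window) are explicit,
    documented stand-ins.
    """

    min_attached_hours: float = 6.0
    min_night_hours: float = 6.0
    study_days: int = 7

    def __post_init__(self) -> None:
        if self.min_attached_hours < 0 or self.min_night_hours < 0:
            raise ConfigurationError("hour thresholds must be >= 0")
        if self.study_days <= 0:
            raise ConfigurationError("study_days must be a positive count")
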