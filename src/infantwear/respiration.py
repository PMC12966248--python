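"""Respiration quality gating, nightly summaries and ultradian-cycle extraction.

The ultradian extractor isolates the 30-120-min oscillation in the nightly
respiration-rate series and reports its period as the mean inter-peak
interval. Pipeline: quality-passing samples are interpolated onto a uniform
1-min grid (gaps <= 10 min bridged, longer gaps split the night into
segments), the night median is removed, a zero-phase Butterworth band-pass
keeps the 30-120-min period band, and peaks separated by at least the lower
band period with prominence >= 0.5 x the band-passed SD are accepted.

Nights whose band-passed component carries less than a configurable
fraction of the total variance (default 0.15) are reported as undefined
with reason ``low_band_power``; this spectral check is what rejects
noise-only recordings, which otherwise always show spurious band-limited
peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .series import POSITION_CATEGORIES, RespirationNight

__all__ = ["NightSummary", "UltradianResult", "quality_mask", "night_summary", "ultradian_cycle"]

#: cadence of the uniform grid used for ultradian extraction (seconds)
_GRID_STEP_S = 60.0


@dataclass
class NightSummary:
    """Per-night roll-up of respiration quality and rate.

    ``mean_resp_rate_bpm`` and ``resp_rate_variance`` are computed only from
    samples passing the autocorrelation quality gate; ``position_fractions``
    covers all samples. ``ultradian_period_min`` is attached downstream when
    the cycle extraction succeeds.
    """

    night_id: str | None
    recording_duration_s: float
    n_samples: int
    prop_above_autocorr: float
    mean_resp_rate_bpm: float  # NaN when no sample passes quality
    resp_rate_variance: float  # sample variance; NaN when < 2 passing samples
    position_fractions: dict[str, float] = field(default_factory=dict)
    ultradian_period_min: float = float("nan")

    @property
    def recording_hours(self) -> float:
        return self.recording_duration_s / 3600.0


@dataclass
class UltradianResult:
    period_min: float  # NaN when undefined
    peak_times_s: np.ndarray
    n_peaks: int
    band_min: tuple[float, float]
    band_variance_ratio: float = float("nan")
    reason: str | None = None  # set when period is undefined

    @property
    def defined(self) -> bool:
        return np.isfinite(self.period_min)


def quality_mask(night: RespirationNight, cfg: AnalysisConfig | None = None) -> np.ndarray:
    """True where the autocorrelation quality score strictly exceeds the threshold."""
    cfg = cfg or AnalysisConfig()
    return np.asarray(night.autocorr) > cfg.autocorr_threshold


def night_summary(night: RespirationNight, cfg: AnalysisConfig | None = None) -> NightSummary:
    cfg = cfg or AnalysisConfig()
    night.validate()
    n = len(night)
    if n == 0:
        return NightSummary(night.night_id, 0.0, 0, 0.0, np.nan, np.nan, {})
    mask = quality_mask(night, cfg)
    passing = night.resp_rate_bpm[mask]
    mean = float(np.mean(passing)) if passing.size else np.nan
    var = float(np.var(passing, ddof=1)) if passing.size >= 2 else np.nan
    fractions = {
        pos: float(np.mean(night.position == pos))
        for pos in POSITION_CATEGORIES
        if np.any(night.position == pos)
    }
    return NightSummary(
        night_id=night.night_id,
        recording_duration_s=night.duration_s,
        n_samples=n,
        prop_above_autocorr=float(np.mean(mask)),
        mean_resp_rate_bpm=mean,
        resp_rate_variance=var,
        position_fractions=fractions,
    )


def _segments(t: np.ndarray, max_gap_s: float) -> list[np.ndarray]:
    """Index arrays of runs whose internal sample gaps are all <= max_gap_s."""
    if t.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > max_gap_s)
    return np.split(np.arange(t.size), breaks + 1)


def _undefined(band, reason, ratio=float("nan"), peaks=None) -> UltradianResult:
    peaks = np.array([]) if peaks is None else peaks
    return UltradianResult(np.nan, peaks, int(peaks.size), band, ratio, reason)


def ultradian_cycle(night: RespirationNight, cfg: AnalysisConfig | None = None) -> UltradianResult:
    cfg = cfg or AnalysisConfig()
    night.validate()
    lo_min, hi_min = cfg.ultradian_period_band_min
    band = (lo_min, hi_min)

    mask = quality_mask(night, cfg)
    t = night.t_s[mask]
    x = night.resp_rate_bpm[mask]
    if t.size < 2 or (t[-1] - t[0]) < 2 * lo_min * 60.0:
        return _undefined(band, "insufficient_duration")

    fs = 1.0 / _GRID_STEP_S
    sos = signal.butter(
        cfg.bandpass_order,
        [1.0 / (hi_min * 60.0), 1.0 / (lo_min * 60.0)],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    median = np.median(x)

    grids: list[tuple[np.ndarray, np.ndarray]] = []  # (grid times, filtered values)
    raw_var_num = 0.0
    band_var_num = 0.0
    n_total = 0
    for idx in _segments(t, cfg.max_gap_bridge_s):
        ts, xs = t[idx], x[idx]
        if ts.size < 2 or (ts[-1] - ts[0]) < 2 * lo_min * 60.0:
            continue  # too short to hold two cycles
        grid = np.arange(ts[0], ts[-1] + _GRID_STEP_S / 2, _GRID_STEP_S)
        xg = np.interp(grid, ts, xs) - median
        yg = signal.sosfiltfilt(sos, xg)
        grids.append((grid, yg))
        raw_var_num += float(np.sum((xg - xg.mean()) ** 2))
        band_var_num += float(np.sum((yg - yg.mean()) ** 2))
        n_total += grid.size
    if not grids:
        return _undefined(band, "insufficient_duration")

    ratio = band_var_num / raw_var_num if raw_var_num > 0 else 0.0
    pooled_sd = np.sqrt(band_var_num / n_total)
    if pooled_sd == 0:
        return _undefined(band, "flat_signal", ratio)
    if ratio < cfg.min_band_variance_ratio:
        return _undefined(band, "low_band_power", ratio)

    peak_times: list[np.ndarray] = []
    intervals: list[np.ndarray] = []
    min_sep = max(1, int(round(lo_min * 60.0 / _GRID_STEP_S)))
    for grid, yg in grids:
        pk, _ = signal.find_peaks(
            yg, distance=min_sep, prominence=cfg.peak_prominence_sd * pooled_sd
        )
        peak_times.append(grid[pk])
        if pk.size >= 2:
            intervals.append(np.diff(grid[pk]))
    peaks = np.concatenate(peak_times) if peak_times else np.array([])
    n_peaks = int(peaks.size)
    if n_peaks < 3 or not intervals:
        return _undefined(band, "too_few_peaks", ratio, peaks)

    period_min = float(np.mean(np.concatenate(intervals)) / 60.0)
    if not lo_min <= period_min <= hi_min:
        return _undefined(band, "period_out_of_band", ratio, peaks)
    return UltradianResult(period_min, peaks, n_peaks, band, ratio, None)
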