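"""Validity-gated heart rate, heart-rate variability and signal-quality coverage.

An interval belongs to the segment containing its beat's *end* time. Heart
rate is reported per 1-min segment only when at least 25 physiological
intervals fall in it; SDRRI is reported per 10-min window only when at
least 100 intervals fall in it, as the mean of the sample SDs of its five
2-min sub-segments (the SDNN-index convention; the combination rule is an
interpretation and the per-sub-segment SDs are retained). Sample SD
(n-1 denominator) is used throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import ValidationError
from .series import RRSeries

__all__ = [
    "HRSeries",
    "HRVSeries",
    "QualityReport",
    "filter_physiological",
    "heart_rate_series",
    "hrv_series",
    "quality_report",
    "zscore",
]

_SUBSEGMENTS_PER_WINDOW = 5


@dataclass
class HRSeries:
    minute_starts_s: np.ndarray
    hr_bpm: np.ndarray  # NaN where the 25-interval gate fails
    n_intervals: np.ndarray
    start_time: str | None = None

    def __len__(self) -> int:
        return self.minute_starts_s.size

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.hr_bpm)


@dataclass
class HRVSeries:
    window_starts_s: np.ndarray
    sdrri_ms: np.ndarray  # NaN where the 100-interval gate fails
    n_intervals: np.ndarray
    subsegment_sd_ms: np.ndarray  # shape (n_windows, 5), NaN where undefined
    start_time: str | None = None

    def __len__(self) -> int:
        return self.window_starts_s.size

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.sdrri_ms)


@dataclass
class QualityReport:
    n_windows: int
    prop_hr_coverage: float  # fraction of windows with >= 50 physiological intervals
    prop_hrv_coverage: float  # fraction with >= 100
    flagged_window_starts_s: np.ndarray  # > 150 non-physiological intervals
    physio_counts: np.ndarray
    nonphysio_counts: np.ndarray


def _segment_counts(t_s: np.ndarray, seg_s: float, n_segments: int) -> np.ndarray:
    idx = np.floor(t_s / seg_s).astype(int)
    idx = idx[(idx >= 0) & (idx < n_segments)]
    return np.bincount(idx, minlength=n_segments)


def _n_segments(rr: RRSeries, seg_s: float, duration_s: float | None) -> int:
    if duration_s is None:
        duration_s = rr.duration_s
    if duration_s <= 0:
        return 0
    # a beat exactly at the duration boundary still needs a segment
    n = int(np.ceil(duration_s / seg_s))
    if len(rr) and rr.t_s[-1] >= n * seg_s:
        n += 1
    return n


def filter_physiological(
    rr: RRSeries, cfg: AnalysisConfig | None = None, duration_s: float | None = None
) -> tuple[RRSeries, np.ndarray]:
    """Split an R-R stream into physiological intervals and per-window outlier counts.

    Returns the series restricted to intervals within
    ``[rr_physio_lower_ms, rr_physio_upper_ms]`` plus, for each 10-min
    window, the count of excluded intervals.
    """
    cfg = cfg or AnalysisConfig()
    keep = (rr.rr_ms >= cfg.rr_physio_lower_ms) & (rr.rr_ms <= cfg.rr_physio_upper_ms)
    kept = RRSeries(rr.t_s[keep], rr.rr_ms[keep], start_time=rr.start_time)
    n_win = _n_segments(rr, cfg.window_s, duration_s)
    outside = _segment_counts(rr.t_s[~keep], cfg.window_s, n_win)
    return kept, outside


def heart_rate_series(
    rr: RRSeries, cfg: AnalysisConfig | None = None, duration_s: float | None = None
) -> HRSeries:
    """Per-minute heart rate, gated on the 25-interval minimum.

    Expects an R-R stream already restricted to the physiological range
    (see :func:`filter_physiological`). HR = 60000 / mean(rr_ms).
    """
    cfg = cfg or AnalysisConfig()
    n_min = _n_segments(rr, 60.0, duration_s)
    starts = np.arange(n_min) * 60.0
    hr = np.full(n_min, np.nan)
    if n_min == 0:
        return HRSeries(starts, hr, np.zeros(0, dtype=int), rr.start_time)
    idx = np.floor(rr.t_s / 60.0).astype(int)
    counts = np.bincount(idx, minlength=n_min)
    sums = np.bincount(idx, weights=rr.rr_ms, minlength=n_min)
    ok = counts >= cfg.min_intervals_hr_minute
    hr[ok] = 60000.0 / (sums[ok] / counts[ok])
    return HRSeries(starts, hr, counts, rr.start_time)


def hrv_series(
    rr: RRSeries, cfg: AnalysisConfig | None = None, duration_s: float | None = None
) -> HRVSeries:
    """Per-10-min-window SDRRI, gated on the 100-interval minimum.

    Expects a physiologically filtered stream. For each qualifying window
    the sample SD of the intervals in each 2-min sub-segment (>= 2 intervals)
    is computed; the window SDRRI is the mean of the defined sub-segment SDs.
    """
    cfg = cfg or AnalysisConfig()
    n_win = _n_segments(rr, cfg.window_s, duration_s)
    starts = np.arange(n_win) * cfg.window_s
    sdrri = np.full(n_win, np.nan)
    sub_sd = np.full((n_win, _SUBSEGMENTS_PER_WINDOW), np.nan)
    if n_win == 0:
        return HRVSeries(starts, sdrri, np.zeros(0, dtype=int), sub_sd, rr.start_time)
    win_idx = np.floor(rr.t_s / cfg.window_s).astype(int)
    counts = np.bincount(win_idx, minlength=n_win)
    sub_s = cfg.window_s / _SUBSEGMENTS_PER_WINDOW
    for w in np.flatnonzero(counts >= cfg.min_intervals_hrv_window):
        in_win = win_idx == w
        t_local = rr.t_s[in_win] - starts[w]
        vals = rr.rr_ms[in_win]
        sub_idx = np.minimum(
            np.floor(t_local / sub_s).astype(int), _SUBSEGMENTS_PER_WINDOW - 1
        )
        for k in range(_SUBSEGMENTS_PER_WINDOW):
            seg = vals[sub_idx == k]
            if seg.size >= cfg.min_subsegment_intervals:
                sub_sd[w, k] = np.std(seg, ddof=1)
        defined = np.isfinite(sub_sd[w])
        if defined.any():
            sdrri[w] = np.mean(sub_sd[w, defined])
    return HRVSeries(starts, sdrri, counts, sub_sd, rr.start_time)


def quality_report(
    rr: RRSeries,
    cfg: AnalysisConfig | None = None,
    duration_s: float | None = None,
    window_mask: np.ndarray | None = None,
) -> QualityReport:
    """Coverage proportions and artefact flags per 10-min window.

    ``window_mask`` optionally restricts the report to a subset of windows
    (e.g. the worn-attached ones from the wear-time module).
    """
    cfg = cfg or AnalysisConfig()
    kept, outside = filter_physiological(rr, cfg, duration_s)
    n_win = outside.size
    physio = _segment_counts(kept.t_s, cfg.window_s, n_win)
    starts = np.arange(n_win) * cfg.window_s
    if window_mask is not None:
        window_mask = np.asarray(window_mask, dtype=bool)
        if window_mask.size != n_win:
            raise ValidationError(
                f"window_mask length {window_mask.size} != number of windows {n_win}"
            )
    else:
        window_mask = np.ones(n_win, dtype=bool)
    physio_sel = physio[window_mask]
    n_sel = int(window_mask.sum())
    if n_sel == 0:
        prop_hr = prop_hrv = np.nan
    else:
        prop_hr = float(np.mean(physio_sel >= cfg.min_intervals_hr_coverage))
        prop_hrv = float(np.mean(physio_sel >= cfg.min_intervals_hrv_window))
    flagged = starts[window_mask & (outside > cfg.nonphysio_limit_per_window)]
    return QualityReport(n_sel, prop_hr, prop_hrv, flagged, physio, outside)


def zscore(
    values: np.ndarray | HRSeries | HRVSeries,
    baseline: np.ndarray | None = None,
    label: str | None = None,
) -> np.ndarray:
    """Express a gated series in SD units of the child's own defined values.

    ``baseline`` defaults to the defined values of the series itself (the
    child's whole recording). NaNs stay NaN. Raises when the baseline has
    fewer than two defined values or zero variance.
    """
    if isinstance(values, HRSeries):
        x = values.hr_bpm
    elif isinstance(values, HRVSeries):
        x = values.sdrri_ms
    else:
        x = np.asarray(values, dtype=float)
    base = x if baseline is None else np.asarray(baseline, dtype=float)
    base = base[np.isfinite(base)]
    who = f" for {label}" if label else ""
    if base.size < 2:
        raise ValidationError(f"z-score baseline{who} needs >= 2 defined values")
    mu = np.mean(base)
    sd = np.std(base, ddof=1)
    if sd == 0:
        raise ValidationError(f"z-score baseline{who} has zero variance")
    return (x - mu) / sd
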