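"""Merge diary events with physiological series; nap-response analysis.

The timeline bundles the per-minute heart rate, per-minute movement
(SD of the accelerometer vector magnitude), wear states and parent-diary
events onto one clock so each labelled event can be annotated with the
physiology observed during it. Nap responses are z-scored against the
child's own baseline (whole recording by default) so excursions are
expressed in within-child SD units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .cardiac import HRSeries, HRVSeries, zscore
from .errors import ValidationError
from .series import AccelSeries, DiaryEntry, DiaryLog
from .wear import WearStateSeries, vector_magnitude_sd

__all__ = ["TimelineBundle", "NapResponse", "build_timeline", "nap_response", "minute_activity"]

logger = logging.getLogger(__name__)

#: context shown either side of a nap window (seconds)
DEFAULT_FLANK_S = 1800.0


@dataclass
class TimelineBundle:
    child_id: str
    hr: HRSeries
    activity_minute_sd_mg: np.ndarray
    wear: WearStateSeries
    events: pd.DataFrame  # one row per diary entry with physiology annotations
    alignment_anchor: str | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: one row per (minute, variable)."""
        minutes = self.hr.minute_starts_s
        win = np.minimum(
            np.floor(minutes / self.wear.window_s).astype(int),
            max(len(self.wear) - 1, 0),
        )
        wear_states = (
            self.wear.states[win] if len(self.wear) else np.full(minutes.size, "not_worn")
        )
        frames = [
            pd.DataFrame(
                {"t_s": minutes, "variable": "hr_bpm", "value": self.hr.hr_bpm}
            ),
            pd.DataFrame(
                {
                    "t_s": minutes,
                    "variable": "activity_sd_mg",
                    "value": self.activity_minute_sd_mg,
                }
            ),
            pd.DataFrame(
                {"t_s": minutes, "variable": "wear_state", "value": wear_states}
            ),
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass
class NapResponse:
    nap_window_s: tuple[float, float]
    t_s: np.ndarray
    hr_z: np.ndarray
    hrv_z: np.ndarray | None
    min_hr_z: float  # NaN with reason when nothing defined in window
    max_hrv_z: float
    reason: str | None = None


def minute_activity(accel: AccelSeries, n_minutes: int) -> np.ndarray:
    """Per-minute SD of the acceleration vector magnitude (mg)."""
    return np.array(
        [vector_magnitude_sd(accel, 60.0 * m, 60.0 * (m + 1)) for m in range(n_minutes)]
    )


def _event_seconds(entry: DiaryEntry, anchor: datetime) -> tuple[float, float]:
    return (
        (entry.start - anchor).total_seconds(),
        (entry.end - anchor).total_seconds(),
    )


def build_timeline(
    child_id: str,
    hr: HRSeries,
    wear: WearStateSeries,
    accel: AccelSeries,
    diary: DiaryLog | None = None,
    anchor: str | None = None,
) -> TimelineBundle:
    """Merge the streams onto one clock and annotate diary events.

    Every event is annotated with the mean defined HR and mean activity of
    the minutes it overlaps; events with no defined HR minutes are marked
    undefined. Event times outside the recording span are clipped (logged).
    """
    anchor = anchor or hr.start_time or accel.start_time
    n_minutes = len(hr)
    if n_minutes == 0:
        raise ValidationError("heart-rate series is empty; nothing to merge")
    recording_end_s = 60.0 * n_minutes
    if accel.duration_s > 0 and accel.t_s[0] >= recording_end_s:
        raise ValidationError("accelerometry lies entirely outside the HR series span")

    activity = minute_activity(accel, n_minutes)
    rows = []
    if diary is not None and len(diary):
        if anchor is None:
            raise ValidationError("diary merging requires an alignment anchor")
        anchor_dt = datetime.fromisoformat(anchor)
        for entry in diary:
            s, e = _event_seconds(entry, anchor_dt)
            if e < 0 or s > recording_end_s:
                raise ValidationError(
                    f"diary event {entry.label!r} lies outside the recording span"
                )
            cs, ce = max(s, 0.0), min(e, recording_end_s)
            if (cs, ce) != (s, e):
                logger.info("clipped diary event %r to the recording span", entry.label)
            sel = (hr.minute_starts_s >= cs) & (hr.minute_starts_s < max(ce, cs + 60.0))
            hr_vals = hr.hr_bpm[sel]
            act_vals = activity[sel]
            hr_defined = hr_vals[np.isfinite(hr_vals)]
            rows.append(
                {
                    "label": entry.label,
                    "category": entry.category,
                    "start_s": cs,
                    "end_s": ce,
                    "mean_hr_bpm": float(hr_defined.mean()) if hr_defined.size else np.nan,
                    "hr_defined": bool(hr_defined.size),
                    "mean_activity_sd_mg": (
                        float(np.nanmean(act_vals)) if act_vals.size else np.nan
                    ),
                }
            )
    events = pd.DataFrame(
        rows,
        columns=[
            "label",
            "category",
            "start_s",
            "end_s",
            "mean_hr_bpm",
            "hr_defined",
            "mean_activity_sd_mg",
        ],
    )
    return TimelineBundle(child_id, hr, activity, wear, events, anchor)


def nap_response(
    hr: HRSeries,
    hrv: HRVSeries | None,
    nap_window_s: tuple[float, float],
    baseline_hr: np.ndarray | None = None,
    baseline_hrv: np.ndarray | None = None,
    flank_s: float = DEFAULT_FLANK_S,
) -> NapResponse:
    """Z-scored HR/HRV traces around one nap, with extrema inside the window.

    The baseline defaults to all defined values of each series (the child's
    whole recording); extrema are taken over defined points strictly inside
    the nap window while the returned traces include ``flank_s`` of context
    either side.
    """
    s, e = nap_window_s
    if e <= s:
        raise ValidationError("nap window must satisfy start < end")
    t = hr.minute_starts_s
    if t.size == 0 or s >= t[-1] + 60.0 or e <= t[0]:
        raise ValidationError("nap window lies outside the recording")

    hr_z_full = zscore(hr, baseline=baseline_hr)
    keep = (t >= s - flank_s) & (t < e + flank_s)
    t_out = t[keep]
    hr_z = hr_z_full[keep]
    in_nap = (t_out >= s) & (t_out < e)
    hr_in = hr_z[in_nap]
    hr_in = hr_in[np.isfinite(hr_in)]

    hrv_z = None
    max_hrv_z = np.nan
    if hrv is not None:
        hrv_z_full = zscore(hrv, baseline=baseline_hrv)
        tw = hrv.window_starts_s
        keep_w = (tw >= s - flank_s) & (tw < e + flank_s)
        hrv_z = hrv_z_full[keep_w]
        in_nap_w = (tw[keep_w] >= s) & (tw[keep_w] < e)
        hrv_in = hrv_z[in_nap_w]
        hrv_in = hrv_in[np.isfinite(hrv_in)]
        if hrv_in.size:
            max_hrv_z = float(hrv_in.max())

    if hr_in.size == 0:
        return NapResponse(
            (s, e), t_out, hr_z, hrv_z, np.nan, max_hrv_z, reason="no_defined_hr_in_window"
        )
    return NapResponse((s, e), t_out, hr_z, hrv_z, float(hr_in.min()), max_hrv_z)
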