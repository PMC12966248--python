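"""Core data containers for the four recording streams.

Times inside every container are float seconds since the recording start;
the wall-clock anchor is a single ISO-8601 ``start_time`` string. Undefined
numeric values are NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .errors import ValidationError

__all__ = [
    "POSITION_CATEGORIES",
    "DIARY_CATEGORIES",
    "WEAR_STATES",
    "RRSeries",
    "AccelSeries",
    "RespirationNight",
    "DiaryEntry",
    "DiaryLog",
]

POSITION_CATEGORIES = ("supine", "prone", "left", "right", "upright", "unknown")
DIARY_CATEGORIES = (
    "sleep",
    "nap",
    "feeding",
    "play_light",
    "play_intense",
    "out_of_home",
    "device_event",
    "other",
)
WEAR_STATES = ("worn_attached", "worn_detached", "not_worn")

#: tolerance (s) for the beat-time / interval consistency check
_RR_CONSISTENCY_TOL_S = 1.05e-3


@dataclass
class RRSeries:
    """Timestamped R-R intervals from one wear period.

    ``rr_ms[i]`` is the interval *ending* at beat time ``t_s[i]``; the first
    interval spans from the recording start to the first beat. Gaps in the
    underlying ECG appear as single long (non-physiological) intervals, so
    consecutive beat times always differ by exactly the later interval.
    """

    t_s: np.ndarray
    rr_ms: np.ndarray
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)

    def __len__(self) -> int:
        return self.t_s.size

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1]) if len(self) else 0.0

    def validate(self) -> "RRSeries":
        if self.t_s.shape != self.rr_ms.shape:
            raise ValidationError("t_s and rr_ms must have equal length")
        if len(self) == 0:
            return self
        if np.any(self.rr_ms <= 0):
            i = int(np.argmax(self.rr_ms <= 0))
            raise ValidationError(f"rr_ms must be > 0 (beat index {i})")
        dt = np.diff(self.t_s)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0)) + 1
            raise ValidationError(f"t_s must be strictly increasing (beat index {i})")
        mismatch = np.abs(dt - self.rr_ms[1:] / 1000.0) > _RR_CONSISTENCY_TOL_S
        if np.any(mismatch):
            i = int(np.argmax(mismatch)) + 1
            raise ValidationError(
                f"beat time step disagrees with rr_ms beyond 1 ms (beat index {i})"
            )
        return self


@dataclass
class AccelSeries:
    """Tri-axial accelerometry in milli-g at a fixed sample rate."""

    samples_mg: np.ndarray  # shape (n, 3)
    sample_rate_hz: float
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.samples_mg = np.asarray(self.samples_mg, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.samples_mg.shape[0]

    @property
    def t_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    def vector_magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.samples_mg**2, axis=1))

    def validate(self) -> "AccelSeries":
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")
        if not np.all(np.isfinite(self.samples_mg)):
            i = int(np.argmax(~np.isfinite(self.samples_mg).all(axis=1)))
            raise ValidationError(f"non-finite acceleration sample (row {i})")
        return self


@dataclass
class RespirationNight:
    """One night of respiration monitor output.

    Each sample carries the device's respiration-rate estimate, its
    autocorrelation quality score in [-1, 1] and the detected sleeping
    position.
    """

    t_s: np.ndarray
    resp_rate_bpm: np.ndarray
    autocorr: np.ndarray
    position: np.ndarray  # dtype object/str, values in POSITION_CATEGORIES
    start_time: str | None = None
    night_id: str | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.resp_rate_bpm = np.asarray(self.resp_rate_bpm, dtype=float)
        self.autocorr = np.asarray(self.autocorr, dtype=float)
        self.position = np.asarray(self.position, dtype=object)

    def __len__(self) -> int:
        return self.t_s.size

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if len(self) else 0.0

    def validate(self) -> "RespirationNight":
        n = len(self)
        for name in ("resp_rate_bpm", "autocorr", "position"):
            if getattr(self, name).size != n:
                raise ValidationError(f"{name} length differs from t_s")
        if n == 0:
            return self
        if np.any(np.diff(self.t_s) <= 0):
            i = int(np.argmax(np.diff(self.t_s) <= 0)) + 1
            raise ValidationError(f"t_s must be strictly increasing (sample {i})")
        if np.any(self.resp_rate_bpm < 0):
            i = int(np.argmax(self.resp_rate_bpm < 0))
            raise ValidationError(f"resp_rate_bpm must be >= 0 (sample {i})")
        bad = (self.autocorr < -1) | (self.autocorr > 1)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValidationError(f"autocorr outside [-1, 1] (sample {i})")
        for i, p in enumerate(self.position):
            if p not in POSITION_CATEGORIES:
                raise ValidationError(f"unknown position {p!r} (sample {i})")
        return self


@dataclass(frozen=True)
class DiaryEntry:
    start: datetime
    end: datetime
    label: str
    category: str = "other"


@dataclass
class DiaryLog:
    """Parent-diary events; overlapping entries are permitted."""

    entries: list[DiaryEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def validate(self) -> "DiaryLog":
        prev = None
        for i, e in enumerate(self.entries):
            if e.end < e.start:
                raise ValidationError(f"diary entry {i}: end before start")
            if e.category not in DIARY_CATEGORIES:
                raise ValidationError(f"diary entry {i}: unknown category {e.category!r}")
            if prev is not None and e.start < prev:
                raise ValidationError(f"diary entry {i}: entries not sorted by start")
            prev = e.start
        return self

    def by_category(self, category: str) -> list[DiaryEntry]:
        return [e for e in self.entries if e.category == category]
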