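"""Canonical CSV readers/writers for the four recording streams.

Format: UTF-8, comma-separated, ``.`` decimal, LF line endings. Metadata
(the wall-clock anchor, the accelerometer sample rate) is carried in
``# key=value`` comment lines before the header row. Round-trips are
lossless to 1 ms for R-R data and 0.1 mg for accelerometry.

Readers are strict about invariants (the first offending line is named in
the error) but tolerant about extras: unknown columns and unknown position
labels produce warnings, not failures.
"""

from __future__ import annotations

import csv
import warnings
from datetime import datetime

import numpy as np

from .errors import ValidationError
from .series import (
    DIARY_CATEGORIES,
    POSITION_CATEGORIES,
    AccelSeries,
    DiaryEntry,
    DiaryLog,
    RespirationNight,
    RRSeries,
)

__all__ = [
    "read_rr",
    "write_rr",
    "read_accel",
    "write_accel",
    "read_nappa",
    "write_nappa",
    "read_diary",
    "write_diary",
    "read_rr_edf",
]


def _read_table(path):
    """Return (meta, fieldnames, rows) where rows are (line_no, dict)."""
    meta: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for raw in lines:
        if raw.startswith("#"):
            body_start += 1
            stripped = raw.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
        else:
            break
    body = lines[body_start:]
    if not body or not body[0].strip():
        return meta, [], []
    reader = csv.DictReader(body)
    rows = [(body_start + 2 + i, row) for i, row in enumerate(reader)]
    return meta, reader.fieldnames or [], rows


def _check_columns(fieldnames, expected, path) -> None:
    missing = [c for c in expected if c not in fieldnames]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    extra = [c for c in fieldnames if c not in expected]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=3)


def _parse_float(value, line, column):
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"column {column}: not a number ({value!r})", line=line)


def _meta_lines(**meta) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items() if v is not None)


# ---------------------------------------------------------------- R-R ----


def write_rr(series: RRSeries, path) -> None:
    series.validate()
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write(_meta_lines(start_time=series.start_time))
        fh.write("t_s,rr_ms\n")
        for t, rr in zip(series.t_s, series.rr_ms):
            fh.write(f"{t:.6f},{rr:.3f}\n")


def read_rr(path) -> RRSeries:
    meta, fieldnames, rows = _read_table(path)
    if fieldnames:
        _check_columns(fieldnames, ["t_s", "rr_ms"], path)
    t, rr = [], []
    for line, row in rows:
        t_val = _parse_float(row["t_s"], line, "t_s")
        rr_val = _parse_float(row["rr_ms"], line, "rr_ms")
        if rr_val <= 0:
            raise ValidationError(f"rr_ms must be > 0 (got {rr_val})", line=line)
        if t and t_val <= t[-1]:
            raise ValidationError("t_s not strictly increasing", line=line)
        t.append(t_val)
        rr.append(rr_val)
    return RRSeries(np.array(t), np.array(rr), start_time=meta.get("start_time")).validate()


# -------------------------------------------------------------- accel ----


def write_accel(series: AccelSeries, path) -> None:
    series.validate()
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write(
            _meta_lines(
                start_time=series.start_time,
                sample_rate_hz=f"{series.sample_rate_hz:g}",
            )
        )
        fh.write("ax_mg,ay_mg,az_mg\n")
        for ax, ay, az in series.samples_mg:
            fh.write(f"{ax:.1f},{ay:.1f},{az:.1f}\n")


def read_accel(path) -> AccelSeries:
    meta, fieldnames, rows = _read_table(path)
    if fieldnames:
        _check_columns(fieldnames, ["ax_mg", "ay_mg", "az_mg"], path)
    if "sample_rate_hz" not in meta:
        raise ValidationError(f"{path}: missing '# sample_rate_hz=' header")
    data = np.empty((len(rows), 3))
    for i, (line, row) in enumerate(rows):
        for j, col in enumerate(("ax_mg", "ay_mg", "az_mg")):
            data[i, j] = _parse_float(row[col], line, col)
        if not np.all(np.isfinite(data[i])):
            raise ValidationError("non-finite acceleration value", line=line)
    return AccelSeries(
        data, float(meta["sample_rate_hz"]), start_time=meta.get("start_time")
    ).validate()


# -------------------------------------------------------------- nappa ----


def write_nappa(night: RespirationNight, path) -> None:
    night.validate()
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write(_meta_lines(start_time=night.start_time, night_id=night.night_id))
        fh.write("t_s,resp_rate_bpm,autocorr,position\n")
        for t, r, a, p in zip(night.t_s, night.resp_rate_bpm, night.autocorr, night.position):
            fh.write(f"{t:.3f},{r:.4f},{a:.6f},{p}\n")


def read_nappa(path) -> RespirationNight:
    meta, fieldnames, rows = _read_table(path)
    if fieldnames:
        _check_columns(fieldnames, ["t_s", "resp_rate_bpm", "autocorr", "position"], path)
    t, rate, ac, pos = [], [], [], []
    for line, row in rows:
        t_val = _parse_float(row["t_s"], line, "t_s")
        r_val = _parse_float(row["resp_rate_bpm"], line, "resp_rate_bpm")
        a_val = _parse_float(row["autocorr"], line, "autocorr")
        if r_val < 0:
            raise ValidationError(f"resp_rate_bpm must be >= 0 (got {r_val})", line=line)
        if not -1.0 <= a_val <= 1.0:
            raise ValidationError(f"autocorr outside [-1, 1] (got {a_val})", line=line)
        if t and t_val <= t[-1]:
            raise ValidationError("t_s not strictly increasing", line=line)
        p_val = (row["position"] or "").strip()
        if p_val not in POSITION_CATEGORIES:
            warnings.warn(
                f"{path} line {line}: unknown position {p_val!r} mapped to 'unknown'",
                stacklevel=2,
            )
            p_val = "unknown"
        t.append(t_val)
        rate.append(r_val)
        ac.append(a_val)
        pos.append(p_val)
    return RespirationNight(
        np.array(t),
        np.array(rate),
        np.array(ac),
        np.array(pos, dtype=object),
        start_time=meta.get("start_time"),
        night_id=meta.get("night_id"),
    ).validate()


# -------------------------------------------------------------- diary ----


def write_diary(diary: DiaryLog, path) -> None:
    diary.validate()
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["start", "end", "label", "category"])
        for e in diary.entries:
            writer.writerow([e.start.isoformat(), e.end.isoformat(), e.label, e.category])


def read_diary(path) -> DiaryLog:
    _, fieldnames, rows = _read_table(path)
    if fieldnames:
        _check_columns(fieldnames, ["start", "end", "label", "category"], path)
    entries = []
    for line, row in rows:
        try:
            start = datetime.fromisoformat(row["start"])
            end = datetime.fromisoformat(row["end"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"bad ISO-8601 timestamp: {exc}", line=line)
        if end < start:
            raise ValidationError("diary entry end before start", line=line)
        category = (row["category"] or "other").strip()
        if category not in DIARY_CATEGORIES:
            warnings.warn(
                f"{path} line {line}: unknown category {category!r} mapped to 'other'",
                stacklevel=2,
            )
            category = "other"
        entries.append(DiaryEntry(start, end, row["label"] or "", category))
    entries.sort(key=lambda e: e.start)
    return DiaryLog(entries).validate()


# ---------------------------------------------------- optional EDF hook ----


def read_rr_edf(path, annotation_channel: str = "RR") -> RRSeries:
    """Ingest an EDF Holter export through the same RRSeries contract.

    Optional adapter: requires ``pyedflib``, which is not a core
    dependency. The core pipeline never calls this.
    """
    try:
        import pyedflib  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF ingestion requires the optional dependency 'pyedflib'"
        ) from exc
    with pyedflib.EdfReader(str(path)) as reader:  # pragma: no cover
        labels = reader.getSignalLabels()
        if annotation_channel not in labels:
            raise ValidationError(
                f"{path}: no channel named {annotation_channel!r} (found {labels})"
            )
        idx = labels.index(annotation_channel)
        rr_ms = np.asarray(reader.readSignal(idx), dtype=float)
        rr_ms = rr_ms[rr_ms > 0]
        t_s = np.cumsum(rr_ms) / 1000.0
        start = reader.getStartdatetime().isoformat()
    return RRSeries(t_s, rr_ms, start_time=start).validate()  # pragma: no cover
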