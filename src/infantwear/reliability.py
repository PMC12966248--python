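"""Per-child reliability statistics, usability counts and device comparison.

The device comparison is a one-sample Wilcoxon signed-rank test of the
per-child differences between night- and day-success proportions against
zero. Zero differences are dropped; tied absolute differences can be ranked
either ``ordinal`` (first occurrence gets the lower rank) or ``average``;
both modes are exposed and neither is silently preferred. The reported
statistic T is the smaller of the two signed-rank sums, with an exact
two-sided p-value for up to 25 non-zero differences and a normal
approximation beyond.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cardiac import quality_report
from .config import AnalysisConfig, UsabilityRules
from .errors import ConfigurationError, ValidationError
from .respiration import NightSummary, night_summary, ultradian_cycle
from .series import AccelSeries, DiaryLog, RespirationNight, RRSeries
from .wear import classify_wear, wear_summary

__all__ = [
    "DaySummary",
    "ChildRecord",
    "StudyCohort",
    "ReliabilityRow",
    "DeviceComparison",
    "usable_units",
    "cohort_usability",
    "reliability_table",
    "wilcoxon_signed_rank",
    "compare_devices",
    "precision_halfwidth",
    "threshold_sensitivity",
]


@dataclass
class DaySummary:
    """One day of heart-rate monitor wear for one child."""

    day_index: int
    mean_hr_bpm: float = float("nan")
    mean_hrv_ms: float = float("nan")
    attached_hours: float = 0.0


@dataclass
class ChildRecord:
    child_id: str
    hr_days: list[DaySummary] = field(default_factory=list)
    nappa_nights: list[NightSummary] = field(default_factory=list)
    diary: DiaryLog | None = None


@dataclass
class StudyCohort:
    children: list[ChildRecord] = field(default_factory=list)
    study_days: int = 7

    def __len__(self) -> int:
        return len(self.children)


@dataclass
class ReliabilityRow:
    metric: str
    mean: float
    ci95: tuple[float, float]  # (NaN, NaN) when n < 2
    cv_percent: float  # NaN when n < 2
    n_units: int


@dataclass
class DeviceComparison:
    per_child: pd.DataFrame
    statistic_t: float  # NaN when undefined
    p_value: float
    n_nonzero: int
    tie_method: str
    reason: str | None = None


def usable_units(
    record: ChildRecord, rules: UsabilityRules | None = None
) -> tuple[int, int, int]:
    """(usable respiration nights, usable HR days, denominator).

    A day is usable when its attached wear meets ``min_attached_hours``; a
    night when its recording meets ``min_night_hours``. The denominator is
    the study-window length in days.
    """
    rules = rules or UsabilityRules()
    if rules.study_days == 0:
        raise ConfigurationError("denominator (study_days) must be positive")
    nights = sum(
        1 for n in record.nappa_nights if n.recording_hours >= rules.min_night_hours
    )
    days = sum(1 for d in record.hr_days if d.attached_hours >= rules.min_attached_hours)
    return nights, days, rules.study_days


def cohort_usability(
    cohort: StudyCohort, rules: UsabilityRules | None = None
) -> pd.DataFrame:
    """Per-child usable-unit counts and proportions over the study window."""
    rules = rules or UsabilityRules(study_days=cohort.study_days)
    rows = []
    for child in cohort.children:
        nappa, hr, denom = usable_units(child, rules)
        rows.append(
            {
                "child_id": child.child_id,
                "nappa_usable": nappa,
                "nappa_prop": nappa / denom,
                "hr_usable": hr,
                "hr_prop": hr / denom,
            }
        )
    df = pd.DataFrame(
        rows, columns=["child_id", "nappa_usable", "nappa_prop", "hr_usable", "hr_prop"]
    )
    # single division keeps tied |differences| exactly tied (rank methods
    # must see equal counts as equal magnitudes)
    denom = rules.study_days
    df["diff"] = (df["nappa_usable"] - df["hr_usable"]) / denom
    return df


def _reliability_row(metric: str, values: Iterable[float]) -> ReliabilityRow:
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    n = x.size
    if n == 0:
        return ReliabilityRow(metric, np.nan, (np.nan, np.nan), np.nan, 0)
    mean = float(np.mean(x))
    if n == 1:
        return ReliabilityRow(metric, mean, (np.nan, np.nan), np.nan, 1)
    sd = float(np.std(x, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    return ReliabilityRow(metric, mean, (mean - half, mean + half), cv, n)


def reliability_table(record: ChildRecord) -> list[ReliabilityRow]:
    """Mean, t-based 95% CI and CV% per metric across a child's units.

    Units are days (HR, HRV) or nights (ultradian period); a single unit
    yields a mean with undefined CI and CV.
    """
    return [
        _reliability_row("HR", (d.mean_hr_bpm for d in record.hr_days)),
        _reliability_row("HRV", (d.mean_hrv_ms for d in record.hr_days)),
        _reliability_row(
            "ultradian_period", (n.ultradian_period_min for n in record.nappa_nights)
        ),
    ]


def _exact_p_le(ranks: np.ndarray, t_stat: float) -> float:
    """P(signed-rank sum <= t_stat) under the null, by convolution.

    Ranks may be half-integers (average-rank ties), so sums are tracked on
    a doubled integer grid.
    """
    r2 = np.rint(2 * ranks).astype(int)
    coeffs = np.zeros(int(r2.sum()) + 1, dtype=float)
    coeffs[0] = 1.0
    for r in r2:
        coeffs[r:] += coeffs[:-r].copy() if r else coeffs.copy()
    limit = int(np.floor(2 * t_stat + 1e-9))
    return float(coeffs[: limit + 1].sum() / 2 ** len(ranks))


def wilcoxon_signed_rank(
    diffs: Sequence[float], tie_method: str = "ordinal"
) -> tuple[float, float, int]:
    """Smaller signed-rank sum T, two-sided p-value and n after zero removal.

    ``tie_method``: 'ordinal' ranks tied absolute differences by first
    occurrence; 'average' assigns the mean rank. Exact p for n <= 25,
    normal approximation (with tie correction) above.
    """
    if tie_method not in ("ordinal", "average"):
        raise ConfigurationError(f"unknown tie_method {tie_method!r}")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return float("nan"), float("nan"), 0
    ranks = stats.rankdata(np.abs(d), method=tie_method)
    pos = float(ranks[d > 0].sum())
    neg = float(ranks[d < 0].sum())
    t_stat = min(pos, neg)
    if n <= 25:
        p = min(1.0, 2.0 * _exact_p_le(ranks, t_stat))
    else:
        mu = n * (n + 1) / 4.0
        var = float(np.sum(ranks**2)) / 4.0
        z = (t_stat - mu + 0.5) / np.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.cdf(z))
    return t_stat, p, n


def compare_devices(
    cohort: StudyCohort,
    rules: UsabilityRules | None = None,
    tie_method: str = "ordinal",
) -> DeviceComparison:
    """Paired comparison of night vs day success proportions across children."""
    if len(cohort) == 0:
        raise ValidationError("cohort must contain at least one child")
    table = cohort_usability(cohort, rules)
    t_stat, p, n_nonzero = wilcoxon_signed_rank(table["diff"].to_numpy(), tie_method)
    reason = "all_differences_zero" if n_nonzero == 0 else None
    return DeviceComparison(table, t_stat, p, n_nonzero, tie_method, reason)


def precision_halfwidth(p: float, n: int) -> float:
    """Half-width of the 95% normal interval for a proportion: 1.96*sqrt(p(1-p)/n)."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must lie in [0, 1]")
    if n < 1:
        raise ValidationError("n must be >= 1")
    return 1.96 * float(np.sqrt(p * (1.0 - p) / n))


def threshold_sensitivity(
    rr: RRSeries,
    accel: AccelSeries,
    sweep: Mapping[str, Sequence],
    cfg: AnalysisConfig | None = None,
    night: RespirationNight | None = None,
) -> pd.DataFrame:
    """Re-run the wear/cardiac (and optional respiration) summaries over a grid.

    ``sweep`` maps AnalysisConfig field names to value lists; the grid is
    their Cartesian product and the result is one long-format row per grid
    point.
    """
    cfg = cfg or AnalysisConfig()
    if not sweep or any(len(v) == 0 for v in sweep.values()):
        raise ConfigurationError("sweep grid must name at least one non-empty parameter")
    names = list(sweep)
    rows = []
    for combo in itertools.product(*(sweep[k] for k in names)):
        point = cfg.replace(**dict(zip(names, combo)))
        states = classify_wear(rr, accel, point)
        summ = wear_summary(states, rr, point)
        report = quality_report(rr, point, window_mask=states.mask("worn_attached"))
        row = dict(zip(names, combo))
        row.update(
            wear_attached_h=summ.attached_hours,
            wear_detached_h=summ.wear_detached_s / 3600.0,
            n_wear_periods=summ.n_wear_periods,
            error_rate_per_min=summ.error_rate_per_min,
            prop_hr_coverage=report.prop_hr_coverage,
            prop_hrv_coverage=report.prop_hrv_coverage,
        )
        if night is not None:
            ns = night_summary(night, point)
            uc = ultradian_cycle(night, point)
            row.update(
                prop_above_autocorr=ns.prop_above_autocorr,
                mean_resp_rate_bpm=ns.mean_resp_rate_bpm,
                ultradian_period_min=uc.period_min,
            )
        rows.append(row)
    return pd.DataFrame(rows)
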