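"""Survival intervals, Kaplan-Meier estimation, log-rank, and the
contingency/rank tests used across an immuno-oncology cohort analysis.

Interval conventions (all times in months, month = 30.4375 days):

- PFS1: ICI monotherapy start -> radiologic progression (censor at last
  follow-up),
- OS1:  monotherapy start -> death from any cause (censor at last follow-up),
- PFS2: salvage-regimen start -> progression or death,
- OS2:  salvage-regimen start -> death (censor at last follow-up).

KM estimation and the log-rank test are delegated to lifelines; Fisher's
exact test, Wilcoxon-Mann-Whitney and response-rate summaries wrap scipy
with the study's conventions (two-sided p-values, conditional-MLE odds
ratio, half-away-from-zero percentage rounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

__all__ = [
    "DAYS_PER_MONTH",
    "SurvivalRecord",
    "IntervalDefinition",
    "KMEstimate",
    "LogrankResult",
    "FisherResult",
    "MannWhitneyResult",
    "RESPONSE_CATEGORIES",
    "build_intervals",
    "km_estimate",
    "logrank_test",
    "fisher_exact",
    "wilcoxon_mw",
    "round_percent",
    "summarize_responses",
]

DAYS_PER_MONTH = 30.4375  # 365.25 / 12


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    group: str
    time: float  # months
    event: bool  # True = death/progression observed; False = censored

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(
                f"negative survival time for subject {self.subject_id}"
            )


class IntervalDefinition(str, Enum):
    """The four interval conventions; value is (start anchor, event anchors)."""

    PFS1 = "PFS1"  # monotherapy start -> radiologic progression
    OS1 = "OS1"  # monotherapy start -> death
    PFS2 = "PFS2"  # salvage start -> progression or death
    OS2 = "OS2"  # salvage start -> death

    @property
    def start_column(self) -> str:
        return "mono_start" if self in (self.PFS1, self.OS1) else "salvage_start"

    @property
    def event_columns(self) -> tuple[str, ...]:
        return {
            IntervalDefinition.PFS1: ("progression_date",),
            IntervalDefinition.OS1: ("death_date",),
            IntervalDefinition.PFS2: ("progression_date", "death_date"),
            IntervalDefinition.OS2: ("death_date",),
        }[self]


def build_intervals(
    anchors: pd.DataFrame, definition: IntervalDefinition
) -> list[SurvivalRecord]:
    """Construct time-to-event records from a table of dated anchors.

    Expected columns: subject_id, group, the definition's start column,
    its event-date column(s) (NaT = did not occur) and last_followup.
    The earliest applicable event date defines the event; otherwise the
    record is censored at last follow-up. Times are days / 30.4375.
    """
    definition = IntervalDefinition(definition)
    start_col = definition.start_column
    needed = {"subject_id", "group", start_col, "last_followup"}
    missing = needed - set(anchors.columns)
    if missing:
        raise ValueError(f"anchor table is missing columns: {sorted(missing)}")

    records: list[SurvivalRecord] = []
    for row in anchors.itertuples(index=False):
        start = getattr(row, start_col)
        if pd.isna(start):
            continue  # subject never reached this interval's start anchor
        event_dates = [
            getattr(row, c)
            for c in definition.event_columns
            if c in anchors.columns and not pd.isna(getattr(row, c))
        ]
        if event_dates:
            stop, event = min(event_dates), True
        else:
            stop, event = row.last_followup, False
        if pd.isna(stop):
            raise ValueError(
                f"subject {row.subject_id}: no event date and no last_followup"
            )
        days = (pd.Timestamp(stop) - pd.Timestamp(start)).days
        if days < 0:
            raise ValueError(
                f"subject {row.subject_id}: stop precedes start for "
                f"{definition.value}"
            )
        records.append(
            SurvivalRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                time=days / DAYS_PER_MONTH,
                event=event,
            )
        )
    return records


@dataclass
class KMEstimate:
    survival_function: pd.DataFrame  # step function, index = time
    median: float | None  # None iff S never reaches 0.5 or no events
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int
    status: str  # "ok" or "median_undefined"


def _to_arrays(records: Iterable[SurvivalRecord]):
    recs = list(records)
    t = np.array([r.time for r in recs], dtype=float)
    e = np.array([r.event for r in recs], dtype=bool)
    g = np.array([r.group for r in recs])
    return t, e, g


def km_estimate(records: Iterable[SurvivalRecord]) -> KMEstimate:
    """Product-limit survival estimate with median and 95% CI.

    The median is the earliest time with S(t) <= 0.5; the CI comes from the
    log(-log) survival-function interval. With no events, or when S never
    drops to 0.5, the median is an explicit undefined status.
    """
    t, e, _ = _to_arrays(records)
    if len(t) == 0:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    n_events = int(e.sum())
    if n_events == 0 or not math.isfinite(kmf.median_survival_time_):
        return KMEstimate(
            survival_function=kmf.survival_function_,
            median=None,
            median_ci=(None, None),
            n=len(t),
            n_events=n_events,
            status="median_undefined",
        )
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMEstimate(
        survival_function=kmf.survival_function_,
        median=float(kmf.median_survival_time_),
        median_ci=(
            lo if math.isfinite(lo) else None,
            hi if math.isfinite(hi) else None,
        ),
        n=len(t),
        n_events=n_events,
        status="ok",
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int


def logrank_test(records: Iterable[SurvivalRecord]) -> LogrankResult:
    """Two-sided log-rank test across the record groups (chi-squared with
    groups-1 degrees of freedom)."""
    t, e, g = _to_arrays(records)
    groups = np.unique(g)
    if len(groups) < 2:
        raise ValueError("log-rank test requires at least two groups")
    if not e.any():
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=len(groups) - 1,
    )


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float  # conditional MLE


def fisher_exact(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test (point-probability method) with the
    conditional maximum-likelihood odds ratio."""
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer cells")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    or_ = _odds_ratio(arr, kind="conditional").statistic
    return FisherResult(p_value=float(p), odds_ratio=float(or_))


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str


def wilcoxon_mw(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact p for combined n <= 20 without ties; otherwise the normal
    approximation with tie correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u_statistic=float(res.statistic), p_value=float(res.pvalue), method=method
    )


RESPONSE_CATEGORIES = ("CR/PR", "SD", "PD")


def round_percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage with half-away-from-zero rounding (the convention used in
    clinical reporting; banker's rounding would print 12.5% of 24 as 12%)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    q = 10.0 ** decimals
    return math.floor(abs(pct) * q + 0.5) / q * (1 if pct >= 0 else -1)


def summarize_responses(
    responses: Mapping[str, str] | Sequence[str], decimals: int = 0
) -> pd.DataFrame:
    """Best-response counts and percentages plus the disease-control rate.

    ``responses`` maps patient -> category (or is a plain sequence of
    categories, one per patient) over CR/PR, SD, PD. Disease control is
    CR/PR + SD. Returns one row per category plus a ``disease_control``
    row, with columns n, total and percent.
    """
    cats = list(responses.values()) if isinstance(responses, Mapping) else list(responses)
    unknown = set(cats) - set(RESPONSE_CATEGORIES)
    if unknown:
        raise ValueError(
            f"unknown response categories: {sorted(unknown)}; "
            f"expected {RESPONSE_CATEGORIES}"
        )
    if not cats:
        raise ValueError("no responses supplied")
    total = len(cats)
    rows = []
    for cat in RESPONSE_CATEGORIES:
        n = cats.count(cat)
        rows.append((cat, n, total, round_percent(n, total, decimals)))
    n_dc = cats.count("CR/PR") + cats.count("SD")
    rows.append(("disease_control", n_dc, total, round_percent(n_dc, total, decimals)))
    return pd.DataFrame(rows, columns=["category", "n", "total", "percent"])
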