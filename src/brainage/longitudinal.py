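"""Longitudinal risk-factor summaries.

Quantitative covariates measured repeatedly over decades of follow-up are
collapsed to a time-weighted mean — each visit's value weighted by the time
elapsed since the preceding measurement — and categorical covariates to
ever-event flags over the follow-up window.  Cumulative severe-hypoglycemia
event counts are binned into the conventional 0 / 1–5 / >5 categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CovariatePanel
from .errors import BrainageError


@dataclass(frozen=True)
class VisitSeries:
    """One subject's ordered visit records for one covariate."""

    subject_id: str
    covariate: str
    times: tuple[float, ...]   # years since baseline, strictly increasing
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise BrainageError(f"empty visit series for {self.subject_id}/{self.covariate}")
        if len(self.times) != len(self.values):
            raise BrainageError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise BrainageError(
                f"visit times must be strictly increasing for {self.subject_id}/{self.covariate}")


def time_weighted_mean(series: VisitSeries, end_time: float | None = None,
                       *, carry_forward: bool = False) -> float:
    """Time-weighted mean: sum(w_i v_i) / sum(w_i), w_i = t_i - t_{i-1}, t_0 = 0.

    A visit at t=0 (the baseline measurement) receives zero weight unless it
    is the only visit, in which case its value is returned.  With
    ``carry_forward=True`` the last value additionally receives weight
    ``end_time - t_last`` (off by default: the weight rule counts only
    elapsed intervals between measurements).
    """
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    if end_time is None:
        end_time = float(t[-1])
    if end_time < t[-1]:
        raise BrainageError(f"end_time {end_time} precedes last visit at {t[-1]}")
    if len(t) == 1:
        return float(v[0])
    w = np.diff(np.concatenate([[0.0], t]))
    if carry_forward and end_time > t[-1]:
        w[-1] += end_time - t[-1]
    total = w.sum()
    if total <= 0:
        return float(v[-1])
    return float(np.dot(w, v) / total)


def ever_event(series: VisitSeries, end_time: float) -> bool:
    """True iff any report with a truthy value at time <= end_time."""
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    return bool(np.any((t <= end_time) & (v != 0)))


HYPO_CATEGORIES = ("0", "1-5", ">5")


def categorize_hypoglycemia(series: VisitSeries) -> str:
    """Bin the cumulative event count into '0', '1-5' or '>5'."""
    v = np.asarray(series.values, dtype=float)
    if np.any(v < 0):
        raise BrainageError("event counts must be non-negative")
    total = v.sum()
    if total == 0:
        return "0"
    return "1-5" if total <= 5 else ">5"


def extract_series(panel: CovariatePanel, subject_id: str, covariate: str) -> VisitSeries:
    """Pull one subject/covariate series from a panel's long-format visits."""
    sub = panel.visits[(panel.visits["subject_id"] == subject_id)
                       & (panel.visits["covariate"] == covariate)]
    sub = sub.sort_values("time")
    return VisitSeries(subject_id, covariate,
                       tuple(sub["time"].tolist()), tuple(sub["value"].tolist()))


def summarize_panel(panel: CovariatePanel, *, quantitative: list[str] | None = None,
                    events: list[str] | None = None,
                    count_events: list[str] | None = None,
                    end_time: float | None = None) -> pd.DataFrame:
    """Wide per-subject summary of all risk histories.

    Quantitative covariates become time-weighted means (column ``twm_<name>``),
    binary events become ever-event flags (``ever_<name>``), and count events
    become cumulative-category columns (``cat_<name>``).  Covariate lists
    default to everything present in the panel's visit records.
    """
    visits = panel.visits
    present = list(dict.fromkeys(visits["covariate"]))
    if quantitative is None:
        quantitative = [c for c in present
                        if c not in (events or []) and c not in (count_events or [])]
    events = events or []
    count_events = count_events or []
    out: dict[str, dict] = {}
    for (sid, cov), sub in visits.groupby(["subject_id", "covariate"], sort=False):
        sub = sub.sort_values("time")
        series = VisitSeries(sid, cov, tuple(sub["time"]), tuple(sub["value"]))
        rec = out.setdefault(sid, {})
        if cov in events:
            et = end_time if end_time is not None else series.times[-1]
            rec[f"ever_{cov}"] = float(ever_event(series, et))
        elif cov in count_events:
            rec[f"cat_{cov}"] = categorize_hypoglycemia(series)
        elif cov in quantitative:
            rec[f"twm_{cov}"] = time_weighted_mean(series, end_time)
    summary = pd.DataFrame.from_dict(out, orient="index")
    summary.index.name = "subject_id"
    return summary.reindex(panel.subjects.intersection(summary.index))
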