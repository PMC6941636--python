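"""Kaplan–Meier disease-free survival and cohort frequency tables.

Disease-free survival (DFS) is the time from surgery to the first recurrence
of either type (local or metastatic), censored at last follow-up.  The
product-limit estimator uses the standard conventions: events precede
censorings at tied times, the Greenwood formula supplies pointwise standard
errors, and the median is the smallest time t with S(t) <= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .io_formats import RECURRENT_TYPES, CovariateSchema, EventHistory


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit curve with Greenwood standard errors.

    ``event_times`` are the distinct times with at least one event;
    ``survival[i] = S(event_times[i])`` (right-continuous step values),
    ``greenwood_se[i]`` the Greenwood SE at that time; ``n_risk``/``n_event``
    the risk-set size and event count at each time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "n_risk": self.n_risk,
            "n_event": self.n_event, "survival": self.survival,
            "se": self.greenwood_se,
        })


@dataclass(frozen=True)
class FrequencyTable:
    """Per-category counts and half-up one-decimal percentages."""

    rows: pd.DataFrame  # variable, level, count, percent
    total_n: int

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()


def percent_half_up(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total rounded half-up (not banker's) to ``decimals`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    return float(val)


def disease_free_times(history: EventHistory) -> pd.DataFrame:
    """Per-subject (time, status): first recurrence of either type, else censoring.

    ``status = 1`` with ``time`` the earliest recurrence (local or metastatic)
    when the subject had any; otherwise ``status = 0`` with ``time`` the last
    follow-up stop over all of the subject's records.
    """
    out = []
    ev = history.events
    grouped = dict(tuple(ev.groupby("subject_id")))
    for subject in history.subjects:
        grp = grouped.get(subject)
        if grp is None or grp.empty:
            raise ValueError(f"subject {subject!r} has no event records")
        rec = grp[grp["event_type"].isin(RECURRENT_TYPES) & (grp["status"] == 1)]
        if len(rec):
            out.append({"subject_id": subject, "time": float(rec["stop"].min()),
                        "status": 1})
        else:
            out.append({"subject_id": subject, "time": float(grp["stop"].max()),
                        "status": 0})
    return pd.DataFrame(out)


def kaplan_meier(times, status) -> KMEstimate:
    """Product-limit estimator with Greenwood variance.

    At a tied time, events are counted before censorings leave the risk set
    (the standard convention).  ``greenwood_se(t) =
    S(t) sqrt(sum_{t_j <= t} d_j / (n_j (n_j - d_j)))``, taken as 0 where
    ``S = 1`` and where the risk set is exhausted by events.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    n = times.size

    order = np.lexsort((1 - status, times))  # events before censorings at ties
    times_s, status_s = times[order], status[order]
    event_times = np.unique(times_s[status_s == 1])

    n_risk = np.empty(event_times.size, dtype=int)
    n_event = np.empty(event_times.size, dtype=int)
    for i, t in enumerate(event_times):
        n_risk[i] = int(np.sum(times_s >= t))
        n_event[i] = int(np.sum((times_s == t) & (status_s == 1)))

    frac = 1.0 - n_event / n_risk
    survival = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_event / (n_risk * (n_risk - n_event))
    terms = np.where(n_risk == n_event, 0.0, terms)  # S hits 0; variance term 0 by convention
    gw = survival * np.sqrt(np.cumsum(terms))
    gw = np.where(survival == 1.0, 0.0, gw)
    return KMEstimate(event_times=event_times, survival=survival,
                      greenwood_se=gw, n_risk=n_risk, n_event=n_event,
                      n_subjects=n)


def km_from_history(history: EventHistory) -> KMEstimate:
    """Disease-free-survival KM curve straight from an event history."""
    dfs = disease_free_times(history)
    return kaplan_meier(dfs["time"], dfs["status"])


def survival_at(km: KMEstimate, t: float) -> tuple[float, float]:
    """Right-continuous step-function lookup of (S(t), Greenwood SE)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(km.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0, 0.0
    return float(km.survival[idx]), float(km.greenwood_se[idx])


def median_survival(km: KMEstimate) -> float | None:
    """Smallest event time with S(t) <= 0.5; ``None`` if never reached."""
    below = km.survival <= 0.5
    if not below.any():
        return None
    return float(km.event_times[np.argmax(below)])


def frequency_table(covariates: pd.DataFrame, schema: CovariateSchema,
                    variables: list[str] | None = None) -> FrequencyTable:
    """Counts and percentages per declared category, in declared order.

    Percentages are 100*count/n rounded half-up to one decimal, the rounding
    that reproduces standard printed cohort tables from their counts.
    """
    if variables is None:
        variables = [c.name for c in schema.covariates if c.is_categorical]
    total_n = len(covariates)
    rows = []
    for name in variables:
        try:
            cov = schema[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None
        if not cov.is_categorical:
            raise ValueError(f"variable {name!r} is numeric; frequency table "
                             "requires categorical variables")
        values = covariates[name]
        for level in cov.levels:
            count = int((values == level).sum())
            rows.append({"variable": name, "level": level, "count": count,
                         "percent": percent_half_up(count, total_n)})
    return FrequencyTable(rows=pd.DataFrame(rows), total_n=total_n)


def frequency_table_from_counts(counts: dict[str, dict[str, int]],
                                total_n: int) -> FrequencyTable:
    """Frequency table computed from pre-tabulated counts (e.g. a printed table)."""
    rows = []
    for variable, level_counts in counts.items():
        for level, count in level_counts.items():
            rows.append({"variable": variable, "level": level, "count": int(count),
                         "percent": percent_half_up(int(count), total_n)})
    return FrequencyTable(rows=pd.DataFrame(rows), total_n=total_n)
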