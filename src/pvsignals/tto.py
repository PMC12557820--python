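"""Time-to-onset (TTO) analysis of adverse-event reports.

TTO is the number of whole days from the start of therapy with the suspect
drug to the onset of the adverse event.  Spontaneous reports carry onset
data only sporadically; reports lacking either date at day precision are
excluded with an explicit reason, never imputed.  Included onsets feed a
tabulation over the conventional bins, a Kaplan–Meier cumulative-incidence
estimate, and log-rank comparisons across subgroups.  Because spontaneous
reports have no follow-up, every included record is an event (no censoring)
in the default analysis path; the estimator still accepts censoring flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2 as chi2_dist

from .core import (ReportRecord, ReportSet, date_sort_key, normalize_name,
                   parse_faers_date)

__all__ = ["TTOResult", "KMCurve", "compute_tto", "compute_tto_table",
           "bin_tto", "km_estimate", "logrank_test", "TTO_BINS"]

#: Inclusive day bins of the descriptive tabulation; same-day onset (day 0)
#: falls in the first bin.
TTO_BINS = ((0, 30), (31, 60), (61, 90), (91, 120), (121, 150), (151, 180),
            (181, 360), (361, None))

EXCLUSION_REASONS = ("missing_start", "missing_event", "partial_date",
                     "negative")


@dataclass(frozen=True)
class TTOResult:
    """Either a TTO in days or an exclusion with its reason."""

    days: int | None
    reason: str | None = None

    @property
    def included(self) -> bool:
        return self.days is not None


def compute_tto(report: ReportRecord, target_synonyms=None) -> TTOResult:
    """TTO of one report, or an exclusion reason.

    The anchor is the earliest day-precision therapy start among the
    report's primary-suspect entries (restricted to ``target_synonyms``
    when given).  Exclusion reasons: ``missing_start`` (no PS start date at
    all), ``missing_event`` (no event date), ``partial_date`` (dates exist
    but none at day precision), ``negative`` (event precedes start).
    """
    syn = ({normalize_name(s) for s in target_synonyms}
           if target_synonyms else None)
    starts = [d.start_dt for d in report.drugs
              if d.role == "PS" and d.start_dt
              and (syn is None or d.name in syn)]
    if not starts:
        return TTOResult(None, "missing_start")
    full_starts = [s for s in starts if parse_faers_date(s)[1] == "day"]
    if not full_starts:
        return TTOResult(None, "partial_date")
    if not report.event_dt:
        return TTOResult(None, "missing_event")
    event, prec = parse_faers_date(report.event_dt)
    if prec != "day":
        return TTOResult(None, "partial_date")
    start = min(parse_faers_date(s)[0] for s in full_starts)
    delta = (event - start).days
    if delta < 0:
        return TTOResult(None, "negative")
    return TTOResult(int(delta))


def compute_tto_table(records: ReportSet, target_synonyms=None
                      ) -> pd.DataFrame:
    """Vectorised TTO for every report: columns primaryid, days, reason."""
    syn = ({normalize_name(s) for s in target_synonyms}
           if target_synonyms else None)
    d = records.drugs
    ps = d[d["role_cod"] == "PS"]
    if syn is not None:
        ps = ps[ps["drugname"].isin(syn)]
    ps = ps[ps["start_dt"].astype(str).str.strip() != ""]
    ps = ps.assign(
        _prec=[parse_faers_date(s)[1] for s in ps["start_dt"]],
        _key=ps["start_dt"].map(date_sort_key),
    )
    full = ps[ps["_prec"] == "day"]
    earliest = full.groupby("primaryid")["_key"].min()
    any_start = set(ps["primaryid"])

    rows = []
    for r in records.demo.itertuples(index=False):
        pid = r.primaryid
        if pid not in any_start:
            rows.append((pid, None, "missing_start"))
            continue
        if pid not in earliest.index:
            rows.append((pid, None, "partial_date"))
            continue
        ev = str(getattr(r, "event_dt", "")).strip()
        if not ev:
            rows.append((pid, None, "missing_event"))
            continue
        ev_date, prec = parse_faers_date(ev)
        if prec != "day":
            rows.append((pid, None, "partial_date"))
            continue
        k = int(earliest.loc[pid])
        start_date = pd.Timestamp(year=k // 10000, month=k // 100 % 100,
                                  day=k % 100).date()
        delta = (ev_date - start_date).days
        if delta < 0:
            rows.append((pid, None, "negative"))
        else:
            rows.append((pid, int(delta), None))
    return pd.DataFrame(rows, columns=["primaryid", "days", "reason"])


def bin_tto(values) -> pd.DataFrame:
    """Tabulate TTO days over the conventional bins.

    Bins are closed on both printed endpoints; percentages are of the
    non-missing total, rounded to one decimal.
    """
    v = np.asarray(list(values), dtype=float)
    if np.any(v < 0):
        raise ValueError("TTO values must be non-negative")
    rows = []
    total = len(v)
    for lo, hi in TTO_BINS:
        if hi is None:
            count = int(np.sum(v >= lo))
            label = f">{lo - 1}"
        else:
            count = int(np.sum((v >= lo) & (v <= hi)))
            label = f"{lo}-{hi}"
        pct = round(100.0 * count / total, 1) if total else 0.0
        rows.append({"bin": label, "count": count, "pct": pct})
    return pd.DataFrame(rows)


@dataclass
class KMCurve:
    """A Kaplan–Meier product-limit curve with onset summary quantiles."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) at each event time, non-increasing from 1
    median: float
    q1: float
    q3: float

    @property
    def cumulative_incidence(self) -> np.ndarray:
        return 1.0 - self.survival


def km_estimate(times, events=None) -> KMCurve:
    """Product-limit estimator ``S(t) = Π (1 − dᵢ/nᵢ)`` over event times.

    With no censoring this equals ``1 − ECDF``.  The onset median and IQR
    are computed on the raw observed event times with linear-interpolation
    quantiles.  Raises on empty input.
    """
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("Kaplan-Meier estimate needs at least one subject")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    e = (np.ones_like(t, dtype=bool) if events is None
         else np.asarray(list(events), dtype=bool))
    if e.shape != t.shape:
        raise ValueError("times and event flags must have equal length")

    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for ti in event_times:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & e))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        n_ev.append(d_i)
        surv.append(s)
    obs = t[e]
    if obs.size:
        q1, med, q3 = np.percentile(obs, [25, 50, 75])
    else:
        q1 = med = q3 = float("nan")
    return KMCurve(times=event_times, at_risk=np.array(at_risk),
                   n_events=np.array(n_ev), survival=np.array(surv),
                   median=float(med), q1=float(q1), q3=float(q3))


def logrank_test(groups: dict) -> tuple[float, float, int]:
    """Log-rank comparison of ≥2 labelled (times, events) samples.

    Standard observed-minus-expected χ² over shared event times with
    ``len(groups) − 1`` degrees of freedom; the two-sided p comes from the
    χ² distribution.  ``groups`` maps a label to ``(times, event_flags)``
    (flags optional — default all events).  Raises on an empty group.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    all_t, all_e, all_g = [], [], []
    for label, sample in groups.items():
        if isinstance(sample, tuple) and len(sample) == 2:
            t, e = sample
        else:
            t, e = sample, None
        t = np.asarray(list(t), dtype=float)
        if t.size == 0:
            raise ValueError(f"group {label!r} has zero subjects")
        e = (np.ones_like(t, dtype=int) if e is None
             else np.asarray(list(e), dtype=int))
        all_t.append(t)
        all_e.append(e)
        all_g.append(np.full(t.size, str(label), dtype=object))
    t = np.concatenate(all_t)
    e = np.concatenate(all_e)
    g = np.concatenate(all_g)
    res = multivariate_logrank_test(t, g, e)
    stat = float(res.test_statistic)
    df = len(groups) - 1
    p = float(chi2_dist.sf(stat, df))
    return stat, p, df
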