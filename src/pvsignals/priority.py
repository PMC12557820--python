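"""Semi-quantitative clinical prioritisation of detected signals.

Every adverse event positive in at least one disproportionality algorithm is
scored 0–2 on four criteria and banded by the total:

* **clinical relevance** — designated medical event (DME) → 2, important
  medical event (IME) → 1, neither → 0;
* **reporting rate** — cases per non-case among the drug's events:
  very common (≥10%) → 2, common (1–10%) → 1, uncommon (≤1%) → 0;
* **signal stability** — positive in all four algorithms → 2, in 2–3 → 1,
  in ≤1 → 0;
* **case fatality** — death outcomes per report of the term: >50% → 2
  (the top score is deliberately conservative), 10–50% → 1, <10% → 0.

Totals 0–2, 3–5 and 6–8 map to low, moderate and high clinical priority.
Every point value and cut-off is overridable through :class:`PriorityRubric`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import ReportSet, normalize_pt

__all__ = ["DesignationLists", "PriorityRubric", "PriorityAssessment",
           "reporting_rate", "case_fatality_rate", "priority_score",
           "prioritize"]

RATE_CATEGORIES = ("uncommon", "common", "very_common")
BANDS = ("low", "moderate", "high")


@dataclass(frozen=True)
class DesignationLists:
    """EMA-style IME/DME term lists (user-supplied; lookup case-insensitive).

    A term on both lists classifies as DME — the rarer, stronger
    designation.
    """

    ime_terms: frozenset
    dme_terms: frozenset

    @classmethod
    def from_files(cls, ime_path, dme_path) -> "DesignationLists":
        def _read(p):
            terms = set()
            for line in Path(p).read_text().splitlines():
                line = line.split("#", 1)[0].strip()
                if line:
                    terms.add(normalize_pt(line))
            return frozenset(terms)

        return cls(ime_terms=_read(ime_path), dme_terms=_read(dme_path))

    @classmethod
    def from_terms(cls, ime, dme) -> "DesignationLists":
        return cls(ime_terms=frozenset(normalize_pt(t) for t in ime),
                   dme_terms=frozenset(normalize_pt(t) for t in dme))

    def classify(self, pt: str) -> str:
        key = normalize_pt(pt)
        if key in self.dme_terms:
            return "DME"
        if key in self.ime_terms:
            return "IME"
        return "none"


@dataclass(frozen=True)
class PriorityRubric:
    """Point map of the four criteria plus the band cut-points."""

    relevance_points: dict = field(
        default_factory=lambda: {"DME": 2, "IME": 1, "none": 0})
    rate_points: dict = field(
        default_factory=lambda: {"very_common": 2, "common": 1, "uncommon": 0})
    stability_points: tuple = (0, 0, 1, 1, 2)  # indexed by n positive (0–4)
    fatality_top_threshold: float = 50.0  # % above which the top score applies
    fatality_mid_threshold: float = 10.0
    fatality_points: tuple = (0, 1, 2)
    low_max: int = 2
    moderate_max: int = 5

    def band(self, total: int) -> str:
        if total <= self.low_max:
            return "low"
        if total <= self.moderate_max:
            return "moderate"
        return "high"


DEFAULT_RUBRIC = PriorityRubric()


@dataclass
class PriorityAssessment:
    """The four rubric components, total score, and band for one term."""

    term: str
    n: int
    reporting_rate: float
    rate_category: str
    cfr: float
    n_pos_algorithms: int
    relevance: str
    relevance_score: int
    rate_score: int
    stability_score: int
    fatality_score: int
    total: int
    band: str


def reporting_rate(n: int, total_events: int) -> tuple[float, str]:
    """Cases-to-non-cases reporting rate (%) and its frequency category.

    The denominator is the drug's *other* adverse events, ``total_events −
    n``, so the rate is the ratio of cases to non-cases.  Categories follow
    the conventional trial labels: very common (≥10%), common (1–10%),
    uncommon (≤1%).
    """
    if not (0 <= n <= total_events):
        raise ValueError("need 0 <= n <= total_events")
    if n == total_events:
        raise ValueError("reporting rate undefined when the term accounts "
                         "for every event (zero non-cases)")
    rate = 100.0 * n / (total_events - n)
    if rate >= 10.0:
        cat = "very_common"
    elif rate > 1.0:
        cat = "common"
    else:
        cat = "uncommon"
    return rate, cat


def case_fatality_rate(deaths: int, n: int) -> float:
    """Death outcomes per report of the term, as a percentage."""
    if n <= 0:
        raise ValueError("case fatality rate undefined for zero reports")
    if not (0 <= deaths <= n):
        raise ValueError("need 0 <= deaths <= n")
    return 100.0 * deaths / n


def priority_score(relevance: str, rate_category: str, n_pos_algorithms: int,
                   cfr_pct: float,
                   rubric: PriorityRubric = DEFAULT_RUBRIC
                   ) -> tuple[tuple[int, int, int, int], int, str]:
    """Score the four criteria and band the total.

    Returns ``((relevance, rate, stability, fatality) points, total, band)``.
    Raises on a missing or unrecognised input, naming the criterion.
    """
    if relevance not in rubric.relevance_points:
        raise ValueError(f"clinical relevance must be one of "
                         f"{sorted(rubric.relevance_points)}, got {relevance!r}")
    if rate_category not in rubric.rate_points:
        raise ValueError(f"reporting-rate category must be one of "
                         f"{sorted(rubric.rate_points)}, got {rate_category!r}")
    if not (0 <= n_pos_algorithms <= 4):
        raise ValueError("signal stability: positive-algorithm count must "
                         "lie in 0–4")
    if cfr_pct is None or cfr_pct < 0:
        raise ValueError("case fatality rate missing or negative")
    rel = rubric.relevance_points[relevance]
    rate = rubric.rate_points[rate_category]
    stab = rubric.stability_points[n_pos_algorithms]
    if cfr_pct > rubric.fatality_top_threshold:
        fat = rubric.fatality_points[2]
    elif cfr_pct >= rubric.fatality_mid_threshold:
        fat = rubric.fatality_points[1]
    else:
        fat = rubric.fatality_points[0]
    total = rel + rate + stab + fat
    return (rel, rate, stab, fat), total, rubric.band(total)


def _death_counts(records: ReportSet) -> pd.Series:
    """Per-PT count of reports carrying the term with a death (DE) outcome."""
    dead = set(records.outcomes.loc[records.outcomes["outc_cod"] == "DE",
                                    "primaryid"])
    pairs = records.pair_table()
    return pairs[pairs["primaryid"].isin(dead)].groupby("pt").size()


def prioritize(signal_df: pd.DataFrame, records: ReportSet,
               designations: DesignationLists,
               rubric: PriorityRubric = DEFAULT_RUBRIC) -> pd.DataFrame:
    """Assess every term positive in at least one algorithm.

    ``signal_df`` is the PT-level output of
    :func:`pvsignals.signals.compute_signal_table` for the target drug;
    ``records`` must be the same PS-filtered report set (it supplies the
    total event count and per-term death counts).  Terms positive in no
    algorithm are skipped.  Returns one row per assessed term with the
    component scores, total and band.
    """
    total_events = records.n_events
    deaths = _death_counts(records)
    rows = []
    for r in signal_df.itertuples(index=False):
        if r.n_positive < 1:
            continue
        n = int(r.a)
        rate, cat = reporting_rate(n, total_events)
        n_dead = int(deaths.get(r.term, 0))
        cfr = case_fatality_rate(n_dead, n) if n > 0 else 0.0
        relevance = designations.classify(r.term)
        comps, total, band = priority_score(relevance, cat,
                                            int(r.n_positive), cfr, rubric)
        rows.append({
            "term": r.term, "n": n, "reporting_rate": round(rate, 2),
            "rate_category": cat, "cfr": round(cfr, 2),
            "n_pos_algorithms": int(r.n_positive), "relevance": relevance,
            "relevance_score": comps[0], "rate_score": comps[1],
            "stability_score": comps[2], "fatality_score": comps[3],
            "total": total, "band": band,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = (out.sort_values(["total", "n"], ascending=[False, False])
               .reset_index(drop=True))
    return out
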