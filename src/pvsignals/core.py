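"""Shared containers and normalisation helpers for spontaneous-report data.

Spontaneous reporting systems such as FAERS distribute each quarter as a set
of '$'-delimited ASCII tables keyed by ``primaryid`` (a report version) and
``caseid`` (a case; one case may have several report versions).  The in-memory
representation used throughout this package is :class:`ReportSet`, a thin
wrapper around pandas DataFrames mirroring those tables, which keeps every
operation vectorised.  :class:`ReportRecord` offers a per-report object view
for code that works one report at a time.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from typing import Iterator

import pandas as pd

ROLE_CODES = ("PS", "SS", "C", "I")
#: FAERS outcome codes: hospitalisation, death, life-threatening, disability,
#: required intervention, other serious.
OUTCOME_CODES = ("HO", "DE", "LT", "DS", "RI", "OT")

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Normalise a free-text drug or term name for matching.

    Uppercases, trims, and collapses internal whitespace.  FAERS drug names
    are free text ("Tavneos", "AVACOPAN  30MG"), so verbatim comparison is
    useless without this.
    """
    return _WS.sub(" ", str(name).strip()).upper()


def normalize_pt(term: str) -> str:
    """Normalise a MedDRA preferred-term string (same rule as drug names)."""
    return normalize_name(term)


def parse_faers_date(value) -> tuple[_dt.date | None, str | None]:
    """Parse a FAERS date string (YYYYMMDD, YYYYMM or YYYY).

    Returns ``(date, precision)`` where precision is one of ``"day"``,
    ``"month"``, ``"year"``; unparseable or empty input yields
    ``(None, None)``.  Partial dates are anchored at the first day of the
    period for display purposes only — day-level arithmetic must check the
    precision flag and treat anything below ``"day"`` as unknown.
    """
    s = str(value).strip() if value is not None else ""
    if not s or not s.isdigit():
        return None, None
    try:
        if len(s) == 8:
            return _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), "day"
        if len(s) == 6:
            return _dt.date(int(s[:4]), int(s[4:6]), 1), "month"
        if len(s) == 4:
            return _dt.date(int(s), 1, 1), "year"
    except ValueError:
        return None, None
    return None, None


def date_sort_key(value) -> int:
    """Sortable integer key for a FAERS date; unparseable dates sort earliest.

    Partial dates are padded (YYYY → YYYY0101, YYYYMM → YYYYMM01) so they
    remain comparable with full dates.
    """
    s = str(value).strip() if value is not None else ""
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return -1
    d, _ = parse_faers_date(s)
    if d is None:
        return -1
    return d.year * 10000 + d.month * 100 + d.day


def primaryid_sort_key(value) -> tuple[int, object]:
    """Tie-break key for primaryids: numeric when possible, else lexicographic.

    FAERS primaryids are numeric strings of varying length; comparing them as
    text would rank "998" above "1002".  Non-numeric ids sort after numeric
    ones, among themselves lexicographically.
    """
    s = str(value).strip()
    if s.isdigit():
        return (0, int(s))
    return (1, s)


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report: normalised name, role code, therapy start."""

    name: str
    role: str
    start_dt: str | None = None

    def __post_init__(self):
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown drug role code {self.role!r}")


@dataclass
class ReportRecord:
    """One safety report (object view of a :class:`ReportSet` row group)."""

    primaryid: str
    caseid: str
    fda_dt: str | None
    event_dt: str | None
    age: float | None
    sex: str  # "female" | "male" | "unknown"
    weight_kg: float | None
    country: str
    reporter: str
    outcomes: frozenset
    drugs: tuple
    reactions: frozenset  # normalised PT strings
    reaction_socs: dict = field(default_factory=dict)  # PT -> SOC (if mapped)

    @property
    def therapy_start(self) -> str | None:
        """Earliest day-precision start date among primary-suspect drugs."""
        keys = [
            date_sort_key(d.start_dt)
            for d in self.drugs
            if d.role == "PS"
            and d.start_dt
            and parse_faers_date(d.start_dt)[1] == "day"
        ]
        if not keys:
            return None
        return str(min(keys))


_EMPTY_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "sex", "wt",
             "occr_country", "occp_cod"],
    "drugs": ["primaryid", "drugname", "role_cod", "start_dt"],
    "reactions": ["primaryid", "pt"],
    "outcomes": ["primaryid", "outc_cod"],
    "indications": ["primaryid", "indi_pt"],
}


def _empty(table: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in _EMPTY_COLUMNS[table]})


@dataclass
class ReportSet:
    """A collection of safety reports as joined, normalised DataFrames.

    ``demo`` has one row per report (primaryid unique after deduplication);
    ``drugs``, ``reactions``, ``outcomes`` and ``indications`` are child
    tables keyed by primaryid.  ``reactions`` is distinct on
    ``(primaryid, pt)`` — the counting unit of every downstream statistic is
    the (report, distinct PT) pair, so one report can contribute several
    adverse events but the same PT at most once.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    indications: pd.DataFrame

    @classmethod
    def empty(cls) -> "ReportSet":
        return cls(*(_empty(t) for t in _EMPTY_COLUMNS))

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    @property
    def n_events(self) -> int:
        """Number of (report, distinct PT) pairs."""
        return len(self.reactions)

    def subset(self, primaryids) -> "ReportSet":
        """Restrict every table to the given primaryids (order of demo kept)."""
        keep = set(primaryids)

        def _f(df: pd.DataFrame) -> pd.DataFrame:
            return df[df["primaryid"].isin(keep)].reset_index(drop=True)

        return ReportSet(_f(self.demo), _f(self.drugs), _f(self.reactions),
                         _f(self.outcomes), _f(self.indications))

    def copy(self) -> "ReportSet":
        return ReportSet(self.demo.copy(), self.drugs.copy(),
                         self.reactions.copy(), self.outcomes.copy(),
                         self.indications.copy())

    def pair_table(self) -> pd.DataFrame:
        """The distinct (primaryid, pt[, soc]) event pairs."""
        return self.reactions.copy()

    def records(self) -> Iterator[ReportRecord]:
        """Iterate reports as :class:`ReportRecord` objects (small data only)."""
        drugs_by = {k: v for k, v in self.drugs.groupby("primaryid")}
        reac_by = {k: v for k, v in self.reactions.groupby("primaryid")}
        outc_by = {k: v for k, v in self.outcomes.groupby("primaryid")}
        for row in self.demo.itertuples(index=False):
            pid = row.primaryid
            d = drugs_by.get(pid)
            drugs = tuple(
                DrugEntry(r.drugname, r.role_cod,
                          r.start_dt if getattr(r, "start_dt", "") else None)
                for r in (d.itertuples(index=False) if d is not None else ())
            )
            r = reac_by.get(pid)
            pts = frozenset(r["pt"]) if r is not None else frozenset()
            socs = {}
            if r is not None and "soc" in r.columns:
                socs = dict(zip(r["pt"], r["soc"]))
            o = outc_by.get(pid)
            outcomes = frozenset(o["outc_cod"]) if o is not None else frozenset()
            age = getattr(row, "age", "")
            try:
                age_v = float(age) if str(age).strip() else None
            except (TypeError, ValueError):
                age_v = None
            wt = getattr(row, "wt", "")
            try:
                wt_v = float(wt) if str(wt).strip() else None
            except (TypeError, ValueError):
                wt_v = None
            sex_raw = str(getattr(row, "sex", "")).strip().upper()
            sex = {"F": "female", "M": "male"}.get(sex_raw, "unknown")
            yield ReportRecord(
                primaryid=str(pid),
                caseid=str(row.caseid),
                fda_dt=str(row.fda_dt) if str(row.fda_dt).strip() else None,
                event_dt=(str(row.event_dt)
                          if str(getattr(row, "event_dt", "")).strip() else None),
                age=age_v,
                sex=sex,
                weight_kg=wt_v,
                country=str(getattr(row, "occr_country", "")),
                reporter=str(getattr(row, "occp_cod", "")),
                outcomes=outcomes,
                drugs=drugs,
                reactions=pts,
                reaction_socs=socs,
            )


def record_subset(rs: ReportSet, primaryid: str) -> ReportRecord:
    """Fetch a single report as a :class:`ReportRecord`."""
    sub = rs.subset([primaryid])
    for rec in sub.records():
        return rec
    raise KeyError(f"primaryid {primaryid!r} not found")
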