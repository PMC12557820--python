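"""Parsing, deduplication and filtering of FAERS-style quarterly tables.

The deduplication follows the regulator-recommended two-round rule: among
reports sharing a ``caseid``, keep the one with the most recent ``fda_dt``;
on a date tie, keep the larger ``primaryid`` (compared numerically when both
parse as integers).  A second pass removes residual duplicate primaryids.
Downstream analyses are restricted to reports naming the target drug as
primary suspect (PS), and reactions are annotated with their primary System
Organ Class through a user-supplied PT→SOC map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (ReportSet, date_sort_key, normalize_name, normalize_pt,
                   primaryid_sort_key)
from .synthetic import RawBundle

__all__ = ["ParseError", "MeddraMap", "parse_quarter_files", "bundle_to_reports",
           "deduplicate", "filter_primary_suspect", "map_pt_to_soc",
           "load_synonyms"]

_TABLE_KEYS = ("demo", "drug", "reac", "outc", "ther", "indi")


class ParseError(ValueError):
    """A mandatory column or table is missing from an input file."""


def load_synonyms(path) -> list[str]:
    """Read a drug-name synonym list (one name per line, '#' comments)."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.append(normalize_name(line))
    return names


@dataclass(frozen=True)
class MeddraMap:
    """A PT → primary-SOC mapping (one SOC per preferred term).

    MedDRA itself is licensed and not redistributed; the user supplies the
    slice of the hierarchy covering the vocabulary in use as a two-column
    TSV (``pt``, ``soc``).  Lookup is case-insensitive on normalised terms.
    """

    pt_to_soc: dict

    def __post_init__(self):
        object.__setattr__(self, "pt_to_soc",
                           {normalize_pt(k): str(v).strip().upper()
                            for k, v in self.pt_to_soc.items()})

    @classmethod
    def from_tsv(cls, path) -> "MeddraMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lower(): c for c in df.columns}
        if "pt" not in cols or "soc" not in cols:
            raise ParseError(f"{path}: PT→SOC map needs 'pt' and 'soc' columns")
        return cls(dict(zip(df[cols["pt"]], df[cols["soc"]])))

    def get(self, pt: str):
        return self.pt_to_soc.get(normalize_pt(pt))


def _classify_file(path: Path) -> str | None:
    low = path.name.lower()
    for key in _TABLE_KEYS:
        if key in low:
            return key
    return None


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def parse_quarter_files(paths) -> ReportSet:
    """Parse one or more quarters of '$'-delimited tables into a ReportSet.

    ``paths`` may mix directories (scanned for files whose names contain
    demo/drug/reac/outc/ther/indi) and individual files.  DEMO must carry
    ``primaryid``, ``caseid`` and ``fda_dt``; child rows whose primaryid has
    no DEMO row are dropped with a warning.  Unknown or absent fields stay
    as the empty string — never silently coerced to a number.  The result is
    *pre-deduplication*: pass it through :func:`deduplicate`.
    """
    files: dict[str, list[Path]] = {k: [] for k in _TABLE_KEYS}
    for p in ([paths] if isinstance(paths, (str, Path)) else list(paths)):
        p = Path(p)
        candidates = sorted(p.iterdir()) if p.is_dir() else [p]
        for f in candidates:
            if not f.is_file():
                continue
            key = _classify_file(f)
            if key is not None:
                files[key].append(f)
    if not files["demo"]:
        raise ParseError("no DEMO table found in the given paths")

    frames: dict[str, pd.DataFrame] = {}
    for key, flist in files.items():
        if flist:
            frames[key] = pd.concat([_read_table(f) for f in flist],
                                    ignore_index=True)
        else:
            frames[key] = pd.DataFrame()

    demo = frames["demo"]
    for col in ("primaryid", "caseid", "fda_dt"):
        if col not in demo.columns:
            raise ParseError(
                f"{files['demo'][0]}: mandatory DEMO column {col!r} missing")
    for col in ("event_dt", "age", "age_cod", "sex", "wt", "occr_country",
                "occp_cod"):
        if col not in demo.columns:
            demo[col] = ""
    demo["primaryid"] = demo["primaryid"].astype(str).str.strip()
    demo["caseid"] = demo["caseid"].astype(str).str.strip()
    known = set(demo["primaryid"])

    def _children(key: str, required: tuple[str, ...]) -> pd.DataFrame:
        df = frames[key]
        if df.empty:
            return pd.DataFrame(columns=["primaryid", *required])
        if "primaryid" not in df.columns:
            raise ParseError(f"{files[key][0]}: column 'primaryid' missing")
        df["primaryid"] = df["primaryid"].astype(str).str.strip()
        orphan = ~df["primaryid"].isin(known)
        if orphan.any():
            warnings.warn(
                f"{key.upper()}: dropped {int(orphan.sum())} orphan rows "
                "whose primaryid has no DEMO entry", stacklevel=2)
            df = df[~orphan]
        for col in required:
            if col not in df.columns:
                df[col] = ""
        return df.reset_index(drop=True)

    drug = _children("drug", ("drug_seq", "role_cod", "drugname"))
    if len(drug):
        drug["drugname"] = drug["drugname"].map(normalize_name)
        drug["role_cod"] = drug["role_cod"].astype(str).str.strip().str.upper()

    ther = _children("ther", ("dsg_drug_seq", "start_dt"))
    if len(drug):
        if len(ther):
            merged = drug.merge(
                ther.rename(columns={"dsg_drug_seq": "drug_seq"})
                    [["primaryid", "drug_seq", "start_dt"]],
                on=["primaryid", "drug_seq"], how="left")
            merged["start_dt"] = merged["start_dt"].fillna("")
            drug = merged
        else:
            drug["start_dt"] = ""
    drugs = (drug[["primaryid", "drugname", "role_cod", "start_dt"]]
             if len(drug) else
             pd.DataFrame(columns=["primaryid", "drugname", "role_cod",
                                   "start_dt"]))

    reac = _children("reac", ("pt",))
    if len(reac):
        reac["pt"] = reac["pt"].map(normalize_pt)
        reac = reac[reac["pt"] != ""]
        reac = (reac[["primaryid", "pt"]]
                .drop_duplicates()  # a PT counts at most once per report
                .reset_index(drop=True))
    else:
        reac = pd.DataFrame(columns=["primaryid", "pt"])

    outc = _children("outc", ("outc_cod",))
    outc = (outc[["primaryid", "outc_cod"]].drop_duplicates()
            .reset_index(drop=True)
            if len(outc) else pd.DataFrame(columns=["primaryid", "outc_cod"]))
    if len(outc):
        outc["outc_cod"] = outc["outc_cod"].astype(str).str.strip().str.upper()

    indi = _children("indi", ("indi_pt",))
    indi = (indi[["primaryid", "indi_pt"]].reset_index(drop=True)
            if len(indi) else pd.DataFrame(columns=["primaryid", "indi_pt"]))

    return ReportSet(demo=demo.reset_index(drop=True), drugs=drugs,
                     reactions=reac, outcomes=outc, indications=indi)


def bundle_to_reports(bundle: RawBundle) -> ReportSet:
    """Convert a generator :class:`RawBundle` directly (no file round trip)."""
    demo = bundle.demo.copy()
    drug = bundle.drug.copy()
    if len(bundle.ther):
        drug = drug.merge(
            bundle.ther.rename(columns={"dsg_drug_seq": "drug_seq"})
            [["primaryid", "drug_seq", "start_dt"]],
            on=["primaryid", "drug_seq"], how="left")
        drug["start_dt"] = drug["start_dt"].fillna("")
    else:
        drug["start_dt"] = ""
    drugs = drug[["primaryid", "drugname", "role_cod", "start_dt"]]
    reac = (bundle.reac[["primaryid", "pt"]].drop_duplicates()
            .reset_index(drop=True))
    outc = bundle.outc[["primaryid", "outc_cod"]].reset_index(drop=True)
    indi = bundle.indi[["primaryid", "indi_pt"]].reset_index(drop=True)
    return ReportSet(demo=demo, drugs=drugs, reactions=reac, outcomes=outc,
                     indications=indi)


def deduplicate(records: ReportSet) -> ReportSet:
    """Two-round duplicate removal (idempotent).

    Round 1: one report per ``caseid`` — most recent ``fda_dt`` wins, ties
    broken by the larger primaryid (numeric comparison when both ids are
    numeric).  Unparseable dates sort earliest, so a dated report always
    beats an undated rival.  Round 2: residual duplicate primaryids are
    collapsed keeping the last row in (fda_dt, source order).
    """
    demo = records.demo
    if demo.empty:
        return records.copy()
    work = demo[["primaryid", "caseid", "fda_dt"]].copy()
    work["_order"] = np.arange(len(work))
    work["_datekey"] = work["fda_dt"].map(date_sort_key)
    work["_pidkey"] = work["primaryid"].map(primaryid_sort_key)
    # round 1: per caseid keep (max fda_dt, then max primaryid)
    work = work.sort_values(["_datekey", "_pidkey"],
                            kind="mergesort")  # stable: source order base
    round1 = work.groupby("caseid", sort=False).tail(1)
    # round 2: residual duplicate primaryids -> last in (fda_dt, source order)
    round2 = (round1.sort_values(["_datekey", "_order"], kind="mergesort")
              .drop_duplicates("primaryid", keep="last"))
    keep = round2.sort_values("_order")
    out_demo = demo.iloc[keep["_order"].to_numpy()].reset_index(drop=True)
    keep_ids = set(keep["primaryid"])

    def _f(df: pd.DataFrame) -> pd.DataFrame:
        # child tables are distinct on their keys, so filtering by the
        # surviving primaryids is exact even when a primaryid was duplicated
        return (df[df["primaryid"].isin(keep_ids)].drop_duplicates()
                .reset_index(drop=True))

    return ReportSet(out_demo, _f(records.drugs), _f(records.reactions),
                     _f(records.outcomes), _f(records.indications))


def filter_primary_suspect(records: ReportSet, drug_names) -> ReportSet:
    """Keep reports with >=1 primary-suspect entry matching the synonym list."""
    syn = {normalize_name(d) for d in drug_names}
    if not syn:
        raise ValueError("synonym list must be non-empty")
    d = records.drugs
    hit = d[(d["role_cod"] == "PS") & (d["drugname"].isin(syn))]
    return records.subset(hit["primaryid"].unique())


def map_pt_to_soc(records: ReportSet, mapping: MeddraMap,
                  policy: str = "strict") -> ReportSet:
    """Annotate every reaction with its primary SOC.

    ``policy="strict"`` raises listing any unmapped PTs; ``"lenient"``
    buckets them under ``"UNMAPPED"`` with a warning.  The SOC-level event
    count of a report is then the number of its distinct PTs mapping to that
    SOC (so SOC counts across a database sum to the total event count).
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown policy {policy!r}")
    out = records.copy()
    if out.reactions.empty:
        out.reactions["soc"] = pd.Series(dtype=object)
        return out
    soc = out.reactions["pt"].map(mapping.pt_to_soc)
    missing = soc.isna()
    if missing.any():
        terms = sorted(out.reactions.loc[missing, "pt"].unique())
        if policy == "strict":
            raise KeyError(f"unmapped preferred terms: {terms}")
        warnings.warn(f"{len(terms)} unmapped preferred terms bucketed as "
                      f"UNMAPPED: {terms[:10]}", stacklevel=2)
        soc = soc.fillna("UNMAPPED")
    out.reactions = out.reactions.assign(soc=soc)
    return out
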