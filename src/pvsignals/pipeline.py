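"""End-to-end orchestration: ingest → dedup → filter → signals → outputs.

The pipeline mirrors how a pharmacovigilance analysis of a single target
drug proceeds: parse the quarterly tables, deduplicate, restrict to
primary-suspect reports of the target, annotate SOCs, run the four
disproportionality algorithms at SOC and PT level, score clinical priority,
tabulate time-to-onset with Kaplan–Meier exports, and fit the hepatobiliary
case/non-case risk model.  Every stage logs its input/output record counts;
all outputs are TSV; a run manifest records the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from . import ingest, priority, risk, signals, tto
from .core import ReportSet

__all__ = ["PipelineConfig", "run_pipeline", "descriptive_table",
           "stratified_signal_tables", "default_data_path"]

log = logging.getLogger("pvsignals")


def default_data_path(name: str) -> Path:
    """Path of a bundled data file (synonym lists, toy designation lists)."""
    return Path(resources.files("pvsignals").joinpath("data", name))


@dataclass
class PipelineConfig:
    """Paths, target-drug synonyms and thresholds of one pipeline run."""

    quarter_dirs: list = field(default_factory=list)
    pt_soc_map: str | None = None         # TSV pt→soc; None = bundled toy map
    ime_list: str | None = None           # None = bundled synthetic stand-in
    dme_list: str | None = None
    target_synonyms: list = field(
        default_factory=lambda: ["AVACOPAN", "TAVNEOS"])
    hepatobiliary_soc: str = "HEPATOBILIARY DISORDERS"
    class_synonyms: dict | None = None    # None = packaged defaults
    criteria: signals.SignalCriteria = field(
        default_factory=signals.SignalCriteria)
    yates: bool = True
    zero_cell_correction: bool = False
    stratify: str | None = None           # None | "sex" | "age"
    seed: int = 0
    out_dir: str = "pvsignals_out"

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        crit = signals.SignalCriteria(**raw.pop("criteria", {}))
        kwargs = {k: v for k, v in raw.items()
                  if k in {f.name for f in dataclasses.fields(cls)}}
        kwargs["criteria"] = crit
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def descriptive_table(records: ReportSet, target_synonyms) -> pd.DataFrame:
    """Report-level descriptive tabulation (sex, age, outcomes, year, TTO).

    Percentages use the stated denominators: all reports for demographics
    and outcomes, non-missing onset records for the TTO bins.
    """
    n = records.n_reports
    rows = []

    def add(section, label, count, denom):
        pct = round(100.0 * count / denom, 1) if denom else 0.0
        rows.append({"section": section, "category": label,
                     "count": int(count), "pct": pct})

    sex = records.demo["sex"].astype(str).str.strip().str.upper()
    add("sex", "female", (sex == "F").sum(), n)
    add("sex", "male", (sex == "M").sum(), n)
    add("sex", "unknown", (~sex.isin(["F", "M"])).sum(), n)

    age = pd.to_numeric(records.demo["age"], errors="coerce")
    add("age", "<18", (age < 18).sum(), n)
    add("age", "18-65", ((age >= 18) & (age < 65)).sum(), n)
    add("age", "65-85", ((age >= 65) & (age < 85)).sum(), n)
    add("age", ">=85", (age >= 85).sum(), n)
    add("age", "unknown", age.isna().sum(), n)

    outc = records.outcomes
    by_code = outc.groupby("outc_cod")["primaryid"].nunique()
    for code in ("HO", "OT", "DE", "LT", "DS", "RI"):
        add("outcomes", code, int(by_code.get(code, 0)), n)
    add("outcomes", "unknown",
        n - records.demo["primaryid"].isin(set(outc["primaryid"])).sum(), n)

    year = records.demo["fda_dt"].astype(str).str.slice(0, 4)
    for y in sorted(year.unique()):
        add("year", y, (year == y).sum(), n)

    tt = tto.compute_tto_table(records, target_synonyms)
    included = tt["days"].dropna()
    bins = tto.bin_tto(included) if len(included) else None
    if bins is not None:
        for r in bins.itertuples(index=False):
            rows.append({"section": "tto_days", "category": r.bin,
                         "count": r.count, "pct": r.pct})
    return pd.DataFrame(rows)


_AGE_STRATA = (("<18", 0, 18), ("18-65", 18, 65), (">=65", 65, 200))


def stratified_signal_tables(records: ReportSet, target_synonyms,
                             by: str, level: str = "PT",
                             **kwargs) -> dict[str, pd.DataFrame]:
    """Rerun the disproportionality analysis within sex or age strata."""
    strata: dict[str, ReportSet] = {}
    if by == "sex":
        sex = records.demo["sex"].astype(str).str.strip().str.upper()
        for code, label in (("F", "female"), ("M", "male")):
            strata[label] = records.subset(
                records.demo.loc[sex == code, "primaryid"])
    elif by == "age":
        age = pd.to_numeric(records.demo["age"], errors="coerce")
        for label, lo, hi in _AGE_STRATA:
            mask = (age >= lo) & (age < hi)
            strata[label] = records.subset(
                records.demo.loc[mask, "primaryid"])
    else:
        raise ValueError("stratify must be 'sex' or 'age'")
    out = {}
    for label, sub in strata.items():
        if sub.n_reports == 0:
            continue
        out[label] = signals.compute_signal_table(
            sub, target_synonyms, level=level, **kwargs)
    return out


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name and cause."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the result tables under ``out_dir``.

    Returns the result bundle as a dict of DataFrames.  Any stage failure
    aborts with :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # ingest
    rs = stage("ingest", lambda: ingest.parse_quarter_files(
        config.quarter_dirs))
    log.info("ingest: %d raw reports, %d event pairs", rs.n_reports,
             rs.n_events)

    rs_d = stage("deduplicate", lambda: ingest.deduplicate(rs))
    log.info("deduplicate: %d -> %d reports", rs.n_reports, rs_d.n_reports)

    rs_ps = stage("ps_filter", lambda: ingest.filter_primary_suspect(
        rs_d, config.target_synonyms))
    log.info("ps_filter: %d target reports, %d adverse events",
             rs_ps.n_reports, rs_ps.n_events)

    map_path = (config.pt_soc_map if config.pt_soc_map
                else default_data_path("toy_pt_soc_map.tsv"))
    mmap = stage("soc_map", lambda: ingest.MeddraMap.from_tsv(map_path))
    rs_all = stage("soc_map", lambda: ingest.map_pt_to_soc(
        rs_d, mmap, policy="lenient"))
    rs_ps = stage("soc_map", lambda: ingest.map_pt_to_soc(
        rs_ps, mmap, policy="lenient"))

    results["descriptive"] = stage(
        "descriptive", lambda: descriptive_table(rs_ps,
                                                 config.target_synonyms))

    # disproportionality (hyperprior fitted once over the whole database)
    dec = stage("signals", lambda: signals.drug_event_cells(rs_all))
    hyper = stage("signals", lambda: signals.mgps_fit(
        dec["a"].to_numpy(), dec["E"].to_numpy()))
    kwargs = dict(priors=signals.BcpnnPriors(), criteria=config.criteria,
                  yates=config.yates,
                  zero_cell_correction=config.zero_cell_correction,
                  hyper=hyper)
    results["soc_signals"] = stage("signals", lambda: (
        signals.compute_signal_table(rs_all, config.target_synonyms,
                                     level="SOC", **kwargs)))
    results["pt_signals"] = stage("signals", lambda: (
        signals.compute_signal_table(rs_all, config.target_synonyms,
                                     level="PT", **kwargs)))
    log.info("signals: %d SOC terms, %d PT terms (%d all-four positive)",
             len(results["soc_signals"]), len(results["pt_signals"]),
             int(results["pt_signals"]["all_four_positive"].sum()))

    if config.stratify:
        strat = stage("signals", lambda: stratified_signal_tables(
            rs_all, config.target_synonyms, by=config.stratify, **kwargs))
        for label, df in strat.items():
            results[f"pt_signals_{config.stratify}_{label}"] = df

    # prioritisation
    ime = config.ime_list or default_data_path("ime_terms_synthetic.tsv")
    dme = config.dme_list or default_data_path("dme_terms_synthetic.tsv")
    desig = stage("prioritize", lambda: priority.DesignationLists.from_files(
        ime, dme))
    results["priority"] = stage("prioritize", lambda: priority.prioritize(
        results["pt_signals"], rs_ps, desig))
    log.info("prioritize: %d terms assessed", len(results["priority"]))

    # time-to-onset
    tt = stage("tto", lambda: tto.compute_tto_table(
        rs_ps, config.target_synonyms))
    included = tt.dropna(subset=["days"])
    log.info("tto: %d/%d reports with onset data", len(included),
             rs_ps.n_reports)
    results["tto_bins"] = stage("tto", lambda: tto.bin_tto(included["days"]))
    km_rows = []
    if len(included):
        curve = tto.km_estimate(included["days"])
        for t, s in zip(curve.times, curve.survival):
            km_rows.append({"group": "all", "days": t,
                            "cumulative_incidence": 1.0 - s})
    results["km_export"] = pd.DataFrame(km_rows)

    # risk factors
    def _risk():
        rows = risk.build_risk_rows(rs_ps, config.hepatobiliary_soc,
                                    class_synonyms=config.class_synonyms)
        uni = []
        for cls in ("rtx", "ctx", "ppi", "statin"):
            tab = pd.crosstab(rows[cls], rows["outcome"])
            try:
                ec = int(tab.loc[True, True])
                uc = int(tab.loc[False, True])
                eo = int(tab.loc[True, False])
                uo = int(tab.loc[False, False])
            except KeyError:
                uni.append({"exposure": cls, "or": None, "reason":
                            "empty margin"})
                continue
            orr, lo, hi, p, reason = risk.univariate_or(ec, uc, eo, uo)
            uni.append({"exposure": cls, "exposed_cases": ec,
                        "unexposed_cases": uc, "exposed_controls": eo,
                        "unexposed_controls": uo, "or": orr, "ci_low": lo,
                        "ci_high": hi, "p": p, "reason": reason})
        multi = None
        if rows["outcome"].any() and not rows["outcome"].all():
            try:
                fit = risk.fit_logistic(rows)
                multi = fit.summary_frame()
            except (risk.SeparationError, risk.RankDeficiencyError,
                    ValueError) as exc:
                log.warning("risk: multivariable fit skipped (%s)", exc)
        return pd.DataFrame(uni), multi

    uni_df, multi_df = stage("risk_models", _risk)
    results["risk_univariate"] = uni_df
    if multi_df is not None:
        results["risk_multivariable"] = multi_df

    # write everything
    for name, df in results.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "n_raw_reports": int(rs.n_reports),
        "n_dedup_reports": int(rs_d.n_reports),
        "n_target_reports": int(rs_ps.n_reports),
        "n_target_events": int(rs_ps.n_events),
        "tables": sorted(results),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return results
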