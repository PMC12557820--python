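"""Case/non-case risk-factor modelling for hepatobiliary adverse events.

Within the target drug's deduplicated reports, a *case* is any report with
at least one preferred term mapping to the hepatobiliary System Organ
Class; everything else is a non-case.  Exposures are binary drug-class
flags (rituximab, cyclophosphamide, proton-pump inhibitors, statins)
matched against synonym lists over the report's co-medication entries.
Unknown age or sex excludes a report (complete-case analysis).  Univariate
odds ratios come from 2×2 tables with Wald inference; the multivariable
model is a maximum-likelihood logistic regression (IRLS) with reference
levels age <45, female, unexposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import erf, exp, log, sqrt

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import ReportSet, normalize_name

__all__ = ["RiskRow", "LogisticFit", "SeparationError", "RankDeficiencyError",
           "exposure_flags", "build_risk_rows", "univariate_or",
           "fit_logistic", "AGE_BANDS"]

AGE_BANDS = ("<45", "45-65", "65-75", ">75")

#: Default drug-class synonym lists (editable files ship under data/).
DEFAULT_CLASS_SYNONYMS = {
    "rtx": ["RITUXIMAB", "RITUXAN", "MABTHERA", "TRUXIMA", "RUXIENCE"],
    "ctx": ["CYCLOPHOSPHAMIDE", "CYTOXAN", "ENDOXAN"],
    "ppi": ["OMEPRAZOLE", "PANTOPRAZOLE", "ESOMEPRAZOLE", "LANSOPRAZOLE",
            "RABEPRAZOLE", "DEXLANSOPRAZOLE"],
    "statin": ["ATORVASTATIN", "SIMVASTATIN", "ROSUVASTATIN", "PRAVASTATIN",
               "LOVASTATIN", "FLUVASTATIN", "PITAVASTATIN"],
}


class SeparationError(RuntimeError):
    """A coefficient diverged — the data separate the outcome on that term."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank-deficient after encoding."""


@dataclass(frozen=True)
class RiskRow:
    """One report's covariates for the case/non-case model."""

    primaryid: str
    outcome: bool
    age_band: str
    sex: str  # "female" | "male"
    rtx: bool = False
    ctx: bool = False
    ppi: bool = False
    statin: bool = False


@dataclass
class LogisticFit:
    """Coefficients, Wald inference and diagnostics of a logistic model."""

    terms: list
    coef: np.ndarray
    se: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    loglik: float
    iterations: int
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "coef": self.coef, "se": self.se,
            "or": np.round(self.odds_ratios, 2),
            "ci_low": np.round(self.ci_low, 2),
            "ci_high": np.round(self.ci_high, 2),
            "p": np.round(self.p_values, 3),
        })


def exposure_flags(report, class_synonyms=None,
                   roles: tuple | None = None) -> dict:
    """Binary drug-class exposure flags for one :class:`ReportRecord`.

    A flag is true when any drug entry matches the class synonym list.  By
    default every role counts ("concomitant medication" without a stated
    role rule); pass ``roles=("SS", "C", "I")`` to restrict to non-primary
    entries.
    """
    syn = class_synonyms or DEFAULT_CLASS_SYNONYMS
    norm = {cls: {normalize_name(n) for n in names}
            for cls, names in syn.items()}
    flags = {cls: False for cls in norm}
    for entry in report.drugs:
        if roles is not None and entry.role not in roles:
            continue
        name = normalize_name(entry.name)
        for cls, names in norm.items():
            if name in names:
                flags[cls] = True
    return flags


def _age_band(age: float) -> str:
    if age < 45:
        return "<45"
    if age < 65:
        return "45-65"
    if age < 75:
        return "65-75"
    return ">75"


def build_risk_rows(records: ReportSet, hepatobiliary_soc: str,
                    class_synonyms=None, roles: tuple | None = None
                    ) -> pd.DataFrame:
    """Assemble the case/non-case analysis frame (complete cases only).

    ``records`` must be SOC-annotated and PS-filtered to the target drug.
    Reports with unknown age or sex are dropped — the model's margins then
    total only known-covariate reports.  Returns one row per report with
    outcome, age_band, sex and the exposure flags.
    """
    soc_key = str(hepatobiliary_soc).strip().upper()
    reac = records.pair_table()
    if "soc" not in reac.columns:
        raise ValueError("reactions lack SOC annotation; run map_pt_to_soc")
    case_ids = set(reac.loc[reac["soc"] == soc_key, "primaryid"])

    syn = class_synonyms or DEFAULT_CLASS_SYNONYMS
    norm = {cls: {normalize_name(n) for n in names}
            for cls, names in syn.items()}
    d = records.drugs
    if roles is not None:
        d = d[d["role_cod"].isin(roles)]
    exposed = {cls: set(d.loc[d["drugname"].isin(names), "primaryid"])
               for cls, names in norm.items()}

    demo = records.demo
    age_num = pd.to_numeric(demo["age"], errors="coerce")
    sex_raw = demo["sex"].astype(str).str.strip().str.upper()
    known = age_num.notna() & sex_raw.isin(["F", "M"])
    sub = demo[known]
    rows = pd.DataFrame({
        "primaryid": sub["primaryid"].to_numpy(),
        "outcome": sub["primaryid"].isin(case_ids).to_numpy(),
        "age_band": age_num[known].map(_age_band).to_numpy(),
        "sex": sex_raw[known].map({"F": "female", "M": "male"}).to_numpy(),
    })
    for cls in norm:
        rows[cls] = rows["primaryid"].isin(exposed[cls]).to_numpy()
    return rows.reset_index(drop=True)


def _norm_sf(z: float) -> float:
    return 0.5 * (1.0 - erf(abs(z) / sqrt(2.0)))


def univariate_or(exposed_cases: int, unexposed_cases: int,
                  exposed_controls: int, unexposed_controls: int
                  ) -> tuple[float | None, float | None, float | None,
                             float | None, str | None]:
    """Odds ratio of one exposure from its 2×2 margins with Wald inference.

    Returns ``(OR, ci_low, ci_high, p, reason)``; a zero cell makes the
    statistic undefined and the reason reports which.  The p-value is
    two-sided normal on ``ln OR / SE``.
    """
    cells = {"exposed cases": exposed_cases,
             "unexposed cases": unexposed_cases,
             "exposed controls": exposed_controls,
             "unexposed controls": unexposed_controls}
    for name, v in cells.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    zeros = [name for name, v in cells.items() if v == 0]
    if zeros:
        return None, None, None, None, f"zero cell ({', '.join(zeros)})"
    orr = (exposed_cases * unexposed_controls) / (
        unexposed_cases * exposed_controls)
    se = sqrt(sum(1.0 / v for v in cells.values()))
    lo = exp(log(orr) - 1.96 * se)
    hi = exp(log(orr) + 1.96 * se)
    z = log(orr) / se
    p = 2.0 * _norm_sf(z)
    return orr, lo, hi, p, None


def _design_matrix(rows: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Reference-encode covariates: age <45, female, unexposed are baseline."""
    X = pd.DataFrame(index=rows.index)
    # categorical levels absent from the data contribute no column (they
    # are not estimable); exposures are kept verbatim so a genuinely
    # constant exposure still trips the rank check
    present = set(rows["age_band"].unique())
    for band in AGE_BANDS[1:]:
        if band in present:
            X[f"age_{band}"] = (rows["age_band"] == band).astype(float)
    if "sex" in rows.columns:
        if {"female", "male"} <= set(rows["sex"].unique()):
            X["male"] = (rows["sex"] == "male").astype(float)
    elif "male" in rows.columns:
        X["male"] = rows["male"].astype(float)
    for cls in ("rtx", "ctx", "ppi", "statin"):
        if cls in rows.columns:
            X[cls] = rows[cls].astype(float)
    X.insert(0, "intercept", 1.0)
    return X, list(X.columns)


def fit_logistic(rows: pd.DataFrame, max_iter: int = 50,
                 tol: float = 1e-10,
                 separation_bound: float = 15.0) -> LogisticFit:
    """Maximum-likelihood logistic fit of case status on the covariates.

    Fitting is iteratively reweighted least squares, capped at ``max_iter``
    iterations with relative log-likelihood tolerance ``tol``.  Errors:
    rank deficiency of the encoded design; apparent separation (any
    |coefficient| exceeding ``separation_bound``), reported with the
    offending term.
    """
    y = rows["outcome"].astype(float).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one case and one non-case")
    X, terms = _design_matrix(rows)
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank {rank} < {Xv.shape[1]} columns "
            "(constant or aliased covariate)")
    def _separating_terms() -> list:
        # a binary covariate with an empty case or non-case arm separates
        bad = []
        for i, name in enumerate(terms):
            if name == "intercept":
                continue
            col = Xv[:, i] > 0.5
            cells = [(col & (y == 1)).sum(), (col & (y == 0)).sum(),
                     (~col & (y == 1)).sum(), (~col & (y == 0)).sum()]
            if 0 in cells:
                bad.append(name)
        return bad or ["<unidentified>"]

    model = sm.GLM(y, Xv, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=max_iter, tol=tol)
    except Exception as exc:  # statsmodels PerfectSeparationError et al.
        if "separation" in str(exc).lower():
            raise SeparationError(
                f"apparent separation: {_separating_terms()}") from exc
        raise
    coef = np.asarray(res.params)
    big = np.abs(coef) > separation_bound
    if big.any():
        bad = [terms[i] for i in np.nonzero(big)[0]]
        raise SeparationError(
            f"apparent separation: coefficient diverged for {bad}")
    se = np.asarray(res.bse)
    z = coef / se
    p = np.array([2.0 * _norm_sf(v) for v in z])
    return LogisticFit(
        terms=terms, coef=coef, se=se,
        odds_ratios=np.exp(coef),
        ci_low=np.exp(coef - 1.96 * se),
        ci_high=np.exp(coef + 1.96 * se),
        p_values=p, loglik=float(res.llf),
        iterations=int(getattr(res, "fit_history", {}).get("iteration", 0)
                       or 0),
        converged=bool(res.converged),
    )
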