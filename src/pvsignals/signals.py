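"""Disproportionality analysis: ROR, PRR+χ², BCPNN IC and MGPS EBGM.

All four algorithms operate on the 2×2 contingency table of a (drug, term)
pair against the rest of the database, where the counting unit is the
(report, distinct PT) pair:

====================  ==============  ===================
                       term            all other terms
target-drug reports    a               b
all other reports      c               d
====================  ==============  ===================

* **ROR** — reporting odds ratio ``ad/bc`` with a Wald log-scale 95% CI.
* **PRR** — proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]`` with the
  Pearson χ² of the table (Yates continuity correction by default).
* **BCPNN IC** — the information component, a Bayesian-shrunk log₂
  observed-to-expected ratio with the conventional Dirichlet-style priors
  (``α₁=β₁=γ₁₁=1``, ``α=β=2``); ``IC025 = E[IC] − 2·SD``.
* **MGPS EBGM** — DuMouchel's empirical-Bayes gamma–Poisson shrinker: a
  two-component gamma mixture prior on the relative reporting ratio λ is
  fitted by maximum marginal likelihood across every drug–event cell; each
  cell's posterior yields the empirical-Bayes geometric mean EBGM and its
  5th percentile EBGM05.

A pair is flagged as a validated signal only when all four algorithms meet
their criteria simultaneously; counts below 10 carry a caution flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import gamma as gamma_dist

from .core import ReportSet, normalize_name, normalize_pt

__all__ = [
    "ContingencyTable", "BcpnnPriors", "MgpsHyper", "SignalCriteria",
    "SignalStats", "MgpsConvergenceError", "build_contingency",
    "contingency_tables", "ror_stats", "prr_stats", "bcpnn_stats",
    "drug_event_cells", "mgps_fit", "mgps_cell", "evaluate_criteria",
    "compute_signal_table",
]


@dataclass(frozen=True)
class ContingencyTable:
    """The 2×2 counts underlying every disproportionality statistic."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Independence expectation E = (a+b)(a+c)/N of the ``a`` cell."""
        if self.n == 0:
            raise ValueError("empty table has no expectation")
        return (self.a + self.b) * (self.a + self.c) / self.n

    @property
    def degenerate(self) -> bool:
        """True when the term is reported exclusively with the target drug."""
        return self.c == 0


@dataclass(frozen=True)
class BcpnnPriors:
    """Priors of the information component (standard published constants)."""

    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.gamma11,
               self.alpha, self.beta) <= 0:
            raise ValueError("all BCPNN priors must be strictly positive")


@dataclass
class MgpsHyper:
    """Gamma-mixture hyperparameters of the MGPS prior on λ.

    Prior: ``λ ~ w · Gamma(a1, rate=b1) + (1−w) · Gamma(a2, rate=b2)``.
    """

    a1: float
    b1: float
    a2: float
    b2: float
    w: float
    converged: bool = True
    loglik: float = float("nan")
    n_iter: int = 0

    def __post_init__(self):
        if min(self.a1, self.b1, self.a2, self.b2) <= 0:
            raise ValueError("gamma shapes and rates must be > 0")
        if not (0.0 < self.w < 1.0):
            raise ValueError("mixture weight must lie strictly in (0, 1)")


class MgpsConvergenceError(RuntimeError):
    """MGPS hyperparameter optimisation failed; carries the best-so-far fit."""

    def __init__(self, message: str, best: MgpsHyper):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SignalCriteria:
    """Positivity thresholds of the four algorithms (all configurable)."""

    min_count: int = 3
    ror_lo_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


@dataclass
class SignalStats:
    """Point estimates, interval bounds and flags for one drug–term pair."""

    term: str
    level: str
    n: int
    table: ContingencyTable
    ror: float | None = None
    ror_lo: float | None = None
    ror_hi: float | None = None
    ror_reason: str | None = None
    prr: float | None = None
    chi2: float | None = None
    prr_reason: str | None = None
    ic: float | None = None
    ic025: float | None = None
    ebgm: float | None = None
    ebgm05: float | None = None
    ebgm_reason: str | None = None
    ror_pos: bool = False
    prr_pos: bool = False
    bcpnn_pos: bool = False
    mgps_pos: bool = False
    n_positive: int = 0
    all_four_positive: bool = False

    @property
    def small_count_caution(self) -> bool:
        return self.n < 10


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def contingency_tables(records: ReportSet, target_synonyms,
                       level: str = "PT") -> pd.DataFrame:
    """2×2 cells for every term at the given level, target vs rest.

    The comparator is every report whose primary-suspect drug is *not* the
    target (target reports are excluded from the background entirely).
    Returns a frame indexed by term with columns a, b, c, d.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")
    syn = {normalize_name(s) for s in target_synonyms}
    d = records.drugs
    target_ids = set(d.loc[(d["role_cod"] == "PS")
                           & (d["drugname"].isin(syn)), "primaryid"])
    pairs = records.pair_table()
    col = "pt" if level == "PT" else "soc"
    if col not in pairs.columns:
        raise ValueError("reactions lack SOC annotation; run map_pt_to_soc "
                         "before SOC-level analysis")
    is_target = pairs["primaryid"].isin(target_ids)
    tgt_counts = pairs.loc[is_target, col].value_counts()
    oth_counts = pairs.loc[~is_target, col].value_counts()
    total_tgt = int(is_target.sum())
    total_oth = int(len(pairs) - total_tgt)
    terms = tgt_counts.index.union(oth_counts.index)
    a = tgt_counts.reindex(terms, fill_value=0).astype(int)
    c = oth_counts.reindex(terms, fill_value=0).astype(int)
    out = pd.DataFrame({"a": a, "b": total_tgt - a, "c": c,
                        "d": total_oth - c})
    out.index.name = "term"
    return out


def build_contingency(records: ReportSet, term: str, target_synonyms,
                      level: str = "PT") -> ContingencyTable:
    """The 2×2 table of one term for the target drug versus the rest.

    ``a`` counts target-drug reports mentioning the term (distinct per
    report; at SOC level, each distinct PT under the SOC counts), ``b`` the
    remaining target report-PT pairs, ``c``/``d`` the analogues over all
    non-target reports.  An unknown term yields an all-target/background
    zero-``a`` table with a warning.
    """
    key = normalize_pt(term) if level == "PT" else str(term).strip().upper()
    cells = contingency_tables(records, target_synonyms, level=level)
    if key not in cells.index:
        import warnings
        warnings.warn(f"term {term!r} absent from the {level} vocabulary; "
                      "returning a zero-count table", stacklevel=2)
        total_tgt = int((cells["a"] + cells["b"]).iloc[0]) if len(cells) else 0
        total_oth = int((cells["c"] + cells["d"]).iloc[0]) if len(cells) else 0
        return ContingencyTable(0, total_tgt, 0, total_oth)
    row = cells.loc[key]
    return ContingencyTable(int(row["a"]), int(row["b"]),
                            int(row["c"]), int(row["d"]))


# ---------------------------------------------------------------------------
# ROR / PRR
# ---------------------------------------------------------------------------

def ror_stats(t: ContingencyTable, correction: bool = False
              ) -> tuple[float | None, float | None, float | None, str | None]:
    """Reporting odds ratio with Wald 95% CI.

    Returns ``(ror, lo, hi, reason)``.  With any zero cell the statistic is
    undefined and the reason says which cell; pass ``correction=True`` for
    the Haldane–Anscombe +0.5 adjustment instead (off by default: it
    silently manufactures estimates for never-co-reported pairs).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if correction and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if 0 in (a, b, c, d):
        zero = [nm for nm, v in zip("abcd", (a, b, c, d)) if v == 0]
        return None, None, None, f"zero cell ({', '.join(zero)})"
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - 1.96 * se)
    hi = math.exp(math.log(ror) + 1.96 * se)
    return ror, lo, hi, None


def prr_stats(t: ContingencyTable, yates: bool = True
              ) -> tuple[float | None, float | None, str | None]:
    """Proportional reporting ratio and table χ².

    ``prr = [a/(a+b)] / [c/(c+d)]`` — defined for ``a = 0`` (returns 0) but
    undefined when the comparator never reports the term (``c = 0``).  The
    χ² is Pearson's with an optional Yates continuity correction, the
    corrected numerator floored at zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    if a + b == 0 or c + d == 0:
        return None, None, "empty margin"
    if c == 0:
        return None, None, "zero comparator count (c = 0)"
    prr = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return prr, None, "degenerate margin for chi2"
    num = abs(a * d - b * c) - (n / 2 if yates else 0.0)
    num = max(num, 0.0)
    chi2 = n * num * num / denom
    return prr, chi2, None


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

def bcpnn_stats(t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()
                ) -> tuple[float, float]:
    """Information component and its lower bound ``IC025 = E[IC] − 2·SD``.

    Closed-form posterior moments of the shrunken log₂ observed/expected
    ratio; defined for every valid table, including ``a = 0``.
    """
    if t.n <= 0:
        raise ValueError("information component needs a non-empty table")
    a, n = t.a, t.n
    a1, b1, g11 = priors.alpha1, priors.beta1, priors.gamma11
    al, be = priors.alpha, priors.beta
    row = t.a + t.b
    col = t.a + t.c
    g = g11 * (n + al) * (n + be) / ((row + a1) * (col + b1))
    ic = math.log2((a + g11) * (n + al) * (n + be)
                   / ((n + g) * (row + a1) * (col + b1)))
    var = (1.0 / math.log(2) ** 2) * (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - row + al - a1) / ((row + a1) * (1 + n + al))
        + (n - col + be - b1) / ((col + b1) * (1 + n + be))
    )
    return ic, ic - 2.0 * math.sqrt(var)


# ---------------------------------------------------------------------------
# MGPS empirical-Bayes gamma–Poisson shrinker
# ---------------------------------------------------------------------------

def drug_event_cells(records: ReportSet) -> pd.DataFrame:
    """Observed and expected counts for every (PS drug, PT) cell.

    ``a`` is the number of reports naming the drug as primary suspect and
    carrying the PT; ``E = n_drug · n_event / N`` from the pair margins —
    the input to the MGPS hyperparameter fit.
    """
    d = records.drugs
    ps = d.loc[d["role_cod"] == "PS", ["primaryid", "drugname"]]
    pairs = records.pair_table().merge(ps, on="primaryid", how="inner")
    counts = (pairs.groupby(["drugname", "pt"], sort=True)
              .size().rename("a").reset_index())
    n_total = counts["a"].sum()
    row = counts.groupby("drugname")["a"].transform("sum")
    col_margin = counts.groupby("pt")["a"].sum()
    col = counts["pt"].map(col_margin)
    counts["E"] = row * col / n_total
    return counts


_MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _nb_logpmf(a, shape, rate, E):
    """log NB(a; shape, rate, E): the gamma-Poisson marginal of one cell."""
    return (gammaln(shape + a) - gammaln(shape) - gammaln(a + 1.0)
            + shape * np.log(rate / (rate + E))
            + a * np.log(E / (rate + E)))


def mgps_fit(a, E, start=_MGPS_START, max_iter: int = 500,
             gtol: float = 1e-8) -> MgpsHyper:
    """Maximum-marginal-likelihood fit of the gamma-mixture hyperprior.

    ``a`` and ``E`` are the observed and expected counts of every drug–event
    cell of the database.  The negative log marginal likelihood of the
    two-component negative-binomial mixture is minimised by bounded
    quasi-Newton (L-BFGS-B) on log/logit-transformed parameters from the
    documented start point.  Raises :class:`MgpsConvergenceError` (carrying
    the best-so-far parameters) if the optimiser does not converge.
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    if a.shape != E.shape or a.ndim != 1:
        raise ValueError("a and E must be equal-length 1-D arrays")
    if len(a) < 2:
        raise ValueError("MGPS fitting needs at least two drug–event cells")
    if np.any(E <= 0):
        raise ValueError("all expected counts must be positive")

    def unpack(theta):
        a1, b1, a2, b2 = np.exp(theta[:4])
        w = 1.0 / (1.0 + np.exp(-theta[4]))
        return a1, b1, a2, b2, w

    def nll(theta):
        a1, b1, a2, b2, w = unpack(theta)
        l1 = _nb_logpmf(a, a1, b1, E) + np.log(w)
        l2 = _nb_logpmf(a, a2, b2, E) + np.log1p(-w)
        return -np.sum(logsumexp(np.stack([l1, l2]), axis=0))

    s = start
    theta0 = np.array([np.log(s[0]), np.log(s[1]), np.log(s[2]), np.log(s[3]),
                       np.log(s[4] / (1.0 - s[4]))])
    # bounds keep the log/logit parameters in a numerically safe range
    bounds = [(-15.0, 15.0)] * 4 + [(-25.0, 25.0)]
    res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "gtol": gtol, "maxfun": 5000})
    a1, b1, a2, b2, w = unpack(res.x)
    w = float(np.clip(w, 1e-12, 1.0 - 1e-12))
    hyper = MgpsHyper(a1=float(a1), b1=float(b1), a2=float(a2), b2=float(b2),
                      w=w, converged=bool(res.success),
                      loglik=float(-res.fun), n_iter=int(res.nit))
    if not res.success:
        raise MgpsConvergenceError(
            f"MGPS optimisation did not converge: {res.message}", hyper)
    return hyper


def mgps_cell(t: ContingencyTable, h: MgpsHyper, tol: float = 1e-8
              ) -> tuple[float | None, float | None, str | None]:
    """EBGM and EBGM05 of one cell under fitted hyperparameters.

    The posterior on the relative reporting ratio λ is the gamma mixture
    ``Q·Gamma(a1+a, b1+E) + (1−Q)·Gamma(a2+a, b2+E)`` with Q the posterior
    component probability.  EBGM is the geometric mean
    ``exp(E[ln λ])``; EBGM05 is the 0.05 posterior quantile, found by
    bisection on the mixture CDF to absolute tolerance ``tol``.
    Returns ``(ebgm, ebgm05, reason)``.
    """
    if t.n == 0:
        return None, None, "empty table"
    E = t.expected
    if E <= 0:
        return None, None, "zero expected count"
    a = t.a
    l1 = _nb_logpmf(a, h.a1, h.b1, E) + math.log(h.w)
    l2 = _nb_logpmf(a, h.a2, h.b2, E) + math.log1p(-h.w)
    m = max(l1, l2)
    q = math.exp(l1 - m) / (math.exp(l1 - m) + math.exp(l2 - m))

    mean_log = (q * (digamma(h.a1 + a) - math.log(h.b1 + E))
                + (1 - q) * (digamma(h.a2 + a) - math.log(h.b2 + E)))
    ebgm = math.exp(mean_log)

    g1 = gamma_dist(h.a1 + a, scale=1.0 / (h.b1 + E))
    g2 = gamma_dist(h.a2 + a, scale=1.0 / (h.b2 + E))

    def cdf(x):
        return q * g1.cdf(x) + (1 - q) * g2.cdf(x)

    hi = max(g1.ppf(0.999), g2.ppf(0.999), 1.0)
    ebgm05 = brentq(lambda x: cdf(x) - 0.05, 0.0, hi, xtol=tol)
    return ebgm, float(ebgm05), None


# ---------------------------------------------------------------------------
# criteria and the assembled signal table
# ---------------------------------------------------------------------------

def evaluate_criteria(s: SignalStats,
                      criteria: SignalCriteria = SignalCriteria()
                      ) -> SignalStats:
    """Apply the four positivity rules and the all-four conjunction in place.

    Absent statistics count as negative.  Also fills ``n_positive`` (0–4),
    the input to the signal-stability rubric criterion.
    """
    s.ror_pos = (s.n >= criteria.min_count and s.ror_lo is not None
                 and s.ror_lo > criteria.ror_lo_gt)
    s.prr_pos = (s.n >= criteria.min_count and s.prr is not None
                 and s.chi2 is not None and s.prr >= criteria.prr_min
                 and s.chi2 >= criteria.chi2_min)
    s.bcpnn_pos = s.ic025 is not None and s.ic025 > criteria.ic025_gt
    s.mgps_pos = s.ebgm05 is not None and s.ebgm05 > criteria.ebgm05_gt
    s.n_positive = sum((s.ror_pos, s.prr_pos, s.bcpnn_pos, s.mgps_pos))
    s.all_four_positive = s.n_positive == 4
    return s


def compute_signal_table(records: ReportSet, target_synonyms,
                         level: str = "PT",
                         priors: BcpnnPriors = BcpnnPriors(),
                         criteria: SignalCriteria = SignalCriteria(),
                         yates: bool = True,
                         zero_cell_correction: bool = False,
                         hyper: MgpsHyper | None = None) -> pd.DataFrame:
    """All four algorithms for every term of the target drug at one level.

    The MGPS hyperprior is fitted once across every drug–event cell of the
    database (pass ``hyper`` to reuse a fit).  Returns one row per term,
    sorted by descending ROR, with counts, estimates, interval bounds,
    per-algorithm flags, the positive-algorithm count, and the small-count
    caution flag.
    """
    cells = contingency_tables(records, target_synonyms, level=level)
    if hyper is None:
        dec = drug_event_cells(records)
        hyper = mgps_fit(dec["a"].to_numpy(), dec["E"].to_numpy())
    rows = []
    for term, r in cells.iterrows():
        t = ContingencyTable(int(r["a"]), int(r["b"]), int(r["c"]),
                             int(r["d"]))
        s = SignalStats(term=str(term), level=level, n=t.a, table=t)
        s.ror, s.ror_lo, s.ror_hi, s.ror_reason = ror_stats(
            t, correction=zero_cell_correction)
        s.prr, s.chi2, s.prr_reason = prr_stats(t, yates=yates)
        s.ic, s.ic025 = bcpnn_stats(t, priors)
        if t.expected > 0:
            s.ebgm, s.ebgm05, s.ebgm_reason = mgps_cell(t, hyper)
        else:
            s.ebgm_reason = "zero expected count"
        evaluate_criteria(s, criteria)
        rows.append({
            "term": s.term, "level": level, "a": t.a, "b": t.b, "c": t.c,
            "d": t.d, "ror": s.ror, "ror_lo": s.ror_lo, "ror_hi": s.ror_hi,
            "prr": s.prr, "chi2": s.chi2, "ic": s.ic, "ic025": s.ic025,
            "ebgm": s.ebgm, "ebgm05": s.ebgm05, "ror_pos": s.ror_pos,
            "prr_pos": s.prr_pos, "bcpnn_pos": s.bcpnn_pos,
            "mgps_pos": s.mgps_pos, "n_positive": s.n_positive,
            "all_four_positive": s.all_four_positive,
            "caution": s.small_count_caution,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = (out.sort_values("ror", ascending=False, na_position="last")
               .reset_index(drop=True))
    return out
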