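# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `pvsignals`.

## Counting unit and contingency tables

The unit of analysis everywhere downstream of ingestion is the *(report,
distinct preferred term)* pair: one report can contribute several adverse
events, but the same PT at most once.  This is why a database can contain,
say, 3,150 reports and 7,187 adverse events.  At SOC level a report
contributes one count per distinct PT mapping to that SOC, so SOC counts
across a database sum to the total event count.

For a target drug and a term, the 2×2 table sets `a` = target-drug
primary-suspect reports carrying the term, `b` = the target drug's
remaining report-PT pairs, and `c`, `d` analogously over all non-target
reports.  The comparator is the full remaining database: target reports
are excluded from the background entirely.  Whether non-primary-suspect
mentions of the target should also be excluded from the comparator is a
genuinely open design point; the full-database comparator is the default
because it is the dominant convention, and the PS filter applies only to
the target side.

## Disproportionality statistics

**ROR.** `ad/bc`, CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.  Any zero
cell makes the statistic undefined; by default no Haldane–Anscombe +0.5
correction is applied (it would silently manufacture estimates for
never-co-reported pairs), but a `correction=True` flag exists.

**PRR.** `[a/(a+b)]/[c/(c+d)]`, defined at `a = 0`, undefined at `c = 0`.
The accompanying χ² is Pearson's with Yates continuity correction by
default (the corrected numerator floored at zero); the correction is the
common choice alongside the PRR ≥ 2, χ² ≥ 4 rule and is configurable.

**BCPNN.** The information component uses the standard published priors
α₁ = β₁ = γ₁₁ = 1, α = β = 2.  With γ = γ₁₁(N+α)(N+β)/[(a+b+α₁)(a+c+β₁)]:

    IC   = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]
    V    = (ln 2)⁻² · [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                      + (N−a−b+α−α₁)/((a+b+α₁)(1+N+α))
                      + (N−a−c+β−β₁)/((a+c+β₁)(1+N+β)) ]
    IC025 = IC − 2√V

The statistic is defined for every valid table, including `a = 0`, and the
E(IC) − 2·SD interval is the convention adopted (not a posterior quantile).

**MGPS.** The relative reporting ratio λ of each drug–event cell gets a
two-component gamma prior `w·Gamma(a₁, rate b₁) + (1−w)·Gamma(a₂, rate
b₂)`.  Hyperparameters are fitted once per database by maximising the
marginal likelihood — a mixture of negative binomials
`NB(a; α, β, E) = Γ(α+a)/(Γ(α)a!) · (β/(β+E))^α · (E/(β+E))^a` with
`E = (a+b)(a+c)/N` per cell — over every (primary-suspect drug, PT) cell.
Optimisation is L-BFGS-B on log/logit-transformed parameters from the
start point (0.2, 0.1, 2, 4, 1/3), iteration cap 500, gradient tolerance
1e-8, with box bounds (|log param| ≤ 15, |logit w| ≤ 25) purely for
numerical safety; non-convergence raises an error carrying the best-so-far
parameters.  Per cell, the posterior is the gamma mixture
`Q·Gamma(a₁+a, b₁+E) + (1−Q)·Gamma(a₂+a, b₂+E)` with Q the posterior
component probability; EBGM is the geometric mean `exp(E[ln λ])` computed
from digamma closed forms, and EBGM05 the 0.05 posterior quantile found by
bisection on the mixture CDF to absolute tolerance 1e-8.  Stratified
(age/sex/period) expected counts are not implemented.

At the single-gamma boundary (w → 1) the mixture weight is only weakly
identified; the parameter-recovery tests therefore check the dominant
component, which is what the shrinkage depends on.

**Criteria.** Defaults — ROR: a ≥ 3 and CI lower bound > 1; PRR: a ≥ 3,
PRR ≥ 2, χ² ≥ 4; BCPNN: IC025 > 0; MGPS: EBGM05 > 2; a validated signal
requires all four, and counts below 10 carry a caution flag.  Every
threshold is configurable; these defaults are the dominant convention in
the disproportionality literature and jointly explain which terms published
four-algorithm tables retain.

## Deduplication

Among reports sharing a caseid the most recent `fda_dt` wins; on a date
tie, the larger primaryid (numeric comparison when both ids parse as
integers — FAERS primaryids are numeric strings of varying length, so
lexicographic order would misrank them).  Unparseable dates sort earliest,
so a dated report always beats an undated rival.  A second pass removes
residual duplicate primaryids, keeping the last row in (fda_dt, source
order).  The operation is idempotent.  Partial dates (YYYY, YYYYMM) are
retained for demographics but treated as unknown wherever day-level
arithmetic is required.

## Clinical prioritisation

Terms positive in ≥ 1 algorithm are scored 0–2 on four criteria:
designation-list relevance (DME → 2, IME → 1, neither → 0; a term on both
lists scores as DME, the rarer and stronger designation), cases-to-
non-cases reporting rate (`100·n/(total−n)`; ≥ 10% very common → 2, 1–10%
common → 1, ≤ 1% uncommon → 0), signal stability (positive in 4
algorithms → 2, in 2–3 → 1, in ≤ 1 → 0), and case fatality (> 50% → 2 — a
deliberately conservative bar for the top score — 10–50% → 1, < 10% → 0).
Totals 0–2/3–5/6–8 band as low/moderate/high.  The per-criterion point
values follow the published banding constraints but are fully overridable
through `PriorityRubric`, since scoring variants exist in the literature.
The EMA IME/DME lists are user-supplied files; the bundled
`*_synthetic.tsv` stand-ins exist only so tests and examples run offline.

## Time-to-onset

Onset is `event_dt − therapy_start` in whole days, requiring both dates at
day precision; when a report has several therapy rows for the target drug
the earliest day-precision start is the anchor (the conservative exposure
origin).  Reports failing any requirement are excluded with an explicit
reason (`missing_start`, `missing_event`, `partial_date`, `negative`) and
never imputed.  Day 0 (same-day onset) falls in the first bin; bins are
0–30, 31–60, 61–90, 91–120, 121–150, 151–180, 181–360, > 360, closed on
both endpoints, with percentages over the non-missing total.

Spontaneous reports carry no follow-up, so the default analysis treats
every included record as an event; the Kaplan–Meier estimator nevertheless
accepts censoring flags for generality.  Without censoring the
product-limit curve equals 1 − ECDF (verified to 1e-12).  Onset median and
IQR are linear-interpolation quantiles of the raw day counts.  Log-rank
comparisons use the standard observed-minus-expected χ² with (groups − 1)
degrees of freedom, delegated to lifelines and verified against an explicit
hand computation and a type-I-error simulation.

## Case/non-case risk model

A case is a target-drug report with ≥ 1 PT mapping to the hepatobiliary
SOC.  Exposures are drug-class flags (rituximab, cyclophosphamide, PPIs,
statins) matched against editable synonym lists over any drug role by
default ("concomitant medication" carries no role rule; a roles filter is
available).  Reports with unknown age or sex are dropped (complete-case
analysis), so model margins cover known-covariate reports only.  Age bands
are < 45, 45–65, 65–75, > 75 with half-open boundaries at 45, 65 and 75.
Univariate ORs come from the 2×2 cross-product with Wald intervals and a
two-sided normal p on `ln OR / SE`.  The multivariable fit is
maximum-likelihood logistic regression via IRLS (statsmodels GLM/Binomial)
with reference levels age < 45, female, unexposed; guards reject
rank-deficient designs and apparent separation (|coefficient| > 15),
naming the offending term.  Multivariable correctness is established by
parameter recovery on cohorts simulated from known coefficients — mean
bias below 0.02 per coefficient over 50 cohorts of 50,000 — not by
comparison to published multivariable ORs, whose individual-level joint
covariate data are not available.

## The synthetic reporting-system generator

The generator emulates the structure of a quarterly extract — DEMO, DRUG,
REAC, OUTC, THER, INDI, '$'-delimited with caseid/primaryid keys — under a
controlled statistical model:

- **Reports.** Each report has one primary-suspect drug from a weighted
  catalogue and independent co-medications (roles SS/C/I).  Defaults give
  the target drug a 10% share among ten drugs.
- **Events.** The number of distinct PTs per report is zero-truncated
  Poisson; the underlying Poisson mean is solved numerically so the
  truncated mean equals the configured 2.3 events/report.  PTs named in a
  planted signal are independent Bernoullis at exactly the background
  probability p₀ (or the boosted p₁ = OR·p₀/(1−p₀+OR·p₀) when the
  report's PS drug matches), and are excluded from slot filling, so the
  per-report odds ratio of carrying a planted term equals its target
  exactly.  Remaining slots are filled without replacement from the rest
  of the catalogue, probability-proportionally via Gumbel top-k.
- **Demographics and missingness.** Age ~ Normal(62, 17) clipped to
  [1, 95], missing at rate 0.421; sex 59/41 female/male, missing at 0.358;
  weight missing at 0.91; outcome codes drawn once per report
  (hospitalisation 0.233, other serious 0.177, death 0.075,
  life-threatening 0.011, disability 0.001, intervention 0.0003, none
  0.5027).
- **Onset dates.** Present for 17.8% of reports: a Weibull(shape 0.85,
  scale 72 days) delay from therapy start, chosen to give a median onset
  near 48 days with a long right tail.  The onset IQR of real report data
  over-determines a two-parameter family, so the median is matched and the
  tail approximated.  A config switch degrades a fraction of dates to
  YYYYMM/YYYY to exercise partial-date handling.
- **Duplicates.** A configurable fraction of cases (default 0.13,
  matching the removal fraction seen in large regulatory databases) gains
  one or two extra versions with later-or-equal dates and larger
  primaryids; the generator records the correct survivor per case during
  construction, so deduplication tests never depend on the logic under
  test.
- **Risk coupling.** Co-medication prevalence is enriched among reports
  carrying hepatobiliary PTs via the same odds-ratio planting, reproducing
  case/non-case exposure margins; a separate direct logistic-cohort
  generator (`simulate_risk_cohort`) provides exact known coefficients for
  regression recovery tests.

Identical (config, seed) yield byte-identical bundles; all randomness runs
through one `numpy` generator.

What the generator does **not** emulate: real MedDRA vocabulary breadth
(the toy catalogue has ~40 PTs over 13 SOCs), correlated event clusters
within reports, reporter- or country-dependent reporting styles, secular
trends, and pharmacologically plausible co-medication patterns.  Passing
tests therefore demonstrate correctness of the statistical machinery under
a known generative model, not performance characteristics on real
spontaneous-report data.

## Problem sizes used in the test suite

Calibration checks run at 10,000 reports; planted-odds-ratio recovery uses
20 independent databases of 50,000 reports (target inside its own 95% CI
in ≥ 90% of replicates); MGPS hyperparameter recovery uses 10,000 cells;
logistic recovery uses 50 cohorts of 50,000; the log-rank null calibration
uses 1,000 two-sample replicates of 30+30.  These sizes were chosen so
each check's Monte-Carlo error is comfortably below the tolerance it
asserts.

## Known limitations

- No stratified or covariate-adjusted MGPS, and no multiple-comparison
  control across terms.
- The E(IC) − 2SD interval is a moment approximation, not an exact
  posterior quantile.
- Exposure flags are name-list matches; dose, duration and indication are
  ignored.
- The TTO path analyses only reports with complete day-precision dates;
  with heavy onset missingness the included subset need not be
  representative.
- Disproportionality quantifies reporting association, not incidence or
  causation.
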