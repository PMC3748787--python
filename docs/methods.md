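# Methods

This note records the statistical models implemented in `natalstrat`, the
conventions and numerical choices behind them, and what the synthetic-data
generator does and does not emulate.

## Data model

The unit of analysis is a month-of-birth table: the twelve monthly birth
counts of one (region-or-country, calendar-year, sex) stratum, with an
optional latitude. Counts are stored as floats because two standard
manipulations — the leap-year February adjustment and rescaling a table to
an equivalent study size — produce fractional counts, and the Pearson
chi-square machinery is well defined for fractional observed and expected
values. Months are indexed 1–12 with January = 1 everywhere; data files
never carry locale month names. Pooled tables (e.g. a case collection
spanning many birth years) set `year=None` and are treated as generic
365-day years for month-length arithmetic; this is the package's own
extension of the per-year record type, needed because a pooled collection
has no single leap status.

## Seasonality and comparison tests

The null model is a uniform daily birth rate: expected monthly counts are
proportional to Gregorian month lengths (29-day February in leap years), and
the observed counts are tested by Pearson chi-square with 11 df. The
normalized daily rate profile divides each month's count by its length and
scales by the year's mean daily rate, so the day-weighted mean of the twelve
rates is exactly 1; per-month "excess" is the percentage deviation of this
rate from 1.

Pairwise comparisons of two tables use the 2×12 contingency chi-square
(11 df) with no continuity correction. Before comparing, leap-year tables
have February multiplied by 28/29 so that both rows describe 365 days;
without this, a leap/non-leap pair drawn from identical daily rates would
show a spurious February difference. A month with zero combined count makes
the product-margin expectation degenerate; the comparison aborts with advice
to pool months rather than silently merging. Sex-stratified comparisons are
expressed as ordinary comparisons of the male and female tables; no separate
operation exists.

Case–control month tests are the twelve one-month-versus-rest 2×2 Pearson
tests (no continuity correction, consistent with the noncentrality theory
below). The replication-pattern verdict is directional: it requires a
nominally significant *excess* in March, April or May, or a nominally
significant *deficit* in November, December or January; a significant effect
in the wrong direction does not count.

## Multinomial logit of month of birth

Month of birth is modelled as a 12-level outcome in a baseline-category
logit with January as baseline: each other month m has a linear predictor
η_m(x) (intercept plus covariates), and P(m|x) = exp(η_m)/Σ_k exp(η_k) with
η_Jan ≡ 0. Covariates supported: country as a factor (reference coding,
alphabetically first level as reference — any full-rank coding gives the
same fit), year of birth as a centered continuous covariate (centering is
for numerical conditioning; slopes are invariant to the centering point),
leap year as a 0/1 indicator, and latitude as a linear term. No
interactions, random effects or overdispersion are modelled.

The likelihood is evaluated directly on aggregated per-stratum counts —
identical, up to an additive constant, to the likelihood of the expanded
individual records — and maximized by Newton–Raphson with the analytic
gradient and block Hessian. Convergence requires gradient max-norm below
1e-6 (default); step halving guards the ascent, with an acceptance tolerance
relative to |log L| because the likelihood plateaus at machine precision on
its own scale near the optimum. Standard errors come from the inverse
observed information. Separation (a month empty in every stratum) is
rejected up front with the month named. Model fit is summarized by McFadden
pseudo-R² against the closed-form intercept-only fit (pooled proportions);
nested models are compared by the likelihood-ratio chi-square with df equal
to the parameter-count difference.

The implementation is hand-rolled because the established multinomial-logit
fitters operate on individual-level outcomes and do not accept
frequency-weighted aggregated counts; the test suite cross-checks
coefficients, standard errors and log-likelihood against an independent
individual-level fit on expanded records.

## Confounded designs and type-I error

Let p_case be the mixture month distribution of cases (stratum weights ∝
population × prevalence × year-of-birth frequency; the weighting convention
is a documented helper, and weights may equally be supplied explicitly) and
p_ctrl the unweighted average of stratum distributions. For a study with n
cases and n controls, each one-vs-rest test has noncentrality

λ_m = (n/2) · (p_case,m − p_ctrl,m)² / (p̄_m(1 − p̄_m)),

the Pearson statistic of the alternative-expected 2×2 counts evaluated
against their own product margins (pooled-variance form, the one consistent
with the plain Pearson statistic). λ is exactly linear in n. Power against
the central critical value c_α uses the exact 1-df identity
P((Z+√λ)² > c) = Φ(√λ−√c) + Φ(−√λ−√c).

The overall false-positive probability of a design combines 12 (discovery)
or 6 directional (replication) tests that share one multinomial draw and are
therefore negatively correlated. The default combination is joint Monte
Carlo (20,000 paired multinomial replicates, seed recorded in the result);
the independence approximation 1 − Π(1 − power_m) is retained as a fast
alternative and is accurate when the signal is concentrated in few months.
Directional power for the replication design uses the signed normal form:
an excess test fires with probability Φ(δ − √c) and a deficit test with
Φ(−δ − √c), where δ = sign(p_case,m − p_ctrl,m)·√λ_m; significance is
two-sided at α with the observed direction required to match. All reported
rates are lower limits: strata are assumed internally homogeneous, which
understates the real structure.

## The stratification (genetics) example

The packaged UK Government Office Region table (11 regions: mid-2010
population, multiple sclerosis prevalence per 100,000, regional frequency of
the lactase-gene rs1042712-C allele) drives four scenarios. Weighted
summaries: overall prevalence = Σ pop·prev / Σ pop = 147.88; control
(population-weighted) allele frequency 11.58%; case (prevalence-weighted)
frequency Σ pop·prev·freq / Σ pop·prev = 11.29%. Allele tests count two
independent alleles per person (Hardy–Weinberg independence — only
frequency-level inputs exist), use the same pooled product-margin
noncentrality generalized to unequal arms, and report two-sided power via
the noncentral chi-square or one-sided power via Φ(√λ − z_{1−α}) with the
direction fixed by the sign of the frequency difference. The "London"
scenario deliberately uses the unrounded population-weighted control
frequency (11.581%), not a rounded 11.6%, so every derived quantity flows
from the table itself. Computed at genome-wide significance (α = 5×10⁻⁸)
the London scenario's power is 39.1% — reported by the code but documented
here as method-sensitive, since small changes in the noncentrality
convention move it across 40%. Missing regional prevalences can be filled
by linear interpolation in latitude between two explicit reference points.

## Synthetic-data generator

Daily birth rates follow a single cosine harmonic,
r(d) = base·(1 + A·cos(2π(d − peak_day)/days_in_year)), with the realized
amplitude A varying linearly in latitude (anchored at 50°N, a mid-European
reference) and calendar year, clamped to [0, 0.95] to keep rates positive.
A configuration needing clamping on more than half its (latitude, year)
grid is rejected as degenerate. Monthly probabilities are exact day-by-day
integrals (366-day leap years); tables are multinomial draws. A
single-harmonic model is the minimal structure that reproduces
realistic-looking normalized daily-rate profiles and the documented
latitude/secular correlations; defaults are a 10% amplitude with an
early-April peak.

Synthetic region tables space latitudes evenly and impose opposing affine
gradients — prevalence rising, exposure frequency falling with latitude —
with defaults spanning roughly 115–227 per 100,000 and 14.0–9.5%, matching
the UK regional ranges. Case collections draw each case's stratum with
probability ∝ population × prevalence × year weight and its month from the
stratum's observed distribution, then pool.

The bundled `uk_like_population` scenario fixes the study conditions used
in the curve tests: 11 regions at 50.5–57.5°N, birth years 1950–1979 with
50,000 births per stratum, amplitude 0.19 at the 1950 anchor declining by
0.003 per year (a secular fading of seasonality), +0.012 amplitude per
degree latitude, and case year-of-birth weights Gaussian around 1958 (sd 8
years), emulating a prevalent-disease case series assembled decades after
the index births. The generator does not attempt demographic realism:
no maternal-age, weekday-of-birth, registration-lag or migration effects,
and within-stratum homogeneity is built in. Passing tests therefore
demonstrate the confounding mechanism and the correctness of the
machinery under known structure — not the magnitude of type-I inflation in
any real registry, which depends on real profiles and real case mixes.

Seeds are explicit arguments echoed in results; reproducibility is promised
within this implementation only (bit-identity across numpy versions or
platforms is not).

## Numerical choices and degenerate inputs

- No continuity correction in any 2×2 test; the noncentrality theory
  assumes the plain Pearson statistic.
- CSV I/O is comma-separated UTF-8 with a header; floats are written at
  full precision and parsed with round-trip precision so write-then-read is
  bit-exact.
- Incomplete strata (fewer than 12 months) are an input error, never
  zero-filled; duplicate (label, year, sex, month) rows are rejected.
- Zero-margin months in one-vs-rest tests are flagged untestable rather
  than dropped; zero combined-count months abort pairwise comparisons.
- Probability inputs to noncentrality formulas must lie strictly inside
  (0, 1); degenerate mixtures (all-zero weights) are rejected.
- Test sizes were chosen to keep the full suite fast while leaving
  Monte-Carlo margins at 3–3.5 standard errors: 20,000 replicates for
  study-level rates, 50,000 for the noncentrality oracle, 1,500 tables for
  null-calibration KS tests, 120–500 replicates for likelihood-ratio power
  and calibration.

## Known limitations

- The multinomial logit treats strata as independent multinomials; real
  registries have extra-multinomial variation the model will call
  significant at large n.
- The analytic "overall" combination assumes independence across months and
  is only an approximation to the joint law; the Monte Carlo path is the
  reference.
- Pairwise comparisons are per year-pair; pooling multiple years per
  population before testing is a user decision, not automated.
- The stratification example works entirely at allele-frequency level;
  genotype-level simulation, ancestry inference and structure correction
  are out of scope.
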