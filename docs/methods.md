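# Methods

## Concentration models

Monitoring records arrive as one row per (zone, date, analyte) with a
concentration in μg/L, a below-LOD flag with the detection limit, and —
for HAA samples — water-chemistry covariates (conductivity, temperature,
TOC, total chlorine). Censored values are substituted at LOD/2 before any
fitting; substitution never touches detected values and never exceeds the
LOD. Bromoform is too heavily censored to model alone, so the three
brominated species are summed per sample into THMBr and the total is
modelled.

**THMs.** Log concentration is regressed on a spline in month-of-year, a
calendar-year factor and a WSZ factor. The spline is a natural cubic
basis (patsy `cr`) with 4 degrees of freedom by default, centred so it is
orthogonal to the intercept; a cyclic basis (`cc`) is available via
`cyclic=True` for users who want December–January continuity — the
default is non-cyclic because the year factor already absorbs level
shifts between years. Predictions are back-transformed by exponentiation
with no smearing correction by default; `smearing=True` applies Duan's
factor (log models) or adds the mean squared residual (square-root
models). With residual log-scale SDs around 0.1 the naive/smearing gap is
under one percent, well inside the uncertainty of the surfaces.

**HAAs.** DCAA and TCAA are modelled on the square-root scale and BDCAA
on the log scale, each with a WSZ factor, a 3-df natural spline on
continuous quarter index, and a fixed analyte-specific covariate set
(conductivity for all three; temperature for DCAA and TCAA; TOC for TCAA;
total chlorine for BDCAA). Covariate selection is *not* re-run — the sets
are part of the model definition. Covariates are standardised to the
observed mean/SD. The frequentist mode is a complete-case OLS fit used
for checking; the Bayesian mode is a conjugate Gibbs sampler:

* β ~ N(0, 10² I) on the standardised design, σ² ~ InvGamma(2, 0.5);
* missing standardised covariate entries get a N(0, 1) prior and are
  sampled from their exact normal full conditionals each sweep, so
  parameter uncertainty and imputation uncertainty propagate into the
  surface;
* 4 chains × (500 burn-in + 1,000 kept) draws by default; convergence is
  declared when split-R-hat < 1.05 on every coefficient (configurable;
  non-convergence raises, or flags when `raise_on_nonconvergence=False`).

Surfaces are the posterior mean of the back-transformed cell prediction
(which also handles transform bias exactly for the Bayesian mode), with
the posterior SD as the uncertainty column. Grid cells excluded from
training (for example a quarter whose laboratory data were judged
unreliable) are refilled by prediction and flagged `gap_filled`;
extrapolation is allowed at most one grid step beyond the training window
and flagged `extrapolated`. Cell covariates for prediction come from a
per-zone/quarter climatology of the observed covariates, falling back to
quarter-of-year and overall means.

## Exposure metrics

Windows are defined in gestational days with day 1 the first day of
pregnancy: trimester 1 = days 1–93, trimester 2 = 94–186, trimester 3 =
187 to the day preceding delivery, which is also the end of the whole
window. Cell weights are day-count overlaps divided by window length;
they are computed in closed form from period boundaries and verified
against a day-by-day oracle to 1e-9. A woman with an assigned workplace
zone receives 72/112 residence + 40/112 workplace concentration (8 h at
work, 5 days per week, of a 112-hour waking week); without one, residence
only. A window that leaves the surface's coverage yields a missing
metric, never a zero — in practice this affects HAA metrics for
pregnancies that begin before the HAA modelling window.

Ingestion multiplies the TWA concentration by drink volumes with
class-specific modifiers: hot beverages (tea + coffee) carry the boiling
adjustment, the tap component of cold tap water carries the filtering
adjustment when a home filter is reported, squash is always unfiltered,
and bottled water contributes nothing. Integrated uptake converts
ingestion and activity minutes (divided by 7 to a daily basis) into blood
dose via pathway × analyte uptake factors; swimming uses configured pool
concentrations rather than tap water. The numeric uptake factors are
study inputs derived from biomonitoring literature that cannot be
reproduced here; the shipped defaults are synthetic placeholder
magnitudes (ingestion 0.003 per (μg/L)·L; shower/bath/swim of order
0.001 per (μg/L)·min; pool TTHM 35 μg/L apportioned by typical tap
proportions) chosen once to land integrated uptake in the low-μg/day
range. Every factor table carries a provenance string and can be loaded
from YAML. Because tertile coding is invariant to monotone rescaling,
effect estimation downstream does not depend on these magnitudes.

Tertile cutpoints are computed on the analysis population; intervals are
closed below and open above except the top category (matching "≥ cut"
notation). Fixed questionnaire schemes (cold-tap volume, shower and bath
minutes, swimming yes/no) use the published bin edges with cuts placed
between questionnaire levels. Missing values get missing codes, never a
bin. Spearman correlations between metrics are pairwise-complete with a
3-pair minimum; constant metrics yield NaN.

## Cohort

The eligibility cascade is order-dependent and fixed: singleton births;
one pregnancy per mother, chosen uniformly at random with a caller-supplied
seed (mothers are visited in sorted order so the run is bit-reproducible);
water-use questionnaire present; THM exposure computable for all
trimesters (operationalised as every trimester window inside the THM
surface); birth weight recorded; term delivery at ≥ 37 completed weeks.
Each stage logs exclusions and remaining counts. Complete-case filtering
is a separate step parameterised by the covariate list of the model being
fitted, and reports per-covariate missingness; no imputation of cohort
covariates is performed.

## Regression

Ordinary least squares on continuous term birth weight, with exposure as
one or two categorical tertile factors (reference = lowest) and an
a-priori adjustment set: caffeine (≥ 200 mg/day), education (5 levels),
fasting and post-load glucose, ethnicity, smoking (3 levels), parity
(0/1/≥2), age, BMI quartile (computed within the analysis population),
IMD quintile, gestational age (linear + quadratic) and sex. Stratified
models drop the ethnicity covariate and their design matrices contain no
ethnicity columns. Confidence intervals are classical t-based Wald
intervals; no robust standard errors and no multiple-testing correction,
with two-sided α = 0.05 throughout. The overall p-value is an F-test on
the exposure factor's coefficients; the trend p-value refits the model
with tertiles coded 0/1/2 as a continuous term (a separate refit, not a
contrast within the factor); the interaction p-value is a joint F-test on
all exposure × ethnicity product terms and is defined only in
total-population models. Rank-deficient designs raise an error naming the
aliased columns. A configurable floor (default 20 observations per
exposure level) guards against degenerate tertiles.

## Synthetic data

The generator emulates the study conditions the pipeline assumes: 8 WSZs;
THMs sampled ~9 times/zone/year over 2006-01–2011-03; HAAs quarterly over
2007Q2–2010Q4; THM species log-normal around means of 37.8/6.6/0.9/0.3
μg/L (chloroform/BDCM/DBCM/bromoform, TTHM their sample-level sum ≈ 45.6)
with shared zone offsets (log-scale SD 0.08), a seasonal sinusoid
(amplitude 0.15) and residual SD 0.15; HAAs around 8.9/12.5/1.3 μg/L
(DCAA/TCAA/BDCAA) with the stated covariate dependencies on the model's
transformed scale and 10% missing covariates. Bromoform's LOD (0.5 μg/L)
censors most of its record, which is why THMBr exists.

The cohort generator draws a 40/45/15 white British/Pakistani-origin/other
mix with ethnicity-conditional water use (population-mean targets: total
tap 1.84 vs 1.51 L/day; doer-conditional bathing 151 vs 96 and showering
86 vs 94 min/week; swimming participation 14% vs 2%), employment (64% vs
23%), smoking, caffeine, glucose, parity, education and deprivation
distributions, conception dates spanning mid-2006 to mid-2010, repeated
pregnancies and missingness rates set so the eligibility cascade removes
proportions close to the reference cascade. Gamma distributions model volumes
and minutes, Bernoulli draws participation — invented forms with every
parameter exposed on `ScenarioConfig`. A separate deterministic fixture
(`exact_cascade_fixture`) reproduces the reference cascade counts exactly:
duplicate-pregnancy mothers are given two fully eligible records each so
the one-per-mother stage removes a fixed count whichever member is kept.

Outcomes are linear: an ethnicity baseline (3,424 / 3,186 / 3,280 g) plus
invented but realistically sized covariate effects (e.g. +130 g male sex,
−160 g current smoking, +135 g per gestational week near term) plus the
configured per-tertile exposure effect plus N(0, 450²) noise. What the
generator does *not* emulate: residential mobility, within-woman
correlation between consumption and bathing (independent by default),
spatial structure beyond exchangeable zone offsets, measurement error in
questionnaires, and non-normal birth-weight tails. Passing tests
therefore demonstrate that the pipeline recovers known structure of this
form without bias — not that the uptake-factor magnitudes or any
particular epidemiological estimate generalise to real cohorts.

## Validation choices and problem sizes

Monte Carlo recovery uses strata of n = 3,298 (single-exposure THM
protocols) and n = 2,916 (joint and concentration protocols) with 100
replicates per protocol — the analysis-population stratum sizes the
models are meant for. Coverage of the generating effect by 95% CIs is
asserted at ≥ 90%; the mean recovered estimate is additionally checked
against the truth within four Monte Carlo standard errors of the mean,
a z-type bound whose false-alarm rate is known, in preference to a fixed
fraction of the per-fit standard error, which at 100–200 replicates would
be of the same order as the Monte Carlo noise itself. Type-I error of the
overall, trend and interaction tests is estimated from 1,000 seeded null
replicates at modest stratum sizes (n = 240 single-stratum, 150 + 150
two-ethnicity) — exact F-tests under the generator's truly normal errors,
so size does not depend on n — and asserted within 5% ± 1.5%.

## Known limitations

* The Gibbs sampler's covariate imputation assumes standardised-normal
  marginals and missingness at random; structured missingness would need
  a richer imputation model.
* Frequentist square-root back-transform can in principle go negative at
  extreme extrapolation; transformed-scale predictions are floored at
  1e-6 (surfaces are strictly positive by construction).
* Workplace exposure uses a fixed 40/112 weighting; actual occupancy
  schedules are not modelled.
* `build_exposure_table` iterates pregnancies in Python; at ~10⁴
  pregnancies × 4 windows expect about a minute, which is acceptable for
  cohort-scale analyses but not for much larger registries.
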