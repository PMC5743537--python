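# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, and what the synthetic data do and do not
establish.

## Thermal sums and the spring indicator

Degree days are truncated at the day level, `DD = max(Tmean − Tbase, 0)`,
and accumulated from January 1; a cold day contributes nothing rather than
cancelling accrued warmth.  Feb 29 is an ordinary accumulation day.  Missing
climate days are linearly interpolated across gaps of at most 3 days
(precipitation filled with zero); longer gaps are an error — interpolation
preserves cumulative sums with minimal modelling, and the 3-day cap keeps
the filled values local.

The indicator grid spans base temperatures −5…+10 °C in 1 °C steps
(configurable; only the range is externally fixed) and thresholds in steps
of 100 DD.  Per base temperature the threshold ceiling is the minimum over
years of the thermal sum at that year's latest first-clutch lay date,
floored to the step — this guarantees every retained candidate crosses its
threshold in every year.  Candidates that miss a year, cover fewer than 3
years, or have zero predictor variance are excluded, not imputed.  Ties on
R² (to 12 decimals) are broken deterministically: higher base temperature,
then lower threshold; ties are recorded in the grid report.

**Identifiability caveat.**  Crossing dates of neighbouring candidates are
near-collinear (correlations 0.86–0.96 across years on the synthetic
climate).  At the calibrated fit quality (R² ≈ 0.78 with 20 years) the
sample argmax over ~50–100 candidates therefore identifies the generating
candidate only ~55% of the time, though the winner is almost always an
immediate neighbour and the downstream tracking slope and matching measures
are insensitive to which near-collinear candidate wins.  Exact grid
identification should not be expected from 20 annual observations.

## Matching measures

Annual matching is computed on first nest attempts as (a) median lay date
minus the indicator's crossing date, in days, positive when breeding lags
thermal spring, and (b) the median individual thermal sum at lay and at
hatch (base 3 °C by default).  Unobserved hatch dates are derived as
`lay + (clutch − 1) + 13` (one egg per day, 13-day incubation from the last
egg; both constants configurable — a standard passerine schedule).  Medians
use the **lower median** for even n, keeping annual medians on observed
dates; this is configurable and documented because the even-n rule affects
integer day-differences.  The two measures are cross-validated by their
Pearson correlation with t on n−2 df.

## Within-season selection and weighted trends

Per-year GLMs regress each rate on relative lay date (days since the year's
earliest clutch), so the intercept is the fitted earliest-breeder
performance.  Fits use first attempts and keep nests failed after hatching
(failure can reflect food shortage) while excluding nests failed before
hatching (predation-dominated).  Families are the canonical choices per
response type — binomial/logit (nest success, adult survival), Poisson/log
(fledglings, recruits), Gaussian/identity (nestling weight, record-level
with nestling age and brood size in the covariate set) — configurable since
the slope scale alone cannot disambiguate them.  Years with fewer than 5
usable records, constant responses/predictors, separation or
non-convergence are flagged and excluded from trend regressions, and the
exclusions logged.

Trend meta-regressions weight each year's slope by **1/SE** — literal
inverse-SE, reflecting sample-size-related uncertainty — not inverse
variance; `1/SE²` is available as a sensitivity switch and its use is
flagged in the report.  With equal SEs the fit reduces to OLS exactly.  A
linear-vs-quadratic AIC check per year is informational only; the pipeline
always uses linear slopes.

## Mixed models

Two model shapes: *trend* (`rate ~ year + lay date + female age + rain days
+ density + field layer`, plus nest success for adult survival and nestling
age + brood size for weight) and *matching* (annual median thermal sum at
hatching as focal predictor; individual thermal sum replacing lay date) —
both with crossed random intercepts for year, territory and individual
(male identity for male survival).  Density is the yearly count of breeding
attempts, centered; continuous covariates are centered so intercepts sit at
sample means.

Estimation is by maximum likelihood (not REML) so likelihood-ratio tests on
fixed effects are valid; REML is available for variance reporting.  The
Gaussian model profiles out fixed effects and the residual variance,
leaving a ≤3-dimensional optimization over log variance ratios; the
likelihood is evaluated through the q×q system `Z'Z + Γ⁻¹` (q = total
random-effect levels), dense Cholesky below 250 levels and sparse LU above.
It reproduces `lmer(…, REML=FALSE)` log-likelihoods to ~1e-4 on test
fixtures.  Binomial and Poisson responses use the Laplace approximation
with the joint (β, u) mode found by penalized IRLS — the fast variant that
corresponds to lme4's `nAGQ=0`; fixed effects agree with `glmer(nAGQ=0)` to
~1e-3 and differ from full Laplace (`nAGQ=1`) by a few hundredths on the
link scale, which is well below the effect sizes of interest here.
Variance parameters are bounded at `log σ² = −14`; estimates at the bound
are reported with a boundary flag (at the boundary the fit coincides with
an ordinary GLM).  Log variance-ratio optimization uses bounded scalar
search (one factor) or adaptive Nelder–Mead (several factors).

LRTs report `(Δloglik, χ² = 2Δloglik, df, p)` with df the fixed-parameter
difference; the χ² identity is structural.  Simulated at n = 400 with 20
groups, the df = 1 LRT's type-I error at α = 0.05 is 0.052 (1000 nulls);
at small n (150) it is anticonservative (~0.07), the known finite-sample
behaviour of fixed-effect LRTs in mixed models.

Marginal/conditional R² partition variance as
`var(Xβ) / (var(Xβ) + Σσ²_random + σ²_dist)`, with the conditional version
adding `Σσ²_random` to the numerator.  The distribution-specific variance
is the residual variance (Gaussian), π²/3 (binomial logit), or the trigamma
function at the expected marginal rate λ̄ = exp(mean(Xβ) + ½Σσ²_random)
(Poisson log) — a variance-partition choice made here, since several
conventions exist for the Poisson term.

Prediction bands are a seeded parametric bootstrap (default B = 1000):
draw β* from N(β̂, V̂), redraw random intercepts and family noise, refit,
predict the fixed-effect curve on the focal grid with other covariates at
sample means, and take pointwise 2.5/50/97.5 percentiles.  Failed refits
are skipped; more than 20% failures abort.  Bit-compatibility with any
particular external bootstrap helper is not a goal.

## Synthetic data: what it emulates, and what passing tests do not show

The climate generator is a seasonal sinusoid (annual mean 6.5 °C, half
amplitude 11 °C, coldest day Jan 15 — boreal-Sweden-like) plus linear
warming (default 0.10 °C/yr, chosen so the 200-DD/3 °C crossing advances
~0.6 d/yr, matching the study site's observed spring advance) and AR(1)
anomalies (ρ = 0.7, SD 3 °C); rain is Bernoulli(0.35)/day.  The population
generator hard-wires the spring driver to (3 °C, 200 DD) so recovery tests
have a known truth, and draws yearly median lay dates as
`80 + 0.424·(spring day-of-year) + N(0, 1.2 d)` — the noise SD calibrated
once so the lay-on-spring regression attains R² ≈ 0.78 with a slope SE of
≈0.05 at 20 years, the fit quality the analysis assumes.  Individuals lay
N(median, 4 d); clutch sizes are uniform on {5, 6, 7} (no external
distribution to anchor); 15% of nests fail before hatching and are excluded
downstream; territories come from a pool ~1.3× the yearly pair count with
reuse across years, and females/males persist with probability equal to
their generated survival, creating realistic crossed random-effect sharing.

Demographic outcomes are drawn on canonical link scales with year trends at
the study's reported magnitudes (e.g. nestling weight −0.130 g/yr, nest
success −0.088 logit/yr), seasonal slopes giving a distinct early-breeding
advantage in the first year, covariate effects (field layer, female age,
rain, density) at reported magnitudes, and independent per-rate random
intercepts.  Fledglings are clutch-limited (1 + Binomial(clutch−1, p)) and
recruits fledgling-limited (Binomial(fledglings, p)), which guarantees the
recruits ≤ fledglings invariant; the recruit logit trend (−0.077/yr) was
chosen so the implied log-count trend approximates the reported −0.082/yr.
Scenarios: `deterioration` re-expresses the declines as early-breeder
deterioration (intercepts fall, performance at relative lay date 25 d is
held, so slopes flatten and correlate negatively with intercepts);
`mismatch_trend` zeroes the year trends and makes rates fall with the
individual thermal sum at hatching instead.

Because warming makes the annual median thermal sum co-trend with year
(~+4 DD/yr against ~50 DD of interannual weather noise), a small fraction
of a planted year trend leaks into matching-focal models even when no
matching effect exists: on nestling weight the leakage is ≈ −0.01 g per
degree-day (roughly a quarter of the planted decline), small but
statistically detectable at nestling-level precision.  Exact zero-centering
of matching-focal estimates under deterioration is therefore not attainable
under warming — the dissociation holds as a strong contrast in magnitude
and significance, not as an exact zero.

The generator omits food-abundance dynamics, renesting/second broods,
spatial structure, dispersal and observation error in dates.  Passing
recovery tests therefore demonstrate estimator correctness and calibration
under the assumed generative structure, not that the structure itself is
the right model of any field system.

## Problem sizes

Default synthetic datasets are 20 years × ~90 pairs (~1,700 nests, ~6,000
nestling weights), matching the study scale.  Recovery and calibration
suites use 100 phenology replicates, 3–4 full-population replicates per
scenario, and 1000 null simulations for LRT calibration; these sizes put
Monte-Carlo error comfortably below the tolerances asserted.
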