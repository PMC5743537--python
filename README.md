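# wheatear-phenology

Analysis pipeline linking the **thermal progression of spring** to the
breeding phenology, within-season selection for breeding time, and annual
demographic rates of a northern wheatear (*Oenanthe oenanthe*) population —
with a synthetic-data generator that stands in for the long-term field data,
so every stage is testable against known truth.

## The science in brief

Arthropod development is driven by accumulated warmth, so thermal spring is
indexed by the **thermal sum**

> TS(d) = Σ<sub>day ≤ d</sub> max(T<sub>mean</sub> − T<sub>base</sub>, 0),  accumulated from January 1,

and the date on which TS first reaches a critical threshold is an indicator
of how far spring has progressed.  The pipeline:

1. **Spring indicator** (`spring`) — grid search over base temperatures
   (−5…+10 °C) and thresholds (steps of 100 DD, capped by the thermal sum at
   the end of egg laying); the (T_base, threshold) pair whose annual
   crossing dates best predict annual median lay dates (largest R²) wins.
2. **Phenological matching** (`matching`) — two annual measures: median lay
   date minus spring date (days; positive = breeding after thermal spring),
   and the median of individual thermal sums at lay/hatch (degree-days), plus
   their Pearson correlation.
3. **Selection for breeding time** (`selection`) — per-year GLM slopes of
   each demographic rate on *relative lay date* (days since the year's first
   clutch; the intercept is the earliest breeder's performance), then
   weighted regressions of annual slopes on year and on annual matching with
   weights **1/SE** (sample-size-related uncertainty).
4. **Demographic GLMMs** (`mixed`, engine in `glmm`) — crossed
   year/territory/individual random-intercept models, Gaussian by exact
   profiled ML and binomial/Poisson by Laplace approximation, with
   likelihood-ratio tests (χ² = 2·Δloglik), marginal/conditional R² by
   variance partition, and seeded parametric-bootstrap prediction bands.
5. **Synthetic data** (`simulate`) — a warming AR(1)+sinusoid daily climate
   and a breeding population whose median lay dates track an internal
   (3 °C, 200 DD) spring driver with slope 0.424, under three scenarios:
   `baseline`, `deterioration` (declines driven by failing early-breeder
   performance; no matching dependence) and `mismatch_trend` (declines
   driven by breeding at ever higher thermal sums).

The analysis-level question the scenarios encode: correlated 20-year trends
in matching, selection and demography do **not** establish that mismatch
drives demography — year-focal models must find the trends while
matching-focal models find nothing unless a matching effect truly exists.

## Worked example

```bash
python analysis/01_simulate_dataset.py --seed 0     # writes results/data/
python analysis/02_derive_spring_indicator.py
python analysis/03_annual_matching.py
python analysis/04_selection_trends.py
python analysis/05_demographic_glmms.py
python analysis/06_decline_endpoints.py
```

Step 02 prints (seed 0):

```
51 valid candidates scanned
winner: T_base=2 °C, threshold=300 DD — median lay = 78.2 + 0.417·(crossing date), R²=0.789, slope SE 0.051 over 20 years
```

The planted driver is (3 °C, 200 DD); at the calibrated noise level
(R² ≈ 0.78) the search lands on a *neighbouring, nearly collinear*
candidate here — crossing dates of adjacent grid candidates correlate at
0.86–0.96, so the identity of the argmax is fragile even though the
recovered tracking slope (0.417 ± 0.051 vs the planted 0.424) and fit
quality are solid.  Step 03 then reports the two matching measures agreeing
at r = 0.973, and step 05 prints the central dissociation on baseline data:

```
rate             focal        estimate       se    R²m    R²c
nestling_weight  year          -0.1548   0.0179  0.682  0.793
nestling_weight  median_ts     -0.0027   0.0035  0.590  0.792
nest_success     year          -0.0972   0.0147  0.135  0.166
nest_success     median_ts     +0.0017   0.0025  0.084  0.151
...
```

Year trends are strong and negative (the planted decline), while the
matching-focal estimates sit near zero — the signature separating
environmental deterioration from thermal mismatch.  Step 06 closes the loop
on the decline arithmetic: the reported endpoint predictions for the
original population give reductions of 23% (nest success), 16% (nestling
weight), 33% (fledglings) and 79% (recruits), and the GLMMs refitted to the
synthetic data reproduce the same magnitudes (27.7/17.6/36.6/87.5% at
seed 0).

A `wheatear` CLI wraps the same steps (`wheatear simulate`, `wheatear
run-all`, …) for file-driven runs.

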