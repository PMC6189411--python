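# Methods

## The model

`conjmlm` implements a two-stage ("multi-level") regression of weekly
conjunctivitis outpatient rates on ambient ozone and meteorology, as used
in environmental epidemiology when a health outcome is modelled per
population stratum and the stratum coefficients are in turn modelled over
the stratifying variables.

**Level 1.** The response is the weekly outpatient rate y = count /
population for one (sex, age-group) stratum or for the pooled
population. The predictors are weekly means transformed as

- x₁ = temperature + 20 (°C) — the offset keeps Korean winter
  temperatures positive so that ln x₁ is defined,
- x₂ = relative humidity (%),
- x₃ = O₃ (ppm).

Three families are fitted by ordinary least squares and compared:

- M1 (linear): y = β₀ + β₁₁x₁ + β₂₁x₂ + β₃₁x₃ + ε
- M2 (linear + log): adds β₁₂ ln x₁ + β₂₂ ln x₂ + β₃₂ ln x₃
- M3 (linear + exp): adds β₁₂ eˣ¹ + β₂₂ eˣ² + β₃₂ eˣ³

Model validation follows a 1-in-3 hold-out: within every consecutive
block of three weeks one uniformly random week is reserved for the
out-of-sample test (52 of 156 weeks), the rest for fitting. A family
that is best on both in-sample adjusted R² and out-of-sample R² is
selected; absent a dominator the out-of-sample R² decides, and exact
ties go to the family with fewer terms. Candidate predictors are first
screened by the sign of their Pearson correlation with the response
(only positively correlated series are kept, mirroring the removal of
PM₁₀, NO₂ and SO₂ in the original screening).

**Level 2.** The chosen family is refitted separately in each of the 18
(sex ∈ {0 male, 1 female}) × (age group 1–9, decades) strata. Each
level-1 coefficient β is then regressed on sex and age across strata,
with the age code (1–9) entering directly, as ln(age), or as exp(age):

    β(sex, age) = c₀ + c₁·sex + c₂·f(age) + c₃·sex·f(age),
      f ∈ {identity, ln, exp}

chosen by highest plain R² (ties prefer identity, then ln, then exp).
The intercept β₀ uses the full form with all three age transforms where
the block has enough strata. Two composite models are assembled by age
block — ages 1–2 and ages 3–7 — because the age effect changes character
around the third decade; age groups 8–9 are excluded. The ages-1-2
block has four strata and four-parameter forms, so its second-level fits
are saturated: they interpolate the stratum coefficients exactly and the
composite prediction coincides with the stratum-wise fit.

## Numerical choices

- OLS goes through statsmodels on a **column-equilibrated** design (each
  column scaled to unit norm, an exact reparameterization). This matters
  for the exp family, where eˣ² ≈ e⁵⁸ mixes column scales by ~25 orders
  of magnitude and defeats any rank test or pseudo-inverse cutoff that is
  relative to the largest singular value. The condition number of the
  equilibrated design is recorded on every fit; rank deficiency raises an
  error naming the collinear columns.
- Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p) with the intercept counted in
  p; the overall F test has (p − 1, n − p) degrees of freedom. All
  logarithms are natural.
- Out-of-sample R² centres the total sum of squares on the test-set mean
  by default; centring on the training mean is available as an option
  (`center="train"`), since either convention is defensible.
- Second-level fits are unweighted OLS on the point estimates (no
  propagation of level-1 standard errors). A saturated second-level fit
  reports R² = 1 by convention, as does a constant-β block (where SST is
  zero up to round-off).
- Predicted rates are floored at 1e−8 before count generation: fitted
  linear models can go negative at extreme inputs and a count mean must
  stay positive.
- Published coefficients are stored as the printed decimal strings and
  parsed once; the 2-significant-figure comparisons use round-half-even
  on the mantissa, matching the tables' print format.

## The synthetic-data generator

The original registry (Korean health-insurance claims) and the Seoul
monitoring-network series are not publicly deposited, so the generator
emulates the study conditions:

- **Environment**: each variable is mean + amplitude·sin(2πw/52 + φ) +
  Gaussian noise, with week 0 at the seasonal minimum (January).
  Defaults: temperature 12.34 ± 12.5 °C (study-period mean; the swing
  brackets the reported quarterly extremes of −0.8 and 24.7 °C), relative
  humidity 58.5 ± 9.75 %, O₃ 0.018 ± 0.012 ppm. The reported seasonal O₃
  figures are internally inconsistent (quarterly averages of 0.12–0.27
  ppm versus a 156-week average of 0.018 ppm, a factor of ~10 that looks
  like a pphm/ppm unit slip); the generator follows the 0.018 ppm average
  and a 0.005–0.04 ppm regime, and both are configurable.
- **Counts**: expected rate μ from a truth model — by default the
  published per-stratum coefficient table, optionally the published
  composite — floored and scaled by the stratum population (default
  5·10⁵, Seoul-like for a sex × decade cell). `poisson` draws Poisson
  counts, with a mean-one gamma multiplier when `rate_noise` > 0
  (negative-binomial-style overdispersion, default 5 %);
  `rounded-gaussian` rounds mean·(1 + rate_noise·z), so zero noise gives
  exactly round(mean). One integer seed spawns two independent
  substreams (environment, counts), so changing count noise never
  perturbs the weather series.

What the generator does **not** emulate: spatial structure across
monitoring sites, weekday/weekend patterns (the weekly averaging already
removes them), serial correlation of the health series beyond what the
seasonal predictors induce, and epidemic conjunctivitis outbreaks.
Passing tests therefore show that the pipeline recovers models of the
assumed form under seasonal forcing and count noise — not that the
published model is correct for real registry data.

## Sensitivity of the composite stage

A property worth knowing: within a stratum, x and ln x (and x and eˣ)
are strongly collinear over the observed seasonal range, so the level-1
coefficient estimates have large, strongly anti-correlated errors that
cancel in the stratum's own predictions. The second stage smooths each
coefficient **independently** over (sex, age), which destroys that
cancellation. With registry-scale counts (~10–100 per stratum-week at
the default populations), the ages-3-7 composite's pooled R² collapses
below zero already at ~2 % relative count noise, even when the truth is
the published composite itself. The saturated ages-1-2 block is immune
(it reproduces the stratum fits exactly). Validation of the composite
stage is therefore run at a low-noise regime — stratum populations
5·10⁶ with 0.5 % rounded-Gaussian count noise, truth = published
composite — where the two-stage smoothing is the dominant error source;
there the wide block reaches R² ≈ 0.8–0.98 and recovers toward 1 as the
noise shrinks. This is a limitation of the two-stage procedure itself,
not of the implementation, and it suggests the original per-stratum
coefficients carry substantial sampling noise.

## Reconstruction of the per-stratum table

Because the ages-1-2 second-level fits are saturated, evaluating the
printed g-functions at the four strata must reproduce the printed
per-stratum coefficients. At two significant figures, 25 of the 28
cells do. The three exceptions are informative: the intercept at
(sex=0, age=1) prints −2.0E−05 where the printed g₀ implies −2.4E−05 — a
genuine inconsistency between the two published tables — and the two
β₃₂ cells at age 2 are near-total cancellations (terms of order 1e−5
summing to ~1e−7) that the four-significant-figure printed g₃₂
coefficients cannot resolve; their reconstruction errors are below half
a unit in the last printed digit of the block's coarsest β₃₂ cell.

## Problem sizes

Defaults mirror the study: 156 weeks (three years), 52-week seasonal
period, 18 strata, 104 training / 52 test weeks. Simulation-based
checks use 50 seeds for coefficient recovery and family selection,
10 000 seeds for the split-position frequencies, and 2 000 replicates
for the F-test calibration; these sizes put Monte-Carlo standard errors
comfortably below the margins being asserted.

## Known limitations

- Plain OLS throughout: no autocorrelation correction,
  heteroscedasticity-robust errors, or regularization (matching the
  original procedure).
- The exp family is evaluable but numerically delicate; its printed
  coefficients (e.g. −4.7E−45 for the eˣ² term) are only plausible on
  the raw predictor scale, which is what the implementation uses.
- Ages 8–9 have no second-level model; requesting them from the
  composite is an explicit error rather than an extrapolation.
- The level-2 stage reuses the single level-1 train/test split; the
  original report does not say whether the stratum fits used their own.
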