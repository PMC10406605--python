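# Methods

This note documents the models and procedures implemented in `resptemp`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## 1. Arrhenius model and pooled estimator

Ecosystem respiration is modelled as

R_E(T) = R_E,ref · exp[−(E_a / k_B)(1/T − 1/T_ref)],

with E_a in eV, R_E,ref in μmol m⁻² s⁻¹ at T_ref = 283.15 K, and
k_B = 8.617333262 × 10⁻⁵ eV K⁻¹. Both T_ref and k_B are fixed constants of
the analysis and may not be overridden on `ArrheniusParams`.

Estimation is by OLS of ln R_E on x = (1/T − 1/T_ref), pooled over every
retained grid-cell month of the domain. Pooling space and time into one
regression ("space for time") assumes a single climatological sensitivity
per domain over the study window; it deliberately absorbs indirect
temperature pathways (moisture, phenology, substrate supply) into the
apparent E_a, which is what a biome-scale sensitivity means here. The
regression is unweighted by default — every valid cell-month counts
equally; an area-weighting argument exists for sensitivity analyses but is
off by default. No low- or high-temperature breakpoints are applied to the
response.

**Flux filter.** R_E values that are negative or close to zero are removed
before taking logs. "Close to zero" is `eps = 0.01` μmol m⁻² s⁻¹ by
default — about 1% of a typical baseline rate, small enough to only drop
cell-months whose log would be unstable — and is configurable everywhere it
appears. Filter counts (`n_used`, `n_filtered`) are carried on the fit.

**Q₁₀ conversion.** Linearising ln R_E in T gives the apparent
Q₁₀(E_a, T) = exp(E_a ΔT₁₀ / (k_B T²)) with ΔT₁₀ = 10 K, evaluated at
T = 283.15 K unless stated. Report tables round Q₁₀ to one decimal,
half-up (`Q10Value.rounded`). The conversion and its inverse round-trip to
machine precision; both are strictly monotone (increasing in E_a,
decreasing in T).

## 2. Transport operator and observation model

A footprint operator H is a sparse non-negative matrix mapping cell-month
fluxes (μmol m⁻² s⁻¹) to per-observation CO₂ signals (ppm):
signal = H · flux.ravel(). Linearity and entry-order invariance are exact
and tested against a brute-force triple-loop oracle.

Observations carry raw, background and fossil mixing ratios; the
biospheric signal is defined as their exact difference. GPP is stored as a
positive uptake magnitude, so NEE = R_E − GPP, and the **respiratory
component** of observed variability is

y_resp = (raw − background − fossil) + H(GPP),

which equals H(R_E) plus observation noise when the GPP field used is the
one that generated the observations. In all per-model analyses each
model's *own* GPP forms y_resp, so GPP bias propagates consistently.

**Explanatory power.** R² is the squared Pearson correlation between a
transported signal and the biospheric reference. The correlation form
(rather than 1 − RSS/TSS) is deliberate: GPP alone is sign-opposed to CO₂
enhancement and shortwave radiation has different units, so only a sign-
and scale-invariant definition lets both act as explainers. The
regression-based R² is available via `method="regression"` for comparison.
The **SW gate** transports the shortwave field through H as a pseudo-flux
and computes its R²; models whose GPP does not exceed this benchmark are
excluded from ensemble synthesis. A constant radiation field is rejected
as carrying no variability. An optional z-score outlier filter on the
biospheric signal exists for screening gross model–data mismatches; it is
off in every default path and never asserted on.

## 3. Adjustment optimization

The per-model, per-domain adjustment is

R_E* = R_E · α · exp[−(ΔE_a / k_B)(1/T − 1/T_ref)], α > 0,

applied inside the domain mask only; outside cells keep their original
respiration, and all observations enter the objective through their
partial footprint sensitivities. (ΔE_a, α) minimise the unweighted sum of
squared ppm residuals between H(R_E*) and y_resp. Choices:

- solved over (ΔE_a, ln α), keeping α positive without constraints;
- three starts, ΔE_a ∈ {−0.3, 0, +0.3} eV, to avoid local minima; the
  best-cost solution is kept, so the optimum never exceeds the (0, 1)
  objective;
- Levenberg–Marquardt with ftol/xtol/gtol at 1e-12;
- asymptotic standard errors from the Jacobian at the optimum, with the α
  error delta-method-propagated from ln α;
- per-site inverse-variance weighting is available behind a `weights`
  argument, off by default;
- fewer than 10 observations, or a domain with zero footprint coverage, is
  an error; non-convergence is flagged on the result, not raised.

Whether a per-biome optimization should transport only biome-restricted
fluxes or hold the residual domain fixed was an open design point; holding
out-of-domain cells at their original values keeps the objective
well-posed and uses the cross-biome information in every observation, and
is what is implemented.

## 4. Ensemble synthesis

Across models the fitted (E_a, ΔE_a) pairs are regressed with orthogonal
distance regression (SciPy's ODR), with the error-variance ratio fixed at
1 since nothing more specific is known about the two axes' errors. The
ensemble optimum is the zero crossing Ê_a,opt = −a/b of the line
ΔE_a = a + b·E_a; its 1σ comes from the delta method on the (a, b)
covariance including their correlation. A slope smaller than 1e-3 in
magnitude leaves the crossing unidentifiable and raises an error rather
than returning an unstable estimate. SW-gated models are removed *before*
the fit; their ids are carried on the result as provenance only and cannot
influence the numbers.

**Prediction interval.** The band at query x combines the parameter
covariance (a + b·x variance) with the residual variance (vertical
residuals, n − 2 dof) under a Student-t quantile. Its empirical coverage
is tested against fresh points drawn from the same errors-in-both-axes
process, whose vertical deviation from the line has variance
σ_y² + b²σ_x² — exactly the residual variance the band uses. (A
*prediction* band checked against the noise-free line would systematically
over-cover; the point-coverage check is the meaningful calibration.)

**Z tests.** One-tailed Z tests compare an estimate against a reference
value (the 0.65 eV plot-scale sensitivity by default), with
z = (null − estimate)/se and p the upper-tail normal probability. p-values
are always computed from unrounded estimates.

## 5. Respiration correction

Two modes:

- **model-specific**: apply each model's own (ΔE_a, α) per domain; α
  carries the magnitude correction, so no renormalisation. Domains must be
  disjoint; unadjusted domains pass through.
- **ensemble-optimum**: multiply R_E by exp(−ΔE_a/(k_B T)) with
  ΔE_a = Ê_a,opt − E_a,model, rescale to conserve the mean over retained
  cell-months, cap at the original per-domain maximum within a 1% relative
  tolerance, and report the clipped fraction.

The exp(−ΔE_a/(k_B T)) form differs from the (1/T − 1/T_ref) form only by
the constant exp(ΔE_a/(k_B T_ref)), which mean conservation absorbs; the
two routes produce identical fields to 1e-10 and this equivalence is a
tested property. Mean conservation is exact (1e-12) *before* capping.
After capping, the mean drifts by the clipped excess: the drift is bounded
by the cap fraction times the mean relative excess of clipped cells, which
for strong shifts (|ΔE_a| ≳ 0.4 eV) can reach the order of the cap
fraction itself — not the 1% tolerance. The cap fraction is monotone in
the shift magnitude. Conservation and capping scope is per domain by
default, paralleling per-domain adjustment; continent-wide conservation is
a one-line variant (pass no mask).

Evaluation rebuilds NEE = R_E,corrected − GPP, transports it through the
same H against the same observations, and reports R² before/after for NEE
alongside R²_GPP, so the change is attributable to the respiration
correction alone.

## 6. Synthetic observing system

The generator emulates the statistical structure of the real inputs, not
their values. Defaults are the study conditions and are not tuned:

| parameter | default | rationale |
|---|---|---|
| grid | 20 × 40 cells, 1° | desk-scale mimic of the continental domain |
| months | 48 | four years of monthly fields |
| biomes | cropland (0.38 eV, 3.0), enf (0.50 eV, 2.0), dbf-mixed (0.53 eV, 2.6), other (0.45 eV, 1.5) | the biome-scale sensitivities the analysis is designed around; baselines are typical mid-latitude rates |
| temperature | 288 K at the southern edge, 0.6 K/° lapse, ±12 K seasonal cycle peaking in July, 0.3 K cell noise | joint space–time gradient for the pooled regression |
| baseline heterogeneity | lognormal σ = 0.10 per cell | keeps the pooled fit realistic rather than exact |
| SW / GPP | 250 W m⁻² mean, ±150 seasonal, 1.5 W m⁻²/° lapse; GPP = 0.02 · SW · greenness, off below 50 W m⁻² | radiation as the first-order GPP driver; peak GPP ≈ 6–8 μmol m⁻² s⁻¹ |
| towers | 44, uniform placement | the network size of the real constraint |
| footprints | Gaussian kernel, 2.5° decay, 3-length support, 0.05 ppm/(μmol m⁻² s⁻¹) peak, month-confined | localized decaying sensitivity at monthly resolution; biospheric signals of a few ppm |
| observations | background 400 ppm, fossil 1.5 ppm constants, i.i.d. Gaussian noise σ = 0.5 ppm | additive constants suffice since background/fossil modelling is out of scope |

Determinism: one seed drives four spawned child generators (temperature
noise, baseline heterogeneity, tower placement, observation noise), so the
deterministic climatology and biome structure are identical across seeds
while stochastic layers redraw. The same seed reproduces every output
bit-for-bit.

Pseudo-model ensembles transform the truth respiration with known
(ΔE_a, α) biases — so recovering the negated bias is an exact oracle — and
may scale GPP multiplicatively for negative controls.
`sample_observations` resamples (tower, month) rows of the base design
with replacement and fresh noise to reach arbitrary observation counts;
the real observing record likewise contains many samples per tower-month.
`simulate_ensemble_points` draws (E_a, ΔE_a) scatter directly from the
zero-crossing construction (ΔE_a = Ê_a,opt − E_a plus noise on both axes)
for replicate studies of the ensemble regression at scale.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real meteorology and its covariance with fluxes
(temperature and radiation here are independent, so radiation/moisture
confounding of the inferred sensitivity cannot arise by construction);
transport error and footprint seasonality; non-Gaussian and correlated
observation errors; model structural error beyond the two-parameter bias
family; lateral and fire fluxes; observation outliers (the optional
mismatch filter is therefore never asserted on). Recovery results on this
system validate the *inference machinery*, not the realism of any
particular sensitivity value.

## 7. Pipeline

`run_pipeline` executes simulate → fit-ea → optimize → ensemble →
rescale-evaluate → report, persisting every artifact under one directory:
gridded fields as classic NetCDF (xarray's scipy backend), footprints as
sparse tables with a JSON grid descriptor (`%.17g` floats, so the text
round-trips float64 exactly), observations and result tables as CSV, the
ensemble synthesis as JSON, plus three figures and a summary table built
from stored stage outputs without recomputation. The manifest records
stage order, durations, seed and SHA-256 checksums of all data artifacts;
a rerun with the same configuration reproduces those checksums exactly.
Figures are listed without checksums since PNG bytes are not guaranteed
stable across plotting-library versions. The default run (12 pseudo-models
with biases uniform in ±0.3 eV and baseline scales in [0.8, 1.25], four
domains) completes in a few seconds on one CPU; `scripts/acceptance.py`
runs it together with the recovery diagnostics at n = 2000 observations
and 200 replicate ensembles.

## 8. Known limitations

- The pooled estimator is consistent only under the space-for-time
  assumption; domains mixing very different baseline rates yield an
  effective continental E_a that is not the mean of the biome values.
- Per-biome adjustment holds out-of-domain bias fixed; for globally biased
  models the per-biome ΔE_a partially compensates out-of-domain error and
  is noisier than the continental estimate.
- The delta-method σ of the zero crossing is first-order; at small
  ensembles (n ≈ 20) its 2σ interval covers the true optimum slightly
  below the nominal rate (the replicate studies in the suite quantify
  this).
- Observation noise is assumed i.i.d.; the unweighted least-squares
  objective is not robust to heavy-tailed mismatch.
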