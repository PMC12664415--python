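# Methods

This note documents the models, numerical choices and limitations of
`sonoextract`. Everything quantitative stated here is computed by the test
suite or the example scripts; nothing is quoted from external measurements.

## Pseudo-second-order kinetics

The dissolution rate of extractable solute into the liquid phase is modelled
as proportional to the squared distance from saturation,

    dC/dt = k (C_s − C_t)²,  C(0) = 0,

giving C_t = C_s² k t / (1 + C_s k t). The estimator of record is the
*linearized* (graphical) fit: OLS of t/C_t on t, slope = 1/C_s, intercept
= 1/h with h = k C_s². This is exact on noise-free model data (the
linearization identity t/C_t = 1/(kC_s²) + t/C_s holds to machine precision)
and is the estimator practitioners report. A direct nonlinear least-squares
refinement of the model curve, seeded at the linearized estimate, is
available behind `refine=True`; on clean data the two coincide.

Two scales coexist in this fit: the regression runs on t/C_t, but all
reported fit-quality metrics (R², MSE, RMSE) are computed on the
*concentration* scale — observed C_t against the model at the fitted
parameters — because that is the scale on which the fit is judged and
reported in this field. Standard errors of C_s and k are propagated from the
OLS slope/intercept covariance by the delta method; when replicates are
available the pipeline fits each replicate separately and reports mean ± SD
across replicates, which is the more honest aggregation for triplicate
designs.

Points with C_t ≤ 0 at t > 0 are excluded with a warning (they are outside
the model's domain on the linearized scale); fewer than three usable points,
or a non-positive slope/intercept (e.g. monotone-decreasing data), raise a
fit error flagging model inadequacy rather than returning nonsense
parameters.

**Arrhenius.** ln k regressed on 1/T gives E_a = −slope·R and
k0 = exp(intercept). Over a wide temperature range k(T) is typically
non-monotone (thermal degradation above the optimum), so the law only holds
on the ascending branch; the temperature subset is therefore an explicit
argument, not a hidden default. The pipeline fits whatever temperatures the
caller includes.

## Temperature convention

Celsius at every boundary; absolute temperature enters only inside
regressions, always through one function implementing **K = °C + 273**
(integer offset). This integer-offset convention is what makes the
thermodynamic chain self-consistent here (the ΔG°(T) series regenerates the
ΔH°/ΔS° pair it was built from, and vice versa, to ~10⁻⁴ relative); the
0.15 K difference is far below any other uncertainty in the chain.

## Crank sphere diffusion

Assumptions: spherical particles of constant radius R (default
1.25 × 10⁻⁴ m, i.e. a 0.25 mm sieved powder), constant internal diffusivity,
uniform initial concentration, constant surface concentration equal to the
equilibrium value C_∞. Under these, the volume-averaged unaccomplished ratio
is the classic series

    y(t) = (6/π²) Σ_{n≥1} n⁻² exp(−n²π² D_e t / R²).

At t = 0 the infinite series sums to 1 (Basel problem: (6/π²)Σn⁻² = 1); a
10-term truncation reaches 0.9421 at t = 0 but is accurate to < 10⁻⁶
against 20 terms for Fourier numbers D_e t/R² ≥ 0.01, which covers every
sampled time in the default design. A one-term fit is biased low; the
truncation study (n = 1, 10, 20) in the pipeline makes this visible.

**C_∞ choice.** By default C_∞ is the PSO-fitted C_s at the same
temperature (saturation = maximum extractable), overridable to the final
measured concentration. C_0 = 0 on the liquid-phase scale: extraction
starts into solute-free solvent. Concentration points above C_∞ (noise
around equilibrium) are dropped with a warning since they leave the model's
domain.

**Fitting.** Nonlinear least squares on the y scale with the physical
constraint D_e ≥ 0, implemented in scipy's trust-region-reflective
`least_squares` with an analytic Jacobian. Internally the optimizer works on
κ = D_e/R² (≈10⁻⁵–10⁻⁴ s⁻¹ for these problems) so the variable is
well-scaled regardless of R. The initial value comes from a one-term
log-linear fit, ln y ≈ ln(6/π²) − π²κt, on the tail half of the series
(where one term dominates); if that fails, κ₀ = 10⁻⁵ s⁻¹. A brute-force
grid-search oracle over 1000 D_e candidates confirms the optimizer finds the
global SSE minimum on noisy instances.

**Residual-resampling bootstrap.** Uncertainty in D_e:

1. centre the residuals, ε′ = ε − ε̄;
2. per iteration, resample ε′ with replacement and add to the fitted curve;
3. refit κ by an *unbounded* Levenberg–Marquardt started at the full-data
   estimate (fast, and the full-data constraint already anchors the start);
   negative refit draws are truncated to 0, consistent with D_e ≥ 0;
4. record D_e* = κ*·R².

The standard error is the SD of the draws; the confidence interval the
2.5/97.5 percentiles with linear interpolation (the percentile construction
matches the residual-resampling recipe; BCa would need jackknife
acceleration for no benefit at these smooth, 1-parameter fits). Each
iteration draws from its own `SeedSequence` substream, so results are exactly
reproducible given the seed and independent of scheduling. Refit failures
are skipped and counted; > 5 % failures invalidates the run. Coverage of
the 95 % interval, measured over 200 synthetic datasets at 1 % y-noise
(B = 500, scaled down from the production default B = 2000 to keep the check
fast), falls inside [0.90, 0.99].

## Mass transfer and the Biot number

The film model ln(C_s/(C_s − C_t)) = (K_T/L_c)·t is fitted through the
origin (exact when C_0 = 0; an intercept variant exists behind a flag),
with time in seconds, and K_T = slope × L_c. The characteristic length L_c
defaults to the sphere's volume-to-surface ratio R/3 and is configurable —
it is a modelling convention, not a measurable.

The Biot number Bi = K_T·L/D_e uses the particle **diameter** 2R as its
default length. The textbook definition uses R, but the diameter convention
is what reproduces the Biot magnitudes (~1100–1600) quoted for this class
of system from transport coefficients of the magnitudes measured there
(K_T ~5 × 10⁻⁶ m/s, D_e ~10⁻¹² m²/s); the convention used is recorded in
every result object. Classification: Bi > 50 (strict) ⇒
internal-diffusion-limited, else external-transfer-limited.

A caveat the tests make explicit: when K_T (with L_c = R/3) and D_e are both
derived from the *same* curve — as in the synthetic pipeline — Bi comes out
small (~5–7), because both coefficients then express the same observed
timescale. The large published-style Bi values arise from independently
determined K_T. The package therefore validates K_T by exact inversion of
its own film model, and Bi by the algebraic identity from given K_T/D_e
inputs, not by expecting the >50 regime on synthetic data.

## Thermodynamics

K_eq = C_s/(C_max − C_s) with a single global C_max (the complete-extraction
reference; a required input — the synthetic module supplies a known one,
default 175 mg GAE/g). Van't Hoff: OLS of ln K_eq on 1/T, ΔH° = −slope·R,
ΔS° = intercept·R; ΔG°(T) = ΔH° − TΔS°, with the isotherm route
−RT ln K_eq available as a cross-check (the two agree to 10⁻¹⁰ relative on
exact data by construction). Internally everything is J/mol; report layers
convert to kJ/mol. The chain is exactly invertible: ΔH°/ΔS° →
K_eq series → Van't Hoff fit recovers the inputs to 10⁻¹⁰ relative.

At these settings the Van't Hoff slope is small (ΔH° of a few kJ/mol over a
40 K span), so single-dataset ΔH° estimates are noisy — with σ_lnK = 0.05
the per-dataset SD is ~35 % of the value. The test suite checks
*unbiasedness* with a z-test over 1000 simulated series rather than a naive
small-ensemble percentage, which would reject an unbiased estimator ~40 % of
the time.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design every stage expects: 5
temperatures (30–70 °C), 8 sampling times (10–80 min), 3 replicates,
PSO-true curves with per-temperature (C_s, k) at realistic magnitudes
(C_s 151–159 mg/g with a 50 °C optimum, k 8–12 × 10⁻⁴ g/(mg min)), additive
homoscedastic Gaussian noise (default σ = 1 mg/g, an order-of-magnitude
match to replicate SDs in this kind of assay), truncated at 0 and capped at
C_max. The UAE/CSE pair scales the CSE truth by 0.90 (C_s) and 0.65 (k) —
the observed intensification ratios. Diffusion-stage data add Gaussian noise
on the y scale (the fitted scale) to a 50-term reference series.

Not emulated: heteroscedastic or autocorrelated noise, replicate-level
variance structure beyond a common σ, cavitation physics, particle-size
distributions, solvent-composition effects. Passing recovery tests on this
generator therefore demonstrates correctness of the *estimators* under the
stated noise model, not robustness to real-data pathologies.

Generators are pure functions of (spec, seed): identical CSV bytes across
runs.

## Problem sizes and defaults

Production defaults: bootstrap B = 2000, series truncations (1, 10, 20),
radius 1.25 × 10⁻⁴ m, L_c = R/3, Biot length 2R, C₀ = 0, K = °C + 273.
The test suite and examples run the same algorithms at smaller Monte Carlo
sizes chosen as the smallest that make the statistical assertions stable:
B = 25–500 inside pipeline tests, 100-curve recovery ensembles, a
200-dataset × B = 500 coverage study, 1000-series bias check.

## Known limitations

- The PSO linearized estimator weights early points heavily (t/C_t
  amplifies small-C noise at small t); the nonlinear refinement mitigates
  this but is not the default, to keep the reported estimator the
  conventional one.
- C_s ≥ C_max raises an error in K_eq rather than being projected; callers
  with noisy C_s near complete extraction must choose C_max sensibly.
- The Crank fit assumes the five listed idealizations; deviations (swelling
  particles, surface resistance, non-uniform initial distribution) bias D_e
  in ways the bootstrap CI does not capture.
- `read_curves` rejects duplicate time points rather than averaging;
  averaging is a caller decision.
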