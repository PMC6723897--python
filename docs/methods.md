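# Methods

This note documents the models implemented in `dissosurrogate`, the defaults
of the synthetic study, the numerical choices, and what the tests do and do
not establish.

## The surrogate cascade

The package predicts the in vitro dissolution profile of an extended-release
tablet from spectroscopy plus press data in three stages.

**Composition from spectra.**  DR and HPMC mass fractions are calibrated by
NIPALS PLS1 on pretreated spectra.  Pretreatment recipes are fixed per
modality: Raman spectra keep 350–1680 cm⁻¹, are baseline-corrected by
asymmetric least squares (Whittaker filter, asymmetry p = 0.001, smoothness
λ = 10 000), normalized by SNV and mean-centered; NIR transmission keeps
7600–8000 and 8500–13 000 cm⁻¹ (NIR reflection 4200–7400 cm⁻¹), is
differentiated by a 5-point quadratic Savitzky–Golay first derivative,
corrected by MSC against the training-mean reference and mean-centered.
All fit-type state (MSC reference, column means) is estimated on the
training tablets only and replayed on held-out spectra.  Latent-variable
count is selected by contiguous-block cross-validation (30 blocks in the
stored acquisition order; block sizes differ by at most one) as the smallest
count whose RMSECV is within 2% of the minimum.  An optional genetic
algorithm selects contiguous 10-channel windows (population 64, ≤6 latent
variables, fitness = best block-CV RMSECV, tournament selection, single-point
crossover at window boundaries, per-window mutation 0.01, one elite,
best of 3 replicate runs).

**Profile from composition and force.**  A 3 → H → 53 feed-forward network
(tanh hidden layer, linear outputs; inputs and targets min-max scaled to
[−1, 1] on the training split only) maps (DR %, HPMC %, force MPa) to the
53-point profile.  Two trainers are implemented on the flattened weights:

- *Levenberg–Marquardt*: damped Gauss–Newton, (JᵀJ + μI)Δ = −Jᵀr, μ₀ = 10⁻³,
  ×10 on a rejected step, ÷10 on acceptance, μmax = 10¹⁰; early stopping when
  the validation MSE rises for 6 consecutive epochs, returning the
  best-validation weights.
- *Bayesian regularization*: minimizes βE_D + αE_W by the same damped
  Gauss–Newton inner step; after each accepted step the evidence
  approximation updates γ = N − 2α·tr(H⁻¹) with H = 2βJᵀJ + 2αI, then
  α = γ/(2E_W), β = (n_obs − γ)/(2E_D).  Because the updated objective is
  pinned near n_obs/2 by construction, convergence is judged on the relative
  change of E_D.  No validation-based stopping.

Training follows the replicate protocol: for each hidden size H the run is
repeated with fresh random 70/15/15 splits of the 120 training tablets;
networks are trained on nominal DR/HPMC plus measured force, then evaluated
on the external test tablets using *PLS-predicted* DR/HPMC (the deployment
condition), and the run with the lowest summed per-tablet RMSEP is selected.
The linear baseline is multi-response PLS2 (3 latent variables) from
autoscaled inputs to mean-centered profiles.

**Evaluation.**  The f2 similarity factor uses unit weights and all 53
points; the regulatory convention of truncating after 85% dissolved is
available behind a flag but off by default, since full profiles are compared
here.  The factorial effects analysis fits, on coded (−1, 0, +1) factors of
the 27-run block, the 10-term model (intercept, three linear, three
quadratic, three linear×linear interactions) to the dissolution value at a
chosen time (15 or 960 min), normalized to the 8% reference drug load;
standardized effects are t statistics on the residual degrees of freedom.
When the fit is numerically exact (zero residual variance) the t statistic is
reported as ∞ for nonzero coefficients and 0 otherwise, so orthogonal
noise-free designs behave sensibly.

## The synthetic study

The generator reproduces the study design exactly: a 3³ factorial (DR 6/8/10
% w/w, HPMC 10/20/30 % w/w, force 63.8/95.7/127.6 MPa, settings 1–27) plus
ten one-factor-at-a-time settings (28–37; DR 7–9, HPMC 5–35, force
31.9–159.5 at the center of the other factors), four tablets per setting,
settings 1, 4, 14, 17, 27, 29, 34 held out for testing.  The dissolution
grid is 2, 5, 10, 15, 30, 45, 60 min and then every 30 min to 1440 min (53
points).

**Kinetics.**  Noise-free release is a Weibull curve
D(t) = Dmax·(1 − exp(−(t/τ)^β)) with β = 0.9 and Dmax = 100·DR/8 — the
plateau scales with drug load relative to the 8% center point.  The time
constant is τ = τ₀·h(HPMC)·g(F) with τ₀ = 4 min,
h(c) = 1 + 70·c⁷/(19⁷ + c⁷) (Hill-type saturation: near-immediate release at
10% HPMC, strong retardation at 20%, only marginally more at 30%) and
g(F) = (F/95.7)^0.15 (a weak force effect visible mainly early in the
curve).  The half-effect concentration (19 % w/w) and steepness (7) place
the sharp gelation transition between the 10% and 20% design levels, which
reproduces the observed curve families: the 10% mean curve dominates the 20%
curve at every pre-plateau time point, and the integrated 20-vs-30 gap is
smaller than the 10-vs-20 gap.

**Spectra.**  Pure-component spectra are sums of Gaussian bands.  The drug
carries narrow, distinctive Raman bands (1645, 1605, 1560, 1345 cm⁻¹), so
Raman transmission is the best DR predictor.  HPMC and the cellulose filler
share nearly identical Raman skeletal bands (1120/1090 cm⁻¹ region, plus a
faint distinct HPMC feature at 945 cm⁻¹) — both are celluloses — so HPMC is
poorly determined from Raman; its broad NIR overtone/combination bands
(11 000, 10 300, 9800, 8850, 7750 cm⁻¹) make NIR transmission the best HPMC
predictor.  All organic components share a common C–H combination band near
8650 cm⁻¹ with equal per-percent response; because the formulation sums to
100% this band is composition-independent and anchors the MSC slope, keeping
the scatter correction linear in composition.  Raman baselines include a
steep low-wavenumber exponential emulating fluorescence; configured noisy
edge regions (Raman <350 and >1680 cm⁻¹; NIR high-absorbance bands) carry
inflated noise.  Reflection modalities carry 3–4× the additive noise of
transmission, which is why reflection-based models rank worse downstream.

**Noise defaults** (chosen once as the study conditions): between-tablet
composition noise 2% relative of nominal; force noise 1 MPa; profile
measurement noise 1% released (additive, clipped at 0); additive spectral
noise per modality 0.08/0.30 (Raman trans/refl) and 0.03/0.20 (NIR
trans/refl) intensity units; multiplicative scatter sd 0.05; baseline
amplitude jitter 30% relative.  These magnitudes put the transmission
calibration errors in the sub-percent (DR) to ~1 % w/w (HPMC-from-Raman)
range characteristic of tablet PLS calibrations, and make all four modality
rankings emerge from construction rather than assertion.  A single
`noise_scale` multiplies every instrument-noise source (additive noise,
scatter spread, baseline jitter) and is used by the parameter-recovery tests
(levels 4×, 1×, 0.25×).

**What the generator does not emulate:** real band shapes and instrument
line-spread functions, detector nonlinearity, water/moisture bands,
tablet-to-tablet geometry effects beyond a scalar scatter factor, and any
physical gel-layer diffusion mechanism.  Passing tests therefore demonstrate
that the pipeline recovers the structure this generator encodes — plateau
scaling, Hill-type retardation, weak force effect, modality-specific
information content — not that it would reach the same error levels on real
instrument data.

## Scale of the shipped experiments

The default "quick" profile (BR trainer, 5 replicate runs, H ∈ {1, 3, 5},
80 training epochs) exercises the full cascade in about a minute and is what
the test suite and the acceptance script run; the "full" profile (both
trainers, H = 1..10, 100 runs) reproduces the complete sweep protocol.
Quick-scale results are stable across seeds: every held-out test tablet
lands inside the f2 equivalence band and the network beats the PLS2 baseline
by a wide margin in every input source, but the selected H and the exact
mean f2 fluctuate more than a 100-run sweep would.

## Numerical choices and edge cases

- AsLS iterates at most 50 weight updates and stops when the weight vector
  changes by less than a 10⁻⁶ fraction of channels; the pentadiagonal system
  is solved in banded Cholesky form.  Fewer than 3 channels is an error.
- Savitzky–Golay derivatives are taken with respect to channel index
  (`delta = 1`); the constant cm⁻¹-per-channel factor is absorbed by the
  regression.  Edges use the truncated-window polynomial fit.  On the NIR
  transmission grid the derivative runs across the retained segments after
  region exclusion, consistently for training and test spectra.
- SNV and autoscaling use the n−1 standard deviation; zero-variance spectra
  raise an error naming the sample.
- NIPALS deflation stops early if a weight or score norm collapses
  (rank-deficient data); cross-validation folds that lose rank reuse the
  deepest available component.
- Network weights initialize uniformly within ±1/√fan-in from a seeded
  generator; a degenerate (constant) scaler feature maps to −1 with unit
  span to avoid division by zero.
- All randomness flows from one master seed through named
  `numpy.random.SeedSequence` spawns (tablets, profiles, one per modality,
  one per training run), so every artifact is bit-reproducible and a run
  manifest (config hash, stage seeds, file inventory, timings) is written
  with each pipeline run.
- f2 is computed per tablet against its own profile; per-setting averaging
  is not applied.  Reports against both the measured (noisy) and the
  simulator-true profiles are produced; the comparison table uses the
  measured ones, mirroring how a real study can only compare to measured
  curves.

## Known limitations

- The GA uses fixed-width contiguous windows; adaptive window widths and
  other selection schemes (iPLS, CARS, UVE) are out of scope.
- LM/BR build the dense Jacobian; this is comfortable at 3→10→53 scale but
  not intended for larger architectures.
- The effects analysis assumes the complete 27-run factorial; fractional or
  unbalanced designs are rejected rather than approximated.
- PLS2 in the baseline is intentionally capped at the 3 input dimensions; it
  exists to quantify the cost of linearity, not as a tuned competitor.
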