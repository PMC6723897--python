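# dissosurrogate

A spectroscopy-based surrogate for in vitro dissolution testing of
extended-release tablets.

In vitro dissolution testing (USP II paddle method) is slow, destructive and
samples only a handful of tablets per batch.  For a hydrophilic-matrix
formulation — drotaverine (DR, the drug) in a hydroxypropyl methylcellulose
(HPMC) matrix with microcrystalline cellulose filler and magnesium stearate —
the dissolution curve is governed by three measurable factors: drug load,
polymer level and compression force.  This package implements the full
surrogate cascade that predicts the 53-point, 24-hour dissolution profile of
a tablet from its NIR/Raman spectrum and its compression force:

1. **Composition calibration.**  Partial least squares (NIPALS PLS1) models
   quantify DR and HPMC mass fractions from pretreated spectra
   (region exclusion, asymmetric-least-squares/Whittaker baseline,
   SNV, Savitzky–Golay derivative, MSC, mean centering), with
   contiguous-block cross-validation and optional genetic-algorithm
   wavelength-window selection.
2. **Profile prediction.**  A feed-forward network, 3 inputs → H tanh hidden
   neurons → 53 linear outputs, trained with Levenberg–Marquardt (LM) or
   Bayesian regularization (BR; evidence-approximation updates of the weight
   decay α and noise precision β, effective parameter count
   γ = N − 2α·tr(H⁻¹)).  Hidden size is chosen by sweeping H with replicate
   runs and ranking by summed test RMSEP.  A multi-response PLS2 model on the
   same inputs serves as the linear baseline.
3. **Evaluation.**  Per-tablet similarity by the regulatory f2 factor,

   f2 = 50·log₁₀( 100 · [1 + (1/n)·Σₜ wₜ(Rₜ−Tₜ)²]^(−1/2) ),

   where f2 = 100 at identity and 50 ≤ f2 ≤ 100 declares two profiles
   equivalent; plus profile RMSEP and a 3³ factorial standardized-effects
   analysis of the dissolution values at 15 and 960 min.

Because no public dataset of matched spectra and dissolution curves exists
for this design, the package ships a first-class synthetic study
(`dissosurrogate.synthetic`): the 37-setting experimental design (27-run 3³
factorial over DR 6–10 %, HPMC 10–30 %, force 63.8–127.6 MPa, plus ten
one-factor settings; 4 tablets per setting, 148 tablets, 30 train / 7 test
settings), Weibull release kinetics with a saturating Hill-type HPMC effect
and a weak compression-force effect, and four spectral modalities (NIR/Raman
× transmission/reflection) built from Gaussian pure-component bands with
realistic baselines, multiplicative scatter and noise.

## Worked example

```python
import numpy as np
from dissosurrogate import (dissolution_time_grid, simulate_profile,
                            f2_similarity)
from dissosurrogate.pipeline import PipelineConfig, run_pipeline

times = dissolution_time_grid()
fast = simulate_profile(8.0, 10.0, 63.8, times)   # 10% HPMC: fast release
slow = simulate_profile(8.0, 30.0, 63.8, times)   # 30% HPMC: retarded
print("grid points:", times.size)
print("released at 15 min (10% vs 30% HPMC):",
      round(fast.released[3], 1), "vs", round(slow.released[3], 1))
print("f2(fast, slow):", round(f2_similarity(fast.released, slow.released), 2))

result = run_pipeline(PipelineConfig(seed=1, out_dir="runs/demo"))
print(result.comparison.round(2).to_string())
rep = result.ann_reports_true["raman"]
print("worst test tablet (Raman ANN vs true profile): f2 =", round(rep.min_f2, 1))
```

prints

```
grid points: 53
released at 15 min (10% vs 30% HPMC): 87.4 vs 7.5
f2(fast, slow): 24.02
                    raman    nir  nir_raman
modeling method
ANN                 84.72  86.36      86.18
PLS                 65.76  67.56      66.77
difference          18.96  18.80      19.41
ANN equivalent (n)  28.00  28.00      28.00
PLS equivalent (n)  28.00  28.00      28.00
worst test tablet (Raman ANN vs true profile): f2 = 75.6
```

The 53-point grid covers 24 h (2–60 min densely, then every 30 min).  The 10%
HPMC tablet has released 87% of its dose at 15 min while the 30% tablet is at
7% — the strongly nonlinear polymer effect; the two curves are far from
equivalent (f2 = 24).  The end-to-end run trains BR networks per input source
(Raman / NIR / NIR–Raman composition predictions plus measured force) and
compares them with the linear PLS2 baseline: the network's mean f2 exceeds
the baseline by ~19 points in every source because only the network can track
the Hill-type HPMC retardation, and every held-out test tablet is inside the
50–100 equivalence band.

The quick profile (default; BR trainer, 5 replicate runs, H ∈ {1,3,5}) runs
end to end in about a minute on one CPU.  `profile="full"` mirrors the
complete protocol: both trainers, H = 1..10, 100 replicate runs each.

A command-line interface wraps each stage:

```bash
dissosurrogate generate --seed 0 --out-dir data/
dissosurrogate preprocess --modality raman_trans --in data/spectra_raman_trans.csv \
    --out pre.csv --state state.json
dissosurrogate calibrate --spectra pre.csv --tablets data/tablets.csv \
    --analyte dr --model-out dr_pls.json
dissosurrogate run --seed 0 --out-dir runs/full --quick
```

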