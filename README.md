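# pbem — whole-brain ³¹P MRS phosphate brain-energy-metabolism analysis

`pbem` is a Python package for quantifying phosphate brain-energy
metabolism (p-BEM) from in-vivo phosphorus-31 magnetic resonance
spectroscopy, aimed at researchers studying brain energetics in aging,
amnestic mild cognitive impairment (aMCI) and Alzheimer's disease (AD).
It covers the full analysis chain:

1. **Simulation** — 13-resonance ³¹P FIDs (PE, PC, Pi_in, Pi_ex, GPE,
   GPC, PCr, α/β/γ-ATP, NAD, UDPG, macromolecule) with Voigt lineshapes,
   pH- and Mg²⁺-driven chemical shifts, complex Gaussian noise, smooth
   baselines, and full three-group cohorts (CN / aMCI / AD) with known
   ground truth.
2. **Preprocessing** — zero-filling (2048 → 4096), apodization, Fourier
   transform, automatic/manual phase correction, ppm referencing to PCr
   at 0 ppm, region summation.
3. **Quantification** — baseline estimation and bounded 13-peak true-Voigt
   fitting (Faddeeva function, analytic Jacobian, shared-linewidth prior
   knowledge).
4. **Markers** — per region: energy reserve PCr/t-ATP, energy consumption
   Pi_in/t-ATP, metabolic state Pi_in/PCr, Pi_ex ratios, membrane index
   (PE+PC)/(GPE+GPC); intracellular pH from the Pi shift
   (Henderson–Hasselbalch) and free Mg²⁺ from the α−β ATP shift
   separation (MgATP binding isotherm). t-ATP is the arithmetic mean of
   the three ATP spin signals.
5. **Cohort statistics** — covariate adjustment (age, education, gender),
   shifted-log symmetrization, common-variance scaling, one-way ANOVA
   with Tukey HSD (α = 0.10 for BEM markers, 0.01 for cognition, Tukey
   at 0.05), and the group × marker interaction model
   `y = b0 + b1·I(aMCI) + b2·I(AD) + b3·x + b4·x·I(aMCI) + b5·x·I(AD) + e`.
6. **Classification** — PCA to two components refit inside each training
   fold, quadratic discriminant analysis, stratified 10-fold
   cross-validation, confusion-matrix metrics.

See `docs/methods.md` for the models, constants and design decisions.

## Worked example

```python
from dataclasses import replace
from pbem import (GroundTruth, simulate_spectrum, fit_spectrum,
                  bem_indices, noise_sd_for_snr)

truth = GroundTruth(pH=7.05, mg=0.18, seed=42)
truth = replace(truth, noise_sd=noise_sd_for_snr(truth, 30.0))
spec = simulate_spectrum(truth)          # 2048 -> 4096, FT, ppm axis
fit = fit_spectrum(spec)
mk = bem_indices(fit, "temporal")
print(f"converged: {fit.converged}, residual rms: {fit.residual_rms:.3g}")
print(f"energy reserve  (PCr/t-ATP): {mk.energy_reserve:.3f}")
print(f"energy consumption (Pi/t-ATP): {mk.energy_consumption:.3f}")
print(f"metabolic state (Pi/PCr):  {mk.metabolic_state:.3f}")
print(f"pH: {mk.ph:.3f}   free Mg2+: {mk.mg:.3f} mM   PME/PDE: {mk.pme_pde:.3f}")
```

prints

```
converged: True, residual rms: 0.673
energy reserve  (PCr/t-ATP): 1.904
energy consumption (Pi/t-ATP): 0.531
metabolic state (Pi/PCr):  0.279
pH: 7.050   free Mg2+: 0.177 mM   PME/PDE: 0.904
```

The simulated subject had reserve 1.90, consumption 0.55, metabolic
state 0.29, pH 7.05 and Mg²⁺ 0.18 mM: at spectral SNR 30 the fit
recovers the ratio indices within a few percent and the shift-derived
pH/Mg²⁺ almost exactly (chemical shifts are estimated far more precisely
than areas).

An end-to-end cohort run (simulate → fit → markers → ANOVA/Tukey →
interaction model → classifier) is one call:

```python
from pbem.synth import CohortDesign
from pbem.workbench import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(output_dir="demo_run"),
                      design=CohortDesign(seed=1))
```

which writes `markers.tsv`, `anova_report.tsv`, `interaction_report.tsv`,
`classification_report.tsv` and a provenance log. The same stages are
available from the shell via the `pbem` command
(`pbem simulate | preprocess | fit | markers | stats | classify | run`).

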