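# Methods

`pbem` analyzes whole-brain in-vivo ³¹P magnetic resonance spectra for
phosphate brain-energy-metabolism (p-BEM) markers across three clinical
groups — cognitively normal (CN), amnestic mild cognitive impairment
(aMCI) and mild Alzheimer's disease (AD) — and includes a synthetic-data
generator so the whole chain is testable against known ground truth.
This note records the models, the tunable constants, and the design
choices made where the procedure was genuinely open.

## Spectral model and simulation

A pulse-acquire ³¹P acquisition is modelled as a complex free induction
decay of 2048 points (zero-filled to 4096 before the transform) over a
5 kHz window at a 120.6 MHz carrier (³¹P at 7 T), TR 0.5 s, TE 0.5 ms.
Each of the 13 resonances — PE, PC, extracellular and intracellular Pi,
GPE, GPC, PCr, γ/α/β-ATP, NAD, UDPG and a broad macromolecular (MM)
component — contributes

    s_k(t) = A_k · exp(2πi ν_k t) · exp(−π Λ_k t) · exp(−(π Γ_k t)² / (4 ln 2)),

whose continuous transform is a Voigt line of area A_k with Lorentzian
FWHM Λ_k and Gaussian FWHM Γ_k. Chemical shifts are referenced to PCr at
0 ppm; all other default centers (PE 6.8, PC 6.2, Pi_ex 5.2, Pi_in ≈ 4.8,
GPE 3.5, GPC 3.0, γ-ATP −2.5, α-ATP −7.6, NAD −8.3, UDPG −9.8,
β-ATP ≈ −16.1, MM ≈ 2 ppm) are conventional ³¹P brain values and are
configuration, not constants of the method. ATP resonances are simulated
as singlets, reflecting their effectively collapsed multiplet structure
at 7 T; a J-coupled mode is not implemented. Noise is additive circular
complex Gaussian on the FID (the standard thermal-noise model); an
optional smooth baseline (low-order Chebyshev polynomial in the frequency
domain) is added after the transform to emulate broad baseline roll.

Two chemical-shift observables carry physiology:

* **pH** from the intracellular-Pi shift δ_Pi via Henderson–Hasselbalch,
  pH = pKa + log₁₀((δ_Pi − δ_acid)/(δ_base − δ_Pi)), defaults
  pKa = 6.75, δ_acid = 3.27 ppm, δ_base = 5.69 ppm;
* **free Mg²⁺** from the α−β ATP shift separation δ_αβ via a 1:1 MgATP
  binding isotherm, δ_αβ = δ_free + (δ_bound − δ_free)·mg/(Kd + mg),
  defaults δ_free = 8.94 ppm, δ_bound = 8.24 ppm, Kd = 0.05 mM.

These calibration constants are taken from standard in-vivo ³¹P
literature and exposed in `CalibrationConstants`; studies with different
temperature/ionic-strength calibrations should substitute their own.
Forward and inverse maps are exact inverses on their open domains and
raise domain errors at the titration/saturation limits.

## Preprocessing

Zero-filling, exponential (and optionally Gaussian) apodization, Fourier
transformation, and zero/first-order phase correction, each pure and
recorded in an append-only history. The transform halves the first FID
point (trapezoid end-correction for a causal decay) and scales by
2·dwell·f₀ so that the ppm-axis integral of an absorption line equals the
resonance amplitude; the factor 2 accounts for the absorption line of a
one-sided decay carrying half the complex-plane area. Automatic phasing
(needed because interactive scanner phasing is not reproducible offline)
minimizes a scale-invariant objective — entropy of the normalized real
part plus a penalty on negative excursions — by a deterministic
coarse-grid search plus Nelder–Mead polish. Quantification uses no
apodization by default; 8 Hz line broadening is a display convention
only. Region spectra are pointwise complex sums of voxel spectra on a
shared ppm axis.

## Voigt fitting

The 13-peak model is fitted to the real part of the phased,
baseline-corrected spectrum by bounded trust-region least squares with an
analytic Jacobian (Faddeeva-function derivatives). Because the sampled
transform of a damped decay equals the *periodized* continuous transform,
each peak is modelled as near alias images of the true Voigt plus the
closed-form Poisson-kernel remainder of the periodized Lorentzian; this
removes an aliasing floor that would otherwise dominate noiseless
residuals. Numerical choices:

* centers bounded to prior ± 0.5 ppm (prevents peak swapping);
* widths in (10⁻⁴, 1] ppm; the MM Gaussian width is bounded below at
  0.3 ppm so the hump cannot absorb metabolite signal;
* one shared (Gaussian, Lorentzian) width pair for the 12 narrow
  metabolite peaks by default — the standard prior-knowledge constraint
  (line width is dominated by shim and relaxation common to the
  metabolites) which roughly halves area variance at realistic SNR; per
  peak widths via `FitOptions(shared_widths=False)`;
* deterministic initialization: centers at priors, areas from trapezoid
  integrals over prior windows, widths at 0.05 ppm (MM 0.5/0.35);
* non-convergence is flagged in the result, never silent.

The baseline is a degree-4 Chebyshev polynomial fitted to points outside
exclusion windows (prior ± 0.8 ppm; MM ± 2 ppm) before peak fitting.
At spectral SNR 20 (PCr height over real-channel noise), the estimator
operates within ~10% of the Cramér–Rao bound of this model (relative
area sd ≈ 3% for PCr, 5% for the ATP spins, 8% for Pi_in); single-fit
errors of several percent at that SNR are an information limit, not an
estimator defect. Mean bias over repeated fits stays below 2%.

## Markers

Per region (frontal, temporal, parietal, occipital), from the fitted
integrals: energy reserve PCr/t-ATP, energy consumption Pi_in/t-ATP,
metabolic state Pi_in/PCr, Pi_ex/t-ATP, Pi_ex/PCr, and the membrane
index PME/PDE = (PE+PC)/(GPE+GPC), with t-ATP the arithmetic *mean* of
the α/β/γ-ATP areas (averaging, not summing). pH and Mg²⁺ come from the
region-summed spectrum's shifts and never depend on areas; all ratios are
invariant to overall spectral scale. Ratio indices are computed from
region-summed spectra by default; per-voxel averaging is a caller-side
option (fit voxels individually and average the indices).

## Cohort generator

Cohorts default to 15 CN / 15 aMCI / 11 AD. Demographics follow the
study population (age 63.5 ± 6.1 / 66.5 ± 6.7 / 71.7 ± 5.7 years,
education ≈ 17 ± 3 years, female fractions 11/15, 10/15, 6/11). Markers
are generated on a latent analysis scale: group contrasts (aMCI−CN,
AD−CN) per region × marker take the reported signed standardized values
of the temporal/frontal/parietal/occipital comparisons (e.g. temporal
energy reserve −0.88 / −1.65; temporal metabolic state −0.21 / +0.95;
temporal Mg²⁺ +0.16 / −1.03), and the per-marker residual SD (0.75–0.87)
is backed out from the internal consistency of those contrasts with
their significance levels. Latent values map to physical markers as
lognormal ratios (CV ≈ 9–13%), Gaussian pH (sd ≈ 0.04) and lognormal
Mg²⁺ around 0.20 mM. Energy consumption is derived as
reserve × metabolic state (the three energy ratios are algebraically
dependent), so its realized contrasts are approximate (correct signs,
aMCI ≈ −0.95, AD ≈ −0.61).

Covariate structure: each marker's latent value carries age (−0.04/yr),
gender (−0.35 for female) and education (+0.02/yr) terms, reflecting the
reported covariate–metabolite relationships. Because group membership
correlates with age, pooled covariate adjustment shrinks injected group
contrasts; the generator pre-compensates with the exact expected linear
shrinkage map computed from the demographic design, so the *stated*
contrasts are what the analysis pipeline recovers post-adjustment.
Spectra per participant-region realize the marker values exactly (ATP
spins at unit area, PCr = reserve, Pi_in = reserve × metabolic, etc.,
times a lognormal subject scale), at a default region-sum SNR of 25.
Cognitive domain z-scores (executive, memory, attention, language,
visuospatial) carry typical aMCI/AD deficits (memory −1.2/−2.0 SD, others
−0.3…−1.2), a small age slope, and a per-group coupling to the temporal
Mg²⁺ residual (+0.30 in CN, −0.25/−0.30 in aMCI/AD).

What the generator does *not* emulate: voxel-level spatial structure and
partial-volume effects, relaxation weighting (areas are relative
concentrations), frequency drift, non-Gaussian artifacts, and any
atrophy-related covariance between regions. Passing tests therefore
demonstrate correctness of the estimation and inference machinery under
the stated generative model, not robustness to those real-data effects.

## Statistics

The chain per marker follows adjust → transform → (scale): OLS
residualization on age, education and gender with the grand mean added
back; shifted-log symmetrization — log(x − a) for positive skew,
−log(a − x) for negative skew (adjusted Fisher–Pearson skewness), with
the metabolite-specific constant a found by a deterministic Brent root
search driving the transformed skewness to zero (fallback: the tightest
skew-reducing offset; the transform never increases |skew|); optional
scaling of all variables to unit variance for the correspondence and
classification analyses. One-way ANOVA uses the classical decomposition,
df = (k−1, N−k) = (2, 38) at the default cohort; Tukey(-Kramer) HSD uses
the exact studentized-range distribution at familywise α = 0.05.
Significance levels: α = 0.01 for cognitive measures, α = 0.10 for the
exploratory BEM markers, interaction tests at 0.05,
Benjamini–Hochberg FDR 0.10 available across the marker × region
F-tests. The marker–cognition model is fixed-effects OLS,

    y = b0 + b1·I(aMCI) + b2·I(AD) + b3·x_c + b4·x_c·I(aMCI) + b5·x_c·I(AD) + e,

with the marker centered at its grand mean, CN as reference, and a 2-df
Wald F for the interaction (b4 = b5 = 0). No random effects are used:
the model contains none, and with one observation per subject per
analysis there is nothing for a random intercept to absorb.

Two calibration facts, established by simulation and asserted in the
tests, are worth knowing. First, the two-step adjust-then-ANOVA is
slightly mis-calibrated by construction: when covariate distributions are
group-independent it runs near nominal level (mildly liberal, since
residualization spends ~3 within-group df the (2, 38) F does not know
about), and under the default age-confounded demographics it is
conservative (≈ 0.05–0.07 at nominal 0.10), because residualizing on
group-structured covariates preferentially removes between-group
variance. Second, the replication metric for direction-of-effect checks
is defined as: omnibus F significant at the BEM α (0.10) *and* the Tukey
pairwise contrast showing the stated direction. Requiring Tukey-adjusted
p < 0.05 for the pair instead would cap replication near 50–70% at the
generator's effect sizes — a property of the effect sizes themselves
(a contrast observed at p ≈ 0.03 replicates at a stricter α about half
the time), not of the implementation.

## Classification

Features are all 32 regional markers plus the 5 cognitive z-scores.
Within each training split of a stratified 10-fold cross-validation
(stratification keeps all three classes in every training fold at
n = 41; fold sizes 4–5), features are standardized and reduced to the
first two principal components; the quadratic discriminant (Gaussian
class-conditional densities, class-specific covariances, empirical
priors) is fitted on the training scores and applied to the held-out
scores projected through the training loadings. The component count (2)
is fixed; explained-variance fractions are reported for transparency.
Posterior ties break toward the earlier class in the order
CN < aMCI < AD. cv_error = misclassified/n with standard error
√(e(1−e)/n); note misclassified/n at 7/41 is 0.1707 (not 0.1704), and the
package reports the exact ratio. Confusion matrices are reported with
rows = predicted, columns = true, class order CN/aMCI/AD.

## Problem sizes

Monte-Carlo checks use: 100 seeds for noisy-fit bias at SNR 20, 2000
replicates for ANOVA/Tukey null calibration, 200 replicates for the
direction-of-effect rates, 1000 replicates for interaction-slope
coverage, and 500 replicates for cohort-level null calibration. These
sizes put the binomial Monte-Carlo error well inside the asserted
tolerances while keeping the default test run short.

## Known limitations

Absolute quantification (mM) is out of scope — areas are relative
concentrations. The fitter assumes the 13-peak panel; unmodelled
resonances will bias neighbours. The generator's effect-size calibration
inherits the internal consistency of the published contrasts it emulates;
it is a study-shaped benchmark, not a physiological model of disease.
Auto-phasing assumes at least one resolvable peak and an
absorption-dominated solution; pathological dispersion-heavy inputs may
settle in a local minimum of the entropy objective.
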