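"""Synthetic 31P spectra and cohorts with known ground truth.

This module is the generative twin of the quantification pipeline: it
produces free induction decays whose Fourier transform is a sum of Voigt
resonances (13-peak phosphorus panel), with the intracellular-Pi position
driven by pH and the alpha-beta ATP separation driven by free Mg2+, plus
circular complex Gaussian noise and a smooth frequency-domain baseline.
It also simulates full three-group cohorts (CN / aMCI / AD) whose regional
marker effects follow the signed standardized group contrasts reported for
this kind of study population, so every downstream stage - fitting,
marker derivation, cohort statistics, classification - can be tested
against known truth without any external data.

Ground-truth marker generation works on a latent "analysis" scale: group
contrasts are specified as mean shifts on that scale and per-subject
residual scatter is calibrated so that the printed pairwise contrasts and
their significance levels are mutually consistent.  Latent values map to
physical markers (ratios are lognormal, pH Gaussian, Mg2+ lognormal) and
each subject-region spectrum is constructed to realize its marker values
exactly, which is what makes generative/inferential consistency testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import DEFAULT_CALIBRATION, CalibrationConstants
from .preprocess import (
    FID,
    AcquisitionParams,
    Spectrum,
    to_spectrum,
    zero_fill,
)

__all__ = [
    "RESONANCE_NAMES",
    "REGIONS",
    "COGNITIVE_DOMAINS",
    "MARKER_NAMES",
    "ResonanceSpec",
    "GroundTruth",
    "CohortDesign",
    "SimulatedRegion",
    "default_panel",
    "delta_pi_from_ph",
    "delta_ab_from_mg",
    "simulate_fid",
    "simulate_spectrum",
    "noise_sd_for_snr",
    "ground_truth_markers",
    "simulate_cohort",
]

_LN2 = math.log(2.0)

#: The 13-resonance phosphorus panel resolved at 7T.
RESONANCE_NAMES = (
    "PE", "PC", "Pi_ex", "Pi_in", "GPE", "GPC", "PCr",
    "gATP", "aATP", "NAD", "UDPG", "bATP", "MM",
)

REGIONS = ("frontal", "temporal", "parietal", "occipital")

COGNITIVE_DOMAINS = ("executive", "memory", "attention", "language", "visuospatial")

#: Marker columns emitted per region by the cohort generator (and by the
#: fitting pipeline), in a fixed order.
MARKER_NAMES = (
    "energy_reserve", "energy_consumption", "metabolic_state",
    "pi_ex_over_tatp", "pi_ex_over_pcr", "pme_pde", "ph", "mg",
)


@dataclass(frozen=True)
class ResonanceSpec:
    """One resonance of the panel: position, area and Voigt widths (ppm)."""

    name: str
    center: float
    area: float
    gaussian_width: float = 0.03
    lorentzian_width: float = 0.05

    def __post_init__(self) -> None:
        if self.name not in RESONANCE_NAMES:
            raise ValueError(f"unknown resonance name {self.name!r}")
        if self.area < 0:
            raise ValueError(f"{self.name}: area must be >= 0")
        if self.gaussian_width < 0 or self.lorentzian_width < 0:
            raise ValueError(f"{self.name}: widths must be >= 0")
        if self.name == "PCr" and self.center != 0.0:
            raise ValueError("PCr defines the ppm reference and must sit at 0 ppm")


# Chemical-shift priors (ppm vs PCr) from standard 31P brain literature;
# only the PCr reference at 0 ppm is fixed by convention.
_DEFAULT_CENTERS = {
    "PE": 6.8, "PC": 6.2, "Pi_ex": 5.2, "Pi_in": 4.8, "GPE": 3.5, "GPC": 3.0,
    "PCr": 0.0, "gATP": -2.5, "aATP": -7.6, "NAD": -8.3, "UDPG": -9.8,
    "bATP": -16.1, "MM": 2.0,
}

# Relative areas of a typical healthy spectrum (arbitrary units; t-ATP = 1).
_DEFAULT_AREAS = {
    "PE": 0.50, "PC": 0.45, "Pi_ex": 0.25, "Pi_in": 0.55, "GPE": 0.50,
    "GPC": 0.55, "PCr": 1.90, "gATP": 1.00, "aATP": 1.00, "NAD": 0.35,
    "UDPG": 0.25, "bATP": 1.00, "MM": 1.20,
}

_DEFAULT_WIDTHS = {name: (0.03, 0.05) for name in RESONANCE_NAMES}
_DEFAULT_WIDTHS["MM"] = (0.60, 0.40)  # broad macromolecular hump


def default_panel(areas: dict[str, float] | None = None,
                  centers: dict[str, float] | None = None) -> tuple[ResonanceSpec, ...]:
    """Build the 13-resonance panel, optionally overriding areas/centers."""
    areas = {**_DEFAULT_AREAS, **(areas or {})}
    centers = {**_DEFAULT_CENTERS, **(centers or {})}
    panel = []
    for name in RESONANCE_NAMES:
        gw, lw = _DEFAULT_WIDTHS[name]
        panel.append(ResonanceSpec(name=name, center=centers[name], area=areas[name],
                                   gaussian_width=gw, lorentzian_width=lw))
    return tuple(panel)


@dataclass(frozen=True)
class GroundTruth:
    """Generative state of one simulated spectrum.

    ``panel`` holds the 13 resonances; the Pi_in center is overridden by
    pH, and the beta-ATP center by the Mg2+-dependent alpha-beta separation,
    at simulation time.  ``baseline_coefficients`` are Chebyshev
    coefficients of a smooth frequency-domain baseline added after the
    transform by :func:`simulate_spectrum`.
    """

    panel: tuple[ResonanceSpec, ...] = field(default_factory=default_panel)
    pH: float = 7.0
    mg: float = 0.20
    noise_sd: float = 0.0
    baseline_coefficients: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        names = [r.name for r in self.panel]
        if sorted(names) != sorted(RESONANCE_NAMES):
            raise ValueError("panel must contain each of the 13 resonances exactly once")
        if self.mg <= 0:
            raise ValueError("mg must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def resonance(self, name: str) -> ResonanceSpec:
        for r in self.panel:
            if r.name == name:
                return r
        raise KeyError(name)


def delta_pi_from_ph(pH: float, calib: CalibrationConstants = DEFAULT_CALIBRATION) -> float:
    """Pi chemical shift (ppm vs PCr) at a given pH.

    Inverse Henderson-Hasselbalch: the shift interpolates between the
    protonated and deprotonated limits with the base fraction
    10**(pH-pKa) / (1 + 10**(pH-pKa)).
    """
    # admissible pH window: keep the base fraction resolvable
    lo, hi = calib.pka - 3.0, calib.pka + 3.0
    if not (lo < pH < hi):
        raise ValueError(
            f"pH {pH} outside the admissible interval ({lo}, {hi}) of the calibration"
        )
    frac = 10.0 ** (pH - calib.pka) / (1.0 + 10.0 ** (pH - calib.pka))
    return calib.delta_acid + (calib.delta_base - calib.delta_acid) * frac


def delta_ab_from_mg(mg: float, calib: CalibrationConstants = DEFAULT_CALIBRATION) -> float:
    """alpha-beta ATP shift separation (ppm) at a given free Mg2+ (mM).

    1:1 binding isotherm: the separation moves from the Mg-free limit to the
    fully bound limit with saturation mg / (Kd + mg); strictly monotone.
    """
    if mg <= 0:
        raise ValueError("mg must be positive (mM)")
    sat = mg / (calib.kd_mgatp + mg)
    return calib.delta_ab_free + (calib.delta_ab_bound - calib.delta_ab_free) * sat


def _effective_panel(truth: GroundTruth, calib: CalibrationConstants) -> tuple[ResonanceSpec, ...]:
    """Panel with Pi_in and beta-ATP centers overridden by pH and Mg2+."""
    delta_pi = delta_pi_from_ph(truth.pH, calib)
    delta_ab = delta_ab_from_mg(truth.mg, calib)
    alpha = truth.resonance("aATP").center
    out = []
    for r in truth.panel:
        if r.name == "Pi_in":
            out.append(replace(r, center=delta_pi))
        elif r.name == "bATP":
            out.append(replace(r, center=alpha - delta_ab))
        else:
            out.append(r)
    return tuple(out)


def simulate_fid(truth: GroundTruth, acq: AcquisitionParams = AcquisitionParams(),
                 calib: CalibrationConstants = DEFAULT_CALIBRATION) -> FID:
    """Synthesize the complex FID of a 13-resonance Voigt spectrum.

    Each resonance contributes A * exp(2*pi*i*nu*t) damped by an exponential
    (Lorentzian FWHM) and a Gaussian (Gaussian FWHM) envelope, so its
    continuous-FT lineshape is exactly the Voigt profile with those widths
    and unit-area normalization times A.  Circular complex Gaussian noise of
    per-component standard deviation ``noise_sd`` is added, seeded by
    ``truth.seed`` (bit-identical under identical seeds).
    """
    panel = _effective_panel(truth, calib)
    half_window = 0.5 * acq.spectral_width * acq.ppm_per_hz
    t = acq.time_axis()
    signal = np.zeros(acq.n_points, dtype=complex)
    for r in panel:
        if not (-half_window < r.center < half_window):
            raise ValueError(
                f"resonance {r.name} at {r.center:.2f} ppm falls outside the "
                f"spectral window (+/-{half_window:.2f} ppm)"
            )
        nu = r.center * acq.transmitter_frequency        # ppm * MHz -> Hz
        lw_hz = r.lorentzian_width * acq.transmitter_frequency
        gw_hz = r.gaussian_width * acq.transmitter_frequency
        envelope = np.exp(-math.pi * lw_hz * t - (math.pi * gw_hz * t) ** 2 / (4.0 * _LN2))
        signal += r.area * np.exp(2j * math.pi * nu * t) * envelope
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        noise = rng.standard_normal(acq.n_points) + 1j * rng.standard_normal(acq.n_points)
        signal = signal + truth.noise_sd * noise
    entry = {"op": "simulate_fid", "seed": truth.seed, "noise_sd": truth.noise_sd}
    return FID(samples=signal, acq=acq, history=(entry,))


def _baseline_on_axis(coeffs: tuple[float, ...], ppm_axis: np.ndarray) -> np.ndarray:
    if len(coeffs) == 0:
        return np.zeros_like(ppm_axis)
    half = max(abs(ppm_axis[0]), abs(ppm_axis[-1]))
    u = ppm_axis / half
    return np.polynomial.chebyshev.chebval(u, list(coeffs))


def simulate_spectrum(truth: GroundTruth, acq: AcquisitionParams = AcquisitionParams(),
                      calib: CalibrationConstants = DEFAULT_CALIBRATION,
                      zero_fill_to: int | None = 4096) -> Spectrum:
    """FID synthesis plus the default processing chain and baseline.

    Zero-fills (2048 -> 4096 by default), Fourier transforms, and adds the
    ground-truth baseline polynomial to the real channel of the spectrum.
    The result is already phased (the simulated decay starts in absorption).
    """
    fid = simulate_fid(truth, acq, calib)
    if zero_fill_to is not None and zero_fill_to > acq.n_points:
        fid = zero_fill(fid, zero_fill_to)
    spec = to_spectrum(fid)
    if truth.baseline_coefficients:
        base = _baseline_on_axis(truth.baseline_coefficients, spec.ppm_axis)
        spec = spec.with_intensities(spec.intensities + base,
                                     {"op": "add_baseline", "coefficients": truth.baseline_coefficients})
    return spec


def noise_sd_for_snr(truth: GroundTruth, snr: float,
                     acq: AcquisitionParams = AcquisitionParams(),
                     calib: CalibrationConstants = DEFAULT_CALIBRATION,
                     zero_fill_to: int | None = 4096) -> float:
    """FID noise level giving a target spectral SNR (PCr height / noise sd).

    In the ppm-integral units of :func:`pbem.preprocess.to_spectrum` the
    real-channel noise sd of the spectrum is
    ``noise_sd * 2 * dwell * f0 * sqrt(n_acquired)``; the PCr height is
    measured on the noiseless simulated spectrum.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean = simulate_spectrum(replace(truth, noise_sd=0.0), acq, calib, zero_fill_to)
    near_pcr = np.abs(clean.ppm_axis) < 0.5
    height = float(clean.real[near_pcr].max())
    scale = 2.0 * acq.dwell_time * acq.transmitter_frequency
    return height / (snr * scale * math.sqrt(acq.n_points))


def ground_truth_markers(truth: GroundTruth) -> dict[str, float]:
    """The marker values implied by a ground-truth panel (see markers module)."""
    a = {r.name: r.area for r in truth.panel}
    t_atp = (a["aATP"] + a["bATP"] + a["gATP"]) / 3.0
    return {
        "energy_reserve": a["PCr"] / t_atp,
        "energy_consumption": a["Pi_in"] / t_atp,
        "metabolic_state": a["Pi_in"] / a["PCr"],
        "pi_ex_over_tatp": a["Pi_ex"] / t_atp,
        "pi_ex_over_pcr": a["Pi_ex"] / a["PCr"],
        "pme_pde": (a["PE"] + a["PC"]) / (a["GPE"] + a["GPC"]),
        "ph": truth.pH,
        "mg": truth.mg,
    }


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

GROUPS = ("CN", "aMCI", "AD")

# Signed group contrasts (aMCI-CN, AD-CN) per region x primitive marker on
# the latent analysis scale, following the directions and approximate sizes
# of the reported temporal/frontal/parietal/occipital ANOVA contrasts:
# energy reserve and consumption lowered in aMCI/AD (temporal), metabolic
# state elevated and Mg2+ lowered in AD (temporal).  Consumption and
# Pi_ex/PCr are algebraically derived from the primitives, so they carry no
# entry here.
_DEFAULT_GROUP_EFFECTS = {
    ("frontal", "energy_reserve"): (0.11, 0.07),
    ("temporal", "energy_reserve"): (-0.88, -1.65),
    ("parietal", "energy_reserve"): (-0.63, -0.23),
    ("occipital", "energy_reserve"): (-0.01, -0.44),
    ("frontal", "metabolic_state"): (-0.07, -0.20),
    ("temporal", "metabolic_state"): (-0.21, 0.95),
    ("parietal", "metabolic_state"): (0.001, 0.44),
    ("occipital", "metabolic_state"): (-0.07, 0.32),
    ("frontal", "pi_ex_over_tatp"): (0.43, 0.93),
    ("temporal", "pi_ex_over_tatp"): (-0.71, -0.32),
    ("parietal", "pi_ex_over_tatp"): (0.22, 0.04),
    ("occipital", "pi_ex_over_tatp"): (-0.35, 0.44),
    ("frontal", "ph"): (-0.17, -0.17),
    ("temporal", "ph"): (-0.03, 0.23),
    ("parietal", "ph"): (0.27, 0.09),
    ("occipital", "ph"): (-0.36, -0.98),
    ("frontal", "mg"): (-0.34, 0.05),
    ("temporal", "mg"): (0.16, -1.03),
    ("parietal", "mg"): (-0.14, 0.61),
    ("occipital", "mg"): (-0.03, -0.61),
    ("frontal", "pme_pde"): (-0.11, 0.59),
    ("temporal", "pme_pde"): (-0.27, 0.27),
    ("parietal", "pme_pde"): (0.61, 0.61),
    ("occipital", "pme_pde"): (-0.73, -0.32),
}

# Residual scatter per primitive marker on the latent scale.  Calibrated so
# the default contrasts above and their significance levels are consistent
# at the default group sizes (a contrast of -0.88 with n=15/15 then carries
# a Tukey-adjusted p near 0.01, as reported for the temporal reserve index).
_DEFAULT_RESIDUAL_SD = {
    "energy_reserve": 0.75,
    "metabolic_state": 0.87,
    "pi_ex_over_tatp": 0.85,
    "ph": 0.85,
    "mg": 0.86,
    "pme_pde": 0.85,
}

# Latent -> physical maps: ratios and Mg2+ are lognormal around a healthy
# mean, pH is Gaussian.  The per-unit latent scales set realistic
# physiological coefficients of variation (~9-13% for ratios, 0.04 pH
# units, ~9% for Mg2+).
_PHYSICAL_MEAN = {
    "energy_reserve": 1.90, "metabolic_state": 0.29, "pi_ex_over_tatp": 0.25,
    "pme_pde": 0.905, "ph": 7.00, "mg": 0.20,
}
_LATENT_UNIT = {
    "energy_reserve": 0.15, "metabolic_state": 0.15, "pi_ex_over_tatp": 0.15,
    "pme_pde": 0.15, "ph": 0.045, "mg": 0.10,
}

# Demographics per group (CN, aMCI, AD): age and education mean/sd in
# years, and the fraction of female participants.
_DEFAULT_AGE = ((63.47, 6.13), (66.53, 6.74), (71.73, 5.68))
_DEFAULT_EDU = ((17.83, 2.91), (17.33, 3.21), (16.82, 3.68))
_DEFAULT_FEMALE_FRAC = (11 / 15, 10 / 15, 6 / 11)

# Group mean shifts of the cognitive domain z-scores (aMCI, AD), typical of
# amnestic MCI and mild dementia neuropsychology.
_DEFAULT_COGNITION_EFFECTS = {
    "executive": (-0.5, -1.2),
    "memory": (-1.2, -2.0),
    "attention": (-0.4, -0.8),
    "language": (-0.3, -0.7),
    "visuospatial": (-0.3, -0.8),
}

# Slope linking the temporal-lobe Mg2+ latent residual to the memory,
# executive and attention z-scores, per group: positive coupling in
# controls, inverted in the impaired groups.
_DEFAULT_MARKER_COGNITION_SLOPES = {"CN": 0.30, "aMCI": -0.25, "AD": -0.30}


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic three-group cohort.

    ``group_effects`` maps (region, marker) to the (aMCI-CN, AD-CN) mean
    shifts on the latent analysis scale; ``covariate_slopes`` inject age /
    gender / education dependence into every marker (removed downstream by
    covariate adjustment, as in the analysis pipeline).
    """

    n_per_group: tuple[int, int, int] = (15, 15, 11)
    group_effects: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_EFFECTS))
    residual_sd: dict = field(default_factory=lambda: dict(_DEFAULT_RESIDUAL_SD))
    covariate_slopes: tuple[float, float, float] = (-0.04, -0.35, 0.02)  # age/yr, female, edu/yr
    age_distribution: tuple = _DEFAULT_AGE
    education_distribution: tuple = _DEFAULT_EDU
    female_fraction: tuple[float, float, float] = _DEFAULT_FEMALE_FRAC
    cognition_effects: dict = field(default_factory=lambda: dict(_DEFAULT_COGNITION_EFFECTS))
    cognition_residual_sd: float = 0.9
    marker_cognition_slopes: dict = field(
        default_factory=lambda: dict(_DEFAULT_MARKER_COGNITION_SLOPES))
    effect_scale: float = 1.0
    spectrum_snr: float = 25.0
    baseline_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs at least 2 participants")
        if len(self.n_per_group) != 3:
            raise ValueError("n_per_group must give counts for (CN, aMCI, AD)")


def _adjustment_compensation(design: "CohortDesign") -> np.ndarray:
    """2x2 map turning target post-adjustment contrasts into injected shifts.

    Group membership is correlated with the covariates (the AD group is
    older), so pooled covariate adjustment soaks up part of any true group
    effect: the expected post-adjustment contrast is a linear shrinkage of
    the injected one.  This computes the expected linear map
    (injected aMCI/AD shifts) -> (post-adjustment aMCI/AD contrasts vs CN)
    from the design's demographic distributions alone and returns its
    inverse, so that the generator realizes the *stated* contrasts after
    the analysis pipeline's own adjustment step.
    """
    w = np.array(design.n_per_group, dtype=float)
    w = w / w.sum()
    mu = np.array([
        [design.age_distribution[g][0], design.female_fraction[g],
         design.education_distribution[g][0]]
        for g in range(3)
    ])
    mu_bar = w @ mu
    dev = mu - mu_bar
    sigma_w = np.zeros((3, 3))
    for g in range(3):
        f = design.female_fraction[g]
        sigma_w += w[g] * np.diag([design.age_distribution[g][1] ** 2,
                                   f * (1.0 - f),
                                   design.education_distribution[g][1] ** 2])
    sigma_tot = sigma_w + dev.T @ (w[:, None] * dev)
    sigma_inv = np.linalg.inv(sigma_tot)

    def post_contrasts(s1: float, s2: float) -> np.ndarray:
        s = np.array([0.0, s1, s2])
        s_bar = float(w @ s)
        cov_cs = dev.T @ (w * (s - s_bar))
        post = s - dev @ (sigma_inv @ cov_cs)
        return np.array([post[1] - post[0], post[2] - post[0]])

    A = np.column_stack([post_contrasts(1.0, 0.0), post_contrasts(0.0, 1.0)])
    return np.linalg.inv(A)


@dataclass(frozen=True)
class SimulatedRegion:
    """One participant-region acquisition: the raw FID and its ground truth."""

    fid: FID
    truth: GroundTruth


def _truth_for_markers(markers: dict[str, float], scale: float, seed: int,
                       noise_sd: float, baseline: tuple[float, ...]) -> GroundTruth:
    """Construct a panel realizing the given marker values exactly."""
    pde = _DEFAULT_AREAS["GPE"] + _DEFAULT_AREAS["GPC"]
    pme = markers["pme_pde"] * pde
    pe_share = _DEFAULT_AREAS["PE"] / (_DEFAULT_AREAS["PE"] + _DEFAULT_AREAS["PC"])
    areas = {
        "aATP": 1.0, "bATP": 1.0, "gATP": 1.0,
        "PCr": markers["energy_reserve"],
        "Pi_in": markers["energy_reserve"] * markers["metabolic_state"],
        "Pi_ex": markers["pi_ex_over_tatp"],
        "GPE": _DEFAULT_AREAS["GPE"], "GPC": _DEFAULT_AREAS["GPC"],
        "PE": pme * pe_share, "PC": pme * (1.0 - pe_share),
        "NAD": _DEFAULT_AREAS["NAD"], "UDPG": _DEFAULT_AREAS["UDPG"],
        "MM": _DEFAULT_AREAS["MM"],
    }
    areas = {k: v * scale for k, v in areas.items()}
    return GroundTruth(panel=default_panel(areas=areas), pH=markers["ph"],
                       mg=markers["mg"], noise_sd=noise_sd,
                       baseline_coefficients=baseline, seed=seed)


def simulate_cohort(design: CohortDesign,
                    acq: AcquisitionParams = AcquisitionParams(),
                    calib: CalibrationConstants = DEFAULT_CALIBRATION,
                    with_spectra: bool = True,
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str], SimulatedRegion]]:
    """Simulate a full cohort: covariates, markers, cognition and spectra.

    Returns the cohort table (one row per participant: group, covariates,
    ground-truth markers per region, cognitive z-scores) and, when
    ``with_spectra`` is set, a mapping (participant_id, region) -> raw FID
    plus its generative ground truth.  Reproducible bit-for-bit under a
    fixed ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    primitives = tuple(_DEFAULT_RESIDUAL_SD)
    # pre-compensate group shifts for the expected shrinkage induced by
    # pooled covariate adjustment under age-confounded group membership,
    # so the stated contrasts are realized post-adjustment
    comp = _adjustment_compensation(design)
    injected: dict[tuple[str, str], np.ndarray] = {}
    for key, eff in design.group_effects.items():
        injected[key] = comp @ (design.effect_scale * np.asarray(eff, dtype=float))
    rows = []
    spectra: dict[tuple[str, str], SimulatedRegion] = {}
    pid_counter = 0
    for gi, group in enumerate(GROUPS):
        n = design.n_per_group[gi]
        age_mu, age_sd = design.age_distribution[gi]
        edu_mu, edu_sd = design.education_distribution[gi]
        for _ in range(n):
            pid = f"P{pid_counter:03d}"
            pid_counter += 1
            age = float(rng.normal(age_mu, age_sd))
            education = float(np.clip(rng.normal(edu_mu, edu_sd), 8.0, 24.0))
            gender = int(rng.random() < design.female_fraction[gi])  # 1 = female
            b_age, b_gender, b_edu = design.covariate_slopes
            covariate_term = (b_age * (age - 65.0) + b_gender * gender
                              + b_edu * (education - 17.0))
            row: dict[str, object] = {
                "id": pid, "group": group, "age": age,
                "education": education, "gender": gender,
            }
            mg_resid_temporal = 0.0
            for region in REGIONS:
                markers: dict[str, float] = {}
                for marker in primitives:
                    shift = 0.0
                    if gi > 0 and (region, marker) in injected:
                        shift = float(injected[(region, marker)][gi - 1])
                    resid = design.residual_sd[marker] * float(rng.standard_normal())
                    latent = shift + covariate_term + resid
                    if marker == "mg" and region == "temporal":
                        mg_resid_temporal = resid
                    mu = _PHYSICAL_MEAN[marker]
                    unit = _LATENT_UNIT[marker]
                    if marker == "ph":
                        markers[marker] = mu + unit * latent
                    else:
                        markers[marker] = mu * math.exp(unit * latent)
                markers["energy_consumption"] = (
                    markers["energy_reserve"] * markers["metabolic_state"])
                markers["pi_ex_over_pcr"] = (
                    markers["pi_ex_over_tatp"] / markers["energy_reserve"])
                for marker in MARKER_NAMES:
                    row[f"{region}_{marker}"] = markers[marker]
                if with_spectra:
                    scale = math.exp(0.1 * float(rng.standard_normal()))
                    seed = int(rng.integers(0, 2**31 - 1))
                    baseline = ()
                    if design.baseline_amplitude > 0:
                        coeffs = design.baseline_amplitude * rng.normal(size=3)
                        coeffs[0] = abs(coeffs[0])
                        baseline = tuple(float(c) for c in coeffs)
                    truth = _truth_for_markers(markers, scale, seed, 0.0, baseline)
                    if design.spectrum_snr > 0:
                        noise_sd = noise_sd_for_snr(truth, design.spectrum_snr, acq, calib)
                        truth = replace(truth, noise_sd=noise_sd)
                    spectra[(pid, region)] = SimulatedRegion(
                        fid=simulate_fid(truth, acq, calib), truth=truth)
            slope = design.marker_cognition_slopes.get(group, 0.0)
            for domain in COGNITIVE_DOMAINS:
                shift = 0.0
                if gi > 0:
                    shift = design.effect_scale * design.cognition_effects.get(
                        domain, (0.0, 0.0))[gi - 1]
                coupled = slope * mg_resid_temporal if domain in (
                    "memory", "executive", "attention") else 0.0
                z = (shift - 0.02 * (age - 65.0) + coupled
                     + design.cognition_residual_sd * float(rng.standard_normal()))
                row[f"cog_{domain}"] = z
            rows.append(row)
    table = pd.DataFrame(rows)
    return table, spectra
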