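"""Phosphate brain-energy-metabolism markers from fitted spectra.

From the 13 fitted resonance integrals and chemical shifts of one
region-summed spectrum this module derives, per brain region:

* the energy indices - energy reserve PCr/t-ATP, energy consumption
  Pi(in)/t-ATP, metabolic state Pi(in)/PCr, where t-ATP is the arithmetic
  mean (not sum) of the alpha-, beta- and gamma-ATP signals;
* the extracellular-Pi ratios Pi(ex)/t-ATP and Pi(ex)/PCr;
* the membrane phospholipid index PME/PDE = (PE+PC)/(GPE+GPC), sums in
  both numerator and denominator;
* the regulatory co-factors: intracellular pH from the Pi(in) shift
  (Henderson-Hasselbalch) and free Mg2+ from the alpha-beta ATP shift
  separation (MgATP binding isotherm).

All ratio indices are scale invariant (areas are relative concentrations);
pH and Mg2+ depend only on chemical shifts, never on areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .calibration import DEFAULT_CALIBRATION, CalibrationConstants
from .voigtfit import FitResult

__all__ = ["RegionMarkers", "total_atp", "ph_from_delta", "mg_from_delta", "bem_indices"]

REGION_NAMES = ("frontal", "temporal", "parietal", "occipital")


@dataclass(frozen=True)
class RegionMarkers:
    """The marker set of one brain region."""

    region: str
    energy_reserve: float       # PCr / t-ATP
    energy_consumption: float   # Pi_in / t-ATP
    metabolic_state: float      # Pi_in / PCr
    pi_ex_over_tatp: float
    pi_ex_over_pcr: float
    pme_pde: float              # (PE + PC) / (GPE + GPC)
    ph: float
    mg: float                   # mM
    t_atp: float                # mean of alpha/beta/gamma ATP areas

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "region"}


def total_atp(alpha: float, beta: float, gamma: float) -> float:
    """Total-ATP signal: the arithmetic mean of the three ATP spin areas."""
    if alpha < 0 or beta < 0 or gamma < 0:
        raise ValueError("ATP areas must be non-negative")
    return (alpha + beta + gamma) / 3.0


def ph_from_delta(delta_pi: float, calib: CalibrationConstants = DEFAULT_CALIBRATION) -> float:
    """Intracellular pH from the Pi chemical shift (ppm vs PCr).

    Henderson-Hasselbalch: pH = pKa + log10((d - d_acid)/(d_base - d));
    strictly monotone between the two limiting shifts.
    """
    lo = min(calib.delta_acid, calib.delta_base)
    hi = max(calib.delta_acid, calib.delta_base)
    if not (lo < delta_pi < hi):
        raise ValueError(
            f"Pi shift {delta_pi:.4f} ppm outside the open titration interval "
            f"({lo:.4f}, {hi:.4f}) ppm"
        )
    return calib.pka + math.log10(
        (delta_pi - calib.delta_acid) / (calib.delta_base - delta_pi)
    )


def mg_from_delta(delta_ab: float, calib: CalibrationConstants = DEFAULT_CALIBRATION) -> float:
    """Free Mg2+ (mM) from the alpha-beta ATP shift separation (ppm).

    Inverts the 1:1 MgATP binding isotherm:
    mg = Kd * (d - d_free) / (d_bound - d).
    """
    lo = min(calib.delta_ab_free, calib.delta_ab_bound)
    hi = max(calib.delta_ab_free, calib.delta_ab_bound)
    if not (lo < delta_ab < hi):
        side = ("at/beyond the Mg-saturated limit"
                if abs(delta_ab - calib.delta_ab_bound) <= abs(delta_ab - calib.delta_ab_free)
                else "at/beyond the Mg-free limit")
        raise ValueError(
            f"delta_ab {delta_ab:.4f} ppm outside the open interval ({lo:.4f}, {hi:.4f}) ppm "
            f"({side})"
        )
    return calib.kd_mgatp * (delta_ab - calib.delta_ab_free) / (calib.delta_ab_bound - delta_ab)


def bem_indices(fit: FitResult, region: str,
                calib: CalibrationConstants = DEFAULT_CALIBRATION) -> RegionMarkers:
    """All region markers from one converged fit of a region-summed spectrum."""
    if region not in REGION_NAMES:
        raise ValueError(f"unknown region {region!r}; expected one of {REGION_NAMES}")
    if not fit.converged:
        raise ValueError("refusing to derive markers from a non-converged fit")
    t_atp = total_atp(fit.area("aATP"), fit.area("bATP"), fit.area("gATP"))
    pcr = fit.area("PCr")
    pde = fit.area("GPE") + fit.area("GPC")
    if t_atp == 0:
        raise ZeroDivisionError("t-ATP signal is zero; ratio indices undefined")
    if pcr == 0:
        raise ZeroDivisionError("PCr signal is zero; ratio indices undefined")
    if pde == 0:
        raise ZeroDivisionError("PDE (GPE+GPC) signal is zero; PME/PDE undefined")
    return RegionMarkers(
        region=region,
        energy_reserve=pcr / t_atp,
        energy_consumption=fit.area("Pi_in") / t_atp,
        metabolic_state=fit.area("Pi_in") / pcr,
        pi_ex_over_tatp=fit.area("Pi_ex") / t_atp,
        pi_ex_over_pcr=fit.area("Pi_ex") / pcr,
        pme_pde=(fit.area("PE") + fit.area("PC")) / pde,
        ph=ph_from_delta(fit.delta_pi, calib),
        mg=mg_from_delta(fit.delta_ab, calib),
        t_atp=t_atp,
    )
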