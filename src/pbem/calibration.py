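"""Chemical-shift calibration constants for pH and free-Mg2+ estimation.

Both quantities are read off chemical shifts referenced to PCr at 0 ppm:

* intracellular pH from the inorganic-phosphate shift ``delta_Pi`` through a
  Henderson-Hasselbalch titration curve, and
* free intracellular Mg2+ from the alpha-beta ATP shift separation
  ``delta_ab = delta(alpha-ATP) - delta(beta-ATP)`` through a 1:1 MgATP
  binding isotherm.

The numeric defaults are conventional in-vivo 31P values (Petroff-type Pi
titration; MgATP separation limits bracketing the usual ~8.5 ppm in-vivo
reading).  They are configuration, not hard-coded physics: studies using a
different temperature or ionic-strength calibration should construct their
own :class:`CalibrationConstants`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CalibrationConstants", "DEFAULT_CALIBRATION"]


@dataclass(frozen=True)
class CalibrationConstants:
    """Titration/binding constants linking chemical shifts to pH and Mg2+.

    Parameters
    ----------
    pka : float
        Apparent pKa of the Pi H2PO4-/HPO4-- equilibrium.
    delta_acid : float
        Limiting Pi shift of the fully protonated species, ppm vs PCr.
    delta_base : float
        Limiting Pi shift of the fully deprotonated species, ppm vs PCr.
    kd_mgatp : float
        Apparent dissociation constant of the MgATP complex, mM.
    delta_ab_free : float
        alpha-beta ATP shift separation of Mg-free ATP, ppm.
    delta_ab_bound : float
        alpha-beta ATP shift separation of fully Mg-bound ATP, ppm.
    """

    pka: float = 6.75
    delta_acid: float = 3.27
    delta_base: float = 5.69
    kd_mgatp: float = 0.05
    delta_ab_free: float = 8.94
    delta_ab_bound: float = 8.24

    def __post_init__(self) -> None:
        if self.delta_acid == self.delta_base:
            raise ValueError("delta_acid and delta_base must differ")
        if self.delta_ab_free == self.delta_ab_bound:
            raise ValueError("delta_ab_free and delta_ab_bound must differ")
        if self.kd_mgatp <= 0:
            raise ValueError("kd_mgatp must be positive")


DEFAULT_CALIBRATION = CalibrationConstants()
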