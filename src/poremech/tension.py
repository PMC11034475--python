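"""Bilayer tension and leaflet adhesion energy from monolayer quantities.

A bilayer zipped together from two lipid monolayers at an oil-buffer
interface meets them at a contact angle ``theta``.  Young's equation gives
the bilayer tension

    Gamma = 2 gamma cos(theta),

and the adhesion energy per unit area between the two leaflets is the
tension deficit

    dW = 2 gamma - Gamma = 2 gamma (1 - cos(theta)).

``gamma`` is the interfacial tension of one lipid-decorated monolayer
(measured e.g. by pendant-drop analysis) in mN/m and ``theta`` the contact
angle in degrees; Gamma is then in mN/m and dW in mJ/m^2 (numerically
identical units).  The identity ``2 gamma = Gamma + dW`` holds exactly.

The AFM pre-stress sigma of a pore-spanning membrane and Gamma are both
in-plane tensions but originate from different preparations (substrate
adhesion vs. leaflet zipping); they are reported side by side, never
equated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["bilayer_tension", "adhesion_energy", "MonolayerInterface"]


def _check(gamma: float, theta_deg: float):
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if not 0.0 <= theta_deg < 90.0:
        raise ValueError(
            f"theta must be in [0, 90) degrees (monolayers would not adhere "
            f"otherwise), got {theta_deg}")


def bilayer_tension(gamma: float, theta_deg: float) -> float:
    """Gamma = 2 gamma cos(theta) [mN/m] (Young's equation)."""
    _check(gamma, theta_deg)
    return 2.0 * gamma * math.cos(math.radians(theta_deg))


def adhesion_energy(gamma: float, theta_deg: float) -> float:
    """dW = 2 gamma (1 - cos(theta)) [mJ/m^2]."""
    _check(gamma, theta_deg)
    return 2.0 * gamma * (1.0 - math.cos(math.radians(theta_deg)))


@dataclass(frozen=True)
class MonolayerInterface:
    """(gamma, theta) pair with derived Gamma, dW and propagated errors.

    First-order (delta-method) propagation of the stated standard errors:
    the derivatives of Gamma are (2 cos theta, -2 gamma sin theta) and of
    dW are (2 (1 - cos theta), 2 gamma sin theta), with theta in radians.
    Zero input errors propagate to zero.
    """

    gamma: float               # mN/m
    theta_deg: float           # degrees
    gamma_se: float = 0.0
    theta_se_deg: float = 0.0
    label: str = ""

    def __post_init__(self):
        _check(self.gamma, self.theta_deg)
        if self.gamma_se < 0 or self.theta_se_deg < 0:
            raise ValueError("standard errors must be >= 0")

    @property
    def bilayer_tension(self) -> float:
        return bilayer_tension(self.gamma, self.theta_deg)

    @property
    def adhesion_energy(self) -> float:
        return adhesion_energy(self.gamma, self.theta_deg)

    @property
    def bilayer_tension_se(self) -> float:
        th = math.radians(self.theta_deg)
        th_se = math.radians(self.theta_se_deg)
        return math.hypot(2.0 * math.cos(th) * self.gamma_se,
                          2.0 * self.gamma * math.sin(th) * th_se)

    @property
    def adhesion_energy_se(self) -> float:
        th = math.radians(self.theta_deg)
        th_se = math.radians(self.theta_se_deg)
        return math.hypot(2.0 * (1.0 - math.cos(th)) * self.gamma_se,
                          2.0 * self.gamma * math.sin(th) * th_se)

    def to_row(self) -> dict:
        return {
            "label": self.label,
            "gamma_mN_m": self.gamma,
            "gamma_se": self.gamma_se,
            "theta_deg": self.theta_deg,
            "theta_se_deg": self.theta_se_deg,
            "Gamma_mN_m": self.bilayer_tension,
            "Gamma_se": self.bilayer_tension_se,
            "dW_mJ_m2": self.adhesion_energy,
            "dW_se": self.adhesion_energy_se,
        }
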