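"""Density-dependent elastic material laws.

Apparent density rho (g/cm^3) maps to a Young's modulus through a power
law E(rho) = a * rho**b in MPa; Poisson's ratio is density-independent.
Three laws from the trabecular-bone literature are built in:

=====  ======  ====  =========================================
label  a, MPa  b     typical use
=====  ======  ====  =========================================
E1     1904    1.64  baseline (stable remodeling trajectories)
E2     2038    2.5   higher-power alternative
E3     3227    3.0   highest-power alternative
=====  ======  ====  =========================================

With densities in g/cm^3 and lengths in mm, stresses and moduli are in
MPa and strain energy density is in MPa = J/cm^3, so the remodeling
stimulus U/rho is in J/g with no conversion factor.

Elements at the lower density clamp keep their (small but positive)
modulus; nothing is ever removed from the mesh, so ill-conditioning, not
singularity, is the failure mode at low density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaterialLaw", "youngs_modulus", "builtin_laws"]


@dataclass(frozen=True)
class MaterialLaw:
    """Power-law density -> Young's modulus relationship.

    E(rho) = coefficient_mpa * rho ** exponent, rho in g/cm^3, E in MPa.
    """

    coefficient_mpa: float
    exponent: float
    poisson_ratio: float = 0.3
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.coefficient_mpa <= 0:
            raise ValueError(f"coefficient_mpa must be > 0, got {self.coefficient_mpa}")
        if self.exponent <= 0:
            raise ValueError(f"exponent must be > 0, got {self.exponent}")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError(
                f"poisson_ratio must lie in (0, 0.5), got {self.poisson_ratio}"
            )

    def youngs_modulus(self, density):
        """Evaluate E(rho) in MPa for scalar or array density in g/cm^3."""
        rho = np.asarray(density, dtype=float)
        if np.any(rho <= 0):
            raise ValueError("density must be strictly positive")
        E = self.coefficient_mpa * rho**self.exponent
        return float(E) if np.isscalar(density) else E

    __call__ = youngs_modulus


def youngs_modulus(law: MaterialLaw, density):
    """Functional form of :meth:`MaterialLaw.youngs_modulus`."""
    return law.youngs_modulus(density)


def builtin_laws() -> dict[str, MaterialLaw]:
    """The three built-in power laws, keyed by label."""
    return {
        "E1": MaterialLaw(1904.0, 1.64, 0.3, "E1"),
        "E2": MaterialLaw(2038.0, 2.5, 0.3, "E2"),
        "E3": MaterialLaw(3227.0, 3.0, 0.3, "E3"),
    }
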