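"""Compressible Neo-Hookean material parameters.

The bead hydrogel is modelled as an isotropic, compressible Neo-Hookean
solid.  The two independent engineering constants are the Young's modulus
``E`` (Pa) and the Poisson ratio ``nu``; the Lamé constants and the bulk
modulus are derived from them via the small-strain relations, so the model
linearizes exactly to isotropic linear elasticity at small strain.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Material", "DEFAULT_MATERIAL"]


@dataclass(frozen=True)
class Material:
    """Compressible Neo-Hookean parameters.

    Parameters
    ----------
    E : float
        Young's modulus in Pa.  Must be positive.
    nu : float
        Poisson ratio, ``0 <= nu < 0.5``.  The incompressible limit
        ``nu = 0.5`` is excluded (the volumetric term diverges).
    """

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(f"Poisson ratio must lie in [0, 0.5), got {self.nu}")

    @property
    def mu(self) -> float:
        """Shear modulus mu = E / (2 (1 + nu)), Pa."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def lam(self) -> float:
        """First Lamé constant lambda = E nu / ((1 + nu)(1 - 2 nu)), Pa."""
        return self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))

    @property
    def kappa(self) -> float:
        """Bulk modulus kappa = E / (3 (1 - 2 nu)), Pa."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))


#: Bead defaults used throughout the validation scenarios: a polyacrylamide
#: microbead with E = 1.8 kPa and nu = 0.443.
DEFAULT_MATERIAL = Material(E=1800.0, nu=0.443)
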