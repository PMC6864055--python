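"""Calibration of bead elastic parameters from osmotic-compression data.

Beads suspended in a dextran solution experience a controlled osmotic
pressure; the resulting relative volume loss ``-dV/V`` is read from
segmented confocal stacks.  At small strains the response is linear with
slope equal to the bulk modulus kappa, and the Young's modulus follows from
``E = 3 kappa (1 - 2 nu)`` once the Poisson ratio is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompressionSeries",
    "fit_bulk_modulus",
    "young_from_bulk",
    "bulk_from_young",
]


@dataclass
class CompressionSeries:
    """Osmotic pressure (Pa) vs volumetric strain ``-dV/V`` pairs."""

    pressure: np.ndarray
    strain: np.ndarray
    strain_sd: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.pressure.shape != self.strain.shape or self.pressure.ndim != 1:
            raise ValueError("pressure and strain must be 1-D arrays of equal length")
        if self.pressure.size < 2:
            raise ValueError("need at least 2 points to fit")
        if np.any(self.pressure < 0):
            raise ValueError("osmotic pressures must be non-negative")
        if np.any(np.abs(self.strain) >= 1):
            raise ValueError("volumetric strains must lie in (-1, 1)")

    @classmethod
    def from_csv(cls, path) -> "CompressionSeries":
        """Read a two-column CSV ``pressure_Pa, volumetric_strain``."""
        df = pd.read_csv(path)
        cols = list(df.columns)
        return cls(pressure=df[cols[0]].to_numpy(), strain=df[cols[1]].to_numpy())


def fit_bulk_modulus(
    series: CompressionSeries, strain_cutoff: float = 0.15
) -> tuple[float, float]:
    """Least-squares slope of pressure vs volumetric strain through the origin.

    Only points with strain below ``strain_cutoff`` enter the fit (the
    response is close to linear up to roughly 15% volumetric strain).

    Returns
    -------
    (kappa, se) : tuple of float
        Bulk modulus in Pa and its standard error estimated from the
        residual variance.
    """
    mask = series.strain <= strain_cutoff
    x = series.strain[mask]
    y = series.pressure[mask]
    if x.size < 2:
        raise ValueError(
            f"fewer than 2 points with strain <= {strain_cutoff}; cannot fit"
        )
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all strains are zero; slope undefined")
    kappa = float(np.dot(x, y)) / sxx
    resid = y - kappa * x
    dof = max(x.size - 1, 1)
    se = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
    return kappa, se


def young_from_bulk(kappa: float, nu: float) -> float:
    """Young's modulus from bulk modulus: ``E = 3 kappa (1 - 2 nu)``."""
    if not kappa > 0:
        raise ValueError("bulk modulus must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    return 3.0 * kappa * (1.0 - 2.0 * nu)


def bulk_from_young(E: float, nu: float) -> float:
    """Bulk modulus from Young's modulus: ``kappa = E / (3 (1 - 2 nu))``."""
    if not E > 0:
        raise ValueError("Young's modulus must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5)")
    return E / (3.0 * (1.0 - 2.0 * nu))
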