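"""Soil sinks: Langmuir sorption to the solid phase and mineralization.

Sorption is treated as an equilibrium process (it operates much faster than
diffusion): each step, every annulus relaxes to the Langmuir isotherm target
S(C)*rho*V by a conservative exchange between the dissolved and sorbed
pools. The joint conservation equation

    C_new + S(C_new)*rho = C_old + Sabs_old/V,   S(C) = Smax*Ks*C/(1+Ks*C)

is a quadratic in C_new with exactly one nonnegative root, which is used
directly (unconditionally stable; same fixed point as iterating the lagged
isotherm assignment).

Mineralization removes dissolved solute as a first-order process with an
effective rate k_eff = kd * f_mb * f_T (base rate modified by the
microbial-biomass and Q10 temperature factors of the soil layer). The
update is the exact exponential decrement C*(1 - exp(-k_eff*dt)), which is
first-order-identical to the Euler form but keeps concentrations
nonnegative at any dt. Sorbed mass is protected from mineralization; a
cumulative per-annulus ledger records everything removed.
"""

from __future__ import annotations

import math

import numpy as np

from .soil_profile import DepthProperties
from .solutes import SoluteParams
from .transport import AnnularGrid

__all__ = [
    "langmuir_sorbed",
    "sorption_equilibrate",
    "mineralization_decrement",
    "effective_mineralization_rate",
]


def langmuir_sorbed(s: SoluteParams, C: np.ndarray | float):
    """Langmuir isotherm: sorbed amount per g of soil, Smax*Ks*C/(1+Ks*C)."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be >= 0")
    out = s.Smax * s.Ks * C / (1.0 + s.Ks * C)
    return out if out.shape else float(out)


def sorption_equilibrate(
    C: np.ndarray,
    Sabs: np.ndarray,
    s: SoluteParams,
    dp: DepthProperties,
    grid: AnnularGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Relax every annulus to sorption equilibrium, conserving mass.

    ``Sabs`` is the sorbed pool in umol per cm root length per annulus.
    Returns updated (C, Sabs); C*V + Sabs is unchanged per annulus.
    """
    if s.Smax == 0.0 or s.Ks == 0.0:
        return C.copy(), Sabs.copy()
    rho = dp.rho
    a = s.Smax * s.Ks * rho
    T = C + Sabs / grid.V  # total mass per unit annulus volume
    # Ks*C^2 + (1 + a - Ks*T)*C - T = 0, positive root written to avoid
    # cancellation when b > 0
    b = 1.0 + a - s.Ks * T
    disc = np.sqrt(b * b + 4.0 * s.Ks * T)
    C_new = 2.0 * T / (b + disc)
    Sabs_new = langmuir_sorbed(s, C_new) * rho * grid.V
    return C_new, Sabs_new


def effective_mineralization_rate(s: SoluteParams, dp: DepthProperties) -> float:
    """Effective first-order mineralization rate k_eff = kd*f_mb*f_T, hr^-1."""
    return s.kd * dp.f_mb * dp.f_T


def mineralization_decrement(
    C: np.ndarray,
    k_eff_per_hr: float,
    dt: float,
    grid: AnnularGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """First-order removal of dissolved solute over one step.

    Returns the updated concentrations and the mass mineralized per annulus
    (umol per cm root length) for the cumulative ledger.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if k_eff_per_hr < 0:
        raise ValueError(f"k_eff must be >= 0, got {k_eff_per_hr}")
    frac = -math.expm1(-k_eff_per_hr / 3600.0 * dt)
    removed = C * frac
    return C - removed, removed * grid.V
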