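"""Depth-dependent peat soil properties.

All soil properties that enter the radial transport problem — bulk density,
porosity, tortuosity, temperature and the two mineralization modifiers — are
pure functions of depth, parameterized for an ombrotrophic raised bog
(Mer Bleue, Ontario). Bulk density follows a power law of depth; porosity is
derived from bulk density against a baseline peat specific gravity;
tortuosity follows Archie's law of porosity; growing-season soil temperature
is logarithmic in depth; microbial biomass declines exponentially with
depth; and the temperature sensitivity of mineralization is a Q10 factor.

The model is a 1-D radial problem at a fixed depth: there is no vertical
coupling between layers. Because the bulk-density power law vanishes at
d = 0 while field observations put the surface value at the 1 cm evaluation,
all depth laws clamp depth to >= 1 cm ("the surface" is the 1 cm horizon).
The working depth range of the parameterization is 1-100 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SoilProfileParams",
    "DepthProperties",
    "MER_BLEUE",
    "bulk_density",
    "porosity",
    "tortuosity",
    "soil_temperature",
    "temperature_factor",
    "microbial_biomass_factor",
    "depth_properties",
]

#: depth (cm) below which all depth laws are clamped
SURFACE_DEPTH_CM = 1.0


@dataclass(frozen=True)
class SoilProfileParams:
    """Constants of the depth laws for one peat profile.

    Attributes
    ----------
    a_rho, b_rho:
        Power-law coefficient (g cm^-3) and exponent of bulk density vs depth.
    gs:
        Baseline specific gravity of peat (g cm^-3).
    m:
        Archie tortuosity exponent (unitless).
    i_mb, j_mb:
        Intercept and slope (per cm) of the exponential microbial-biomass
        depth modifier.
    x_T, y_T:
        Surface temperature (deg C) and log-slope (deg C per ln cm) of the
        growing-season soil temperature profile.
    q10:
        Temperature sensitivity of mineralization (factor per 10 deg C).
    """

    a_rho: float = 0.0107
    b_rho: float = 0.567
    gs: float = 1.5
    m: float = 2.3
    i_mb: float = 0.0287
    j_mb: float = -0.024
    x_T: float = 17.8
    y_T: float = 2.12
    q10: float = 2.3

    def __post_init__(self) -> None:
        if self.a_rho <= 0:
            raise ValueError(f"a_rho must be > 0, got {self.a_rho}")
        if self.gs <= 0:
            raise ValueError(f"gs must be > 0, got {self.gs}")
        if self.q10 <= 1:
            raise ValueError(f"q10 must be > 1, got {self.q10}")
        if self.y_T < 0:
            raise ValueError(f"y_T must be >= 0, got {self.y_T}")


#: Mer Bleue bog defaults
MER_BLEUE = SoilProfileParams()


@dataclass(frozen=True)
class DepthProperties:
    """Bundle of soil properties evaluated at one depth.

    rho: bulk density (g cm^-3); eps: porosity (cm^3 cm^-3);
    tau: tortuosity (>= 1); T: temperature (deg C);
    f_T: Q10 temperature factor; f_mb: microbial-biomass factor.
    """

    depth: float
    rho: float
    eps: float
    tau: float
    T: float
    f_T: float
    f_mb: float


def _clamped(d: float) -> float:
    if d < 0:
        raise ValueError(f"depth must be >= 0 cm, got {d}")
    return max(d, SURFACE_DEPTH_CM)


def bulk_density(d: float, p: SoilProfileParams = MER_BLEUE) -> float:
    """Bulk density (g cm^-3) at depth ``d`` (cm), power law of depth.

    Depth is clamped to >= 1 cm so the surface returns ``a_rho``.
    """
    return p.a_rho * _clamped(d) ** p.b_rho


def porosity(rho: float, p: SoilProfileParams = MER_BLEUE) -> float:
    """Porosity (cm^3 cm^-3) from bulk density: (gs - rho) / gs."""
    if not 0 <= rho < p.gs:
        raise ValueError(
            f"bulk density must be in [0, gs={p.gs}) for positive porosity, got {rho}"
        )
    return (p.gs - rho) / p.gs


def tortuosity(eps: float, p: SoilProfileParams = MER_BLEUE) -> float:
    """Tortuosity from porosity via Archie's power law, eps^(-m)."""
    if eps <= 0 or eps > 1:
        raise ValueError(f"porosity must be in (0, 1], got {eps}")
    return eps ** (-p.m)


def soil_temperature(d: float, p: SoilProfileParams = MER_BLEUE) -> float:
    """Growing-season soil temperature (deg C) at depth ``d`` (cm).

    Logarithmic decline with depth: x_T - y_T * ln(d), d clamped to >= 1 cm.
    """
    return p.x_T - p.y_T * math.log(_clamped(d))


def temperature_factor(T: float, p: SoilProfileParams = MER_BLEUE) -> float:
    """Q10 mineralization temperature factor, q10^(T/10).

    Mineralization shuts off in frozen soil: returns 0 for T <= 0 deg C.
    """
    if T <= 0.0:
        return 0.0
    return p.q10 ** (T / 10.0)


def microbial_biomass_factor(d: float, p: SoilProfileParams = MER_BLEUE) -> float:
    """Microbial-biomass mineralization modifier exp(i_mb + j_mb * d)."""
    if d < 0:
        raise ValueError(f"depth must be >= 0 cm, got {d}")
    return math.exp(p.i_mb + p.j_mb * d)


def depth_properties(d: float, p: SoilProfileParams = MER_BLEUE) -> DepthProperties:
    """Evaluate all depth laws consistently at one depth.

    Porosity is computed from the bulk density at ``d``, tortuosity from that
    porosity, and the temperature factor from the temperature at ``d``.
    """
    rho = bulk_density(d, p)
    eps = porosity(rho, p)
    tau = tortuosity(eps, p)
    T = soil_temperature(d, p)
    return DepthProperties(
        depth=d,
        rho=rho,
        eps=eps,
        tau=tau,
        T=T,
        f_T=temperature_factor(T, p),
        f_mb=microbial_biomass_factor(d, p),
    )
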