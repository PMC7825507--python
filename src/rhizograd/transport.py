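"""Radial annular geometry and Fickian exchange between concentric shells.

The soil around the root segment is divided into ``n`` concentric annuli of
equal width ``dr``; each annulus is homogeneous, with volume per cm of root
length V_i = pi*(r_out^2 - r_in^2) and interface area per cm length
A_i = 2*pi*r_out. Solute diffuses between adjacent annuli down the
concentration gradient with an effective diffusion coefficient

    De = D_inf * eps / (tau^2 * R(C)),

where eps and tau are the porosity and tortuosity of the peat layer and
R(C) >= 1 is the sorption retardation factor. The retardation factor uses
the textbook form R = 1 + (rho/eps) * dS/dC with the Langmuir isotherm
slope dS/dC = Smax*Ks/(1 + Ks*C)^2, so diffusion is slowest at trace
concentrations and the sorption hindrance saturates away as binding sites
fill. A secant variant (S(C)/C in place of the slope) is available via
``kind="secant"``.

Time stepping is explicit (forward Euler); callers must respect the
stability bound max(De)*dt/dr^2 <= 1/2. The outer boundary is closed
(zero flux): the domain is sized so the gradient dies out well before the
last annulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .soil_profile import DepthProperties
from .solutes import SoluteParams

__all__ = [
    "AnnularGrid",
    "StabilityError",
    "build_grid",
    "retardation_factor",
    "effective_diffusion",
    "diffusion_step",
    "advective_step",
]


class StabilityError(RuntimeError):
    """The explicit diffusion step violates its stability bound."""


@dataclass(frozen=True)
class AnnularGrid:
    """Concentric-annulus geometry around a root of radius ``r0``.

    Arrays are indexed by annulus, innermost (the rhizoplane annulus) first.
    ``A_int[i]`` is the interface area at ``r_outer[i]``; the last interface
    is the closed outer boundary.
    """

    r0: float
    n: int
    dr: float
    r_inner: np.ndarray
    r_outer: np.ndarray
    r_center: np.ndarray
    V: np.ndarray  # shell volume per cm root length, cm^3 cm^-1
    A_int: np.ndarray  # interface area per cm root length, cm^2 cm^-1

    @property
    def outer_radius(self) -> float:
        return self.r0 + self.n * self.dr


def build_grid(r0: float, n: int = 500, dr: float = 0.02) -> AnnularGrid:
    """Construct the annular grid (defaults: 500 annuli of 0.2 mm, a
    potential rhizosphere radius of 10 cm)."""
    if r0 <= 0 or dr <= 0 or n < 2:
        raise ValueError(f"need r0 > 0, dr > 0, n >= 2; got r0={r0}, n={n}, dr={dr}")
    edges = r0 + dr * np.arange(n + 1)
    r_inner = edges[:-1]
    r_outer = edges[1:]
    return AnnularGrid(
        r0=r0,
        n=n,
        dr=dr,
        r_inner=r_inner,
        r_outer=r_outer,
        r_center=0.5 * (r_inner + r_outer),
        V=np.pi * (r_outer**2 - r_inner**2),
        A_int=2.0 * np.pi * r_outer,
    )


def retardation_factor(
    s: SoluteParams,
    dp: DepthProperties,
    C: np.ndarray | float,
    kind: str = "slope",
):
    """Sorption retardation factor R(C) >= 1.

    ``kind="slope"`` (default): R = 1 + (rho/eps) * Smax*Ks/(1 + Ks*C)^2.
    ``kind="secant"``: R = 1 + (rho/eps) * S(C)/C (the C -> 0 limits agree).
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be >= 0")
    if kind == "slope":
        r = 1.0 + (dp.rho / dp.eps) * s.Smax * s.Ks / (1.0 + s.Ks * C) ** 2
    elif kind == "secant":
        # S(C)/C = Smax*Ks/(1+Ks*C), also correct at C = 0
        r = 1.0 + (dp.rho / dp.eps) * s.Smax * s.Ks / (1.0 + s.Ks * C)
    else:
        raise ValueError(f"unknown retardation kind {kind!r}")
    return r if r.shape else float(r)


def effective_diffusion(
    s: SoluteParams,
    dp: DepthProperties,
    C: np.ndarray | float,
    kind: str = "slope",
):
    """Effective diffusion coefficient De = D_inf*eps/(tau^2 * R), cm^2 s^-1."""
    return s.D_inf * dp.eps / (dp.tau**2 * retardation_factor(s, dp, C, kind))


def diffusion_step(
    C: np.ndarray,
    grid: AnnularGrid,
    De: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One explicit Fickian exchange step between adjacent annuli.

    ``De`` is the per-interface effective diffusivity (length n-1, at the
    internal interfaces). Returns the updated concentrations and the mass
    moved outward across each internal interface during the step
    (umol per cm root length). The outer boundary is closed; internal
    exchange conserves total solution-phase mass.
    """
    De = np.asarray(De, dtype=float)
    bound = float(np.max(De, initial=0.0)) * dt / grid.dr**2
    if bound > 0.5:
        raise StabilityError(
            f"explicit diffusion unstable: max(De)*dt/dr^2 = {bound:.3g} > 0.5 "
            f"(reduce dt below {0.5 * grid.dr**2 / float(np.max(De)):.3g} s)"
        )
    # outward flux at internal interface i (between annuli i and i+1)
    J = -De * (C[1:] - C[:-1]) / grid.dr * grid.A_int[:-1] * dt
    C_new = C.copy()
    C_new[:-1] -= J / grid.V[:-1]
    C_new[1:] += J / grid.V[1:]
    return C_new, J


def advective_step(
    C: np.ndarray,
    grid: AnnularGrid,
    v0: float,
    dt: float,
) -> tuple[np.ndarray, float]:
    """Inward advection of solute with root water uptake (optional term).

    Water converges on the root: a volumetric flow of ``v0`` (cm^3 s^-1 per
    cm root length) crosses every cylindrical interface, i.e. the radial
    velocity is v(r) = v0/(2*pi*r). Solute is carried with it using upwind
    (outer-annulus) concentrations. Returns the updated concentrations and
    the mass delivered into the root across the rhizoplane (umol per cm root
    length); no solute enters through the closed outer boundary.
    """
    if v0 < 0:
        raise ValueError(f"v0 must be >= 0, got {v0}")
    if v0 == 0.0:
        return C.copy(), 0.0
    # mass crossing interface i inward = v0 * C_upwind * dt
    m_in = v0 * C * dt  # m_in[i]: mass leaving annulus i toward annulus i-1
    C_new = C.copy()
    C_new -= m_in / grid.V
    C_new[:-1] += m_in[1:] / grid.V[:-1]
    into_root = float(m_in[0])
    return C_new, into_root
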