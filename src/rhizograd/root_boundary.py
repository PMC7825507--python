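"""Fluxes across the rhizoplane.

Net exudation is the difference between efflux out of the root and influx
back into it, both evaluated at the concentration of the soil annulus
touching the root (the rhizoplane annulus). Uncharged compounds leak
passively down the cytoplasm-to-soil gradient and are recaptured by
Michaelis-Menten carriers; negatively charged compounds (organic acid
anions) are driven out by the membrane potential following a
Goldman-Hodgkin-Katz (GHK) flux law and are not recaptured.

Sign convention: efflux and the GHK flux are positive out of the root;
influx is positive into the root; net = efflux - influx. All fluxes are per
cm of root length and per hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .solutes import SoluteParams

__all__ = [
    "FARADAY",
    "R_GAS",
    "RootParams",
    "BoundaryFlux",
    "passive_efflux",
    "mm_influx",
    "ghk_flux",
    "boundary_flux",
]

#: Faraday constant, J mol^-1 V^-1
FARADAY = 9.649e4
#: gas constant, J mol^-1 K^-1
R_GAS = 8.3143


@dataclass(frozen=True)
class RootParams:
    """Geometry and electrophysiology of the simulated root segment.

    All fluxes are expressed per cm of root length, so the relevant surface
    is the area per cm length, A = 2*pi*r0. ``v0`` (volume of water entering
    the root, cm^3 s^-1 per cm length) does not enter the boundary flux laws;
    it is carried so the sensitivity analysis can include it and so the
    optional advective transport term can be driven by it.
    """

    r0: float = 0.0642  # root radius, cm
    Em: float = -0.120  # membrane potential, V
    v0: float = 0.0  # water uptake, cm^3 s^-1 per cm root length

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"root radius must be > 0, got {self.r0}")
        if self.Em >= 0:
            raise ValueError(f"membrane potential must be < 0 V, got {self.Em}")

    @property
    def A(self) -> float:
        """Root surface area per cm length, cm^2 cm^-1."""
        return 2.0 * math.pi * self.r0


@dataclass(frozen=True)
class BoundaryFlux:
    """Rhizoplane flux triple (umol cm^-1 hr^-1); net = efflux - influx."""

    efflux: float
    influx: float
    net: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "net", self.efflux - self.influx)


def passive_efflux(s: SoluteParams, root: RootParams, Csoil: float) -> float:
    """Passive efflux of an uncharged solute, A*P*(Ccyto - Csoil).

    May be negative when the soil concentration exceeds the cytoplasm
    concentration (diffusive re-entry).
    """
    if s.Z != 0:
        raise ValueError(
            f"{s.name}: passive efflux applies to uncharged solutes only "
            f"(Z={s.Z}); use ghk_flux"
        )
    if Csoil < 0:
        raise ValueError(f"Csoil must be >= 0, got {Csoil}")
    return root.A * s.P * (s.Ccyto - Csoil)


def mm_influx(s: SoluteParams, Csoil: float) -> float:
    """Michaelis-Menten influx, Imax*Csoil/(KI + Csoil).

    Zero when Imax = 0 (or at Csoil = 0, including the KI = 0 corner);
    saturates at Imax.
    """
    if Csoil < 0:
        raise ValueError(f"Csoil must be >= 0, got {Csoil}")
    if s.Imax == 0.0 or Csoil == 0.0:
        return 0.0
    return s.Imax * Csoil / (s.KI + Csoil)


def ghk_flux(s: SoluteParams, root: RootParams, Csoil: float, T_kelvin: float) -> float:
    """GHK net flux density for a charged solute, positive out of the root.

    With u = Z*Em*F/(R*T), the efflux is
    A*P*u*(Ccyto*e^u - Csoil)/(e^u - 1); for Z < 0 and Em < 0 (u > 0) the
    membrane potential draws the anion out faster than the uncharged law,
    and the flux vanishes at the reversal concentration Csoil = Ccyto*e^u.
    The u -> 0 limit recovers the passive law A*P*(Ccyto - Csoil).
    """
    if s.Z >= 0:
        raise ValueError(
            f"{s.name}: GHK flux applies to charged solutes only (Z={s.Z})"
        )
    if T_kelvin <= 0:
        raise ValueError(f"temperature must be > 0 K, got {T_kelvin}")
    u = s.Z * root.Em * FARADAY / (R_GAS * T_kelvin)
    return _ghk(root.A, s.P, u, s.Ccyto, Csoil)


def _ghk(A: float, P: float, u: float, Ccyto: float, Csoil: float) -> float:
    if abs(u) < 1e-12:  # L'Hopital limit of the flux law
        return A * P * (Ccyto - Csoil)
    return A * P * u * (Ccyto * math.exp(u) - Csoil) / math.expm1(u)


def boundary_flux(
    s: SoluteParams, root: RootParams, Csoil: float, T_kelvin: float
) -> BoundaryFlux:
    """Dispatch on charge: uncharged -> (passive efflux, MM influx);
    charged -> (GHK efflux, no influx)."""
    if s.Z == 0:
        return BoundaryFlux(
            efflux=passive_efflux(s, root, Csoil),
            influx=mm_influx(s, Csoil),
        )
    return BoundaryFlux(efflux=ghk_flux(s, root, Csoil, T_kelvin), influx=0.0)
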