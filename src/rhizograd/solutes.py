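"""Solute parameter sets: definition, validation, CSV I/O and sampling.

A solute is described by its charge, aqueous diffusivity, Langmuir sorption
constants, base mineralization rate, root cytoplasm concentration, membrane
permeability and Michaelis-Menten uptake kinetics. Membrane permeability is
assumed invariable within an exudate class (sugars and amino acids share
1.15e-4 cm hr^-1; organic acids 4.32e-4 cm hr^-1, based on malate exudation
from wheat root tips). Negatively charged solutes (organic acids) are not
recaptured by the root: the negative interior potential makes influx
energetically unfavorable, so their Imax is fixed at zero and exudation is
regulated by efflux alone.

``PARAM_RANGES`` carries the literature ranges used both for validating
parameter sets and as the sampling box for the global sensitivity analysis.
The cytoplasm-concentration *sampling* range tops out at 40 umol cm^-3,
while measured cytosol values for sedge roots run slightly higher (glucose
44.7, tartarate 59.5 umol cm^-3); validation therefore accepts Ccyto up to
60 umol cm^-3.

Unit conventions (documented in the CSV header names): D_inf in cm^2 s^-1
(small-molecule aqueous diffusivities are ~1e-5 to 1e-6 cm^2 s^-1), rates in
hr^-1, concentrations in umol cm^-3, permeability in cm hr^-1, Imax in
umol cm^-1 root hr^-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SoluteParams",
    "ParamRanges",
    "PARAM_RANGES",
    "SoluteValidationError",
    "CLASS_PERMEABILITY",
    "SOLUTE_CLASSES",
    "SAMPLED_FIELDS",
    "load_solutes",
    "write_solutes",
    "sample_solute",
    "builtin_fixtures",
]

logger = logging.getLogger(__name__)

SOLUTE_CLASSES = ("sugar", "amino_acid", "organic_acid")

#: class-default membrane permeability, cm hr^-1
CLASS_PERMEABILITY = {
    "sugar": 1.15e-4,
    "amino_acid": 1.15e-4,
    "organic_acid": 4.32e-4,
}

#: CSV column order for solute tables
CSV_COLUMNS = [
    "name",
    "class",
    "Z",
    "D_inf_cm2_s",
    "Smax_umol_g",
    "Ks",
    "kd_per_hr",
    "Ccyto_umol_cm3",
    "P_cm_hr",
    "Imax_umol_cm_hr",
    "KI_umol_cm3",
]

#: fields drawn from ``ParamRanges`` when sampling an uncharged solute
SAMPLED_FIELDS = ("D_inf", "Smax", "Ks", "kd", "Ccyto", "P", "Imax", "KI")


class SoluteValidationError(ValueError):
    """A solute parameter set violates an invariant or a range bound."""


@dataclass(frozen=True)
class SoluteParams:
    """Physics, chemistry and biology of one exuded carbon compound."""

    name: str
    solute_class: str
    Z: int = 0  # charge in solution, 0 or negative
    D_inf: float = 6.7e-6  # aqueous diffusion coefficient, cm^2 s^-1
    Smax: float = 0.0  # maximum sorption, umol g^-1
    Ks: float = 0.0  # Langmuir affinity coefficient, unitless
    kd: float = 1.0  # base mineralization rate, hr^-1
    Ccyto: float = 1.0  # root cytoplasm concentration, umol cm^-3
    P: float | None = None  # membrane permeability, cm hr^-1 (None -> class default)
    Imax: float = 0.0  # maximum uptake rate, umol cm^-1 root hr^-1
    KI: float = 0.0  # Michaelis-Menten coefficient, umol cm^-3

    def __post_init__(self) -> None:
        if self.solute_class not in SOLUTE_CLASSES:
            raise SoluteValidationError(
                f"{self.name}: unknown solute class {self.solute_class!r} "
                f"(expected one of {SOLUTE_CLASSES})"
            )
        if self.Z not in (0, -1, -2, -3):
            raise SoluteValidationError(
                f"{self.name}: charge Z must be in {{0, -1, -2, -3}}, got {self.Z}"
            )
        if self.P is None:
            object.__setattr__(self, "P", CLASS_PERMEABILITY[self.solute_class])
        for fname in ("D_inf", "Smax", "Ks", "kd", "Ccyto", "P", "Imax", "KI"):
            v = getattr(self, fname)
            if not (v >= 0 and math.isfinite(v)):
                raise SoluteValidationError(
                    f"{self.name}: field {fname} must be finite and >= 0, got {v}"
                )
        if self.Z < 0 and self.Imax != 0:
            raise SoluteValidationError(
                f"{self.name}: charged solutes (Z={self.Z}) have no influx "
                f"pathway; Imax must be 0, got {self.Imax}"
            )
        if self.solute_class == "organic_acid" and self.Z >= 0:
            raise SoluteValidationError(
                f"{self.name}: organic acids carry negative charge, got Z={self.Z}"
            )

    @property
    def charged(self) -> bool:
        return self.Z < 0


@dataclass(frozen=True)
class ParamRanges:
    """(lo, hi) literature bounds per solute/root parameter.

    ``bounds`` is the sampling box for the sensitivity analysis;
    ``validation`` adds headroom on Ccyto for the measured cytosol values of
    the built-in fixtures (see module docstring).
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "D_inf": (0.52e-5, 1.28e-5),
            "Smax": (0.12, 19.98),
            "Ks": (0.145, 4.3),
            "kd": (0.15, 2.35),
            "Ccyto": (0.5, 40.0),
            "P": (1.15e-4, 4.32e-4),
            "Imax": (0.006, 0.07),
            "KI": (0.002, 5.9),
            "v0": (5.0e-10, 5.0e-6),
        }
    )
    ccyto_validation_hi: float = 60.0

    def __post_init__(self) -> None:
        for k, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"range for {k} has lo > hi: ({lo}, {hi})")

    def validation_bounds(self, fname: str) -> tuple[float, float]:
        lo, hi = self.bounds[fname]
        if fname == "Ccyto":
            hi = self.ccyto_validation_hi
        return lo, hi

    def validate(self, s: SoluteParams) -> None:
        """Check a solute's fields against the literature bounds.

        Charged solutes are exempt from the Imax/KI bounds (their influx
        pathway is disabled, both are 0 by construction).
        """
        checked = list(SAMPLED_FIELDS)
        if s.charged:
            checked = [f for f in checked if f not in ("Imax", "KI")]
        for fname in checked:
            lo, hi = self.validation_bounds(fname)
            v = getattr(s, fname)
            if not lo <= v <= hi:
                raise SoluteValidationError(
                    f"{s.name}: field {fname}={v} outside literature range "
                    f"[{lo}, {hi}]"
                )


#: literature parameter ranges (sugars/amino acids unless solute specific)
PARAM_RANGES = ParamRanges()

#: geometric mean of the Michaelis-Menten coefficient range, the default KI
#: used when calibration leaves KI under-determined
KI_GEOMETRIC_MEAN = math.sqrt(0.002 * 5.9)


def sample_solute(
    ranges: ParamRanges, u: Sequence[float], name: str = "sample"
) -> SoluteParams:
    """Map a unit-hypercube point affinely onto the parameter box.

    ``u`` has one component in [0, 1] per entry of ``SAMPLED_FIELDS`` (in
    that order). Returns an uncharged sugar-class solute; deterministic.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (len(SAMPLED_FIELDS),):
        raise ValueError(
            f"expected {len(SAMPLED_FIELDS)} hypercube components "
            f"({SAMPLED_FIELDS}), got shape {u.shape}"
        )
    if np.any((u < 0) | (u > 1)):
        raise ValueError("hypercube components must lie in [0, 1]")
    vals = {}
    for fname, ui in zip(SAMPLED_FIELDS, u):
        lo, hi = ranges.bounds[fname]
        vals[fname] = lo + (hi - lo) * float(ui)
    return SoluteParams(name=name, solute_class="sugar", Z=0, **vals)


def load_solutes(path: str | Path) -> list[SoluteParams]:
    """Read a solute table CSV into validated ``SoluteParams``.

    An empty ``P_cm_hr`` cell is filled with the class default. Validation
    failures report the offending row and field.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SoluteValidationError(f"{path}: missing required columns {missing}")
    if df.empty:
        logger.warning("solute table %s is empty", path)
        return []
    out = []
    for idx, row in df.iterrows():
        p_cell = row["P_cm_hr"]
        try:
            out.append(
                SoluteParams(
                    name=str(row["name"]),
                    solute_class=str(row["class"]),
                    Z=int(row["Z"]),
                    D_inf=float(row["D_inf_cm2_s"]),
                    Smax=float(row["Smax_umol_g"]),
                    Ks=float(row["Ks"]),
                    kd=float(row["kd_per_hr"]),
                    Ccyto=float(row["Ccyto_umol_cm3"]),
                    P=None if pd.isna(p_cell) else float(p_cell),
                    Imax=float(row["Imax_umol_cm_hr"]),
                    KI=float(row["KI_umol_cm3"]),
                )
            )
        except (SoluteValidationError, ValueError) as e:
            raise SoluteValidationError(f"{path} row {idx}: {e}") from e
    return out


def write_solutes(solutes: Sequence[SoluteParams], path: str | Path) -> None:
    """Write solutes to the documented CSV layout (full precision)."""
    rows = [
        {
            "name": s.name,
            "class": s.solute_class,
            "Z": s.Z,
            "D_inf_cm2_s": s.D_inf,
            "Smax_umol_g": s.Smax,
            "Ks": s.Ks,
            "kd_per_hr": s.kd,
            "Ccyto_umol_cm3": s.Ccyto,
            "P_cm_hr": s.P,
            "Imax_umol_cm_hr": s.Imax,
            "KI_umol_cm3": s.KI,
        }
        for s in solutes
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def builtin_fixtures() -> list[SoluteParams]:
    """Named example solutes spanning the three exudate classes.

    These are synthetic parameter sets: the measured cytosol concentrations
    (glucose 44.7, malate 27.4, tartarate 59.5 umol cm^-3) and class-default
    permeabilities are literature values, the remaining constants are chosen
    inside the literature ranges to place each class in its reported
    qualitative regime (sugars: low sorption, strong recapture; amino acids:
    low cytosol pool, fast mineralization; organic acids: charged, sorbing,
    no recapture). Glucose's Smax*Ks product (~0.494) reproduces the reported
    sorbed-pool fractions in the linear-isotherm limit.
    """
    return [
        SoluteParams(
            name="glucose", solute_class="sugar", Z=0, D_inf=6.7e-6,
            Smax=0.625, Ks=0.79, kd=0.46, Ccyto=44.7,
            Imax=0.028, KI=KI_GEOMETRIC_MEAN,
        ),
        SoluteParams(
            name="sucrose", solute_class="sugar", Z=0, D_inf=5.2e-6,
            Smax=0.5, Ks=0.6, kd=0.8, Ccyto=20.0,
            Imax=0.02, KI=0.2,
        ),
        SoluteParams(
            name="glycine", solute_class="amino_acid", Z=0, D_inf=1.06e-5,
            Smax=0.8, Ks=0.7, kd=1.8, Ccyto=2.5,
            Imax=0.03, KI=0.05,
        ),
        SoluteParams(
            name="malate", solute_class="organic_acid", Z=-2, D_inf=7.9e-6,
            Smax=4.0, Ks=1.5, kd=1.0, Ccyto=27.4,
            Imax=0.0, KI=0.0,
        ),
        SoluteParams(
            name="tartarate", solute_class="organic_acid", Z=-2, D_inf=5.4e-6,
            Smax=6.0, Ks=2.0, kd=1.2, Ccyto=59.5,
            Imax=0.0, KI=0.0,
        ),
        SoluteParams(
            name="oxalate", solute_class="organic_acid", Z=-2, D_inf=1.0e-5,
            Smax=15.0, Ks=4.0, kd=0.9, Ccyto=5.0,
            Imax=0.0, KI=0.0,
        ),
    ]


def get_fixture(name: str) -> SoluteParams:
    """Look up a built-in fixture by name."""
    for s in builtin_fixtures():
        if s.name == name:
            return s
    raise KeyError(f"no built-in solute fixture named {name!r}")
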