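"""Configuration files, result serialization and run manifests.

Configs are YAML (JSON is a YAML subset) with sections ``soil``, ``root``,
``numerics``, ``solutes`` and ``outputs``; every section is optional and
falls back to the documented defaults (Mer Bleue soil, calibration-era root,
500 annuli of 0.2 mm, 1 s steps, 1e-7 equilibrium tolerance, 0.01 nmol cm^-3
rhizosphere threshold). Unknown keys are rejected to catch typos. Numeric
output is serialized at full precision so downstream recomputation is exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .root_boundary import RootParams
from .simulator import SimConfig, SimResult
from .soil_profile import MER_BLEUE, SoilProfileParams
from .solutes import SoluteParams, builtin_fixtures, load_solutes

__all__ = [
    "RunConfig",
    "RunManifest",
    "ConfigError",
    "load_config",
    "write_config",
    "write_results",
    "DEFAULT_NUMERICS",
]

logger = logging.getLogger(__name__)

DEFAULT_NUMERICS = {
    "n_annuli": 500,
    "dr_cm": 0.02,
    "dt_s": 1.0,
    "eq_rel_tol": 1e-7,
    "max_sim_time_s": 5.0e6,
    "rhizosphere_threshold_nmol_cm3": 0.01,
    "retardation": "slope",
    "advection": False,
}

_SOIL_KEYS = {f.name for f in dataclasses.fields(SoilProfileParams)}
_ROOT_KEYS = {"r0_cm", "Em_mV", "v0_cm3_s"}
_SECTIONS = {"soil", "root", "numerics", "solutes", "outputs"}


class ConfigError(ValueError):
    """Malformed or out-of-range configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (soil + root + numerics + solute table)."""

    soil: SoilProfileParams = MER_BLEUE
    root: RootParams = field(default_factory=RootParams)
    numerics: dict = field(default_factory=lambda: dict(DEFAULT_NUMERICS))
    solutes: tuple[SoluteParams, ...] = field(
        default_factory=lambda: tuple(builtin_fixtures())
    )
    solutes_path: str | None = None
    out_dir: str = "runs"

    def solute(self, name: str) -> SoluteParams:
        for s in self.solutes:
            if s.name == name:
                return s
        raise KeyError(
            f"no solute named {name!r} in the configured table "
            f"(have {[s.name for s in self.solutes]})"
        )

    def sim_config(self, solute: SoluteParams, depth: float) -> SimConfig:
        n = self.numerics
        return SimConfig(
            solute=solute,
            root=self.root,
            depth=depth,
            soil=self.soil,
            n_annuli=int(n["n_annuli"]),
            dr=float(n["dr_cm"]),
            dt=float(n["dt_s"]),
            eq_rel_tol=float(n["eq_rel_tol"]),
            max_sim_time=float(n["max_sim_time_s"]),
            rhizosphere_threshold=float(n["rhizosphere_threshold_nmol_cm3"]),
            retardation=str(n["retardation"]),
            advection=bool(n["advection"]),
        )


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r} "
            f"(allowed: {sorted(allowed)})"
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys("<top>", raw, _SECTIONS)

    soil_raw = raw.get("soil", {}) or {}
    _check_keys("soil", soil_raw, _SOIL_KEYS)
    try:
        soil = SoilProfileParams(**soil_raw)
    except ValueError as e:
        raise ConfigError(f"soil: {e}") from e

    root_raw = raw.get("root", {}) or {}
    _check_keys("root", root_raw, _ROOT_KEYS)
    try:
        root = RootParams(
            r0=float(root_raw.get("r0_cm", RootParams().r0)),
            Em=float(root_raw.get("Em_mV", -120.0)) / 1e3,
            v0=float(root_raw.get("v0_cm3_s", 0.0)),
        )
    except ValueError as e:
        raise ConfigError(f"root: {e}") from e

    num_raw = raw.get("numerics", {}) or {}
    _check_keys("numerics", num_raw, set(DEFAULT_NUMERICS))
    numerics = dict(DEFAULT_NUMERICS, **num_raw)
    if float(numerics["eq_rel_tol"]) <= 0:
        raise ConfigError("numerics: eq_rel_tol must be > 0")
    if float(numerics["rhizosphere_threshold_nmol_cm3"]) <= 0:
        raise ConfigError("numerics: rhizosphere_threshold_nmol_cm3 must be > 0")
    if float(numerics["dt_s"]) <= 0 or float(numerics["dr_cm"]) <= 0:
        raise ConfigError("numerics: dt_s and dr_cm must be > 0")
    if int(numerics["n_annuli"]) < 2:
        raise ConfigError("numerics: n_annuli must be >= 2")
    if numerics["retardation"] not in ("slope", "secant"):
        raise ConfigError("numerics: retardation must be 'slope' or 'secant'")

    solutes_path = raw.get("solutes")
    if solutes_path is not None:
        sp = Path(solutes_path)
        if not sp.is_absolute():
            sp = Path(path).parent / sp
        solutes = tuple(load_solutes(sp))
    else:
        solutes = tuple(builtin_fixtures())

    outputs = raw.get("outputs", {}) or {}
    _check_keys("outputs", outputs, {"dir"})

    return RunConfig(
        soil=soil,
        root=root,
        numerics=numerics,
        solutes=solutes,
        solutes_path=solutes_path,
        out_dir=str(outputs.get("dir", "runs")),
    )


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a config back to YAML (inverse of ``load_config`` up to the
    solute table, which is referenced by path when one was given)."""
    doc: dict = {
        "soil": dataclasses.asdict(cfg.soil),
        "root": {
            "r0_cm": cfg.root.r0,
            "Em_mV": cfg.root.Em * 1e3,
            "v0_cm3_s": cfg.root.v0,
        },
        "numerics": dict(cfg.numerics),
        "outputs": {"dir": cfg.out_dir},
    }
    if cfg.solutes_path is not None:
        doc["solutes"] = cfg.solutes_path
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass
class RunManifest:
    """Reproducibility record written alongside every result set."""

    config_echo: dict
    seed: int | None = None
    package_version: str = ""
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    convergence: dict = field(default_factory=dict)
    output_files: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def write_results(
    results: dict[str, SimResult],
    manifest: RunManifest,
    out_dir: str | Path,
) -> list[Path]:
    """Write per-run profile CSVs, summary JSONs, a sweep table and the
    manifest. ``results`` maps a run label (e.g. 'glucose_d10') to its
    result. Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    rows = []
    if not results:
        logger.warning("empty result set; writing manifest only")
    for label, res in results.items():
        prof = out / f"{label}_profile.csv"
        res.profile_frame().to_csv(prof, index=False)
        summ = out / f"{label}_summary.json"
        summ.write_text(json.dumps(res.summary(), indent=2))
        written += [prof, summ]
        manifest.convergence[label] = res.converged
        rows.append({"run": label, **res.summary()})
    if rows:
        table = out / "sweep_table.csv"
        pd.DataFrame(rows).to_csv(table, index=False)
        written.append(table)
    manifest.output_files = [str(p) for p in written]
    man_path = out / "manifest.json"
    manifest.write(man_path)
    written.append(man_path)
    return written
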