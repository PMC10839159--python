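"""Flat configuration layer for the simulation defaults.

Every physical default lives in one table, keyed one-to-one to the rows of
the simulation parameter set (diffusivities, surface charge densities,
geometry, electrolyte, protein dimensions).  Config files are flat
TOML-style ``key = value`` text; unknown keys are rejected by name.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .model import (
    ChainConfig,
    Domain,
    Electrolyte,
    Orientation,
    PipetteGeometry,
    ProteinSpheroid,
)

__all__ = ["DEFAULTS", "load_config", "dump_config", "domain_from_config"]

# One key per simulation-parameter row, defaults equal to the published
# values used throughout this package.
DEFAULTS: dict[str, float | str] = {
    "diffusivity_na_m2_s": 1.33e-9,
    "diffusivity_cl_m2_s": 2.03e-9,
    "protein_density_g_cm3": 1.35,
    "scd_glass_c_m2": -0.032,
    "scd_protein_c_m2": 0.012,
    "glass_thickness_orifice_nm": 9.0,
    "pore_diameter_nm": 4.6,
    "cone_angle_waist_deg": 2.0,
    "cone_angle_orifice_deg": 13.0,
    "nacl_molarity_mm": 125.0,
    "glass_relative_permittivity": 3.9,
    "water_relative_permittivity": 78.5,
    "protein_relative_permittivity": 60.0,
    "ion_radius_nm": 0.15,
    "voltage_v": 1.0,
    "protein_a_semiaxis_nm": 1.7015,
    "protein_b_semiaxis_nm": 1.5705,
    # run controls (not physical constants)
    "orientation": "prolate",
    "n_proteins": 1,
    "window_half_extent_nm": 20.0,
    "temperature_k": 298.0,
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Read a flat ``key = value`` config file on top of the defaults.

    Unknown keys raise a ``ValueError`` naming the key.
    """
    cfg = dict(DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        for ln, line in enumerate(text.splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip().strip('"').strip("'")
            if key not in cfg:
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            cfg[key] = _coerce(cfg[key], value)
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        cfg[key] = _coerce(cfg[key], value)
    return cfg


def _coerce(template, value):
    if isinstance(value, (int, float)) or isinstance(template, str):
        return value if not isinstance(template, str) else str(value)
    if isinstance(template, int) and not isinstance(template, bool):
        return int(float(value))
    return float(value)


def dump_config(cfg: dict, path: str | Path) -> None:
    lines = [f"{k} = {v!r}" if isinstance(v, str) else f"{k} = {v}"
             for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def domain_from_config(cfg: dict, with_protein: bool = False,
                       z_center: float = 0.0) -> Domain:
    """Materialise a :class:`Domain` from a flat config dictionary."""
    geometry = PipetteGeometry(
        pore_diameter=cfg["pore_diameter_nm"],
        wall_thickness_orifice=cfg["glass_thickness_orifice_nm"],
        cone_angle_waist=cfg["cone_angle_waist_deg"],
        cone_angle_orifice=cfg["cone_angle_orifice_deg"],
        scd_glass=cfg["scd_glass_c_m2"],
        eps_glass=cfg["glass_relative_permittivity"],
    )
    electrolyte = Electrolyte(
        c_bulk=cfg["nacl_molarity_mm"],
        D_Na=cfg["diffusivity_na_m2_s"],
        D_Cl=cfg["diffusivity_cl_m2_s"],
        eps_water=cfg["water_relative_permittivity"],
        temperature=cfg["temperature_k"],
        ion_radius=cfg["ion_radius_nm"],
    )
    protein = chain = None
    if with_protein:
        protein = ProteinSpheroid(
            a_semiaxis=cfg["protein_a_semiaxis_nm"],
            b_semiaxis=cfg["protein_b_semiaxis_nm"],
            orientation=Orientation(cfg["orientation"]),
            scd_protein=cfg["scd_protein_c_m2"],
            eps_protein=cfg["protein_relative_permittivity"],
            density=cfg["protein_density_g_cm3"],
        )
        chain = ChainConfig(n_proteins=int(cfg["n_proteins"]),
                            z_center=z_center)
    return Domain(
        geometry=geometry,
        electrolyte=electrolyte,
        protein=protein,
        chain=chain,
        window_half_extent=cfg["window_half_extent_nm"],
        applied_voltage=cfg["voltage_v"],
    )
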