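"""Geometric and physical description of the nanopipette sensor.

The sensor is a pulled borosilicate glass capillary terminating in a conical
nanopore (orifice diameter a few nm).  Everything downstream of this module
works in an axisymmetric (r, z) half-plane with

* ``z = 0`` at the orifice plane,
* ``z > 0`` inside the pipette,
* ``z < 0`` in the external bath,
* all lengths in nanometres.

Proteins are modelled as rigid spheroids centred on the pore axis, either
*prolate* (major semi-axis along the translocation axis) or *oblate* (major
semi-axis radial).  Chains of 2-3 touching spheroids model co-translocating
protein aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
import numpy as np

__all__ = [
    "Orientation",
    "PipetteGeometry",
    "ProteinSpheroid",
    "ChainConfig",
    "Electrolyte",
    "Domain",
    "SpheroidSurface",
    "build_pipette_profile",
    "build_protein_chain",
    "ellipsoid_surface_area",
    "spheroid_surface_area_exact",
    "scd_from_sequence",
    "net_charge_at_pH",
    "assemble_domain",
    "EMBOSS_PKA",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C
FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m


class Orientation(str, Enum):
    """Spheroid orientation relative to the pore (translocation) axis."""

    PROLATE = "prolate"  # major semi-axis a along the axis
    OBLATE = "oblate"  # major semi-axis a radial, minor axis b along z


@dataclass(frozen=True)
class PipetteGeometry:
    """Conical pipette tip profile.

    The inner wall is a cone of half-angle ``cone_angle_orifice / 2`` near
    the tip, transitioning to ``cone_angle_waist / 2`` a distance
    ``transition_z`` up the barrel.  The outer wall is offset radially so the
    glass thickness at the orifice equals ``wall_thickness_orifice``.
    """

    pore_diameter: float = 4.6  # nm
    wall_thickness_orifice: float = 9.0  # nm
    cone_angle_waist: float = 2.0  # degrees (full cone angle)
    cone_angle_orifice: float = 13.0  # degrees (full cone angle)
    scd_glass: float = -0.032  # C/m^2 on wetted faces
    eps_glass: float = 3.9  # relative permittivity
    transition_z: float = 20.0  # nm, orifice->waist cone transition

    def __post_init__(self) -> None:
        if self.pore_diameter <= 0:
            raise ValueError("pore_diameter must be positive")
        if not (0 <= self.cone_angle_waist <= self.cone_angle_orifice < 90):
            raise ValueError(
                "cone angles must satisfy 0 <= waist <= orifice < 90 degrees"
            )
        if self.wall_thickness_orifice <= 0:
            raise ValueError("wall_thickness_orifice must be positive")
        if self.eps_glass <= 0:
            raise ValueError("eps_glass must be positive")

    @property
    def pore_radius(self) -> float:
        return 0.5 * self.pore_diameter

    def inner_radius(self, z):
        """Radius of the wetted inner wall at height ``z >= 0`` (nm)."""
        z = np.asarray(z, dtype=float)
        t_o = math.tan(math.radians(self.cone_angle_orifice) / 2.0)
        t_w = math.tan(math.radians(self.cone_angle_waist) / 2.0)
        zt = self.transition_z
        r = np.where(
            z <= zt,
            self.pore_radius + z * t_o,
            self.pore_radius + zt * t_o + (z - zt) * t_w,
        )
        return r if r.ndim else float(r)

    def outer_radius(self, z):
        """Radius of the outer glass wall at height ``z >= 0`` (nm)."""
        r = np.asarray(self.inner_radius(z)) + self.wall_thickness_orifice
        return r if r.ndim else float(r)


@dataclass(frozen=True)
class ProteinSpheroid:
    """Rigid spheroid protein model (rotationally symmetric about the pore axis).

    ``a_semiaxis`` is the major and ``b_semiaxis`` the minor semi-axis; the
    orientation decides which one points along the translocation axis.
    """

    a_semiaxis: float = 1.7015  # nm (major)
    b_semiaxis: float = 1.5705  # nm (minor)
    orientation: Orientation = Orientation.PROLATE
    scd_protein: float = 0.012  # C/m^2
    eps_protein: float = 60.0  # relative permittivity (metadata)
    density: float = 1.35  # g/cm^3 (metadata only)

    def __post_init__(self) -> None:
        if not (self.a_semiaxis >= self.b_semiaxis > 0):
            raise ValueError("require a_semiaxis >= b_semiaxis > 0")
        object.__setattr__(self, "orientation", Orientation(self.orientation))

    @property
    def axial_semiaxis(self) -> float:
        """Semi-axis along the pore axis (sets chain spacing)."""
        if self.orientation is Orientation.PROLATE:
            return self.a_semiaxis
        return self.b_semiaxis

    @property
    def radial_semiaxis(self) -> float:
        """Semi-axis perpendicular to the pore axis (sets occlusion)."""
        if self.orientation is Orientation.PROLATE:
            return self.b_semiaxis
        return self.a_semiaxis


@dataclass(frozen=True)
class ChainConfig:
    """1-3 touching spheroids translocating as a rigid chain.

    ``z_center`` is the axial position of the *lead* protein; trailing
    proteins sit behind it (at more negative z, i.e. toward the bath).
    Centre-to-centre spacing is twice the axial semi-axis (touching).
    """

    n_proteins: int = 1
    z_center: float = 0.0  # nm

    def __post_init__(self) -> None:
        if self.n_proteins not in (1, 2, 3):
            raise ValueError("n_proteins must be 1, 2 or 3")


@dataclass(frozen=True)
class Electrolyte:
    """Binary NaCl electrolyte at room temperature."""

    c_bulk: float = 125.0  # mM
    D_Na: float = 1.33e-9  # m^2/s
    D_Cl: float = 2.03e-9  # m^2/s
    eps_water: float = 78.5
    temperature: float = 298.0  # K
    ion_radius: float = 0.15  # nm; reserved (Stern-layer offset), unused
    viscosity: float = 8.9e-4  # Pa s; used only by the Stokes coupling

    def __post_init__(self) -> None:
        for name in ("c_bulk", "D_Na", "D_Cl", "eps_water", "temperature",
                     "ion_radius", "viscosity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def thermal_voltage(self) -> float:
        """RT/F in volts (~25.7 mV at 298 K)."""
        return GAS_CONSTANT * self.temperature / FARADAY

    @property
    def c_bulk_si(self) -> float:
        """Bulk concentration in mol/m^3."""
        return self.c_bulk  # 1 mM == 1 mol/m^3

    @property
    def debye_length(self) -> float:
        """Debye screening length in nm (1:1 electrolyte)."""
        lam2 = (
            VACUUM_PERMITTIVITY
            * self.eps_water
            * GAS_CONSTANT
            * self.temperature
            / (2.0 * FARADAY**2 * self.c_bulk_si)
        )
        return math.sqrt(lam2) * 1e9

    @property
    def conductivity(self) -> float:
        """Bulk conductivity kappa in S/m: (F^2/RT) (D_Na + D_Cl) c."""
        return (
            FARADAY**2
            / (GAS_CONSTANT * self.temperature)
            * (self.D_Na + self.D_Cl)
            * self.c_bulk_si
        )


@dataclass(frozen=True)
class SpheroidSurface:
    """One spheroid of a chain, resolved into axial/radial semi-axes."""

    z_center: float  # nm
    axial_semiaxis: float  # nm
    radial_semiaxis: float  # nm
    scd: float  # C/m^2


@dataclass(frozen=True)
class Domain:
    """Complete problem description handed to the mesher and solver."""

    geometry: PipetteGeometry = field(default_factory=PipetteGeometry)
    electrolyte: Electrolyte = field(default_factory=Electrolyte)
    protein: ProteinSpheroid | None = None
    chain: ChainConfig | None = None
    window_half_extent: float = 20.0  # nm
    applied_voltage: float = 1.0  # V at the inner (pipette-top) electrode

    def __post_init__(self) -> None:
        if self.window_half_extent < 15.0:
            raise ValueError(
                "window_half_extent must be >= 15 nm so the full position "
                "sweep (-10..+15 nm) fits inside the simulation window"
            )
        if self.chain is not None and self.protein is None:
            raise ValueError("chain requires a protein model")

    @property
    def spheroids(self) -> tuple[SpheroidSurface, ...]:
        if self.protein is None or self.chain is None:
            return ()
        return tuple(build_protein_chain(self.protein, self.chain))


# ---------------------------------------------------------------------------
# geometry operations
# ---------------------------------------------------------------------------

def build_pipette_profile(
    geometry: PipetteGeometry, window: float, n_points: int = 200
) -> np.ndarray:
    """Sample the inner-wall boundary polyline in the (r, z) half-plane.

    Returns an array of shape (n_points, 2) with columns (r, z), running
    from the orifice (z = 0) to the top of the simulation window.  The
    radius is monotone non-decreasing with z (conical, no re-entrant
    geometry).
    """
    if window <= geometry.pore_diameter:
        raise ValueError(
            "simulation window must exceed the pore diameter to contain the tip"
        )
    z = np.linspace(0.0, window, n_points)
    r = geometry.inner_radius(z)
    return np.column_stack([r, z])


def build_protein_chain(
    protein: ProteinSpheroid, chain: ChainConfig
) -> list[SpheroidSurface]:
    """Place 1-3 touching spheroids behind the lead protein.

    Centres sit at ``z_center - k * spacing`` for k = 0..n-1 with spacing
    twice the axial semi-axis, so neighbouring spheroids touch pole-to-pole:
    3.403 nm for the default prolate chain, 3.141 nm for the oblate one.
    """
    spacing = 2.0 * protein.axial_semiaxis
    return [
        SpheroidSurface(
            z_center=chain.z_center - k * spacing,
            axial_semiaxis=protein.axial_semiaxis,
            radial_semiaxis=protein.radial_semiaxis,
            scd=protein.scd_protein,
        )
        for k in range(chain.n_proteins)
    ]


def ellipsoid_surface_area(a: float, b: float, c: float, p: float = 1.6075) -> float:
    """Approximate ellipsoid surface area (nm^2), Thomsen's formula.

    ``S ~= 4 pi ((a^p b^p + a^p c^p + b^p c^p) / 3)^(1/p)`` with
    p = 1.6075, accurate to ~1.06% worst case over all aspect ratios.
    """
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("all semi-axes must be positive")
    s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * math.pi * s ** (1.0 / p)


def spheroid_surface_area_exact(a: float, b: float) -> float:
    """Closed-form spheroid surface area (nm^2).

    ``a`` is the polar (symmetry-axis) semi-axis and ``b`` the equatorial
    one; a > b is prolate, a < b oblate, a == b a sphere.
    """
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if math.isclose(a, b, rel_tol=1e-12):
        return 4.0 * math.pi * a * b
    if a > b:  # prolate
        e = math.sqrt(1.0 - (b / a) ** 2)
        return 2.0 * math.pi * b**2 * (1.0 + (a / (b * e)) * math.asin(e))
    # oblate
    e = math.sqrt(1.0 - (a / b) ** 2)
    return 2.0 * math.pi * b**2 * (1.0 + ((a / b) ** 2 / e) * math.atanh(e))


# Henderson-Hasselbalch side-chain / termini pKa values (EMBOSS set).
EMBOSS_PKA: dict[str, float] = {
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
    "Nterm": 8.6,
    "Cterm": 3.6,
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")
_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


def _parse_sequence(sequence: str) -> str:
    """Accept a raw residue string or single-record FASTA text."""
    text = sequence.strip()
    if text.startswith(">"):
        lines = text.splitlines()
        text = "".join(line.strip() for line in lines[1:])
    seq = "".join(text.split()).upper()
    for i, ch in enumerate(seq):
        if ch not in _AMINO_ACIDS:
            raise ValueError(f"unknown residue {ch!r} at position {i + 1}")
    if not seq:
        raise ValueError("empty sequence")
    return seq


def net_charge_at_pH(
    sequence: str, pH: float = 7.0, pka: dict[str, float] | None = None
) -> float:
    """Net protein charge in elementary charges via Henderson-Hasselbalch.

    Each basic group contributes ``1 / (1 + 10^(pH - pKa))`` and each acidic
    group ``-1 / (1 + 10^(pKa - pH))``; free termini are included.
    """
    seq = _parse_sequence(sequence)
    pka = dict(EMBOSS_PKA if pka is None else pka)
    q = 1.0 / (1.0 + 10.0 ** (pH - pka["Nterm"]))
    q -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - pH))
    for res in seq:
        if res in _BASIC:
            q += 1.0 / (1.0 + 10.0 ** (pH - pka[res]))
        elif res in _ACIDIC:
            q -= 1.0 / (1.0 + 10.0 ** (pka[res] - pH))
    return q


def scd_from_sequence(
    sequence: str,
    pH: float = 7.0,
    area: float | None = None,
    pka: dict[str, float] | None = None,
) -> float:
    """Surface charge density (C/m^2) from an amino-acid sequence.

    The net Henderson-Hasselbalch charge at the given pH is spread uniformly
    over the spheroid surface ``area`` (nm^2; defaults to the Thomsen area of
    the default protein spheroid).
    """
    if area is None:
        p = ProteinSpheroid()
        area = ellipsoid_surface_area(p.a_semiaxis, p.b_semiaxis, p.b_semiaxis)
    if area <= 0:
        raise ValueError("area must be positive")
    q = net_charge_at_pH(sequence, pH=pH, pka=pka)
    return q * ELEMENTARY_CHARGE / (area * 1e-18)


def _wall_clearance(
    geometry: PipetteGeometry, sph: SpheroidSurface, n_theta: int = 91
) -> float:
    """Minimum radial clearance between a spheroid surface and the glass wall.

    Sampled along the spheroid's upper half (z >= 0 region matters; below the
    orifice plane there is no glass on-axis).  Negative means interference.
    """
    theta = np.linspace(0.0, math.pi, n_theta)
    z = sph.z_center + sph.axial_semiaxis * np.cos(theta)
    r = sph.radial_semiaxis * np.sin(theta)
    mask = z >= 0.0
    if not mask.any():
        return math.inf
    wall = np.asarray(geometry.inner_radius(z[mask]))
    return float(np.min(wall - r[mask]))


def assemble_domain(
    geometry: PipetteGeometry | None = None,
    electrolyte: Electrolyte | None = None,
    protein: ProteinSpheroid | None = None,
    chain: ChainConfig | None = None,
    voltage: float = 1.0,
    window_half_extent: float = 20.0,
    require_full_translocation: bool = True,
) -> Domain:
    """Bundle validated components into a solver-ready :class:`Domain`.

    Rejects a protein whose radial semi-axis reaches the pore radius when a
    full translocation is requested, and any chain placement that intersects
    the glass wall.
    """
    geometry = geometry or PipetteGeometry()
    electrolyte = electrolyte or Electrolyte()
    if protein is not None and chain is None:
        chain = ChainConfig()
    dom = Domain(
        geometry=geometry,
        electrolyte=electrolyte,
        protein=protein,
        chain=chain,
        window_half_extent=window_half_extent,
        applied_voltage=voltage,
    )
    if protein is not None:
        if require_full_translocation and (
            protein.radial_semiaxis >= geometry.pore_radius
        ):
            raise ValueError(
                f"protein radial semi-axis {protein.radial_semiaxis} nm does "
                f"not fit through the pore (radius {geometry.pore_radius} nm)"
            )
        for sph in dom.spheroids:
            if _wall_clearance(geometry, sph) <= 0.0:
                raise ValueError(
                    f"protein at z = {sph.z_center:g} nm intersects the glass wall"
                )
    return dom
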