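"""Solver oracles: equilibrium, Debye-Huckel layer, analytic conductance,
flux conservation and voltage symmetry."""

import numpy as np
import pytest
from scipy.special import iv as bessel_iv

from nanopipette.meshing import generate_mesh
from nanopipette.model import (
    VACUUM_PERMITTIVITY,
    Domain,
    Electrolyte,
    PipetteGeometry,
    assemble_domain,
)
from nanopipette.pnp import (
    SolverOptions,
    check_flux_conservation,
    compute_current,
    solve_pnp,
)

CYL = PipetteGeometry(scd_glass=0.0, cone_angle_waist=0.0,
                      cone_angle_orifice=0.0)


@pytest.fixture(scope="module")
def cylinder_solution():
    dom = Domain(geometry=CYL, applied_voltage=0.05)
    mesh = generate_mesh(dom)
    return dom, mesh, solve_pnp(dom, mesh, SolverOptions(tol=1e-5))


class TestEquilibrium:
    def test_uncharged_at_zero_volts_is_trivial(self):
        dom = Domain(geometry=CYL, applied_voltage=0.0)
        mesh = generate_mesh(dom)
        f = solve_pnp(dom, mesh)
        assert np.nanmax(np.abs(f.phi)) < 1e-9
        c = f.c_na[np.isfinite(f.c_na)]
        assert c == pytest.approx(125.0, rel=1e-9)
        assert abs(f.electrode_current) < 1e-16

    def test_charged_wall_matches_linearized_double_layer(self):
        # wide uncharged-geometry cylinder with a tiny wall charge at V=0:
        # the radial potential profile must follow the linearised
        # Poisson-Boltzmann solution  phi(r) = A I0(r/lam)
        sigma = -1e-3  # C/m^2, linear regime (|phi| << thermal voltage)
        geom = PipetteGeometry(scd_glass=sigma, cone_angle_waist=0.0,
                               cone_angle_orifice=0.0, pore_diameter=30.0)
        dom = Domain(geometry=geom, applied_voltage=0.0)
        mesh = generate_mesh(dom)
        f = solve_pnp(dom, mesh)
        el = dom.electrolyte
        lam = el.debye_length  # nm
        R = geom.pore_radius
        A = (
            sigma
            * lam * 1e-9
            / (VACUUM_PERMITTIVITY * el.eps_water * bessel_iv(1, R / lam))
        )
        pts = mesh.points
        sel = (np.abs(pts[:, 1] - 10.0) < 0.5) & (pts[:, 0] > R - 3.0) & (
            pts[:, 0] < R - 0.2
        )
        phi_num = f.phi[sel]
        phi_ref = A * bessel_iv(0, pts[sel, 0] / lam)
        wall = abs(A * bessel_iv(0, R / lam))
        assert len(phi_num) > 10
        assert np.max(np.abs(phi_num - phi_ref)) < 0.05 * wall


class TestConductance:
    def test_uncharged_cylinder_matches_pore_plus_access_resistance(
        self, cylinder_solution
    ):
        dom, mesh, f = cylinder_solution
        el = dom.electrolyte
        kappa = el.conductivity
        a = dom.geometry.pore_radius * 1e-9
        L = dom.window_half_extent * 1e-9
        resistance = L / (kappa * np.pi * a**2) + 1.0 / (4.0 * kappa * a)
        expected = dom.applied_voltage / resistance
        assert f.electrode_current == pytest.approx(expected, rel=0.2)

    def test_cross_sections_agree_with_electrode_flux(self, cylinder_solution):
        dom, mesh, f = cylinder_solution
        i_section = compute_current(f, 10.0)
        assert i_section == pytest.approx(f.electrode_current, rel=0.02)

    def test_flux_conservation_inside_bore(self, cylinder_solution):
        dom, mesh, f = cylinder_solution
        dev, absolute = check_flux_conservation(f, [4.0, 8.0, 12.0, 16.0])
        assert not absolute
        assert dev < 0.01

    def test_unconverged_solve_is_flagged_and_inaccurate(self, cylinder_solution):
        # each Gummel sweep solves the linear transport problem exactly, so
        # species flux is conserved even before convergence; an unconverged
        # state is detected by the convergence flag and a wrong current,
        # not by a conservation defect
        dom, mesh, f = cylinder_solution
        rough = solve_pnp(
            dom, generate_mesh(dom),
            SolverOptions(max_gummel=1, strict=False),
        )
        assert not rough.converged
        assert abs(rough.electrode_current / f.electrode_current - 1) > 0.01
        dev_rough, _ = check_flux_conservation(rough, [4.0, 12.0])
        assert dev_rough < 0.01  # conserved by construction

    def test_equilibrium_conservation_flagged_absolute(self):
        dom = Domain(geometry=CYL, applied_voltage=0.0)
        f = solve_pnp(dom, generate_mesh(dom))
        dev, absolute = check_flux_conservation(f, [5.0, 10.0])
        assert absolute
        assert dev < 1e-16

    def test_section_outside_window_rejected(self, cylinder_solution):
        _, _, f = cylinder_solution
        with pytest.raises(ValueError):
            compute_current(f, 25.0)


class TestSymmetry:
    def test_zero_charge_cylinder_is_ohmic(self):
        currents = {}
        for v in (0.2, -0.2):
            dom = Domain(geometry=CYL, applied_voltage=v)
            f = solve_pnp(dom, generate_mesh(dom), SolverOptions(tol=1e-5))
            currents[v] = f.electrode_current
        ratio = abs(currents[0.2]) / abs(currents[-0.2])
        assert ratio == pytest.approx(1.0, abs=0.02)
        assert currents[0.2] > 0 > currents[-0.2]

    def test_voltage_outside_validated_range_rejected(self):
        dom = Domain(geometry=CYL, applied_voltage=0.05)
        mesh = generate_mesh(dom)
        from dataclasses import replace

        with pytest.raises(ValueError):
            solve_pnp(replace(dom, applied_voltage=1.5), mesh)


class TestChargedPore:
    def test_rectification_exceeds_one_with_negative_glass(self):
        # conical geometry + negative wall charge rectifies; the heavier
        # current flows at negative inner-electrode bias
        currents = {}
        for v in (0.2, -0.2):
            dom = Domain(window_half_extent=40.0, applied_voltage=v)
            f = solve_pnp(dom, generate_mesh(dom), SolverOptions(tol=1e-5))
            currents[v] = f.electrode_current
        assert abs(currents[-0.2]) > abs(currents[0.2]) * 1.05

    def test_negative_concentration_never_returned(self):
        dom = Domain(applied_voltage=0.5)
        f = solve_pnp(dom, generate_mesh(dom), SolverOptions(tol=1e-4))
        c = np.concatenate([f.c_na[np.isfinite(f.c_na)],
                            f.c_cl[np.isfinite(f.c_cl)]])
        assert c.min() > 0.0


def test_fields_export_roundtrip(tmp_path, cylinder_solution):
    import pandas as pd

    from nanopipette.pnp import fields_to_csv, fields_to_hdf5

    _, _, f = cylinder_solution
    csv = tmp_path / "fields.csv"
    fields_to_csv(f, csv)
    df = pd.read_csv(csv)
    assert set(df.columns) == {"r_nm", "z_nm", "phi_V", "c_na_mol_m3",
                               "c_cl_mol_m3"}
    assert len(df) == f.mesh.n_nodes
    h5 = tmp_path / "fields.h5"
    fields_to_hdf5(f, h5)
    import h5py

    with h5py.File(h5) as fh:
        assert fh.attrs["applied_voltage_V"] == 0.05
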