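"""Geometry, chain construction, surface area and sequence-charge tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanopipette.model import (
    ChainConfig,
    Electrolyte,
    Orientation,
    PipetteGeometry,
    ProteinSpheroid,
    assemble_domain,
    build_pipette_profile,
    build_protein_chain,
    ellipsoid_surface_area,
    net_charge_at_pH,
    scd_from_sequence,
    spheroid_surface_area_exact,
)

# mature elafin peptide (57 residues) of the elastase-specific inhibitor
# precursor; used as a representative cationic analyte sequence
ELAFIN = "AQEPVKGPVSTKPGSCPIILIRCAMLNPPNRCLKDTDCPGIKKCCEGSCGMACFVPQ"


class TestPipetteProfile:
    def test_orifice_radius_is_half_pore_diameter(self):
        prof = build_pipette_profile(PipetteGeometry(), window=20.0)
        assert prof[0, 1] == 0.0
        assert prof[0, 0] == pytest.approx(2.3)

    def test_cone_trigonometry_inside_tip(self):
        geom = PipetteGeometry()
        expected = 2.3 + 10.0 * math.tan(math.radians(6.5))
        assert geom.inner_radius(10.0) == pytest.approx(expected, rel=1e-12)
        assert geom.inner_radius(10.0) == pytest.approx(3.44, abs=0.01)

    def test_degenerate_zero_angle_gives_cylinder(self):
        geom = PipetteGeometry(cone_angle_waist=0.0, cone_angle_orifice=0.0)
        z = np.linspace(0, 20, 50)
        assert np.allclose(geom.inner_radius(z), 2.3)

    def test_profile_monotone_nondecreasing(self):
        prof = build_pipette_profile(PipetteGeometry(), window=40.0)
        assert np.all(np.diff(prof[:, 0]) >= -1e-12)

    def test_waist_transition_reduces_slope(self):
        geom = PipetteGeometry(transition_z=10.0)
        slope_tip = geom.inner_radius(9.0) - geom.inner_radius(8.0)
        slope_waist = geom.inner_radius(16.0) - geom.inner_radius(15.0)
        assert slope_waist < slope_tip
        assert slope_waist == pytest.approx(math.tan(math.radians(1.0)), rel=1e-9)

    def test_window_smaller_than_tip_rejected(self):
        with pytest.raises(ValueError):
            build_pipette_profile(PipetteGeometry(), window=3.0)

    def test_invalid_angles_rejected(self):
        with pytest.raises(ValueError):
            PipetteGeometry(cone_angle_waist=20.0, cone_angle_orifice=13.0)

    def test_outer_wall_offset_by_thickness(self):
        geom = PipetteGeometry()
        assert geom.outer_radius(0.0) == pytest.approx(2.3 + 9.0)


class TestProteinChain:
    def test_prolate_pair_touches_at_poles(self):
        chain = build_protein_chain(
            ProteinSpheroid(orientation=Orientation.PROLATE),
            ChainConfig(n_proteins=2, z_center=0.0),
        )
        assert [s.z_center for s in chain] == pytest.approx([0.0, -3.403])

    def test_single_protein_sits_at_z_center(self):
        chain = build_protein_chain(ProteinSpheroid(), ChainConfig(1, 4.2))
        assert len(chain) == 1
        assert chain[0].z_center == 4.2

    def test_oblate_triple_spacing(self):
        chain = build_protein_chain(
            ProteinSpheroid(orientation=Orientation.OBLATE),
            ChainConfig(n_proteins=3, z_center=2.0),
        )
        assert [s.z_center for s in chain] == pytest.approx(
            [2.0, -1.141, -4.282]
        )

    def test_orientation_selects_axial_semiaxis(self):
        p = ProteinSpheroid(orientation=Orientation.PROLATE)
        o = ProteinSpheroid(orientation=Orientation.OBLATE)
        assert p.axial_semiaxis == pytest.approx(1.7015)
        assert p.radial_semiaxis == pytest.approx(1.5705)
        assert o.axial_semiaxis == pytest.approx(1.5705)
        assert o.radial_semiaxis == pytest.approx(1.7015)

    @given(
        z0=st.floats(-10, 15),
        shift=st.floats(-5, 5),
        n=st.sampled_from([1, 2, 3]),
    )
    def test_translation_equivariance(self, z0, shift, n):
        prot = ProteinSpheroid()
        a = build_protein_chain(prot, ChainConfig(n, z0))
        b = build_protein_chain(prot, ChainConfig(n, z0 + shift))
        for sa, sb in zip(a, b):
            assert sb.z_center - sa.z_center == pytest.approx(shift, abs=1e-9)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(n_proteins=4)


class TestSurfaceArea:
    def test_sphere(self):
        assert ellipsoid_surface_area(1, 1, 1) == pytest.approx(
            4 * math.pi, rel=1e-3
        )

    def test_default_protein_against_closed_form(self):
        approx = ellipsoid_surface_area(1.7015, 1.5705, 1.5705)
        exact = spheroid_surface_area_exact(1.7015, 1.5705)
        assert approx == pytest.approx(exact, rel=0.011)
        # frozen value from an independent surface-of-revolution quadrature
        assert exact == pytest.approx(32.731868, abs=2e-4)

    def test_two_to_one_prolate_within_bound(self):
        approx = ellipsoid_surface_area(2, 1, 1)
        exact = spheroid_surface_area_exact(2, 1)
        assert abs(approx / exact - 1) < 0.011

    @given(a=st.floats(0.5, 5.0), b=st.floats(0.5, 5.0))
    def test_thomsen_error_bound_over_range(self, a, b):
        hi, lo = max(a, b), min(a, b)
        approx = ellipsoid_surface_area(hi, lo, lo)  # prolate-style ordering
        exact = spheroid_surface_area_exact(hi, lo)
        assert abs(approx / exact - 1) < 0.011
        oblate_exact = spheroid_surface_area_exact(lo, hi)
        oblate_approx = ellipsoid_surface_area(hi, hi, lo)
        assert abs(oblate_approx / oblate_exact - 1) < 0.011

    def test_rejects_nonpositive_axis(self):
        with pytest.raises(ValueError):
            ellipsoid_surface_area(1, -1, 1)


class TestSequenceCharge:
    def test_polyglycine_only_termini(self):
        q = net_charge_at_pH("G" * 20, pH=7.0)
        assert abs(q) < 1.0

    def test_polylysine_positive(self):
        assert scd_from_sequence("KKKK", pH=7.0) > 0

    def test_aspartate_negative(self):
        assert scd_from_sequence("DDDD", pH=7.0) < 0

    def test_unknown_residue_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            scd_from_sequence("GGXG")

    def test_fasta_input_equivalent_to_raw(self):
        fasta = ">sp|test| example\nKKDE\nRH\n"
        assert scd_from_sequence(fasta) == pytest.approx(
            scd_from_sequence("KKDERH")
        )

    def test_elafin_scd_order_of_magnitude(self):
        # compare with the 0.012 C/m^2 working value for this analyte
        scd = scd_from_sequence(ELAFIN, pH=7.0)
        assert scd > 0
        assert 0.012 / 5 < scd < 0.012 * 5

    def test_charge_decreases_with_pH(self):
        q_acid = net_charge_at_pH(ELAFIN, pH=4.0)
        q_base = net_charge_at_pH(ELAFIN, pH=10.0)
        assert q_acid > q_base


class TestAssembleDomain:
    def test_defaults_valid(self):
        dom = assemble_domain()
        assert dom.applied_voltage == 1.0
        assert dom.spheroids == ()

    def test_oversized_oblate_rejected(self):
        prot = ProteinSpheroid(
            a_semiaxis=2.4, b_semiaxis=2.0, orientation=Orientation.OBLATE
        )
        with pytest.raises(ValueError, match="does not fit"):
            assemble_domain(protein=prot)

    def test_triple_prolate_outside_pore_valid(self):
        dom = assemble_domain(
            protein=ProteinSpheroid(orientation=Orientation.PROLATE),
            chain=ChainConfig(n_proteins=3, z_center=-10.0),
        )
        assert len(dom.spheroids) == 3

    def test_wall_interference_rejected(self):
        # a spheroid wider than the orifice, held at the orifice plane
        prot = ProteinSpheroid(a_semiaxis=2.5, b_semiaxis=2.35)
        with pytest.raises(ValueError):
            assemble_domain(
                protein=prot,
                chain=ChainConfig(1, 0.0),
                require_full_translocation=False,
            )


class TestElectrolyte:
    def test_debye_length_at_125_mM(self):
        assert Electrolyte().debye_length == pytest.approx(0.86, abs=0.02)

    def test_bulk_conductivity_from_diffusivities(self):
        assert Electrolyte().conductivity == pytest.approx(1.58, abs=0.02)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            Electrolyte(c_bulk=-1.0)
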