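"""Interface and architecture analysis: SASA, buried areas, contacts,
radial geometry, lumen electrostatics."""

import numpy as np
import pytest

from helifil.interfaces import (
    VDW_RADII,
    buried_fraction,
    lumen_potential,
    neighbor_count,
    pairwise_buried_table,
    radial_geometry,
    sasa,
    structure_atoms,
)


class TestSasaQuadrature:
    def test_isolated_carbon_matches_closed_form(self):
        areas = sasa(np.zeros((1, 3)), np.array([1.70]))
        assert areas[0] == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)

    def test_distant_atoms_sum_of_isolated_areas(self):
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        radii = np.array([1.70, 1.52])
        areas = sasa(coords, radii)
        iso = 4 * np.pi * (radii + 1.4) ** 2
        assert np.allclose(areas, iso, rtol=0.01)

    def test_fully_enclosed_atom_has_no_area(self):
        # cage of carbons on a sphere tight enough to occlude the centre
        from helifil.interfaces import _fibonacci_sphere

        shell = 3.0 * _fibonacci_sphere(200)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.70)
        areas = sasa(coords, radii, subset=np.array([0]))
        assert areas[0] < 1.0

    def test_quadrature_converges_under_point_doubling(self, pilus_atoms):
        sub = pilus_atoms[pilus_atoms["chain"] == "C8"]
        coords = sub[["x", "y", "z"]].to_numpy()
        radii = sub["radius"].to_numpy()
        a = sasa(coords, radii, n_sphere_points=960).sum()
        b = sasa(coords, radii, n_sphere_points=1920).sum()
        assert abs(a - b) / b < 0.005

    def test_agrees_with_independent_implementation(self):
        """Cross-check against biotite's Shrake-Rupley on matched radii."""
        import biotite.structure as struc

        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 12, (30, 3))
        radii = np.full(30, 1.70)
        arr = struc.AtomArray(30)
        arr.coord = coords.astype(np.float32)
        arr.set_annotation("element", np.array(["C"] * 30))
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=1000)
        mine = sasa(coords, radii, n_sphere_points=1000)
        assert np.allclose(mine, ref, rtol=0.03, atol=1.0)

    def test_unknown_element_named_in_error(self, pilus_model):
        bad = pilus_model.clone()
        atom = bad[0]["A1"][0][0]
        import gemmi

        atom.element = gemmi.Element("Fe")
        with pytest.raises(ValueError, match="Fe"):
            structure_atoms(bad)


class TestBuriedAreas:
    def test_isolated_component_has_zero_buried(self):
        from helifil.synthetic_unit import make_pilin_unit

        unit = make_pilin_unit()
        # assembly = component: the whole pilin+lipid unit on its own
        total, buried, frac = buried_fraction(unit, ["A", "B"])
        assert buried == pytest.approx(0.0, abs=1e-6)
        assert frac == 0.0

    def test_pairwise_areas_nearly_symmetric(self, pilus_atoms):
        # the two sides of an interface lose slightly different areas
        # (surface curvature differs); they must agree to ~10%
        from helifil.interfaces import _pair_buried

        ab = _pair_buried(pilus_atoms, "C8", "C9", 960)
        ba = _pair_buried(pilus_atoms, "C9", "C8", 960)
        assert ab > 100 and ba > 100
        assert abs(ab - ba) < 0.1 * max(ab, ba)

    def test_pair_table_totals_consistent(self, pilus_atoms):
        rep = pairwise_buried_table(pilus_atoms, "C8")
        assert rep.total_sasa_A2 > 0
        assert 0 < rep.buried_fraction < 1
        assert rep.protein_buried_A2() + rep.lipid_buried_A2() == pytest.approx(
            sum(rep.pair_buried_A2.values())
        )
        # pairwise sum can exceed the assembly-context buried area only
        # through triple contacts; it must at least reach it approximately
        assert sum(rep.pair_buried_A2.values()) >= 0.8 * rep.buried_in_assembly_A2

    def test_non_touching_components_absent_from_table(self, pilus_atoms):
        rep = pairwise_buried_table(pilus_atoms, "C8")
        assert "A1" not in rep.pair_buried_A2
        assert all(v > 0 for v in rep.pair_buried_A2.values())

    def test_empty_selection_rejected(self, pilus_atoms):
        with pytest.raises(ValueError):
            buried_fraction(pilus_atoms, ["ZZ"])

    def test_interior_subunits_helically_equivalent(self, pilus_atoms):
        """All interior subunits of an ideal filament share the same
        buried fraction to within 1% - helical equivalence."""
        fracs = [buried_fraction(pilus_atoms, [c])[2] for c in ("B8", "C8", "D8", "C7", "C9")]
        assert (max(fracs) - min(fracs)) / np.mean(fracs) < 0.01


class TestNeighbors:
    def test_terminal_subunit_has_fewer_neighbors(self, pilus_atoms):
        n_interior, _ = neighbor_count(pilus_atoms, "C8")
        n_terminal, _ = neighbor_count(pilus_atoms, "C16")
        assert n_terminal < n_interior

    def test_buried_and_distance_criteria_agree_on_protein_contacts(self, pilus_atoms):
        _, by_buried = neighbor_count(pilus_atoms, "C8", criterion="buried")
        _, by_distance = neighbor_count(pilus_atoms, "C8", criterion="distance")
        prot_b = {c for c in by_buried if c[0].isupper()}
        prot_d = {c for c in by_distance if c[0].isupper()}
        assert prot_d <= prot_b  # 4 A contact implies buried surface here

    def test_missing_reference_rejected(self, pilus_atoms):
        with pytest.raises(ValueError):
            neighbor_count(pilus_atoms, "ZZ")

    def test_unknown_criterion_rejected(self, pilus_atoms):
        with pytest.raises(ValueError):
            neighbor_count(pilus_atoms, "C8", criterion="bogus")


class TestRadialGeometry:
    def test_hollow_cylinder_of_atoms(self):
        import pandas as pd

        ang = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        rows = []
        for z in np.arange(-30, 31, 3.0):
            for a in ang:
                rows.append(("X", 1, "ALA", "CA", "C", 30 * np.cos(a), 30 * np.sin(a), z, 1.70))
        atoms = pd.DataFrame(
            rows, columns=["chain", "seqid", "resname", "atom", "element", "x", "y", "z", "radius"]
        )
        prof = radial_geometry(atoms)
        assert prof.lumen_diameter_A < 60.0 + 1e-6
        assert prof.outer_diameter_A == pytest.approx(60.0, abs=1.0)
        assert prof.outer_diameter_vdw_A == pytest.approx(63.4, abs=1.0)

    def test_pilus_dimensions_in_expected_range(self, pilus_atoms):
        prof = radial_geometry(pilus_atoms)
        # synthetic assembly is calibrated to the pilus architecture:
        # ~87 A outer diameter, ~28 A lumen
        assert 80.0 < prof.outer_diameter_vdw_A < 95.0
        assert 24.0 < prof.lumen_diameter_vdw_A < 34.0
        assert np.all(prof.r_min <= prof.r_max)

    def test_single_slice_rejected(self):
        import pandas as pd

        atoms = pd.DataFrame(
            [("A", 1, "ALA", "CA", "C", 1.0, 0.0, 0.0, 1.7)],
            columns=["chain", "seqid", "resname", "atom", "element", "x", "y", "z", "radius"],
        )
        with pytest.raises(ValueError):
            radial_geometry(atoms)


class TestLumenPotential:
    def test_no_charges_gives_zero(self):
        import pandas as pd

        # glycine-only chain: no side-chain charges, termini suppressed
        rows = [("A", i, "GLY", "CA", "C", 15.0, 0.0, float(i), 1.7) for i in range(2, 12)]
        atoms = pd.DataFrame(
            rows, columns=["chain", "seqid", "resname", "atom", "element", "x", "y", "z", "radius"]
        )
        from helifil.interfaces import _assign_charges

        charges = _assign_charges(atoms, include_lipids=True, termini=False)
        assert len(charges) == 0

    def test_single_positive_charge_decays_monotonically(self):
        import pandas as pd

        rows = [
            ("A", 2, "LYS", "NZ", "N", 0.0, 0.0, 0.0, 1.55),
            ("A", 2, "LYS", "CA", "C", 1.5, 0.0, 0.0, 1.70),
        ]
        atoms = pd.DataFrame(
            rows, columns=["chain", "seqid", "resname", "atom", "element", "x", "y", "z", "radius"]
        )
        from helifil.interfaces import _assign_charges, BJERRUM_LENGTH_A

        charges = _assign_charges(atoms, include_lipids=False, termini=False)
        assert len(charges) == 1 and charges["q"].iloc[0] == 1.0
        d = np.array([2.0, 4.0, 8.0, 16.0])
        kappa = np.sqrt(0.15) / 3.04
        phi = BJERRUM_LENGTH_A * np.exp(-kappa * d) / d
        assert np.all(np.diff(phi) < 0) and np.all(phi > 0)

    def test_lipid_phosphates_flip_lumen_sign(self, pilus_atoms):
        """Without the phospholipids the lumen is positive (lysine loop);
        with their phosphates lining the lumen it turns negative."""
        with_l = lumen_potential(pilus_atoms, include_lipids=True)
        without = lumen_potential(pilus_atoms, include_lipids=False)
        assert without.mean_lumen_potential > 0
        assert with_l.mean_lumen_potential < 0

    def test_unparameterized_residue_named(self, pilus_atoms):
        bad = pilus_atoms.copy()
        bad.loc[bad.index[:3], "resname"] = "XYZ"
        with pytest.raises(ValueError, match="XYZ"):
            lumen_potential(bad, include_lipids=True)


def test_vdw_radii_standard_set():
    assert VDW_RADII["C"] == 1.70 and VDW_RADII["P"] == 1.80
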