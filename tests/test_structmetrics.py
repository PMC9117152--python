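"""Geometry: dot surfaces, CMS, interface/layer selection, RMSD protocols."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from binderscreen.structmetrics import (
    ComparisonError,
    SurfaceDots,
    SurfaceError,
    contact_molecular_surface,
    dot_surface,
    element_radius,
    interface_core_heavy_rmsd,
    interface_residues,
    layer_classify,
    molecular_surface,
    pair_residues,
    read_pdb,
    rmsd_superimposed,
    rmsd_target_aligned,
    write_pdb,
)

from conftest import backbone_residue, build_structure, extended_chain


# ---------------------------------------------------------------------------
# Oracles


def two_sphere_exposed_area(r1, r2, d):
    """Closed-form exposed area of two intersecting spheres (cap formula)."""
    if d >= r1 + r2:
        return 4 * math.pi * (r1**2 + r2**2)
    h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
    a1 = 4 * math.pi * r1**2 - 2 * math.pi * r1 * max(h1, 0.0)
    a2 = 4 * math.pi * r2**2 - 2 * math.pi * r2 * max(h2, 0.0)
    return a1 + a2


def kabsch_oracle(fixed, moving):
    """Closed-form Kabsch via numpy SVD, independent of the implementation."""
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    fc = fixed - fixed.mean(axis=0)
    mc = moving - moving.mean(axis=0)
    v, s, wt = np.linalg.svd(mc.T @ fc)
    d = np.sign(np.linalg.det(v @ wt))
    rot = (v @ np.diag([1, 1, d]) @ wt)
    moved = mc @ rot + fixed.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))


def plane_dots(n_side, spacing, z, area_per_dot=1.0):
    xs = np.arange(n_side) * spacing
    grid = np.array([[x, y, z] for x in xs for y in xs], dtype=float)
    return SurfaceDots(
        grid, np.full(len(grid), area_per_dot), np.zeros(len(grid), dtype=int)
    )


# ---------------------------------------------------------------------------
# Dot surfaces


class TestDotSurface:
    def test_single_sphere_matches_closed_form(self):
        r, probe = 1.7, 1.4
        dots = dot_surface([[0, 0, 0]], [r], probe, density=5.0)
        exact = 4 * math.pi * (r + probe) ** 2
        assert abs(dots.total_area - exact) / exact < 0.02

    def test_two_distant_spheres_add(self):
        dots = dot_surface([[0, 0, 0], [50, 0, 0]], [1.7, 1.5], 1.4, density=5.0)
        exact = 4 * math.pi * ((1.7 + 1.4) ** 2 + (1.5 + 1.4) ** 2)
        assert abs(dots.total_area - exact) / exact < 0.02

    def test_overlapping_spheres_match_cap_oracle(self):
        r1, r2, probe, d = 1.7, 1.52, 1.4, 2.0
        dots = dot_surface(
            [[0, 0, 0], [d, 0, 0]], [r1, r2], probe, density=10.0
        )
        exact = two_sphere_exposed_area(r1 + probe, r2 + probe, d)
        assert abs(dots.total_area - exact) / exact < 0.03

    def test_area_converges_with_density(self):
        coords = [[0, 0, 0], [2.5, 0.5, 0], [1.0, 2.0, 1.0]]
        radii = [1.7, 1.55, 1.52]
        coarse = dot_surface(coords, radii, density=2.0).total_area
        fine = dot_surface(coords, radii, density=20.0).total_area
        assert abs(coarse - fine) / fine < 0.03

    def test_empty_selection_rejected(self):
        with pytest.raises(SurfaceError):
            dot_surface(np.empty((0, 3)), [], 1.4)

    def test_molecular_surface_from_structure(self, toy_complex):
        model = toy_complex[0]
        dots = molecular_surface(model, "A", density=3.0)
        assert dots.total_area > 0
        with pytest.raises(SurfaceError):
            molecular_surface(model, [], density=3.0)

    def test_element_radius_table(self):
        assert element_radius("C") == 1.70
        assert element_radius("ZZ") == 1.70  # default for unknown elements
        assert element_radius("S") == 1.80


class TestContactMolecularSurface:
    def test_coincident_surfaces_give_binder_area(self):
        a = plane_dots(10, 1.0, z=0.0)
        b = plane_dots(10, 1.0, z=0.0)
        cms = contact_molecular_surface(a, b)
        assert cms == pytest.approx(a.total_area)

    def test_unit_distance_weight(self):
        a = SurfaceDots(np.array([[0.0, 0, 0]]), np.array([2.0]), np.array([0]))
        b = SurfaceDots(np.array([[1.0, 0, 0]]), np.array([5.0]), np.array([0]))
        assert contact_molecular_surface(a, b) == pytest.approx(
            2.0 * math.exp(-0.5)
        )

    def test_distant_surfaces_score_zero(self):
        a = plane_dots(5, 1.0, z=0.0)
        b = plane_dots(5, 1.0, z=50.0)
        assert contact_molecular_surface(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decreasing_with_plane_separation(self):
        a = plane_dots(10, 1.0, z=0.0)
        values = [
            contact_molecular_surface(a, plane_dots(10, 1.0, z=gap))
            for gap in (0.5, 1.0, 2.0, 3.0, 5.0)
        ]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_bounded_by_binder_area_and_pair_invariant(self):
        rng = np.random.default_rng(1)
        a = SurfaceDots(rng.normal(0, 3, (40, 3)), rng.uniform(0.5, 2, 40), np.zeros(40, int))
        b = SurfaceDots(rng.normal(1, 3, (30, 3)), rng.uniform(0.5, 2, 30), np.zeros(30, int))
        cms = contact_molecular_surface(a, b)
        assert cms <= a.total_area + 1e-9
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        shift = np.array([4.0, -2.0, 7.0])
        a2 = SurfaceDots(a.centers @ rot.T + shift, a.areas, a.atom_index)
        b2 = SurfaceDots(b.centers @ rot.T + shift, b.areas, b.atom_index)
        assert contact_molecular_surface(a2, b2) == pytest.approx(cms, rel=1e-9)

    def test_symmetric_mode_averages_sides(self):
        a = plane_dots(6, 1.0, z=0.0)
        b = plane_dots(3, 1.0, z=1.0)
        sym = contact_molecular_surface(a, b, symmetric=True)
        one = contact_molecular_surface(a, b)
        other = contact_molecular_surface(b, a)
        assert sym == pytest.approx(0.5 * (one + other))


# ---------------------------------------------------------------------------
# PDB IO


ALTLOC_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.60  0.00           C
ATOM      3  CA BALA A   1      12.639   6.071  -5.147  0.40  0.00           C
ATOM      4  C   ALA A   1      10.560   5.626  -4.162  1.00  0.00           C
END
"""


class TestPDBIO:
    def test_round_trip_preserves_geometry(self, tmp_path, toy_complex):
        path = tmp_path / "toy.pdb"
        write_pdb(toy_complex, path)
        back = read_pdb(path)
        orig = list(toy_complex.get_atoms())
        new = list(back.get_atoms())
        assert len(orig) == len(new)
        for a, b in zip(orig, new):
            assert a.get_name() == b.get_name()
            np.testing.assert_allclose(a.coord, b.coord, atol=1e-2)

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        structure = read_pdb(path)
        residue = next(structure.get_residues())
        cas = [a for a in residue if a.get_name() == "CA"]
        assert len(cas) == 1
        assert cas[0].coord[0] == pytest.approx(11.639, abs=1e-3)

    def test_chain_and_residue_counts(self, toy_complex):
        model = toy_complex[0]
        assert len(list(model["A"].get_residues())) == 6
        assert len(list(model["B"].get_residues())) == 8


# ---------------------------------------------------------------------------
# Interface and layers


class TestInterfaceResidues:
    def _pair_at(self, distance):
        binder = [backbone_residue("ALA", (0, 0, 0), (0, 1.5, 0))]
        target = [backbone_residue("LEU", (0, distance - 1.5 + 1.5, 0), (0, -1.5, 0))]
        # place target CB exactly `distance` from binder CB
        binder_cb = np.array([0, 1.5, 0])
        target = [
            backbone_residue(
                "LEU", (0, 1.5 + distance + 1.5, 0), (0, -1.5, 0)
            )
        ]
        return build_structure({"A": binder, "B": target})[0]

    def test_inside_cutoff_selected(self):
        model = self._pair_at(7.9)
        assert len(interface_residues(model, "A", "B")) == 1

    def test_outside_cutoff_not_selected(self):
        model = self._pair_at(8.1)
        assert interface_residues(model, "A", "B") == []

    def test_exact_selection_count(self, toy_complex):
        # binder Ca at y=0 (CB alternating +/-1.5), target Ca at y=5
        # (CB at y=3.5): binder CBs at +1.5 are 2.0 A away, at -1.5 are 5.0 A
        # from the nearest target CB in y; x offsets decide the rest
        model = toy_complex[0]
        selected = interface_residues(model, "A", "B")
        assert len(selected) == 6  # every binder residue has a CB within 8 A

    def test_glycine_uses_ca(self):
        binder = [backbone_residue("GLY", (0, 0, 0), with_cb=False)]
        target = [backbone_residue("LEU", (0, 6.0, 0), (0, -1.5, 0))]
        model = build_structure({"A": binder, "B": target})[0]
        assert len(interface_residues(model, "A", "B")) == 1


class TestLayerClassify:
    def test_extended_peptide_has_no_core(self):
        model = build_structure({"A": extended_chain(12)})[0]
        layers = layer_classify(model, "A")
        assert "core" not in layers.values()

    def test_single_residue_chain_is_surface(self):
        model = build_structure(
            {"A": [backbone_residue("ALA", (0, 0, 0))]}
        )[0]
        assert set(layer_classify(model, "A").values()) == {"surface"}

    def test_buried_centre_of_dense_cluster_is_core(self):
        rng = np.random.default_rng(0)
        residues = [backbone_residue("ALA", (0, 0, 0), (0, 1.5, 0))]
        # shell of neighbours in the side-chain hemisphere of the centre
        for k in range(24):
            direction = rng.normal(size=3)
            direction[1] = abs(direction[1]) + 0.3  # bias toward +y
            direction /= np.linalg.norm(direction)
            residues.append(
                backbone_residue("ALA", tuple(6.0 * direction), (0, 1.5, 0))
            )
        model = build_structure({"A": residues})[0]
        layers = layer_classify(model, "A")
        assert layers[(" ", 1, " ")] == "core"

    def test_invariant_under_rigid_transform(self):
        chain = extended_chain(8)
        model1 = build_structure({"A": chain})[0]
        rot = Rotation.from_euler("zyx", [0.7, -0.2, 1.9]).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        moved = []
        for resname, atoms in chain:
            moved.append(
                (
                    resname,
                    [
                        (n, e, tuple(rot @ np.array(c) + shift))
                        for n, e, c in atoms
                    ],
                )
            )
        model2 = build_structure({"A": moved})[0]
        assert layer_classify(model1, "A") == layer_classify(model2, "A")


# ---------------------------------------------------------------------------
# RMSD protocols


def transform_structure(structure, rot=None, shift=None, chains=None):
    rot = np.eye(3) if rot is None else rot
    shift = np.zeros(3) if shift is None else np.asarray(shift, float)
    for chain in structure[0]:
        if chains is not None and chain.id not in chains:
            continue
        for atom in chain.get_atoms():
            atom.coord = rot @ atom.coord + shift
    return structure


class TestRMSD:
    def test_identical_structures_zero(self, toy_complex):
        model = toy_complex[0]
        assert rmsd_superimposed(model, model, {"A": "A"}) == pytest.approx(
            0.0, abs=1e-9
        )
        assert rmsd_target_aligned(
            model, model, {"B": "B"}, {"A": "A"}
        ) == pytest.approx(0.0, abs=1e-9)

    def test_identical_after_rigid_transform_zero(self):
        a = build_structure({"A": extended_chain(5)})
        b = build_structure({"A": extended_chain(5)})
        rot = Rotation.from_euler("xyz", [1.0, 0.4, -0.7]).as_matrix()
        transform_structure(b, rot, [3.0, 4.0, 5.0])
        assert rmsd_superimposed(a[0], b[0], {"A": "A"}) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_translated_binder_fixed_target(self):
        a = build_structure(
            {"A": extended_chain(5, z=0.0), "B": extended_chain(7, z=8.0)}
        )
        b = build_structure(
            {"A": extended_chain(5, z=0.0), "B": extended_chain(7, z=8.0)}
        )
        transform_structure(b, shift=[0.0, 2.0, 0.0], chains={"A"})
        value = rmsd_target_aligned(a[0], b[0], {"B": "B"}, {"A": "A"})
        assert value == pytest.approx(2.0, abs=1e-9)

    def test_whole_complex_rotation_leaves_rmsd_unchanged(self):
        rng = np.random.default_rng(2)
        # target Ca positions must not be collinear or the target
        # superposition is degenerate
        target_cas = rng.normal(0, 4, (7, 3)) + [0, 0, 8.0]
        target = [backbone_residue("LEU", tuple(p)) for p in target_cas]
        a = build_structure(
            {"A": extended_chain(5), "B": [(rn, list(at)) for rn, at in target]}
        )
        b = build_structure(
            {"A": extended_chain(5), "B": [(rn, list(at)) for rn, at in target]}
        )
        # perturb the binder, then rotate the whole crystal complex
        for atom in b[0]["A"].get_atoms():
            atom.coord = atom.coord + rng.normal(0, 0.5, 3)
        before = rmsd_target_aligned(a[0], b[0], {"B": "B"}, {"A": "A"})
        rot = Rotation.from_euler("xyz", [0.5, 1.2, -0.3]).as_matrix()
        transform_structure(b, rot, [10.0, -4.0, 2.0])
        after = rmsd_target_aligned(a[0], b[0], {"B": "B"}, {"A": "A"})
        assert after == pytest.approx(before, abs=1e-5)  # float32 atom coords

    def test_matches_kabsch_oracle_on_three_point_toys(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            ca_a = rng.normal(0, 5, (3, 3))
            ca_b = rng.normal(0, 5, (3, 3))
            a = build_structure(
                {"A": [backbone_residue("ALA", tuple(p)) for p in ca_a]}
            )
            b = build_structure(
                {"A": [backbone_residue("ALA", tuple(p)) for p in ca_b]}
            )
            value = rmsd_superimposed(a[0], b[0], {"A": "A"})
            assert value == pytest.approx(kabsch_oracle(ca_a, ca_b), abs=1e-6)

    def test_superposition_is_optimal(self):
        rng = np.random.default_rng(4)
        ca_a = rng.normal(0, 5, (6, 3))
        ca_b = ca_a + rng.normal(0, 1.0, (6, 3))
        a = build_structure({"A": [backbone_residue("ALA", tuple(p)) for p in ca_a]})
        b = build_structure({"A": [backbone_residue("ALA", tuple(p)) for p in ca_b]})
        sup = rmsd_superimposed(a[0], b[0], {"A": "A"})
        raw = float(np.sqrt(np.mean(np.sum((ca_a - ca_b) ** 2, axis=1))))
        assert sup <= raw + 1e-12

    def test_no_correspondence_raises(self):
        a = build_structure({"A": [backbone_residue("ALA", (0, 0, 0)),
                                   backbone_residue("GLY", (3.8, 0, 0), with_cb=False)]})
        b = build_structure({"A": [backbone_residue("TRP", (0, 0, 0)),
                                   backbone_residue("PHE", (3.8, 0, 0))]})
        with pytest.raises(ComparisonError):
            pair_residues(a[0]["A"], b[0]["A"])


class TestInterfaceCoreRMSD:
    def _buried_complex(self):
        """Binder with one buried interface residue against a dense target."""
        rng = np.random.default_rng(7)
        binder = [backbone_residue("ALA", (3.8 * i, 0, 0), (0, 1.5, 0)) for i in range(4)]
        target = []
        for k in range(26):
            direction = rng.normal(size=3)
            direction[1] = abs(direction[1]) + 0.5
            direction /= np.linalg.norm(direction)
            centre = np.array([3.8, 0, 0]) + 6.5 * direction
            target.append(backbone_residue("LEU", tuple(centre), (0, -1.5, 0)))
        return build_structure({"A": binder, "B": target})

    def test_identical_complex_zero(self):
        design = self._buried_complex()
        crystal = self._buried_complex()
        value, n_res = interface_core_heavy_rmsd(
            design[0], crystal[0], {"B": "B"}, {"A": "A"}
        )
        assert value == pytest.approx(0.0, abs=1e-9)
        assert n_res >= 1

    def test_displaced_side_chain_analytic(self):
        design = self._buried_complex()
        crystal = self._buried_complex()
        selection_model = design[0]
        from binderscreen.structmetrics import select_interface

        sel = select_interface(selection_model, "A", "B")
        core_ids = sel.core_residue_ids()
        assert core_ids
        res_id = core_ids[0]
        # displace one atom of one selected residue by 1 A; RMSD over the m
        # heavy atoms of the selection is sqrt(1/m)
        total_atoms = 0
        for rid in core_ids:
            residue = crystal[0]["A"][rid]
            total_atoms += sum(1 for a in residue if a.element != "H")
        crystal[0]["A"][res_id]["CB"].coord = (
            crystal[0]["A"][res_id]["CB"].coord + np.array([0.0, 0.0, 1.0])
        )
        value, n_res = interface_core_heavy_rmsd(
            design[0], crystal[0], {"B": "B"}, {"A": "A"}
        )
        assert value == pytest.approx(math.sqrt(1.0 / total_atoms), abs=1e-6)

    def test_empty_selection_raises(self):
        design = build_structure(
            {"A": extended_chain(4), "B": extended_chain(4, z=30.0)}
        )
        with pytest.raises(ComparisonError):
            interface_core_heavy_rmsd(
                design[0], design[0], {"B": "B"}, {"A": "A"}
            )
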