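import numpy as np
import pytest

from carotenostruct import synthetic_data as synth
from carotenostruct.carotenoid_geometry import (
    bla,
    bla_for_ligand,
    builtin_templates,
    dihedral,
    extract_polyene,
    fit_plane,
    pair_geometry,
    pseudo_twofold_axes,
    ring_conformation,
    torsion_for_ligand,
)
from carotenostruct.errors import (
    DegenerateGeometryError,
    MissingAtomError,
    ScopeError,
)
from carotenostruct.structure_io import Atom

from _oracles import dihedral_atan2, plane_normal_eig


def _chain_atoms(lengths):
    """Straight-line pseudo-polyene with the given consecutive bond lengths."""
    xs = np.concatenate([[0.0], np.cumsum(lengths)])
    return [Atom(f"C{i+1}", "C", np.array([x, 0.0, 0.0]))
            for i, x in enumerate(xs)]


class TestExtractPolyene:
    def test_path_counts(self):
        spec = synth.SyntheticComplexSpec(n_polyene_atoms=22)
        lig, _ = synth.make_polyene(spec)
        atoms, orders = extract_polyene(lig)
        assert len(atoms) == 22
        assert len(orders) == 21

    def test_orders_alternate(self, polyene):
        lig, _ = polyene
        _, orders = extract_polyene(lig)
        is_single = [o == 1 for o in orders]
        assert all(a != b for a, b in zip(is_single, is_single[1:]))

    def test_missing_path_atom_is_named_in_error(self, polyene):
        lig, _ = polyene
        lig.residue.atoms = [a for a in lig.residue.atoms if a.name != "C5"]
        with pytest.raises(MissingAtomError, match="C5"):
            extract_polyene(lig)


class TestBLA:
    def test_equal_lengths_give_zero(self):
        atoms = _chain_atoms([1.40] * 7)
        res = bla(atoms, [2, 1, 2, 1, 2, 1, 2])
        assert res.bla == pytest.approx(0.0, abs=1e-9)

    def test_alternating_145_135(self):
        lengths = [1.35 if i % 2 == 0 else 1.45 for i in range(9)]
        atoms = _chain_atoms(lengths)
        res = bla(atoms, [2 if i % 2 == 0 else 1 for i in range(9)])
        assert res.bla == pytest.approx(0.10, abs=1e-6)
        assert res.bla == pytest.approx(res.mean_single - res.mean_double, abs=1e-9)

    def test_randomized_lengths_match_brute_force(self):
        rng = np.random.default_rng(17)
        lengths = rng.uniform(1.30, 1.50, size=17)
        orders = [2 if i % 2 == 0 else 1 for i in range(17)]
        atoms = _chain_atoms(lengths)
        # independent: recompute actual inter-atom distances, average by class
        pts = np.array([a.pos for a in atoms])
        actual = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        expect = (np.mean([d for d, o in zip(actual, orders) if o == 1])
                  - np.mean([d for d, o in zip(actual, orders) if o == 2]))
        assert bla(atoms, orders).bla == pytest.approx(expect, abs=1e-12)

    def test_triple_bond_excluded_from_both_means(self):
        atoms = _chain_atoms([1.20, 1.45, 1.35, 1.45, 1.35])
        res = bla(atoms, [3, 1, 2, 1, 2])
        assert res.n_single == 2 and res.n_double == 2
        assert res.bla == pytest.approx(0.10, abs=1e-6)

    def test_halves_reconstruct_full_mean(self):
        rng = np.random.default_rng(3)
        lengths = rng.uniform(1.30, 1.50, size=17)
        orders = [2 if i % 2 == 0 else 1 for i in range(17)]
        atoms = _chain_atoms(lengths)
        full = bla(atoms, orders)
        left = bla(atoms, orders, scope="beta_side")
        right = bla(atoms, orders, scope="beta_prime_side")
        # odd bond count: the central (double) bond belongs to neither half
        n_d = left.n_double + right.n_double + 1
        mean_d = (left.mean_double * left.n_double
                  + right.mean_double * right.n_double
                  + np.linalg.norm(atoms[9].pos - atoms[8].pos)) / n_d
        mean_s = (left.mean_single * left.n_single
                  + right.mean_single * right.n_single) / (
                      left.n_single + right.n_single)
        assert full.bla == pytest.approx(mean_s - mean_d, abs=1e-12)

    def test_scope_without_single_bonds_raises(self):
        atoms = _chain_atoms([1.4, 1.4])
        with pytest.raises(ScopeError):
            bla(atoms, [2, 2])


class TestDihedral:
    def test_planar_cis_is_zero(self):
        ang = dihedral([1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, 1, 0])
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        ang = dihedral([1, 1, 0], [1, 0, 0], [-1, 0, 0], [-1, -1, 0])
        assert abs(ang) == pytest.approx(180.0, abs=1e-9)

    def test_mirror_negates_sign(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                a = dihedral(*pts)
            except DegenerateGeometryError:
                continue
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            b = dihedral(*mirrored)
            if abs(abs(a) - 180.0) > 1e-6:
                assert b == pytest.approx(-a, abs=1e-9)

    def test_agrees_with_independent_atan2_formula(self):
        rng = np.random.default_rng(2024)
        n = 0
        while n < 1000:
            pts = rng.normal(size=(4, 3)) * 4
            try:
                mine = dihedral(*pts)
            except DegenerateGeometryError:
                continue
            ref = dihedral_atan2(*pts)
            delta = abs(mine - ref) % 360.0
            assert min(delta, 360.0 - delta) < 1e-9
            n += 1

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestRingConformation:
    @pytest.mark.parametrize("torsion,klass", [
        (-39.9, "s-cis"),      # free-pigment-like ring rotation
        (-40.0, "s-cis"),
        (170.6, "s-trans"),    # protein-bound coplanar rings
        (164.4, "s-trans"),
        (90.0, "s-cis"),       # boundary: strict > rule assigns s-cis
        (-90.0, "s-cis"),
        (90.1, "s-trans"),
    ])
    def test_ninety_degree_rule(self, torsion, klass):
        spec = synth.SyntheticComplexSpec(end_ring_torsions=(torsion, 170.0))
        lig, _ = synth.make_polyene(spec)
        conf = ring_conformation(lig, "ring")
        assert conf.torsion.angle == pytest.approx(torsion, abs=1e-6)
        assert conf.klass == klass

    def test_missing_atom_raises(self, polyene):
        lig, _ = polyene
        lig.residue.atoms = [a for a in lig.residue.atoms if a.name != "R2"]
        with pytest.raises(MissingAtomError):
            ring_conformation(lig, "ring")


class TestFitPlane:
    def test_coplanar_points_zero_rms(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [2, 3, 0.0]])
        normal, _, rms = fit_plane(pts)
        assert rms == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(normal, [0, 0, 1], atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            pts = rng.normal(size=(10, 3)) * np.array([3.0, 2.0, 0.5])
            normal, _, _ = fit_plane(pts)
            ref = plane_normal_eig(pts)
            assert abs(abs(np.dot(normal, ref)) - 1.0) < 1e-9

    def test_collinear_raises(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            fit_plane(pts)


class TestPairGeometry:
    def test_parallel_offset_polyenes(self, shell_complex):
        _, ligands, truth = shell_complex
        geom = pair_geometry(ligands[0], ligands[1])
        assert geom.interplanar_angle == pytest.approx(0.0, abs=1e-6)
        assert geom.min_distance == pytest.approx(truth.min_distance, abs=1e-9)

    def test_crossing_dihedral_spans_both_ligands(self, shell_complex):
        _, ligands, _ = shell_complex
        quad = [("A", "C5"), ("A", "C9"), ("B", "C9"), ("B", "C5")]
        geom = pair_geometry(ligands[0], ligands[1], crossing_quadruple=quad)
        a = ligands[0].residue
        b = ligands[1].residue
        expect = dihedral(a.get_atom("C5").pos, a.get_atom("C9").pos,
                          b.get_atom("C9").pos, b.get_atom("C5").pos)
        assert geom.crossing_dihedral == pytest.approx(expect, abs=1e-12)

    def test_min_distance_uses_polyene_atoms_only(self):
        # bring the ring stubs much closer than the chains: min_distance must
        # still report the chain-chain separation
        spec = synth.SyntheticComplexSpec(inter_polyene_offset=9.0,
                                          end_ring_torsions=(90.0, 90.0))
        _, ligands, _ = synth.make_complex(spec)
        geom = pair_geometry(ligands[0], ligands[1])
        assert geom.min_distance == pytest.approx(9.0, abs=1e-9)


class TestPseudoTwofold:
    @pytest.mark.parametrize("mode,angle", [("coincident", 0.0),
                                            ("perpendicular", 90.0)])
    def test_constructed_axis_relations(self, mode, angle):
        structure, ligA, ligB, expected = synth.make_twofold_complex(mode, seed=5)
        rel = pseudo_twofold_axes(structure, ligA, ligB)
        assert rel.axis_klass == expected
        assert rel.axis_angle == pytest.approx(angle, abs=1e-4)
        assert rel.dimer_rotation_angle == pytest.approx(180.0, abs=1e-6)

    def test_weak_twofold_warns(self):
        structure, ligA, ligB, _ = synth.make_twofold_complex("coincident", seed=6)
        from scipy.spatial.transform import Rotation

        # overwrite chain B with a small-angle copy of chain A: no twofold
        R = Rotation.from_euler("z", 20, degrees=True).as_matrix()
        chainA, chainB = structure.protein_chains()
        for ra, rb in zip(chainA.residues, chainB.residues):
            for aa, ab in zip(ra.atoms, rb.atoms):
                ab.pos = R @ aa.pos
        with pytest.warns(UserWarning, match="twofold"):
            pseudo_twofold_axes(structure, ligA, ligB)


class TestRigidInvariance:
    def test_descriptors_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        # a generic (slightly jittered, tilted) pair so no descriptor sits at
        # an ill-conditioned extreme such as exactly parallel planes
        ligA, _ = synth.make_polyene(
            synth.SyntheticComplexSpec(jitter=0.02, seed=1), code="SYA")
        ligB0, _ = synth.make_polyene(
            synth.SyntheticComplexSpec(jitter=0.02, seed=2), code="SYB")
        tilt = Rotation.from_euler("x", 6.0, degrees=True).as_matrix()
        ligB = synth.transform_ligand(ligB0, rotation=tilt,
                                      translation=(0.3, 0.5, 7.0))
        ligands = [ligA, ligB]
        base_pair = pair_geometry(ligands[0], ligands[1])
        base_bla = bla_for_ligand(ligands[0]).bla
        base_tors = torsion_for_ligand(ligands[0], "ring").angle
        base_klass = ring_conformation(ligands[0], "ring").klass
        rng = np.random.default_rng(99)
        for _ in range(100):
            q = rng.normal(size=4)
            R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
            t = rng.normal(scale=15.0, size=3)
            moved = [synth.transform_ligand(l, rotation=R, translation=t)
                     for l in ligands]
            geom = pair_geometry(moved[0], moved[1])
            assert geom.interplanar_angle == pytest.approx(
                base_pair.interplanar_angle, abs=1e-6)
            assert geom.min_distance == pytest.approx(base_pair.min_distance,
                                                      abs=1e-6)
            assert bla_for_ligand(moved[0]).bla == pytest.approx(base_bla, abs=1e-6)
            assert torsion_for_ligand(moved[0], "ring").angle == pytest.approx(
                base_tors, abs=1e-6)
            assert ring_conformation(moved[0], "ring").klass == base_klass


class TestParameterRecovery:
    @pytest.mark.parametrize("single,double,tau1,tau2", [
        (1.45, 1.35, 170.0, -35.0),
        (1.48, 1.33, -40.0, 164.4),
        (1.42, 1.39, 10.0, -170.0),
    ])
    def test_bla_and_torsions_recovered_exactly(self, single, double, tau1, tau2):
        spec = synth.SyntheticComplexSpec(single_len=single, double_len=double,
                                          end_ring_torsions=(tau1, tau2))
        lig, truth = synth.make_polyene(spec)
        assert bla_for_ligand(lig).bla == pytest.approx(truth.bla, abs=1e-6)
        assert torsion_for_ligand(lig, "ring").angle == pytest.approx(
            truth.torsions["ring"], abs=1e-6)
        assert torsion_for_ligand(lig, "ring_prime").angle == pytest.approx(
            truth.torsions["ring_prime"], abs=1e-6)


def test_builtin_templates_are_consistent():
    templates = builtin_templates()
    assert set(templates) == {"AXT", "MXT"}
    axt, mxt = templates["AXT"], templates["MXT"]
    assert len(axt.polyene_path) == len(mxt.polyene_path) == 18
    assert 3 in mxt.path_bond_orders()       # the acetylenic bond
    assert 3 not in axt.path_bond_orders()
    assert set(axt.end_rings) == {"beta", "beta_prime"}
    assert set(mxt.end_rings) == {"beta", "kappa"}
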