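import numpy as np
import pytest

from carotenostruct import synthetic_data as synth
from carotenostruct.errors import UnknownElementError
from carotenostruct.interaction_analysis import (
    VDW_RADII,
    contact_residues,
    fragment_bfactor,
    hydrogen_bonds,
    sasa,
    sasa_partition,
)
from carotenostruct.structure_io import Atom, Chain, Residue, Structure

from _oracles import sasa_dense


def _single_ligand_complex(shell):
    spec = synth.SyntheticComplexSpec(inter_polyene_offset=None, shell=shell)
    return synth.make_complex(spec)


class TestContacts:
    def test_cutoff_semantics(self):
        st, ligs, _ = _single_ligand_complex([
            synth.ShellSpec("A", "SER", 3.9),
            synth.ShellSpec("A", "LYS", 4.1),
        ])
        shell = contact_residues(st, ligs[0], cutoff=4.0)
        assert [(c, s, n) for c, s, n, _ in shell.residues] == [("A", 1, "SER")]
        d = shell.residues[0][3]
        assert d == pytest.approx(3.9, abs=1e-9)

    def test_far_ligand_gives_empty_shell(self):
        st, ligs, _ = _single_ligand_complex([synth.ShellSpec("A", "SER", 10.0)])
        assert contact_residues(st, ligs[0], cutoff=4.0).residues == []

    def test_monotone_in_cutoff(self):
        st, ligs, _ = _single_ligand_complex([
            synth.ShellSpec("A", "SER", 2.8),
            synth.ShellSpec("A", "LYS", 3.5),
            synth.ShellSpec("B", "TYR", 4.5),
            synth.ShellSpec("B", "THR", 6.0),
        ])
        previous: set = set()
        for cutoff in (3.0, 4.0, 5.0, 7.0):
            members = {tuple(r[:3]) for r in
                       contact_residues(st, ligs[0], cutoff=cutoff).residues}
            assert previous <= members
            previous = members

    def test_partner_carotenoid_not_listed(self, shell_complex):
        st, ligs, _ = shell_complex
        labels = contact_residues(st, ligs[0], cutoff=8.0).labels()
        assert all("Sy2" not in lab for lab in labels)

    def test_ground_truth_shell_recovered(self):
        shell = [synth.ShellSpec("A", "SER", 2.8), synth.ShellSpec("A", "LYS", 3.9),
                 synth.ShellSpec("B", "TYR", 3.2)]
        st, ligs, truth = _single_ligand_complex(shell)
        got = contact_residues(st, ligs[0], cutoff=4.0)
        assert [(c, s, n) for c, s, n, _ in got.residues] == \
            [(c, s, n) for c, s, n, _ in truth.contacts[1]]
        for (_, _, _, d_got), (_, _, _, d_true) in zip(got.residues,
                                                       truth.contacts[1]):
            assert d_got == pytest.approx(d_true, abs=1e-9)


class TestHydrogenBonds:
    def test_hydroxyl_pair_within_cutoff_reported_once(self):
        st, ligs, truth = _single_ligand_complex(
            [synth.ShellSpec("A", "SER", 2.8, anchor_atom="O1")])
        bonds = hydrogen_bonds(st, ligs[0], include_internal=False)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.8, abs=1e-9)
        assert bonds[0].klass == "protein-ligand"
        assert truth.hbond_partners[1] == [("A", 1, "SER")]

    def test_pair_beyond_cutoff_not_reported(self):
        st, ligs, _ = _single_ligand_complex(
            [synth.ShellSpec("A", "SER", 5.0, anchor_atom="O1")])
        assert hydrogen_bonds(st, ligs[0], include_internal=False) == []

    def test_acceptor_acceptor_pair_rejected(self):
        # a carboxylate O near a keto-like ligand O: no donor on either side
        keto_o = Atom("O2", "O", np.array([0.0, 0.0, 0.0]))
        c1 = Atom("C1", "C", np.array([1.3, 0.0, 0.0]))
        lig = Residue(name="LIG", seq_id=1, chain_id="L",
                      atoms=[c1, keto_o], is_polymer=False)
        from carotenostruct.structure_io import LigandInstance
        from carotenostruct.carotenoid_geometry import CarotenoidTemplate

        # minimal template so O2 types as double-bonded (acceptor only)
        lig_inst = LigandInstance(
            residue=lig, template=None, bond_graph=[("C1", "O2", 2)])
        glu = Residue(name="GLU", seq_id=5, chain_id="A", atoms=[
            Atom("CD", "C", np.array([0.0, 4.0, 0.0])),
            Atom("OE1", "O", np.array([0.0, 2.9, 0.0])),
        ], is_polymer=True)
        st = Structure(chains=[Chain("A", [glu]), Chain("L", [lig])])
        assert hydrogen_bonds(st, lig_inst, include_internal=False) == []

    def test_geometry_filter_rejects_acute_approach(self):
        # acceptor placed behind the donor's antecedent: angle < 90 deg
        og = Atom("OG", "O", np.array([0.0, 0.0, 0.0]))
        cb = Atom("CB", "C", np.array([0.0, 1.5, 0.0]))
        ser = Residue(name="SER", seq_id=1, chain_id="A", atoms=[og, cb],
                      is_polymer=True)
        o1 = Atom("O1", "O", np.array([0.0, 2.8, 0.0]))  # behind CB
        c1 = Atom("C1", "C", np.array([0.0, 1.55, 0.0]))  # O1's antecedent
        lig = Residue(name="LIG", seq_id=9, chain_id="L", atoms=[o1, c1],
                      is_polymer=False)
        st = Structure(chains=[Chain("A", [ser]), Chain("L", [lig])])
        loose = hydrogen_bonds(st, lig, include_internal=False)
        strict = hydrogen_bonds(st, lig, require_geometry=True,
                                include_internal=False)
        assert len(loose) == 1
        assert strict == []


class TestSASA:
    @pytest.mark.parametrize("element", ["C", "O", "N", "S"])
    def test_isolated_sphere_closed_form(self, element):
        atom = Atom("X", element, np.zeros(3))
        area = sasa([atom], probe=1.4, n_points=960)[0]
        expect = 4 * np.pi * (VDW_RADII[element] + 1.4) ** 2
        assert area == pytest.approx(expect, rel=0.005)

    def test_single_carbon_reference_value(self):
        atom = Atom("C1", "C", np.zeros(3))
        assert sasa([atom])[0] == pytest.approx(4 * np.pi * 3.10 ** 2, rel=0.005)

    def test_fully_overlapping_pair_each_half(self):
        a = Atom("C1", "C", np.zeros(3))
        b = Atom("C2", "C", np.zeros(3) + 1e-9)
        areas = sasa([a, b], n_points=4000)
        full = 4 * np.pi * 3.10 ** 2
        for area in areas:
            assert area == pytest.approx(full / 2, rel=0.02)

    def test_random_cluster_matches_dense_oracle(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(scale=2.5, size=(20, 3))
        elements = rng.choice(["C", "N", "O", "S"], size=20)
        atoms = [Atom(f"X{i}", el, c) for i, (el, c) in
                 enumerate(zip(elements, coords))]
        mine = sasa(atoms, n_points=960)
        ref = sasa_dense(coords, [VDW_RADII[e] for e in elements],
                         n_points=10000)
        assert float(mine.sum()) == pytest.approx(float(ref.sum()), rel=0.02)

    def test_unknown_element_raises(self):
        with pytest.raises(UnknownElementError, match="Zz"):
            sasa([Atom("Q", "Zz", np.zeros(3))])

    def test_determinism(self):
        rng = np.random.default_rng(3)
        atoms = [Atom(f"C{i}", "C", p) for i, p in
                 enumerate(rng.normal(scale=2, size=(8, 3)))]
        assert np.array_equal(sasa(atoms), sasa(atoms))


class TestSASAPartition:
    def test_no_neighbors_all_exposed(self):
        st, ligs, _ = _single_ligand_complex([synth.ShellSpec("A", "SER", 30.0)])
        part = sasa_partition(st, ligs[0])
        assert part.fraction_exposed == pytest.approx(1.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in part.fraction_by_chain.values())

    def test_symmetric_shell_gives_equal_fractions(self):
        st, ligs, truth = _single_ligand_complex([
            synth.ShellSpec("A", "SER", 2.8),
            synth.ShellSpec("B", "SER", 2.8),
            synth.ShellSpec("A", "LYS", 3.5, anchor_atom="C6"),
            synth.ShellSpec("B", "LYS", 3.5, anchor_atom="C6"),
        ])
        assert truth.symmetric_chains
        part = sasa_partition(st, ligs[0])
        fa, fb = part.fraction_by_chain["A"], part.fraction_by_chain["B"]
        assert fa > 0.01
        assert fa == pytest.approx(fb, abs=0.01)

    def test_burial_bounds_and_partner_entry(self, shell_complex):
        st, ligs, _ = shell_complex
        part = sasa_partition(st, ligs[0])
        assert 0.0 < part.fraction_exposed <= 1.0 + 1e-9
        for v in part.fraction_by_chain.values():
            assert -1e-9 <= v <= 1.0
        partner = [k for k in part.fraction_by_chain if k.startswith("Sy2")]
        assert partner and part.fraction_by_chain[partner[0]] > 0.0


class TestFragmentB:
    def test_constant_b(self):
        spec = synth.SyntheticComplexSpec(ring_b_factors=(20.0, 20.0))
        lig, _ = synth.make_polyene(spec)
        stats = fragment_bfactor(lig, "ring")
        assert stats.mean_b == pytest.approx(20.0)
        assert stats.sd_b == pytest.approx(0.0)

    def test_two_point_formula(self):
        lig, _ = synth.make_polyene(synth.SyntheticComplexSpec())
        ring_atoms = [a for a in lig.residue.atoms
                      if a.name in lig.template.end_rings["ring"]]
        ring_atoms[0].b_factor = 10.0
        ring_atoms[1].b_factor = 30.0
        lig.residue.atoms = [a for a in lig.residue.atoms
                             if a.name not in lig.template.end_rings["ring"]] \
            + ring_atoms[:2]
        stats = fragment_bfactor(lig, "ring")
        assert stats.atom_count == 2
        assert stats.mean_b == pytest.approx(20.0)
        assert stats.sd_b == pytest.approx(10.0)  # population SD of {10, 30}

    def test_generator_truth_recovered(self):
        spec = synth.SyntheticComplexSpec(ring_b_factors=(31.0, 56.0))
        lig, truth = synth.make_polyene(spec)
        assert fragment_bfactor(lig, "ring").mean_b == pytest.approx(
            truth.ring_mean_b[0])
        assert fragment_bfactor(lig, "ring_prime").mean_b == pytest.approx(
            truth.ring_mean_b[1])

    def test_undefined_fragment_raises(self, polyene):
        lig, _ = polyene
        with pytest.raises(KeyError):
            fragment_bfactor(lig, "gamma")
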