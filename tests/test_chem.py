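"""Molecule I/O, torsion enumeration/manipulation, MMFF94 relaxation."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from torsionrl import chem


def _independent_dihedral(p0, p1, p2, p3):
    """Praxeides formula oracle: angle between the two bond planes, signed by
    the scalar triple product (kept separate from chem.dihedral_deg)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestLoadMolecule:
    def test_butane_sdf_roundtrip(self, butane, tmp_path):
        path = tmp_path / "butane.sdf"
        chem.write_mol(butane.reference, butane.molecule, path)
        spec = chem.load_molecule(path)
        assert spec.molecule.n_atoms == 14
        assert len(spec.molecule.bonds) == 13
        assert spec.molecule.n_torsions == 1

    def test_cyclohexane_all_ring_torsions_rigid(self):
        spec = chem.mol_spec_from_smiles("C1CCCCC1")
        assert spec.molecule.n_torsions == 0

    def test_zero_byte_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.mol"
        path.write_text("")
        with pytest.raises(chem.MoleculeError):
            chem.load_molecule(path)

    def test_missing_file_is_error(self, tmp_path):
        with pytest.raises(chem.MoleculeError):
            chem.load_molecule(tmp_path / "nope.mol")

    def test_disconnected_fragments_rejected(self, tmp_path):
        rdmol = Chem.AddHs(Chem.MolFromSmiles("C.C"))
        AllChem.EmbedMolecule(rdmol, randomSeed=0)
        path = tmp_path / "frags.mol"
        Chem.MolToMolFile(rdmol, str(path))
        with pytest.raises(chem.MoleculeError):
            chem.load_molecule(path)

    def test_2d_input_gets_deterministic_embedding(self, tmp_path):
        rdmol = Chem.MolFromSmiles("CCCC")
        path = tmp_path / "flat.mol"
        Chem.MolToMolFile(rdmol, str(path))  # no 3D coordinates
        a = chem.load_molecule(path)
        b = chem.load_molecule(path)
        assert np.allclose(a.reference.coordinates, b.reference.coordinates)
        assert a.reference.energy is not None  # embedded structures are relaxed


class TestTorsionEnumeration:
    @pytest.mark.parametrize(
        "smiles,n",
        [("CCCCC", 2), ("CC", 0), ("C", 0), ("CCCC", 1), ("CC(C)C", 0)],
    )
    def test_counts_by_hand_enumeration(self, smiles, n):
        assert chem.mol_spec_from_smiles(smiles).molecule.n_torsions == n

    def test_pentane_torsions_about_interior_bonds(self, pentane):
        centers = {(t.b, t.c) for t in pentane.molecule.torsions}
        assert centers == {(1, 2), (2, 3)}

    def test_enumeration_is_topological(self, pentane):
        """Atom-order permutation yields the same torsion set up to relabeling."""
        rdmol = pentane.molecule.rdkit_mol
        perm = list(range(rdmol.GetNumAtoms()))[::-1]
        renumbered = Chem.RenumberAtoms(rdmol, perm)
        spec2 = chem.mol_spec_from_rdkit(renumbered)
        mapped = {
            tuple(sorted((perm.index(t.b), perm.index(t.c))))
            for t in spec2.molecule.torsions
        }
        original = {(t.b, t.c) for t in pentane.molecule.torsions}
        assert mapped == original


class TestSetTorsions:
    def test_exact_profile_before_relaxation(self, pentane):
        conf = chem.set_torsions(pentane.reference, pentane.molecule, [0.0, 120.0])
        profile = chem.measure_torsions(conf, pentane.molecule)
        wrapped = (profile - np.array([0.0, 120.0]) + 180) % 360 - 180
        assert np.all(np.abs(wrapped) < 1e-6)

    def test_idempotent(self, pentane):
        g = pentane.molecule
        once = chem.set_torsions(pentane.reference, g, [45.0, 270.0])
        twice = chem.set_torsions(once, g, [45.0, 270.0])
        assert np.allclose(once.coordinates, twice.coordinates, atol=1e-9)

    def test_random_angles_match_independent_dihedral_oracle(self, pentane):
        g = pentane.molecule
        rng = np.random.default_rng(3)
        for _ in range(10):
            angles = rng.uniform(0, 360, 2)
            conf = chem.set_torsions(pentane.reference, g, angles)
            for t, target in zip(g.torsions, angles):
                xyz = conf.coordinates
                meas = _independent_dihedral(xyz[t.a], xyz[t.b], xyz[t.c], xyz[t.d])
                assert abs(((meas - target) + 180) % 360 - 180) < 1e-6

    def test_length_mismatch_raises(self, pentane):
        with pytest.raises(ValueError):
            chem.set_torsions(pentane.reference, pentane.molecule, [0.0])

    def test_order_commutes_for_disjoint_subtrees(self, pentane):
        """Setting (t0 then t1) equals (t1 then t0): rotations act on disjoint
        or nested atom sets and the final absolute angles coincide."""
        g = pentane.molecule
        a = chem.set_torsions(
            chem.set_torsions(pentane.reference, g, [30.0, *(pentane.reference.torsion_profile[1:] if pentane.reference.torsion_profile is not None else [0.0])]),
            g, [30.0, 250.0],
        )
        b = chem.set_torsions(pentane.reference, g, [30.0, 250.0])
        assert np.allclose(
            chem.measure_torsions(a, g), chem.measure_torsions(b, g), atol=1e-6
        )


class TestRelaxAndEnergy:
    def test_relax_never_increases_energy(self, pentane):
        g = pentane.molecule
        rng = np.random.default_rng(5)
        for _ in range(5):
            start = chem.set_torsions(pentane.reference, g, rng.uniform(0, 360, 2))
            e_before = chem.mmff_energy(start, g)
            relaxed = chem.relax(start, g)
            assert relaxed.energy <= e_before + 1e-6

    def test_relaxing_a_minimum_is_a_fixed_point(self, pentane):
        g = pentane.molecule
        once = chem.relax(pentane.reference, g)
        again = chem.relax(once, g)
        assert abs(again.energy - once.energy) < 1e-3

    def test_energy_is_deterministic(self, pentane):
        g = pentane.molecule
        e1 = chem.mmff_energy(pentane.reference, g)
        e2 = chem.mmff_energy(pentane.reference, g)
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_energy_rigid_motion_invariant(self, pentane):
        g = pentane.molecule
        e0 = chem.mmff_energy(pentane.reference, g)
        rng = np.random.default_rng(1)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        moved = chem.Conformer(pentane.reference.coordinates @ q + np.array([5.0, -3.0, 1.0]))
        assert chem.mmff_energy(moved, g) == pytest.approx(e0, abs=1e-6)

    def test_anti_anti_below_gauche_anti(self, pentane):
        """The extended (180,180) minimum is the MMFF94 global minimum; a
        gauche-anti minimum lies above it."""
        g = pentane.molecule
        anti = chem.relax(chem.set_torsions(pentane.reference, g, [180.0, 180.0]), g)
        gauche = chem.relax(chem.set_torsions(pentane.reference, g, [60.0, 180.0]), g)
        assert anti.energy < gauche.energy


class TestGenerateBranchedAlkane:
    @pytest.mark.parametrize("n", [1, 4, 9])
    def test_formula_cnh2n2(self, n):
        spec = chem.generate_branched_alkane(n, seed=2)
        symbols = [a.element for a in spec.molecule.atoms]
        assert symbols.count("C") == n
        assert symbols.count("H") == 2 * n + 2

    def test_same_seed_same_graph(self):
        a = chem.generate_branched_alkane(8, seed=7)
        b = chem.generate_branched_alkane(8, seed=7)
        assert [
            (x.atom_a, x.atom_b) for x in a.molecule.bonds
        ] == [(x.atom_a, x.atom_b) for x in b.molecule.bonds]
        assert np.allclose(a.reference.coordinates, b.reference.coordinates)

    def test_acyclic_and_tetravalent(self):
        for seed in range(4):
            spec = chem.generate_branched_alkane(12, seed=seed)
            rdmol = spec.molecule.rdkit_mol
            assert rdmol.GetRingInfo().NumRings() == 0
            for atom in rdmol.GetAtoms():
                if atom.GetSymbol() == "C":
                    assert atom.GetDegree() == 4

    def test_methane_edge_case(self):
        spec = chem.generate_branched_alkane(1, seed=0)
        assert spec.molecule.n_torsions == 0

    def test_invalid_count_raises(self):
        with pytest.raises(ValueError):
            chem.generate_branched_alkane(0)


class TestWriteMol:
    def test_roundtrip_coordinates_energy_topology(self, pentane, tmp_path):
        g = pentane.molecule
        conf = chem.relax(pentane.reference, g)
        path = tmp_path / "pent.mol"
        chem.write_mol(conf, g, path)
        back = chem.load_molecule(path)
        assert np.abs(back.reference.coordinates - conf.coordinates).max() <= 1e-4
        assert back.molecule.n_atoms == g.n_atoms
        assert len(back.molecule.bonds) == len(g.bonds)
        e_back = chem.mmff_energy(back.reference, back.molecule)
        assert e_back == pytest.approx(conf.energy, abs=1e-2)
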