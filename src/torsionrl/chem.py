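"""Molecule representation, MOL/SDF I/O, torsion manipulation and MMFF94 relaxation.

Everything downstream (the RL environment, rewards, observations) works with two
lightweight containers: :class:`MoleculeGraph`, the fixed bonded topology of one
molecule together with its ordered list of rotatable torsions, and
:class:`Conformer`, one set of 3D coordinates plus (after relaxation or an energy
call) its MMFF94 energy in kcal/mol.  RDKit does the heavy lifting behind the
scenes; an ``rdkit.Chem.Mol`` with explicit hydrogens is kept on the graph and
used as scratch space for dihedral setting, minimisation and file export.

Conventions:

* dihedrals are signed, in ``(-180, 180]`` degrees; comparisons are mod 360;
* a bond is rotatable iff it is a single, non-ring bond and both of its atoms
  have at least one *additional heavy-atom* neighbour (so methyl and ethane-type
  rotors are excluded -- they produce no conformationally distinct states);
* torsions are ordered by their central bond ``(b, c)`` with ``b < c``, which
  makes the action dimension deterministic for a given input file.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

__all__ = [
    "AtomRecord",
    "BondRecord",
    "TorsionQuadruple",
    "MoleculeGraph",
    "Conformer",
    "MolSpec",
    "MoleculeError",
    "load_molecule",
    "mol_spec_from_rdkit",
    "enumerate_rotatable_torsions",
    "measure_torsions",
    "set_torsions",
    "relax",
    "mmff_energy",
    "generate_branched_alkane",
    "write_mol",
    "dihedral_deg",
]

#: RDKit embedding seed used whenever an input file carries no 3D coordinates.
DEFAULT_EMBED_SEED = 0

BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RDKIT_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class MoleculeError(ValueError):
    """Raised for unparseable files, disconnected species or force-field failures."""


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    index: int
    element: str
    formal_charge: int = 0


@dataclasses.dataclass(frozen=True)
class BondRecord:
    atom_a: int
    atom_b: int
    order: str
    in_ring: bool = False

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise ValueError("bond endpoints must differ")
        if self.atom_a > self.atom_b:
            object.__setattr__(self, "atom_a", self.atom_b)
            object.__setattr__(self, "atom_b", self.atom_a)


@dataclasses.dataclass(frozen=True)
class TorsionQuadruple:
    """Four atom indices a-b-c-d defining a dihedral about the single bond b-c."""

    a: int
    b: int
    c: int
    d: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


class MoleculeGraph:
    """Bonded topology of one molecule plus its ordered rotatable torsions.

    Wraps an RDKit Mol (explicit hydrogens, exactly one conformer used as
    coordinate scratch space).  The wrapped mol is an implementation detail;
    consumers should use the ``atoms`` / ``bonds`` / ``torsions`` views.
    """

    def __init__(self, rdkit_mol: Chem.Mol):
        if rdkit_mol.GetNumConformers() == 0:
            raise MoleculeError("MoleculeGraph requires an embedded molecule")
        self._mol = rdkit_mol
        self.atoms: list[AtomRecord] = [
            AtomRecord(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge())
            for a in rdkit_mol.GetAtoms()
        ]
        self.bonds: list[BondRecord] = sorted(
            (
                BondRecord(
                    min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                    _RDKIT_ORDER.get(b.GetBondType(), "single"),
                    b.IsInRing(),
                )
                for b in rdkit_mol.GetBonds()
            ),
            key=lambda b: (b.atom_a, b.atom_b),
        )
        self.torsions: list[TorsionQuadruple] = enumerate_rotatable_torsions(self)
        self._ff_props = None

    # -- basic views -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_torsions(self) -> int:
        return len(self.torsions)

    @property
    def rdkit_mol(self) -> Chem.Mol:
        return self._mol

    def neighbors(self, idx: int) -> list[int]:
        return sorted(
            n.GetIdx() for n in self._mol.GetAtomWithIdx(idx).GetNeighbors()
        )

    def heavy_neighbors(self, idx: int) -> list[int]:
        return sorted(
            n.GetIdx()
            for n in self._mol.GetAtomWithIdx(idx).GetNeighbors()
            if n.GetAtomicNum() > 1
        )

    # -- force-field plumbing ---------------------------------------------
    def _force_field(self):
        if self._ff_props is None:
            self._ff_props = AllChem.MMFFGetMoleculeProperties(self._mol)
            if self._ff_props is None:
                raise MoleculeError("MMFF94 cannot parameterize this molecule")
        ff = AllChem.MMFFGetMoleculeForceField(self._mol, self._ff_props)
        if ff is None:
            raise MoleculeError("MMFF94 cannot parameterize this molecule")
        return ff

    def _load_coords(self, coordinates: np.ndarray) -> None:
        conf = self._mol.GetConformer()
        coords = np.asarray(coordinates, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(
                f"expected coordinates of shape {(self.n_atoms, 3)}, got {coords.shape}"
            )
        for i in range(self.n_atoms):
            conf.SetAtomPosition(i, coords[i].tolist())

    def _read_coords(self) -> np.ndarray:
        return np.array(self._mol.GetConformer().GetPositions(), dtype=float)


@dataclasses.dataclass
class Conformer:
    """One 3D structure of a molecule: coordinates in Å, optional MMFF94 energy."""

    coordinates: np.ndarray
    energy: Optional[float] = None
    torsion_profile: Optional[np.ndarray] = None

    def copy(self) -> "Conformer":
        return Conformer(
            self.coordinates.copy(),
            self.energy,
            None if self.torsion_profile is None else self.torsion_profile.copy(),
        )


@dataclasses.dataclass
class MolSpec:
    """A molecule ready for the RL environment: graph + reference conformer.

    ``e0`` optionally fixes the Boltzmann-reward normalising energy for this
    molecule; when ``None`` the environment uses the energy of each episode's
    initial relaxed conformer.
    """

    molecule: MoleculeGraph
    reference: Conformer
    source_path: Optional[str] = None
    e0: Optional[float] = None


# ---------------------------------------------------------------------------
# torsion enumeration and measurement
# ---------------------------------------------------------------------------

def enumerate_rotatable_torsions(mol: MoleculeGraph) -> list[TorsionQuadruple]:
    """One quadruple per rotatable bond: single, non-ring, both ends bearing
    at least one additional heavy neighbour.  Reference atoms ``a`` and ``d``
    are the lowest-index heavy neighbours of ``b`` and ``c`` respectively.
    Ordering is by the central bond ``(b, c)``, ``b < c``."""
    quads: list[TorsionQuadruple] = []
    for bond in mol.bonds:
        if bond.order != "single" or bond.in_ring:
            continue
        b, c = bond.atom_a, bond.atom_b
        b_heavy = [n for n in mol.heavy_neighbors(b) if n != c]
        c_heavy = [n for n in mol.heavy_neighbors(c) if n != b]
        if not b_heavy or not c_heavy:
            continue  # terminal rotor (methyl, hydroxyl, ethane C-C): no new conformers
        quads.append(TorsionQuadruple(b_heavy[0], b, c, c_heavy[0]))
    return quads


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / np.linalg.norm(b1)))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def measure_torsions(conf: Conformer, mol: MoleculeGraph) -> np.ndarray:
    """Signed dihedral (degrees) of every rotatable torsion, from coordinates."""
    xyz = conf.coordinates
    return np.array(
        [dihedral_deg(xyz[t.a], xyz[t.b], xyz[t.c], xyz[t.d]) for t in mol.torsions],
        dtype=float,
    )


def set_torsions(
    conf: Conformer, mol: MoleculeGraph, angles: Sequence[float]
) -> Conformer:
    """Return a new conformer with each rotatable dihedral set to ``angles[j]``.

    Only the atoms on one side of each rotated bond move; bond lengths and
    angles are untouched.  The energy of the result is unknown (``None``) until
    relaxed or evaluated.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (mol.n_torsions,):
        raise ValueError(
            f"expected {mol.n_torsions} torsion angles, got shape {angles.shape}"
        )
    mol._load_coords(conf.coordinates)
    rdconf = mol.rdkit_mol.GetConformer()
    for t, angle in zip(mol.torsions, angles):
        rdMolTransforms.SetDihedralDeg(rdconf, t.a, t.b, t.c, t.d, float(angle))
    out = Conformer(mol._read_coords())
    out.torsion_profile = measure_torsions(out, mol)
    return out


# ---------------------------------------------------------------------------
# MMFF94 relaxation and energy
# ---------------------------------------------------------------------------

def mmff_energy(conf: Conformer, mol: MoleculeGraph) -> float:
    """MMFF94 energy (kcal/mol) of the coordinates; pure function, no movement."""
    mol._load_coords(conf.coordinates)
    return float(mol._force_field().CalcEnergy())


def relax(
    conf: Conformer,
    mol: MoleculeGraph,
    max_iters: int = 1000,
    tol: float = 1e-4,
) -> Conformer:
    """Locally minimise the conformer under MMFF94.

    Returns a new conformer carrying the minimised coordinates, its energy and
    its torsion profile.  Energy never increases (up to 1e-6 numerical slack).
    """
    mol._load_coords(conf.coordinates)
    ff = mol._force_field()
    ff.Initialize()
    ff.Minimize(maxIts=int(max_iters), forceTol=float(tol))
    out = Conformer(mol._read_coords(), energy=float(ff.CalcEnergy()))
    out.torsion_profile = measure_torsions(out, mol)
    return out


# ---------------------------------------------------------------------------
# I/O and fixture generation
# ---------------------------------------------------------------------------

def _finalize(rdmol: Chem.Mol, source_path: Optional[str]) -> MolSpec:
    if rdmol is None:
        raise MoleculeError(f"cannot parse molecule file: {source_path}")
    if len(Chem.GetMolFrags(rdmol)) > 1:
        raise MoleculeError("multiple disconnected fragments are not supported")
    needs_h = any(a.GetNumImplicitHs() > 0 for a in rdmol.GetAtoms())
    has_3d = rdmol.GetNumConformers() > 0 and rdmol.GetConformer().Is3D()
    if needs_h:
        rdmol = Chem.AddHs(rdmol, addCoords=has_3d)
        has_3d = has_3d and rdmol.GetConformer().Is3D() if rdmol.GetNumConformers() else False
    if not has_3d:
        if AllChem.EmbedMolecule(rdmol, randomSeed=DEFAULT_EMBED_SEED) != 0:
            raise MoleculeError("distance-geometry embedding failed")
    graph = MoleculeGraph(rdmol)
    start = Conformer(graph._read_coords())
    reference = relax(start, graph) if not has_3d else start
    if reference.torsion_profile is None:
        reference.torsion_profile = measure_torsions(reference, graph)
    return MolSpec(molecule=graph, reference=reference, source_path=source_path)


def load_molecule(path: str | Path) -> MolSpec:
    """Read a MOL or SDF file into a :class:`MolSpec`.

    Hydrogens are made explicit.  Files without 3D coordinates get a
    deterministic distance-geometry embedding (fixed seed) followed by one
    MMFF94 relaxation, so every spec carries exactly one reference structure.
    """
    path = Path(path)
    if not path.exists():
        raise MoleculeError(f"no such file: {path}")
    if path.suffix.lower() in {".sdf", ".sd"}:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        rdmol = next(iter(supplier), None)
    else:
        rdmol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=True)
    return _finalize(rdmol, str(path))


def mol_spec_from_rdkit(rdmol: Chem.Mol) -> MolSpec:
    """Build a MolSpec from an in-memory RDKit molecule (hydrogens added,
    embedded deterministically if no 3D conformer is present)."""
    return _finalize(Chem.Mol(rdmol), None)


def mol_spec_from_smiles(smiles: str) -> MolSpec:
    """Build a MolSpec from a SMILES string (embedded with the fixed seed)."""
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise MoleculeError(f"cannot parse SMILES: {smiles!r}")
    return _finalize(rdmol, None)


def generate_branched_alkane(n_carbons: int, seed: int = 0) -> MolSpec:
    """Seeded random branched alkane C_n H_{2n+2}.

    Grows a random carbon tree: each new carbon attaches to a uniformly chosen
    existing carbon that still has an open valence.  The same ``(n_carbons,
    seed)`` pair always yields the same graph and the same embedding.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    rng = np.random.default_rng(seed)
    rw = Chem.RWMol()
    rw.AddAtom(Chem.Atom(6))
    degree = [0]
    for _ in range(n_carbons - 1):
        open_sites = [i for i, d in enumerate(degree) if d < 4]
        parent = int(open_sites[rng.integers(len(open_sites))])
        new = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(parent, new, Chem.BondType.SINGLE)
        degree[parent] += 1
        degree.append(1)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    mol = Chem.AddHs(mol)
    embed_seed = int(seed) % (2**31 - 1) + 1  # RDKit wants a positive seed
    if AllChem.EmbedMolecule(mol, randomSeed=embed_seed) != 0:
        raise MoleculeError(f"embedding failed for C{n_carbons} alkane (seed {seed})")
    graph = MoleculeGraph(mol)
    reference = relax(Conformer(graph._read_coords()), graph)
    return MolSpec(molecule=graph, reference=reference)


def write_mol(conf: Conformer, mol: MoleculeGraph, path: str | Path) -> None:
    """Write the conformer as a V2000 MOL file (round-trips to 1e-4 Å)."""
    mol._load_coords(conf.coordinates)
    path = Path(path)
    try:
        Chem.MolToMolFile(mol.rdkit_mol, str(path), forceV3000=False)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise IOError(f"cannot write MOL file to {path}: {exc}") from exc
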