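"""Featurized graph observations of a conformer.

The agent never sees raw RDKit objects; it sees a :class:`GraphObservation`:
per-atom feature vectors (element one-hot + 3D coordinates), directed edges
with bond-type one-hot and Euclidean distance features, and the atom quadruple
of every rotatable torsion (used by per-torsion action heads).

Coordinates can be normalized for translation (centroid at origin), rotation
(principal-axes frame with a deterministic sign convention) and scale (unit RMS
radius), so that rigidly superimposable conformers produce identical
observations.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np

from .chem import Conformer, MoleculeGraph, BOND_ORDERS

__all__ = [
    "ObservationConfig",
    "GraphObservation",
    "extract_node_features",
    "extract_edge_features",
    "build_observation",
    "normalize_graph",
]

DEFAULT_ALPHABET = ("C", "H", "O", "N", "S", "F", "Cl", "other")

#: bond-type one-hot slots: the four covalent orders plus a "nonbonded" slot
#: used for within-cutoff spatial edges.
EDGE_TYPES = BOND_ORDERS + ("nonbonded",)


@dataclasses.dataclass(frozen=True)
class ObservationConfig:
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    cutoff_radius: float = 0.0
    normalize_modes: frozenset[str] = frozenset({"translation"})

    def __post_init__(self):
        if "other" not in self.alphabet:
            raise ValueError('alphabet must include the reserved "other" slot')
        bad = set(self.normalize_modes) - {"translation", "rotation", "scale"}
        if bad:
            raise ValueError(f"unknown normalization modes: {sorted(bad)}")


@dataclasses.dataclass
class GraphObservation:
    """Arrays-of-records view of one conformer.

    node_features: (N, |alphabet| + 3) — element one-hot then x, y, z
    edge_index:    (2, E) directed pairs; both directions per undirected edge
    edge_features: (E, 6) — bond-type one-hot (incl. nonbonded) then distance (Å)
    torsion_atom_index: (n_torsions, 4) atom indices of each rotatable dihedral
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    torsion_atom_index: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_torsions(self) -> int:
        return self.torsion_atom_index.shape[0]

    @property
    def coordinates(self) -> np.ndarray:
        return self.node_features[:, -3:]

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_features": self.node_features.tolist(),
                "edge_index": self.edge_index.tolist(),
                "edge_features": self.edge_features.tolist(),
                "torsion_atom_index": self.torsion_atom_index.tolist(),
            }
        )


def _one_hot(symbol: str, alphabet: Sequence[str]) -> np.ndarray:
    v = np.zeros(len(alphabet))
    idx = alphabet.index(symbol) if symbol in alphabet else alphabet.index("other")
    v[idx] = 1.0
    return v


def extract_node_features(
    mol: MoleculeGraph, conf: Conformer, alphabet: Sequence[str] = DEFAULT_ALPHABET
) -> np.ndarray:
    """Per-atom vectors: one-hot(element) ++ (x, y, z). Shape (N, |alphabet|+3)."""
    onehots = np.stack([_one_hot(a.element, alphabet) for a in mol.atoms])
    return np.hstack([onehots, np.asarray(conf.coordinates, dtype=float)])


def extract_edge_features(
    mol: MoleculeGraph, conf: Conformer, cutoff_radius: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Directed edge index (2, E) and features (E, 6).

    All covalent bonds are always included; with ``cutoff_radius > 0`` every
    non-bonded atom pair closer than the cutoff gains a "nonbonded" edge.  Each
    undirected edge appears in both directions with identical features, ordered
    deterministically by (min, max) pair.
    """
    if cutoff_radius < 0:
        raise ValueError("cutoff_radius must be >= 0")
    xyz = np.asarray(conf.coordinates, dtype=float)
    pairs: list[tuple[int, int, str]] = [
        (b.atom_a, b.atom_b, b.order) for b in mol.bonds
    ]
    if cutoff_radius > 0:
        bonded = {(b.atom_a, b.atom_b) for b in mol.bonds}
        n = mol.n_atoms
        dmat = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) not in bonded and dmat[i, j] <= cutoff_radius:
                    pairs.append((i, j, "nonbonded"))
    pairs.sort(key=lambda p: (p[0], p[1]))
    src, dst, feats = [], [], []
    for i, j, order in pairs:
        dist = float(np.linalg.norm(xyz[i] - xyz[j]))
        one_hot = np.zeros(len(EDGE_TYPES))
        one_hot[EDGE_TYPES.index(order)] = 1.0
        feat = np.concatenate([one_hot, [dist]])
        src += [i, j]
        dst += [j, i]
        feats += [feat, feat]
    if not feats:
        return np.zeros((2, 0), dtype=np.int64), np.zeros((0, len(EDGE_TYPES) + 1))
    return np.array([src, dst], dtype=np.int64), np.stack(feats)


def _principal_frame(centered: np.ndarray) -> np.ndarray:
    """Rotation matrix into the principal-axes frame, deterministically signed.

    Axes are eigenvectors of the coordinate covariance ordered by descending
    eigenvalue; each axis sign is fixed so the lowest-index atom with a nonzero
    projection on it projects positively.  Degenerate directions (e.g. a linear
    molecule's zero-variance axes) fall out of ``eigh`` deterministically.
    """
    cov = centered.T @ centered / max(len(centered), 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order]
    proj = centered @ axes
    for k in range(3):
        col = proj[:, k]
        nz = np.nonzero(np.abs(col) > 1e-8)[0]
        if len(nz) and col[nz[0]] < 0:
            axes[:, k] = -axes[:, k]
    return axes


def normalize_graph(
    obs: GraphObservation, modes: Iterable[str] = ("translation",)
) -> GraphObservation:
    """Return a copy with coordinates normalized by the requested modes.

    translation — centroid moved to the origin;
    rotation    — coordinates expressed in the principal-axes frame;
    scale       — divided by the RMS atomic distance from the centroid
                  (edge distance features are recomputed).
    """
    modes = set(modes)
    bad = modes - {"translation", "rotation", "scale"}
    if bad:
        raise ValueError(f"unknown normalization modes: {sorted(bad)}")
    xyz = obs.coordinates.copy()
    centroid = xyz.mean(axis=0)
    centered = xyz - centroid
    if "rotation" in modes:
        new = centered @ _principal_frame(centered)
        if "translation" not in modes:
            new = new + centroid
    elif "translation" in modes:
        new = centered
    else:
        new = xyz
    edge_features = obs.edge_features.copy()
    if "scale" in modes:
        rms = float(np.sqrt((np.linalg.norm(new - new.mean(axis=0), axis=1) ** 2).mean()))
        if rms > 0:
            new = new / rms
            edge_features[:, -1] = edge_features[:, -1] / rms
    node_features = obs.node_features.copy()
    node_features[:, -3:] = new
    return GraphObservation(
        node_features=node_features,
        edge_index=obs.edge_index.copy(),
        edge_features=edge_features,
        torsion_atom_index=obs.torsion_atom_index.copy(),
    )


def build_observation(
    mol: MoleculeGraph, conf: Conformer, config: ObservationConfig = ObservationConfig()
) -> GraphObservation:
    """Full featurization pipeline: nodes, edges, torsion index, normalization."""
    node_features = extract_node_features(mol, conf, config.alphabet)
    edge_index, edge_features = extract_edge_features(mol, conf, config.cutoff_radius)
    torsion_atom_index = (
        np.array([t.as_tuple() for t in mol.torsions], dtype=np.int64)
        if mol.torsions
        else np.zeros((0, 4), dtype=np.int64)
    )
    obs = GraphObservation(node_features, edge_index, edge_features, torsion_atom_index)
    if config.normalize_modes:
        obs = normalize_graph(obs, config.normalize_modes)
    return obs
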