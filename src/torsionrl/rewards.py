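"""Reward handlers for the conformer-generation environment.

Three handlers are provided, all derived from the MMFF94 energy E(m) of the
newly generated (post-relaxation) conformer m:

* ``basic_energy``   — f(m) = -E(m);
* ``pruning_energy`` — f(m) = 0 if the episode already saw this exact action
  vector, else -E(m);
* ``boltzmann``      — f(m) = 0 if min{TFD(m, x) : x in S} < threshold, else
  exp(-(E(m) - E0) / kT), where S is the set of conformers accepted so far in
  the episode, E0 a normalising energy and kT the thermal energy.

TFD is the torsional fingerprint deviation: per-torsion wrapped absolute
angular deviations normalised by 180°, combined as a weighted mean.  Torsion
weights decay as a Gaussian of the topological distance of each torsion's
central bond from the molecule's most central bond, anchored so that the
weight at half the maximal bond distance is 0.1.  The metric is symmetric,
zero iff the torsion profiles coincide mod 360°, and bounded by 1.

Episode memory (the pruning action set / the Boltzmann seen-set S) lives in
the handler and is cleared by ``reset``; a conformer that is pruned is *not*
added to S — an existing member already covers its neighbourhood.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from rdkit import Chem

from .chem import Conformer, MoleculeGraph, measure_torsions

__all__ = [
    "RewardConfig",
    "SeenSet",
    "RewardHandler",
    "basic_energy_reward",
    "pruning_energy_reward",
    "boltzmann_reward",
    "tfd",
    "torsion_weights",
    "make_reward_handler",
    "KT_ROOM_TEMPERATURE",
]

#: k_B * 298.15 K in kcal/mol.
KT_ROOM_TEMPERATURE = 0.5924

REWARD_KINDS = ("basic_energy", "pruning_energy", "boltzmann")


@dataclasses.dataclass
class RewardConfig:
    kind: str = "boltzmann"
    e0: Optional[float] = None  # None -> energy of the episode's first relaxed conformer
    thermal_energy: float = KT_ROOM_TEMPERATURE
    tfd_threshold: float = 0.05

    def __post_init__(self):
        if self.kind not in REWARD_KINDS:
            raise ValueError(f"unknown reward kind {self.kind!r}; expected {REWARD_KINDS}")
        if self.thermal_energy <= 0:
            raise ValueError("thermal_energy must be > 0")
        if self.tfd_threshold <= 0:
            raise ValueError("tfd_threshold must be > 0")


@dataclasses.dataclass
class SeenSet:
    """Episode memory: conformers accepted so far (the set S) and the action
    vectors taken so far.  Cleared at every environment reset."""

    conformers: list[Conformer] = dataclasses.field(default_factory=list)
    actions: set[tuple[int, ...]] = dataclasses.field(default_factory=set)

    def clear(self) -> None:
        self.conformers.clear()
        self.actions.clear()


# ---------------------------------------------------------------------------
# torsional fingerprint deviation
# ---------------------------------------------------------------------------

def torsion_weights(mol: MoleculeGraph) -> np.ndarray:
    """Gaussian topological-distance weights for the rotatable torsions.

    The most central bond is found from the heavy-atom distance spread: the
    non-terminal atom whose shortest-path distances to all other atoms have
    the least standard deviation, bonded to the next most central such atom.
    For a torsion about bond (b, c), d = 0 for the central bond itself and
    otherwise the minimal path distance between {b, c} and the central pair
    plus one; the weight is exp(-beta * d^2) with beta set by w(dmax/2) = 0.1,
    dmax the largest distance from the central atom to a non-terminal bond.
    """
    if mol.n_torsions == 0:
        return np.zeros(0)
    rdmol = mol.rdkit_mol
    distmat = Chem.GetDistanceMatrix(rdmol)
    # most central non-terminal atom by least std of shortest-path distances
    stds = []
    for i in range(mol.n_atoms):
        if len(mol.heavy_neighbors(i)) < 2:
            continue
        row = np.delete(distmat[i], i)
        stds.append((float(np.std(row)), i))
    stds.sort()
    if not stds:  # no non-terminal atom: fall back to uniform weights
        return np.ones(mol.n_torsions)
    aid1 = stds[0][1]
    aid2 = next(
        (i for _, i in stds[1:] if rdmol.GetBondBetweenAtoms(aid1, i) is not None),
        None,
    )
    if aid2 is None:
        return np.ones(mol.n_torsions)
    # beta anchored at half the maximal central-atom-to-bond distance
    dmax = 0.0
    for bond in mol.bonds:
        if len(mol.heavy_neighbors(bond.atom_a)) < 2 or len(
            mol.heavy_neighbors(bond.atom_b)
        ) < 2:
            continue
        dmax = max(dmax, distmat[aid1][bond.atom_a], distmat[aid1][bond.atom_b])
    if dmax == 0:
        return np.ones(mol.n_torsions)
    beta = -math.log(0.1) / (dmax / 2.0) ** 2
    weights = []
    for t in mol.torsions:
        if {t.b, t.c} == {aid1, aid2}:
            d = 0.0
        else:
            d = min(
                distmat[aid1][t.b], distmat[aid1][t.c],
                distmat[aid2][t.b], distmat[aid2][t.c],
            ) + 1.0
        weights.append(math.exp(-beta * d * d))
    return np.array(weights)


def _wrapped_deviation_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise |a - b| on the circle, in [0, 180]."""
    diff = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(diff, 360.0 - diff)


def tfd(
    x: Conformer,
    y: Conformer,
    mol: MoleculeGraph,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Torsional fingerprint deviation between two conformers of ``mol``.

    Symmetric, in [0, 1]; 0 iff the torsion profiles agree mod 360°.
    ``weights`` may be precomputed (e.g. cached per molecule) to skip the
    topological analysis; pass an all-ones array for the unweighted variant.
    """
    if mol.n_torsions == 0:
        raise ValueError("TFD is undefined for a molecule with no rotatable torsions")
    tx = x.torsion_profile if x.torsion_profile is not None else measure_torsions(x, mol)
    ty = y.torsion_profile if y.torsion_profile is not None else measure_torsions(y, mol)
    dev = _wrapped_deviation_deg(tx, ty) / 180.0
    if weights is None:
        weights = torsion_weights(mol)
    wsum = float(np.sum(weights))
    if wsum == 0:
        return float(np.mean(dev))
    return float(np.dot(dev, weights) / wsum)


# ---------------------------------------------------------------------------
# the three reward functions
# ---------------------------------------------------------------------------

def basic_energy_reward(energy: float) -> float:
    """f(m) = -E(m)."""
    if not math.isfinite(energy):
        raise ValueError(f"non-finite conformer energy: {energy}")
    return -energy


def pruning_energy_reward(
    action: tuple[int, ...], seen: SeenSet, energy: float
) -> float:
    """0 for an action vector already taken this episode, else -E(m).
    Records the action in the seen-set."""
    key = tuple(int(v) for v in action)
    if key in seen.actions:
        return 0.0
    seen.actions.add(key)
    return basic_energy_reward(energy)


def boltzmann_reward(
    m: Conformer,
    seen: SeenSet,
    mol: MoleculeGraph,
    cfg: RewardConfig,
    e0: float,
    weights: Optional[np.ndarray] = None,
) -> tuple[float, bool]:
    """Boltzmann-factor reward with TFD pruning.

    Returns ``(reward, pruned)``.  A conformer within ``cfg.tfd_threshold``
    of any member of S is pruned (reward 0, not added to S); otherwise the
    reward is exp(-(E(m) - e0) / kT) and m joins S.  Molecules without
    rotatable torsions skip pruning (the metric is undefined there).
    """
    if m.energy is None:
        raise ValueError("boltzmann_reward requires a relaxed conformer with energy")
    if mol.n_torsions > 0 and seen.conformers:
        min_tfd = min(tfd(m, x, mol, weights=weights) for x in seen.conformers)
        if min_tfd < cfg.tfd_threshold:
            return 0.0, True
    seen.conformers.append(m)
    return math.exp(-(m.energy - e0) / cfg.thermal_energy), False


# ---------------------------------------------------------------------------
# stateful handler used by the environment
# ---------------------------------------------------------------------------

class RewardHandler:
    """Binds a reward kind to one molecule and keeps the per-episode memory."""

    def __init__(self, mol: MoleculeGraph, cfg: RewardConfig):
        self.mol = mol
        self.cfg = cfg
        self.seen = SeenSet()
        self._weights = torsion_weights(mol) if mol.n_torsions else np.zeros(0)
        self._episode_e0: Optional[float] = None

    @property
    def e0(self) -> Optional[float]:
        return self.cfg.e0 if self.cfg.e0 is not None else self._episode_e0

    def reset(self, initial: Conformer) -> None:
        """Clear episode memory; capture E0 from the initial relaxed conformer."""
        self.seen.clear()
        self._episode_e0 = initial.energy

    def __call__(self, conf: Conformer, action: tuple[int, ...]) -> tuple[float, bool]:
        """Reward of the post-relaxation conformer; returns (reward, pruned)."""
        if self.cfg.kind == "basic_energy":
            return basic_energy_reward(conf.energy), False
        if self.cfg.kind == "pruning_energy":
            r = pruning_energy_reward(action, self.seen, conf.energy)
            return r, r == 0.0
        e0 = self.e0
        if e0 is None:
            raise RuntimeError("reward handler used before reset")
        return boltzmann_reward(
            conf, self.seen, self.mol, self.cfg, e0, weights=self._weights
        )


def make_reward_handler(mol: MoleculeGraph, cfg: RewardConfig) -> RewardHandler:
    return RewardHandler(mol, cfg)
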