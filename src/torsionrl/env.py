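"""The episodic conformer-generation environment.

One episode generates exactly C conformers of a molecule.  The state is the
current conformer; an action assigns every rotatable torsion a discrete angle
bucket (multiples of ``granularity_deg``, default 60°) or, in continuous mode,
any angle in [0, 360).  Each step sets the torsions, relaxes the structure
under MMFF94, scores the relaxed conformer with the configured reward handler
and returns a featurized graph observation of the new state.  The initial
state is a relaxed random conformer drawn from the environment's seeded RNG.

The API follows the familiar reset/step convention::

    env = ConformerEnv(EnvConfig(mol_specs=[spec], max_steps=10, seed=1))
    obs = env.reset()
    while True:
        result = env.step(policy(obs))
        obs = result.observation
        if result.done:
            break
    record = env.episode_record
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from .chem import Conformer, MolSpec, relax, set_torsions
from .observations import GraphObservation, ObservationConfig, build_observation
from .rewards import RewardConfig, RewardHandler

__all__ = [
    "EnvConfig",
    "ActionVector",
    "StepResult",
    "EpisodeRecord",
    "ConformerEnv",
    "decode_action",
    "run_parallel",
]

ActionVector = Sequence[int]  # one bucket index per rotatable torsion


@dataclasses.dataclass
class EnvConfig:
    mol_specs: list[MolSpec]
    max_steps: int = 10
    granularity_deg: float = 60.0
    action_mode: str = "discrete"
    reward: RewardConfig = dataclasses.field(default_factory=RewardConfig)
    observation: ObservationConfig = dataclasses.field(default_factory=ObservationConfig)
    seed: int = 0
    relax_max_iters: int = 1000
    relax_tol: float = 1e-4

    def __post_init__(self):
        if not self.mol_specs:
            raise ValueError("EnvConfig requires at least one MolSpec")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.action_mode not in ("discrete", "continuous"):
            raise ValueError(f"unknown action_mode {self.action_mode!r}")
        if self.action_mode == "discrete" and 360.0 % self.granularity_deg != 0:
            raise ValueError("granularity_deg must divide 360")

    @property
    def n_buckets(self) -> int:
        """B = 360 / granularity; bucket B-1 is 360 - granularity (360° ≡ 0°)."""
        return int(round(360.0 / self.granularity_deg))


@dataclasses.dataclass
class StepResult:
    observation: GraphObservation
    reward: float
    done: bool
    info: dict


@dataclasses.dataclass
class EpisodeRecord:
    """Everything one episode produced: C conformers with parallel traces."""

    conformers: list[Conformer] = dataclasses.field(default_factory=list)
    actions: list[tuple] = dataclasses.field(default_factory=list)
    rewards: list[float] = dataclasses.field(default_factory=list)
    energies: list[float] = dataclasses.field(default_factory=list)
    pruned: list[bool] = dataclasses.field(default_factory=list)
    molecule_index: int = 0

    @property
    def total_reward(self) -> float:
        return float(sum(self.rewards))

    def __len__(self) -> int:
        return len(self.conformers)


def decode_action(
    action, granularity_deg: float = 60.0, action_mode: str = "discrete"
) -> np.ndarray:
    """Turn an action vector into torsion angles in degrees.

    Discrete mode: ``angle_j = bucket_j * granularity_deg`` with buckets in
    [0, B-1].  Continuous mode: angles pass through (must lie in [0, 360)).
    """
    arr = np.asarray(action, dtype=float)
    if action_mode == "continuous":
        if arr.size and (arr.min() < 0 or arr.max() >= 360.0):
            raise ValueError("continuous angles must lie in [0, 360)")
        return arr
    n_buckets = int(round(360.0 / granularity_deg))
    buckets = np.asarray(action)
    if buckets.size and (
        np.any(buckets != np.floor(buckets))
        or buckets.min() < 0
        or buckets.max() >= n_buckets
    ):
        raise ValueError(
            f"discrete action buckets must be integers in [0, {n_buckets - 1}]"
        )
    return buckets.astype(float) * granularity_deg


class ConformerEnv:
    """Episodic environment producing exactly ``max_steps`` conformers."""

    def __init__(self, config: EnvConfig):
        self.config = config
        self._mol_index = 0
        self._rng = np.random.default_rng(config.seed)
        self._handlers = [
            RewardHandler(spec.molecule, self._reward_cfg_for(spec))
            for spec in config.mol_specs
        ]
        self._current: Optional[Conformer] = None
        self._steps = 0
        self._done = True
        self._record: Optional[EpisodeRecord] = None

    def _reward_cfg_for(self, spec: MolSpec) -> RewardConfig:
        cfg = self.config.reward
        if spec.e0 is None:
            return cfg
        return dataclasses.replace(cfg, e0=spec.e0)

    # -- molecule selection (supports curriculum) --------------------------
    @property
    def molecule_index(self) -> int:
        return self._mol_index

    def set_molecule_index(self, index: int) -> None:
        if not 0 <= index < len(self.config.mol_specs):
            raise IndexError(f"molecule index {index} out of range")
        self._mol_index = index

    @property
    def active_spec(self) -> MolSpec:
        return self.config.mol_specs[self._mol_index]

    @property
    def n_torsions(self) -> int:
        return self.active_spec.molecule.n_torsions

    @property
    def episode_record(self) -> Optional[EpisodeRecord]:
        return self._record

    # -- RL API ------------------------------------------------------------
    def reset(self, seed: Optional[int] = None) -> GraphObservation:
        """Start a new episode from a relaxed random conformer.

        Each torsion is drawn uniformly from the B buckets (or from [0, 360)
        in continuous mode) and the structure relaxed; the reward handler's
        episode memory is cleared and E0 captured from the initial energy.
        """
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        spec = self.active_spec
        mol = spec.molecule
        if self.config.action_mode == "continuous":
            angles = self._rng.uniform(0.0, 360.0, mol.n_torsions)
        else:
            buckets = self._rng.integers(0, self.config.n_buckets, mol.n_torsions)
            angles = buckets.astype(float) * self.config.granularity_deg
        start = set_torsions(spec.reference, mol, angles)
        self._current = relax(
            start, mol, self.config.relax_max_iters, self.config.relax_tol
        )
        self._handlers[self._mol_index].reset(self._current)
        self._steps = 0
        self._done = False
        self._record = EpisodeRecord(molecule_index=self._mol_index)
        return build_observation(mol, self._current, self.config.observation)

    def step(self, action) -> StepResult:
        """Apply one action: set torsions, relax, reward, record."""
        if self._done or self._current is None:
            raise RuntimeError("step() called on a done environment; call reset()")
        mol = self.active_spec.molecule
        angles = decode_action(
            action, self.config.granularity_deg, self.config.action_mode
        )
        if angles.shape != (mol.n_torsions,):
            raise ValueError(
                f"action has {angles.size} entries; molecule has {mol.n_torsions} torsions"
            )
        new = relax(
            set_torsions(self._current, mol, angles),
            mol,
            self.config.relax_max_iters,
            self.config.relax_tol,
        )
        action_key = tuple(int(v) if self.config.action_mode == "discrete" else float(v)
                           for v in np.asarray(action).tolist())
        reward, pruned = self._handlers[self._mol_index](new, action_key)
        self._current = new
        self._steps += 1
        self._done = self._steps >= self.config.max_steps
        self._record.conformers.append(new.copy())
        self._record.actions.append(action_key)
        self._record.rewards.append(float(reward))
        self._record.energies.append(float(new.energy))
        self._record.pruned.append(bool(pruned))
        obs = build_observation(mol, new, self.config.observation)
        info = {
            "step": self._steps,
            "energy": float(new.energy),
            "pruned": bool(pruned),
            "molecule_index": self._mol_index,
        }
        return StepResult(observation=obs, reward=float(reward), done=self._done, info=info)


def run_parallel(
    envs: Sequence[ConformerEnv],
    policy: Callable[[GraphObservation], ActionVector],
    episodes_per_env: int = 1,
) -> list[list[EpisodeRecord]]:
    """Run ``episodes_per_env`` full episodes in every environment.

    Environments are independent (each owns its RNG and reward memory), so the
    per-env traces equal those of sequential execution with the same seeds
    regardless of launch order.  Returns one list of EpisodeRecords per env.
    """
    if not envs:
        raise ValueError("run_parallel requires at least one environment")
    results: list[list[EpisodeRecord]] = []
    for env in envs:
        records = []
        for _ in range(episodes_per_env):
            obs = env.reset()
            done = False
            while not done:
                res = env.step(policy(obs))
                obs, done = res.observation, res.done
            records.append(env.episode_record)
        results.append(records)
    return results
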