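"""Curriculum learning over an ordered molecule list.

Training starts on the first molecule; once the rolling mean of total episode
reward over the last ``window`` episodes reaches the threshold, the curriculum
advances to the next molecule (and the rolling window is cleared).  At the
final molecule the index never moves again.  The threshold may be a single
value or one value per molecule.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from typing import Sequence, Union

from .chem import MolSpec

__all__ = ["CurriculumState", "Curriculum", "record_episode", "active_molecule"]


@dataclasses.dataclass
class CurriculumState:
    molecule_index: int = 0
    window: int = 10
    threshold: Union[float, Sequence[float]] = 0.0
    recent_rewards: deque = dataclasses.field(default_factory=deque)

    def threshold_for(self, index: int) -> float:
        if isinstance(self.threshold, (int, float)):
            return float(self.threshold)
        return float(self.threshold[index])


def record_episode(state: CurriculumState, total_reward: float, n_molecules: int) -> CurriculumState:
    """Append one episode total; advance when the full rolling window's mean
    first reaches the threshold (never past the last molecule)."""
    state.recent_rewards.append(float(total_reward))
    while len(state.recent_rewards) > state.window:
        state.recent_rewards.popleft()
    window_full = len(state.recent_rewards) >= state.window
    at_last = state.molecule_index >= n_molecules - 1
    if window_full and not at_last:
        mean = sum(state.recent_rewards) / len(state.recent_rewards)
        if mean >= state.threshold_for(state.molecule_index):
            state.molecule_index += 1
            state.recent_rewards.clear()
    return state


def active_molecule(state: CurriculumState, mol_specs: Sequence[MolSpec]) -> MolSpec:
    return mol_specs[state.molecule_index]


class Curriculum:
    """Convenience wrapper binding a CurriculumState to a molecule list."""

    def __init__(
        self,
        mol_specs: Sequence[MolSpec],
        threshold: Union[float, Sequence[float]] = 0.0,
        window: int = 10,
    ):
        if not mol_specs:
            raise ValueError("curriculum requires at least one molecule")
        if not isinstance(threshold, (int, float)) and len(threshold) != len(mol_specs):
            raise ValueError("per-molecule thresholds must match the molecule list")
        self.mol_specs = list(mol_specs)
        self.state = CurriculumState(window=window, threshold=threshold)

    @property
    def molecule_index(self) -> int:
        return self.state.molecule_index

    def record_episode(self, total_reward: float) -> None:
        record_episode(self.state, total_reward, len(self.mol_specs))

    def active_molecule(self) -> MolSpec:
        return active_molecule(self.state, self.mol_specs)
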