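"""Flat-file training/episode logging, conformer export and ensemble summaries.

Training metrics go to an append-only CSV (or JSONL) that a viewer can tail;
each evaluated episode can be dumped as C MOL files plus a JSON manifest from
which every summary number is recomputable.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import MoleculeGraph, load_molecule, mmff_energy, write_mol
from .env import EpisodeRecord
from .rewards import tfd, torsion_weights

__all__ = ["TrainLogger", "EpisodeDump", "dump_episode", "load_episode_dump",
           "summarize_ensemble", "distance_histogram"]

METRIC_FIELDS = [
    "iteration", "env_steps", "mean_episode_reward",
    "policy_loss", "value_loss", "entropy", "eval_reward", "wall_time",
]


class TrainLogger:
    """Append-only metric log; one row per training iteration.

    Rows are flushed line-by-line so a truncated final line after a crash
    never corrupts earlier rows.  Iterations must be strictly increasing.
    """

    def __init__(self, path: str | Path, fmt: str = "csv"):
        if fmt not in ("csv", "jsonl"):
            raise ValueError(f"unknown log format {fmt!r}")
        self.path = Path(path)
        self.fmt = fmt
        self._last_iteration = 0
        self._fh = open(self.path, "a", newline="")
        self._writer = None
        if fmt == "csv":
            self._writer = csv.DictWriter(self._fh, fieldnames=METRIC_FIELDS)
            if self.path.stat().st_size == 0:
                self._writer.writeheader()
                self._fh.flush()

    def log(self, row: dict) -> None:
        it = int(row["iteration"])
        if it <= self._last_iteration:
            raise ValueError(
                f"iteration {it} out of order (last was {self._last_iteration})"
            )
        self._last_iteration = it
        clean = {k: row.get(k) for k in METRIC_FIELDS}
        for key, value in clean.items():
            if isinstance(value, float) and not np.isfinite(value) and key != "eval_reward":
                if key == "mean_episode_reward":
                    continue  # rollouts shorter than one episode yield no total
                raise ValueError(f"non-finite metric {key}={value}")
        if self.fmt == "csv":
            self._writer.writerow(clean)
        else:
            self._fh.write(json.dumps(clean) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


@dataclasses.dataclass
class EpisodeDump:
    """On-disk record of one episode: C MOL files plus a manifest."""

    directory: Path
    mol_files: list[Path]
    actions: list
    energies: list[float]
    rewards: list[float]
    pruned: list[bool]
    total_reward: float
    min_energy: float
    distinct_conformers: int


def _distinct_count(record: EpisodeRecord, mol: MoleculeGraph, threshold: float) -> int:
    """Greedy distinct-conformer count under the TFD threshold (exact
    duplicates when threshold == 0)."""
    if mol.n_torsions == 0:
        return 1 if record.conformers else 0
    weights = torsion_weights(mol)
    kept = []
    for conf in record.conformers:
        dists = [tfd(conf, other, mol, weights=weights) for other in kept]
        # duplicate: within the pruning threshold of a kept conformer, or an
        # exact torsion-profile match when the threshold is zero
        if not any(d < threshold or d == 0.0 for d in dists):
            kept.append(conf)
    return len(kept)


def dump_episode(
    record: EpisodeRecord,
    mol: MoleculeGraph,
    outdir: str | Path,
    tfd_threshold: float = 0.05,
) -> EpisodeDump:
    """Write one MOL file per generated conformer plus ``episode.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mol_files = []
    for i, conf in enumerate(record.conformers):
        path = outdir / f"conformer_{i:03d}.mol"
        write_mol(conf, mol, path)
        mol_files.append(path)
    summary = {
        "n_conformers": len(record),
        "actions": [list(a) for a in record.actions],
        "energies": record.energies,
        "rewards": record.rewards,
        "pruned": record.pruned,
        "total_reward": record.total_reward,
        "min_energy": float(min(record.energies)),
        "distinct_conformers": _distinct_count(record, mol, tfd_threshold),
        "tfd_threshold": tfd_threshold,
        "mol_files": [p.name for p in mol_files],
    }
    (outdir / "episode.json").write_text(json.dumps(summary, indent=2))
    return EpisodeDump(
        directory=outdir,
        mol_files=mol_files,
        actions=record.actions,
        energies=record.energies,
        rewards=record.rewards,
        pruned=record.pruned,
        total_reward=record.total_reward,
        min_energy=summary["min_energy"],
        distinct_conformers=summary["distinct_conformers"],
    )


def load_episode_dump(directory: str | Path) -> EpisodeDump:
    directory = Path(directory)
    summary = json.loads((directory / "episode.json").read_text())
    return EpisodeDump(
        directory=directory,
        mol_files=[directory / name for name in summary["mol_files"]],
        actions=summary["actions"],
        energies=summary["energies"],
        rewards=summary["rewards"],
        pruned=summary["pruned"],
        total_reward=summary["total_reward"],
        min_energy=summary["min_energy"],
        distinct_conformers=summary["distinct_conformers"],
    )


def summarize_ensemble(dumps: Sequence[EpisodeDump]) -> pd.DataFrame:
    """Per-episode summary table with an aggregate row.

    Columns: episode, n_conformers, min_energy, mean_energy, total_reward,
    distinct_conformers.  The final row (episode = "aggregate") takes the
    min/mean/sum over episodes as appropriate.
    """
    if not dumps:
        raise ValueError("summarize_ensemble requires at least one episode dump")
    rows = []
    for i, d in enumerate(dumps):
        rows.append({
            "episode": str(i),
            "n_conformers": len(d.energies),
            "min_energy": float(np.min(d.energies)),
            "mean_energy": float(np.mean(d.energies)),
            "total_reward": float(d.total_reward),
            "distinct_conformers": int(d.distinct_conformers),
        })
    agg = {
        "episode": "aggregate",
        "n_conformers": int(sum(r["n_conformers"] for r in rows)),
        "min_energy": float(min(r["min_energy"] for r in rows)),
        "mean_energy": float(np.mean([r["mean_energy"] for r in rows])),
        "total_reward": float(np.mean([r["total_reward"] for r in rows])),
        "distinct_conformers": int(sum(r["distinct_conformers"] for r in rows)),
    }
    return pd.DataFrame(rows + [agg])


def distance_histogram(
    dumps: Sequence[EpisodeDump],
    atom_a: int,
    atom_b: int,
    out_path: Optional[str | Path] = None,
    bins: int = 30,
):
    """Histogram of the atom_a-atom_b Euclidean distance over all dumped
    conformers (re-read from the MOL files, so the plot is self-describing)."""
    distances = []
    for d in dumps:
        for path in d.mol_files:
            spec = load_molecule(path)
            xyz = spec.reference.coordinates
            distances.append(float(np.linalg.norm(xyz[atom_a] - xyz[atom_b])))
    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots()
        ax.hist(distances, bins=bins)
        ax.set_xlabel(f"distance atoms {atom_a}-{atom_b} (Å)")
        ax.set_ylabel("conformers")
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return np.asarray(distances)
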