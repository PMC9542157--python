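"""Graph policy-value network over featurized conformer observations.

The network is size-agnostic: three rounds of edge-conditioned message
passing produce per-atom embeddings; a sum-pooled readout feeds the scalar
value head, and a shared MLP over the concatenated embeddings of each
rotatable torsion's four atoms produces one categorical head (B logits) per
torsion.  The same parameters therefore apply to any molecule, whatever its
atom count or number of torsions.

Implemented on the package's numpy autodiff engine; observations are batched
by stacking graphs block-diagonally.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concatenate, segment_sum
from .observations import GraphObservation

__all__ = ["BatchedGraphs", "PolicyValueNet", "PolicyValueOutput"]


@dataclasses.dataclass
class PolicyValueOutput:
    """Per-torsion action logits (n_torsions, B) and state values (n_graphs,)."""

    logits: Tensor
    value: Tensor
    torsion_graph_ids: np.ndarray  # graph id of every torsion row


@dataclasses.dataclass
class BatchedGraphs:
    """Several observations stacked into one disjoint graph."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    torsion_atom_index: np.ndarray
    node_graph_ids: np.ndarray
    torsion_graph_ids: np.ndarray
    n_graphs: int

    @staticmethod
    def from_observations(observations: Sequence[GraphObservation]) -> "BatchedGraphs":
        node_parts, edge_idx_parts, edge_feat_parts = [], [], []
        torsion_parts, node_ids, torsion_ids = [], [], []
        offset = 0
        for g, obs in enumerate(observations):
            node_parts.append(obs.node_features)
            edge_idx_parts.append(obs.edge_index + offset)
            edge_feat_parts.append(obs.edge_features)
            torsion_parts.append(obs.torsion_atom_index + offset)
            node_ids.append(np.full(obs.n_atoms, g, dtype=np.int64))
            torsion_ids.append(np.full(obs.n_torsions, g, dtype=np.int64))
            offset += obs.n_atoms
        return BatchedGraphs(
            node_features=np.vstack(node_parts),
            edge_index=np.hstack(edge_idx_parts),
            edge_features=np.vstack(edge_feat_parts),
            torsion_atom_index=np.vstack(torsion_parts),
            node_graph_ids=np.concatenate(node_ids),
            torsion_graph_ids=np.concatenate(torsion_ids),
            n_graphs=len(observations),
        )


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    # He-style scaling keeps activations O(1) through the relu stack
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


class PolicyValueNet:
    """3-round message-passing network with per-torsion categorical heads."""

    N_ROUNDS = 3

    def __init__(
        self,
        node_dim: int,
        edge_dim: int,
        n_buckets: int,
        hidden: int = 64,
        seed: int = 0,
    ):
        self.node_dim = node_dim
        self.edge_dim = edge_dim
        self.n_buckets = n_buckets
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        H = hidden
        p: dict[str, Tensor] = {}

        def lin(name, fi, fo, scale=1.0):
            p[f"{name}.W"] = Tensor(scale * _linear_init(rng, fi, fo), requires_grad=True)
            p[f"{name}.b"] = Tensor(np.zeros(fo), requires_grad=True)

        lin("enc", node_dim, H)
        for r in range(self.N_ROUNDS):
            lin(f"msg{r}.0", H + edge_dim, H)
            lin(f"msg{r}.1", H, H)
            lin(f"upd{r}", 2 * H, H)
        lin("val.0", H, H)
        lin("val.1", H, 1, scale=0.1)
        lin("head.0", 4 * H, H)
        # small final policy layer: near-uniform initial action distribution
        lin("head.1", H, n_buckets, scale=0.01)
        self.params = p

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data[...] = v

    def _lin(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    # -- forward -----------------------------------------------------------
    def forward(self, batch: BatchedGraphs) -> PolicyValueOutput:
        h = self._lin("enc", Tensor(batch.node_features)).relu()
        src, dst = batch.edge_index
        n_nodes = batch.node_features.shape[0]
        edge_feat = Tensor(batch.edge_features)
        for r in range(self.N_ROUNDS):
            msg_in = concatenate([h.gather_rows(src), edge_feat], axis=1)
            msg = self._lin(f"msg{r}.1", self._lin(f"msg{r}.0", msg_in).relu()).relu()
            agg = segment_sum(msg, dst, n_nodes)
            h = self._lin(f"upd{r}", concatenate([h, agg], axis=1)).relu()
        pooled = segment_sum(h, batch.node_graph_ids, batch.n_graphs)
        value = self._lin("val.1", self._lin("val.0", pooled).relu()).reshape(-1)
        quad = concatenate(
            [h.gather_rows(batch.torsion_atom_index[:, k]) for k in range(4)], axis=1
        )
        logits = self._lin("head.1", self._lin("head.0", quad).relu())
        return PolicyValueOutput(logits, value, batch.torsion_graph_ids)

    def forward_single(self, obs: GraphObservation) -> PolicyValueOutput:
        return self.forward(BatchedGraphs.from_observations([obs]))
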