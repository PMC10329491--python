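"""Drug structure channel: attention-gated message passing over molecular
graphs with GRU state updates and an attentive super-node readout
(the Attentive FP architecture).

Each message-passing layer lets an atom attend over its neighbors: an
additive-attention score (leaky-ReLU, softmax-normalized within the
neighborhood) weights learned messages built from the neighbor state and the
bond features, and the attention context updates the atom state through a
GRU cell.  The readout introduces a virtual super node per molecule that
attends over all atom states for a fixed number of GRU timesteps; its final
state is the drug embedding.  All aggregations are order-independent, so the
embedding is invariant to atom relabeling.

Molecules are encoded as one batched disconnected graph, which keeps the
NumPy implementation vectorized across a whole dataset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from .chem_graph import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph
from .nn import (Dropout, GRUCell, Linear, Module, Tensor, concat,
                 segment_sum)

__all__ = ["AttentiveFPConfig", "AttentiveFPEncoder", "BatchedGraph",
           "batch_graphs", "segment_softmax", "config_hash"]


@dataclass
class AttentiveFPConfig:
    n_atom_layers: int = 2
    n_readout_timesteps: int = 2
    hidden_dim: int = 64
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_atom_layers, self.n_readout_timesteps, self.hidden_dim) < 1:
            raise ValueError("layer counts and hidden_dim must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def config_hash(config) -> str:
    """Stable short hash of a dataclass config, for checkpoint keying."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class BatchedGraph:
    """Several molecular graphs packed as one disconnected graph."""

    atom_features: np.ndarray   # (N, 39)
    edge_src: np.ndarray        # (E,) global atom indices
    edge_dst: np.ndarray        # (E,)
    edge_features: np.ndarray   # (E, 11)
    mol_ids: np.ndarray         # (N,) molecule index per atom
    n_mols: int


def batch_graphs(graphs: list[MolecularGraph]) -> BatchedGraph:
    feats, srcs, dsts, efeats, mids = [], [], [], [], []
    offset = 0
    for i, g in enumerate(graphs):
        if g.n_atoms < 1:
            raise ValueError("cannot encode an empty molecular graph")
        feats.append(g.atom_features)
        if len(g.edges):
            srcs.append(g.edges[:, 0] + offset)
            dsts.append(g.edges[:, 1] + offset)
            efeats.append(g.edge_features)
        mids.append(np.full(g.n_atoms, i, dtype=np.intp))
        offset += g.n_atoms
    return BatchedGraph(
        np.concatenate(feats),
        np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.intp),
        np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.intp),
        np.concatenate(efeats) if efeats else np.zeros((0, BOND_FEATURE_DIM)),
        np.concatenate(mids), len(graphs))


def segment_softmax(scores: Tensor, segment_ids: np.ndarray,
                    num_segments: int) -> Tensor:
    """Softmax of (n, 1) scores normalized within each segment."""
    m = np.full(num_segments, -np.inf)
    np.maximum.at(m, segment_ids, scores.data[:, 0])
    m[~np.isfinite(m)] = 0.0
    e = (scores - Tensor(m[segment_ids][:, None])).exp()
    denom = segment_sum(e, segment_ids, num_segments)
    return e / denom[segment_ids]


class _AttentionLayer(Module):
    """One neighborhood-attention + GRU update layer."""

    def __init__(self, hidden: int, edge_dim: int, rng: np.random.Generator):
        super().__init__()
        nbr_dim = hidden + edge_dim
        self.align = Linear(hidden + nbr_dim, 1, rng)
        self.value = Linear(nbr_dim, hidden, rng)
        self.gru = GRUCell(hidden, hidden, rng)

    def context(self, h: Tensor, batch: BatchedGraph, drop: Dropout) -> Tensor:
        n_atoms = h.shape[0]
        if len(batch.edge_src) == 0:
            return Tensor(np.zeros(h.shape))
        h_u = h[batch.edge_src]
        nbr = concat([h_u, Tensor(batch.edge_features)], axis=1)
        score = self.align(concat([h[batch.edge_dst], nbr], axis=1)).leaky_relu(0.01)
        attn = segment_softmax(score, batch.edge_dst, n_atoms)
        msg = drop(self.value(nbr).leaky_relu(0.01))
        return segment_sum(attn * msg, batch.edge_dst, n_atoms)


class _ReadoutLayer(Module):
    """Super-node attention over a molecule's atoms + GRU update."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.align = Linear(2 * hidden, 1, rng)
        self.value = Linear(hidden, hidden, rng)
        self.gru = GRUCell(hidden, hidden, rng)

    def step(self, s: Tensor, h: Tensor, batch: BatchedGraph,
             drop: Dropout) -> Tensor:
        score = self.align(concat([s[batch.mol_ids], h], axis=1)).leaky_relu(0.01)
        attn = segment_softmax(score, batch.mol_ids, batch.n_mols)
        msg = drop(self.value(h).leaky_relu(0.01))
        ctx = segment_sum(attn * msg, batch.mol_ids, batch.n_mols)
        return self.gru(ctx, s)


class AttentiveFPEncoder(Module):
    def __init__(self, config: AttentiveFPConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.atom_init = Linear(ATOM_FEATURE_DIM, h, rng)
        for k in range(config.n_atom_layers):
            setattr(self, f"layer{k}", _AttentionLayer(h, BOND_FEATURE_DIM, rng))
        for t in range(config.n_readout_timesteps):
            setattr(self, f"readout{t}", _ReadoutLayer(h, rng))
        self.drop = Dropout(config.dropout, rng)

    # --- stages ------------------------------------------------------------
    def init_states(self, batch: BatchedGraph) -> Tensor:
        return self.atom_init(Tensor(batch.atom_features)).leaky_relu(0.01)

    def message_pass(self, batch: BatchedGraph, h: Tensor, layer: int) -> Tensor:
        """Attention-weighted neighbor context C_v (zero for isolated atoms)."""
        return getattr(self, f"layer{layer}").context(h, batch, self.drop)

    def gru_update(self, context: Tensor, h_prev: Tensor, layer: int) -> Tensor:
        return getattr(self, f"layer{layer}").gru(context, h_prev)

    def readout(self, batch: BatchedGraph, h: Tensor) -> Tensor:
        """Attentive super-node readout -> one embedding row per molecule."""
        counts = np.bincount(batch.mol_ids, minlength=batch.n_mols).astype(float)
        s = segment_sum(h, batch.mol_ids, batch.n_mols) / Tensor(counts[:, None])
        for t in range(self.config.n_readout_timesteps):
            s = getattr(self, f"readout{t}").step(s, h, batch, self.drop)
        return s

    def encode_batch(self, graphs: list[MolecularGraph]) -> Tensor:
        batch = batch_graphs(graphs)
        h = self.init_states(batch)
        for k in range(self.config.n_atom_layers):
            h = self.gru_update(self.message_pass(batch, h, k), h, k)
        return self.readout(batch, h)

    def encode_drug(self, graph: MolecularGraph) -> Tensor:
        """Fixed-size embedding of one molecule; shape (hidden_dim,)."""
        return self.encode_batch([graph]).reshape(self.config.hidden_dim)
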