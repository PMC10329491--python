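"""Knowledge-graph channel: ConvE embeddings of entities and relations.

A triple (h, r, t) is scored by 2D-reshaping the head and relation
embeddings, stacking them, convolving with a bank of 3x3 filters, applying a
ReLU, flattening, projecting back to the embedding dimension, applying a
second ReLU, and taking the inner product with the tail embedding (plus a
per-entity output bias).  Training is 1-N: every (h, r) query is scored
against all entities at once and optimized with multi-label binary
cross-entropy over the observed tails; inverse relations are added so that
head-side queries become tail predictions.

The trained entity table provides the K-channel representations of drugs and
targets, and :func:`kg_link_predict` serves side-effect/indication style
queries.  :func:`build_k_channel` enforces the leakage guard: no evaluation
drug-target pair may ever reach ConvE training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import (Adam, Dropout, Embedding, Module, Tensor, bce_with_logits,
                 concat, take_axis1)

logger = logging.getLogger(__name__)

__all__ = [
    "KnowledgeGraph", "ConvEConfig", "ConvEModel", "EmbeddingTable",
    "ConvEResult", "LeakageError", "train_conve", "build_k_channel",
    "kg_link_predict", "filtered_ranks", "DTI_RELATION",
]

DTI_RELATION = "interacts_with"


class LeakageError(RuntimeError):
    """An evaluation drug-target pair was about to enter KGE training."""


@dataclass
class KnowledgeGraph:
    entities: list[str]
    relations: list[str]
    triples: list[tuple[str, str, str]]
    entity_index: dict[str, int] = field(init=False)
    relation_index: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.entity_index = {e: i for i, e in enumerate(self.entities)}
        self.relation_index = {r: i for i, r in enumerate(self.relations)}
        if len(self.entity_index) != len(self.entities):
            raise ValueError("duplicate entities")
        if len(self.relation_index) != len(self.relations):
            raise ValueError("duplicate relations")
        if len(set(self.triples)) != len(self.triples):
            raise ValueError("duplicate triples")
        for h, r, t in self.triples:
            if h not in self.entity_index or t not in self.entity_index:
                raise ValueError(f"triple references unknown entity: {(h, r, t)}")
            if r not in self.relation_index:
                raise ValueError(f"triple references unknown relation: {(h, r, t)}")

    @classmethod
    def from_triples(cls, triples: list[tuple[str, str, str]]) -> "KnowledgeGraph":
        triples = list(dict.fromkeys(triples))  # dedupe, keep order
        entities = list(dict.fromkeys([h for h, _, _ in triples]
                                      + [t for _, _, t in triples]))
        relations = list(dict.fromkeys([r for _, r, _ in triples]))
        return cls(entities, relations, triples)

    def with_extra_triples(self, extra) -> "KnowledgeGraph":
        return KnowledgeGraph.from_triples(self.triples + list(extra))


@dataclass
class ConvEConfig:
    k: int = 200                 # embedding dimension
    k_w: int = 20                # reshape width;  k = k_w * k_h
    k_h: int = 10
    n_filters: int = 32
    filter_size: int = 3
    dropout_input: float = 0.1
    dropout_feature: float = 0.1
    dropout_hidden: float = 0.2
    label_smoothing: float = 0.0
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.k_w * self.k_h != self.k:
            raise ValueError(f"k_w*k_h must equal k: {self.k_w}*{self.k_h} != {self.k}")
        if self.k_h < self.filter_size or 2 * self.k_w < self.filter_size:
            raise ValueError("reshape smaller than the convolution filter")


@dataclass
class EmbeddingTable:
    entity_vectors: np.ndarray       # |entities| x k
    relation_vectors: np.ndarray     # |relations| x k (forward relations)
    entity_index: dict[str, int]
    relation_index: dict[str, int]

    def entity(self, name: str) -> np.ndarray:
        if name not in self.entity_index:
            raise KeyError(f"unknown entity {name!r} (K modality unavailable)")
        return self.entity_vectors[self.entity_index[name]]

    def save(self, entity_path, relation_path) -> None:
        pd.DataFrame(self.entity_vectors,
                     index=list(self.entity_index)).to_csv(entity_path, sep="\t",
                                                           header=False)
        pd.DataFrame(self.relation_vectors,
                     index=list(self.relation_index)).to_csv(relation_path,
                                                             sep="\t", header=False)

    @classmethod
    def load(cls, entity_path, relation_path) -> "EmbeddingTable":
        e = pd.read_csv(entity_path, sep="\t", header=None, index_col=0)
        r = pd.read_csv(relation_path, sep="\t", header=None, index_col=0)
        return cls(e.to_numpy(float), r.to_numpy(float),
                   {n: i for i, n in enumerate(e.index)},
                   {n: i for i, n in enumerate(r.index)})


def _patch_indices(height: int, width: int, fs: int) -> np.ndarray:
    """Flat gather indices turning an image into valid-conv patches."""
    rows = height - fs + 1
    cols = width - fs + 1
    idx = []
    for i in range(rows):
        for j in range(cols):
            for di in range(fs):
                for dj in range(fs):
                    idx.append((i + di) * width + (j + dj))
    return np.asarray(idx, dtype=np.intp)


class ConvEModel(Module):
    def __init__(self, kg: KnowledgeGraph, config: ConvEConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.config = config
        self.kg = kg
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        n_e, n_r = len(kg.entities), len(kg.relations)
        self.n_entities = n_e
        self.n_relations = n_r
        # inverse relations occupy indices n_r .. 2*n_r-1
        self.ent = Embedding(n_e, config.k, rng)
        self.rel = Embedding(2 * n_r, config.k, rng)
        fs = config.filter_size
        self.filters = Tensor(rng.normal(0, 0.1, size=(fs * fs, config.n_filters)),
                              requires_grad=True)
        self.filter_bias = Tensor(np.zeros(config.n_filters), requires_grad=True)
        height, width = 2 * config.k_w, config.k_h
        self._patches = _patch_indices(height, width, fs)
        n_patch = (height - fs + 1) * (width - fs + 1)
        self.fc = Tensor(rng.normal(0, 0.05, size=(n_patch * config.n_filters,
                                                   config.k)),
                         requires_grad=True)
        self.fc_bias = Tensor(np.zeros(config.k), requires_grad=True)
        self.ent_bias = Tensor(np.zeros(n_e), requires_grad=True)
        self.drop_in = Dropout(config.dropout_input, rng)
        self.drop_feat = Dropout(config.dropout_feature, rng)
        self.drop_hid = Dropout(config.dropout_hidden, rng)

    def query(self, h_idx: np.ndarray, r_idx: np.ndarray) -> Tensor:
        """Hidden query vector ReLU(vec(ReLU(conv([e_h; r_r]))) W); (B, k)."""
        cfg = self.config
        b = len(h_idx)
        e_h = self.ent(h_idx)                       # (B, k)
        r_r = self.rel(r_idx)
        stacked = concat([e_h.reshape(b, cfg.k_w, cfg.k_h),
                          r_r.reshape(b, cfg.k_w, cfg.k_h)], axis=1)
        flat = self.drop_in(stacked.reshape(b, 2 * cfg.k_w * cfg.k_h))
        fs = cfg.filter_size
        patches = take_axis1(flat, self._patches).reshape(b, -1, fs * fs)
        feat = ((patches @ self.filters) + self.filter_bias).relu()   # inner f
        feat = self.drop_feat(feat)
        hidden = (feat.reshape(b, -1) @ self.fc + self.fc_bias).relu()
        return self.drop_hid(hidden)

    def score_all_tails(self, h_idx: np.ndarray, r_idx: np.ndarray) -> Tensor:
        """1-N logits against every entity; shape (B, |entities|)."""
        return self.query(h_idx, r_idx) @ self.ent.weight.transpose() + self.ent_bias

    def score(self, head: str, relation: str, tail: str,
              inverse: bool = False) -> float:
        """Single-triple score (the 1-N row entry for this tail)."""
        h = self.kg.entity_index[head]
        r = self.kg.relation_index[relation] + (self.n_relations if inverse else 0)
        t = self.kg.entity_index[tail]
        logits = self.score_all_tails(np.array([h]), np.array([r]))
        return float(logits.data[0, t])

    def embedding_table(self) -> EmbeddingTable:
        return EmbeddingTable(self.ent.weight.data.copy(),
                              self.rel.weight.data[:self.n_relations].copy(),
                              dict(self.kg.entity_index),
                              dict(self.kg.relation_index))


@dataclass
class ConvEResult:
    model: ConvEModel
    table: EmbeddingTable
    losses: list[float]


def _grouped_queries(kg: KnowledgeGraph, n_relations: int):
    """(h, r) -> set of observed tail indices, including inverse queries."""
    groups: dict[tuple[int, int], set[int]] = {}
    for h, r, t in kg.triples:
        hi, ri, ti = (kg.entity_index[h], kg.relation_index[r],
                      kg.entity_index[t])
        groups.setdefault((hi, ri), set()).add(ti)
        groups.setdefault((ti, ri + n_relations), set()).add(hi)
    return groups


def train_conve(kg: KnowledgeGraph, config: ConvEConfig) -> ConvEResult:
    """Train ConvE with 1-N multi-label binary cross-entropy.

    Raises RuntimeError on divergence (non-finite loss).
    """
    if len(kg.triples) < 1:
        raise ValueError("empty knowledge graph")
    rng = np.random.default_rng(config.seed)
    model = ConvEModel(kg, config, rng=np.random.default_rng(config.seed + 1))
    groups = _grouped_queries(kg, model.n_relations)
    keys = sorted(groups)
    labels = np.zeros((len(keys), model.n_entities))
    for i, key in enumerate(keys):
        labels[i, sorted(groups[key])] = 1.0
    if config.label_smoothing > 0:
        labels = (labels * (1 - config.label_smoothing)
                  + config.label_smoothing / model.n_entities)
    queries = np.asarray(keys, dtype=np.intp)
    opt = Adam(model.parameters(), lr=config.lr)
    losses: list[float] = []
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(len(keys))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(keys), config.batch_size):
            sel = order[start:start + config.batch_size]
            logits = model.score_all_tails(queries[sel, 0], queries[sel, 1])
            loss = bce_with_logits(logits, labels[sel])
            if not np.isfinite(loss.data).all():
                raise RuntimeError(
                    f"ConvE training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    model.eval()
    logger.info("ConvE: loss %.4f -> %.4f over %d epochs",
                losses[0], losses[-1], config.epochs)
    return ConvEResult(model, model.embedding_table(), losses)


def build_k_channel(kg_support: KnowledgeGraph,
                    train_positives: list,
                    eval_pairs: list,
                    config: ConvEConfig,
                    dti_relation: str = DTI_RELATION) -> ConvEResult:
    """Train ConvE on support knowledge plus train-split positive DTPs.

    The leakage guard is total: if any held-out (validation/test) drug-target
    pair appears either among the supplied training positives or as a
    head-tail pair anywhere in the support graph, a :class:`LeakageError` is
    raised before any training happens.
    """
    eval_keys = {(p.drug_id, p.target_id) for p in eval_pairs if p.label == 1}
    train_keys = {(p.drug_id, p.target_id) for p in train_positives}
    overlap = eval_keys & train_keys
    if overlap:
        raise LeakageError(
            f"evaluation DTPs present in training positives: {sorted(overlap)[:5]}")
    support_pairs = {(h, t) for h, _, t in kg_support.triples}
    overlap = eval_keys & support_pairs
    if overlap:
        raise LeakageError(
            f"evaluation DTPs present in the support KG: {sorted(overlap)[:5]}")
    dti_triples = [(p.drug_id, dti_relation, p.target_id)
                   for p in train_positives if p.label == 1]
    kg = kg_support.with_extra_triples(dti_triples)
    return train_conve(kg, config)


def filtered_ranks(model: ConvEModel, eval_triples, known_triples) -> np.ndarray:
    """1-based filtered rank of each true tail among all entities."""
    known: dict[tuple[int, int], set[int]] = {}
    kg = model.kg
    for h, r, t in known_triples:
        known.setdefault((kg.entity_index[h], kg.relation_index[r]),
                         set()).add(kg.entity_index[t])
    model.eval()
    ranks = []
    for h, r, t in eval_triples:
        hi, ri, ti = (kg.entity_index[h], kg.relation_index[r],
                      kg.entity_index[t])
        scores = model.score_all_tails(np.array([hi]), np.array([ri])).data[0].copy()
        for other in known.get((hi, ri), ()):
            if other != ti:
                scores[other] = -np.inf
        ranks.append(1 + int((scores > scores[ti]).sum()))
    return np.asarray(ranks)


def kg_link_predict(model: ConvEModel, head: str, relation: str,
                    top_k: int | None = 10) -> list[tuple[str, float]]:
    """Rank candidate tails for (head, relation), filtering known triples."""
    kg = model.kg
    if head not in kg.entity_index:
        raise KeyError(f"unknown head entity {head!r}")
    if relation not in kg.relation_index:
        raise KeyError(f"unknown relation {relation!r}")
    model.eval()
    hi, ri = kg.entity_index[head], kg.relation_index[relation]
    scores = model.score_all_tails(np.array([hi]), np.array([ri])).data[0].copy()
    known = {kg.entity_index[t] for h, r, t in kg.triples
             if h == head and r == relation}
    order = np.argsort(-scores)
    ranked = [(kg.entities[i], float(scores[i])) for i in order if i not in known]
    if top_k is not None:
        ranked = ranked[:top_k]
    return ranked
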