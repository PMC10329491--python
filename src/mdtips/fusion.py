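"""Late fusion of the K/S/E channels and the sigmoid DTI classifier.

Each configured modality contributes a drug vector and a target vector:

- K: rows of the (pretrained, optionally fine-tuned) ConvE entity table;
- S: the Attentive FP drug embedding and the Transformer target embedding,
  trained end-to-end from random initialization;
- E: the raw consensus expression signatures (non-trainable inputs).

Per modality the two vectors are concatenated and mapped into a latent space
(affine -> dropout -> ReLU -> layer normalization).  The latents are
concatenated and fed through a four-layer perceptron (three hidden layers,
1024/1024/512 units by default, ReLU) whose sigmoid output is the
interaction probability.  Training minimizes binary cross-entropy end to end
and early-stops on validation AUPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chem_graph import MolecularGraph
from .data_io import DatasetSplit, DTPRecord
from .drug_encoder import AttentiveFPConfig, AttentiveFPEncoder
from .expr import SignatureStore, drug_signature, target_signature
from .kge import EmbeddingTable
from .nn import (Adam, Dropout, LayerNorm, Linear, Module, Tensor,
                 bce_with_logits, concat)
from .target_encoder import (SubwordVocab, TargetTransformer, TokenizedSequence,
                             TransformerConfig)

logger = logging.getLogger(__name__)

__all__ = [
    "FusionConfig", "FusionModel", "ChannelInputs", "PairBatch",
    "TrainedFusion", "prepare_pair_data", "filter_modality_complete",
    "modality_availability", "train_fusion", "predict_pairs",
]

VALID_MODALITIES = ("K", "S", "E")


@dataclass
class FusionConfig:
    modalities: str = "KSE"
    proj_dim: int = 256
    hidden: tuple[int, int, int] = (1024, 1024, 512)
    dropout: float = 0.1
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int | None = None        # None = full batch
    patience: int = 10
    min_epochs: int = 0                  # no early stop before this epoch
    seed: int = 0
    freeze_kge: bool = False
    unknown_policy: str = "xpr"          # E-channel direction for unknowns
    drug_encoder: AttentiveFPConfig = field(default_factory=AttentiveFPConfig)
    target_encoder: TransformerConfig = field(default_factory=TransformerConfig)

    def __post_init__(self):
        mods = set(self.modalities)
        if not mods or not mods <= set(VALID_MODALITIES):
            raise ValueError(
                f"modalities must be a nonempty subset of K/S/E, "
                f"got {self.modalities!r}")
        # canonical order K, S, E
        self.modalities = "".join(m for m in VALID_MODALITIES if m in mods)
        if len(self.hidden) != 3:
            raise ValueError("classifier takes exactly three hidden layers")


@dataclass
class ChannelInputs:
    """Featurized per-entity inputs shared across models and repeats."""

    graphs: dict[str, MolecularGraph] | None = None          # S: drugs
    tokens: dict[str, TokenizedSequence] | None = None       # S: targets
    kge_table: EmbeddingTable | None = None                  # K
    store: SignatureStore | None = None                      # E


@dataclass
class PairBatch:
    pairs: list[DTPRecord]
    labels: np.ndarray
    # S channel
    drug_graphs: list[MolecularGraph] | None = None
    drug_index: np.ndarray | None = None      # pair -> row of drug_graphs
    target_tokens: list[TokenizedSequence] | None = None
    target_index: np.ndarray | None = None
    # K channel
    k_drug_idx: np.ndarray | None = None      # pair -> entity table row
    k_target_idx: np.ndarray | None = None
    # E channel
    e_drug: np.ndarray | None = None          # (n, G)
    e_target: np.ndarray | None = None

    def __len__(self):
        return len(self.pairs)


def modality_availability(pair: DTPRecord, inputs: ChannelInputs,
                          unknown_policy: str = "xpr") -> frozenset:
    """Which of K/S/E are available for this pair given the loaded inputs."""
    flags = set()
    if inputs.graphs is not None and inputs.tokens is not None:
        if pair.drug_id in inputs.graphs and pair.target_id in inputs.tokens:
            flags.add("S")
    if inputs.kge_table is not None:
        idx = inputs.kge_table.entity_index
        if pair.drug_id in idx and pair.target_id in idx:
            flags.add("K")
    if inputs.store is not None:
        if (drug_signature(pair.drug_id, inputs.store) is not None
                and target_signature(pair.target_id, pair.direction,
                                     inputs.store, unknown_policy) is not None):
            flags.add("E")
    return frozenset(flags)


def filter_modality_complete(pairs: list[DTPRecord], inputs: ChannelInputs,
                             modalities: str,
                             unknown_policy: str = "xpr"):
    """Split pairs into (complete, incomplete) for the requested modalities,
    and return per-modality availability counts for diagnostics."""
    need = set(modalities)
    complete, incomplete = [], []
    counts = {m: 0 for m in VALID_MODALITIES}
    for p in pairs:
        flags = modality_availability(p, inputs, unknown_policy)
        for m in flags:
            counts[m] += 1
        (complete if need <= flags else incomplete).append(p)
    return complete, incomplete, counts


def prepare_pair_data(pairs: list[DTPRecord], inputs: ChannelInputs,
                      config: FusionConfig) -> PairBatch:
    """Assemble the featurized batch for a list of modality-complete pairs."""
    batch = PairBatch(pairs=list(pairs),
                      labels=np.array([p.label for p in pairs], dtype=float))
    mods = config.modalities
    if "S" in mods:
        if inputs.graphs is None or inputs.tokens is None:
            raise ValueError("S modality requested but graphs/tokens missing")
        drug_ids = sorted({p.drug_id for p in pairs})
        target_ids = sorted({p.target_id for p in pairs})
        d_pos = {d: i for i, d in enumerate(drug_ids)}
        t_pos = {t: i for i, t in enumerate(target_ids)}
        try:
            batch.drug_graphs = [inputs.graphs[d] for d in drug_ids]
            batch.target_tokens = [inputs.tokens[t] for t in target_ids]
        except KeyError as exc:
            raise ValueError(f"S modality unavailable for {exc}") from exc
        batch.drug_index = np.array([d_pos[p.drug_id] for p in pairs], dtype=np.intp)
        batch.target_index = np.array([t_pos[p.target_id] for p in pairs],
                                      dtype=np.intp)
    if "K" in mods:
        if inputs.kge_table is None:
            raise ValueError("K modality requested but no embedding table")
        idx = inputs.kge_table.entity_index
        try:
            batch.k_drug_idx = np.array([idx[p.drug_id] for p in pairs],
                                        dtype=np.intp)
            batch.k_target_idx = np.array([idx[p.target_id] for p in pairs],
                                          dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"K modality unavailable for {exc}") from exc
    if "E" in mods:
        if inputs.store is None:
            raise ValueError("E modality requested but no signature store")
        e_d, e_t = [], []
        for p in pairs:
            d = drug_signature(p.drug_id, inputs.store)
            t = target_signature(p.target_id, p.direction, inputs.store,
                                 config.unknown_policy)
            if d is None or t is None:
                raise ValueError(f"E modality unavailable for pair {p.key}")
            e_d.append(d)
            e_t.append(t)
        batch.e_drug = np.asarray(e_d)
        batch.e_target = np.asarray(e_t)
    return batch


class _Projection(Module):
    """Eq.-style per-modality map: concat -> affine -> dropout -> ReLU -> LN."""

    def __init__(self, in_dim: int, out_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.lin = Linear(in_dim, out_dim, rng)
        self.drop = Dropout(dropout, rng)
        self.norm = LayerNorm(out_dim)

    def __call__(self, drug_vec: Tensor, target_vec: Tensor) -> Tensor:
        x = concat([drug_vec, target_vec], axis=-1)
        return self.norm(self.drop(self.lin(x)).relu())


class FusionModel(Module):
    def __init__(self, config: FusionConfig, inputs: ChannelInputs,
                 vocab: SubwordVocab | None = None):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        mods = config.modalities
        if "S" in mods:
            self.drug_enc = AttentiveFPEncoder(
                config.drug_encoder, rng=np.random.default_rng(rng.integers(2**31)))
            if vocab is None:
                raise ValueError("S modality requires a subword vocabulary")
            self.target_enc = TargetTransformer(
                vocab.size, config.target_encoder,
                rng=np.random.default_rng(rng.integers(2**31)))
            s_in = config.drug_encoder.hidden_dim + config.target_encoder.d
            self.proj_S = _Projection(s_in, config.proj_dim, config.dropout, rng)
        if "K" in mods:
            if inputs.kge_table is None:
                raise ValueError("K modality requires a pretrained table")
            from .nn import Embedding
            k = inputs.kge_table.entity_vectors.shape[1]
            self.k_emb = Embedding(len(inputs.kge_table.entity_index), k, rng)
            self.k_emb.weight.data = inputs.kge_table.entity_vectors.copy()
            self.proj_K = _Projection(2 * k, config.proj_dim, config.dropout, rng)
        if "E" in mods:
            if inputs.store is None:
                raise ValueError("E modality requires a signature store")
            g = inputs.store.n_genes
            self.proj_E = _Projection(2 * g, config.proj_dim, config.dropout, rng)
        in_dim = config.proj_dim * len(mods)
        h1, h2, h3 = config.hidden
        self.fc1 = Linear(in_dim, h1, rng)
        self.fc2 = Linear(h1, h2, rng)
        self.fc3 = Linear(h2, h3, rng)
        self.out = Linear(h3, 1, rng)
        self.clf_drop = Dropout(config.dropout, rng)

    def trainable_parameters(self) -> list[Tensor]:
        params = self.parameters()
        if self.config.freeze_kge and "K" in self.config.modalities:
            params = [p for p in params if p is not self.k_emb.weight]
        return params

    # --- forward -----------------------------------------------------------
    def modality_latents(self, batch: PairBatch) -> list[Tensor]:
        latents = []
        if "K" in self.config.modalities:
            latents.append(self.proj_K(self.k_emb(batch.k_drug_idx),
                                       self.k_emb(batch.k_target_idx)))
        if "S" in self.config.modalities:
            d_all = self.drug_enc.encode_batch(batch.drug_graphs)
            t_all = self.target_enc.encode_batch(batch.target_tokens)
            latents.append(self.proj_S(d_all[batch.drug_index],
                                       t_all[batch.target_index]))
        if "E" in self.config.modalities:
            latents.append(self.proj_E(Tensor(batch.e_drug),
                                       Tensor(batch.e_target)))
        return latents

    def classify(self, latents: list[Tensor]) -> Tensor:
        """Fusion MLP logits from one latent per configured modality."""
        if len(latents) != len(self.config.modalities):
            raise ValueError(
                f"expected {len(self.config.modalities)} latents, "
                f"got {len(latents)}")
        x = concat(latents, axis=-1) if len(latents) > 1 else latents[0]
        x = self.clf_drop(self.fc1(x).relu())
        x = self.clf_drop(self.fc2(x).relu())
        x = self.clf_drop(self.fc3(x).relu())
        return self.out(x).reshape(len(latents[0].data))

    def forward_logits(self, batch: PairBatch) -> Tensor:
        return self.classify(self.modality_latents(batch))

    def predict_scores(self, batch: PairBatch) -> np.ndarray:
        was = self.training
        self.eval()
        scores = self.forward_logits(batch).sigmoid().data
        self.train(was)
        return scores


@dataclass
class TrainedFusion:
    model: FusionModel
    history: list[dict]       # per-epoch train loss / val AUPR / val AUROC
    best_epoch: int
    best_val_aupr: float


def train_fusion(split: DatasetSplit, inputs: ChannelInputs,
                 config: FusionConfig,
                 vocab: SubwordVocab | None = None) -> TrainedFusion:
    """End-to-end BCE training with early stopping on validation AUPR."""
    from .evaluation import auprc, auroc

    complete, _, counts = filter_modality_complete(
        split.train, inputs, config.modalities, config.unknown_policy)
    if not complete:
        raise ValueError(
            f"no modality-complete training pairs for {config.modalities}; "
            f"per-modality availability over training pairs: {counts}")
    train_batch = prepare_pair_data(complete, inputs, config)
    val_complete, _, _ = filter_modality_complete(
        split.valid, inputs, config.modalities, config.unknown_policy)
    val_batch = prepare_pair_data(val_complete, inputs, config)

    model = FusionModel(config, inputs, vocab=vocab)
    opt = Adam(model.trainable_parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 101)
    history: list[dict] = []
    best_state, best_aupr, best_epoch, since_best = None, -np.inf, -1, 0
    n = len(train_batch)
    bs = config.batch_size or n
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, bs):
            sel = order[start:start + bs]
            sub = _subset_batch(train_batch, sel)
            logits = model.forward_logits(sub)
            loss = bce_with_logits(logits, sub.labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_scores = model.predict_scores(val_batch)
        if len(np.unique(val_batch.labels)) < 2:
            # degenerate validation part (single class): metrics undefined,
            # no early stopping credit
            val_aupr = val_auroc = float("nan")
        else:
            val_aupr = auprc(val_scores, val_batch.labels)
            val_auroc = auroc(val_scores, val_batch.labels)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                        "val_aupr": val_aupr, "val_auroc": val_auroc})
        if val_aupr > best_aupr:
            best_aupr, best_epoch, since_best = val_aupr, epoch, 0
            best_state = model.state_dict()
        else:
            since_best += 1
            if since_best >= config.patience and epoch + 1 >= config.min_epochs:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    logger.info("fusion %s: best val AUPR %.3f at epoch %d",
                config.modalities, best_aupr, best_epoch)
    return TrainedFusion(model, history, best_epoch, best_aupr)


def _subset_batch(batch: PairBatch, sel: np.ndarray) -> PairBatch:
    if len(sel) == len(batch) and (sel == np.arange(len(batch))).all():
        return batch
    sub = PairBatch(pairs=[batch.pairs[i] for i in sel],
                    labels=batch.labels[sel])
    if batch.drug_graphs is not None:
        # keep only graphs/tokens referenced by the subset
        d_used = sorted(set(batch.drug_index[sel]))
        t_used = sorted(set(batch.target_index[sel]))
        d_map = {g: i for i, g in enumerate(d_used)}
        t_map = {g: i for i, g in enumerate(t_used)}
        sub.drug_graphs = [batch.drug_graphs[i] for i in d_used]
        sub.target_tokens = [batch.target_tokens[i] for i in t_used]
        sub.drug_index = np.array([d_map[i] for i in batch.drug_index[sel]],
                                  dtype=np.intp)
        sub.target_index = np.array([t_map[i] for i in batch.target_index[sel]],
                                    dtype=np.intp)
    if batch.k_drug_idx is not None:
        sub.k_drug_idx = batch.k_drug_idx[sel]
        sub.k_target_idx = batch.k_target_idx[sel]
    if batch.e_drug is not None:
        sub.e_drug = batch.e_drug[sel]
        sub.e_target = batch.e_target[sel]
    return sub


def predict_pairs(model: FusionModel, pairs: list[DTPRecord],
                  inputs: ChannelInputs) -> list[tuple[DTPRecord, float]]:
    """Deterministic eval-mode scores, one per pair, independent of batch
    composition."""
    batch = prepare_pair_data(pairs, inputs, model.config)
    scores = model.predict_scores(batch)
    return list(zip(pairs, [float(s) for s in scores]))
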