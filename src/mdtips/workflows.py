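"""High-level workflows: featurization, desk-scale configs, training of the
deployable model family, and checkpoint persistence.

The "desk-scale" configuration profile shrinks every width, depth and epoch
count so that the complete pipeline — simulation, knowledge-graph embedding,
end-to-end fusion training, ablation grids — runs in minutes on one CPU.
The architectural defaults of the individual modules (embedding width 64 and
maximum length 545 for the target encoder, ConvE dimension 200, fusion
hidden layers 1024/1024/512, dropout 0.1) are unchanged; the profile only
overrides sizes, which are all ordinary config fields.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .chem_graph import smiles_to_graph
from .data_io import DatasetSplit, DrugRecord, TargetRecord
from .drug_encoder import AttentiveFPConfig
from .evaluation import AblationResources
from .fusion import ChannelInputs, FusionConfig, FusionModel, train_fusion
from .kge import ConvEConfig, build_k_channel
from .router import PredictionSystem
from .synthetic import World
from .target_encoder import (SubwordVocab, TransformerConfig,
                             learn_subword_vocab, tokenize)

logger = logging.getLogger(__name__)

__all__ = [
    "desk_fusion_config", "desk_kge_config", "build_resources",
    "train_prediction_system", "save_fusion_model", "load_fusion_model",
]


def desk_fusion_config(modalities: str = "KSE", seed: int = 0,
                       **overrides) -> FusionConfig:
    """Small-width fusion config for fixture-scale experiments."""
    cfg = FusionConfig(
        modalities=modalities,
        proj_dim=32,
        hidden=(64, 64, 32),
        dropout=0.1,
        lr=3e-3,
        epochs=100,
        patience=25,
        min_epochs=50,
        seed=seed,
        freeze_kge=True,
        drug_encoder=AttentiveFPConfig(hidden_dim=32, n_atom_layers=2,
                                       n_readout_timesteps=2, seed=seed),
        target_encoder=TransformerConfig(d=32, m=64, n_heads=2, ffn_dim=64,
                                         seed=seed),
    )
    return replace(cfg, **overrides) if overrides else cfg


def desk_kge_config(seed: int = 0, **overrides) -> ConvEConfig:
    """Small ConvE config (k=32 reshaped 8x4, 8 filters) for fixtures."""
    cfg = ConvEConfig(k=32, k_w=8, k_h=4, n_filters=8, epochs=200,
                      lr=5e-3, batch_size=256, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def build_resources(world: World, kge_config: ConvEConfig | None = None,
                    max_len: int = 64, n_merges: int = 60,
                    vocab: SubwordVocab | None = None) -> AblationResources:
    """Featurize a world once: graphs, subword vocabulary, tokenized targets."""
    graphs = {d.drug_id: smiles_to_graph(d.smiles) for d in world.drugs}
    if vocab is None:
        vocab = learn_subword_vocab([t.sequence for t in world.targets],
                                    n_merges=n_merges)
    tokens = {t.target_id: tokenize(t.sequence, vocab, m=max_len)
              for t in world.targets}
    return AblationResources(
        positives=world.positives, drugs=world.drugs, targets=world.targets,
        kg_support=world.kg, store=world.store, graphs=graphs, tokens=tokens,
        vocab=vocab, kge_config=kge_config or desk_kge_config())


def train_prediction_system(res: AblationResources, split: DatasetSplit,
                            fusion_config: FusionConfig,
                            labels: tuple[str, ...] = ("KSE", "KS", "S"),
                            ) -> PredictionSystem:
    """Train the deployable model family on one split, sharing the K channel.

    The ConvE table is pretrained once (on support knowledge plus the train
    positives, with the leakage guard against the held-out pairs) and reused
    by every model that includes K, so KSE and KS read the same channel
    inputs.
    """
    inputs = ChannelInputs(graphs=res.graphs, tokens=res.tokens,
                           store=res.store)
    if any("K" in label for label in labels):
        train_pos = [p for p in split.train if p.label == 1]
        held_out = ([p for p in split.valid if p.label == 1]
                    + [p for p in split.test if p.label == 1])
        inputs.kge_table = build_k_channel(res.kg_support, train_pos, held_out,
                                           res.kge_config).table
    models = {}
    for label in labels:
        cfg = replace(fusion_config, modalities=label)
        models[label] = train_fusion(split, inputs, cfg,
                                     vocab=res.vocab).model
    return PredictionSystem(models=models, inputs=inputs, kg=res.kg_support)


# ----- checkpoint persistence ----------------------------------------------

def _config_to_dict(cfg: FusionConfig) -> dict:
    d = asdict(cfg)
    d["hidden"] = list(d["hidden"])
    return d


def _config_from_dict(d: dict) -> FusionConfig:
    d = dict(d)
    d["hidden"] = tuple(d["hidden"])
    d["drug_encoder"] = AttentiveFPConfig(**d["drug_encoder"])
    te = dict(d["target_encoder"])
    d["target_encoder"] = TransformerConfig(**te)
    return FusionConfig(**d)


def save_fusion_model(model: FusionModel, out_dir,
                      vocab: SubwordVocab | None = None,
                      kge_table=None) -> None:
    """Persist a trained fusion model (weights + config + vocab + K table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", **model.state_dict())
    (out / "config.yaml").write_text(
        yaml.safe_dump(_config_to_dict(model.config)))
    if vocab is not None:
        vocab.save(out / "subword_codes.txt", out / "subword_tokens.tsv")
    if kge_table is not None:
        kge_table.save(out / "entities.tsv", out / "relations.tsv")


def load_fusion_model(model_dir, store=None):
    """Rebuild a fusion model from a checkpoint directory.

    Returns (model, inputs, vocab); ``inputs`` carries the stored K table and
    the given signature store but not graphs/tokens, which callers featurize
    from their own data files.
    """
    from .kge import EmbeddingTable

    d = Path(model_dir)
    config = _config_from_dict(yaml.safe_load((d / "config.yaml").read_text()))
    vocab = None
    if (d / "subword_codes.txt").exists():
        vocab = SubwordVocab.load(d / "subword_codes.txt",
                                  d / "subword_tokens.tsv")
    table = None
    if (d / "entities.tsv").exists():
        table = EmbeddingTable.load(d / "entities.tsv", d / "relations.tsv")
    inputs = ChannelInputs(kge_table=table, store=store)
    model = FusionModel(config, inputs, vocab=vocab)
    state = dict(np.load(d / "weights.npz"))
    model.load_state_dict(state)
    model.eval()
    return model, inputs, vocab
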