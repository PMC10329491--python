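"""Modality routing, reverse screening, and K-model drug-info prediction.

Given an input compound the system resolves which modalities exist for it —
structure is always available (the SMILES is the input), the knowledge-graph
channel exists iff the compound is a KG entity, and the expression channel
iff a compound signature row is present — and dispatches to the best
available trained model with the fixed priority KSE > KS > S.  Reverse
screening scores one drug against a universe of targets, marks scores above
the credibility threshold (0.7 by default) and keeps the top 10 credible
candidates.  Side effects, indications and other drug-related relations are
predicted with the pretrained K model, optionally after re-training it on
the union of the knowledge graph and credible predicted interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .data_io import DrugRecord, DTPRecord, TargetRecord
from .expr import SignatureStore
from .fusion import (ChannelInputs, FusionModel, filter_modality_complete,
                     predict_pairs)
from .kge import (DTI_RELATION, ConvEConfig, ConvEModel, KnowledgeGraph,
                  kg_link_predict, train_conve)

logger = logging.getLogger(__name__)

__all__ = ["PredictionResult", "PredictionSystem", "resolve_modalities",
           "dispatch", "reverse_screen", "predict_drug_info",
           "write_predictions", "CREDIBLE_THRESHOLD", "DEFAULT_TOP_K"]

CREDIBLE_THRESHOLD = 0.7
DEFAULT_TOP_K = 10

#: dispatch priority: use the richest trained model the modalities allow
DISPATCH_PRIORITY = ("KSE", "KS", "S")


@dataclass(frozen=True)
class PredictionResult:
    drug_id: str
    target_id: str
    score: float
    model_used: str            # one of KSE / KS / S / K
    credible: bool             # score > threshold

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score outside [0,1]: {self.score}")


def resolve_modalities(drug: DrugRecord, kg: KnowledgeGraph | None,
                       store: SignatureStore | None) -> frozenset:
    """Modalities available for an input compound.

    S is always present (the structure is the input itself); K requires KG
    membership; E requires a compound signature row.
    """
    flags = {"S"}
    if kg is not None and drug.drug_id in kg.entity_index:
        flags.add("K")
    if store is not None and store.has_drug(drug.drug_id):
        flags.add("E")
    return frozenset(flags)


def dispatch(flags: frozenset) -> str:
    """Pick the model for a modality set: KSE > KS > S, deterministically."""
    if not flags:
        raise ValueError("empty modality set")
    for label in DISPATCH_PRIORITY:
        if set(label) <= set(flags):
            return label
    return "S"


@dataclass
class PredictionSystem:
    """Trained fusion models plus the shared featurized channel inputs."""

    models: dict[str, FusionModel]          # label -> trained model
    inputs: ChannelInputs
    kg: KnowledgeGraph | None = None
    threshold: float = CREDIBLE_THRESHOLD

    def model_for(self, label: str) -> FusionModel:
        if label not in self.models:
            raise KeyError(f"no trained model for modality set {label!r}; "
                           f"available: {sorted(self.models)}")
        return self.models[label]


def reverse_screen(system: PredictionSystem, drugs: list[DrugRecord],
                   target_universe: list[TargetRecord],
                   threshold: float = CREDIBLE_THRESHOLD,
                   top_k: int = DEFAULT_TOP_K) -> list[PredictionResult]:
    """Score each drug against the target universe with its dispatched model.

    Returns, per drug, the top ``top_k`` credible (score > threshold)
    candidates in descending score order — possibly fewer when credibility
    thins.  Targets missing a modality the dispatched model needs are skipped.
    """
    if not target_universe:
        raise ValueError("empty target universe")
    results: list[PredictionResult] = []
    for drug in drugs:
        flags = resolve_modalities(drug, system.kg, system.inputs.store)
        label = dispatch(flags)
        model = system.model_for(label)
        candidates = [DTPRecord(drug.drug_id, t.target_id, 0, "unknown")
                      for t in target_universe]
        usable, skipped, _ = filter_modality_complete(
            candidates, system.inputs, label, model.config.unknown_policy)
        if skipped:
            logger.info("drug %s: %d targets lack a modality needed by %s",
                        drug.drug_id, len(skipped), label)
        scored = predict_pairs(model, usable, system.inputs)
        credible = sorted((s for s in scored if s[1] > threshold),
                          key=lambda x: -x[1])[:top_k]
        results.extend(
            PredictionResult(p.drug_id, p.target_id, score, label,
                             credible=True)
            for p, score in credible)
    return results


def predict_drug_info(conve_model: ConvEModel, drug_id: str, relation: str,
                      top_k: int = DEFAULT_TOP_K,
                      inject_predictions: list[PredictionResult] | None = None,
                      kge_config: ConvEConfig | None = None
                      ) -> list[tuple[str, float]]:
    """Rank tails (side effects, indications, ...) for a drug via the K model.

    With ``inject_predictions`` the K model is re-trained on the knowledge
    graph augmented with the credible predicted interactions before ranking;
    otherwise the call delegates directly to link prediction and the KG is
    left untouched.
    """
    if drug_id not in conve_model.kg.entity_index:
        raise KeyError(
            f"{drug_id!r} is not a KG entity; the structure route covers "
            "target prediction only, not drug-info relations")
    model = conve_model
    if inject_predictions:
        extra = [(p.drug_id, DTI_RELATION, p.target_id)
                 for p in inject_predictions if p.credible]
        if kge_config is None:
            raise ValueError("re-training after injection needs a ConvEConfig")
        new_kg = conve_model.kg.with_extra_triples(extra)
        logger.info("re-training K model with %d injected credible DTIs "
                    "(%d -> %d triples)", len(extra),
                    len(conve_model.kg.triples), len(new_kg.triples))
        model = train_conve(new_kg, kge_config).model
    return kg_link_predict(model, drug_id, relation, top_k=top_k)


def write_predictions(results: list[PredictionResult], path) -> None:
    pd.DataFrame(
        [(r.drug_id, r.target_id, r.score, r.model_used, r.credible)
         for r in results],
        columns=["drug_id", "target_id", "score", "model_used", "credible"],
    ).to_csv(path, sep="\t", index=False)
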