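"""Modality routing, reverse screening, and K-model drug-info queries."""

import numpy as np
import pytest

from mdtips import data_io, workflows
from mdtips.data_io import DrugRecord
from mdtips.evaluation import pretrain_k_channel
from mdtips.fusion import ChannelInputs, train_fusion
from mdtips.kge import ConvEConfig, kg_link_predict, train_conve
from mdtips.router import (PredictionResult, PredictionSystem, dispatch,
                           predict_drug_info, resolve_modalities,
                           reverse_screen, write_predictions)


@pytest.fixture(scope="module")
def system(request):
    """KSE/KS/S models trained briefly on the tiny world."""
    world = request.getfixturevalue("tiny_world")
    res = request.getfixturevalue("tiny_resources")
    negs = data_io.sample_negatives(world.positives, world.drugs,
                                    world.targets, 2, seed=11)
    split = data_io.make_splits(world.positives + negs, n_repeats=1,
                                base_seed=0)[0]
    table = pretrain_k_channel(split, res)
    inputs = ChannelInputs(graphs=res.graphs, tokens=res.tokens,
                           store=res.store, kge_table=table)
    models = {}
    for label in ("KSE", "KS", "S"):
        cfg = workflows.desk_fusion_config(label, seed=0, epochs=6,
                                           min_epochs=0)
        models[label] = train_fusion(split, inputs, cfg,
                                     vocab=res.vocab).model
    return PredictionSystem(models=models, inputs=inputs, kg=world.kg)


def test_resolve_modalities(tiny_world, system):
    known = tiny_world.drugs[0]
    assert resolve_modalities(known, tiny_world.kg,
                              tiny_world.store) == frozenset("KSE")
    novel = DrugRecord("novel", "CCO")
    assert resolve_modalities(novel, tiny_world.kg,
                              tiny_world.store) == frozenset("S")
    assert resolve_modalities(novel, None, None) == frozenset("S")


def test_dispatch_priority():
    assert dispatch(frozenset("KSE")) == "KSE"
    assert dispatch(frozenset("KS")) == "KS"
    assert dispatch(frozenset("S")) == "S"
    assert dispatch(frozenset("SE")) == "S"   # no KSE without K
    with pytest.raises(ValueError):
        dispatch(frozenset())


def test_screen_uses_dispatched_model_and_defaults(tiny_world, system):
    """Default credibility threshold 0.7 and top-10 per drug."""
    results = reverse_screen(system, tiny_world.drugs[:3], tiny_world.targets)
    per_drug = {}
    for r in results:
        per_drug.setdefault(r.drug_id, []).append(r)
        assert r.model_used == "KSE"  # all modalities exist in the world
        assert r.credible and r.score > 0.7
    for rs in per_drug.values():
        assert len(rs) <= 10
        scores = [r.score for r in rs]
        assert scores == sorted(scores, reverse=True)


def test_novel_compound_routes_to_structure_model(tiny_world, system):
    novel = DrugRecord("novel_compound", "CCOc1ccccc1")
    system.inputs.graphs["novel_compound"] = \
        __import__("mdtips.chem_graph", fromlist=["smiles_to_graph"]
                   ).smiles_to_graph("CCOc1ccccc1")
    results = reverse_screen(system, [novel], tiny_world.targets,
                             threshold=0.0)
    assert results and all(r.model_used == "S" for r in results)


def test_high_threshold_gives_empty_credible_list(tiny_world, system):
    results = reverse_screen(system, tiny_world.drugs[:2], tiny_world.targets,
                             threshold=1.0)
    assert results == []


def test_screen_requires_targets_and_models(tiny_world, system):
    with pytest.raises(ValueError, match="universe"):
        reverse_screen(system, tiny_world.drugs[:1], [])
    bare = PredictionSystem(models={"S": system.models["S"]},
                            inputs=system.inputs, kg=tiny_world.kg)
    with pytest.raises(KeyError, match="KSE"):
        bare.model_for("KSE")


def test_prediction_result_validation():
    with pytest.raises(ValueError):
        PredictionResult("d", "t", 1.3, "KSE", True)


def test_predictions_tsv_round_trip(tmp_path):
    results = [PredictionResult("d1", "t1", 0.91, "KSE", True),
               PredictionResult("d2", "t2", 0.82, "S", True)]
    path = tmp_path / "predictions.tsv"
    write_predictions(results, path)
    text = path.read_text().splitlines()
    assert text[0].split("\t") == ["drug_id", "target_id", "score",
                                   "model_used", "credible"]
    assert len(text) == 3


# ----- drug-info prediction -------------------------------------------------

@pytest.fixture(scope="module")
def conve(tiny_world):
    cfg = ConvEConfig(k=16, k_w=4, k_h=4, n_filters=4, epochs=30, lr=1e-2,
                      seed=0)
    return train_conve(tiny_world.kg, cfg), cfg


def test_drug_info_delegates_to_link_prediction(tiny_world, conve):
    result, _ = conve
    drug = tiny_world.drugs[0].drug_id
    direct = kg_link_predict(result.model, drug, "treats", top_k=5)
    routed = predict_drug_info(result.model, drug, "treats", top_k=5)
    assert routed == direct


def test_drug_info_injection_grows_kg_by_credible_count(tiny_world, conve):
    result, cfg = conve
    n_before = len(result.model.kg.triples)
    preds = [PredictionResult(tiny_world.drugs[0].drug_id,
                              tiny_world.targets[j].target_id, 0.9, "KSE",
                              True) for j in range(3)]
    predict_drug_info(result.model, tiny_world.drugs[0].drug_id, "treats",
                      inject_predictions=preds, kge_config=cfg)
    # the original model and KG are untouched; retraining used an augmented copy
    assert len(result.model.kg.triples) == n_before
    augmented = result.model.kg.with_extra_triples(
        [(p.drug_id, "interacts_with", p.target_id) for p in preds])
    assert len(augmented.triples) == n_before + 3


def test_drug_info_unknown_drug_mentions_structure_route(conve):
    result, _ = conve
    with pytest.raises(KeyError, match="structure route"):
        predict_drug_info(result.model, "no_such_drug", "treats")
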