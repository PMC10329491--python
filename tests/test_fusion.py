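"""Late-fusion model: projections, classifier, training loop contracts."""

import numpy as np
import pytest

from mdtips import data_io, workflows
from mdtips.evaluation import pretrain_k_channel
from mdtips.fusion import (ChannelInputs, FusionConfig, FusionModel,
                           filter_modality_complete, modality_availability,
                           predict_pairs, prepare_pair_data, train_fusion)
from mdtips.nn import Tensor


@pytest.fixture(scope="module")
def tiny_setup(request):
    world = request.getfixturevalue("tiny_world")
    res = request.getfixturevalue("tiny_resources")
    negs = data_io.sample_negatives(world.positives, world.drugs,
                                    world.targets, 2, seed=11)
    split = data_io.make_splits(world.positives + negs, n_repeats=1,
                                base_seed=0)[0]
    table = pretrain_k_channel(split, res)
    inputs = ChannelInputs(graphs=res.graphs, tokens=res.tokens,
                           store=res.store, kge_table=table)
    return world, res, split, inputs


def quick_config(mods="KSE", **kw):
    defaults = dict(epochs=6, min_epochs=0, patience=10)
    defaults.update(kw)
    return workflows.desk_fusion_config(mods, seed=0, **defaults)


def test_projection_output_is_layer_normalized(tiny_setup, rng):
    _, res, _, inputs = tiny_setup
    model = FusionModel(quick_config("E"), inputs, vocab=res.vocab)
    model.eval()
    g = inputs.store.n_genes
    out = model.proj_E(Tensor(rng.normal(size=(5, g))),
                       Tensor(rng.normal(size=(5, g))))
    assert out.shape == (5, model.config.proj_dim)
    assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-4)


def test_zero_final_layer_scores_half(tiny_setup):
    _, res, split, inputs = tiny_setup
    cfg = quick_config("KSE")
    model = FusionModel(cfg, inputs, vocab=res.vocab)
    model.out.weight.data[:] = 0.0
    model.out.bias.data[:] = 0.0
    batch = prepare_pair_data(split.test, inputs, cfg)
    scores = model.predict_scores(batch)
    assert np.allclose(scores, 0.5)


def test_scores_strictly_inside_unit_interval(tiny_setup):
    _, res, split, inputs = tiny_setup
    cfg = quick_config("KS")
    model = FusionModel(cfg, inputs, vocab=res.vocab)
    scores = model.predict_scores(prepare_pair_data(split.test, inputs, cfg))
    assert np.all((scores > 0.0) & (scores < 1.0))


def test_classifier_rejects_wrong_latent_count(tiny_setup, rng):
    _, res, _, inputs = tiny_setup
    model = FusionModel(quick_config("KSE"), inputs, vocab=res.vocab)
    with pytest.raises(ValueError, match="latents"):
        model.classify([Tensor(rng.normal(size=(4, 32)))])


def test_modality_config_validation():
    with pytest.raises(ValueError, match="modalities"):
        FusionConfig(modalities="KSQ")
    with pytest.raises(ValueError, match="modalities"):
        FusionConfig(modalities="")
    assert FusionConfig(modalities="ESK").modalities == "KSE"  # canonical order


def test_availability_flags(tiny_setup):
    world, res, _, inputs = tiny_setup
    pair = data_io.DTPRecord(world.drugs[0].drug_id,
                             world.targets[0].target_id, 1, "inhibit")
    assert modality_availability(pair, inputs) == frozenset("KSE")
    stranger = data_io.DTPRecord("unknown_drug", world.targets[0].target_id,
                                 1, "inhibit")
    flags = modality_availability(stranger, inputs)
    assert "K" not in flags and "E" not in flags and "S" not in flags


def test_prepare_rejects_modality_incomplete_pair(tiny_setup):
    world, res, _, inputs = tiny_setup
    bad = data_io.DTPRecord("unknown_drug", world.targets[0].target_id, 0)
    with pytest.raises(ValueError, match="unavailable"):
        prepare_pair_data([bad], inputs, quick_config("K"))


def test_empty_training_set_error_lists_counts(tiny_setup):
    world, res, split, _ = tiny_setup
    # inputs with no KG table: K-complete training set is empty
    inputs = ChannelInputs(graphs=res.graphs, tokens=res.tokens,
                           store=res.store, kge_table=None)
    with pytest.raises(ValueError, match="availability"):
        train_fusion(split, inputs, quick_config("K"), vocab=res.vocab)


def test_training_reduces_bce_and_is_reproducible(tiny_setup):
    """Same seed, same data: identical loss/metric trajectories."""
    _, res, split, inputs = tiny_setup
    cfg = quick_config("KE", epochs=12)
    t1 = train_fusion(split, inputs, cfg, vocab=res.vocab)
    t2 = train_fusion(split, inputs, cfg, vocab=res.vocab)
    assert t1.history[-1]["train_loss"] < t1.history[0]["train_loss"]
    assert t1.history == t2.history
    p1 = {k: v for k, v in t1.model.named_parameters().items()}
    p2 = {k: v for k, v in t2.model.named_parameters().items()}
    for k in p1:
        assert np.array_equal(p1[k].data, p2[k].data)


def test_prediction_order_independent(tiny_setup):
    _, res, split, inputs = tiny_setup
    cfg = quick_config("KSE", epochs=3)
    trained = train_fusion(split, inputs, cfg, vocab=res.vocab)
    pairs = split.test
    fwd = dict((p.key, s) for p, s in
               predict_pairs(trained.model, pairs, inputs))
    rev = dict((p.key, s) for p, s in
               predict_pairs(trained.model, list(reversed(pairs)), inputs))
    for key in fwd:
        assert abs(fwd[key] - rev[key]) < 1e-6


def test_freeze_kge_keeps_entity_table_fixed(tiny_setup):
    _, res, split, inputs = tiny_setup
    before = inputs.kge_table.entity_vectors.copy()
    cfg = quick_config("K", epochs=4, freeze_kge=True)
    trained = train_fusion(split, inputs, cfg, vocab=res.vocab)
    assert np.array_equal(trained.model.k_emb.weight.data, before)
    cfg2 = quick_config("K", epochs=4, freeze_kge=False)
    trained2 = train_fusion(split, inputs, cfg2, vocab=res.vocab)
    assert not np.array_equal(trained2.model.k_emb.weight.data, before)


def test_filter_modality_complete_counts(tiny_setup):
    world, res, split, inputs = tiny_setup
    pairs = split.train
    complete, incomplete, counts = filter_modality_complete(pairs, inputs,
                                                            "KSE")
    assert len(complete) + len(incomplete) == len(pairs)
    assert counts["S"] == len(pairs)  # every simulated pair has structure


def test_checkpoint_round_trip(tiny_setup, tmp_path):
    _, res, split, inputs = tiny_setup
    cfg = quick_config("KSE", epochs=3)
    trained = train_fusion(split, inputs, cfg, vocab=res.vocab)
    batch = prepare_pair_data(split.test, inputs, cfg)
    before = trained.model.predict_scores(batch)
    workflows.save_fusion_model(trained.model, tmp_path, vocab=res.vocab,
                                kge_table=inputs.kge_table)
    model, loaded_inputs, vocab = workflows.load_fusion_model(
        tmp_path, store=res.store)
    loaded_inputs.graphs, loaded_inputs.tokens = res.graphs, res.tokens
    after = model.predict_scores(
        prepare_pair_data(split.test, loaded_inputs, model.config))
    assert np.allclose(before, after, atol=1e-12)
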