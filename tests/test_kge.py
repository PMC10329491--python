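"""ConvE knowledge-graph embedding: scoring, training, ranking, leakage."""

import numpy as np
import pytest

from mdtips.data_io import DTPRecord
from mdtips.kge import (ConvEConfig, ConvEModel, EmbeddingTable,
                        KnowledgeGraph, LeakageError, build_k_channel,
                        filtered_ranks, kg_link_predict, train_conve)

TOY_CONFIG = ConvEConfig(k=16, k_w=4, k_h=4, n_filters=4, epochs=200,
                         lr=1e-2, batch_size=64, seed=0)


def toy_kg() -> KnowledgeGraph:
    """Planted 2-community KG: 20 members + 2 hubs, 2 relations, 60 triples.

    Every member is attached to its community hub and "linked" edges only
    join members of the same community, so held-out links are predictable
    from the community structure.
    """
    rng = np.random.default_rng(0)
    comm = {f"e{i}": i % 2 for i in range(20)}
    triples = [(f"e{i}", "in_group", f"hub{i % 2}") for i in range(20)]
    links: set = set()
    while len(links) < 40:
        a, b = rng.choice(20, size=2, replace=False)
        if comm[f"e{a}"] == comm[f"e{b}"]:
            links.add((f"e{a}", "linked", f"e{b}"))
    entities = [f"e{i}" for i in range(20)] + ["hub0", "hub1"]
    return KnowledgeGraph(entities, ["in_group", "linked"],
                          triples + sorted(links))


@pytest.fixture(scope="module")
def trained():
    return train_conve(toy_kg(), TOY_CONFIG)


def test_kg_validation():
    with pytest.raises(ValueError, match="unknown entity"):
        KnowledgeGraph(["a"], ["r"], [("a", "r", "b")])
    with pytest.raises(ValueError, match="duplicate triples"):
        KnowledgeGraph(["a", "b"], ["r"], [("a", "r", "b"), ("a", "r", "b")])


def test_config_reshape_invariant():
    with pytest.raises(ValueError, match="k_w"):
        ConvEConfig(k=16, k_w=5, k_h=4)


def test_zero_projection_gives_zero_scores():
    kg = toy_kg()
    model = ConvEModel(kg, TOY_CONFIG)
    model.eval()
    model.fc.data[:] = 0.0
    model.fc_bias.data[:] = 0.0
    model.ent_bias.data[:] = 0.0
    logits = model.score_all_tails(np.array([0, 3]), np.array([0, 1]))
    assert np.array_equal(logits.data, np.zeros_like(logits.data))


def test_batched_one_to_n_scoring_equals_per_triple_loop(trained):
    """The 1-N scoring row reproduces loop-wise single-triple scores."""
    model = trained.model
    kg = model.kg
    model.eval()
    rows = model.score_all_tails(np.array([0, 5]), np.array([0, 1])).data
    for b, (h, r) in enumerate([("e0", "in_group"), ("e5", "linked")]):
        for t in kg.entities:
            assert abs(rows[b, kg.entity_index[t]]
                       - model.score(h, r, t)) < 1e-5


def test_training_reduces_loss(trained):
    assert trained.losses[-1] < trained.losses[0]
    assert np.isfinite(trained.losses).all()


def test_same_seed_identical_tables():
    a = train_conve(toy_kg(), ConvEConfig(k=16, k_w=4, k_h=4, n_filters=4,
                                          epochs=20, lr=1e-2, seed=0))
    b = train_conve(toy_kg(), ConvEConfig(k=16, k_w=4, k_h=4, n_filters=4,
                                          epochs=20, lr=1e-2, seed=0))
    assert np.abs(a.table.entity_vectors - b.table.entity_vectors).max() < 1e-6


def held_out_split():
    kg = toy_kg()
    rng = np.random.default_rng(1)
    linked = [t for t in kg.triples if t[1] == "linked"]
    idx = rng.permutation(len(linked))
    held_out = [linked[i] for i in idx[:10]]
    train_triples = [t for t in kg.triples if t not in held_out]
    return (KnowledgeGraph(kg.entities, kg.relations, train_triples),
            held_out, train_triples)


def test_trained_beats_random_filtered_rank():
    """Held-out true tails rank higher under trained than random embeddings
    in every one of three seeded repeats."""
    train_kg, held_out, train_triples = held_out_split()
    for seed in range(3):
        cfg = ConvEConfig(k=16, k_w=4, k_h=4, n_filters=4, epochs=300,
                          lr=1e-2, seed=seed, label_smoothing=0.1)
        result = train_conve(train_kg, cfg)
        random_model = ConvEModel(train_kg, cfg,
                                  rng=np.random.default_rng(seed + 50))
        random_model.eval()
        trained_mr = filtered_ranks(result.model, held_out,
                                    train_triples).mean()
        random_mr = filtered_ranks(random_model, held_out,
                                   train_triples).mean()
        assert trained_mr < random_mr


def test_non_finite_loss_aborts(monkeypatch):
    """A non-finite training loss aborts with a diagnostic."""
    import mdtips.kge as kge_mod
    from mdtips.nn import Tensor

    def poisoned(logits, targets, weights=None):
        return Tensor(np.array(np.nan))

    monkeypatch.setattr(kge_mod, "bce_with_logits", poisoned)
    with pytest.raises(RuntimeError, match="diverged"):
        train_conve(toy_kg(), ConvEConfig(k=16, k_w=4, k_h=4, n_filters=4,
                                          epochs=5, lr=1e-2, seed=0))


def test_embedding_table_save_load(tmp_path, trained):
    trained.table.save(tmp_path / "e.tsv", tmp_path / "r.tsv")
    loaded = EmbeddingTable.load(tmp_path / "e.tsv", tmp_path / "r.tsv")
    assert np.allclose(loaded.entity_vectors, trained.table.entity_vectors)
    assert loaded.entity_index == trained.table.entity_index


def test_table_lookup_unknown_entity(trained):
    with pytest.raises(KeyError, match="unavailable"):
        trained.table.entity("nonexistent")


# ----- leakage guard --------------------------------------------------------

def _pairs(keys, label=1):
    return [DTPRecord(d, t, label) for d, t in keys]


def test_guard_fires_on_eval_pair_in_support_kg():
    kg = KnowledgeGraph.from_triples(
        [("d1", "interacts_with", "t1"), ("d2", "in_pathway", "p1"),
         ("t2", "in_pathway", "p1")])
    with pytest.raises(LeakageError, match="support KG"):
        build_k_channel(kg, _pairs([("d2", "t2")]), _pairs([("d1", "t1")]),
                        TOY_CONFIG)


def test_guard_fires_on_eval_pair_in_train_positives():
    kg = KnowledgeGraph.from_triples([("d1", "in_pathway", "p1")])
    with pytest.raises(LeakageError, match="training positives"):
        build_k_channel(kg, _pairs([("d1", "t1")]), _pairs([("d1", "t1")]),
                        TOY_CONFIG)


def test_guard_checks_any_relation_between_the_pair():
    kg = KnowledgeGraph.from_triples([("d1", "binds", "t1")])
    with pytest.raises(LeakageError):
        build_k_channel(kg, [], _pairs([("d1", "t1")]), TOY_CONFIG)


def test_k_channel_trains_when_clean():
    cfg = ConvEConfig(k=16, k_w=4, k_h=4, n_filters=4, epochs=10, lr=1e-2,
                      seed=0)
    kg = KnowledgeGraph.from_triples(
        [("d1", "in_pathway", "p1"), ("t1", "in_pathway", "p1"),
         ("d2", "in_pathway", "p1"), ("t2", "in_pathway", "p1")])
    result = build_k_channel(kg, _pairs([("d1", "t1")]),
                             _pairs([("d2", "t2")]), cfg)
    for name in ["d1", "t1", "d2", "t2"]:
        assert result.table.entity(name).shape == (16,)


# ----- link prediction ------------------------------------------------------

def test_link_predict_matches_brute_force_loop(trained):
    model = trained.model
    ranked = kg_link_predict(model, "e0", "linked", top_k=None)
    known = {t for h, r, t in model.kg.triples
             if h == "e0" and r == "linked"}
    brute = sorted(((t, model.score("e0", "linked", t))
                    for t in model.kg.entities if t not in known),
                   key=lambda x: -x[1])
    assert [e for e, _ in ranked] == [e for e, _ in brute]
    assert ranked[0][1] >= ranked[-1][1]


def test_link_predict_filters_known_and_truncates(trained):
    known = {t for h, r, t in trained.model.kg.triples
             if h == "e0" and r == "linked"}
    full = kg_link_predict(trained.model, "e0", "linked", top_k=1000)
    n_entities = len(trained.model.kg.entities)
    assert len(full) == n_entities - len(known)  # top_k beyond entity count
    assert not known & {e for e, _ in full}
    top3 = kg_link_predict(trained.model, "e0", "linked", top_k=3)
    assert full[:3] == top3


def test_link_predict_unknown_head(trained):
    with pytest.raises(KeyError):
        kg_link_predict(trained.model, "nope", "linked")
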