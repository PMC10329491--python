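"""Synthetic fixture world: a coherent toy drug-target universe.

The generator plants a cross-modality interaction signal so that every stage
of the pipeline — graph featurization, sequence tokenization, knowledge-graph
embedding, signature lookup, fusion, ablation — can be exercised offline:

- each drug and target carries a latent structure trait (2-D, +/-1 entries),
  a community id, and a latent expression factor (2-D Gaussian), all
  independent of one another;
- drug SMILES are composed from a closed, valence-safe fragment grammar whose
  fragment mix reflects the structure trait (aromatic vs aliphatic content,
  nitrogen vs oxygen chemistry), so the trait is recoverable from the graph;
- target sequences are sampled with trait-dependent residue composition
  (hydrophobic/polar, basic/acidic);
- the knowledge graph connects drugs and targets to per-community pathway
  hubs and community-assigned diseases, plus side-effect edges;
- signature rows are noisy linear images of the expression factors over a
  G-gene panel (overexpression and knockdown rows share the latent loading);
- interaction propensity is a weighted sum of community match, structure
  trait affinity and expression-factor affinity plus Gaussian noise; the top
  ``positive_rate`` fraction of all pairs become labeled positives, with the
  interaction direction set by the target's expression factor sign.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from . import data_io
from .data_io import DrugRecord, DTPRecord, TargetRecord
from .expr import SignatureStore
from .kge import KnowledgeGraph

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "World", "simulate_world", "write_world", "load_world"]

AROMATIC_FRAGMENTS = ["c1ccccc1", "c1ccncc1", "Cc1ccccc1"]
ALIPHATIC_FRAGMENTS = ["CC", "CCC", "C(C)C", "C1CCCCC1"]
NITROGEN_FRAGMENTS = ["CN", "NC", "CNC", "N"]
OXYGEN_FRAGMENTS = ["CO", "OC", "C(=O)", "O"]

HYDROPHOBIC = "AVLIF"
POLAR = "STNQY"
BASIC = "KRH"
ACIDIC = "DE"
BACKGROUND = "GMCWP"


@dataclass
class SimConfig:
    n_drugs: int = 60
    n_targets: int = 80
    n_kg_extra_entities: int = 40     # diseases + side effects
    n_communities: int = 4
    G: int = 50                       # gene-panel size (978 in real data)
    signal_weights: tuple[float, float, float] = (1.5, 1.0, 1.0)  # (w_K, w_S, w_E)
    noise_sd: float = 0.5
    positive_rate: float = 0.1
    seq_len_range: tuple[int, int] = (50, 400)
    seed: int = 0

    def __post_init__(self):
        if any(w < 0 for w in self.signal_weights):
            raise ValueError("signal weights must be nonnegative")
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError("positive_rate must be in (0, 1)")
        if max(self.signal_weights) == 0 and self.noise_sd == 0:
            raise ValueError("degenerate config: all signal weights zero and "
                             "no noise — propensities would be constant")


@dataclass
class World:
    config: SimConfig
    drugs: list[DrugRecord]
    targets: list[TargetRecord]
    kg: KnowledgeGraph
    store: SignatureStore
    positives: list[DTPRecord]
    # latent state, kept for diagnostics and tests
    drug_traits: np.ndarray = field(repr=False, default=None)
    target_traits: np.ndarray = field(repr=False, default=None)
    drug_communities: np.ndarray = field(repr=False, default=None)
    target_communities: np.ndarray = field(repr=False, default=None)


def _sample_smiles(rng: np.random.Generator, trait: np.ndarray) -> str:
    """Trait-biased fragment composition; guaranteed parseable."""
    w_arom = 0.50 if trait[0] > 0 else 0.06
    w_ali = 0.56 - w_arom
    w_n = 0.38 if trait[1] > 0 else 0.06
    w_o = 0.44 - w_n
    pools = [AROMATIC_FRAGMENTS, ALIPHATIC_FRAGMENTS,
             NITROGEN_FRAGMENTS, OXYGEN_FRAGMENTS]
    weights = np.array([w_arom, w_ali, w_n, w_o])
    weights = weights / weights.sum()
    while True:
        n_frags = rng.integers(3, 7)
        parts = []
        for _ in range(n_frags):
            pool = pools[rng.choice(4, p=weights)]
            parts.append(pool[rng.integers(len(pool))])
        smiles = "".join(parts)
        if Chem.MolFromSmiles(smiles) is not None:  # grammar is valence-safe
            return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))


def _sample_sequence(rng: np.random.Generator, trait: np.ndarray,
                     length: int) -> str:
    p_h = 0.45 if trait[0] > 0 else 0.10
    p_p = 0.55 - p_h
    p_b = 0.28 if trait[1] > 0 else 0.05
    p_a = 0.33 - p_b
    p_bg = 1.0 - (p_h + p_p + p_b + p_a)
    pools = [HYDROPHOBIC, POLAR, BASIC, ACIDIC, BACKGROUND]
    probs = [p_h, p_p, p_b, p_a, p_bg]
    letters = []
    for _ in range(length):
        pool = pools[rng.choice(5, p=probs)]
        letters.append(pool[rng.integers(len(pool))])
    return "".join(letters)


def simulate_world(config: SimConfig) -> World:
    rng = np.random.default_rng(config.seed)
    nd, nt = config.n_drugs, config.n_targets

    drug_traits = rng.choice([-1.0, 1.0], size=(nd, 2))
    target_traits = rng.choice([-1.0, 1.0], size=(nt, 2))
    drug_comm = rng.integers(config.n_communities, size=nd)
    target_comm = rng.integers(config.n_communities, size=nt)
    drug_factor = rng.normal(size=(nd, 2))
    target_factor = rng.normal(size=(nt, 2))

    drugs = [DrugRecord(f"drug_{i:03d}", _sample_smiles(rng, drug_traits[i]))
             for i in range(nd)]
    lo, hi = config.seq_len_range
    targets = [TargetRecord(f"target_{j:03d}",
                            _sample_sequence(rng, target_traits[j],
                                             int(rng.integers(lo, hi + 1))))
               for j in range(nt)]

    # --- knowledge graph ---------------------------------------------------
    triples: list[tuple[str, str, str]] = []
    for i, d in enumerate(drugs):
        triples.append((d.drug_id, "in_pathway", f"pathway_{drug_comm[i]}"))
    for j, t in enumerate(targets):
        triples.append((t.target_id, "in_pathway", f"pathway_{target_comm[j]}"))
    # within-community neighbor edges make the community recoverable from
    # graph structure alone (the K channel's planted signal)
    for i in range(nd):
        peers = [drugs[p].drug_id for p in range(nd)
                 if p != i and drug_comm[p] == drug_comm[i]]
        for p in rng.choice(peers, size=min(2, len(peers)), replace=False):
            triples.append((drugs[i].drug_id, "similar_to", p))
    for j in range(nt):
        peers = [targets[p].target_id for p in range(nt)
                 if p != j and target_comm[p] == target_comm[j]]
        for p in rng.choice(peers, size=min(2, len(peers)), replace=False):
            triples.append((targets[j].target_id, "functions_with", p))
    n_dis = config.n_kg_extra_entities // 2
    n_se = config.n_kg_extra_entities - n_dis
    dis_comm = rng.integers(config.n_communities, size=n_dis)
    for e in range(n_dis):
        disease = f"disease_{e:03d}"
        same_comm_drugs = [drugs[i].drug_id for i in range(nd)
                           if drug_comm[i] == dis_comm[e]]
        same_comm_targets = [targets[j].target_id for j in range(nt)
                             if target_comm[j] == dis_comm[e]]
        for d in rng.choice(same_comm_drugs, size=min(3, len(same_comm_drugs)),
                            replace=False):
            triples.append((d, "treats", disease))
        for t in rng.choice(same_comm_targets,
                            size=min(2, len(same_comm_targets)), replace=False):
            triples.append((t, "associated_with", disease))
    for e in range(n_se):
        se = f"side_effect_{e:03d}"
        for d in rng.choice([d.drug_id for d in drugs], size=3, replace=False):
            triples.append((d, "causes", se))
    kg = KnowledgeGraph.from_triples(list(dict.fromkeys(triples)))

    # --- expression signatures --------------------------------------------
    loading_d = rng.normal(size=(config.G, 2))
    loading_t = rng.normal(size=(config.G, 2))
    genes = [f"gene_{g:03d}" for g in range(config.G)]
    m_d = drug_factor @ loading_d.T + 0.3 * rng.normal(size=(nd, config.G))
    # overexpression and knockdown rows share the latent loading (independent
    # noise); see the methods note for why the fixture does not anti-correlate
    # them the way real perturbation pairs are
    m_oe = target_factor @ loading_t.T + 0.3 * rng.normal(size=(nt, config.G))
    m_xpr = target_factor @ loading_t.T + 0.3 * rng.normal(size=(nt, config.G))
    store = SignatureStore(
        pd.DataFrame(m_d, index=[d.drug_id for d in drugs], columns=genes),
        pd.DataFrame(m_oe, index=[t.target_id for t in targets], columns=genes),
        pd.DataFrame(m_xpr, index=[t.target_id for t in targets], columns=genes))

    # --- planted interactions ---------------------------------------------
    w_k, w_s, w_e = config.signal_weights
    comm_match = (drug_comm[:, None] == target_comm[None, :]).astype(float)
    trait_aff = 0.5 * (drug_traits @ target_traits.T)
    factor_aff = 0.5 * (drug_factor @ target_factor.T)
    propensity = (w_k * comm_match + w_s * trait_aff + w_e * factor_aff
                  + config.noise_sd * rng.normal(size=(nd, nt)))
    n_pos = max(1, int(round(config.positive_rate * nd * nt)))
    flat_order = np.argsort(-propensity, axis=None)[:n_pos]
    positives = []
    for flat in flat_order:
        i, j = np.unravel_index(flat, propensity.shape)
        direction = "activate" if target_factor[j, 0] > 0 else "inhibit"
        positives.append(DTPRecord(drugs[i].drug_id, targets[j].target_id, 1,
                                   direction))
    logger.info("simulated world: %d drugs, %d targets, %d triples, "
                "%d positives", nd, nt, len(kg.triples), len(positives))
    return World(config, drugs, targets, kg, store, positives,
                 drug_traits=drug_traits, target_traits=target_traits,
                 drug_communities=drug_comm, target_communities=target_comm)


def write_world(world: World, out_dir) -> dict[str, Path]:
    """Emit the on-disk fixture formats; write-then-load reproduces the world."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": out / "drugs.tsv",
        "targets": out / "targets.fasta",
        "kg": out / "kg.tsv",
        "pairs": out / "pairs.tsv",
    }
    data_io.write_drugs(world.drugs, paths["drugs"])
    data_io.write_targets(world.targets, paths["targets"])
    data_io.write_triples(world.kg.triples, paths["kg"])
    data_io.write_pairs(world.positives, paths["pairs"])
    sig_paths = data_io.write_signatures(world.store, out)
    paths.update({f"signatures_{k}": v for k, v in sig_paths.items()})
    return paths


def load_world(dir_path) -> World:
    """Load a written world back from disk (latent state is not recoverable)."""
    d = Path(dir_path)
    drugs = data_io.load_drugs(d / "drugs.tsv")
    targets = data_io.load_targets(d / "targets.fasta")
    kg = KnowledgeGraph.from_triples(data_io.load_triples(d / "kg.tsv"))
    store = data_io.load_signatures(d / "signatures_D.tsv",
                                    d / "signatures_OE.tsv",
                                    d / "signatures_XPR.tsv")
    positives = data_io.load_pairs(d / "pairs.tsv")
    return World(None, drugs, targets, kg, store, positives)
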