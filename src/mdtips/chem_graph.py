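"""SMILES to molecular graphs with fixed-width atom and bond feature vectors.

A drug is represented as its heavy-atom graph: nodes are atoms, edges are
chemical bonds (each bond emits two directed edges with identical features).
Atom vectors are 39-dimensional and bond vectors 11-dimensional.  Formal
charge and radical-electron count are encoded as signed integers; every other
feature is a one-hot block (with an "other" bucket absorbing out-of-set
values) or a binary flag.

The schema is a data table (:data:`ATOM_SCHEMA` / :data:`BOND_SCHEMA`), not
hard-coded logic, so an alternative feature inventory can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")  # SMILES parse errors are reported by us

__all__ = [
    "MolecularGraph", "FeaturizationError",
    "featurize_atom", "featurize_bond", "smiles_to_graph",
    "ATOM_FEATURE_DIM", "BOND_FEATURE_DIM",
]


class FeaturizationError(ValueError):
    pass


def _one_hot(value, choices: list, other_bucket: bool) -> list[float]:
    vec = [0.0] * (len(choices) + (1 if other_bucket else 0))
    if value in choices:
        vec[choices.index(value)] = 1.0
    elif other_bucket:
        vec[-1] = 1.0
    return vec


def _clip_one_hot(value: int, top: int) -> list[float]:
    """One-hot over 0..top with values above the range clipped to the top bucket."""
    vec = [0.0] * (top + 1)
    vec[min(value, top)] = 1.0
    return vec


# (name, encoder) pairs; each encoder maps an RDKit atom to a list of floats.
ATOM_SCHEMA = [
    ("element", lambda a: _one_hot(
        a.GetSymbol(),
        ["B", "C", "N", "O", "F", "Si", "P", "S",
         "Cl", "As", "Se", "Br", "Te", "I", "At"], other_bucket=True)),   # 16
    ("degree", lambda a: _clip_one_hot(a.GetDegree(), 5)),                # 6
    ("formal_charge", lambda a: [float(a.GetFormalCharge())]),            # 1
    ("radical_electrons", lambda a: [float(a.GetNumRadicalElectrons())]), # 1
    ("hybridization", lambda a: _one_hot(
        a.GetHybridization(),
        [Chem.HybridizationType.SP, Chem.HybridizationType.SP2,
         Chem.HybridizationType.SP3, Chem.HybridizationType.SP3D,
         Chem.HybridizationType.SP3D2], other_bucket=True)),              # 6
    ("aromatic", lambda a: [1.0 if a.GetIsAromatic() else 0.0]),          # 1
    ("total_h", lambda a: _clip_one_hot(a.GetTotalNumHs(), 4)),           # 5
    ("chiral_center", lambda a: [1.0 if a.HasProp("_ChiralityPossible") else 0.0]),  # 1
    ("chirality_type", lambda a: _one_hot(
        a.GetPropsAsDict().get("_CIPCode", ""), ["R", "S"],
        other_bucket=False)),                                             # 2
]

BOND_SCHEMA = [
    ("bond_type", lambda b: _one_hot(
        b.GetBondType(),
        [Chem.BondType.SINGLE, Chem.BondType.DOUBLE,
         Chem.BondType.TRIPLE, Chem.BondType.AROMATIC],
        other_bucket=False)),                                             # 4
    ("conjugated", lambda b: [1.0 if b.GetIsConjugated() else 0.0]),      # 1
    ("in_ring", lambda b: [1.0 if b.IsInRing() else 0.0]),                # 1
    ("stereo", lambda b: _one_hot(
        b.GetStereo(),
        [Chem.BondStereo.STEREONONE, Chem.BondStereo.STEREOANY,
         Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOE,
         Chem.BondStereo.STEREOCIS], other_bucket=False)),                # 5
]

ATOM_FEATURE_DIM = 39
BOND_FEATURE_DIM = 11


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one molecule (possibly multi-fragment)."""

    n_atoms: int
    atom_features: np.ndarray          # (n_atoms, 39)
    edges: np.ndarray                  # (n_edges, 2) directed pairs
    edge_features: np.ndarray          # (n_edges, 11)
    smiles: str = ""

    def __post_init__(self):
        assert self.atom_features.shape == (self.n_atoms, ATOM_FEATURE_DIM)
        assert self.edge_features.shape == (len(self.edges), BOND_FEATURE_DIM)
        if len(self.edges):
            assert self.edges.min() >= 0 and self.edges.max() < self.n_atoms


def featurize_atom(atom: Chem.Atom, schema=None) -> np.ndarray:
    schema = ATOM_SCHEMA if schema is None else schema
    try:
        vec = [x for _, enc in schema for x in enc(atom)]
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        raise FeaturizationError(
            f"cannot featurize atom index {atom.GetIdx()}: {exc}") from exc
    return np.asarray(vec, dtype=np.float64)


def featurize_bond(bond: Chem.Bond, schema=None) -> np.ndarray:
    schema = BOND_SCHEMA if schema is None else schema
    vec = [x for _, enc in schema for x in enc(bond)]
    return np.asarray(vec, dtype=np.float64)


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Build the featurized heavy-atom graph for a SMILES string.

    Hydrogens stay implicit (folded into the total-H atom feature); each
    chemical bond contributes two directed edges carrying the same features.
    Multi-fragment SMILES become disconnected components of one graph.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True,
                               flagPossibleStereoCenters=True)
    atom_feats = np.zeros((mol.GetNumAtoms(), ATOM_FEATURE_DIM))
    for atom in mol.GetAtoms():
        atom_feats[atom.GetIdx()] = featurize_atom(atom)
    edges, edge_feats = [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        edges.append((u, v))
        edge_feats.append(f)
        edges.append((v, u))
        edge_feats.append(f)
    edges_arr = (np.asarray(edges, dtype=np.intp) if edges
                 else np.zeros((0, 2), dtype=np.intp))
    feats_arr = (np.asarray(edge_feats) if edge_feats
                 else np.zeros((0, BOND_FEATURE_DIM)))
    return MolecularGraph(mol.GetNumAtoms(), atom_feats, edges_arr, feats_arr,
                          smiles=smiles)


def write_graph_tsv(graph: MolecularGraph, path) -> None:
    """Debug writer: dump a graph as an edge-list TSV."""
    with open(path, "w") as fh:
        fh.write(f"# smiles={graph.smiles} n_atoms={graph.n_atoms}\n")
        for (u, v), f in zip(graph.edges, graph.edge_features):
            fh.write(f"{u}\t{v}\t" + "\t".join(f"{x:g}" for x in f) + "\n")
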