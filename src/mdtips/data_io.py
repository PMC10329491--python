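"""Readers/writers for the on-disk formats, dataset assembly and splitting.

Formats
-------
- ``drugs.tsv``: ``drug_id<TAB>smiles`` with a header row.
- ``targets.fasta``: standard FASTA; the record id is the target id.
- ``kg.tsv``: ``head<TAB>relation<TAB>tail``, no header.
- ``signatures_{D,OE,XPR}.tsv``: first column the perturbagen id, remaining
  columns the shared gene panel (header row = gene identifiers).
- ``pairs.tsv``: ``drug_id<TAB>target_id<TAB>label<TAB>direction``.

Dataset assembly draws unlabeled negatives uniformly from the complement of
the positive (drug, target) set at a fixed negatives-per-positive ratio, and
evaluation uses repeated random 8:1:1 train/validation/test partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem

logger = logging.getLogger(__name__)

DIRECTIONS = ("activate", "inhibit", "unknown")

__all__ = [
    "DrugRecord", "TargetRecord", "DTPRecord", "DatasetSplit",
    "canonicalize_smiles", "load_drugs", "load_targets", "load_triples",
    "load_signatures", "load_pairs", "sample_negatives", "make_splits",
    "write_drugs", "write_targets", "write_triples", "write_signatures",
    "write_pairs",
]


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str  # canonical


@dataclass(frozen=True)
class TargetRecord:
    target_id: str
    sequence: str


@dataclass(frozen=True)
class DTPRecord:
    drug_id: str
    target_id: str
    label: int
    direction: str = "unknown"
    modality_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, "
                             f"got {self.direction!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_id, self.target_id)


@dataclass
class DatasetSplit:
    train: list
    valid: list
    test: list
    split_seed: int
    ratio: tuple[float, float, float] = (0.8, 0.1, 0.1)

    @property
    def parts(self):
        return {"train": self.train, "valid": self.valid, "test": self.test}


def canonicalize_smiles(smiles: str) -> str:
    """Return RDKit's canonical SMILES; idempotent by construction."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")


def load_drugs(path) -> list[DrugRecord]:
    """Load the drug table, canonicalizing SMILES.

    Rows with unparseable SMILES are dropped with a logged warning; duplicate
    drug ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["drug_id", "smiles"], path)
    if df["drug_id"].duplicated().any():
        dups = df.loc[df["drug_id"].duplicated(), "drug_id"].tolist()
        raise ValueError(f"{path}: duplicate drug ids {dups}")
    records = []
    for row in df.itertuples():
        try:
            records.append(DrugRecord(row.drug_id, canonicalize_smiles(row.smiles)))
        except ValueError as exc:
            logger.warning("dropping drug %s: %s", row.drug_id, exc)
    logger.info("loaded %d drugs from %s", len(records), path)
    return records


def load_targets(path) -> list[TargetRecord]:
    """Load protein sequences from FASTA (record id = target id)."""
    records, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate target id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            logger.warning("dropping target %s: empty sequence", rec.id)
            continue
        records.append(TargetRecord(rec.id, seq))
    logger.info("loaded %d targets from %s", len(records), path)
    return records


def load_triples(path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["head", "relation", "tail"], dtype=str)
    if df.isna().any().any():
        raise ValueError(f"{path}: malformed triple rows")
    triples = list(df.itertuples(index=False, name=None))
    logger.info("loaded %d triples from %s", len(triples), path)
    return triples


def load_signatures(path_d, path_oe, path_xpr):
    """Load the three consensus-signature matrices into a SignatureStore."""
    from .expr import SignatureStore  # avoid import cycle

    frames = {}
    for name, path in [("D", path_d), ("OE", path_oe), ("XPR", path_xpr)]:
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.duplicated().any():
            raise ValueError(f"{path}: duplicate perturbagen ids")
        frames[name] = df
        logger.info("loaded %d %s signatures from %s", len(df), name, path)
    panels = [tuple(frames[k].columns) for k in ("D", "OE", "XPR")]
    if len(set(panels)) != 1:
        raise ValueError("signature files do not share an identical gene panel")
    return SignatureStore(frames["D"], frames["OE"], frames["XPR"])


def load_pairs(path) -> list[DTPRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["drug_id", "target_id", "label", "direction"], path)
    records = []
    for row in df.itertuples():
        if row.label not in ("0", "1"):
            raise ValueError(f"{path}: label outside {{0,1}}: {row.label!r}")
        records.append(DTPRecord(row.drug_id, row.target_id, int(row.label),
                                 row.direction))
    logger.info("loaded %d pairs from %s", len(records), path)
    return records


def sample_negatives(positives: list[DTPRecord], drugs: list[DrugRecord],
                     targets: list[TargetRecord], ratio: int,
                     seed: int) -> list[DTPRecord]:
    """Under-sample unlabeled pairs as negatives at ``ratio`` per positive.

    Negatives are drawn uniformly without replacement from the complement of
    the positive (drug, target) set over the full n x m pair grid, carry label
    0 and direction ``unknown``, and are fully determined by ``seed``.
    """
    if ratio < 1 or int(ratio) != ratio:
        raise ValueError(f"ratio must be a positive integer, got {ratio}")
    pos_keys = {p.key for p in positives}
    n_grid = len(drugs) * len(targets)
    n_needed = int(ratio) * len(positives)
    n_available = n_grid - len(pos_keys)
    if n_needed > n_available:
        max_ratio = n_available // max(len(positives), 1)
        raise ValueError(
            f"complement has only {n_available} pairs; cannot sample "
            f"{n_needed}; maximum feasible ratio is {max_ratio}")
    rng = np.random.default_rng(seed)
    drug_ids = [d.drug_id for d in drugs]
    target_ids = [t.target_id for t in targets]
    chosen: list[DTPRecord] = []
    chosen_keys: set[tuple[str, str]] = set()
    # rejection sampling against the positive hash set
    while len(chosen) < n_needed:
        di = rng.integers(len(drug_ids))
        ti = rng.integers(len(target_ids))
        key = (drug_ids[di], target_ids[ti])
        if key in pos_keys or key in chosen_keys:
            continue
        chosen_keys.add(key)
        chosen.append(DTPRecord(key[0], key[1], 0, "unknown"))
    return chosen


def make_splits(records: list, n_repeats: int = 10,
                ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
                base_seed: int = 0) -> list[DatasetSplit]:
    """Repeated random partitions into train/valid/test at the given ratio.

    Repeat ``i`` is seeded ``base_seed + i``; each repeat is an exact
    partition (disjoint and exhaustive).
    """
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    if not np.isclose(sum(ratio), 1.0):
        raise ValueError(f"split ratio must sum to 1, got {ratio}")
    splits = []
    for i in range(n_repeats):
        seed = base_seed + i
        perm = np.random.default_rng(seed).permutation(n)
        n_train = int(round(ratio[0] * n))
        n_valid = int(round(ratio[1] * n))
        train = [records[j] for j in perm[:n_train]]
        valid = [records[j] for j in perm[n_train:n_train + n_valid]]
        test = [records[j] for j in perm[n_train + n_valid:]]
        splits.append(DatasetSplit(train, valid, test, split_seed=seed,
                                   ratio=ratio))
    return splits


# ----- writers (used by the synthetic-world generator and the CLI) ---------

def write_drugs(drugs: list[DrugRecord], path) -> None:
    pd.DataFrame([(d.drug_id, d.smiles) for d in drugs],
                 columns=["drug_id", "smiles"]).to_csv(path, sep="\t", index=False)


def write_targets(targets: list[TargetRecord], path) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f">{t.target_id}\n")
            for i in range(0, len(t.sequence), 60):
                fh.write(t.sequence[i:i + 60] + "\n")


def write_triples(triples: list[tuple[str, str, str]], path) -> None:
    pd.DataFrame(triples).to_csv(path, sep="\t", index=False, header=False)


def write_signatures(store, dir_path) -> dict[str, Path]:
    dir_path = Path(dir_path)
    paths = {}
    for name, frame in [("D", store.m_d), ("OE", store.m_oe), ("XPR", store.m_xpr)]:
        p = dir_path / f"signatures_{name}.tsv"
        frame.to_csv(p, sep="\t")
        paths[name] = p
    return paths


def write_pairs(pairs: list[DTPRecord], path) -> None:
    pd.DataFrame([(p.drug_id, p.target_id, p.label, p.direction) for p in pairs],
                 columns=["drug_id", "target_id", "label", "direction"]
                 ).to_csv(path, sep="\t", index=False)
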