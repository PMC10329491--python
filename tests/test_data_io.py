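"""File formats, canonicalization, negative sampling, repeated splits."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from mdtips import data_io
from mdtips.data_io import (DrugRecord, DTPRecord, TargetRecord,
                            canonicalize_smiles, make_splits,
                            sample_negatives)


# ----- canonicalization -----------------------------------------------------

def test_canonicalize_maps_equivalent_smiles_to_one_string():
    # independent check: RDKit maps both notations of ethanol to one form
    expected = Chem.MolToSmiles(Chem.MolFromSmiles("OCC"))
    assert canonicalize_smiles("OCC") == expected
    assert canonicalize_smiles("CCO") == canonicalize_smiles("OCC")


def test_canonicalize_is_idempotent():
    for s in ["OCC", "c1ccccc1O", "CC(=O)Oc1ccccc1C(=O)O"]:
        once = canonicalize_smiles(s)
        assert canonicalize_smiles(once) == once


def test_canonicalize_rejects_invalid_smiles():
    with pytest.raises(ValueError):
        canonicalize_smiles("C1CC")  # unclosed ring


# ----- loaders --------------------------------------------------------------

def test_drug_table_round_trip(tmp_path):
    drugs = [DrugRecord("d1", canonicalize_smiles("CCO")),
             DrugRecord("d2", canonicalize_smiles("c1ccccc1")),
             DrugRecord("d3", canonicalize_smiles("CCN"))]
    path = tmp_path / "drugs.tsv"
    data_io.write_drugs(drugs, path)
    assert data_io.load_drugs(path) == drugs


def test_load_drugs_drops_bad_smiles_with_warning(tmp_path, caplog):
    path = tmp_path / "drugs.tsv"
    path.write_text("drug_id\tsmiles\nd1\tCCO\nd2\tC1CC\n")
    with caplog.at_level("WARNING"):
        records = data_io.load_drugs(path)
    assert [r.drug_id for r in records] == ["d1"]
    assert "d2" in caplog.text


def test_load_drugs_duplicate_ids_error(tmp_path):
    path = tmp_path / "drugs.tsv"
    path.write_text("drug_id\tsmiles\nd1\tCCO\nd1\tCCN\n")
    with pytest.raises(ValueError, match="duplicate"):
        data_io.load_drugs(path)


def test_load_drugs_missing_column_names_column(tmp_path):
    path = tmp_path / "drugs.tsv"
    path.write_text("drug_id\tstructure\nd1\tCCO\n")
    with pytest.raises(ValueError, match="smiles"):
        data_io.load_drugs(path)


def test_fasta_wrapped_lines_concatenated(tmp_path):
    path = tmp_path / "targets.fasta"
    path.write_text(">t1 some description\nMKV\nLAW\n>t2\nGG\n")
    records = data_io.load_targets(path)
    assert records == [TargetRecord("t1", "MKVLAW"), TargetRecord("t2", "GG")]


def test_pairs_label_domain_check(tmp_path):
    path = tmp_path / "pairs.tsv"
    path.write_text("drug_id\ttarget_id\tlabel\tdirection\nd1\tt1\t2\tunknown\n")
    with pytest.raises(ValueError, match="label"):
        data_io.load_pairs(path)


def test_pairs_direction_domain_check(tmp_path):
    path = tmp_path / "pairs.tsv"
    path.write_text("drug_id\ttarget_id\tlabel\tdirection\nd1\tt1\t1\tup\n")
    with pytest.raises(ValueError, match="direction"):
        data_io.load_pairs(path)


def test_signature_loader_requires_shared_panel(tmp_path):
    (tmp_path / "a.tsv").write_text("id\tg1\tg2\nx\t0\t1\n")
    (tmp_path / "b.tsv").write_text("id\tg1\tg2\ny\t0\t1\n")
    (tmp_path / "c.tsv").write_text("id\tg2\tg1\ny\t0\t1\n")
    with pytest.raises(ValueError, match="gene panel"):
        data_io.load_signatures(tmp_path / "a.tsv", tmp_path / "b.tsv",
                                tmp_path / "c.tsv")


# ----- negative under-sampling ---------------------------------------------

def _grid(n_drugs, n_targets):
    drugs = [DrugRecord(f"d{i}", "C") for i in range(n_drugs)]
    targets = [TargetRecord(f"t{j}", "M") for j in range(n_targets)]
    return drugs, targets


def test_negatives_stay_in_enumerated_complement():
    drugs, targets = _grid(3, 4)
    positives = [DTPRecord("d0", "t0", 1), DTPRecord("d1", "t2", 1)]
    negs = sample_negatives(positives, drugs, targets, ratio=2, seed=0)
    assert len(negs) == 4
    grid = {(d.drug_id, t.target_id)
            for d, t in itertools.product(drugs, targets)}
    complement = grid - {p.key for p in positives}
    assert len(complement) == 10
    keys = [n.key for n in negs]
    assert set(keys) <= complement
    assert len(set(keys)) == 4  # without replacement
    assert all(n.label == 0 and n.direction == "unknown" for n in negs)


@pytest.mark.parametrize("ratio", [1, 2, 5, 10])
def test_sampling_ratio_grid_counts(ratio):
    drugs, targets = _grid(10, 10)
    positives = [DTPRecord(f"d{i}", f"t{i}", 1) for i in range(4)]
    negs = sample_negatives(positives, drugs, targets, ratio=ratio, seed=1)
    assert len(negs) == ratio * len(positives)
    assert not {n.key for n in negs} & {p.key for p in positives}


def test_negative_sampling_deterministic():
    drugs, targets = _grid(5, 5)
    positives = [DTPRecord("d0", "t1", 1)]
    a = sample_negatives(positives, drugs, targets, 3, seed=42)
    b = sample_negatives(positives, drugs, targets, 3, seed=42)
    assert a == b
    c = sample_negatives(positives, drugs, targets, 3, seed=43)
    assert a != c


def test_negative_sampling_reports_max_feasible_ratio():
    drugs, targets = _grid(3, 4)
    positives = [DTPRecord("d0", "t0", 1), DTPRecord("d1", "t2", 1)]
    with pytest.raises(ValueError, match="maximum feasible ratio is 5"):
        sample_negatives(positives, drugs, targets, ratio=6, seed=0)


# ----- splits ---------------------------------------------------------------

def test_splits_exact_ratio_and_partition():
    records = [DTPRecord(f"d{i}", f"t{i}", 1) for i in range(100)]
    splits = make_splits(records, n_repeats=3, base_seed=0)
    for s in splits:
        assert (len(s.train), len(s.valid), len(s.test)) == (80, 10, 10)
        union = s.train + s.valid + s.test
        assert sorted(r.key for r in union) == sorted(r.key for r in records)


def test_splits_differ_across_repeats():
    records = [DTPRecord(f"d{i}", f"t{i}", 1) for i in range(40)]
    splits = make_splits(records, n_repeats=10, base_seed=0)
    test_sets = {frozenset(r.key for r in s.test) for s in splits}
    assert len(test_sets) >= 2
    assert [s.split_seed for s in splits] == list(range(10))


def test_splits_seed_determines_membership():
    records = [DTPRecord(f"d{i}", f"t{i}", 1) for i in range(30)]
    a = make_splits(records, n_repeats=2, base_seed=7)
    b = make_splits(records, n_repeats=2, base_seed=7)
    for sa, sb in zip(a, b):
        assert sa.train == sb.train and sa.test == sb.test


def test_splits_require_enough_records():
    with pytest.raises(ValueError):
        make_splits([DTPRecord("d", "t", 1)] * 5, n_repeats=1, base_seed=0)
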