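"""Metrics, the repeated-split experiment driver, and significance testing.

AUROC is the Mann-Whitney statistic (ties at half credit); AUPR is average
precision (area under the precision-recall step curve).  AUPR is the primary
metric because the datasets are negative-heavy by construction.  Experiments
run every (modality set, sampling ratio, repeat) cell on identical splits
within a repeat, so models are compared pairwise, and across-repeat
differences are tested with a two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from . import data_io
from .data_io import DatasetSplit, DTPRecord
from .fusion import ChannelInputs, FusionConfig, prepare_pair_data, train_fusion

logger = logging.getLogger(__name__)

__all__ = ["MetricReport", "auroc", "auprc", "run_ablation", "compare_models",
           "AblationResources", "train_and_test_cell", "pretrain_k_channel",
           "reports_to_frame"]


def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("metric undefined: labels contain a single class")


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney with ties at half credit)."""
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Area under the precision-recall step curve (average precision)."""
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


@dataclass
class MetricReport:
    model_label: str                      # e.g. "KSE"
    ratio_label: str                      # e.g. "1:2"
    repeat_seeds: list[int]
    aupr: list[float]
    auroc: list[float]

    def __post_init__(self):
        for v in self.aupr + self.auroc:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"metric outside [0,1]: {v}")

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.aupr))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc))

    def summary(self) -> str:
        return (f"{self.model_label} @ {self.ratio_label}: "
                f"AUPR {self.mean_aupr:.3f} +/- {np.std(self.aupr):.3f}, "
                f"AUROC {self.mean_auroc:.3f} +/- {np.std(self.auroc):.3f}")


@dataclass
class AblationResources:
    """Everything the experiment driver needs to build datasets and models."""

    positives: list[DTPRecord]
    drugs: list                       # DrugRecord
    targets: list                     # TargetRecord
    kg_support: "object" = None       # KnowledgeGraph, for K cells
    store: "object" = None            # SignatureStore, for E cells
    graphs: dict = None               # drug_id -> MolecularGraph, for S cells
    tokens: dict = None               # target_id -> TokenizedSequence
    vocab: "object" = None            # SubwordVocab
    kge_config: "object" = None       # ConvEConfig


def pretrain_k_channel(split: DatasetSplit, res: AblationResources):
    """ConvE table for one split (support KG + train positives, guarded)."""
    from .kge import build_k_channel

    train_pos = [p for p in split.train if p.label == 1]
    held_out = ([p for p in split.valid if p.label == 1]
                + [p for p in split.test if p.label == 1])
    return build_k_channel(res.kg_support, train_pos, held_out,
                           res.kge_config).table


def train_and_test_cell(split: DatasetSplit, modalities: str,
                        res: AblationResources, fusion_config: FusionConfig,
                        shuffle_labels_seed: int | None = None,
                        kge_table=None):
    """Train one (modality set, split) cell and return test scores/labels."""
    inputs = ChannelInputs(graphs=res.graphs, tokens=res.tokens,
                           store=res.store)
    if "K" in modalities:
        inputs.kge_table = (kge_table if kge_table is not None
                            else pretrain_k_channel(split, res))
    cfg = FusionConfig(**{**fusion_config.__dict__, "modalities": modalities})
    work_split = split
    if shuffle_labels_seed is not None:
        work_split = _shuffle_split_labels(split, shuffle_labels_seed)
    trained = train_fusion(work_split, inputs, cfg, vocab=res.vocab)
    test_batch = prepare_pair_data(work_split.test, inputs, cfg)
    scores = trained.model.predict_scores(test_batch)
    return scores, test_batch.labels


def _shuffle_split_labels(split: DatasetSplit, seed: int) -> DatasetSplit:
    """Random label permutation within each part (null-signal control)."""
    rng = np.random.default_rng(seed)

    def shuf(records):
        labels = rng.permutation([p.label for p in records])
        return [DTPRecord(p.drug_id, p.target_id, int(l), p.direction)
                for p, l in zip(records, labels)]

    return DatasetSplit(shuf(split.train), shuf(split.valid), shuf(split.test),
                        split.split_seed, split.ratio)


def run_ablation(res: AblationResources, modality_sets: list[str],
                 fusion_config: FusionConfig, n_repeats: int = 10,
                 ratios: list[int] = (2,), base_seed: int = 0,
                 shuffle_labels: bool = False) -> list[MetricReport]:
    """Train and test every (modality set, ratio, repeat) grid cell.

    Within one (ratio, repeat) the negatives and the 8:1:1 split are sampled
    once and shared by every modality set, so per-repeat metrics are paired
    across models.  ``shuffle_labels`` permutes labels within each split part
    (a null-signal control).
    """
    reports: dict[tuple[str, int], dict[str, list[float]]] = {}
    for ratio in ratios:
        for rep in range(n_repeats):
            seed = base_seed + rep
            negatives = data_io.sample_negatives(
                res.positives, res.drugs, res.targets, ratio,
                seed=10_000 * (ratio + 1) + seed)
            dataset = res.positives + negatives
            split = data_io.make_splits(dataset, n_repeats=1,
                                        base_seed=seed)[0]
            # one K pretraining per (ratio, repeat), shared by every
            # K-containing modality set (paired channel inputs)
            kge_table = (pretrain_k_channel(split, res)
                         if any("K" in m for m in modality_sets) else None)
            for mods in modality_sets:
                try:
                    scores, labels = train_and_test_cell(
                        split, mods, res, fusion_config,
                        shuffle_labels_seed=seed if shuffle_labels else None,
                        kge_table=kge_table)
                except Exception as exc:
                    raise RuntimeError(
                        f"ablation cell failed (modalities={mods}, "
                        f"ratio=1:{ratio}, repeat={rep})") from exc
                cell = reports.setdefault((mods, ratio),
                                          {"aupr": [], "auroc": [],
                                           "seeds": []})
                cell["aupr"].append(auprc(scores, labels))
                cell["auroc"].append(auroc(scores, labels))
                cell["seeds"].append(seed)
                logger.info("cell %s 1:%d rep %d: aupr %.3f auroc %.3f",
                            mods, ratio, rep, cell["aupr"][-1],
                            cell["auroc"][-1])
    return [MetricReport(mods, f"1:{ratio}", cell["seeds"], cell["aupr"],
                         cell["auroc"])
            for (mods, ratio), cell in reports.items()]


def reports_to_frame(reports: list[MetricReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for seed, ap, roc in zip(r.repeat_seeds, r.aupr, r.auroc):
            rows.append({"model": r.model_label, "ratio": r.ratio_label,
                         "repeat_seed": seed, "aupr": ap, "auroc": roc})
    return pd.DataFrame(rows)


def compare_models(report_a: MetricReport, report_b: MetricReport,
                   metric: str = "aupr") -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-repeat metrics.

    Reports must come from identical split seeds (paired comparison);
    identical metric vectors give p = 1 (no evidence of a difference).
    """
    if report_a.repeat_seeds != report_b.repeat_seeds:
        raise ValueError("reports are not paired: split seeds differ")
    a = np.asarray(getattr(report_a, metric))
    b = np.asarray(getattr(report_b, metric))
    if len(a) < 6:
        warnings.warn("fewer than 6 paired repeats: the signed-rank test "
                      "has essentially no power", stacklevel=2)
    if np.allclose(a, b):
        return 1.0
    result = stats.wilcoxon(a, b, alternative="two-sided", mode="exact")
    return float(result.pvalue)
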