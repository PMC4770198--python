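"""Evaluation utilities: AUROC, stratified cross-validation, relative
error reduction and benchmark-table summaries.

A published comparison of binding-site predictors on 24 CLIP-seq datasets
(AUROC of the GraphProt baseline against multimodal DBNs with — mDBN+ —
and without — mDBN- — tertiary structural profiles) ships with the package
as ``data/clip_benchmark_auroc.csv`` and feeds the summary functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dbn import ArchitectureSpec, fit_classifier, predict, pretrain
from .encoding import EncodedDataset
from .rbm import CdConfig


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney convention (ties count 0.5)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def relative_error_reduction(c: float, c_prime: float) -> float:
    """(c' - c) / (1 - c): the fraction of the baseline's error removed."""
    if c >= 1.0:
        raise ValueError("baseline AUROC of 1 leaves no error to reduce")
    return (c_prime - c) / (1.0 - c)


def _subset(profiles: EncodedDataset, idx: np.ndarray) -> EncodedDataset:
    return EncodedDataset(
        site_ids=[profiles.site_ids[i] for i in idx],
        counts_1d=profiles.counts_1d[idx],
        counts_2d=profiles.counts_2d[idx],
        bits_3d=profiles.bits_3d[idx],
        dictionary_1d=profiles.dictionary_1d,
        dictionary_2d=profiles.dictionary_2d,
        catalog=profiles.catalog,
    )


@dataclass
class CrossValidationResult:
    fold_aurocs: list[float]
    fold_assignment: np.ndarray  # fold index per site

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_aurocs))


def cross_validate(
    profiles: EncodedDataset,
    labels: np.ndarray,
    architecture: ArchitectureSpec,
    config: CdConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    head_mode: str = "discriminative_head",
) -> CrossValidationResult:
    """Stratified k-fold cross-validation, retraining the DBN per fold.

    Fold assignment is deterministic given ``seed``; each fold's model is
    pretrained and head-fitted on the training split only and scored on
    the held-out split.
    """
    labels = np.asarray(labels, dtype=int)
    if profiles.n_sites < folds:
        raise ValueError("dataset smaller than the number of folds")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.full(profiles.n_sites, -1, dtype=int)
    fold_aurocs = []
    for fold, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(profiles.n_sites), labels)
    ):
        if len(np.unique(labels[test_idx])) < 2 or len(np.unique(labels[train_idx])) < 2:
            raise ValueError(
                f"fold {fold} lacks one class "
                f"(train counts {np.bincount(labels[train_idx])}, "
                f"test counts {np.bincount(labels[test_idx])})"
            )
        assignment[test_idx] = fold
        model = pretrain(_subset(profiles, train_idx), architecture, config, seed=seed + fold)
        model = fit_classifier(
            model, _subset(profiles, train_idx), labels[train_idx],
            mode=head_mode, config=config, seed=seed + fold,
        )
        scores = predict(model, _subset(profiles, test_idx))
        fold_aurocs.append(auroc(scores, labels[test_idx]))
    return CrossValidationResult(fold_aurocs=fold_aurocs, fold_assignment=assignment)


# ---------------------------------------------------------------------------
# benchmark tables
# ---------------------------------------------------------------------------

def load_benchmark_table() -> pd.DataFrame:
    """The bundled 24-dataset CLIP-seq AUROC benchmark, indexed by dataset."""
    with resources.files("rbpdeep.data").joinpath("clip_benchmark_auroc.csv").open() as fh:
        return pd.read_csv(fh, index_col="dataset")


@dataclass
class BenchmarkSummary:
    wins: int
    per_row_rer: pd.Series
    mean_rer: float
    median_rer: float
    flagged: list[str]  # rows where new - baseline > drop_threshold


def summarize_benchmark(
    table: pd.DataFrame,
    baseline: str,
    new: str,
    drop_threshold: float = 0.02,
) -> BenchmarkSummary:
    """Strict win count, per-row relative error reduction, and the rows
    where the ``new`` column exceeds ``baseline`` by more than
    ``drop_threshold`` AUROC (read the pair as ablated vs full model to
    flag structure-dependent datasets)."""
    for col in (baseline, new):
        if col not in table.columns:
            raise KeyError(f"column {col!r} missing from benchmark table")
    base = table[baseline].astype(float)
    other = table[new].astype(float)
    rer = (other - base) / (1.0 - base)
    flagged = list(table.index[(other - base) > drop_threshold])
    return BenchmarkSummary(
        wins=int((other > base).sum()),
        per_row_rer=rer,
        mean_rer=float(rer.mean()),
        median_rer=float(rer.median()),
        flagged=flagged,
    )
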