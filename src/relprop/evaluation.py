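"""Stratified cross-validation harness and metrics.

Propositionalization is fitted per fold: vocabulary document frequencies
and numeric bin edges come from training instances only, and items unseen
in training are dropped from held-out bags.  This keeps the pipeline free
of test-fold leakage; a ``global_vocab`` switch restores the laxer
whole-database fit for comparison.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import propdrm, propstar
from .store import RelationalDatabase
from .wordify import (
    WordifyParams,
    bags_to_matrix,
    build_join_index,
    build_vocabulary,
    fit_bin_edges,
    wordify_all,
)


@dataclass
class FoldAssignment:
    k: int
    fold_of: np.ndarray   # per-instance fold index
    seed: int


@dataclass
class CVResult:
    method: str
    fold_accuracies: list[float]
    fold_aucs: list[float]
    config: dict
    runtime_seconds: float

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def stratified_kfold(labels: Sequence, k: int, seed: int) -> FoldAssignment:
    """Seeded stratified fold assignment; per-fold class proportions stay
    within one instance of the global proportions."""
    labels = list(labels)
    if k > len(labels):
        raise ValueError("k cannot exceed the number of instances")
    fold_of = np.empty(len(labels), dtype=int)
    y = np.asarray([str(l) for l in labels])
    counts = {c: int((y == c).sum()) for c in np.unique(y)}
    if min(counts.values()) >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
            fold_of[test_idx] = f
    else:
        # best effort: a class smaller than k cannot appear in every fold;
        # spread each class round-robin so fold sizes stay within one
        warnings.warn(
            f"class counts {counts} below k={k}; using round-robin stratification",
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        offset = 0
        for c in sorted(counts):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            for pos, i in enumerate(idx):
                fold_of[i] = (offset + pos) % k
            offset += len(idx)
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


def accuracy(predicted: Sequence, truth: Sequence) -> float:
    """Fraction of exact matches."""
    if len(predicted) != len(truth):
        raise ValueError("length mismatch")
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Area under the ROC curve: the probability that a random positive
    outscores a random negative, ties counted half."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("AUC requires both classes in the truth vector")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def majority_baseline_accuracy(labels: Sequence) -> float:
    """Accuracy of always predicting the most frequent label."""
    labels = list(labels)
    counts: dict = {}
    for l in labels:
        counts[l] = counts.get(l, 0) + 1
    majority = max(counts, key=counts.get)
    return accuracy([majority] * len(labels), labels)


def _positive_label(label_order: list) -> object:
    # deterministic convention: last label in sorted order is "positive"
    return label_order[-1]


def run_experiment(
    db: RelationalDatabase,
    method: str,
    cfg=None,
    k: int = 10,
    seed: int = 42,
    runs: int = 5,
    params: WordifyParams = WordifyParams(),
    global_vocab: bool = False,
) -> CVResult:
    """k-fold stratified CV of one method, repeated ``runs`` times with
    seeds ``seed .. seed+runs-1``; per-fold fit of bins and vocabulary."""
    if method not in ("propstar", "propdrm"):
        raise ValueError(f"unknown method {method!r}")
    t0 = time.time()
    labels = db.target_labels
    label_order = sorted(set(labels), key=str)
    if len(label_order) != 2:
        raise ValueError("the harness currently scores binary problems")
    pos = _positive_label(label_order)
    ji = build_join_index(db, params.max_order)
    ids = db.instance_ids

    accs: list[float] = []
    aucs: list[float] = []
    for r in range(runs):
        run_seed = seed + r
        folds = stratified_kfold(labels, k, run_seed)
        if global_vocab:
            all_bags = wordify_all(db, params)
            global_vocabulary = build_vocabulary(all_bags, params.min_freq)
        for f in range(k):
            train_idx = np.flatnonzero(folds.fold_of != f)
            test_idx = np.flatnonzero(folds.fold_of == f)
            if global_vocab:
                bags = all_bags
                vocab = global_vocabulary
            else:
                edges = fit_bin_edges(db, ji, params, [ids[i] for i in train_idx])
                bags = wordify_all(db, params, bin_edges=edges)
                vocab = build_vocabulary([bags[i] for i in train_idx], params.min_freq)
            train_bags = [bags[i] for i in train_idx]
            test_bags = [bags[i] for i in test_idx]
            y_train = [labels[i] for i in train_idx]
            y_test = [labels[i] for i in test_idx]

            if method == "propstar":
                ps_cfg = cfg or propstar.PropStarConfig()
                ps_cfg = propstar.PropStarConfig(**{**vars(ps_cfg), "seed": run_seed})
                model = propstar.train_propstar(train_bags, vocab, y_train, ps_cfg)
                preds = propstar.predict_many(model, test_bags)
                scores = propstar.decision_scores(model, test_bags, pos)
            else:
                drm_cfg = cfg or propdrm.DRMConfig()
                drm_cfg = propdrm.DRMConfig(**{**vars(drm_cfg), "seed": run_seed})
                P_train = bags_to_matrix(train_bags, vocab)
                P_test = bags_to_matrix(test_bags, vocab)
                model = propdrm.train_drm(P_train, y_train, drm_cfg)
                pred = propdrm.predict_drm(model, P_test)
                preds = pred.labels
                scores = propdrm.positive_scores(pred, model.label_order, pos)

            accs.append(accuracy(preds, y_test))
            aucs.append(auc(scores, [y == pos for y in y_test]))
    snapshot = vars(cfg) if cfg is not None else {}
    return CVResult(method=method, fold_accuracies=accs, fold_aucs=aucs,
                    config={"k": k, "seed": seed, "runs": runs, **snapshot},
                    runtime_seconds=time.time() - t0)
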