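"""PropStar: supervised embedding of relational items and class labels.

Every unique relational item in the vocabulary and every class label get a
vector in one shared d-dimensional space.  An instance (a bag of items) is
embedded as the element-wise sum of its unique in-vocabulary item vectors
divided by sqrt(|M_unique|), and classified as the label whose vector has
the highest inner-product similarity.  Training minimizes a margin ranking
loss with k-negative sampling over labels:

    L = max(0, m - sim(e_M, e_true)) + (1/k) * sum_i max(0, m + sim(e_M, e_neg_i))

so the true label is pulled above the margin m while sampled wrong labels
are pushed below -m.  Plain SGD with a fixed learning rate; all randomness
(initialization, epoch shuffling, negative sampling) flows from one seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .wordify import InstanceBag, Vocabulary


@dataclass
class PropStarConfig:
    dim: int = 32
    k_negatives: int = 5
    margin: float = 0.05
    learning_rate: float = 0.05
    epochs: int = 5
    seed: int = 0
    #: sum item vectors over the multiset (with multiplicity) instead of the
    #: unique item set; the divisor stays sqrt(|M_unique|) either way
    multiset_sum: bool = False

    def __post_init__(self) -> None:
        if min(self.dim, self.k_negatives, self.epochs + 1) < 1:
            raise ValueError("dim and k_negatives must be >= 1, epochs >= 0")
        if self.learning_rate <= 0 or self.margin < 0:
            raise ValueError("learning_rate must be > 0 and margin >= 0")


@dataclass
class EmbeddingModel:
    """Item and label vectors in a shared space, plus the training config."""

    item_vectors: np.ndarray          # |W| x d
    label_vectors: np.ndarray         # |C| x d
    label_order: list
    vocabulary: Vocabulary
    config: PropStarConfig
    loss_trace: list[float] = field(default_factory=list)


def similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Inner-product similarity between two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(u @ v)


def _bag_indices(bag: InstanceBag, vocab: Vocabulary) -> np.ndarray:
    idx = sorted({vocab.index[it] for it in bag.unique_items if it in vocab.index})
    return np.asarray(idx, dtype=np.intp)


def embed_instance(model: EmbeddingModel, bag: InstanceBag) -> np.ndarray:
    """e_M = (sum of unique in-vocabulary item vectors) / sqrt(|M_unique|).

    With ``config.multiset_sum`` the numerator ranges over the multiset
    (each item weighted by its multiplicity); the divisor is unchanged.
    """
    idx = _bag_indices(bag, model.vocabulary)
    if idx.size == 0:
        raise ValueError(
            f"instance {bag.instance_id!r} has no in-vocabulary relational items"
        )
    if model.config.multiset_sum:
        weights = np.array([
            bag.items[it] for it in sorted(
                (it for it in bag.unique_items if it in model.vocabulary.index),
                key=lambda it: model.vocabulary.index[it])
        ], dtype=float)
        return (weights[:, None] * model.item_vectors[idx]).sum(axis=0) / np.sqrt(idx.size)
    return model.item_vectors[idx].sum(axis=0) / np.sqrt(idx.size)


def sample_negatives(label_order: Sequence, true_label, k: int,
                     rng: np.random.Generator) -> list:
    """k labels drawn uniformly with replacement from the non-true labels."""
    others = [lab for lab in label_order if lab != true_label]
    if not others:
        raise ValueError("negative sampling needs at least two distinct labels")
    picks = rng.integers(0, len(others), size=k)
    return [others[p] for p in picks]


def pair_loss(sim_pos: float, sim_negs: Sequence[float], margin: float) -> float:
    """Margin ranking loss for one training pair.

    Zero exactly when the true-label similarity reaches the margin and every
    sampled negative similarity is at or below minus the margin.
    """
    k = len(sim_negs)
    if k < 1:
        raise ValueError("at least one negative similarity required")
    loss = max(0.0, margin - sim_pos)
    loss += sum(max(0.0, margin + s) for s in sim_negs) / k
    return loss


def init_model(vocab: Vocabulary, label_order: Sequence,
               cfg: PropStarConfig) -> EmbeddingModel:
    """Uniform init in [-0.5/d, +0.5/d], reproducible under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    lim = 0.5 / cfg.dim
    iv = rng.uniform(-lim, lim, size=(len(vocab), cfg.dim))
    lv = rng.uniform(-lim, lim, size=(len(label_order), cfg.dim))
    return EmbeddingModel(item_vectors=iv, label_vectors=lv,
                          label_order=list(label_order), vocabulary=vocab,
                          config=cfg)


def train_propstar(
    bags: Sequence[InstanceBag],
    vocab: Vocabulary,
    labels: Sequence,
    cfg: PropStarConfig = PropStarConfig(),
) -> EmbeddingModel:
    """SGD over shuffled instances; one margin-ranking update per instance.

    The gradient of e_M is distributed equally to each participating item
    vector, scaled by 1/sqrt(|M_unique|) (chain rule through the bag
    normalization).  Returns the model with a per-epoch mean-loss trace.
    """
    label_order = sorted(set(labels), key=str)
    if len(label_order) < 2:
        raise ValueError("training requires at least two classes")
    if len(bags) != len(labels):
        raise ValueError("bags and labels must align")
    model = init_model(vocab, label_order, cfg)
    lab_idx = {lab: j for j, lab in enumerate(label_order)}
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    bag_idx = [_bag_indices(b, vocab) for b in bags]
    if cfg.multiset_sum:
        bag_wts = [
            np.array([b.items[it] for it in sorted(
                (it for it in b.unique_items if it in vocab.index),
                key=lambda it: vocab.index[it])], dtype=float)
            for b in bags
        ]
    else:
        bag_wts = [None] * len(bags)
    iv, lv = model.item_vectors, model.label_vectors
    lr, m, k = cfg.learning_rate, cfg.margin, cfg.k_negatives

    for _epoch in range(cfg.epochs):
        perm = rng.permutation(len(bags))
        epoch_loss = 0.0
        n_seen = 0
        for i in perm:
            idx = bag_idx[i]
            if idx.size == 0:
                continue
            norm = np.sqrt(idx.size)
            wts = bag_wts[i]
            if wts is None:
                e = iv[idx].sum(axis=0) / norm
            else:
                e = (wts[:, None] * iv[idx]).sum(axis=0) / norm
            jt = lab_idx[labels[i]]
            negs = sample_negatives(label_order, labels[i], k, rng)
            neg_js = [lab_idx[lab] for lab in negs]

            sim_pos = float(e @ lv[jt])
            sim_negs = [float(e @ lv[j]) for j in neg_js]
            epoch_loss += pair_loss(sim_pos, sim_negs, m)
            n_seen += 1

            grad_e = np.zeros_like(e)
            if m - sim_pos > 0:
                grad_e -= lv[jt]
                lv[jt] -= lr * (-e)
            for j, s in zip(neg_js, sim_negs):
                if m + s > 0:
                    grad_e += lv[j] / k
                    lv[j] -= lr * (e / k)
            if wts is None:
                iv[idx] -= lr * (grad_e / norm)
            else:
                iv[idx] -= lr * (wts[:, None] * grad_e / norm)
        mean_loss = epoch_loss / max(n_seen, 1)
        if not np.isfinite(mean_loss):
            raise FloatingPointError(
                f"non-finite loss {mean_loss} in epoch {_epoch}; lower the learning rate"
            )
        model.loss_trace.append(mean_loss)
    return model


def predict_propstar(model: EmbeddingModel, bag: InstanceBag):
    """Top-ranked label by similarity, plus all per-label similarities.

    Ties break to the earliest label in ``label_order``.  Exactly |C|
    similarity evaluations are performed.
    """
    e = embed_instance(model, bag)
    sims = model.label_vectors @ e
    return model.label_order[int(np.argmax(sims))], dict(zip(model.label_order, sims.tolist()))


def decision_scores(model: EmbeddingModel, bags: Sequence[InstanceBag],
                    positive_label) -> np.ndarray:
    """Binary score per bag: sim to the positive label minus sim to the other.

    Bags with no in-vocabulary items score 0 (indifferent).
    """
    jp = model.label_order.index(positive_label)
    jn = [j for j in range(len(model.label_order)) if j != jp]
    if len(jn) != 1:
        raise ValueError("decision_scores is defined for binary problems")
    out = np.zeros(len(bags))
    for i, bag in enumerate(bags):
        idx = _bag_indices(bag, model.vocabulary)
        if idx.size == 0:
            continue
        e = model.item_vectors[idx].sum(axis=0) / np.sqrt(idx.size)
        out[i] = float(e @ model.label_vectors[jp]) - float(e @ model.label_vectors[jn[0]])
    return out


def predict_many(model: EmbeddingModel, bags: Sequence[InstanceBag]) -> list:
    """Predicted label per bag; empty-in-vocabulary bags get the first label."""
    preds = []
    for bag in bags:
        idx = _bag_indices(bag, model.vocabulary)
        if idx.size == 0:
            preds.append(model.label_order[0])
            continue
        e = model.item_vectors[idx].sum(axis=0) / np.sqrt(idx.size)
        sims = model.label_vectors @ e
        preds.append(model.label_order[int(np.argmax(sims))])
    return preds


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    meta = {
        "kind": "propstar",
        "label_order": [str(l) for l in model.label_order],
        "config": vars(model.config),
        "vocab_keys": [it.canonical_key for it in model.vocabulary.items_in_order],
        "doc_freq": [model.vocabulary.doc_freq[it]
                     for it in model.vocabulary.items_in_order],
    }
    np.savez(
        path,
        item_vectors=model.item_vectors,
        label_vectors=model.label_vectors,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> EmbeddingModel:
    from .wordify import parse_item_key

    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    if meta["kind"] != "propstar":
        raise ValueError(f"not a propstar model: {meta['kind']}")
    items = [parse_item_key(k) for k in meta["vocab_keys"]]
    vocab = Vocabulary(index={it: j for j, it in enumerate(items)},
                       doc_freq=dict(zip(items, meta["doc_freq"])))
    return EmbeddingModel(
        item_vectors=data["item_vectors"],
        label_vectors=data["label_vectors"],
        label_order=meta["label_order"],
        vocabulary=vocab,
        config=PropStarConfig(**meta["config"]),
    )
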