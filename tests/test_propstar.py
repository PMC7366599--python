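"""PropStar: similarity, bag embedding, margin ranking loss, training."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relprop.propstar import (
    EmbeddingModel,
    PropStarConfig,
    embed_instance,
    init_model,
    load_model,
    pair_loss,
    predict_propstar,
    sample_negatives,
    save_model,
    similarity,
    train_propstar,
)
from relprop.synthetic import SyntheticSpec, generate_trains
from relprop.wordify import (
    InstanceBag,
    RelationalItem,
    Vocabulary,
    WordifyParams,
    build_vocabulary,
    wordify_all,
)


def _toy_model(vectors: dict[str, list[float]], labels: dict[str, list[float]]):
    items = [RelationalItem.single("t", "c", k) for k in sorted(vectors)]
    vocab = Vocabulary(index={it: j for j, it in enumerate(items)},
                       doc_freq={it: 1 for it in items})
    iv = np.array([vectors[k] for k in sorted(vectors)], dtype=float)
    order = sorted(labels)
    lv = np.array([labels[k] for k in order], dtype=float)
    return EmbeddingModel(item_vectors=iv, label_vectors=lv, label_order=order,
                          vocabulary=vocab, config=PropStarConfig(dim=iv.shape[1]))


def _bag(*values):
    return InstanceBag("i", Counter(RelationalItem.single("t", "c", v) for v in values))


def test_similarity_is_inner_product():
    assert similarity([1, 2], [3, 4]) == 11
    assert similarity([1, 0], [0, 1]) == 0
    assert similarity([1, 0], [1, 0]) == 1
    with pytest.raises(ValueError):
        similarity([1, 2], [1, 2, 3])


def test_embed_single_item_is_its_vector():
    m = _toy_model({"f1": [1, 0], "f2": [0, 1]}, {"a": [1, 0], "b": [0, 1]})
    np.testing.assert_allclose(embed_instance(m, _bag("f1")), [1, 0])


def test_embed_two_items_normalized_by_sqrt():
    m = _toy_model({"f1": [1, 0], "f2": [0, 1]}, {"a": [1, 0], "b": [0, 1]})
    e = embed_instance(m, _bag("f1", "f2"))
    np.testing.assert_allclose(e, [1 / np.sqrt(2), 1 / np.sqrt(2)])


def test_embed_collapses_multiplicity():
    m = _toy_model({"f1": [1, 0], "f2": [0, 1]}, {"a": [1, 0], "b": [0, 1]})
    e1 = embed_instance(m, _bag("f1", "f1", "f2"))
    e2 = embed_instance(m, _bag("f1", "f2"))
    np.testing.assert_array_equal(e1, e2)


def test_embed_empty_bag_errors():
    m = _toy_model({"f1": [1, 0]}, {"a": [1, 0], "b": [0, 1]})
    with pytest.raises(ValueError, match="i"):
        embed_instance(m, _bag("unknown"))


def test_sample_negatives_binary_forced():
    rng = np.random.default_rng(0)
    assert sample_negatives(["a", "b"], "a", 5, rng) == ["b"] * 5


def test_sample_negatives_uniform_and_deterministic():
    rng = np.random.default_rng(42)
    negs = sample_negatives(["a", "b", "c"], "a", 10000, rng)
    frac_b = negs.count("b") / len(negs)
    assert abs(frac_b - 0.5) < 0.02
    rng2 = np.random.default_rng(42)
    assert sample_negatives(["a", "b", "c"], "a", 100, rng2) == \
           sample_negatives(["a", "b", "c"], "a", 100, np.random.default_rng(42))


def test_sample_negatives_single_label_errors():
    with pytest.raises(ValueError):
        sample_negatives(["a"], "a", 3, np.random.default_rng(0))


def test_pair_loss_boundary_zero():
    assert pair_loss(0.05, [-0.05, -0.05], 0.05) == 0.0


def test_pair_loss_hand_value():
    assert pair_loss(0.0, [0.0], 0.05) == pytest.approx(0.10)


@given(st.floats(-1, 1), st.floats(-1, 1), st.floats(0, 0.5))
@settings(max_examples=50, deadline=None)
def test_pair_loss_monotone_and_nonnegative(sim_pos, sim_neg, margin):
    base = pair_loss(sim_pos, [sim_neg], margin)
    assert base >= 0
    assert pair_loss(sim_pos + 0.1, [sim_neg], margin) <= base
    assert pair_loss(sim_pos, [sim_neg + 0.1], margin) >= base


def test_predict_nearest_label_and_tie_break():
    m = _toy_model({"f1": [1, 0]}, {"a": [1, 0], "b": [0, 1]})
    label, sims = predict_propstar(m, _bag("f1"))
    assert label == "a"
    assert sims == {"a": 1.0, "b": 0.0}
    tied = _toy_model({"f1": [1, 0]}, {"a": [1, 0], "b": [1, 0]})
    label, _ = predict_propstar(tied, _bag("f1"))
    assert label == "a"  # first in label_order wins


def test_prediction_invariant_to_order_and_multiplicity():
    m = _toy_model({"f1": [1, 0], "f2": [0, 1]}, {"a": [1, 1], "b": [-1, -1]})
    l1, s1 = predict_propstar(m, _bag("f1", "f2", "f2"))
    l2, s2 = predict_propstar(m, _bag("f2", "f1"))
    assert (l1, s1) == (l2, s2)


def _trains_training_setup(n=200, seed=42):
    db, oracle = generate_trains(SyntheticSpec(schema_kind="trains",
                                               n_instances=n, seed=seed))
    bags = wordify_all(db, WordifyParams())
    vocab = build_vocabulary(bags, 1)
    return bags, vocab, list(db.target_labels)


def test_epochs_zero_equals_seeded_init():
    bags, vocab, labels = _trains_training_setup(n=20)
    cfg = PropStarConfig(epochs=0, seed=3)
    model = train_propstar(bags, vocab, labels, cfg)
    ref = init_model(vocab, sorted(set(labels), key=str), cfg)
    np.testing.assert_array_equal(model.item_vectors, ref.item_vectors)
    np.testing.assert_array_equal(model.label_vectors, ref.label_vectors)


def test_loss_descends_on_separable_data():
    bags, vocab, labels = _trains_training_setup()
    model = train_propstar(bags, vocab, labels, PropStarConfig(seed=1))
    assert model.loss_trace[-1] < model.loss_trace[0]


def test_planted_rule_training_accuracy():
    """Noiseless conjunct rule: the embedding recovers >= 95% on train."""
    bags, vocab, labels = _trains_training_setup(n=200, seed=42)
    model = train_propstar(bags, vocab, labels, PropStarConfig(seed=42))
    from relprop.propstar import predict_many
    preds = predict_many(model, bags)
    acc = np.mean([p == l for p, l in zip(preds, labels)])
    assert acc >= 0.95


def test_training_is_bit_reproducible():
    bags, vocab, labels = _trains_training_setup(n=40)
    m1 = train_propstar(bags, vocab, labels, PropStarConfig(seed=9))
    m2 = train_propstar(bags, vocab, labels, PropStarConfig(seed=9))
    np.testing.assert_array_equal(m1.item_vectors, m2.item_vectors)
    np.testing.assert_array_equal(m1.label_vectors, m2.label_vectors)
    assert m1.loss_trace == m2.loss_trace


def test_model_round_trip(tmp_path):
    bags, vocab, labels = _trains_training_setup(n=20)
    model = train_propstar(bags, vocab, labels, PropStarConfig(seed=5, epochs=1))
    path = tmp_path / "m.npz"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_array_equal(back.item_vectors, model.item_vectors)
    assert back.label_order == [str(l) for l in model.label_order]
    l1, _ = predict_propstar(model, bags[0])
    l2, _ = predict_propstar(back, bags[0])
    assert str(l1) == str(l2)
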