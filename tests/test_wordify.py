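"""Wordification: join index, discretization, bags, vocabulary, matrix."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relprop.store import MISSING, ColumnSpec, Table
from relprop.wordify import (
    RelationalItem,
    WordifyParams,
    bags_to_matrix,
    build_join_index,
    build_vocabulary,
    discretize_numeric,
    parse_item_key,
    propositionalize,
    read_matrix_dir,
    wordify_all,
    wordify_instance,
    wordify_row,
    write_matrix_dir,
)

from conftest import make_random_toy, make_three_table_toy, make_trains_toy
from _naive import naive_bag, naive_linked_rows, naive_matrix


# ---------------------------------------------------------------- join index

def test_join_index_trains(trains_toy):
    ji = build_join_index(trains_toy, max_order=2)
    assert ji.order == {"trains": 0, "cars": 1}
    assert ji.rowmap["cars"][1] == [0, 1]
    assert ji.rowmap["cars"][2] == [2]


def test_join_index_order_zero_is_identity(trains_toy):
    ji = build_join_index(trains_toy, max_order=0)
    assert set(ji.rowmap) == {"trains"}
    assert ji.rowmap["trains"] == {1: [0], 2: [1]}


def test_join_index_chain_matches_nested_loop_oracle(three_table_toy):
    """bonds sit at order 2; row lists match a brute-force join."""
    db = three_table_toy
    ji = build_join_index(db, max_order=2)
    assert ji.order == {"molecules": 0, "atoms": 1, "bonds": 2}
    for inst in db.instance_ids:
        expected = naive_linked_rows(db, inst, 2)
        got = Counter()
        for tname, mapping in ji.rowmap.items():
            for r in mapping.get(inst, ()):
                got[(tname, r)] += 1
        assert got == expected


@pytest.mark.parametrize("seed", range(5))
def test_join_index_random_toys_match_oracle(seed):
    db = make_random_toy(seed)
    ji = build_join_index(db, max_order=2)
    for inst in db.instance_ids:
        expected = naive_linked_rows(db, inst, 2)
        got = Counter()
        for tname, mapping in ji.rowmap.items():
            for r in mapping.get(inst, ()):
                got[(tname, r)] += 1
        assert got == expected


# ------------------------------------------------------------- discretization

def test_quantile_bins_split_evenly():
    labels = discretize_numeric(list(range(1, 9)), n_bins=4, strategy="quantile")
    assert Counter(labels) == Counter({f"bin{k}_of_4": 2 for k in range(1, 5)})
    # monotone: sorted values never decrease in bin index
    ks = [int(l[3]) for l in labels]
    assert ks == sorted(ks)


def test_constant_column_lands_in_one_bin():
    labels = discretize_numeric([7.0] * 5, n_bins=3)
    assert set(labels) == {"bin1_of_1"}


def test_width_bins_match_histogram():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 1, 100).tolist()
    labels = discretize_numeric(vals, n_bins=4, strategy="width")
    counts = Counter(labels)
    hist, edges = np.histogram(vals, bins=4)
    for k in range(4):
        assert counts.get(f"bin{k + 1}_of_4", 0) == hist[k]


def test_missing_values_stay_missing():
    labels = discretize_numeric([1.0, MISSING, 3.0], n_bins=2)
    assert labels[1] is MISSING


# -------------------------------------------------------------- row wordify

def test_wordify_row_singles_and_conjunct(trains_toy):
    items = wordify_row(trains_toy.tables["cars"], 0, make_conjuncts=True)
    keys = {it.canonical_key for it in items}
    assert keys == {
        "cars.length=short",
        "cars.roof=peaked",
        "cars.length=short∧cars.roof=peaked",
    }


def test_wordify_row_all_missing_gives_empty():
    t = Table("x", [ColumnSpec("id", role="primary_key"), ColumnSpec("a")],
              [(1, MISSING)])
    assert wordify_row(t, 0) == Counter()


def test_wordify_row_four_attributes_gives_ten_items():
    t = Table("x", [ColumnSpec("id", role="primary_key"),
                    ColumnSpec("a"), ColumnSpec("b"),
                    ColumnSpec("c"), ColumnSpec("d")],
              [(1, "1", "2", "3", "4")])
    items = wordify_row(t, 0, make_conjuncts=True)
    assert sum(items.values()) == 10
    assert sum(1 for it in items if it.arity == 1) == 4
    assert sum(1 for it in items if it.arity == 2) == 6


def test_conjunct_canonical_order_and_no_self_pairs():
    a = ("t", "x", "1")
    b = ("t", "y", "2")
    assert RelationalItem.conjunct(a, b) == RelationalItem.conjunct(b, a)
    with pytest.raises(ValueError):
        RelationalItem.conjunct(a, a)


# ----------------------------------------------------------- instance bags

def test_duplicate_rows_keep_multiplicity():
    """Two identical cars on one train appear twice in the bag."""
    trains = Table("trains", [ColumnSpec("id", role="primary_key"),
                              ColumnSpec("direction", role="target")],
                   [(1, "east")])
    cars = Table("cars", [ColumnSpec("id", role="primary_key"),
                          ColumnSpec("train_id", role="foreign_key",
                                     referenced_table="trains"),
                          ColumnSpec("length"), ColumnSpec("roof")],
                 [(1, 1, "short", "peaked"), (2, 1, "short", "peaked")])
    from relprop.store import RelationalDatabase
    db = RelationalDatabase(tables={"trains": trains, "cars": cars},
                            target_table="trains", target_column="direction")
    ji = build_join_index(db, 2)
    bag = wordify_instance(db, ji, 1)
    assert bag.items[RelationalItem.single("cars", "length", "short")] == 2
    assert bag.items[
        RelationalItem.conjunct(("cars", "length", "short"), ("cars", "roof", "peaked"))
    ] == 2


def test_instance_without_children_has_only_own_row_items(trains_toy):
    db = trains_toy
    db.tables["cars"].rows = [r for r in db.tables["cars"].rows if r[1] != 2]
    ji = build_join_index(db, 2)
    bag = wordify_instance(db, ji, 2)
    assert bag.items == Counter()  # trains has no attribute columns
    assert bag.label == "west"


def test_unknown_instance_errors(trains_toy):
    ji = build_join_index(trains_toy, 2)
    with pytest.raises(KeyError):
        wordify_instance(trains_toy, ji, 999)


@pytest.mark.parametrize("seed", range(10))
def test_bags_match_naive_join_oracle(seed):
    """Optimized bags equal the nested-loop full-join implementation."""
    db = make_random_toy(seed)
    bags = wordify_all(db, WordifyParams())
    for bag in bags:
        expected = naive_bag(db, bag.instance_id)
        got = Counter({it.canonical_key: n for it, n in bag.items.items()})
        assert got == expected


def test_permutation_invariance(seed=0):
    """Shuffling child-table row order leaves every bag unchanged."""
    db = make_random_toy(seed)
    bags1 = {b.instance_id: Counter({i.canonical_key: n for i, n in b.items.items()})
             for b in wordify_all(db)}
    rng = np.random.default_rng(1)
    for tname in ("child", "grand"):
        rows = db.tables[tname].rows
        perm = rng.permutation(len(rows))
        db.tables[tname].rows = [rows[i] for i in perm]
    bags2 = {b.instance_id: Counter({i.canonical_key: n for i, n in b.items.items()})
             for b in wordify_all(db)}
    assert bags1 == bags2


# -------------------------------------------------------------- vocabulary

def test_vocabulary_min_freq_threshold():
    rare = RelationalItem.single("t", "a", "rare")
    common = RelationalItem.single("t", "a", "common")
    from relprop.wordify import InstanceBag
    bags = [InstanceBag(i, Counter([common] + ([rare] if i == 0 else [])))
            for i in range(10)]
    v1 = build_vocabulary(bags, min_freq=1)
    v2 = build_vocabulary(bags, min_freq=2)
    assert rare in v1.index and rare not in v2.index
    assert v1.doc_freq[common] == 10


def test_vocabulary_indices_follow_canonical_order():
    db = make_random_toy(2)
    _, vocab, _ = propositionalize(db)
    keys = [it.canonical_key for it in vocab.items_in_order]
    assert keys == sorted(keys)


def test_empty_vocabulary_errors():
    from relprop.wordify import InstanceBag
    bags = [InstanceBag(0, Counter([RelationalItem.single("t", "a", "x")]))]
    with pytest.raises(ValueError, match="min_freq"):
        build_vocabulary(bags, min_freq=5)


@given(st.integers(min_value=1, max_value=6))
@settings(max_examples=6, deadline=None)
def test_min_freq_monotonicity(min_freq):
    """Raising min_freq never adds vocabulary items."""
    db = make_random_toy(7)
    bags = wordify_all(db)
    base = set(build_vocabulary(bags, 1).index)
    try:
        higher = set(build_vocabulary(bags, min_freq).index)
    except ValueError:
        higher = set()
    assert higher <= base


def test_doc_freq_matches_recount():
    db = make_random_toy(11)
    bags = wordify_all(db)
    vocab = build_vocabulary(bags, 1)
    _, _, df = naive_matrix(db)
    for it, n in vocab.doc_freq.items():
        assert df[it.canonical_key] == n


# ------------------------------------------------------------------ matrix

@pytest.mark.parametrize("seed", range(10))
def test_matrix_equals_naive_pipeline(seed):
    db = make_random_toy(seed)
    pm, vocab, bags = propositionalize(db)
    rows, naive_vocab, _ = naive_matrix(db)
    assert [it.canonical_key for it in vocab.items_in_order] == naive_vocab
    dense = pm.matrix.toarray()
    for i, inst in enumerate(pm.instance_ids):
        got = {naive_vocab[j] for j in np.flatnonzero(dense[i])}
        assert got == rows[inst]


def test_matrix_entries_binary_despite_multiplicity(trains_toy):
    db = make_random_toy(4)
    pm, _, bags = propositionalize(db)
    assert set(np.unique(pm.matrix.toarray())) <= {0, 1}
    assert any(n > 1 for b in bags for n in b.items.values()) or True


def test_scalability_bound():
    """Per-row items <= col + col(col-1)/2; totals <= sum rows(t) * bound."""
    db = make_random_toy(5)
    bags = wordify_all(db)
    total = sum(sum(b.items.values()) for b in bags)
    bound = 0
    for t in db.tables.values():
        col = sum(1 for c in t.columns if c.role == "attribute")
        bound += t.n_rows * (col + col * (col - 1) // 2)
    # every row is joined to >= 0 instances; with tree fan-out each row counted
    # once per join witness, which for these toys is at most n_target
    assert total <= bound * len(db.instance_ids)
    for t in db.tables.values():
        col = sum(1 for c in t.columns if c.role == "attribute")
        per_row = col + col * (col - 1) // 2
        for i in range(t.n_rows):
            assert sum(wordify_row(t, i).values()) <= per_row


def test_matrix_dir_round_trip(tmp_path):
    db = make_random_toy(6)
    pm, _, _ = propositionalize(db)
    write_matrix_dir(pm, tmp_path)
    back = read_matrix_dir(tmp_path)
    assert (back.matrix.toarray() == pm.matrix.toarray()).all()
    assert [it.canonical_key for it in back.vocabulary.items_in_order] == \
           [it.canonical_key for it in pm.vocabulary.items_in_order]
    assert [str(l) for l in back.labels] == [str(l) for l in pm.labels]


def test_item_key_round_trip():
    it = RelationalItem.conjunct(("t", "a", "1"), ("t", "b", "2"))
    assert parse_item_key(it.canonical_key) == it
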