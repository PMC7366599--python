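"""Wordification: turn a relational database into per-instance bags of
relational items and a sparse binary propositional matrix.

Each target-table instance is described by the multiset of
``(table, column, value)`` triples found in its foreign-key neighborhood
(shortest FK path length at most ``max_order``, edges traversed in both
directions; default 2).  Within a single row, unordered pairs of those
triples are additionally emitted as size-2 conjuncts, capturing within-row
co-occurrence (e.g. a car that is *both* short and peaked-roofed).  Key,
id, and target columns never generate items.  Items whose document
frequency — the number of instance bags containing them — falls below
``min_freq`` are pruned from the vocabulary.  The final representation is
a binary (presence/absence) instance-by-item sparse matrix.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .store import (
    MISSING,
    ROLE_ATTRIBUTE,
    RelationalDatabase,
    Table,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelationalItem:
    """An arity-1 ``(table, column, value)`` feature or an arity-2 conjunct.

    Conjunct parts are stored in canonical lexicographic order so that the
    pair (A, B) and (B, A) are the same item.
    """

    parts: tuple[tuple[str, str, str], ...]

    @staticmethod
    def single(table: str, column: str, value: str) -> "RelationalItem":
        return RelationalItem(((table, column, str(value)),))

    @staticmethod
    def conjunct(a: tuple[str, str, str], b: tuple[str, str, str]) -> "RelationalItem":
        if a == b:
            raise ValueError("conjunct of an item with itself is not allowed")
        return RelationalItem(tuple(sorted((a, b))))

    @property
    def arity(self) -> int:
        return len(self.parts)

    @property
    def canonical_key(self) -> str:
        return "∧".join(f"{t}.{c}={v}" for t, c, v in self.parts)

    def __lt__(self, other: "RelationalItem") -> bool:
        return self.canonical_key < other.canonical_key

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Item({self.canonical_key})"


def parse_item_key(key: str) -> RelationalItem:
    """Inverse of :attr:`RelationalItem.canonical_key`."""
    parts = []
    for piece in key.split("∧"):
        tc, _, v = piece.partition("=")
        t, _, c = tc.partition(".")
        parts.append((t, c, v))
    return RelationalItem(tuple(parts))


@dataclass
class JoinIndex:
    """Maps each target instance to its linked row indices per reachable table.

    ``rowmap[table][instance_id]`` is the (multiset) list of row indices of
    ``table`` joined to that instance; ``order[table]`` is the FK-path length
    at which the table was reached (target table at order 0).
    """

    rowmap: dict[str, dict[object, list[int]]]
    order: dict[str, int]


def build_join_index(db: RelationalDatabase, max_order: int = 2) -> JoinIndex:
    """BFS over the FK graph from the target table, joining rows along the way.

    Each table is indexed once, at its minimal order; FK cycles therefore
    terminate naturally (logged).  Edges are traversed both child-to-parent
    and parent-to-child.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    target = db.tables[db.target_table]
    pk = target.primary_key
    if pk is None:
        raise ValueError(f"target table {target.name!r} has no primary key")
    pk_j = target.column_index(pk.name)

    rowmap: dict[str, dict[object, list[int]]] = {
        target.name: {row[pk_j]: [i] for i, row in enumerate(target.rows)}
    }
    order = {target.name: 0}

    # adjacency: table -> list of (other_table, child_table, fk_column)
    adj: dict[str, list[tuple[str, str, str]]] = {}
    for child, fkcol, parent in db.fk_edges:
        adj.setdefault(child, []).append((parent, child, fkcol))
        adj.setdefault(parent, []).append((child, child, fkcol))

    queue = deque([target.name])
    while queue:
        a = queue.popleft()
        if order[a] >= max_order:
            continue
        for other, child, fkcol in sorted(adj.get(a, [])):
            if other in order:
                if order[other] < order[a] + 1:
                    continue
                logger.info("fk cycle: table %s already indexed at order %d", other, order[other])
                continue
            ta, tb = db.tables[a], db.tables[other]
            new: dict[object, list[int]] = {}
            if child == a:
                # a holds the fk: follow child -> parent (pk lookup in b)
                fk_j = ta.column_index(fkcol)
                pk_b = tb.primary_key
                pk_bj = tb.column_index(pk_b.name)
                by_pk: dict[object, list[int]] = {}
                for i, row in enumerate(tb.rows):
                    by_pk.setdefault(row[pk_bj], []).append(i)
                for inst, rows_a in rowmap[a].items():
                    acc: list[int] = []
                    for r in rows_a:
                        v = ta.rows[r][fk_j]
                        if v is not MISSING:
                            acc.extend(by_pk.get(v, ()))
                    new[inst] = acc
            else:
                # b holds the fk: follow parent -> child (fk lookup in b)
                pk_a = ta.primary_key
                pk_aj = ta.column_index(pk_a.name)
                fk_j = tb.column_index(fkcol)
                by_fk: dict[object, list[int]] = {}
                for i, row in enumerate(tb.rows):
                    v = row[fk_j]
                    if v is not MISSING:
                        by_fk.setdefault(v, []).append(i)
                for inst, rows_a in rowmap[a].items():
                    acc = []
                    for r in rows_a:
                        acc.extend(by_fk.get(ta.rows[r][pk_aj], ()))
                    new[inst] = acc
            rowmap[other] = new
            order[other] = order[a] + 1
            queue.append(other)
    return JoinIndex(rowmap=rowmap, order=order)


def discretize_numeric(
    values: Sequence,
    n_bins: int = 4,
    strategy: str = "quantile",
    edges: np.ndarray | None = None,
) -> list:
    """Map numeric values to deterministic ``binK_of_N`` labels.

    ``strategy`` is ``quantile`` (equal-frequency) or ``width``
    (equal-width).  Pre-computed ``edges`` (from :func:`numeric_bin_edges`)
    override the strategy, which is how training-fold edges are applied to
    held-out rows.  Missing values stay missing; an all-missing column
    yields all missing markers with a warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    finite = [v for v in values if v is not MISSING]
    if edges is None:
        if not finite:
            logger.warning("discretize_numeric: all values missing")
            return [MISSING] * len(values)
        edges = numeric_bin_edges(finite, n_bins, strategy)
    n = len(edges) + 1
    out = []
    for v in values:
        if v is MISSING:
            out.append(MISSING)
        else:
            k = int(np.searchsorted(edges, v, side="right")) + 1
            out.append(f"bin{k}_of_{n}")
    return out


def numeric_bin_edges(values: Sequence, n_bins: int, strategy: str = "quantile") -> np.ndarray:
    """Interior bin edges for :func:`discretize_numeric` (n_bins - 1 of them)."""
    arr = np.asarray([v for v in values if v is not MISSING], dtype=float)
    if arr.size == 0:
        return np.empty(0)
    if strategy == "quantile":
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = np.unique(np.quantile(arr, qs))
        edges = edges[(edges > arr.min()) & (edges < arr.max())]
    elif strategy == "width":
        lo, hi = arr.min(), arr.max()
        if lo == hi:
            return np.empty(0)
        edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return edges


@dataclass
class InstanceBag:
    """The multiset of relational items collected for one target instance."""

    instance_id: object
    items: Counter
    label: object = None

    @property
    def unique_items(self) -> set[RelationalItem]:
        return set(self.items)


@dataclass
class Vocabulary:
    """Bijection between retained items and dense column indices."""

    index: dict[RelationalItem, int]
    doc_freq: dict[RelationalItem, int]
    min_freq: int = 1

    def __len__(self) -> int:
        return len(self.index)

    @property
    def items_in_order(self) -> list[RelationalItem]:
        inv = sorted(self.index, key=self.index.__getitem__)
        return inv


@dataclass
class PropositionalMatrix:
    """Sparse binary instance-by-item matrix paired with its vocabulary."""

    matrix: sp.csr_matrix
    vocabulary: Vocabulary
    instance_ids: list
    labels: list

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class WordifyParams:
    """Knobs of the propositionalization pipeline."""

    max_order: int = 2
    make_conjuncts: bool = True
    min_freq: int = 1
    n_bins: int = 4
    bin_strategy: str = "quantile"


def _attribute_columns(table: Table) -> list[int]:
    return [j for j, c in enumerate(table.columns) if c.role == ROLE_ATTRIBUTE]


def wordify_row(
    table: Table,
    row_index: int,
    make_conjuncts: bool = True,
    values: Sequence | None = None,
) -> Counter:
    """Items of one row: one per non-missing attribute column, plus all
    unordered size-2 conjuncts of those if requested.

    ``values`` optionally overrides the raw row (used to substitute
    discretized symbols for numeric values).
    """
    row = values if values is not None else table.rows[row_index]
    singles: list[tuple[str, str, str]] = []
    for j in _attribute_columns(table):
        v = row[j]
        if v is MISSING:
            continue
        singles.append((table.name, table.columns[j].name, str(v)))
    items = Counter(RelationalItem((p,)) for p in singles)
    if make_conjuncts:
        for i in range(len(singles)):
            for j in range(i + 1, len(singles)):
                items[RelationalItem.conjunct(singles[i], singles[j])] += 1
    return items


def _symbolized_rows(db: RelationalDatabase, bin_edges: dict) -> dict[str, list[list]]:
    """Per-table rows with numeric attribute values replaced by bin labels."""
    out: dict[str, list[list]] = {}
    for t in db.tables.values():
        cols = [list(r) for r in t.rows]
        for j, c in enumerate(t.columns):
            if c.role == ROLE_ATTRIBUTE and c.value_kind == "numeric":
                edges = bin_edges.get((t.name, c.name))
                if edges is None:
                    continue
                labels = discretize_numeric([r[j] for r in t.rows], edges=edges,
                                            n_bins=len(edges) + 1)
                for row, lab in zip(cols, labels):
                    row[j] = lab
        out[t.name] = cols
    return out


def fit_bin_edges(
    db: RelationalDatabase,
    ji: JoinIndex,
    params: WordifyParams,
    instance_ids: Iterable | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Quantile/width bin edges per numeric attribute column, computed only
    from rows linked to the given instances (all instances by default)."""
    edges: dict[tuple[str, str], np.ndarray] = {}
    for tname, mapping in ji.rowmap.items():
        t = db.tables[tname]
        num_cols = [
            (j, c.name) for j, c in enumerate(t.columns)
            if c.role == ROLE_ATTRIBUTE and c.value_kind == "numeric"
        ]
        if not num_cols:
            continue
        ids = list(mapping) if instance_ids is None else list(instance_ids)
        row_idx = sorted({r for i in ids for r in mapping.get(i, ())})
        for j, cname in num_cols:
            vals = [t.rows[r][j] for r in row_idx if t.rows[r][j] is not MISSING]
            edges[(tname, cname)] = numeric_bin_edges(vals, params.n_bins, params.bin_strategy)
    return edges


def wordify_instance(
    db: RelationalDatabase,
    ji: JoinIndex,
    instance_id,
    params: WordifyParams = WordifyParams(),
    symbolized: dict[str, list[list]] | None = None,
) -> InstanceBag:
    """Disjoint multiset union of row items over the instance's FK neighborhood."""
    if instance_id not in ji.rowmap[db.target_table]:
        raise KeyError(f"unknown instance id {instance_id!r}")
    if symbolized is None:
        symbolized = _symbolized_rows(
            db, fit_bin_edges(db, ji, params))
    bag: Counter = Counter()
    for tname, mapping in ji.rowmap.items():
        t = db.tables[tname]
        rows = symbolized[tname]
        for r in mapping.get(instance_id, ()):
            bag.update(wordify_row(t, r, params.make_conjuncts, values=rows[r]))
    tt = db.tables[db.target_table]
    label_j = tt.column_index(db.target_column)
    (row_i,) = ji.rowmap[db.target_table][instance_id]
    return InstanceBag(instance_id=instance_id, items=bag, label=tt.rows[row_i][label_j])


def wordify_all(
    db: RelationalDatabase,
    params: WordifyParams = WordifyParams(),
    bin_edges: dict | None = None,
) -> list[InstanceBag]:
    """Bags for every target instance, in target-table row order."""
    ji = build_join_index(db, params.max_order)
    if bin_edges is None:
        bin_edges = fit_bin_edges(db, ji, params)
    symb = _symbolized_rows(db, bin_edges)
    return [
        wordify_instance(db, ji, i, params, symbolized=symb)
        for i in db.instance_ids
    ]


def build_vocabulary(bags: Sequence[InstanceBag], min_freq: int = 1) -> Vocabulary:
    """Retain items present in at least ``min_freq`` bags; indices follow
    canonical lexicographic item order."""
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    df: Counter = Counter()
    for bag in bags:
        df.update(bag.unique_items)
    kept = sorted((it for it, n in df.items() if n >= min_freq),
                  key=lambda it: it.canonical_key)
    if not kept:
        raise ValueError(
            f"no relational item reaches document frequency {min_freq}; lower min_freq"
        )
    return Vocabulary(index={it: j for j, it in enumerate(kept)},
                      doc_freq={it: df[it] for it in kept}, min_freq=min_freq)


def bags_to_matrix(bags: Sequence[InstanceBag], vocab: Vocabulary) -> PropositionalMatrix:
    """Binary indicator matrix: entry (i, j) is 1 iff bag i contains item j.

    Multiplicity is collapsed — presence, not count.  Out-of-vocabulary
    items (e.g. on held-out folds) are dropped.
    """
    rows, cols = [], []
    for i, bag in enumerate(bags):
        for it in bag.unique_items:
            j = vocab.index.get(it)
            if j is not None:
                rows.append(i)
                cols.append(j)
    m = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(bags), len(vocab)),
    )
    return PropositionalMatrix(
        matrix=m,
        vocabulary=vocab,
        instance_ids=[b.instance_id for b in bags],
        labels=[b.label for b in bags],
    )


def propositionalize(
    db: RelationalDatabase,
    params: WordifyParams = WordifyParams(),
) -> tuple[PropositionalMatrix, Vocabulary, list[InstanceBag]]:
    """Full pipeline: join index -> bags -> vocabulary -> binary sparse matrix."""
    bags = wordify_all(db, params)
    vocab = build_vocabulary(bags, params.min_freq)
    return bags_to_matrix(bags, vocab), vocab, bags


# ---------------------------------------------------------------------------
# On-disk trio: MatrixMarket matrix + vocabulary TSV + labels CSV
# ---------------------------------------------------------------------------

def write_matrix_dir(pm: PropositionalMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), pm.matrix.tocoo(), field="integer")
    with open(directory / "vocabulary.tsv", "w") as fh:
        for it in pm.vocabulary.items_in_order:
            fh.write(
                f"{pm.vocabulary.index[it]}\t{it.arity}\t{it.canonical_key}\t"
                f"{pm.vocabulary.doc_freq[it]}\n"
            )
    with open(directory / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["instance_id", "label"])
        for i, lab in zip(pm.instance_ids, pm.labels):
            w.writerow([i, "" if lab is MISSING else lab])


def read_matrix_dir(directory: str | Path) -> PropositionalMatrix:
    directory = Path(directory)
    m = sp.csr_matrix(mmread(str(directory / "matrix.mtx")))
    index: dict[RelationalItem, int] = {}
    df: dict[RelationalItem, int] = {}
    with open(directory / "vocabulary.tsv") as fh:
        for line in fh:
            idx, _arity, key, freq = line.rstrip("\n").split("\t")
            it = parse_item_key(key)
            index[it] = int(idx)
            df[it] = int(freq)
    ids, labels = [], []
    with open(directory / "labels.csv", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for i, lab in reader:
            ids.append(i)
            labels.append(lab if lab != "" else MISSING)
    return PropositionalMatrix(
        matrix=m, vocabulary=Vocabulary(index=index, doc_freq=df),
        instance_ids=ids, labels=labels,
    )
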