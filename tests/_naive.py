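"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: foreign-key joins are materialized by nested loops over
full row sets, items are collected as plain string tuples, and document
frequencies are recounted from scratch.  Nothing here shares code with the
package's optimized path.
"""

from collections import Counter
from itertools import combinations

from relprop.store import MISSING, RelationalDatabase


def _attr_cols(table):
    return [(j, c.name) for j, c in enumerate(table.columns) if c.role == "attribute"]


def _edges(db: RelationalDatabase):
    return db.fk_edges


def naive_reachable(db: RelationalDatabase, max_order: int):
    """Shortest-path orders from the target table, edges undirected."""
    order = {db.target_table: 0}
    frontier = [db.target_table]
    while frontier:
        nxt = []
        for a in frontier:
            for child, fk, parent in _edges(db):
                for b in (parent if child == a else child if parent == a else None,):
                    if b is not None and b not in order and order[a] + 1 <= max_order:
                        order[b] = order[a] + 1
                        nxt.append(b)
        frontier = nxt
    return order


def naive_linked_rows(db: RelationalDatabase, instance_id, max_order: int):
    """Multiset of (table, row_index) joined to an instance, by nested loops.

    Rows are accumulated path-step by path-step: the multiplicity of a row
    equals the number of join witnesses, matching disjoint multiset union.
    """
    order = naive_reachable(db, max_order)
    tt = db.tables[db.target_table]
    pk_j = tt.column_index(tt.primary_key.name)
    current = {db.target_table: [i for i, r in enumerate(tt.rows) if r[pk_j] == instance_id]}
    result = Counter({(db.target_table, i): 1 for i in current[db.target_table]})
    done = {db.target_table}
    for o in range(1, max_order + 1):
        new = {}
        for b, ob in order.items():
            if ob != o:
                continue
            # find the edge connecting b to some table at order o-1
            for child, fk, parent in _edges(db):
                a = None
                if child == b and parent in current and order[parent] == o - 1:
                    a = parent
                elif parent == b and child in current and order[child] == o - 1:
                    a = child
                if a is None:
                    continue
                ta, tb = db.tables[a], db.tables[b]
                rows_b = []
                if child == b:  # b holds the fk to a
                    fk_j = tb.column_index(fk)
                    pk_a = ta.column_index(ta.primary_key.name)
                    for ra in current[a]:
                        for i, rb in enumerate(tb.rows):
                            if rb[fk_j] is not MISSING and rb[fk_j] == ta.rows[ra][pk_a]:
                                rows_b.append(i)
                else:  # a holds the fk to b
                    fk_j = ta.column_index(fk)
                    pk_b = tb.column_index(tb.primary_key.name)
                    for ra in current[a]:
                        v = ta.rows[ra][fk_j]
                        if v is MISSING:
                            continue
                        for i, rb in enumerate(tb.rows):
                            if rb[pk_b] == v:
                                rows_b.append(i)
                if b not in done:
                    new.setdefault(b, []).extend(rows_b)
                break  # one (shortest) path per table
        for b, rows in new.items():
            done.add(b)
            for i in rows:
                result[(b, i)] += 1
        current = {**current, **{b: rows for b, rows in new.items()}}
    return result


def naive_row_items(db, table_name, row_index, make_conjuncts):
    """Items of one row as canonical strings."""
    t = db.tables[table_name]
    row = t.rows[row_index]
    singles = [
        f"{table_name}.{cname}={row[j]}"
        for j, cname in _attr_cols(t)
        if row[j] is not MISSING
    ]
    items = list(singles)
    if make_conjuncts:
        for a, b in combinations(sorted(singles), 2):
            items.append(f"{a}∧{b}")
    return items


def naive_bag(db, instance_id, max_order=2, make_conjuncts=True):
    """Multiset of canonical item strings for one instance."""
    bag = Counter()
    for (tname, i), mult in naive_linked_rows(db, instance_id, max_order).items():
        for it in naive_row_items(db, tname, i, make_conjuncts):
            bag[it] += mult
    return bag


def naive_matrix(db, max_order=2, make_conjuncts=True, min_freq=1):
    """Binary matrix as dict-of-sets plus sorted vocabulary list."""
    bags = {i: naive_bag(db, i, max_order, make_conjuncts) for i in db.instance_ids}
    df = Counter()
    for b in bags.values():
        df.update(set(b))
    vocab = sorted(k for k, n in df.items() if n >= min_freq)
    rows = {i: {k for k in bags[i] if k in set(vocab)} for i in db.instance_ids}
    return rows, vocab, df
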