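"""Seeded synthetic relational databases with planted classification rules.

Two schema templates are provided.  The *trains* template mimics the
classic East-West challenge: a target table of trains, each linked to a
variable number of cars with categorical attributes (length, roof, shape,
wheels, load).  The *molecules* template mimics small-molecule activity
data: a target table of molecules with child tables of atoms (element,
charge bin) and bonds (bond type, ring flag).  Bonds reference the
molecule only, so all signal lives within the FK neighborhood of order 1.

Each generated instance is labeled by a planted rule — presence of one
relational item, of a same-row size-2 conjunct, or of two separate items —
and attribute values are minimally edited so the assigned class holds
exactly.  Class balance is exact; optional label noise flips each label
independently.  The pre-noise oracle labels are always returned so that
recovery experiments have a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .store import ColumnSpec, RelationalDatabase, Table
from .wordify import InstanceBag, RelationalItem

RULE_SINGLE = "single_item"
RULE_CONJUNCT = "same_row_conjunct"
RULE_TWO_ITEMS = "two_items"

TRAIN_ALPHABETS = {
    "length": ["short", "long"],
    "roof": ["none", "flat", "peaked", "jagged"],
    "shape": ["rectangle", "oval", "bucket"],
    "wheels": ["w2", "w3"],
    "load": ["circle", "triangle", "square", "nothing"],
}

MOLECULE_ALPHABETS = {
    "atoms": {
        "element": ["c", "n", "o", "h", "cl"],
        "charge_bin": ["neg", "neutral", "pos"],
    },
    "bonds": {
        "bond_type": ["single", "double", "aromatic"],
        "ring_flag": ["yes", "no"],
    },
}


@dataclass(frozen=True)
class PlantedRule:
    """Ground-truth labeling rule decidable from a single instance's bag."""

    rule_kind: str
    conditions: tuple[tuple[str, str, str], ...]
    positive_label: str = "east"
    negative_label: str = "west"

    def __post_init__(self) -> None:
        want = {RULE_SINGLE: 1, RULE_CONJUNCT: 2, RULE_TWO_ITEMS: 2}
        if self.rule_kind not in want:
            raise ValueError(f"unknown rule kind {self.rule_kind!r}")
        if len(self.conditions) != want[self.rule_kind]:
            raise ValueError(
                f"{self.rule_kind} rule needs {want[self.rule_kind]} condition(s)"
            )
        if self.rule_kind == RULE_CONJUNCT:
            (t1, *_), (t2, *_) = self.conditions
            if t1 != t2:
                raise ValueError("same-row conjunct conditions must share a table")


DEFAULT_TRAINS_RULE = PlantedRule(
    rule_kind=RULE_CONJUNCT,
    conditions=(("cars", "length", "short"), ("cars", "roof", "peaked")),
    positive_label="east",
    negative_label="west",
)

DEFAULT_MOLECULES_RULE = PlantedRule(
    rule_kind=RULE_CONJUNCT,
    conditions=(("bonds", "bond_type", "aromatic"), ("bonds", "ring_flag", "yes")),
    positive_label="active",
    negative_label="inactive",
)


@dataclass
class SyntheticSpec:
    """Everything that determines a generated database, including the seed."""

    schema_kind: str = "trains"
    n_instances: int = 200
    class_balance: float = 0.5
    rule: PlantedRule | None = None
    label_noise: float = 0.0
    child_count_range: tuple[int, int] = (2, 5)
    balance_marginals: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schema_kind not in ("trains", "molecules"):
            raise ValueError(f"unknown schema kind {self.schema_kind!r}")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_instances < 2:
            raise ValueError("n_instances must be >= 2")
        if not (0 < self.class_balance < 1):
            raise ValueError("class_balance must be in (0, 1)")
        if self.rule is None:
            self.rule = (DEFAULT_TRAINS_RULE if self.schema_kind == "trains"
                         else DEFAULT_MOLECULES_RULE)


def apply_rule_oracle(rule: PlantedRule, bag: InstanceBag) -> str:
    """Positive label iff the rule's item(s) are present in the bag."""
    if rule.rule_kind == RULE_SINGLE:
        hit = RelationalItem((rule.conditions[0],)) in bag.items
    elif rule.rule_kind == RULE_CONJUNCT:
        hit = RelationalItem.conjunct(*rule.conditions) in bag.items
    else:
        hit = all(RelationalItem((c,)) in bag.items for c in rule.conditions)
    return rule.positive_label if hit else rule.negative_label


def _assign_classes(n: int, balance: float, rng: np.random.Generator) -> np.ndarray:
    """Exact class counts: round(n * balance) positives, shuffled."""
    n_pos = round(n * balance)
    flags = np.zeros(n, dtype=bool)
    flags[:n_pos] = True
    rng.shuffle(flags)
    return flags


def _row_satisfies(row: dict, conds) -> bool:
    return all(row.get(c) == v for _, c, v in conds)


def _deny_condition(row: dict, conds, alphabets, rng) -> None:
    """Minimally edit the row so it no longer satisfies all of ``conds``."""
    _, col, val = conds[rng.integers(len(conds))]
    choices = [a for a in alphabets[col] if a != val]
    row[col] = choices[rng.integers(len(choices))]


def _sample_row(alphabets: dict, rng) -> dict:
    return {c: vals[rng.integers(len(vals))] for c, vals in alphabets.items()}


def _plant_trains_instance(
    positive: bool, rule: PlantedRule, spec: SyntheticSpec, rng
) -> list[dict]:
    lo, hi = spec.child_count_range
    n_cars = int(rng.integers(lo, hi + 1))
    cars = [_sample_row(TRAIN_ALPHABETS, rng) for _ in range(n_cars)]
    conds = [c for c in rule.conditions if c[0] == "cars"]
    if positive:
        tgt = cars[rng.integers(n_cars)]
        if rule.rule_kind == RULE_TWO_ITEMS:
            for t, c, v in rule.conditions:
                cars[rng.integers(n_cars)][c] = v
        else:
            for _, c, v in conds:
                tgt[c] = v
    else:
        if rule.rule_kind == RULE_TWO_ITEMS:
            # deny one condition everywhere
            _, col, val = rule.conditions[rng.integers(2)]
            for car in cars:
                if car[col] == val:
                    _deny_condition(car, [(None, col, val)], TRAIN_ALPHABETS, rng)
        else:
            for car in cars:
                if _row_satisfies(car, conds):
                    _deny_condition(car, conds, TRAIN_ALPHABETS, rng)
        if spec.balance_marginals and rule.rule_kind == RULE_CONJUNCT:
            # plant each singleton separately so marginals carry no signal
            (_, c1, v1), (_, c2, v2) = rule.conditions
            a, b = rng.permutation(n_cars)[:2] if n_cars >= 2 else (0, 0)
            if n_cars >= 2:
                cars[a][c1] = v1
                if cars[a][c2] == v2:
                    _deny_condition(cars[a], [(None, c2, v2)], TRAIN_ALPHABETS, rng)
                cars[b][c2] = v2
                if cars[b][c1] == v1:
                    _deny_condition(cars[b], [(None, c1, v1)], TRAIN_ALPHABETS, rng)
    return cars


def generate_trains(spec: SyntheticSpec) -> tuple[RelationalDatabase, list[str]]:
    """East-West style database: trains 1-to-many cars, rule over car items."""
    if spec.schema_kind != "trains":
        raise ValueError("spec.schema_kind must be 'trains'")
    rule = spec.rule
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10]))
    pos_flags = _assign_classes(spec.n_instances, spec.class_balance, rng)

    train_rows, car_rows = [], []
    oracle: list[str] = []
    car_id = 1
    for i in range(spec.n_instances):
        cars = _plant_trains_instance(bool(pos_flags[i]), rule, spec, rng)
        label = rule.positive_label if pos_flags[i] else rule.negative_label
        oracle.append(label)
        for car in cars:
            car_rows.append((car_id, i + 1, car["length"], car["roof"],
                             car["shape"], car["wheels"], car["load"]))
            car_id += 1
        train_rows.append([i + 1, label])

    noisy = _apply_label_noise(oracle, rule, spec, rng)
    for row, lab in zip(train_rows, noisy):
        row[1] = lab

    trains = Table("trains", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("direction", role="target"),
    ], [tuple(r) for r in train_rows])
    cars_t = Table("cars", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("train_id", role="foreign_key", referenced_table="trains"),
        ColumnSpec("length"), ColumnSpec("roof"), ColumnSpec("shape"),
        ColumnSpec("wheels"), ColumnSpec("load"),
    ], car_rows)
    db = RelationalDatabase(tables={"trains": trains, "cars": cars_t},
                            target_table="trains", target_column="direction")
    return db, oracle


def _plant_molecule_instance(positive: bool, rule: PlantedRule,
                             spec: SyntheticSpec, rng):
    lo, hi = spec.child_count_range
    atoms = [_sample_row(MOLECULE_ALPHABETS["atoms"], rng)
             for _ in range(int(rng.integers(lo, hi + 1)))]
    bonds = [_sample_row(MOLECULE_ALPHABETS["bonds"], rng)
             for _ in range(int(rng.integers(lo, hi + 1)))]
    rows_by_table = {"atoms": atoms, "bonds": bonds}
    by_table: dict[str, list] = {}
    for cond in rule.conditions:
        by_table.setdefault(cond[0], []).append(cond)
    if positive:
        if rule.rule_kind == RULE_TWO_ITEMS:
            for t, c, v in rule.conditions:
                rows = rows_by_table[t]
                rows[rng.integers(len(rows))][c] = v
        else:
            t = rule.conditions[0][0]
            rows = rows_by_table[t]
            tgt = rows[rng.integers(len(rows))]
            for _, c, v in rule.conditions:
                tgt[c] = v
    else:
        if rule.rule_kind == RULE_TWO_ITEMS:
            t, col, val = rule.conditions[rng.integers(2)]
            for row in rows_by_table[t]:
                if row[col] == val:
                    _deny_condition(row, [(None, col, val)],
                                    MOLECULE_ALPHABETS[t], rng)
        else:
            t = rule.conditions[0][0]
            conds = by_table[t]
            for row in rows_by_table[t]:
                if _row_satisfies(row, conds):
                    _deny_condition(row, conds, MOLECULE_ALPHABETS[t], rng)
    return atoms, bonds


def generate_molecules(spec: SyntheticSpec) -> tuple[RelationalDatabase, list[str]]:
    """Molecule-style database: molecules with atoms and bonds child tables."""
    if spec.schema_kind != "molecules":
        raise ValueError("spec.schema_kind must be 'molecules'")
    rule = spec.rule
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 20]))
    pos_flags = _assign_classes(spec.n_instances, spec.class_balance, rng)

    mol_rows, atom_rows, bond_rows = [], [], []
    oracle: list[str] = []
    atom_id = bond_id = 1
    for i in range(spec.n_instances):
        atoms, bonds = _plant_molecule_instance(bool(pos_flags[i]), rule, spec, rng)
        label = rule.positive_label if pos_flags[i] else rule.negative_label
        oracle.append(label)
        for a in atoms:
            atom_rows.append((atom_id, i + 1, a["element"], a["charge_bin"]))
            atom_id += 1
        for b in bonds:
            bond_rows.append((bond_id, i + 1, b["bond_type"], b["ring_flag"]))
            bond_id += 1
        mol_rows.append([i + 1, label])

    noisy = _apply_label_noise(oracle, rule, spec, rng)
    for row, lab in zip(mol_rows, noisy):
        row[1] = lab

    molecules = Table("molecules", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("active", role="target"),
    ], [tuple(r) for r in mol_rows])
    atoms_t = Table("atoms", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("mol_id", role="foreign_key", referenced_table="molecules"),
        ColumnSpec("element"), ColumnSpec("charge_bin"),
    ], atom_rows)
    bonds_t = Table("bonds", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("mol_id", role="foreign_key", referenced_table="molecules"),
        ColumnSpec("bond_type"), ColumnSpec("ring_flag"),
    ], bond_rows)
    db = RelationalDatabase(
        tables={"molecules": molecules, "atoms": atoms_t, "bonds": bonds_t},
        target_table="molecules", target_column="active")
    return db, oracle


def _apply_label_noise(oracle: Sequence[str], rule: PlantedRule,
                       spec: SyntheticSpec, rng) -> list[str]:
    if spec.label_noise == 0:
        return list(oracle)
    flip = rng.random(len(oracle)) < spec.label_noise
    other = {rule.positive_label: rule.negative_label,
             rule.negative_label: rule.positive_label}
    return [other[l] if f else l for l, f in zip(oracle, flip)]


def generate(spec: SyntheticSpec) -> tuple[RelationalDatabase, list[str]]:
    """Dispatch on schema kind."""
    if spec.schema_kind == "trains":
        return generate_trains(spec)
    return generate_molecules(spec)


def generate_null(spec: SyntheticSpec) -> tuple[RelationalDatabase, list[str]]:
    """Negative control: same schema, labels independent of all attributes.

    Label counts are exact at the configured balance (a seeded balanced
    shuffle), so chance-level accuracy is well defined.
    """
    db, _ = generate(replace(spec, label_noise=0.0))
    rule = spec.rule
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 30]))
    flags = _assign_classes(spec.n_instances, spec.class_balance, rng)
    labels = [rule.positive_label if f else rule.negative_label for f in flags]
    tt = db.tables[db.target_table]
    j = tt.column_index(db.target_column)
    tt.rows = [tuple(list(r[:j]) + [lab] + list(r[j + 1:]))
               for r, lab in zip(tt.rows, labels)]
    return db, labels
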