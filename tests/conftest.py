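"""Shared fixtures: tiny hand-built databases and seeded random toy schemas."""

import numpy as np
import pytest

from relprop.store import ColumnSpec, RelationalDatabase, Table


def make_trains_toy():
    """2 trains, 3 cars; the classic 1-to-many shape."""
    trains = Table("trains", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("direction", role="target"),
    ], [(1, "east"), (2, "west")])
    cars = Table("cars", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("train_id", role="foreign_key", referenced_table="trains"),
        ColumnSpec("length"),
        ColumnSpec("roof"),
    ], [(1, 1, "short", "peaked"), (2, 1, "long", "flat"), (3, 2, "long", "none")])
    return RelationalDatabase(tables={"trains": trains, "cars": cars},
                              target_table="trains", target_column="direction")


def make_three_table_toy():
    """molecules -> atoms -> bonds chain; bonds reachable only at order 2."""
    molecules = Table("molecules", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("active", role="target"),
    ], [(1, "yes"), (2, "no")])
    atoms = Table("atoms", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("mol_id", role="foreign_key", referenced_table="molecules"),
        ColumnSpec("element"),
    ], [(1, 1, "c"), (2, 1, "n"), (3, 2, "o")])
    bonds = Table("bonds", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("atom_id", role="foreign_key", referenced_table="atoms"),
        ColumnSpec("kind"),
    ], [(1, 1, "single"), (2, 2, "double"), (3, 2, "aromatic"), (4, 3, "single")])
    return RelationalDatabase(
        tables={"molecules": molecules, "atoms": atoms, "bonds": bonds},
        target_table="molecules", target_column="active")


def make_random_toy(seed, n_target=4, n_child=5, n_grand=5):
    """Seeded random 3-table tree schema with <= 5 rows per table."""
    rng = np.random.default_rng(seed)
    cats = ["a", "b", "c"]
    t = Table("t", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("y", role="target"),
        ColumnSpec("p"),
    ], [(i + 1, cats[rng.integers(2)], cats[rng.integers(3)]) for i in range(n_target)])
    child = Table("child", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("t_id", role="foreign_key", referenced_table="t"),
        ColumnSpec("u"),
        ColumnSpec("v"),
    ], [(i + 1, int(rng.integers(1, n_target + 1)), cats[rng.integers(3)],
         cats[rng.integers(3)]) for i in range(n_child)])
    grand = Table("grand", [
        ColumnSpec("id", role="primary_key"),
        ColumnSpec("child_id", role="foreign_key", referenced_table="child"),
        ColumnSpec("w"),
    ], [(i + 1, int(rng.integers(1, n_child + 1)), cats[rng.integers(3)])
        for i in range(n_grand)])
    return RelationalDatabase(tables={"t": t, "child": child, "grand": grand},
                              target_table="t", target_column="y")


@pytest.fixture
def trains_toy():
    return make_trains_toy()


@pytest.fixture
def three_table_toy():
    return make_three_table_toy()
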