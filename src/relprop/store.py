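"""Typed in-memory representation of a multi-relational database.

A database is a set of named tables connected by foreign keys.  Every
column carries an explicit *role* — plain attribute, primary key, foreign
key, or classification target — because downstream propositionalization
must exclude key and target columns from feature construction.  Databases
can be loaded from (and written to) a small SQL dialect (``CREATE TABLE``
with key declarations plus ``INSERT INTO ... VALUES``) or from per-table
CSV files accompanied by a YAML/JSON schema config.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import yaml

logger = logging.getLogger(__name__)

#: Marker for an absent value.  Missing values never generate relational items.
MISSING = None

ROLE_ATTRIBUTE = "attribute"
ROLE_PRIMARY_KEY = "primary_key"
ROLE_FOREIGN_KEY = "foreign_key"
ROLE_TARGET = "target"

_ROLES = {ROLE_ATTRIBUTE, ROLE_PRIMARY_KEY, ROLE_FOREIGN_KEY, ROLE_TARGET}
_KINDS = {"categorical", "numeric"}


class SchemaError(ValueError):
    """Raised when a database or schema config violates structural invariants."""


class ParseError(ValueError):
    """Raised when an SQL dump cannot be parsed."""


@dataclass
class ColumnSpec:
    """Declaration of one column: its name, role, and value kind."""

    name: str
    role: str = ROLE_ATTRIBUTE
    referenced_table: str | None = None
    value_kind: str = "categorical"

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise SchemaError(f"unknown column role {self.role!r} for {self.name!r}")
        if self.value_kind not in _KINDS:
            raise SchemaError(f"unknown value kind {self.value_kind!r} for {self.name!r}")
        if self.role == ROLE_FOREIGN_KEY and not self.referenced_table:
            raise SchemaError(f"foreign key column {self.name!r} lacks a referenced table")
        if self.role != ROLE_FOREIGN_KEY and self.referenced_table:
            raise SchemaError(f"column {self.name!r} has role {self.role} but references a table")


@dataclass
class Table:
    """A named table: an ordered column list and a list of row tuples."""

    name: str
    columns: list[ColumnSpec]
    rows: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.columns:
            if c.name in seen:
                raise SchemaError(f"duplicate column {c.name!r} in table {self.name!r}")
            seen.add(c.name)
        pks = [c for c in self.columns if c.role == ROLE_PRIMARY_KEY]
        if len(pks) > 1:
            raise SchemaError(
                f"table {self.name!r} declares a composite primary key "
                f"({', '.join(c.name for c in pks)}); composite keys are not supported"
            )
        for r in self.rows:
            if len(r) != len(self.columns):
                raise SchemaError(
                    f"row arity {len(r)} != {len(self.columns)} columns in table {self.name!r}"
                )

    def column_index(self, name: str) -> int:
        for i, c in enumerate(self.columns):
            if c.name == name:
                return i
        raise KeyError(f"no column {name!r} in table {self.name!r}")

    @property
    def primary_key(self) -> ColumnSpec | None:
        for c in self.columns:
            if c.role == ROLE_PRIMARY_KEY:
                return c
        return None

    def column_values(self, name: str) -> list:
        j = self.column_index(name)
        return [r[j] for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class RelationalDatabase:
    """Tables plus the designated target table/column and the FK graph."""

    tables: dict[str, Table]
    target_table: str
    target_column: str

    def __post_init__(self) -> None:
        if self.target_table not in self.tables:
            raise SchemaError(f"target table {self.target_table!r} does not exist")
        tt = self.tables[self.target_table]
        tcol = tt.columns[tt.column_index(self.target_column)]
        if tcol.role == ROLE_ATTRIBUTE:
            tcol.role = ROLE_TARGET
        elif tcol.role != ROLE_TARGET:
            raise SchemaError(
                f"target column {self.target_column!r} has key role {tcol.role!r}"
            )
        targets = [
            (t.name, c.name)
            for t in self.tables.values()
            for c in t.columns
            if c.role == ROLE_TARGET
        ]
        if targets != [(self.target_table, self.target_column)]:
            raise SchemaError(f"expected exactly one target column, found {targets}")
        for child, fkcol, parent in self.fk_edges:
            if parent not in self.tables:
                raise SchemaError(
                    f"foreign key {child}.{fkcol} references missing table {parent!r}"
                )
            if self.tables[parent].primary_key is None:
                raise SchemaError(
                    f"foreign key {child}.{fkcol} references table {parent!r} "
                    "which has no primary key"
                )

    @property
    def fk_edges(self) -> list[tuple[str, str, str]]:
        """(child_table, fk_column, parent_table) triples, in declaration order."""
        return [
            (t.name, c.name, c.referenced_table)
            for t in self.tables.values()
            for c in t.columns
            if c.role == ROLE_FOREIGN_KEY
        ]

    @property
    def target_labels(self) -> list:
        tt = self.tables[self.target_table]
        return tt.column_values(self.target_column)

    @property
    def instance_ids(self) -> list:
        tt = self.tables[self.target_table]
        pk = tt.primary_key
        if pk is None:
            raise SchemaError(f"target table {self.target_table!r} has no primary key")
        return tt.column_values(pk.name)


@dataclass
class DatabaseStats:
    """Diagnostic counts produced by :func:`validate_database`."""

    n_tables: int
    rows_per_table: dict[str, int]
    cols_per_table: dict[str, int]
    dangling_fk_count: int
    duplicate_pk_count: int


def validate_database(db: RelationalDatabase) -> DatabaseStats:
    """Count tables/rows/columns and flag dangling FKs and duplicate PKs.

    Purely diagnostic — the database is never mutated.
    """
    dangling = 0
    duplicates = 0
    for t in db.tables.values():
        pk = t.primary_key
        if pk is not None:
            vals = t.column_values(pk.name)
            duplicates += len(vals) - len(set(vals))
    for child, fkcol, parent in db.fk_edges:
        parent_t = db.tables[parent]
        pk = parent_t.primary_key
        parent_keys = set(parent_t.column_values(pk.name))
        for v in db.tables[child].column_values(fkcol):
            if v is not MISSING and v not in parent_keys:
                dangling += 1
    return DatabaseStats(
        n_tables=len(db.tables),
        rows_per_table={t.name: t.n_rows for t in db.tables.values()},
        cols_per_table={t.name: len(t.columns) for t in db.tables.values()},
        dangling_fk_count=dangling,
        duplicate_pk_count=duplicates,
    )


# ---------------------------------------------------------------------------
# SQL dump reader / writer (minimal dialect)
# ---------------------------------------------------------------------------

_NUMERIC_INT_TYPES = {"INT", "INTEGER", "BIGINT", "SMALLINT", "TINYINT"}
_NUMERIC_FLOAT_TYPES = {"REAL", "FLOAT", "DOUBLE", "NUMERIC", "DECIMAL"}


def _split_statements(text: str) -> list[tuple[int, str]]:
    """Split on ';' outside single-quoted strings; return (line_no, stmt) pairs."""
    out = []
    buf: list[str] = []
    in_str = False
    line = 1
    start_line = 1
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "\n":
            line += 1
        if in_str:
            buf.append(ch)
            if ch == "'":
                if i + 1 < len(text) and text[i + 1] == "'":
                    buf.append("'")
                    i += 1
                else:
                    in_str = False
        elif ch == "'":
            in_str = True
            buf.append(ch)
        elif ch == ";":
            stmt = "".join(buf).strip()
            if stmt:
                out.append((start_line, stmt))
            buf = []
            start_line = line
        else:
            if not buf and not ch.isspace():
                start_line = line
            buf.append(ch)
        i += 1
    tail = "".join(buf).strip()
    if tail:
        out.append((start_line, tail))
    return out


def _unquote(ident: str) -> str:
    return ident.strip().strip('`"')


def _split_top_level_commas(s: str) -> list[str]:
    parts, depth, buf, in_str = [], 0, [], False
    for ch in s:
        if in_str:
            buf.append(ch)
            if ch == "'":
                in_str = False
            continue
        if ch == "'":
            in_str = True
            buf.append(ch)
        elif ch == "(":
            depth += 1
            buf.append(ch)
        elif ch == ")":
            depth -= 1
            buf.append(ch)
        elif ch == "," and depth == 0:
            parts.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
    if buf:
        parts.append("".join(buf).strip())
    return parts


_CREATE_RE = re.compile(r"CREATE\s+TABLE\s+(?:IF\s+NOT\s+EXISTS\s+)?([`\"\w]+)\s*\((.*)\)\s*$",
                        re.IGNORECASE | re.DOTALL)
_INSERT_RE = re.compile(
    r"INSERT\s+INTO\s+([`\"\w]+)\s*(\([^)]*\))?\s*VALUES\s*(.*)$",
    re.IGNORECASE | re.DOTALL,
)
_FK_RE = re.compile(
    r"FOREIGN\s+KEY\s*\(([^)]+)\)\s*REFERENCES\s+([`\"\w]+)\s*(?:\([^)]*\))?",
    re.IGNORECASE,
)
_PK_RE = re.compile(r"PRIMARY\s+KEY\s*\(([^)]+)\)", re.IGNORECASE)


def _parse_create(body_match: re.Match) -> Table:
    name = _unquote(body_match.group(1))
    body = body_match.group(2)
    columns: list[ColumnSpec] = []
    kinds: dict[str, str] = {}
    parsers: dict[str, Any] = {}
    pk_cols: list[str] = []
    fk_map: dict[str, str] = {}
    for part in _split_top_level_commas(body):
        mfk = _FK_RE.match(part)
        mpk = _PK_RE.match(part)
        if mfk:
            cols = [_unquote(c) for c in mfk.group(1).split(",")]
            if len(cols) != 1:
                raise ParseError(f"composite foreign key in table {name!r} is not supported")
            fk_map[cols[0]] = _unquote(mfk.group(2))
        elif mpk:
            pk_cols.extend(_unquote(c) for c in mpk.group(1).split(","))
        elif re.match(r"(UNIQUE|CHECK|CONSTRAINT|KEY|INDEX)\b", part, re.IGNORECASE):
            logger.info("skipping constraint clause in table %s: %s", name, part[:60])
        else:
            tokens = part.split()
            cname = _unquote(tokens[0])
            ctype = tokens[1].upper().split("(")[0] if len(tokens) > 1 else "TEXT"
            if re.search(r"PRIMARY\s+KEY", part, re.IGNORECASE):
                pk_cols.append(cname)
            columns.append(ColumnSpec(name=cname))
            if ctype in _NUMERIC_INT_TYPES:
                kinds[cname] = "numeric"
                parsers[cname] = int
            elif ctype in _NUMERIC_FLOAT_TYPES:
                kinds[cname] = "numeric"
                parsers[cname] = float
            else:
                kinds[cname] = "categorical"
                parsers[cname] = str
    if len(pk_cols) > 1:
        raise SchemaError(
            f"table {name!r} declares a composite primary key; composite keys are not supported"
        )
    specs = []
    for c in columns:
        role = ROLE_ATTRIBUTE
        ref = None
        if c.name in pk_cols:
            role = ROLE_PRIMARY_KEY
        elif c.name in fk_map:
            role = ROLE_FOREIGN_KEY
            ref = fk_map[c.name]
        specs.append(ColumnSpec(c.name, role=role, referenced_table=ref,
                                value_kind=kinds[c.name]))
    t = Table(name=name, columns=specs)
    t._parsers = parsers  # type: ignore[attr-defined]
    return t


def _parse_sql_value(tok: str, parser) -> Any:
    tok = tok.strip()
    if tok.upper() == "NULL" or tok == "":
        return MISSING
    if tok.startswith("'") and tok.endswith("'"):
        inner = tok[1:-1].replace("''", "'")
        return inner.strip() if parser is str else parser(inner)
    return parser(tok)


def _parse_insert(m: re.Match, tables: dict[str, Table]) -> None:
    tname = _unquote(m.group(1))
    if tname not in tables:
        raise ParseError(f"INSERT into undeclared table {tname!r}")
    t = tables[tname]
    parsers = getattr(t, "_parsers", {c.name: str for c in t.columns})
    if m.group(2):
        col_names = [_unquote(c) for c in m.group(2).strip("()").split(",")]
    else:
        col_names = [c.name for c in t.columns]
    tuples = _split_top_level_commas(m.group(3))
    for tup in tuples:
        tup = tup.strip()
        if not (tup.startswith("(") and tup.endswith(")")):
            raise ParseError(f"malformed VALUES tuple in INSERT INTO {tname}: {tup[:60]}")
        raw = _split_top_level_commas(tup[1:-1])
        if len(raw) != len(col_names):
            raise ParseError(
                f"INSERT INTO {tname} arity {len(raw)} != {len(col_names)} columns"
            )
        row = [MISSING] * len(t.columns)
        for cname, tok in zip(col_names, raw):
            j = t.column_index(cname)
            row[j] = _parse_sql_value(tok, parsers.get(cname, str))
        t.rows.append(tuple(row))


def load_sql_dump(path: str | Path, target_table: str, target_column: str) -> RelationalDatabase:
    """Load a database from an SQL dump.

    Supports ``CREATE TABLE`` with inline or clause-level ``PRIMARY KEY`` and
    ``FOREIGN KEY ... REFERENCES`` declarations (MySQL backtick quoting
    tolerated) and multi-row ``INSERT INTO ... VALUES``.  Any other statement
    is skipped with a log message.  The target table/column are supplied by
    the caller since SQL carries no such designation.
    """
    text = Path(path).read_text()
    tables: dict[str, Table] = {}
    for line_no, stmt in _split_statements(text):
        mc = _CREATE_RE.match(stmt)
        mi = _INSERT_RE.match(stmt)
        try:
            if mc:
                t = _parse_create(mc)
                tables[t.name] = t
            elif mi:
                _parse_insert(mi, tables)
            else:
                logger.info("skipping unsupported SQL statement at line %d: %s",
                            line_no, stmt.split("\n")[0][:60])
        except (SchemaError, ParseError):
            raise
        except Exception as exc:  # malformed statement content
            raise ParseError(f"failed to parse statement at line {line_no}: {exc}") from exc
    return RelationalDatabase(tables=tables, target_table=target_table,
                              target_column=target_column)


def _sql_literal(v: Any) -> str:
    if v is MISSING:
        return "NULL"
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, (int, float)):
        return repr(v)
    return "'" + str(v).replace("'", "''") + "'"


def _sql_type(table: Table, col: ColumnSpec) -> str:
    vals = [v for v in table.column_values(col.name) if v is not MISSING]
    if vals and all(isinstance(v, bool) is False and isinstance(v, int) for v in vals):
        return "INTEGER"
    if vals and all(isinstance(v, (int, float)) for v in vals):
        return "DOUBLE"
    return "TEXT"


def write_sql_dump(db: RelationalDatabase, path: str | Path) -> None:
    """Serialize the database to the SQL subset read by :func:`load_sql_dump`."""
    lines: list[str] = []
    for t in db.tables.values():
        defs = [f"  `{c.name}` {_sql_type(t, c)}" for c in t.columns]
        pk = t.primary_key
        if pk is not None:
            defs.append(f"  PRIMARY KEY (`{pk.name}`)")
        for c in t.columns:
            if c.role == ROLE_FOREIGN_KEY:
                parent_pk = db.tables[c.referenced_table].primary_key
                defs.append(
                    f"  FOREIGN KEY (`{c.name}`) REFERENCES `{c.referenced_table}` (`{parent_pk.name}`)"
                )
        lines.append(f"CREATE TABLE `{t.name}` (\n" + ",\n".join(defs) + "\n);")
        for row in t.rows:
            vals = ", ".join(_sql_literal(v) for v in row)
            lines.append(f"INSERT INTO `{t.name}` VALUES ({vals});")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV-per-table + schema config reader / writer
# ---------------------------------------------------------------------------

def _infer_role(colname: str) -> str:
    if colname == "id":
        return ROLE_PRIMARY_KEY
    if colname.endswith("_id"):
        return ROLE_FOREIGN_KEY
    return ROLE_ATTRIBUTE


def load_csv_with_schema(directory: str | Path, schema: dict | str | Path) -> RelationalDatabase:
    """Load one CSV per table with roles/kinds given by a schema config.

    The schema maps ``tables.<name>.columns.<name>.{role, references, kind}``
    and ``target.{table, column}``.  Columns absent from the schema fall back
    to name-based role inference (``id`` → primary key, ``*_id`` → foreign
    key to the table named by the prefix); explicit config always wins.
    Empty CSV cells are missing values.
    """
    directory = Path(directory)
    if not isinstance(schema, dict):
        text = Path(schema).read_text()
        schema = yaml.safe_load(text)
    target = schema.get("target", {})
    tables: dict[str, Table] = {}
    for tname, tcfg in schema.get("tables", {}).items():
        csv_path = directory / f"{tname}.csv"
        if not csv_path.exists():
            raise SchemaError(f"no CSV file for table {tname!r} at {csv_path}")
        with open(csv_path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            raw_rows = [row for row in reader]
        colcfg = (tcfg or {}).get("columns", {})
        extra = set(colcfg) - set(header)
        if extra:
            raise SchemaError(
                f"schema for table {tname!r} names columns absent from the CSV: {sorted(extra)}"
            )
        missing_from_schema = [h for h in header if h not in colcfg]
        if colcfg and missing_from_schema and (tcfg or {}).get("strict", False):
            raise SchemaError(
                f"schema for table {tname!r} omits CSV columns: {missing_from_schema}"
            )
        specs: list[ColumnSpec] = []
        parsers = {}
        for h in header:
            cfg = colcfg.get(h, {})
            role = cfg.get("role")
            ref = cfg.get("references")
            kind = cfg.get("kind", "categorical")
            if role is None:
                role = _infer_role(h)
                if role == ROLE_FOREIGN_KEY and ref is None:
                    ref = h[:-3] + "s"
                if role == ROLE_FOREIGN_KEY and ref not in schema.get("tables", {}):
                    role = ROLE_ATTRIBUTE
                    ref = None
            if role == "target":
                role = ROLE_TARGET
            specs.append(ColumnSpec(h, role=role, referenced_table=ref, value_kind=kind))
            if role in (ROLE_PRIMARY_KEY, ROLE_FOREIGN_KEY):
                parsers[h] = "key"
            else:
                parsers[h] = kind
        rows = []
        for raw in raw_rows:
            if len(raw) != len(header):
                raise SchemaError(f"row arity mismatch in {csv_path}")
            row = []
            for h, cell in zip(header, raw):
                cell = cell.strip()
                if cell == "":
                    row.append(MISSING)
                elif parsers[h] == "key":
                    row.append(int(cell) if re.fullmatch(r"-?\d+", cell) else cell)
                elif parsers[h] == "numeric":
                    row.append(int(cell) if re.fullmatch(r"-?\d+", cell) else float(cell))
                else:
                    row.append(cell)
            rows.append(tuple(row))
        tables[tname] = Table(name=tname, columns=specs, rows=rows)
    return RelationalDatabase(tables=tables, target_table=target["table"],
                              target_column=target["column"])


def write_csv_with_schema(db: RelationalDatabase, directory: str | Path) -> Path:
    """Write one CSV per table plus ``schema.yaml``; returns the schema path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema: dict[str, Any] = {
        "target": {"table": db.target_table, "column": db.target_column},
        "tables": {},
    }
    for t in db.tables.values():
        cols: dict[str, Any] = {}
        for c in t.columns:
            entry: dict[str, Any] = {"role": c.role, "kind": c.value_kind}
            if c.referenced_table:
                entry["references"] = c.referenced_table
            cols[c.name] = entry
        schema["tables"][t.name] = {"columns": cols}
        with open(directory / f"{t.name}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([c.name for c in t.columns])
            for row in t.rows:
                w.writerow(["" if v is MISSING else v for v in row])
    schema_path = directory / "schema.yaml"
    schema_path.write_text(yaml.safe_dump(schema, sort_keys=True))
    return schema_path


def databases_equal(a: RelationalDatabase, b: RelationalDatabase) -> bool:
    """Structural equality up to row order within each table."""
    if set(a.tables) != set(b.tables):
        return False
    if (a.target_table, a.target_column) != (b.target_table, b.target_column):
        return False
    for name, ta in a.tables.items():
        tb = b.tables[name]
        if [(c.name, c.role, c.referenced_table) for c in ta.columns] != [
            (c.name, c.role, c.referenced_table) for c in tb.columns
        ]:
            return False
        if sorted(map(repr, ta.rows)) != sorted(map(repr, tb.rows)):
            return False
    return True
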