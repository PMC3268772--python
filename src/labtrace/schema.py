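"""Relational core: the 23-relation schema, controlled-vocabulary codes,
blob storage and the declarative business-rule checker guarding every write.

The schema is deliberately small and generic: every categorical foreign key
points into the single ``codes`` relation (one row per vocabulary entry,
grouped by a fixed set of 14 classes), raw files of any kind live in
``blobs``, and physical storage is an adjacency-list tree in ``storage``.

All mutation anywhere in the package funnels through
:meth:`Database.insert` / :meth:`Database.update` / :meth:`Database.delete`,
which (1) ask the access-control policy whether the active session may
write, and (2) run the record through :func:`Database.check_rules`; a record
with violations is never persisted.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
import re
import sqlite3
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Any, Iterable, Sequence

from .errors import (
    LimsError,
    NotFoundError,
    PermissionDeniedError,
    RuleViolationError,
    SchemaError,
)
from . import access


def _load_resource(name: str) -> dict:
    with _ilres.files("labtrace.resources").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


#: The closed enumeration of controlled-vocabulary classes.
CODE_CLASSES: dict[str, str] = _load_resource("code_classes.json")

#: Sentinel short name seeded in every code class for incomplete legacy data.
UNKNOWN_CODE = "UNKNOWN"

IUPAC_RE = re.compile(r"^[ACGTURYSWKMBDHVNacgturyswkmbdhvn.\-]+$")

CHECKSUM_ALGO = "sha256"

_DDL = """
CREATE TABLE codes (
    code_id     INTEGER PRIMARY KEY,
    code_class  TEXT NOT NULL,
    short_name  TEXT NOT NULL,
    long_name   TEXT,
    description TEXT,
    active      INTEGER DEFAULT 1
);
CREATE TABLE unit (
    unit_id     INTEGER PRIMARY KEY,
    name        TEXT NOT NULL,
    description TEXT
);
CREATE TABLE contacts (
    contact_id  INTEGER PRIMARY KEY,
    name        TEXT NOT NULL,
    unit_id     INTEGER,
    country_id  INTEGER,
    language_id INTEGER,
    email       TEXT,
    phone       TEXT
);
CREATE TABLE blobs (
    blob_id        INTEGER PRIMARY KEY,
    content        BLOB NOT NULL,
    filename       TEXT,
    mimetype_id    INTEGER,
    checksum       TEXT NOT NULL,
    checksum_algo  TEXT NOT NULL,
    size           INTEGER NOT NULL,
    owner_relation TEXT,
    owner_id       INTEGER
);
CREATE TABLE protocols (
    protocol_id      INTEGER PRIMARY KEY,
    name             TEXT NOT NULL,
    protocol_type_id INTEGER,
    blob_id          INTEGER,
    description      TEXT
);
CREATE TABLE projects (
    project_id       INTEGER PRIMARY KEY,
    name             TEXT NOT NULL,
    purpose_id       INTEGER NOT NULL,
    owner_contact_id INTEGER,
    start_date       TEXT
);
CREATE TABLE organisms (
    organism_id INTEGER PRIMARY KEY,
    species_id  INTEGER NOT NULL,
    breed_id    INTEGER,
    sex_id      INTEGER,
    birth_date  TEXT,
    comment     TEXT
);
CREATE TABLE transfer (
    transfer_id INTEGER PRIMARY KEY,
    organism_id INTEGER NOT NULL,
    external_id TEXT NOT NULL,
    id_system   TEXT NOT NULL
);
CREATE TABLE storage (
    storage_id   INTEGER PRIMARY KEY,
    storage_name TEXT NOT NULL,
    parent_id    INTEGER
);
CREATE TABLE samples (
    sample_id        INTEGER PRIMARY KEY,
    organism_id      INTEGER NOT NULL,
    project_id       INTEGER NOT NULL,
    material_type_id INTEGER NOT NULL,
    vessel_type_id   INTEGER,
    amount           REAL,
    amount_unit      TEXT,
    comment          TEXT
);
CREATE TABLE storage_samples (
    placement_id   INTEGER PRIMARY KEY,
    item_type      TEXT NOT NULL,
    item_id        INTEGER NOT NULL,
    storage_id     INTEGER NOT NULL,
    date_in        TEXT NOT NULL,
    date_out       TEXT,
    position_label TEXT
);
CREATE TABLE sample_collection (
    collection_id INTEGER PRIMARY KEY,
    sample_id     INTEGER NOT NULL,
    contact_id    INTEGER,
    date          TEXT,
    comment       TEXT
);
CREATE TABLE dna_extraction (
    extraction_row_id INTEGER PRIMARY KEY,
    dna_id            INTEGER NOT NULL,
    sample_id         INTEGER NOT NULL,
    protocol_id       INTEGER,
    date              TEXT,
    concentration     REAL,
    contact_id        INTEGER
);
CREATE TABLE pcr_amplification (
    pcr_id      INTEGER PRIMARY KEY,
    protocol_id INTEGER,
    date        TEXT,
    comment     TEXT
);
CREATE TABLE pcr_markers (
    pcr_marker_id  INTEGER PRIMARY KEY,
    pcr_id         INTEGER NOT NULL,
    primer_id      INTEGER NOT NULL,
    marker_type_id INTEGER
);
CREATE TABLE amplified_samples (
    amplified_id INTEGER PRIMARY KEY,
    pcr_id       INTEGER NOT NULL,
    dna_id       INTEGER NOT NULL,
    well         TEXT
);
CREATE TABLE electrophoresis (
    run_id    INTEGER PRIMARY KEY,
    pcr_id    INTEGER NOT NULL,
    method_id INTEGER,
    machine   TEXT,
    date      TEXT
);
CREATE TABLE validation (
    validation_id INTEGER PRIMARY KEY,
    target_type   TEXT NOT NULL,
    target_id     INTEGER NOT NULL,
    result        TEXT NOT NULL,
    comment       TEXT
);
CREATE TABLE gel_images (
    gel_image_id  INTEGER PRIMARY KEY,
    validation_id INTEGER NOT NULL,
    blob_id       INTEGER NOT NULL
);
CREATE TABLE sequences (
    seq_id      INTEGER PRIMARY KEY,
    pcr_id      INTEGER NOT NULL,
    dna_id      INTEGER NOT NULL,
    primer_id   INTEGER NOT NULL,
    name        TEXT,
    bases       TEXT NOT NULL,
    software_id INTEGER,
    length      INTEGER
);
CREATE TABLE microsatellites (
    msat_id     INTEGER PRIMARY KEY,
    dna_id      INTEGER NOT NULL,
    primer_id   INTEGER NOT NULL,
    allele1     INTEGER,
    allele2     INTEGER,
    software_id INTEGER
);
CREATE TABLE users (
    user_id     INTEGER PRIMARY KEY,
    login       TEXT NOT NULL,
    salt        TEXT NOT NULL,
    pw_hash     TEXT NOT NULL,
    contact_id  INTEGER,
    system_role TEXT NOT NULL,
    db_role     TEXT NOT NULL,
    active      INTEGER DEFAULT 1
);
CREATE TABLE user_roles (
    role_id   INTEGER PRIMARY KEY,
    role_type TEXT NOT NULL,
    role_name TEXT NOT NULL,
    grants    TEXT
);
CREATE INDEX idx_codes_class ON codes (code_class, short_name);
CREATE INDEX idx_transfer_ext ON transfer (id_system, external_id);
CREATE INDEX idx_transfer_org ON transfer (organism_id);
CREATE INDEX idx_samples_project ON samples (project_id);
CREATE INDEX idx_samples_org ON samples (organism_id);
CREATE INDEX idx_storage_parent ON storage (parent_id);
CREATE INDEX idx_place_item ON storage_samples (item_type, item_id);
CREATE INDEX idx_place_node ON storage_samples (storage_id);
CREATE INDEX idx_dna_group ON dna_extraction (dna_id);
CREATE INDEX idx_dna_sample ON dna_extraction (sample_id);
CREATE INDEX idx_amp_pcr ON amplified_samples (pcr_id);
CREATE INDEX idx_amp_dna ON amplified_samples (dna_id);
CREATE INDEX idx_seq_dna ON sequences (dna_id);
CREATE INDEX idx_seq_primer ON sequences (primer_id);
CREATE INDEX idx_msat_dna ON microsatellites (dna_id);
CREATE INDEX idx_msat_primer ON microsatellites (primer_id);
"""

#: Primary-key column per relation (integer surrogate, sqlite rowid alias).
PRIMARY_KEYS = {
    "codes": "code_id",
    "unit": "unit_id",
    "contacts": "contact_id",
    "blobs": "blob_id",
    "protocols": "protocol_id",
    "projects": "project_id",
    "organisms": "organism_id",
    "transfer": "transfer_id",
    "storage": "storage_id",
    "samples": "sample_id",
    "storage_samples": "placement_id",
    "sample_collection": "collection_id",
    "dna_extraction": "extraction_row_id",
    "pcr_amplification": "pcr_id",
    "pcr_markers": "pcr_marker_id",
    "amplified_samples": "amplified_id",
    "electrophoresis": "run_id",
    "validation": "validation_id",
    "gel_images": "gel_image_id",
    "sequences": "seq_id",
    "microsatellites": "msat_id",
    "users": "user_id",
    "user_roles": "role_id",
}

RELATIONS = tuple(PRIMARY_KEYS)

#: Data action required to mutate each relation; user bookkeeping needs the
#: dedicated manage_user right, everything else is plain write/delete.
_MANAGE_USER_RELATIONS = frozenset({"users", "user_roles"})

_OPERATORS = ("equals", "contains", "<", ">", "between")


@dataclass(frozen=True)
class Violation:
    rule: str
    column: str
    message: str


@dataclass(frozen=True)
class Code:
    code_id: int
    code_class: str
    short_name: str
    long_name: str | None = None
    description: str | None = None
    active: bool = True


@dataclass(frozen=True)
class BlobRecord:
    blob_id: int
    filename: str | None
    checksum: str
    checksum_algo: str
    size: int
    mimetype_id: int | None = None


class BusinessRuleSet:
    """Per-relation declarative rules loaded from a plain-text JSON config.

    Vocabulary: ``not_null``, ``unique`` (column sets), ``foreign_key``
    (per column, either a code class or a relation/column target), ``type``,
    plus the value constraints ``enum``, ``non_empty``, ``non_negative``,
    ``positive`` and ``iupac``.
    """

    def __init__(self, config: dict[str, dict]):
        self.config = config
        for relation in RELATIONS:
            if relation not in config:
                raise SchemaError(f"business-rule config lacks relation {relation!r}")
        for relation, rules in config.items():
            for col, target in rules.get("foreign_key", {}).items():
                if "class" in target:
                    if target["class"] not in CODE_CLASSES:
                        raise SchemaError(
                            f"{relation}.{col}: unknown code class {target['class']!r}")
                elif target.get("relation") not in PRIMARY_KEYS:
                    raise SchemaError(
                        f"{relation}.{col}: unknown target relation {target.get('relation')!r}")

    @classmethod
    def default(cls) -> "BusinessRuleSet":
        return cls(_load_resource("rules.json"))

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "BusinessRuleSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(json.load(fh))

    def rules_for(self, relation: str) -> dict:
        try:
            return self.config[relation]
        except KeyError:
            raise NotFoundError(f"unknown relation {relation!r}") from None


def _type_ok(kind: str, value: Any) -> bool:
    if kind == "int":
        return isinstance(value, int) and not isinstance(value, bool)
    if kind == "num":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if kind == "text":
        return isinstance(value, str)
    if kind == "blob":
        return isinstance(value, (bytes, bytearray, memoryview))
    if kind == "bool":
        return value in (0, 1, True, False)
    if kind == "date":
        if isinstance(value, (_dt.date, _dt.datetime)):
            return True
        if isinstance(value, str):
            try:
                _dt.date.fromisoformat(value)
                return True
            except ValueError:
                return False
        return False
    raise SchemaError(f"unknown type rule {kind!r}")


def _normalize_value(value: Any) -> Any:
    if isinstance(value, bool):
        return int(value)
    if isinstance(value, _dt.datetime):
        return value.date().isoformat()
    if isinstance(value, _dt.date):
        return value.isoformat()
    return value


class Database:
    """Handle on an initialized single-file database.

    Thin wrapper around :mod:`sqlite3` adding the business-rule gate, the
    access-control gate and a nestable transaction context (savepoints).
    """

    def __init__(self, path: str | os.PathLike, *,
                 ruleset: BusinessRuleSet | None = None,
                 policy: "access.AccessPolicy | None" = None,
                 session: "access.Session | None" = None):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        self.conn.isolation_level = None  # explicit transaction control
        self.ruleset = ruleset or BusinessRuleSet.default()
        self.policy = policy or access.AccessPolicy.default()
        self.session = session or access.SYSTEM_SESSION
        self._tx_depth = 0
        self._columns_cache: dict[str, tuple[str, ...]] = {}

    # -- plumbing ---------------------------------------------------------

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "Database":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def execute(self, sql: str, params: Sequence = ()) -> sqlite3.Cursor:
        return self.conn.execute(sql, params)

    def query(self, sql: str, params: Sequence = ()) -> list[sqlite3.Row]:
        return self.conn.execute(sql, params).fetchall()

    def one(self, sql: str, params: Sequence = ()) -> sqlite3.Row | None:
        return self.conn.execute(sql, params).fetchone()

    def relations(self) -> list[str]:
        rows = self.query(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name NOT LIKE 'sqlite_%' ORDER BY name")
        return [r["name"] for r in rows]

    def columns(self, relation: str) -> tuple[str, ...]:
        if relation not in self._columns_cache:
            if relation not in PRIMARY_KEYS:
                raise NotFoundError(f"unknown relation {relation!r}")
            info = self.query(f"PRAGMA table_info({relation})")
            self._columns_cache[relation] = tuple(r["name"] for r in info)
        return self._columns_cache[relation]

    def transaction(self):
        return _Transaction(self)

    def digest(self) -> str:
        """Order-insensitive content digest of the whole database.

        Used by atomicity and read-only-ness checks: two byte-identical
        states hash equal, any persisted change hashes different.
        """
        h = hashlib.sha256()
        for relation in RELATIONS:
            h.update(relation.encode())
            pk = PRIMARY_KEYS[relation]
            for row in self.query(f"SELECT * FROM {relation} ORDER BY {pk}"):
                for v in tuple(row):
                    h.update(repr(v).encode())
                    h.update(b"\x1f")
                h.update(b"\x1e")
        return h.hexdigest()

    # -- access gate ------------------------------------------------------

    def _require(self, action: str) -> None:
        if not self.policy.allows_data(self.session, action):
            raise PermissionDeniedError(
                f"session {self.session.login!r} (db role "
                f"{self.session.db_role!r}) may not {action}")

    def _write_action(self, relation: str) -> str:
        return "manage_user" if relation in _MANAGE_USER_RELATIONS else "write"

    # -- rule checking ----------------------------------------------------

    def check_rules(self, relation: str, record: dict[str, Any],
                    *, exclude_pk: int | None = None) -> list[Violation]:
        """Evaluate the declared business rules for ``record``.

        Returns the full violation list (empty iff the record is valid).
        ``exclude_pk`` skips the record itself in uniqueness checks when
        validating an update.
        """
        rules = self.ruleset.rules_for(relation)
        cols = self.columns(relation)
        out: list[Violation] = []
        get = lambda c: record.get(c)

        for col in record:
            if col not in cols:
                out.append(Violation("column", col, f"unknown column {col!r}"))
        for col in rules.get("not_null", []):
            if get(col) is None:
                out.append(Violation("not_null", col, f"{col} must not be null"))
        for col, kind in rules.get("type", {}).items():
            v = get(col)
            if v is not None and not _type_ok(kind, v):
                out.append(Violation("type", col, f"{col} must be of type {kind}"))
        for col in rules.get("non_empty", []):
            v = get(col)
            if v is not None and (not isinstance(v, str) or not v.strip()):
                out.append(Violation("non_empty", col, f"{col} must be non-empty text"))
        for col in rules.get("non_negative", []):
            v = get(col)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                out.append(Violation("non_negative", col, f"{col} must be >= 0"))
        for col in rules.get("positive", []):
            v = get(col)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v <= 0:
                out.append(Violation("positive", col, f"{col} must be > 0"))
        for col, allowed in rules.get("enum", {}).items():
            v = get(col)
            if v is not None and v not in allowed:
                out.append(Violation("enum", col, f"{col} must be one of {allowed}"))
        for col in rules.get("iupac", []):
            v = get(col)
            if isinstance(v, str) and v and not IUPAC_RE.match(v):
                out.append(Violation("iupac", col, f"{col} contains non-IUPAC characters"))
        for col, target in rules.get("foreign_key", {}).items():
            v = get(col)
            if v is None:
                continue
            if "class" in target:
                hit = self.one(
                    "SELECT 1 FROM codes WHERE code_id=? AND code_class=?",
                    (v, target["class"]))
                if hit is None:
                    out.append(Violation(
                        "foreign_key", col,
                        f"{col}={v!r} is not a code of class {target['class']}"))
            else:
                rel, tcol = target["relation"], target["column"]
                hit = self.one(f"SELECT 1 FROM {rel} WHERE {tcol}=? LIMIT 1", (v,))
                if hit is None:
                    out.append(Violation(
                        "foreign_key", col, f"{col}={v!r} not found in {rel}.{tcol}"))
        for colset in rules.get("unique", []):
            vals = [_normalize_value(get(c)) for c in colset]
            cond = " AND ".join(f"{c} IS ?" for c in colset)
            sql = f"SELECT {PRIMARY_KEYS[relation]} AS pk FROM {relation} WHERE {cond}"
            for row in self.query(sql, vals):
                if exclude_pk is not None and row["pk"] == exclude_pk:
                    continue
                out.append(Violation(
                    "unique", ",".join(colset),
                    f"duplicate value for unique columns {colset}"))
                break
        return out

    # -- guarded mutation -------------------------------------------------

    def insert(self, relation: str, record: dict[str, Any]) -> int:
        self._require(self._write_action(relation))
        record = {k: _normalize_value(v) for k, v in record.items()}
        violations = self.check_rules(relation, record)
        if violations:
            raise RuleViolationError(relation, violations)
        cols = ", ".join(record)
        ph = ", ".join("?" for _ in record)
        with self.transaction():
            cur = self.execute(
                f"INSERT INTO {relation} ({cols}) VALUES ({ph})",
                list(record.values()))
        return cur.lastrowid

    def update(self, relation: str, pk: int, changes: dict[str, Any]) -> None:
        self._require(self._write_action(relation))
        pk_col = PRIMARY_KEYS[relation]
        row = self.one(f"SELECT * FROM {relation} WHERE {pk_col}=?", (pk,))
        if row is None:
            raise NotFoundError(f"{relation}[{pk}] does not exist")
        merged = dict(row)
        merged.update({k: _normalize_value(v) for k, v in changes.items()})
        merged.pop(pk_col, None)
        violations = self.check_rules(relation, merged, exclude_pk=pk)
        if violations:
            raise RuleViolationError(relation, violations)
        sets = ", ".join(f"{c}=?" for c in changes)
        with self.transaction():
            self.execute(
                f"UPDATE {relation} SET {sets} WHERE {pk_col}=?",
                [_normalize_value(v) for v in changes.values()] + [pk])

    def delete(self, relation: str, pk: int) -> None:
        action = "manage_user" if relation in _MANAGE_USER_RELATIONS else "delete"
        self._require(action)
        pk_col = PRIMARY_KEYS[relation]
        if self.one(f"SELECT 1 FROM {relation} WHERE {pk_col}=?", (pk,)) is None:
            raise NotFoundError(f"{relation}[{pk}] does not exist")
        with self.transaction():
            self.execute(f"DELETE FROM {relation} WHERE {pk_col}=?", (pk,))

    # -- search -----------------------------------------------------------

    def search_records(self, relation: str,
                       criteria: Iterable[tuple[str, str, Any]] = (),
                       sort: Sequence[str] = ()) -> list[dict]:
        """Criteria-based search: conjunction of (column, operator, value).

        Operators: equals, contains, ``<``, ``>``, between (value = 2-tuple).
        """
        self._require("read")
        cols = self.columns(relation)
        where, params = [], []
        for column, op, value in criteria:
            if column not in cols:
                raise NotFoundError(f"unknown column {relation}.{column}")
            if op == "equals":
                where.append(f"{column} IS ?")
                params.append(_normalize_value(value))
            elif op == "contains":
                esc = str(value).replace("\\", "\\\\").replace("%", "\\%").replace("_", "\\_")
                where.append(f"{column} LIKE ? ESCAPE '\\'")
                params.append(f"%{esc}%")
            elif op == "<":
                where.append(f"{column} < ?")
                params.append(_normalize_value(value))
            elif op == ">":
                where.append(f"{column} > ?")
                params.append(_normalize_value(value))
            elif op == "between":
                lo, hi = value
                where.append(f"{column} BETWEEN ? AND ?")
                params.extend([_normalize_value(lo), _normalize_value(hi)])
            else:
                raise NotFoundError(
                    f"unknown operator {op!r}; expected one of {_OPERATORS}")
        sql = f"SELECT * FROM {relation}"
        if where:
            sql += " WHERE " + " AND ".join(where)
        order = []
        for column in sort:
            if column not in cols:
                raise NotFoundError(f"unknown sort column {relation}.{column}")
            order.append(column)
        order.append(PRIMARY_KEYS[relation])  # deterministic tie-break
        sql += " ORDER BY " + ", ".join(order)
        return [dict(r) for r in self.query(sql, params)]


class _Transaction:
    """Nestable transaction; the outermost level owns BEGIN/COMMIT, inner
    levels use savepoints so partial rollbacks compose."""

    def __init__(self, db: Database):
        self.db = db

    def __enter__(self):
        if self.db._tx_depth == 0:
            self.db.execute("BEGIN")
        else:
            self.db.execute(f"SAVEPOINT sp{self.db._tx_depth}")
        self.db._tx_depth += 1
        return self

    def __exit__(self, exc_type, exc, tb):
        self.db._tx_depth -= 1
        depth = self.db._tx_depth
        if exc_type is None:
            if depth == 0:
                self.db.execute("COMMIT")
            else:
                self.db.execute(f"RELEASE sp{depth}")
        else:
            if depth == 0:
                self.db.execute("ROLLBACK")
            else:
                self.db.execute(f"ROLLBACK TO sp{depth}")
                self.db.execute(f"RELEASE sp{depth}")
        return False


# -- schema lifecycle -----------------------------------------------------

def init_schema(path: str | os.PathLike, *, overwrite: bool = False,
                ruleset: BusinessRuleSet | None = None,
                policy: "access.AccessPolicy | None" = None) -> Database:
    """Create the full 23-relation schema at ``path`` and seed vocabulary.

    Every code class receives a sentinel ``UNKNOWN`` code and the role
    tables are seeded from the access policy.  Refuses to touch an existing
    schema unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists():
        if not overwrite:
            with sqlite3.connect(path) as probe:
                existing = probe.execute(
                    "SELECT count(*) FROM sqlite_master WHERE type='table'").fetchone()[0]
            if existing:
                raise SchemaError(f"schema exists at {path}; pass overwrite=True")
        else:
            path.unlink()
    if not os.access(path.parent if path.parent != Path("") else Path("."), os.W_OK):
        raise SchemaError(f"location {path.parent} is not writable")
    db = Database(path, ruleset=ruleset, policy=policy)
    db.conn.executescript(_DDL)  # executescript manages its own commit
    with db.transaction():
        for cls in CODE_CLASSES:
            db.insert("codes", {
                "code_class": cls, "short_name": UNKNOWN_CODE,
                "long_name": "unknown", "description": "sentinel for missing data"})
        for role_type, names in (("system", db.policy.system_roles),
                                 ("database", db.policy.db_roles)):
            for name, grants in names.items():
                db.insert("user_roles", {
                    "role_type": role_type, "role_name": name,
                    "grants": ",".join(grants)})
    return db


def open_database(path: str | os.PathLike, **kw) -> Database:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no database at {path}")
    db = Database(path, **kw)
    if "codes" not in db.relations():
        raise SchemaError(f"{path} is not an initialized database")
    return db


# -- codes ---------------------------------------------------------------

def add_code(db: Database, code_class: str, short_name: str,
             long_name: str | None = None, description: str | None = None) -> Code:
    """Insert a vocabulary entry; the 14 classes are closed, values open."""
    if code_class not in CODE_CLASSES:
        raise NotFoundError(
            f"unknown code class {code_class!r}; valid: {sorted(CODE_CLASSES)}")
    cid = db.insert("codes", {
        "code_class": code_class, "short_name": short_name,
        "long_name": long_name, "description": description})
    return Code(cid, code_class, short_name, long_name, description)


def get_code(db: Database, code_class: str, short_name: str) -> Code:
    row = db.one(
        "SELECT * FROM codes WHERE code_class=? AND short_name=?",
        (code_class, short_name))
    if row is None:
        raise NotFoundError(f"no code {short_name!r} in class {code_class}")
    return Code(row["code_id"], row["code_class"], row["short_name"],
                row["long_name"], row["description"], bool(row["active"]))


def ensure_code(db: Database, code_class: str, short_name: str,
                long_name: str | None = None) -> Code:
    try:
        return get_code(db, code_class, short_name)
    except NotFoundError:
        return add_code(db, code_class, short_name, long_name)


def code_name(db: Database, code_id: int | None) -> str | None:
    if code_id is None:
        return None
    row = db.one("SELECT short_name FROM codes WHERE code_id=?", (code_id,))
    return None if row is None else row["short_name"]


# -- blobs ---------------------------------------------------------------

def store_blob(db: Database, source: str | os.PathLike | bytes, *,
               mimetype_id: int | None = None, filename: str | None = None,
               owner_relation: str | None = None,
               owner_id: int | None = None) -> BlobRecord:
    """Store a file (or raw bytes) as an opaque blob with a recorded digest."""
    if isinstance(source, (bytes, bytearray)):
        content = bytes(source)
    else:
        p = Path(source)
        if not p.is_file():
            raise NotFoundError(f"cannot read file {p}")
        content = p.read_bytes()
        filename = filename or p.name
    checksum = hashlib.sha256(content).hexdigest()
    bid = db.insert("blobs", {
        "content": content, "filename": filename, "mimetype_id": mimetype_id,
        "checksum": checksum, "checksum_algo": CHECKSUM_ALGO,
        "size": len(content), "owner_relation": owner_relation,
        "owner_id": owner_id})
    return BlobRecord(bid, filename, checksum, CHECKSUM_ALGO, len(content), mimetype_id)


def fetch_blob(db: Database, blob_id: int) -> bytes:
    """Retrieve blob content, verifying the stored checksum on every read."""
    db._require("read")
    row = db.one("SELECT content, checksum, size FROM blobs WHERE blob_id=?", (blob_id,))
    if row is None:
        raise NotFoundError(f"no blob {blob_id}")
    content = bytes(row["content"])
    if hashlib.sha256(content).hexdigest() != row["checksum"]:
        raise LimsError(f"blob {blob_id} failed checksum verification")
    if len(content) != row["size"]:
        raise LimsError(f"blob {blob_id} size mismatch")
    return content
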