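"""Projects, individuals (organisms with external IDs) and samples.

The sample is the central entry point of the tracking model:
:func:`trace_sample` walks every association chain (organism, storage,
extractions, raw files, final results) and returns the full bundle.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
from dataclasses import dataclass, field

from .errors import LimsError, NotFoundError
from .schema import Database, ensure_code, get_code, code_name
from . import storage as _storage


@dataclass
class TraceBundle:
    """Everything reachable from one sample through foreign keys."""
    sample: dict
    organism: dict
    external_ids: list[dict]
    storage_path: list  # list[StorageNode], empty if unplaced
    dna_extractions: list[dict]
    raw_blobs: list[dict]  # blob metadata (no content)
    sequences: list[dict]
    microsatellites: list[dict]


def create_project(db: Database, name: str, purpose: str,
                   owner_contact_id: int | None = None,
                   start_date: str | _dt.date | None = None) -> int:
    purpose_code = get_code(db, "PURPOSE", purpose)
    return db.insert("projects", {
        "name": name, "purpose_id": purpose_code.code_id,
        "owner_contact_id": owner_contact_id, "start_date": start_date})


def get_project(db: Database, name_or_id) -> dict:
    if isinstance(name_or_id, int):
        row = db.one("SELECT * FROM projects WHERE project_id=?", (name_or_id,))
    else:
        row = db.one("SELECT * FROM projects WHERE name=?", (name_or_id,))
    if row is None:
        raise NotFoundError(f"no project {name_or_id!r}")
    return dict(row)


def register_individual(db: Database, id_system: str, external_id: str,
                        species: str, breed: str | None = None,
                        sex: str | None = None,
                        birth_date: str | None = None,
                        comment: str | None = None) -> int:
    """Create an organism plus its external ID; idempotent on the ID pair.

    Registering the same (id_system, external_id) twice returns the
    existing organism untouched, which makes batch loads re-runnable.
    """
    existing = db.one(
        "SELECT organism_id FROM transfer WHERE id_system=? AND external_id=?",
        (id_system, external_id))
    if existing is not None:
        return existing["organism_id"]
    species_id = get_code(db, "SPECIES", species).code_id
    breed_id = get_code(db, "BREED", breed).code_id if breed else None
    sex_id = get_code(db, "SEX", sex).code_id if sex else None
    with db.transaction():
        organism_id = db.insert("organisms", {
            "species_id": species_id, "breed_id": breed_id, "sex_id": sex_id,
            "birth_date": birth_date, "comment": comment})
        db.insert("transfer", {
            "organism_id": organism_id, "external_id": external_id,
            "id_system": id_system})
    return organism_id


def add_external_id(db: Database, organism_id: int, id_system: str,
                    external_id: str) -> int:
    return db.insert("transfer", {
        "organism_id": organism_id, "external_id": external_id,
        "id_system": id_system})


def external_ids(db: Database, organism_id: int) -> list[dict]:
    return [dict(r) for r in db.query(
        "SELECT * FROM transfer WHERE organism_id=? ORDER BY transfer_id",
        (organism_id,))]


def find_organism(db: Database, external_id: str,
                  id_system: str | None = None) -> int | None:
    if id_system is None:
        rows = db.query(
            "SELECT DISTINCT organism_id FROM transfer WHERE external_id=?",
            (external_id,))
        if len(rows) > 1:
            raise LimsError(f"external id {external_id!r} is ambiguous")
        return rows[0]["organism_id"] if rows else None
    row = db.one(
        "SELECT organism_id FROM transfer WHERE id_system=? AND external_id=?",
        (id_system, external_id))
    return row["organism_id"] if row else None


def register_sample(db: Database, organism_id: int, project_id: int,
                    material_type: str, vessel_type: str | None = None,
                    amount: float | None = None, amount_unit: str | None = None,
                    comment: str | None = None) -> int:
    material_id = get_code(db, "MATERIAL_TYPE", material_type).code_id
    vessel_id = get_code(db, "VESSEL_TYPE", vessel_type).code_id if vessel_type else None
    return db.insert("samples", {
        "organism_id": organism_id, "project_id": project_id,
        "material_type_id": material_id, "vessel_type_id": vessel_id,
        "amount": amount, "amount_unit": amount_unit, "comment": comment})


def audit_external_ids(db: Database) -> list[int]:
    """Organisms violating the 'at least one external ID' invariant."""
    rows = db.query(
        "SELECT o.organism_id FROM organisms o "
        "LEFT JOIN transfer t ON t.organism_id=o.organism_id "
        "WHERE t.transfer_id IS NULL")
    return [r["organism_id"] for r in rows]


def trace_sample(db: Database, sample_id: int) -> TraceBundle:
    """Assemble the association bundle around one sample."""
    sample = db.one("SELECT * FROM samples WHERE sample_id=?", (sample_id,))
    if sample is None:
        raise NotFoundError(f"no sample {sample_id}")
    organism = db.one("SELECT * FROM organisms WHERE organism_id=?",
                      (sample["organism_id"],))
    ext = external_ids(db, sample["organism_id"])
    try:
        path = _storage.locate_item(db, ("sample", sample_id))
    except NotFoundError:
        path = []

    dna_rows = [dict(r) for r in db.query(
        "SELECT * FROM dna_extraction WHERE sample_id=? ORDER BY dna_id", (sample_id,))]
    dna_ids = sorted({r["dna_id"] for r in dna_rows})

    raw_blobs: list[dict] = []
    seq_rows: list[dict] = []
    msat_rows: list[dict] = []
    if dna_ids:
        qm = ",".join("?" for _ in dna_ids)
        pcr_ids = sorted({r["pcr_id"] for r in db.query(
            f"SELECT DISTINCT pcr_id FROM amplified_samples WHERE dna_id IN ({qm})",
            dna_ids)})
        if pcr_ids:
            qp = ",".join("?" for _ in pcr_ids)
            # raw files of electrophoresis runs over those PCRs
            raw_blobs += [dict(r) for r in db.query(
                f"SELECT b.blob_id, b.filename, b.checksum, b.size, b.owner_relation, "
                f"b.owner_id FROM blobs b JOIN electrophoresis e ON "
                f"b.owner_relation='electrophoresis' AND b.owner_id=e.run_id "
                f"WHERE e.pcr_id IN ({qp}) ORDER BY b.blob_id", pcr_ids)]
            # gel images from validations of those PCRs
            raw_blobs += [dict(r) for r in db.query(
                f"SELECT b.blob_id, b.filename, b.checksum, b.size, b.owner_relation, "
                f"b.owner_id FROM blobs b JOIN gel_images g ON g.blob_id=b.blob_id "
                f"JOIN validation v ON v.validation_id=g.validation_id "
                f"WHERE v.target_type='pcr' AND v.target_id IN ({qp}) "
                f"ORDER BY b.blob_id", pcr_ids)]
        # gel images from validations of the DNA itself
        raw_blobs += [dict(r) for r in db.query(
            f"SELECT b.blob_id, b.filename, b.checksum, b.size, b.owner_relation, "
            f"b.owner_id FROM blobs b JOIN gel_images g ON g.blob_id=b.blob_id "
            f"JOIN validation v ON v.validation_id=g.validation_id "
            f"WHERE v.target_type='dna' AND v.target_id IN ({qm}) "
            f"ORDER BY b.blob_id", dna_ids)]
        seq_rows = [dict(r) for r in db.query(
            f"SELECT * FROM sequences WHERE dna_id IN ({qm}) ORDER BY seq_id", dna_ids)]
        msat_rows = [dict(r) for r in db.query(
            f"SELECT * FROM microsatellites WHERE dna_id IN ({qm}) ORDER BY msat_id",
            dna_ids)]

    seen, uniq = set(), []
    for b in raw_blobs:
        if b["blob_id"] not in seen:
            seen.add(b["blob_id"])
            uniq.append(b)
    return TraceBundle(dict(sample), dict(organism), ext, path,
                       dna_rows, uniq, seq_rows, msat_rows)


# -- spreadsheet interchange ---------------------------------------------

SAMPLE_SHEET_COLUMNS = ("id_system", "external_id", "species", "breed", "sex",
                        "material_type", "vessel_type", "amount", "unit")


def export_sample_sheet(db: Database, project_id: int) -> str:
    """Project sample list as CSV in the import column layout."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(SAMPLE_SHEET_COLUMNS)
    rows = db.query(
        "SELECT s.*, o.species_id, o.breed_id, o.sex_id FROM samples s "
        "JOIN organisms o ON o.organism_id=s.organism_id "
        "WHERE s.project_id=? ORDER BY s.sample_id", (project_id,))
    for r in rows:
        ext = external_ids(db, r["organism_id"])
        id_system, external_id = (ext[0]["id_system"], ext[0]["external_id"]) if ext else ("", "")
        w.writerow([
            id_system, external_id,
            code_name(db, r["species_id"]) or "",
            code_name(db, r["breed_id"]) or "",
            code_name(db, r["sex_id"]) or "",
            code_name(db, r["material_type_id"]) or "",
            code_name(db, r["vessel_type_id"]) or "",
            "" if r["amount"] is None else r["amount"],
            r["amount_unit"] or ""])
    return buf.getvalue()


def import_sample_sheet(db: Database, project_id: int, text: str, *,
                        create_codes: bool = False) -> list[int]:
    """Load samples (and their individuals) from CSV; all-or-nothing."""
    reader = csv.DictReader(io.StringIO(text))
    missing = set(SAMPLE_SHEET_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise LimsError(f"sample sheet lacks columns: {sorted(missing)}")
    created: list[int] = []
    with db.transaction():
        for lineno, row in enumerate(reader, start=2):
            def code_of(cls, value):
                if not value:
                    return None
                if create_codes:
                    ensure_code(db, cls, value)
                return value
            try:
                organism_id = register_individual(
                    db, row["id_system"], row["external_id"],
                    code_of("SPECIES", row["species"]) or "",
                    code_of("BREED", row["breed"]),
                    code_of("SEX", row["sex"]))
                amount = float(row["amount"]) if row["amount"] else None
                created.append(register_sample(
                    db, organism_id, project_id,
                    code_of("MATERIAL_TYPE", row["material_type"]) or "",
                    code_of("VESSEL_TYPE", row["vessel_type"]),
                    amount, row["unit"] or None))
            except LimsError as exc:
                raise LimsError(f"row {lineno}: {exc}") from exc
    return created
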