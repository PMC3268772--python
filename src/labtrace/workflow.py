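"""Lab workflow records and final-data imports.

Covers the chain collection -> DNA extraction -> PCR -> validation ->
electrophoresis -> final sequence / microsatellite results.  Every record
keeps its back-references so the full provenance of a result can be walked
down to samples and organisms.  Bulk imports are all-or-nothing: any
unresolvable identifier or rule violation leaves the database untouched.

A DNA extraction may pool several samples; it is stored as one row per
(dna_id, source sample) sharing the extraction's group id, which keeps the
source traces inside the single ``dna_extraction`` relation.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import os
from pathlib import Path

from Bio import SeqIO

from .errors import ImportError_, LimsError, NotFoundError
from .schema import Database, get_code, store_blob
from .registry import find_organism

VALIDATION_RESULTS = ("pass", "fail", "ambiguous")

#: Row-major 96-well plate order used when wells are not given explicitly.
PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12


def well_label(index: int) -> str:
    """Row-major A1..H12 position for a 0-based index (wraps per plate)."""
    index %= len(PLATE_ROWS) * PLATE_COLS
    return f"{PLATE_ROWS[index // PLATE_COLS]}{index % PLATE_COLS + 1}"


# -- collection / extraction ---------------------------------------------


def record_collection(db: Database, sample_id: int,
                      contact_id: int | None = None,
                      date: str | _dt.date | None = None,
                      comment: str | None = None) -> int:
    return db.insert("sample_collection", {
        "sample_id": sample_id, "contact_id": contact_id,
        "date": date, "comment": comment})


def next_dna_id(db: Database) -> int:
    row = db.one("SELECT MAX(dna_id) AS m FROM dna_extraction")
    return (row["m"] or 0) + 1


def dna_sources(db: Database, dna_id: int) -> list[int]:
    rows = db.query(
        "SELECT sample_id FROM dna_extraction WHERE dna_id=? ORDER BY sample_id",
        (dna_id,))
    if not rows:
        raise NotFoundError(f"no DNA extraction {dna_id}")
    return [r["sample_id"] for r in rows]


def dna_project(db: Database, dna_id: int) -> int:
    sample_id = dna_sources(db, dna_id)[0]
    return db.one("SELECT project_id FROM samples WHERE sample_id=?",
                  (sample_id,))["project_id"]


def extract_dna(db: Database, sample_ids: list[int],
                protocol_id: int | None = None,
                date: str | _dt.date | None = None,
                operator_contact_id: int | None = None,
                concentration: float | None = None) -> int:
    """Create one extraction (group id) tracing all source samples."""
    if not sample_ids:
        raise LimsError("an extraction needs at least one source sample")
    projects = set()
    for sid in sample_ids:
        row = db.one("SELECT project_id FROM samples WHERE sample_id=?", (sid,))
        if row is None:
            raise NotFoundError(f"no sample {sid}")
        projects.add(row["project_id"])
    if len(projects) > 1:
        raise LimsError("pooled samples must belong to the same project")
    dna_id = next_dna_id(db)
    with db.transaction():
        for sid in sample_ids:
            db.insert("dna_extraction", {
                "dna_id": dna_id, "sample_id": sid, "protocol_id": protocol_id,
                "date": date, "concentration": concentration,
                "contact_id": operator_contact_id})
    return dna_id


# -- PCR / validation / electrophoresis -----------------------------------


def setup_pcr(db: Database, dna_ids: list[int], markers: list[str],
              protocol_id: int | None = None,
              date: str | _dt.date | None = None,
              marker_type: str | None = None,
              wells: list[str] | None = None) -> int:
    if not dna_ids or not markers:
        raise LimsError("PCR needs at least one DNA and one marker")
    marker_codes = [get_code(db, "PRIMER", m) for m in markers]
    mtype_id = get_code(db, "MARKER_TYPE", marker_type).code_id if marker_type else None
    if wells is not None and len(wells) != len(dna_ids):
        raise LimsError("wells list must match DNA list length")
    for d in dna_ids:
        dna_sources(db, d)  # existence check
    with db.transaction():
        pcr_id = db.insert("pcr_amplification", {"protocol_id": protocol_id, "date": date})
        for mc in marker_codes:
            db.insert("pcr_markers", {
                "pcr_id": pcr_id, "primer_id": mc.code_id, "marker_type_id": mtype_id})
        for i, d in enumerate(dna_ids):
            db.insert("amplified_samples", {
                "pcr_id": pcr_id, "dna_id": d,
                "well": wells[i] if wells else well_label(i)})
    return pcr_id


def pcr_markers_of(db: Database, pcr_id: int) -> list[int]:
    return [r["primer_id"] for r in db.query(
        "SELECT primer_id FROM pcr_markers WHERE pcr_id=? ORDER BY pcr_marker_id",
        (pcr_id,))]


def record_validation(db: Database, target: tuple[str, int], result: str,
                      gel_image: str | os.PathLike | bytes | None = None,
                      comment: str | None = None) -> int:
    target_type, target_id = target
    if target_type == "dna":
        dna_sources(db, target_id)
    elif target_type == "pcr":
        if db.one("SELECT 1 FROM pcr_amplification WHERE pcr_id=?", (target_id,)) is None:
            raise NotFoundError(f"no PCR {target_id}")
    else:
        raise LimsError(f"validation target must be ('dna'|'pcr', id), got {target!r}")
    with db.transaction():
        vid = db.insert("validation", {
            "target_type": target_type, "target_id": target_id,
            "result": result, "comment": comment})
        if gel_image is not None:
            blob = store_blob(db, gel_image, owner_relation="validation", owner_id=vid)
            db.insert("gel_images", {"validation_id": vid, "blob_id": blob.blob_id})
    return vid


def record_electrophoresis(db: Database, pcr_id: int, method: str | None = None,
                           machine: str | None = None,
                           date: str | _dt.date | None = None,
                           raw_files: list | None = None) -> int:
    if db.one("SELECT 1 FROM pcr_amplification WHERE pcr_id=?", (pcr_id,)) is None:
        raise NotFoundError(f"no PCR {pcr_id}")
    method_id = get_code(db, "METHOD", method).code_id if method else None
    with db.transaction():
        run_id = db.insert("electrophoresis", {
            "pcr_id": pcr_id, "method_id": method_id,
            "machine": machine, "date": date})
        for f in raw_files or []:
            store_blob(db, f, owner_relation="electrophoresis", owner_id=run_id)
    return run_id


def run_raw_blobs(db: Database, run_id: int) -> list[int]:
    return [r["blob_id"] for r in db.query(
        "SELECT blob_id FROM blobs WHERE owner_relation='electrophoresis' "
        "AND owner_id=? ORDER BY blob_id", (run_id,))]


# -- identifier resolution ------------------------------------------------


def resolve_dna_token(db: Database, token: str, *,
                      project_id: int | None = None,
                      candidates: set[int] | None = None) -> int:
    """Map a record identifier to a DNA group id.

    Tries (a) a literal DNA id, then (b) a sample external ID resolved
    through organism -> samples -> extractions.  Ambiguity is an error.
    """
    token = token.strip()
    if token.isdigit():
        dna_id = int(token)
        if db.one("SELECT 1 FROM dna_extraction WHERE dna_id=? LIMIT 1", (dna_id,)):
            if candidates is not None and dna_id not in candidates:
                raise ImportError_(f"DNA {dna_id} not eligible for this import")
            if project_id is not None and dna_project(db, dna_id) != project_id:
                raise ImportError_(f"DNA {dna_id} belongs to another project")
            return dna_id
    organism_id = find_organism(db, token)
    if organism_id is None:
        raise ImportError_(f"identifier {token!r} matches no DNA id or external ID")
    sql = "SELECT sample_id FROM samples WHERE organism_id=?"
    params: list = [organism_id]
    if project_id is not None:
        sql += " AND project_id=?"
        params.append(project_id)
    sample_ids = [r["sample_id"] for r in db.query(sql, params)]
    hits: set[int] = set()
    for sid in sample_ids:
        for r in db.query("SELECT dna_id FROM dna_extraction WHERE sample_id=?", (sid,)):
            hits.add(r["dna_id"])
    if candidates is not None:
        hits &= candidates
    if not hits:
        raise ImportError_(f"identifier {token!r} resolves to no eligible DNA")
    if len(hits) > 1:
        raise ImportError_(f"identifier {token!r} is ambiguous (DNA {sorted(hits)})")
    return hits.pop()


def _pcr_for(db: Database, dna_id: int, primer_id: int) -> int | None:
    row = db.one(
        "SELECT a.pcr_id FROM amplified_samples a JOIN pcr_markers m "
        "ON m.pcr_id=a.pcr_id WHERE a.dna_id=? AND m.primer_id=? "
        "ORDER BY a.pcr_id LIMIT 1", (dna_id, primer_id))
    return row["pcr_id"] if row else None


# -- final-data imports ---------------------------------------------------


def import_sequences(db: Database, fasta: str, marker: str,
                     software: str | None = None, *,
                     run_id: int | None = None,
                     project_id: int | None = None) -> list[int]:
    """Import final sequences from FASTA text; atomic.

    Record IDs (first whitespace token) resolve to amplified DNA either
    within one electrophoresis run or within a project.  Any unresolvable
    or duplicate ID aborts the import with nothing persisted.
    """
    if run_id is None and project_id is None:
        raise LimsError("import_sequences needs run_id or project_id")
    text = fasta.strip()
    if not text.startswith(">"):
        raise ImportError_("input does not parse as FASTA")
    records = list(SeqIO.parse(io.StringIO(fasta), "fasta"))
    if not records:
        raise ImportError_("FASTA contains no records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ImportError_("duplicate record identifiers in FASTA")

    primer_id = get_code(db, "PRIMER", marker).code_id
    software_id = get_code(db, "SOFTWARE", software).code_id if software else None

    fixed_pcr = None
    candidates = None
    if run_id is not None:
        run = db.one("SELECT * FROM electrophoresis WHERE run_id=?", (run_id,))
        if run is None:
            raise NotFoundError(f"no electrophoresis run {run_id}")
        fixed_pcr = run["pcr_id"]
        candidates = {r["dna_id"] for r in db.query(
            "SELECT dna_id FROM amplified_samples WHERE pcr_id=?", (fixed_pcr,))}

    resolved: list[tuple[int, int, str, str]] = []
    for rec in records:
        dna_id = resolve_dna_token(db, rec.id, project_id=project_id,
                                   candidates=candidates)
        pcr_id = fixed_pcr if fixed_pcr is not None else _pcr_for(db, dna_id, primer_id)
        if pcr_id is None:
            raise ImportError_(
                f"DNA {dna_id} ({rec.id}) was never amplified with marker {marker}")
        resolved.append((dna_id, pcr_id, rec.id, str(rec.seq)))

    seq_ids: list[int] = []
    with db.transaction():
        for dna_id, pcr_id, name, bases in resolved:
            seq_ids.append(db.insert("sequences", {
                "pcr_id": pcr_id, "dna_id": dna_id, "primer_id": primer_id,
                "name": name, "bases": bases, "software_id": software_id,
                "length": len(bases)}))
    return seq_ids


MISSING_ALLELE = "0"


def _parse_allele(cell: str) -> int | None:
    cell = (cell or "").strip()
    if cell in ("", MISSING_ALLELE):
        return None
    try:
        value = int(cell)
    except ValueError:
        raise ImportError_(f"allele {cell!r} is not an integer") from None
    if value <= 0:
        raise ImportError_(f"allele {cell!r} must be a positive length")
    return value


def import_microsat_matrix(db: Database, project_id: int, table: str,
                           markers: list[str], ploidy: str = "diploid",
                           software: str | None = None) -> list[int]:
    """Import a genotype matrix (CSV text; rows = samples, columns = markers).

    Diploid tables carry two allele columns per marker, haploid one.
    Empty cells and "0" are missing; a fully missing genotype produces no
    record.  Structural errors abort with nothing persisted.
    """
    if ploidy not in ("diploid", "haploid"):
        raise LimsError(f"ploidy must be diploid or haploid, not {ploidy!r}")
    per_marker = 2 if ploidy == "diploid" else 1
    marker_ids = [get_code(db, "PRIMER", m).code_id for m in markers]
    software_id = get_code(db, "SOFTWARE", software).code_id if software else None

    rows = list(csv.reader(io.StringIO(table)))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise ImportError_("empty genotype table")
    header, body = rows[0], rows[1:]
    expected = 1 + per_marker * len(markers)
    if len(header) != expected:
        raise ImportError_(
            f"table has {len(header)} columns; {ploidy} layout with "
            f"{len(markers)} markers requires {expected}")

    staged: list[dict] = []
    for lineno, row in enumerate(body, start=2):
        if len(row) != expected:
            raise ImportError_(f"row {lineno}: {len(row)} cells, expected {expected}")
        dna_id = resolve_dna_token(db, row[0], project_id=project_id)
        for mi, primer_id in enumerate(marker_ids):
            cells = row[1 + mi * per_marker: 1 + (mi + 1) * per_marker]
            a1 = _parse_allele(cells[0])
            a2 = _parse_allele(cells[1]) if per_marker == 2 else None
            if a1 is None and a2 is None:
                continue
            staged.append({
                "dna_id": dna_id, "primer_id": primer_id,
                "allele1": a1, "allele2": a2, "software_id": software_id})

    out: list[int] = []
    with db.transaction():
        for record in staged:
            out.append(db.insert("microsatellites", record))
    return out


# -- workflow step pipelining ---------------------------------------------

DNA_SHEET_COLUMNS = ("dna_group", "external_id", "protocol", "date",
                     "operator", "concentration")
PCR_SHEET_COLUMNS = ("dna_id", "well")
ELECTROPHORESIS_SHEET_COLUMNS = ("pcr_id", "method", "machine", "date")

WORKFLOW_STEPS = ("prepare_samples", "extract_dna", "setup_pcr")


def export_step_template(db: Database, step: str, project_id: int) -> str:
    """Spreadsheet pre-filled for the *next* workflow step's import."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    if step == "prepare_samples":
        w.writerow(DNA_SHEET_COLUMNS)
        rows = db.query(
            "SELECT s.sample_id, s.organism_id FROM samples s "
            "WHERE s.project_id=? ORDER BY s.sample_id", (project_id,))
        for r in rows:
            ext = db.one(
                "SELECT external_id FROM transfer WHERE organism_id=? "
                "ORDER BY transfer_id LIMIT 1", (r["organism_id"],))
            w.writerow(["", ext["external_id"] if ext else "", "", "", "", ""])
    elif step == "extract_dna":
        w.writerow(PCR_SHEET_COLUMNS)
        seen = set()
        for r in db.query(
                "SELECT d.dna_id FROM dna_extraction d JOIN samples s "
                "ON s.sample_id=d.sample_id WHERE s.project_id=? "
                "ORDER BY d.dna_id", (project_id,)):
            if r["dna_id"] not in seen:
                seen.add(r["dna_id"])
                w.writerow([r["dna_id"], ""])
    elif step == "setup_pcr":
        w.writerow(ELECTROPHORESIS_SHEET_COLUMNS)
        pcr_ids = sorted({r["pcr_id"] for r in db.query(
            "SELECT DISTINCT a.pcr_id FROM amplified_samples a "
            "JOIN dna_extraction d ON d.dna_id=a.dna_id "
            "JOIN samples s ON s.sample_id=d.sample_id WHERE s.project_id=?",
            (project_id,))})
        for p in pcr_ids:
            w.writerow([p, "", "", ""])
    else:
        raise NotFoundError(
            f"unknown workflow step {step!r}; expected one of {WORKFLOW_STEPS}")
    return buf.getvalue()


def import_dna_sheet(db: Database, project_id: int, text: str,
                     default_date: str | None = None) -> list[int]:
    """Pipelined import of the extract-DNA step from a prepare-samples sheet.

    Rows sharing a non-empty ``dna_group`` tag are pooled into one
    extraction; blank tags get one extraction per row.  Atomic.
    """
    reader = csv.DictReader(io.StringIO(text))
    missing = set(DNA_SHEET_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise ImportError_(f"DNA sheet lacks columns: {sorted(missing)}")
    groups: dict[str, list[dict]] = {}
    singletons: list[dict] = []
    for lineno, row in enumerate(reader, start=2):
        row["_line"] = lineno
        tag = (row.get("dna_group") or "").strip()
        if tag:
            groups.setdefault(tag, []).append(row)
        else:
            singletons.append(row)

    def resolve_sample(row) -> int:
        token = (row.get("external_id") or "").strip()
        organism_id = find_organism(db, token)
        if organism_id is None:
            raise ImportError_(f"row {row['_line']}: unknown external id {token!r}")
        sids = [r["sample_id"] for r in db.query(
            "SELECT sample_id FROM samples WHERE organism_id=? AND project_id=? "
            "ORDER BY sample_id", (organism_id, project_id))]
        if not sids:
            raise ImportError_(f"row {row['_line']}: {token!r} has no sample in project")
        if len(sids) > 1:
            raise ImportError_(f"row {row['_line']}: {token!r} is ambiguous")
        return sids[0]

    def resolve_protocol(row) -> int | None:
        name = (row.get("protocol") or "").strip()
        if not name:
            return None
        hit = db.one("SELECT protocol_id FROM protocols WHERE name=?", (name,))
        if hit is None:
            raise ImportError_(f"row {row['_line']}: unknown protocol {name!r}")
        return hit["protocol_id"]

    out: list[int] = []
    with db.transaction():
        for batch in list(groups.values()) + [[r] for r in singletons]:
            sample_ids = [resolve_sample(r) for r in batch]
            lead = batch[0]
            conc = (lead.get("concentration") or "").strip()
            out.append(extract_dna(
                db, sample_ids,
                protocol_id=resolve_protocol(lead),
                date=(lead.get("date") or "").strip() or default_date,
                concentration=float(conc) if conc else None))
    return out


def import_pcr_sheet(db: Database, text: str, markers: list[str],
                     protocol_id: int | None = None,
                     date: str | None = None) -> int:
    """Pipelined import of the setup-PCR step from an extract-DNA sheet."""
    reader = csv.DictReader(io.StringIO(text))
    missing = set(PCR_SHEET_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise ImportError_(f"PCR sheet lacks columns: {sorted(missing)}")
    dna_ids, wells = [], []
    for row in reader:
        dna_ids.append(int(row["dna_id"]))
        wells.append((row.get("well") or "").strip())
    if not dna_ids:
        raise ImportError_("PCR sheet has no rows")
    explicit = [w if w else well_label(i) for i, w in enumerate(wells)]
    return setup_pcr(db, dna_ids, markers, protocol_id=protocol_id,
                     date=date, wells=explicit)
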