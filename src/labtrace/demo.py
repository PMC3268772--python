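"""Deterministic demo-data generator.

Populates a database exclusively through the public API (guarded inserts,
workflow operations, final-data imports) so that every other subsystem can
be exercised without external downloads.  Identical seed + spec always
yields an identical database digest.

The generator can also emit its dataset as batch-loader sheets plus a
configuration file, closing the loop for interactive-vs-batch equivalence
testing.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass
from pathlib import Path

from .errors import LimsError
from . import access
from .schema import Database, add_code, ensure_code, init_schema, code_name
from .registry import (create_project, register_individual, register_sample,
                       external_ids, export_sample_sheet)
from . import storage as _storage
from . import workflow as _wf

SEQ_MARKERS = ("DLOOP", "CYTB", "COI")
STR_MARKERS = ("BM1824", "BM2113", "ETH3", "ETH10", "ETH225", "INRA023",
               "SPS115", "TGLA53", "TGLA122", "TGLA126", "TGLA227", "BM1818",
               "CSRM60", "CSSM66", "HAUT27", "ILSTS006")

_CODE_SEED = {
    "SPECIES": [("BOS", "Bos taurus"), ("OVIS", "Ovis aries"),
                ("CAPRA", "Capra hircus"), ("SUS", "Sus scrofa")],
    "BREED": [("HOLSTEIN", None), ("ANGUS", None), ("MERINO", None),
              ("BOER", None), ("DUROC", None)],
    "SEX": [("F", "female"), ("M", "male")],
    "MATERIAL_TYPE": [("BLOOD", None), ("TISSUE", None), ("HAIR", None),
                      ("SEMEN", None)],
    "VESSEL_TYPE": [("VIAL", None), ("TUBE", None), ("STRAW", None)],
    "MARKER_TYPE": [("SEQUENCE", None), ("MICROSATELLITE", None)],
    "METHOD": [("CAPILLARY", None), ("GEL", None)],
    "SOFTWARE": [("SEQANALYZER", None), ("PEAKCALLER", None)],
    "MIMETYPE": [("AB1", "chromatogram"), ("PNG", "image"), ("TXT", "text")],
    "PURPOSE": [("sequencing", None), ("genotyping", None)],
    "PROTOCOL_TYPE": [("EXTRACTION", None), ("PCR", None)],
    "COUNTRY": [("DE", "Germany"), ("FR", "France")],
    "LANGUAGE": [("EN", "English"), ("DE", "German")],
    "PRIMER": [(m, None) for m in SEQ_MARKERS + STR_MARKERS],
}

ID_SYSTEM = "demo-tag"
_DATE = "2024-03-01"


@dataclass
class DemoSpec:
    seed: int = 1
    n_projects: int = 2
    n_individuals: int = 40
    n_samples: int = 40
    n_markers: int = 4        # microsatellite markers in use
    n_sequences: int = 20
    n_microsats: int = 60     # attempted genotypes (missing ones not stored)
    missing_rate: float = 0.05
    raw_file_size: int = 2048
    pool_every: int = 10      # every k-th extraction pools 3 samples

    def validate(self) -> None:
        counts = (self.n_projects, self.n_individuals, self.n_samples,
                  self.n_markers, self.n_sequences, self.n_microsats,
                  self.raw_file_size)
        if any(c < 0 for c in counts):
            raise LimsError("demo spec counts must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise LimsError("missing_rate must be in [0, 1]")
        if self.n_projects > 0 and self.n_projects < 2 and (
                self.n_sequences and self.n_microsats):
            raise LimsError(
                "need >= 2 projects to host both sequencing and genotyping data")
        if self.n_markers > len(STR_MARKERS):
            raise LimsError(f"at most {len(STR_MARKERS)} microsatellite markers")


def _random_bases(rng: random.Random, length: int) -> str:
    bases = rng.choices("ACGT", k=length)
    for i in range(0, length, 97):  # sprinkle ambiguity codes
        if rng.random() < 0.3:
            bases[i] = "N"
    return "".join(bases)


def generate_demo(spec: DemoSpec, path, *, overwrite: bool = False
                  ) -> tuple[Database, dict]:
    """Build a populated demo database; returns (handle, manifest)."""
    spec.validate()
    rng = random.Random(spec.seed)
    db = init_schema(path, overwrite=overwrite)
    with db.transaction():
        manifest = _populate(db, spec, rng)
    return db, manifest


def _populate(db: Database, spec: DemoSpec, rng: random.Random) -> dict:
    for cls, entries in _CODE_SEED.items():
        for short, long_ in entries:
            add_code(db, cls, short, long_)

    unit_id = db.insert("unit", {"name": "Molecular Genetics Unit"})
    contact_ids = [db.insert("contacts", {
        "name": name, "unit_id": unit_id,
        "email": f"{name.split()[0].lower()}@example.org"})
        for name in ("Ada Keller", "Jonas Brandt", "Mai Tran")]
    protocol_ids = {
        "EXTRACTION": db.insert("protocols", {
            "name": "salting-out extraction",
            "protocol_type_id": db.one(
                "SELECT code_id FROM codes WHERE code_class='PROTOCOL_TYPE' "
                "AND short_name='EXTRACTION'")["code_id"]}),
        "PCR": db.insert("protocols", {
            "name": "standard touchdown PCR",
            "protocol_type_id": db.one(
                "SELECT code_id FROM codes WHERE code_class='PROTOCOL_TYPE' "
                "AND short_name='PCR'")["code_id"]}),
    }

    def _salt() -> str:
        return "".join(rng.choices("0123456789abcdef", k=32))

    access.create_user(db, "admin", "demo-admin-pw", salt=_salt(),
                       system_role="user_administrator", db_role="full_right")
    access.create_user(db, "alice", "demo-scientist-pw", salt=_salt(),
                       system_role="scientist", db_role="write",
                       contact_id=contact_ids[0])
    access.create_user(db, "guest", "demo-guest-pw", salt=_salt(),
                       system_role="visitor", db_role="read")

    # projects alternate purpose: even index sequencing, odd genotyping
    project_ids, project_purpose = [], {}
    for i in range(spec.n_projects):
        purpose = "sequencing" if i % 2 == 0 else "genotyping"
        pid = create_project(db, f"DEMO-P{i + 1}", purpose,
                             owner_contact_id=contact_ids[i % len(contact_ids)],
                             start_date=_DATE)
        project_ids.append(pid)
        project_purpose[pid] = purpose

    # storage tree: Lab -> Freezer -> Shelf -> Rack -> Box (boxes on demand)
    lab = _storage.add_node(db, None, "Main Lab")
    freezers = [_storage.add_node(db, lab, f"Freezer {i + 1}") for i in range(2)]
    racks = []
    for fz in freezers:
        for s in range(2):
            shelf = _storage.add_node(db, fz, f"Shelf {s + 1}")
            racks.append(_storage.add_node(db, shelf, "Rack 1"))
    boxes: list[_storage.StorageNode] = []
    box_fill: list[int] = []

    def next_box() -> _storage.StorageNode:
        if boxes and box_fill[-1] < 100:
            box_fill[-1] += 1
            return boxes[-1]
        rack = racks[len(boxes) % len(racks)]
        box = _storage.add_node(db, rack, f"Box {len(boxes) + 1}")
        boxes.append(box)
        box_fill.append(1)
        return box

    species = [s for s, _ in _CODE_SEED["SPECIES"]]
    breeds = [b for b, _ in _CODE_SEED["BREED"]]
    materials = [m for m, _ in _CODE_SEED["MATERIAL_TYPE"]]
    vessels = [v for v, _ in _CODE_SEED["VESSEL_TYPE"]]

    organism_ids = [
        register_individual(
            db, ID_SYSTEM, f"AN{i + 1:05d}", rng.choice(species),
            rng.choice(breeds), rng.choice(("F", "M")))
        for i in range(spec.n_individuals)]

    sample_ids, sample_project = [], {}
    for i in range(spec.n_samples):
        pid = project_ids[i % spec.n_projects] if project_ids else None
        sid = register_sample(
            db, organism_ids[i % max(spec.n_individuals, 1)], pid,
            rng.choice(materials), rng.choice(vessels),
            round(rng.uniform(0.5, 10.0), 1), "ml")
        sample_ids.append(sid)
        sample_project[sid] = pid
        _storage.place_item(db, ("sample", sid), next_box(), _DATE)
        if i % 7 == 0:
            _wf.record_collection(db, sid, contact_ids[i % len(contact_ids)], _DATE)

    # DNA extraction: mostly singletons, periodic 3-sample pools per project
    dna_by_project: dict[int, list[int]] = {pid: [] for pid in project_ids}
    by_project: dict[int, list[int]] = {pid: [] for pid in project_ids}
    for sid in sample_ids:
        by_project[sample_project[sid]].append(sid)
    for pid, sids in by_project.items():
        i = 0
        count = 0
        while i < len(sids):
            count += 1
            if spec.pool_every and count % spec.pool_every == 0 and i + 3 <= len(sids):
                group = sids[i:i + 3]
                i += 3
            else:
                group = [sids[i]]
                i += 1
            dna_id = _wf.extract_dna(
                db, group, protocol_id=protocol_ids["EXTRACTION"], date=_DATE,
                operator_contact_id=contact_ids[0],
                concentration=round(rng.uniform(10, 80), 1))
            dna_by_project[pid].append(dna_id)

    # PCR + validation + electrophoresis
    seq_projects = [p for p in project_ids if project_purpose[p] == "sequencing"]
    gen_projects = [p for p in project_ids if project_purpose[p] == "genotyping"]
    msat_markers = list(STR_MARKERS[:spec.n_markers])
    pcr_marker: dict[int, str] = {}
    pcr_project: dict[int, int] = {}
    for pid in project_ids:
        purpose = project_purpose[pid]
        markers = SEQ_MARKERS if purpose == "sequencing" else msat_markers
        mtype = "SEQUENCE" if purpose == "sequencing" else "MICROSATELLITE"
        dnas = dna_by_project[pid]
        for start in range(0, len(dnas), 8):
            chunk = dnas[start:start + 8]
            marker = markers[(start // 8) % len(markers)] if markers else None
            if marker is None:
                continue
            pcr_id = _wf.setup_pcr(db, chunk, [marker],
                                   protocol_id=protocol_ids["PCR"], date=_DATE,
                                   marker_type=mtype)
            pcr_marker[pcr_id] = marker
            pcr_project[pcr_id] = pid
            if start == 0:
                _wf.record_validation(
                    db, ("pcr", pcr_id), "pass",
                    gel_image=rng.randbytes(spec.raw_file_size) or b"\x00",
                    comment="demo gel")
            raw = ([rng.randbytes(spec.raw_file_size)]
                   if purpose == "sequencing" and start == 0 and spec.raw_file_size
                   else [])
            _wf.record_electrophoresis(
                db, pcr_id, method="CAPILLARY" if purpose == "sequencing" else "GEL",
                machine="demo-sequencer", date=_DATE, raw_files=raw)

    # final sequences, imported through the FASTA path per (project, marker)
    n_seq = 0
    seq_targets: dict[tuple[int, str], list[int]] = {}
    for pcr_id, marker in pcr_marker.items():
        pid = pcr_project[pcr_id]
        if project_purpose[pid] != "sequencing":
            continue
        dnas = [r["dna_id"] for r in db.query(
            "SELECT dna_id FROM amplified_samples WHERE pcr_id=? ORDER BY dna_id",
            (pcr_id,))]
        seq_targets.setdefault((pid, marker), []).extend(dnas)
    for (pid, marker), dnas in sorted(seq_targets.items()):
        if n_seq >= spec.n_sequences:
            break
        batch = []
        for dna_id in dnas:
            if n_seq >= spec.n_sequences:
                break
            bases = _random_bases(rng, rng.randint(180, 320))
            batch.append((str(dna_id), bases))
            n_seq += 1
        if batch:
            fasta = "".join(f">{name}\n{seq}\n" for name, seq in batch)
            _wf.import_sequences(db, fasta, marker, "SEQANALYZER", project_id=pid)

    # final microsatellites, imported through the matrix path per project
    n_msat_attempted = 0
    for pid in gen_projects:
        if n_msat_attempted >= spec.n_microsats:
            break
        dnas = dna_by_project[pid]
        if not dnas or not msat_markers:
            continue
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        header = ["sample"]
        for m in msat_markers:
            header += [f"{m}_1", f"{m}_2"]
        w.writerow(header)
        wrote = False
        for dna_id in dnas:
            if n_msat_attempted >= spec.n_microsats:
                break
            row = [str(dna_id)]
            any_cell = False
            for _ in msat_markers:
                if n_msat_attempted >= spec.n_microsats:
                    row += ["0", "0"]
                    continue
                n_msat_attempted += 1
                if rng.random() < spec.missing_rate:
                    row += ["0", "0"]
                else:
                    base = 80 + 2 * rng.randint(10, 80)
                    a1 = base
                    a2 = base + 2 * rng.randint(0, 6)
                    row += [str(a1), str(a2)]
                    any_cell = True
            w.writerow(row)
            wrote = wrote or any_cell
        if wrote:
            _wf.import_microsat_matrix(db, pid, buf.getvalue(), msat_markers,
                                       "diploid", "PEAKCALLER")

    manifest = {
        "projects": len(project_ids),
        "individuals": len(organism_ids),
        "samples": len(sample_ids),
        "dna_extractions": db.one(
            "SELECT COUNT(DISTINCT dna_id) AS n FROM dna_extraction")["n"],
        "pcr_runs": db.one("SELECT COUNT(*) AS n FROM pcr_amplification")["n"],
        "electrophoresis_runs": db.one(
            "SELECT COUNT(*) AS n FROM electrophoresis")["n"],
        "validations": db.one("SELECT COUNT(*) AS n FROM validation")["n"],
        "sequences": db.one("SELECT COUNT(*) AS n FROM sequences")["n"],
        "microsatellites": db.one("SELECT COUNT(*) AS n FROM microsatellites")["n"],
        "storage_nodes": db.one("SELECT COUNT(*) AS n FROM storage")["n"],
        "placements": db.one("SELECT COUNT(*) AS n FROM storage_samples")["n"],
        "blobs": db.one("SELECT COUNT(*) AS n FROM blobs")["n"],
        "users": db.one("SELECT COUNT(*) AS n FROM users")["n"],
    }
    return manifest


# -- loader bundle + content equivalence -----------------------------------


def emit_loader_bundle(db: Database, project_id: int, outdir) -> Path:
    """Write batch-loader sheets + config reproducing one project's content.

    Requires each organism to own exactly one sample in the project (so
    external IDs resolve unambiguously during the load).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    project = db.one("SELECT * FROM projects WHERE project_id=?", (project_id,))
    purpose = code_name(db, project["purpose_id"])

    (outdir / "samples.csv").write_text(export_sample_sheet(db, project_id),
                                        encoding="utf-8")

    def first_extid(sample_id: int) -> str:
        org = db.one("SELECT organism_id FROM samples WHERE sample_id=?",
                     (sample_id,))
        ext = external_ids(db, org["organism_id"])
        return ext[0]["external_id"]

    # DNA sheet: group tag per extraction so pools survive the round trip
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_wf.DNA_SHEET_COLUMNS)
    dna_rows = db.query(
        "SELECT d.* FROM dna_extraction d JOIN samples s ON s.sample_id=d.sample_id "
        "WHERE s.project_id=? ORDER BY d.dna_id, d.sample_id", (project_id,))
    for r in dna_rows:
        w.writerow([f"G{r['dna_id']}", first_extid(r["sample_id"]), "",
                    r["date"] or "", "", r["concentration"] or ""])
    (outdir / "dna.csv").write_text(buf.getvalue(), encoding="utf-8")

    config = [
        "mode = samples_and_final",
        f"project = {project['name']}",
        f"purpose = {purpose}",
        f"id_system = {ID_SYSTEM}",
        "samples = samples.csv",
        "dna = dna.csv",
    ]

    # sequences: one FASTA per marker, keyed by external ID
    seq_parts = []
    markers = sorted({code_name(db, r["primer_id"]) for r in db.query(
        "SELECT DISTINCT q.primer_id FROM sequences q "
        "JOIN dna_extraction d ON d.dna_id=q.dna_id "
        "JOIN samples s ON s.sample_id=d.sample_id WHERE s.project_id=?",
        (project_id,))})
    for marker in markers:
        rows = db.query(
            "SELECT DISTINCT q.seq_id, q.dna_id, q.bases FROM sequences q "
            "JOIN dna_extraction d ON d.dna_id=q.dna_id "
            "JOIN samples s ON s.sample_id=d.sample_id "
            "JOIN codes c ON c.code_id=q.primer_id "
            "WHERE s.project_id=? AND c.short_name=? ORDER BY q.seq_id",
            (project_id, marker))
        fasta = ""
        for r in rows:
            src = db.one("SELECT sample_id FROM dna_extraction WHERE dna_id=? "
                         "ORDER BY sample_id LIMIT 1", (r["dna_id"],))
            fasta += f">{first_extid(src['sample_id'])}\n{r['bases']}\n"
        fname = f"seqs_{marker}.fasta"
        (outdir / fname).write_text(fasta, encoding="utf-8")
        seq_parts.append(f"{marker}={fname}")
        softw = db.one(
            "SELECT software_id FROM sequences q JOIN codes c "
            "ON c.code_id=q.primer_id WHERE c.short_name=? LIMIT 1", (marker,))
        if softw and softw["software_id"]:
            config.append(f"software = {code_name(db, softw['software_id'])}")
    if seq_parts:
        config.append("sequences = " + ";".join(seq_parts))

    # microsatellites: two-column diploid matrix keyed by external ID
    msat_markers = sorted({code_name(db, r["primer_id"]) for r in db.query(
        "SELECT DISTINCT m.primer_id FROM microsatellites m "
        "JOIN dna_extraction d ON d.dna_id=m.dna_id "
        "JOIN samples s ON s.sample_id=d.sample_id WHERE s.project_id=?",
        (project_id,))})
    if msat_markers:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        header = ["sample"]
        for m in msat_markers:
            header += [f"{m}_1", f"{m}_2"]
        w.writerow(header)
        dna_ids = sorted({r["dna_id"] for r in db.query(
            "SELECT m.dna_id FROM microsatellites m "
            "JOIN dna_extraction d ON d.dna_id=m.dna_id "
            "JOIN samples s ON s.sample_id=d.sample_id WHERE s.project_id=?",
            (project_id,))})
        for dna_id in dna_ids:
            src = db.one("SELECT sample_id FROM dna_extraction WHERE dna_id=? "
                         "ORDER BY sample_id LIMIT 1", (dna_id,))
            row = [first_extid(src["sample_id"])]
            for m in msat_markers:
                g = db.one(
                    "SELECT m2.allele1, m2.allele2 FROM microsatellites m2 "
                    "JOIN codes c ON c.code_id=m2.primer_id "
                    "WHERE m2.dna_id=? AND c.short_name=?", (dna_id, m))
                row += ([str(g["allele1"] or 0), str(g["allele2"] or 0)]
                        if g else ["0", "0"])
            w.writerow(row)
        (outdir / "microsats.csv").write_text(buf.getvalue(), encoding="utf-8")
        config.append("microsats = microsats.csv")
        config.append("markers = " + ",".join(msat_markers))
        config.append("ploidy = diploid")

    conf_path = outdir / "load.conf"
    conf_path.write_text("\n".join(dict.fromkeys(config)) + "\n", encoding="utf-8")
    return conf_path


def content_summary(db: Database, project_name: str | None = None) -> dict:
    """Normalized natural-key view of database content, surrogate-ID free.

    Used to compare databases populated through different routes
    (interactive API vs batch loader).
    """
    where, params = "", ()
    if project_name is not None:
        where, params = "WHERE p.name=?", (project_name,)

    def extid(organism_id: int) -> str:
        ext = external_ids(db, organism_id)
        return ext[0]["external_id"] if ext else f"org{organism_id}"

    organisms = set()
    for r in db.query(
            f"SELECT DISTINCT o.* FROM organisms o "
            f"JOIN samples s ON s.organism_id=o.organism_id "
            f"JOIN projects p ON p.project_id=s.project_id {where}", params):
        organisms.add((extid(r["organism_id"]), code_name(db, r["species_id"]),
                       code_name(db, r["breed_id"]), code_name(db, r["sex_id"])))

    samples = {}
    for r in db.query(
            f"SELECT s.*, p.name AS pname FROM samples s "
            f"JOIN projects p ON p.project_id=s.project_id {where}", params):
        key = (extid(r["organism_id"]), r["pname"],
               code_name(db, r["material_type_id"]),
               code_name(db, r["vessel_type_id"]), r["amount"], r["amount_unit"])
        samples[key] = samples.get(key, 0) + 1
    sample_ext = {r["sample_id"]: extid(r["organism_id"]) for r in db.query(
        f"SELECT s.sample_id, s.organism_id FROM samples s "
        f"JOIN projects p ON p.project_id=s.project_id {where}", params)}

    dna_groups: dict[int, frozenset] = {}
    for r in db.query("SELECT dna_id, sample_id FROM dna_extraction"):
        if r["sample_id"] in sample_ext:
            dna_groups.setdefault(r["dna_id"], set())
    for r in db.query("SELECT dna_id, sample_id FROM dna_extraction"):
        if r["dna_id"] in dna_groups and r["sample_id"] in sample_ext:
            dna_groups[r["dna_id"]].add(sample_ext[r["sample_id"]])
    dna = {frozenset(v) for v in dna_groups.values()}

    sequences = set()
    for r in db.query("SELECT * FROM sequences"):
        if r["dna_id"] in dna_groups:
            sequences.add((code_name(db, r["primer_id"]),
                           frozenset(dna_groups[r["dna_id"]]), r["bases"]))

    msats = set()
    for r in db.query("SELECT * FROM microsatellites"):
        if r["dna_id"] in dna_groups:
            msats.add((code_name(db, r["primer_id"]),
                       frozenset(dna_groups[r["dna_id"]]),
                       r["allele1"], r["allele2"]))

    return {"organisms": organisms,
            "samples": frozenset(samples.items()),
            "dna": dna, "sequences": sequences, "microsatellites": msats}
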