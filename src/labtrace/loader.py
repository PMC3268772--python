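"""Batch migration of historical project data from spreadsheets.

A plain-text configuration file of name/value records drives the load:
which project, which sheets, which mode.  The whole load runs in a single
transaction through the same rule-checked paths as interactive entry; any
row error rolls everything back, leaving the database byte-identical to its
pre-load state.  Dry-run mode performs the full load and report inside the
transaction, then rolls back unconditionally.

Foreign keys arriving as text are resolved against the code tables
case-insensitively; unmatched values create a new code and near-matches
(edit distance <= 1 after case folding) are flagged as similar-key warnings
for post-hoc review — never silently merged.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ImportError_, LimsError, NotFoundError
from .schema import Database, RELATIONS, add_code, Code
from .registry import register_individual, register_sample, get_project, create_project
from . import workflow as _wf

MODES = ("individuals_only", "samples_and_final", "samples_raw_and_final",
         "final_only")

_KNOWN_KEYS = ("mode", "project", "purpose", "id_system", "software",
               "individuals", "samples", "dna", "sequences", "microsats",
               "markers", "ploidy", "raw_dir", "dry_run")

_SHEET_KEYS = ("individuals", "samples", "dna", "microsats")

INDIVIDUAL_SHEET_COLUMNS = ("id_system", "external_id", "species", "breed", "sex")

from .registry import SAMPLE_SHEET_COLUMNS  # noqa: E402  (shared layout)


@dataclass
class LoaderConfig:
    mode: str
    project: str
    base_dir: Path
    sheets: dict[str, Path] = field(default_factory=dict)
    sequences: list[tuple[str, Path]] = field(default_factory=list)  # (marker, fasta)
    markers: list[str] = field(default_factory=list)
    ploidy: str = "diploid"
    purpose: str | None = None
    id_system: str = "legacy"
    software: str | None = None
    raw_dir: Path | None = None
    dry_run: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass
class LoadReport:
    inserted: dict[str, int] = field(default_factory=dict)
    new_codes: list[tuple[str, str]] = field(default_factory=list)
    similar_keys: list[dict] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    rows_processed: int = 0
    rolled_back: bool = False
    dry_run: bool = False

    def summary(self) -> str:
        lines = [f"mode rows={self.rows_processed} rolled_back={self.rolled_back}"
                 f" dry_run={self.dry_run}"]
        for rel, n in sorted(self.inserted.items()):
            if n:
                lines.append(f"  inserted {rel}: {n}")
        for cls, val in self.new_codes:
            lines.append(f"  new code {cls}:{val}")
        for w in self.similar_keys:
            lines.append(f"  similar keys: {w['value']!r} ~ {w['existing']!r} "
                         f"(class {w['class']}, distance {w['distance']})")
        lines += [f"  warning: {w}" for w in self.warnings]
        lines += [f"  error: {e}" for e in self.errors]
        return "\n".join(lines)


def parse_config(path: str | os.PathLike) -> LoaderConfig:
    """Read a name/value configuration file (``key = value`` records)."""
    path = Path(path)
    if not path.is_file():
        raise NotFoundError(f"cannot read config {path}")
    pairs: dict[str, str] = {}
    warnings: list[str] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ImportError_(f"config line {lineno}: not a name = value record")
        key, _, value = line.partition("=")
        key, value = key.strip().lower(), value.strip()
        if key in pairs:
            warnings.append(f"duplicate key {key!r}: last value wins")
        if key not in _KNOWN_KEYS:
            warnings.append(f"unknown key {key!r} ignored")
            continue
        pairs[key] = value

    if "mode" not in pairs:
        raise ImportError_("config lacks required key 'mode'")
    mode = pairs["mode"]
    if mode not in MODES:
        raise ImportError_(f"invalid mode {mode!r}; valid: {MODES}")
    if "project" not in pairs:
        raise ImportError_("config lacks required key 'project'")

    cfg = LoaderConfig(mode=mode, project=pairs["project"], base_dir=path.parent,
                       warnings=warnings)
    for key in _SHEET_KEYS:
        if key in pairs and pairs[key]:
            p = (cfg.base_dir / pairs[key]).resolve()
            if not p.is_file():
                raise ImportError_(f"sheet {key}: file {p} does not exist")
            cfg.sheets[key] = p
    if pairs.get("sequences"):
        for part in pairs["sequences"].split(";"):
            marker, _, rel = part.strip().partition("=")
            if not rel:
                raise ImportError_(
                    "sequences value must be MARKER=path[;MARKER=path...]")
            p = (cfg.base_dir / rel.strip()).resolve()
            if not p.is_file():
                raise ImportError_(f"sequence file {p} does not exist")
            cfg.sequences.append((marker.strip(), p))
    if pairs.get("markers"):
        cfg.markers = [m.strip() for m in pairs["markers"].split(",") if m.strip()]
    cfg.ploidy = pairs.get("ploidy", "diploid")
    cfg.purpose = pairs.get("purpose")
    cfg.id_system = pairs.get("id_system", "legacy")
    cfg.software = pairs.get("software")
    if pairs.get("raw_dir"):
        cfg.raw_dir = (cfg.base_dir / pairs["raw_dir"]).resolve()
        if not cfg.raw_dir.is_dir():
            raise ImportError_(f"raw_dir {cfg.raw_dir} does not exist")
    cfg.dry_run = pairs.get("dry_run", "").lower() in ("1", "true", "yes")
    return cfg


def edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance (small inputs: code values)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def resolve_code(db: Database, code_class: str, value: str,
                 report: LoadReport) -> Code:
    """Case-insensitive code lookup; creates + flags near-misses otherwise."""
    if not value or not value.strip():
        raise ImportError_(f"empty value for code class {code_class}")
    value = value.strip()
    rows = db.query("SELECT * FROM codes WHERE code_class=?", (code_class,))
    folded = value.casefold()
    for r in rows:
        if r["short_name"].casefold() == folded:
            return Code(r["code_id"], r["code_class"], r["short_name"],
                        r["long_name"], r["description"], bool(r["active"]))
    for r in rows:
        if edit_distance(r["short_name"].casefold(), folded) <= 1:
            report.similar_keys.append({
                "class": code_class, "value": value,
                "existing": r["short_name"],
                "distance": edit_distance(r["short_name"].casefold(), folded)})
    code = add_code(db, code_class, value)
    report.new_codes.append((code_class, value))
    return code


class _DryRunRollback(Exception):
    pass


def _read_csv(path: Path) -> str:
    return path.read_text(encoding="utf-8")


def _table_counts(db: Database) -> dict[str, int]:
    return {rel: db.one(f"SELECT COUNT(*) AS n FROM {rel}")["n"]
            for rel in RELATIONS}


def run_load(db: Database, config: LoaderConfig) -> LoadReport:
    """Execute a batch load; atomic, optionally dry-run.

    Load order is fixed (codes/contacts resolve on the fly, then project,
    organisms, samples, DNA, amplification scaffolding, final data) so
    forward references never occur.
    """
    report = LoadReport(dry_run=config.dry_run)
    report.warnings.extend(config.warnings)
    before = _table_counts(db)
    try:
        with db.transaction():
            _load_all(db, config, report)
            after = _table_counts(db)
            report.inserted = {rel: after[rel] - before[rel]
                               for rel in RELATIONS if after[rel] != before[rel]}
            if config.dry_run:
                raise _DryRunRollback
    except _DryRunRollback:
        report.rolled_back = True
    except (LimsError, ValueError) as exc:
        report.errors.append(str(exc))
        report.rolled_back = True
        report.inserted = {}
        report.new_codes = []
    return report


def _load_all(db: Database, config: LoaderConfig, report: LoadReport) -> None:
    # project
    try:
        project = get_project(db, config.project)
    except NotFoundError:
        if config.mode == "final_only":
            raise ImportError_(
                f"final_only mode requires existing project {config.project!r}")
        purpose = resolve_code(db, "PURPOSE", config.purpose or "genotyping", report)
        pid = create_project(db, config.project, purpose.short_name)
        project = get_project(db, pid)
    project_id = project["project_id"]
    software_code = (resolve_code(db, "SOFTWARE", config.software, report)
                     if config.software else None)

    # individuals
    if "individuals" in config.sheets:
        reader = csv.DictReader(io.StringIO(_read_csv(config.sheets["individuals"])))
        missing = set(INDIVIDUAL_SHEET_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ImportError_(
                f"individuals sheet lacks columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            report.rows_processed += 1
            try:
                register_individual(
                    db,
                    row["id_system"] or config.id_system,
                    row["external_id"],
                    resolve_code(db, "SPECIES", row["species"], report).short_name,
                    resolve_code(db, "BREED", row["breed"], report).short_name
                    if (row.get("breed") or "").strip() else None,
                    resolve_code(db, "SEX", row["sex"], report).short_name
                    if (row.get("sex") or "").strip() else None)
            except LimsError as exc:
                raise ImportError_(f"individuals row {lineno}: {exc}") from exc
    if config.mode == "individuals_only":
        return

    # samples (with embedded individual data)
    if "samples" in config.sheets:
        reader = csv.DictReader(io.StringIO(_read_csv(config.sheets["samples"])))
        missing = set(SAMPLE_SHEET_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ImportError_(f"samples sheet lacks columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            report.rows_processed += 1
            try:
                organism_id = register_individual(
                    db, row["id_system"] or config.id_system, row["external_id"],
                    resolve_code(db, "SPECIES", row["species"], report).short_name,
                    resolve_code(db, "BREED", row["breed"], report).short_name
                    if (row.get("breed") or "").strip() else None,
                    resolve_code(db, "SEX", row["sex"], report).short_name
                    if (row.get("sex") or "").strip() else None)
                register_sample(
                    db, organism_id, project_id,
                    resolve_code(db, "MATERIAL_TYPE", row["material_type"],
                                 report).short_name,
                    resolve_code(db, "VESSEL_TYPE", row["vessel_type"],
                                 report).short_name
                    if (row.get("vessel_type") or "").strip() else None,
                    float(row["amount"]) if row.get("amount") else None,
                    row.get("unit") or None)
            except (LimsError, ValueError) as exc:
                raise ImportError_(f"samples row {lineno}: {exc}") from exc
    elif config.mode in ("samples_and_final", "samples_raw_and_final"):
        raise ImportError_(f"mode {config.mode} requires a samples sheet")

    # DNA extractions
    if "dna" in config.sheets:
        dna_ids = _wf.import_dna_sheet(db, project_id,
                                       _read_csv(config.sheets["dna"]))
        report.rows_processed += len(dna_ids)
    elif config.mode != "final_only" and (config.sequences or
                                          "microsats" in config.sheets):
        # final data without an explicit DNA sheet: one extraction per sample
        dna_ids = []
        for r in db.query(
                "SELECT s.sample_id FROM samples s LEFT JOIN dna_extraction d "
                "ON d.sample_id=s.sample_id WHERE s.project_id=? "
                "AND d.extraction_row_id IS NULL ORDER BY s.sample_id",
                (project_id,)):
            dna_ids.append(_wf.extract_dna(db, [r["sample_id"]]))

    project_dnas = sorted({r["dna_id"] for r in db.query(
        "SELECT d.dna_id FROM dna_extraction d JOIN samples s "
        "ON s.sample_id=d.sample_id WHERE s.project_id=?", (project_id,))})

    # sequences need an amplification trace: one migration PCR per marker
    raw_files = sorted(config.raw_dir.iterdir()) if (
        config.mode == "samples_raw_and_final" and config.raw_dir) else []
    for i, (marker, fasta_path) in enumerate(config.sequences):
        if not project_dnas:
            raise ImportError_("no DNA available for sequence import")
        marker_code = resolve_code(db, "PRIMER", marker, report)
        pcr_id = _wf.setup_pcr(db, project_dnas, [marker_code.short_name])
        batch = [p for j, p in enumerate(raw_files)
                 if j % max(len(config.sequences), 1) == i]
        _wf.record_electrophoresis(db, pcr_id, raw_files=batch)
        seq_ids = _wf.import_sequences(
            db, fasta_path.read_text(encoding="utf-8"), marker_code.short_name,
            software_code.short_name if software_code else None,
            project_id=project_id)
        report.rows_processed += len(seq_ids)

    # microsatellites
    if "microsats" in config.sheets:
        if not config.markers:
            raise ImportError_("microsats sheet requires the 'markers' key")
        for m in config.markers:
            resolve_code(db, "PRIMER", m, report)
        msat_ids = _wf.import_microsat_matrix(
            db, project_id, _read_csv(config.sheets["microsats"]),
            config.markers, config.ploidy,
            software_code.short_name if software_code else None)
        report.rows_processed += len(msat_ids)


def emit_templates(mode: str, outdir: str | os.PathLike) -> list[Path]:
    """Write empty, header-only sheets for a given load mode."""
    if mode not in MODES:
        raise NotFoundError(f"invalid mode {mode!r}; valid: {MODES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def sheet(name: str, columns):
        p = outdir / f"{name}.csv"
        p.write_text(",".join(columns) + "\n", encoding="utf-8")
        written.append(p)

    if mode == "individuals_only":
        sheet("individuals", INDIVIDUAL_SHEET_COLUMNS)
    else:
        if mode != "final_only":
            sheet("samples", SAMPLE_SHEET_COLUMNS)
            sheet("dna", _wf.DNA_SHEET_COLUMNS)
        sheet("microsats", ("sample", "marker1_allele1", "marker1_allele2"))
    config = outdir / "load.conf"
    lines = [f"mode = {mode}", "project = PROJECT_NAME"]
    lines += [f"{p.stem} = {p.name}" for p in written]
    config.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(config)
    return written
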