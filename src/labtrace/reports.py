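"""The thirteen predefined report types, rendered as text or CSV.

Every report is built from direct queries against the current database
state (no caching, no mutation) and headed by a small external template so
layouts can be adjusted without code changes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources as _ilres

from .errors import NotFoundError
from .schema import Database, code_name, get_code
from .registry import get_project, external_ids
from . import storage as _storage


@dataclass(frozen=True)
class ReportType:
    name: str
    params: tuple[str, ...]
    description: str


@dataclass
class ReportDocument:
    report_type: str
    title: str
    subtitle: str
    columns: list[str]
    rows: list[list]

    def as_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(self.columns)
        w.writerows(self.rows)
        return buf.getvalue()

    def as_text(self) -> str:
        widths = [len(c) for c in self.columns]
        srows = [[("" if v is None else str(v)) for v in r] for r in self.rows]
        for r in srows:
            for i, v in enumerate(r):
                widths[i] = max(widths[i], len(v))
        def fmt(cells):
            return "  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip()
        lines = [self.title, self.subtitle, "",
                 fmt(self.columns), fmt(["-" * w for w in widths])]
        lines += [fmt(r) for r in srows]
        lines.append(f"\n{len(self.rows)} row(s)")
        return "\n".join(lines) + "\n"


_REGISTRY: dict[str, ReportType] = {}


def _register(name: str, params: tuple[str, ...], description: str):
    _REGISTRY[name] = ReportType(name, params, description)


_register("project_list", (), "list of all projects")
_register("contact_list", (), "list of all contacts")
_register("individual_list", (), "list of all individuals")
_register("project_samples_storage", ("project",),
          "samples of a project with storage locations")
_register("project_dna_storage", ("project",),
          "DNA of a project with storage locations")
_register("seq_stats_marker", ("marker",), "sequence statistics for one marker")
_register("seq_stats_project", ("project",), "sequence statistics for one project")
_register("seq_stats_lab", (), "sequence statistics for the whole lab")
_register("msat_stats_marker", ("marker",),
          "microsatellite statistics for one marker")
_register("msat_stats_project", ("project",),
          "microsatellite statistics for one project")
_register("msat_stats_lab", (), "microsatellite statistics for the whole lab")
_register("lab_summary", (), "data volume of the entire lab")
_register("sample_distribution", ("project",),
          "sample counts per material type in one project")


def list_report_types() -> dict[str, ReportType]:
    """The closed registry of the 13 predefined report types."""
    return dict(_REGISTRY)


def _template(name: str) -> tuple[str, str]:
    path = _ilres.files("labtrace.resources.report_templates").joinpath(f"{name}.tmpl")
    lines = path.read_text(encoding="utf-8").splitlines()
    title = lines[0] if lines else name
    subtitle = lines[1] if len(lines) > 1 else ""
    return title, subtitle


def _storage_path_of(db: Database, item) -> str:
    try:
        return _storage.format_path(_storage.locate_item(db, item))
    except NotFoundError:
        return ""


def _seq_stats(db: Database, where: str, params: tuple) -> list[list]:
    rows = db.query(
        f"SELECT q.primer_id, COUNT(*) AS n, MIN(q.length) AS mn, "
        f"AVG(q.length) AS avg, MAX(q.length) AS mx "
        f"FROM sequences q {where} GROUP BY q.primer_id ORDER BY q.primer_id",
        params)
    return [[code_name(db, r["primer_id"]), r["n"], r["mn"],
             round(r["avg"], 2), r["mx"]] for r in rows]


def _msat_stats(db: Database, where: str, params: tuple) -> list[list]:
    rows = db.query(
        f"SELECT m.primer_id, m.allele1, m.allele2 FROM microsatellites m {where}",
        params)
    by_marker: dict[int, list] = {}
    for r in rows:
        by_marker.setdefault(r["primer_id"], []).append((r["allele1"], r["allele2"]))
    out = []
    for primer_id in sorted(by_marker):
        genotypes = by_marker[primer_id]
        sizes = [a for g in genotypes for a in g if a is not None]
        out.append([code_name(db, primer_id), len(genotypes),
                    len(set(sizes)),
                    min(sizes) if sizes else None,
                    max(sizes) if sizes else None])
    return out


_MSAT_PROJECT_JOIN = (
    "JOIN dna_extraction d ON d.dna_id=m.dna_id "
    "JOIN samples s ON s.sample_id=d.sample_id WHERE s.project_id=?")
_SEQ_PROJECT_JOIN = (
    "JOIN dna_extraction d ON d.dna_id=q.dna_id "
    "JOIN samples s ON s.sample_id=d.sample_id WHERE s.project_id=?")


def generate_report(db: Database, report_type: str,
                    params: dict | None = None) -> ReportDocument:
    """Build one report; every cell derives from a direct query."""
    if report_type not in _REGISTRY:
        raise NotFoundError(f"unknown report type {report_type!r}")
    spec = _REGISTRY[report_type]
    params = params or {}
    for p in spec.params:
        if p not in params:
            raise NotFoundError(f"report {report_type} requires parameter {p!r}")
    title, subtitle = _template(report_type)

    project = None
    if "project" in spec.params:
        project = get_project(db, params["project"])
        title = title.format(project=project["name"])
        subtitle = subtitle.format(project=project["name"])
    if "marker" in spec.params:
        get_code(db, "PRIMER", params["marker"])  # must resolve
        title = title.format(marker=params["marker"])
        subtitle = subtitle.format(marker=params["marker"])

    if report_type == "project_list":
        columns = ["project", "purpose", "start_date", "samples"]
        rows = [[r["name"], code_name(db, r["purpose_id"]), r["start_date"],
                 db.one("SELECT COUNT(*) AS n FROM samples WHERE project_id=?",
                        (r["project_id"],))["n"]]
                for r in db.query("SELECT * FROM projects ORDER BY project_id")]
    elif report_type == "contact_list":
        columns = ["name", "unit", "email", "phone"]
        rows = []
        for r in db.query("SELECT * FROM contacts ORDER BY contact_id"):
            unit = db.one("SELECT name FROM unit WHERE unit_id=?", (r["unit_id"],))
            rows.append([r["name"], unit["name"] if unit else None,
                         r["email"], r["phone"]])
    elif report_type == "individual_list":
        columns = ["external_id", "id_system", "species", "breed", "sex"]
        rows = []
        for r in db.query("SELECT * FROM organisms ORDER BY organism_id"):
            ext = external_ids(db, r["organism_id"])
            first = ext[0] if ext else {"external_id": None, "id_system": None}
            rows.append([first["external_id"], first["id_system"],
                         code_name(db, r["species_id"]),
                         code_name(db, r["breed_id"]),
                         code_name(db, r["sex_id"])])
    elif report_type == "project_samples_storage":
        columns = ["sample_id", "external_id", "material", "amount", "unit", "location"]
        rows = []
        for r in db.query("SELECT * FROM samples WHERE project_id=? ORDER BY sample_id",
                          (project["project_id"],)):
            ext = external_ids(db, r["organism_id"])
            rows.append([r["sample_id"],
                         ext[0]["external_id"] if ext else None,
                         code_name(db, r["material_type_id"]),
                         r["amount"], r["amount_unit"],
                         _storage_path_of(db, ("sample", r["sample_id"]))])
    elif report_type == "project_dna_storage":
        columns = ["dna_id", "source_samples", "date", "location"]
        rows = []
        dna_ids = sorted({r["dna_id"] for r in db.query(
            "SELECT d.dna_id FROM dna_extraction d JOIN samples s "
            "ON s.sample_id=d.sample_id WHERE s.project_id=?",
            (project["project_id"],))})
        for dna_id in dna_ids:
            src = db.query(
                "SELECT sample_id, date FROM dna_extraction WHERE dna_id=? "
                "ORDER BY sample_id", (dna_id,))
            rows.append([dna_id,
                         ";".join(str(s["sample_id"]) for s in src),
                         src[0]["date"],
                         _storage_path_of(db, ("dna", dna_id))])
    elif report_type in ("seq_stats_marker", "seq_stats_project", "seq_stats_lab"):
        columns = ["marker", "sequences", "min_length", "mean_length", "max_length"]
        if report_type == "seq_stats_marker":
            pid = get_code(db, "PRIMER", params["marker"]).code_id
            rows = _seq_stats(db, "WHERE q.primer_id=?", (pid,))
        elif report_type == "seq_stats_project":
            rows = _seq_stats(db, _SEQ_PROJECT_JOIN, (project["project_id"],))
        else:
            rows = _seq_stats(db, "", ())
    elif report_type in ("msat_stats_marker", "msat_stats_project", "msat_stats_lab"):
        columns = ["marker", "genotypes", "distinct_alleles", "min_size", "max_size"]
        if report_type == "msat_stats_marker":
            pid = get_code(db, "PRIMER", params["marker"]).code_id
            rows = _msat_stats(db, "WHERE m.primer_id=?", (pid,))
        elif report_type == "msat_stats_project":
            rows = _msat_stats(db, _MSAT_PROJECT_JOIN, (project["project_id"],))
        else:
            rows = _msat_stats(db, "", ())
    elif report_type == "lab_summary":
        columns = ["entity", "count"]
        rows = [
            ["projects", db.one("SELECT COUNT(*) AS n FROM projects")["n"]],
            ["individuals", db.one("SELECT COUNT(*) AS n FROM organisms")["n"]],
            ["samples", db.one("SELECT COUNT(*) AS n FROM samples")["n"]],
            ["dna_extractions",
             db.one("SELECT COUNT(DISTINCT dna_id) AS n FROM dna_extraction")["n"]],
            ["sequences", db.one("SELECT COUNT(*) AS n FROM sequences")["n"]],
            ["microsatellites",
             db.one("SELECT COUNT(*) AS n FROM microsatellites")["n"]],
        ]
    elif report_type == "sample_distribution":
        columns = ["material_type", "samples"]
        rows = [[code_name(db, r["material_type_id"]), r["n"]]
                for r in db.query(
                    "SELECT material_type_id, COUNT(*) AS n FROM samples "
                    "WHERE project_id=? GROUP BY material_type_id "
                    "ORDER BY material_type_id", (project["project_id"],))]
    else:  # pragma: no cover - registry is closed
        raise NotFoundError(report_type)

    return ReportDocument(report_type, title, subtitle, columns, rows)
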