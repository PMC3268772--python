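"""Conversion of final data for downstream analyses.

Sequences can be written in seven formats (fasta, nexus, phylip, mega, msf,
psi-blast, pfam/Stockholm) with cross-project merging; microsatellites in
three matrix layouts (one-column diploid, two-column diploid, one-column
haploid) as CSV or an XLSX workbook.  All exporters are read-only and
deterministic for a fixed selection.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import ExportError, LimsError, NotFoundError
from .schema import Database, get_code, code_name

SEQUENCE_FORMATS = ("fasta", "nexus", "phylip", "mega", "msf", "psi-blast", "pfam")
MICROSAT_LAYOUTS = ("one_column_diploid", "two_column_diploid", "one_column_haploid")
MICROSAT_FILE_FORMATS = ("csv", "xlsx")

GAP = "-"
MISSING_ALLELE = "0"
ALLELE_SEPARATOR = "/"


@dataclass
class SequenceSelection:
    """Named sequences sharing one marker, ready for export."""
    marker: str
    records: list[tuple[str, str]]  # (display name, bases)

    def __post_init__(self):
        names = [n for n, _ in self.records]
        if len(set(names)) != len(names):
            raise ExportError("display names must be unique within a selection")


@dataclass
class MicrosatSelection:
    project_ids: list[int]
    markers: list[str]            # ordered marker short names
    sample_ids: list[int]         # ordered samples
    layout: str = "two_column_diploid"
    file_format: str = "csv"

    def __post_init__(self):
        if self.layout not in MICROSAT_LAYOUTS:
            raise ExportError(f"unknown layout {self.layout!r}; valid: {MICROSAT_LAYOUTS}")
        if self.file_format not in MICROSAT_FILE_FORMATS:
            raise ExportError(
                f"unknown file format {self.file_format!r}; valid: {MICROSAT_FILE_FORMATS}")


# -- sequence writers -----------------------------------------------------


def _wrap(seq: str, width: int = 70) -> list[str]:
    return [seq[i:i + width] for i in range(0, len(seq), width)]


def _prepare(records: list[tuple[str, str]], fmt: str,
             pad: bool) -> list[tuple[str, str]]:
    if not records:
        raise ExportError("empty selection")
    if fmt == "fasta":
        return records
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        if not pad:
            raise ExportError(
                f"{fmt} is an alignment format and sequences have unequal "
                f"lengths {sorted(lengths)}; pass pad=True to right-pad with '-'")
        width = max(lengths)
        records = [(n, s + GAP * (width - len(s))) for n, s in records]
    return records


def _write_fasta(records) -> str:
    out = []
    for name, seq in records:
        out.append(f">{name}")
        out.extend(_wrap(seq))
    return "\n".join(out) + "\n"


_NEXUS_SAFE = __import__("re").compile(r"^[A-Za-z0-9_.]+$")


def _nexus_name(name: str) -> str:
    if _NEXUS_SAFE.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _write_nexus(records) -> str:
    ntax, nchar = len(records), len(records[0][1])
    lines = ["#NEXUS", "BEGIN DATA;",
             f"DIMENSIONS NTAX={ntax} NCHAR={nchar};",
             "FORMAT DATATYPE=DNA MISSING=? GAP=-;", "MATRIX"]
    names = [_nexus_name(n) for n, _ in records]
    width = max(len(n) for n in names)
    for quoted, (_, seq) in zip(names, records):
        lines.append(f"{quoted.ljust(width)}  {seq}")
    lines += [";", "END;"]
    return "\n".join(lines) + "\n"


def phylip_names(names: list[str]) -> tuple[list[str], dict[str, str]]:
    """Truncate to the 10-character PHYLIP limit, keeping names unique.

    Returns the new names and a map {new: original} for every changed name.
    """
    out: list[str] = []
    used: set[str] = set()
    mapping: dict[str, str] = {}
    for name in names:
        short = name[:10]
        if short in used:
            i = 1
            while True:
                suffix = f"_{i}"
                cand = name[:10 - len(suffix)] + suffix
                if cand not in used:
                    short = cand
                    break
                i += 1
        used.add(short)
        out.append(short)
        if short != name:
            mapping[short] = name
    return out, mapping


def _write_phylip(records) -> str:
    names, _ = phylip_names([n for n, _ in records])
    lines = [f" {len(records)} {len(records[0][1])}"]
    for short, (_, seq) in zip(names, records):
        lines.append(f"{short.ljust(10)}{seq}")
    return "\n".join(lines) + "\n"


def _write_mega(records) -> str:
    lines = ["#mega", "!Title exported sequences;", ""]
    for name, seq in records:
        lines.append(f"#{name}")
        lines.extend(_wrap(seq))
        lines.append("")
    return "\n".join(lines)


def _gcg_checksum(seq: str) -> int:
    total = 0
    for i, ch in enumerate(seq):
        total += ((i % 57) + 1) * ord(ch.upper())
    return total % 10000


def _write_msf(records) -> str:
    nchar = len(records[0][1])
    checks = {n: _gcg_checksum(s) for n, s in records}
    total = sum(checks.values()) % 10000
    lines = ["PileUp", "",
             f" exported.msf  MSF: {nchar}  Type: N  Check: {total} ..", ""]
    width = max(len(n) for n, _ in records)
    for name, seq in records:
        lines.append(f" Name: {name.ljust(width)}  Len: {nchar}  "
                     f"Check: {checks[name]}  Weight: 1.00")
    lines += ["", "//", ""]
    for start in range(0, nchar, 50):
        for name, seq in records:
            chunk = seq[start:start + 50]
            spaced = " ".join(chunk[i:i + 10] for i in range(0, len(chunk), 10))
            lines.append(f"{name.ljust(width)}  {spaced}")
        lines.append("")
    return "\n".join(lines) + "\n"


def _write_psiblast(records) -> str:
    # flat master-slave alignment accepted as PSI-BLAST restart input:
    # one "name sequence" line per entry
    width = max(len(n) for n, _ in records)
    return "\n".join(f"{n.ljust(width)}  {s}" for n, s in records) + "\n"


def _write_pfam(records) -> str:
    # Pfam flavour of Stockholm: whole alignment in one block
    width = max(len(n) for n, _ in records)
    lines = ["# STOCKHOLM 1.0"]
    lines += [f"{n.ljust(width)}  {s}" for n, s in records]
    lines.append("//")
    return "\n".join(lines) + "\n"


_WRITERS = {
    "fasta": _write_fasta,
    "nexus": _write_nexus,
    "phylip": _write_phylip,
    "mega": _write_mega,
    "msf": _write_msf,
    "psi-blast": _write_psiblast,
    "pfam": _write_pfam,
}


def write_sequences(records: list[tuple[str, str]], fmt: str,
                    pad: bool = False) -> str:
    """Render (name, bases) pairs in one of the seven supported formats."""
    if fmt not in SEQUENCE_FORMATS:
        raise ExportError(f"unknown format {fmt!r}; valid: {SEQUENCE_FORMATS}")
    names = [n for n, _ in records]
    if len(set(names)) != len(names):
        raise ExportError("duplicate sequence names")
    return _WRITERS[fmt](_prepare(list(records), fmt, pad))


def export_sequences(selection: SequenceSelection, fmt: str,
                     pad: bool = False) -> str:
    return write_sequences(selection.records, fmt, pad)


def convert_fasta(document: str, fmt: str, pad: bool = False) -> str:
    """Convert an uploaded FASTA document without touching the database."""
    if not document.strip().startswith(">"):
        raise ExportError("input does not parse as FASTA")
    records = [(r.id, str(r.seq))
               for r in SeqIO.parse(io.StringIO(document), "fasta")]
    if not records:
        raise ExportError("FASTA contains no records")
    return write_sequences(records, fmt, pad)


def merge_project_sequences(db: Database, marker: str,
                            project_ids: list[int]) -> SequenceSelection:
    """All sequences of one marker across projects, with unique display names.

    Names are "<project>_<sample external id>"; colliding names receive
    numeric suffixes in order of appearance.
    """
    primer_id = get_code(db, "PRIMER", marker).code_id
    raw: list[tuple[str, str]] = []
    for pid in project_ids:
        project = db.one("SELECT name FROM projects WHERE project_id=?", (pid,))
        if project is None:
            raise NotFoundError(f"no project {pid}")
        rows = db.query(
            "SELECT DISTINCT q.seq_id, q.bases, q.dna_id FROM sequences q "
            "JOIN dna_extraction d ON d.dna_id=q.dna_id "
            "JOIN samples s ON s.sample_id=d.sample_id "
            "WHERE q.primer_id=? AND s.project_id=? ORDER BY q.seq_id",
            (primer_id, pid))
        for r in rows:
            first_sample = db.one(
                "SELECT sample_id FROM dna_extraction WHERE dna_id=? "
                "ORDER BY sample_id LIMIT 1", (r["dna_id"],))
            org = db.one("SELECT organism_id FROM samples WHERE sample_id=?",
                         (first_sample["sample_id"],))
            ext = db.one(
                "SELECT external_id FROM transfer WHERE organism_id=? "
                "ORDER BY transfer_id LIMIT 1", (org["organism_id"],))
            label = f"{project['name']}_{ext['external_id'] if ext else r['dna_id']}"
            raw.append((label, r["bases"]))
    if not raw:
        raise NotFoundError(f"no sequences found for marker {marker!r}")
    counts: dict[str, int] = {}
    for name, _ in raw:
        counts[name] = counts.get(name, 0) + 1
    seen: dict[str, int] = {}
    records: list[tuple[str, str]] = []
    for name, bases in raw:
        if counts[name] > 1:
            seen[name] = seen.get(name, 0) + 1
            records.append((f"{name}_{seen[name]}", bases))
        else:
            records.append((name, bases))
    return SequenceSelection(marker=marker, records=records)


# -- microsatellite export ------------------------------------------------


def build_microsat_selection(db: Database, project_ids: list[int],
                             markers: list[str] | None = None,
                             sample_ids: list[int] | None = None,
                             layout: str = "two_column_diploid",
                             file_format: str = "csv") -> MicrosatSelection:
    """Fill in marker/sample order from the database when not given."""
    for pid in project_ids:
        if db.one("SELECT 1 FROM projects WHERE project_id=?", (pid,)) is None:
            raise NotFoundError(f"no project {pid}")
    qp = ",".join("?" for _ in project_ids)
    if markers is None:
        rows = db.query(
            f"SELECT DISTINCT m.primer_id FROM microsatellites m "
            f"JOIN dna_extraction d ON d.dna_id=m.dna_id "
            f"JOIN samples s ON s.sample_id=d.sample_id "
            f"WHERE s.project_id IN ({qp})", project_ids)
        markers = sorted(code_name(db, r["primer_id"]) for r in rows)
    if sample_ids is None:
        rows = db.query(
            f"SELECT DISTINCT s.sample_id FROM samples s "
            f"JOIN dna_extraction d ON d.sample_id=s.sample_id "
            f"JOIN microsatellites m ON m.dna_id=d.dna_id "
            f"WHERE s.project_id IN ({qp}) ORDER BY s.sample_id", project_ids)
        sample_ids = [r["sample_id"] for r in rows]
    return MicrosatSelection(project_ids, markers, sample_ids, layout, file_format)


def _sample_label(db: Database, sample_id: int) -> str:
    org = db.one("SELECT organism_id FROM samples WHERE sample_id=?", (sample_id,))
    if org is None:
        raise NotFoundError(f"no sample {sample_id}")
    ext = db.one("SELECT external_id FROM transfer WHERE organism_id=? "
                 "ORDER BY transfer_id LIMIT 1", (org["organism_id"],))
    return ext["external_id"] if ext else f"sample{sample_id}"


def _genotype(db: Database, sample_id: int, primer_id: int) -> tuple[int | None, int | None]:
    row = db.one(
        "SELECT m.allele1, m.allele2 FROM microsatellites m "
        "JOIN dna_extraction d ON d.dna_id=m.dna_id "
        "WHERE d.sample_id=? AND m.primer_id=? ORDER BY m.msat_id LIMIT 1",
        (sample_id, primer_id))
    if row is None:
        return (None, None)
    return (row["allele1"], row["allele2"])


def microsat_matrix(db: Database, selection: MicrosatSelection
                    ) -> tuple[list[str], list[list[str]]]:
    """Header + rows in the selected layout; missing data written as "0"."""
    per2 = selection.layout == "two_column_diploid"
    haploid = selection.layout == "one_column_haploid"
    primer_ids = [get_code(db, "PRIMER", m).code_id for m in selection.markers]
    if not selection.sample_ids or not selection.markers:
        raise ExportError("empty selection")
    header = ["sample"]
    for m in selection.markers:
        header += [f"{m}_1", f"{m}_2"] if per2 else [m]
    rows: list[list[str]] = []
    for sid in selection.sample_ids:
        row = [_sample_label(db, sid)]
        for primer_id in primer_ids:
            a1, a2 = _genotype(db, sid, primer_id)
            if haploid and a2 is not None:
                raise ExportError(
                    f"sample {sid} has a diploid genotype; haploid layout refused")
            c1 = MISSING_ALLELE if a1 is None else str(a1)
            c2 = MISSING_ALLELE if a2 is None else str(a2)
            if per2:
                row += [c1, c2]
            elif haploid:
                row.append(c1)
            else:
                row.append(f"{c1}{ALLELE_SEPARATOR}{c2}")
        rows.append(row)
    return header, rows


def export_microsats(db: Database, selection: MicrosatSelection) -> str | bytes:
    """Matrix document; CSV text or XLSX bytes per the selection."""
    header, rows = microsat_matrix(db, selection)
    if selection.file_format == "csv":
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)
        return buf.getvalue()
    from openpyxl import Workbook
    wb = Workbook()
    ws = wb.active
    ws.title = "microsatellites"
    ws.append(header)
    for row in rows:
        ws.append(row)
    out = io.BytesIO()
    wb.save(out)
    return out.getvalue()
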