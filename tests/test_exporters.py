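import io
import random

import pytest
from Bio import AlignIO, SeqIO

from labtrace import ExportError, NotFoundError
from labtrace import exporters as ex
from labtrace import workflow as wf
from labtrace.registry import create_project, register_individual, register_sample

RECS = [("alpha", "ACGTACGTAC"), ("beta", "ACGTTTGTAC"), ("gamma", "ACG-ACGTAC")]


def parse_mega(text: str) -> dict[str, str]:
    """Independent minimal MEGA reader (#mega, then #name / sequence blocks)."""
    lines = [l.strip() for l in text.splitlines()]
    assert lines[0].lower() == "#mega"
    out: dict[str, list[str]] = {}
    current = None
    for line in lines[1:]:
        if line.startswith("!") or not line:
            continue
        if line.startswith("#"):
            current = line[1:]
            out[current] = []
        elif current:
            out[current].append(line)
    return {k: "".join(v) for k, v in out.items()}


def parse_psiblast(text: str) -> dict[str, str]:
    """Independent reader for the flat 'name sequence' alignment layout."""
    out = {}
    for line in text.splitlines():
        if line.strip():
            name, seq = line.split()
            out[name] = seq
    return out


class TestFormatRegistry:
    def test_seven_formats(self):
        assert len(ex.SEQUENCE_FORMATS) == 7
        assert set(ex.SEQUENCE_FORMATS) == {
            "fasta", "nexus", "phylip", "mega", "msf", "psi-blast", "pfam"}

    def test_three_layouts_two_file_formats(self):
        assert len(ex.MICROSAT_LAYOUTS) == 3
        assert len(ex.MICROSAT_FILE_FORMATS) == 2

    def test_unknown_format(self):
        with pytest.raises(ExportError):
            ex.write_sequences(RECS, "genbank")


class TestSequenceWriters:
    def test_nexus_header_arithmetic(self):
        text = ex.write_sequences(RECS, "nexus")
        assert "NTAX=3" in text and "NCHAR=10" in text

    def test_ragged_fasta_ok_phylip_refused_then_padded(self):
        ragged = [("a", "ACGT"), ("b", "ACGTAC")]
        ex.write_sequences(ragged, "fasta")
        with pytest.raises(ExportError, match="pad"):
            ex.write_sequences(ragged, "phylip")
        padded = ex.write_sequences(ragged, "phylip", pad=True)
        aln = AlignIO.read(io.StringIO(padded), "phylip")
        assert {str(r.seq) for r in aln} == {"ACGT--", "ACGTAC"}

    def test_empty_selection_refused(self):
        with pytest.raises(ExportError):
            ex.write_sequences([], "fasta")

    def test_duplicate_names_refused(self):
        with pytest.raises(ExportError):
            ex.write_sequences([("x", "AC"), ("x", "GT")], "fasta")

    @pytest.mark.parametrize("fmt,parser", [
        ("fasta", "fasta"), ("nexus", "nexus"), ("phylip", "phylip"),
        ("msf", "msf"), ("pfam", "stockholm")])
    def test_round_trip_independent_parser(self, fmt, parser):
        text = ex.write_sequences(RECS, fmt)
        if fmt == "fasta":
            back = {r.id: str(r.seq) for r in SeqIO.parse(io.StringIO(text), "fasta")}
        else:
            back = {r.id: str(r.seq)
                    for r in AlignIO.read(io.StringIO(text), parser)}
        assert back == dict(RECS)

    @pytest.mark.parametrize("fmt,parser", [
        ("mega", parse_mega), ("psi-blast", parse_psiblast)])
    def test_round_trip_hand_parser(self, fmt, parser):
        assert parser(ex.write_sequences(RECS, fmt)) == dict(RECS)

    def test_round_trip_random_sequences(self):
        rng = random.Random(17)
        recs = [(f"s{i}", "".join(rng.choices("ACGTN-", k=137)))
                for i in range(12)]
        for fmt, reader in [("nexus", "nexus"), ("msf", "msf"),
                            ("pfam", "stockholm")]:
            back = {r.id: str(r.seq) for r in AlignIO.read(
                io.StringIO(ex.write_sequences(recs, fmt)), reader)}
            assert {k: v.upper() for k, v in back.items()} == dict(recs)

    def test_deterministic(self):
        assert ex.write_sequences(RECS, "nexus") == ex.write_sequences(RECS, "nexus")


class TestPhylipNames:
    def test_truncation_with_unique_suffixes(self):
        names = ["verylongsamplename_A", "verylongsamplename_B", "short"]
        shorts, mapping = ex.phylip_names(names)
        assert len(set(shorts)) == 3
        assert all(len(s) <= 10 for s in shorts)
        assert set(mapping.values()) <= set(names)
        assert "short" not in mapping  # unchanged names are not reported


class TestConvertFasta:
    def test_two_records_to_mega(self):
        doc = ">a\nACGT\n>b\nAGGT\n"
        assert set(parse_mega(ex.convert_fasta(doc, "mega"))) == {"a", "b"}

    def test_duplicate_ids_refused(self):
        with pytest.raises(ExportError):
            ex.convert_fasta(">a\nAC\n>a\nGT\n", "fasta")

    def test_idempotent_on_canonical_form(self):
        doc = ">a\nACGTACGT\n>b\nAGGTAGGT\n"
        once = ex.convert_fasta(doc, "fasta")
        assert ex.convert_fasta(once, "fasta") == once

    def test_not_fasta(self):
        with pytest.raises(ExportError):
            ex.convert_fasta("LOCUS blah", "fasta")


@pytest.fixture()
def two_projects(seeded):
    db = seeded
    p1 = create_project(db, "PRJA", "sequencing")
    p2 = create_project(db, "PRJB", "sequencing")
    rng = random.Random(1)
    for pid, n, prefix in ((p1, 4, "A"), (p2, 6, "B")):
        dnas = []
        for i in range(n):
            org = register_individual(db, "tag", f"{prefix}{i}", "BOS")
            sid = register_sample(db, org, pid, "BLOOD")
            dnas.append(wf.extract_dna(db, [sid]))
        wf.setup_pcr(db, dnas, ["DLOOP"])
        fasta = "".join(f">{d}\n{''.join(rng.choices('ACGT', k=50))}\n"
                        for d in dnas)
        wf.import_sequences(db, fasta, "DLOOP", project_id=pid)
    return db, p1, p2


class TestMergeProjects:
    def test_union_across_projects(self, two_projects):
        db, p1, p2 = two_projects
        sel = ex.merge_project_sequences(db, "DLOOP", [p1, p2])
        assert len(sel.records) == 10
        # brute-force scan oracle
        assert len(db.query("SELECT * FROM sequences")) == 10

    def test_display_names(self, two_projects):
        db, p1, p2 = two_projects
        sel = ex.merge_project_sequences(db, "DLOOP", [p1])
        assert all(name.startswith("PRJA_A") for name, _ in sel.records)

    def test_collision_suffixing(self, two_projects):
        db, p1, p2 = two_projects
        # same external id in both projects under another id system
        org = register_individual(db, "tag2", "A0", "BOS")
        sid = register_sample(db, org, p2, "BLOOD")
        dna = wf.extract_dna(db, [sid])
        wf.setup_pcr(db, [dna], ["DLOOP"])
        wf.import_sequences(db, f">{dna}\nACGT\n", "DLOOP", project_id=p2)
        db.execute("UPDATE projects SET name='PRJA' WHERE project_id=?", (p2,))
        sel = ex.merge_project_sequences(db, "DLOOP", [p1, p2])
        names = [n for n, _ in sel.records]
        assert len(set(names)) == len(names)
        assert "PRJA_A0_1" in names and "PRJA_A0_2" in names

    def test_no_sequences_found(self, seeded):
        pid = create_project(seeded, "EMPTY", "sequencing")
        with pytest.raises(NotFoundError):
            ex.merge_project_sequences(seeded, "DLOOP", [pid])

    def test_export_is_read_only(self, two_projects):
        db, p1, p2 = two_projects
        before = db.digest()
        sel = ex.merge_project_sequences(db, "DLOOP", [p1, p2])
        for fmt in ex.SEQUENCE_FORMATS:
            ex.export_sequences(sel, fmt, pad=True)
        assert db.digest() == before


@pytest.fixture()
def genotyped(seeded):
    db = seeded
    pid = create_project(db, "MS", "genotyping")
    dnas, sids = [], []
    for i in range(2):
        org = register_individual(db, "tag", f"M{i}", "BOS")
        sid = register_sample(db, org, pid, "BLOOD")
        sids.append(sid)
        dnas.append(wf.extract_dna(db, [sid]))
    table = ("sample,BM1824_1,BM1824_2,ETH10_1,ETH10_2\n"
             f"{dnas[0]},100,104,200,202\n"
             f"{dnas[1]},102,102,0,0\n")
    wf.import_microsat_matrix(db, pid, table, ["BM1824", "ETH10"], "diploid")
    return db, pid, sids


class TestMicrosatExport:
    def test_two_column_diploid_shape(self, genotyped):
        db, pid, sids = genotyped
        out = ex.export_microsats(db, ex.MicrosatSelection(
            [pid], ["BM1824", "ETH10"], sids))
        lines = out.strip().splitlines()
        assert lines[0] == "sample,BM1824_1,BM1824_2,ETH10_1,ETH10_2"
        assert len(lines) == 3
        assert all(len(l.split(",")) == 5 for l in lines)

    def test_one_column_diploid_missing_encoding(self, genotyped):
        db, pid, sids = genotyped
        out = ex.export_microsats(db, ex.MicrosatSelection(
            [pid], ["BM1824", "ETH10"], sids, "one_column_diploid"))
        lines = out.strip().splitlines()
        assert lines[1].split(",") == ["M0", "100/104", "200/202"]
        assert lines[2].split(",") == ["M1", "102/102", "0/0"]

    def test_haploid_layout_on_diploid_refused(self, genotyped):
        db, pid, sids = genotyped
        with pytest.raises(ExportError, match="haploid"):
            ex.export_microsats(db, ex.MicrosatSelection(
                [pid], ["BM1824"], sids, "one_column_haploid"))

    def test_haploid_layout_on_haploid_data(self, seeded):
        db = seeded
        pid = create_project(db, "HAP", "genotyping")
        org = register_individual(db, "tag", "H0", "BOS")
        sid = register_sample(db, org, pid, "BLOOD")
        dna = wf.extract_dna(db, [sid])
        wf.import_microsat_matrix(db, pid, f"sample,BM1824\n{dna},123\n",
                                  ["BM1824"], "haploid")
        out = ex.export_microsats(db, ex.MicrosatSelection(
            [pid], ["BM1824"], [sid], "one_column_haploid"))
        assert out.strip().splitlines()[1] == "H0,123"

    def test_unknown_layout_refused(self):
        with pytest.raises(ExportError):
            ex.MicrosatSelection([1], ["M"], [1], "three_column")

    def test_xlsx_output(self, genotyped):
        db, pid, sids = genotyped
        blob = ex.export_microsats(db, ex.MicrosatSelection(
            [pid], ["BM1824"], sids, file_format="xlsx"))
        from openpyxl import load_workbook
        ws = load_workbook(io.BytesIO(blob)).active
        assert ws.cell(1, 1).value == "sample"
        assert str(ws.cell(2, 2).value) == "100"

    def test_count_matches_brute_force_tally(self, demo_db):
        db = demo_db
        projects = [r["project_id"] for r in db.query("SELECT project_id FROM projects")]
        sel = ex.build_microsat_selection(db, projects)
        out = ex.export_microsats(db, sel)
        non_missing = 0
        for line in out.strip().splitlines()[1:]:
            cells = line.split(",")[1:]
            for i in range(0, len(cells), 2):
                if cells[i] != "0" or cells[i + 1] != "0":
                    non_missing += 1
        # brute-force oracle: one exported genotype per (sample, marker) pair
        # with data (pooled extractions legitimately repeat per source sample)
        oracle = 0
        for sid in sel.sample_ids:
            for marker in sel.markers:
                hit = db.one(
                    "SELECT 1 FROM microsatellites m "
                    "JOIN dna_extraction d ON d.dna_id=m.dna_id "
                    "JOIN codes c ON c.code_id=m.primer_id "
                    "WHERE d.sample_id=? AND c.short_name=? LIMIT 1",
                    (sid, marker))
                if hit:
                    oracle += 1
        assert non_missing == oracle
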