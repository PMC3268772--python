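import hashlib
import io
import random

import pytest
from Bio import SeqIO

from labtrace import ImportError_, LimsError, NotFoundError, fetch_blob
from labtrace import workflow as wf
from labtrace.registry import create_project, register_individual, register_sample


@pytest.fixture()
def proj(seeded):
    return create_project(seeded, "WF", "sequencing")


def _samples(db, project, n, prefix="S"):
    out = []
    for i in range(n):
        org = register_individual(db, "tag", f"{prefix}{i}", "BOS")
        out.append(register_sample(db, org, project, "BLOOD", "VIAL", 1.0, "ml"))
    return out


class TestExtraction:
    def test_single_source(self, seeded, proj):
        (sid,) = _samples(seeded, proj, 1)
        dna = wf.extract_dna(seeded, [sid])
        assert wf.dna_sources(seeded, dna) == [sid]

    def test_pool_of_five(self, seeded, proj):
        sids = _samples(seeded, proj, 5)
        dna = wf.extract_dna(seeded, sids)
        assert wf.dna_sources(seeded, dna) == sorted(sids)

    def test_empty_sources_refused(self, seeded):
        with pytest.raises(LimsError):
            wf.extract_dna(seeded, [])

    def test_cross_project_pool_refused(self, seeded, proj):
        p2 = create_project(seeded, "Other", "genotyping")
        (a,) = _samples(seeded, proj, 1, "A")
        (b,) = _samples(seeded, p2, 1, "B")
        with pytest.raises(LimsError, match="same project"):
            wf.extract_dna(seeded, [a, b])


class TestPcr:
    def test_three_dnas_two_markers(self, seeded, proj):
        sids = _samples(seeded, proj, 3)
        dnas = [wf.extract_dna(seeded, [s]) for s in sids]
        pcr = wf.setup_pcr(seeded, dnas, ["DLOOP", "BM1824"])
        assert len(seeded.query(
            "SELECT * FROM amplified_samples WHERE pcr_id=?", (pcr,))) == 3
        assert len(wf.pcr_markers_of(seeded, pcr)) == 2

    def test_empty_marker_list_refused(self, seeded, proj):
        (sid,) = _samples(seeded, proj, 1)
        dna = wf.extract_dna(seeded, [sid])
        with pytest.raises(LimsError):
            wf.setup_pcr(seeded, [dna], [])

    def test_unknown_marker_code(self, seeded, proj):
        (sid,) = _samples(seeded, proj, 1)
        dna = wf.extract_dna(seeded, [sid])
        with pytest.raises(NotFoundError):
            wf.setup_pcr(seeded, [dna], ["NOT-A-MARKER"])

    def test_wells_auto_assigned_row_major(self, seeded, proj):
        sids = _samples(seeded, proj, 14)
        dnas = [wf.extract_dna(seeded, [s]) for s in sids]
        pcr = wf.setup_pcr(seeded, dnas, ["DLOOP"])
        wells = [r["well"] for r in seeded.query(
            "SELECT well FROM amplified_samples WHERE pcr_id=? "
            "ORDER BY amplified_id", (pcr,))]
        # independent re-derivation of the plate-order rule
        expect = [f"{'ABCDEFGH'[i // 12]}{i % 12 + 1}" for i in range(14)]
        assert wells == expect
        assert wells[:3] == ["A1", "A2", "A3"] and wells[12] == "B1"


class TestValidationAndElectrophoresis:
    def test_dna_validation_with_gel(self, seeded, proj):
        (sid,) = _samples(seeded, proj, 1)
        dna = wf.extract_dna(seeded, [sid])
        vid = wf.record_validation(seeded, ("dna", dna), "pass",
                                   gel_image=b"\x89PNGfake")
        gel = seeded.one("SELECT * FROM gel_images WHERE validation_id=?", (vid,))
        assert fetch_blob(seeded, gel["blob_id"]) == b"\x89PNGfake"

    def test_pcr_validation_without_image(self, seeded, proj):
        (sid,) = _samples(seeded, proj, 1)
        dna = wf.extract_dna(seeded, [sid])
        pcr = wf.setup_pcr(seeded, [dna], ["DLOOP"])
        vid = wf.record_validation(seeded, ("pcr", pcr), "pass")
        assert seeded.one("SELECT * FROM gel_images WHERE validation_id=?",
                          (vid,)) is None

    def test_invalid_result_refused(self, seeded, proj):
        (sid,) = _samples(seeded, proj, 1)
        dna = wf.extract_dna(seeded, [sid])
        with pytest.raises(Exception):
            wf.record_validation(seeded, ("dna", dna), "maybe")

    def test_electrophoresis_blob_round_trip(self, seeded, proj):
        rng = random.Random(3)
        (sid,) = _samples(seeded, proj, 1)
        dna = wf.extract_dna(seeded, [sid])
        pcr = wf.setup_pcr(seeded, [dna], ["DLOOP"])
        payloads = [rng.randbytes(rng.randint(1, 4096)) for _ in range(10)]
        run = wf.record_electrophoresis(seeded, pcr, "CAPILLARY", "m1",
                                        raw_files=payloads)
        blob_ids = wf.run_raw_blobs(seeded, run)
        assert len(blob_ids) == 10
        got = {hashlib.sha256(fetch_blob(seeded, b)).hexdigest() for b in blob_ids}
        assert got == {hashlib.sha256(p).hexdigest() for p in payloads}

    def test_zero_raw_files_allowed(self, seeded, proj):
        (sid,) = _samples(seeded, proj, 1)
        dna = wf.extract_dna(seeded, [sid])
        pcr = wf.setup_pcr(seeded, [dna], ["DLOOP"])
        run = wf.record_electrophoresis(seeded, pcr)
        assert wf.run_raw_blobs(seeded, run) == []


@pytest.fixture()
def amplified(seeded, proj):
    """3 samples, 3 single-source DNAs amplified for DLOOP."""
    sids = _samples(seeded, proj, 3)
    dnas = [wf.extract_dna(seeded, [s]) for s in sids]
    wf.setup_pcr(seeded, dnas, ["DLOOP"])
    return dnas


class TestSequenceImport:
    def test_three_records_resolve(self, seeded, proj, amplified):
        fasta = "".join(f">{d}\nACGTACGT\n" for d in amplified)
        ids = wf.import_sequences(seeded, fasta, "DLOOP", "SEQANALYZER",
                                  project_id=proj)
        assert len(ids) == 3
        row = seeded.one("SELECT * FROM sequences WHERE seq_id=?", (ids[0],))
        assert row["length"] == 8

    def test_external_id_resolution(self, seeded, proj, amplified):
        ids = wf.import_sequences(seeded, ">S0 extra words\nACGT\n", "DLOOP",
                                  project_id=proj)
        assert len(ids) == 1

    def test_unknown_identifier_aborts_all(self, seeded, proj, amplified):
        fasta = f">{amplified[0]}\nACGT\n>GHOST\nACGT\n"
        before = seeded.digest()
        with pytest.raises(ImportError_):
            wf.import_sequences(seeded, fasta, "DLOOP", project_id=proj)
        assert seeded.digest() == before
        assert seeded.one("SELECT COUNT(*) AS n FROM sequences")["n"] == 0

    def test_not_fasta_refused(self, seeded, proj):
        with pytest.raises(ImportError_):
            wf.import_sequences(seeded, "just some text", "DLOOP", project_id=proj)

    def test_non_iupac_bases_abort(self, seeded, proj, amplified):
        before = seeded.digest()
        with pytest.raises(Exception):
            wf.import_sequences(seeded, f">{amplified[0]}\nACGT!!\n",
                                "DLOOP", project_id=proj)
        assert seeded.digest() == before

    def test_round_trip_re_export(self, seeded, proj, amplified):
        rng = random.Random(9)
        seqs = ["".join(rng.choices("ACGTN", k=60)) for _ in amplified]
        fasta = "".join(f">{d}\n{s}\n" for d, s in zip(amplified, seqs))
        wf.import_sequences(seeded, fasta, "DLOOP", project_id=proj)
        from labtrace.exporters import export_sequences, merge_project_sequences
        out = export_sequences(
            merge_project_sequences(seeded, "DLOOP", [proj]), "fasta")
        back = sorted(str(r.seq) for r in SeqIO.parse(io.StringIO(out), "fasta"))
        assert back == sorted(seqs)

    def test_import_via_run(self, seeded, proj):
        sids = _samples(seeded, proj, 2)
        dnas = [wf.extract_dna(seeded, [s]) for s in sids]
        pcr = wf.setup_pcr(seeded, dnas, ["DLOOP"])
        run = wf.record_electrophoresis(seeded, pcr, "CAPILLARY")
        ids = wf.import_sequences(seeded, f">{dnas[0]}\nACGT\n", "DLOOP",
                                  run_id=run)
        row = seeded.one("SELECT pcr_id FROM sequences WHERE seq_id=?", (ids[0],))
        assert row["pcr_id"] == pcr


class TestMicrosatImport:
    @pytest.fixture()
    def gen(self, seeded):
        pid = create_project(seeded, "GEN", "genotyping")
        sids = _samples(seeded, pid, 134, "G")
        dnas = [wf.extract_dna(seeded, [s]) for s in sids]
        return pid, dnas

    def test_134_rows_two_markers_diploid(self, seeded, gen):
        pid, dnas = gen
        lines = ["sample,BM1824_1,BM1824_2,ETH10_1,ETH10_2"]
        lines += [f"{d},100,104,200,202" for d in dnas]
        ids = wf.import_microsat_matrix(seeded, pid, "\n".join(lines),
                                        ["BM1824", "ETH10"], "diploid")
        assert len(ids) == 268  # 134 rows x 2 markers

    def test_missing_cells_skipped(self, seeded, gen):
        pid, dnas = gen
        table = ("sample,BM1824_1,BM1824_2\n"
                 f"{dnas[0]},100,104\n"
                 f"{dnas[1]},0,0\n"
                 f"{dnas[2]},,\n")
        ids = wf.import_microsat_matrix(seeded, pid, table, ["BM1824"], "diploid")
        assert len(ids) == 1

    def test_haploid_with_two_columns_refused(self, seeded, gen):
        pid, dnas = gen
        table = f"sample,M_1,M_2\n{dnas[0]},100,104\n"
        with pytest.raises(ImportError_, match="columns"):
            wf.import_microsat_matrix(seeded, pid, table, ["BM1824"], "haploid")

    def test_unresolvable_row_key_atomic(self, seeded, gen):
        pid, dnas = gen
        table = f"sample,BM1824_1,BM1824_2\n{dnas[0]},100,104\nGHOST,1,2\n"
        before = seeded.digest()
        with pytest.raises(ImportError_):
            wf.import_microsat_matrix(seeded, pid, table, ["BM1824"], "diploid")
        assert seeded.digest() == before

    def test_duplicate_genotype_per_marker_refused(self, seeded, gen):
        pid, dnas = gen
        table = f"sample,BM1824_1,BM1824_2\n{dnas[0]},100,104\n"
        wf.import_microsat_matrix(seeded, pid, table, ["BM1824"], "diploid")
        with pytest.raises(Exception):
            wf.import_microsat_matrix(seeded, pid, table, ["BM1824"], "diploid")

    def test_round_trip_matrix(self, seeded, gen):
        pid, dnas = gen
        rows = ["sample,BM1824_1,BM1824_2,ETH10_1,ETH10_2"]
        rng = random.Random(5)
        expect = {}
        for d in dnas[:20]:
            g = [2 * rng.randint(50, 150) for _ in range(4)]
            if rng.random() < 0.2:
                g[2] = g[3] = 0
            rows.append(f"{d},{g[0]},{g[1]},{g[2]},{g[3]}")
            expect[d] = g
        wf.import_microsat_matrix(seeded, pid, "\n".join(rows),
                                  ["BM1824", "ETH10"], "diploid")
        from labtrace.exporters import MicrosatSelection, export_microsats
        sample_ids = [wf.dna_sources(seeded, d)[0] for d in dnas[:20]]
        out = export_microsats(seeded, MicrosatSelection(
            [pid], ["BM1824", "ETH10"], sample_ids, "two_column_diploid", "csv"))
        got_rows = out.strip().splitlines()[1:]
        for d, line in zip(dnas[:20], got_rows):
            cells = [int(c) for c in line.split(",")[1:]]
            assert cells == expect[d]


class TestStepPipelining:
    def test_prepare_samples_template_feeds_extract_dna(self, seeded, proj):
        _samples(seeded, proj, 10)
        sheet = wf.export_step_template(seeded, "prepare_samples", proj)
        assert sheet.splitlines()[0] == ",".join(wf.DNA_SHEET_COLUMNS)
        assert len(sheet.strip().splitlines()) == 11
        before = seeded.one("SELECT COUNT(DISTINCT dna_id) AS n "
                            "FROM dna_extraction")["n"]
        dna_ids = wf.import_dna_sheet(seeded, proj, sheet)
        assert len(dna_ids) == 10
        after = seeded.one("SELECT COUNT(DISTINCT dna_id) AS n "
                           "FROM dna_extraction")["n"]
        assert after - before == 10

    def test_empty_project_header_only(self, seeded, proj):
        sheet = wf.export_step_template(seeded, "prepare_samples", proj)
        assert sheet.strip() == ",".join(wf.DNA_SHEET_COLUMNS)

    def test_extract_dna_template_feeds_pcr(self, seeded, proj):
        _samples(seeded, proj, 4)
        wf.import_dna_sheet(seeded, proj,
                            wf.export_step_template(seeded, "prepare_samples", proj))
        sheet = wf.export_step_template(seeded, "extract_dna", proj)
        pcr = wf.import_pcr_sheet(seeded, sheet, ["DLOOP"])
        n = seeded.one("SELECT COUNT(*) AS n FROM amplified_samples "
                       "WHERE pcr_id=?", (pcr,))["n"]
        assert n == 4

    def test_dna_group_pooling(self, seeded, proj):
        _samples(seeded, proj, 3)
        sheet = ("dna_group,external_id,protocol,date,operator,concentration\n"
                 "G1,S0,,,,\nG1,S1,,,,\n,S2,,,,\n")
        dna_ids = wf.import_dna_sheet(seeded, proj, sheet)
        assert len(dna_ids) == 2
        sizes = sorted(len(wf.dna_sources(seeded, d)) for d in dna_ids)
        assert sizes == [1, 2]

    def test_unknown_step(self, seeded, proj):
        with pytest.raises(NotFoundError):
            wf.export_step_template(seeded, "sequence_stuff", proj)


class TestTraceabilityInvariant:
    def test_all_final_results_reach_samples(self, demo_db):
        db = demo_db
        for table in ("sequences", "microsatellites"):
            for r in db.query(f"SELECT * FROM {table}"):
                sources = wf.dna_sources(db, r["dna_id"])
                assert sources
                for sid in sources:
                    org = db.one("SELECT organism_id FROM samples WHERE sample_id=?",
                                 (sid,))
                    assert org is not None
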