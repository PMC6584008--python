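"""Hit-table readers/writers across dialects."""

import logging

import pytest
from openpyxl import Workbook

from barcodehits import hit_io
from barcodehits.adjudication import adjudicate_tables
from barcodehits.errors import ConfigError, ParseError
from barcodehits.synthetic_data import SimConfig, simulate_study
from barcodehits.taxonomy import Lineage

BLAST_LINE = "Q1\tKY123\t99.84\t614\t1\t0\t1\t614\t1\t614\t3e-52\t1130\tAus bus\n"


class TestBlastTabular:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST_LINE)
        [table] = hit_io.read_blast_tabular(p)
        rec = table.records[0]
        assert rec.percent_identity == 99.84
        assert rec.evalue == 3e-52
        assert rec.bitscore == 1130
        assert rec.align_length == 614
        assert rec.subject_label == "Aus bus"
        assert table.source_db == "genbank"

    def test_without_label_column_subject_id_is_label(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST_LINE.rsplit("\t", 1)[0] + "\n")
        [table] = hit_io.read_blast_tabular(p)
        assert table.records[0].subject_label == "KY123"

    def test_empty_file_yields_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert hit_io.read_blast_tabular(p) == []

    def test_truncation_to_max_hits(self, tmp_path):
        p = tmp_path / "hits.tsv"
        lines = []
        for i in range(15):
            cols = BLAST_LINE.rstrip("\n").split("\t")
            cols[1] = f"S{i}"
            lines.append("\t".join(cols))
        p.write_text("\n".join(lines) + "\n")
        [table] = hit_io.read_blast_tabular(p, max_hits=10)
        # truncation keeps the first 10 in file order
        assert [r.subject_id for r in table.records] == [f"S{i}" for i in range(10)]

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST_LINE + "Q2\tonly\tthree\n")
        with pytest.raises(ParseError, match=r":2"):
            hit_io.read_blast_tabular(p)

    def test_non_numeric_statistic_is_parse_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST_LINE.replace("99.84", "NA"))
        with pytest.raises(ParseError, match="NA"):
            hit_io.read_blast_tabular(p)

    def test_zero_evalue_allowed(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(BLAST_LINE.replace("3e-52", "0.0"))
        [table] = hit_io.read_blast_tabular(p)
        assert table.records[0].evalue == 0.0


BOLD_CSV = (
    "Query ID,Subject ID,Class,Order,Family,Genus,Species,Similarity\n"
    "Q1,B1,Agaricomycetes,Agaricales,Amanitaceae,Amanita,phalloides,99.1\n"
    "Q1,B2,Agaricomycetes,Agaricales,Amanitaceae,Amanita,,98.0\n"
)


class TestBoldResults:
    def test_label_assembled_from_rank_columns(self, tmp_path):
        p = tmp_path / "bold.csv"
        p.write_text(BOLD_CSV)
        [table] = hit_io.read_bold_results(p)
        assert table.source_db == "bold"
        assert table.records[0].subject_label == "Amanita phalloides"
        assert table.records[0].similarity == 99.1
        assert table.records[0].lineage.family == "Amanitaceae"
        # empty species column -> genus-only label, undetermined downstream
        assert table.records[1].subject_label == "Amanita"

    def test_similarity_out_of_bounds_rejected(self, tmp_path):
        p = tmp_path / "bold.csv"
        p.write_text(BOLD_CSV.replace("99.1", "101"))
        with pytest.raises(ParseError):
            hit_io.read_bold_results(p)

    def test_missing_mapped_column_is_config_error(self, tmp_path):
        p = tmp_path / "bold.csv"
        p.write_text(BOLD_CSV.replace("Similarity", "Sim%"))
        with pytest.raises(ConfigError, match="Similarity"):
            hit_io.read_bold_results(p)

    def test_blank_similarity_row_is_no_match(self, tmp_path):
        p = tmp_path / "bold.csv"
        p.write_text("Query ID,Subject ID,Class,Order,Family,Genus,Species,Similarity\n"
                     "Q9,,,,,,,\n")
        [table] = hit_io.read_bold_results(p)
        assert table.query_id == "Q9"
        assert len(table.records) == 0


class TestQueryFasta:
    def test_lengths_and_ids(self, tmp_path):
        p = tmp_path / "q.fasta"
        p.write_text(">Q1 some description\nACGT\n>Q2\nACGTACGT\n")
        assert hit_io.read_query_fasta(p) == {"Q1": 4, "Q2": 8}

    def test_gaps_not_counted(self, tmp_path):
        p = tmp_path / "q.fasta"
        p.write_text(">Q1\nAC-GT\n")
        assert hit_io.read_query_fasta(p) == {"Q1": 4}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "q.fasta"
        p.write_text(">Q1\nACGT\n>Q1\nACGT\n")
        with pytest.raises(ParseError, match="duplicate"):
            hit_io.read_query_fasta(p)

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "q.fasta"
        p.write_text(">Q1\n---\n")
        with pytest.raises(ParseError, match="empty"):
            hit_io.read_query_fasta(p)


def test_canonical_tsv_round_trip(tmp_path, rng):
    """Writing the canonical TSV and re-reading reproduces tables exactly."""
    cfg = SimConfig(seed=11, n_queries=12, n_classes=1, n_orders_per_class=2,
                    n_families_per_order=2, n_genera_per_family=2,
                    n_species_per_genus=3)
    _, _, _, tables, _ = simulate_study(cfg)
    tables.append(hit_io.HitTable(query_id="NOHIT", locus="COI",
                                  source_db="genbank", run_id="default"))
    path = tmp_path / "canon.tsv"
    hit_io.write_hit_tables(tables, path)
    back = hit_io.read_hit_tables(path)
    orig = {(t.query_id, t.locus, t.source_db, t.run_id): t for t in tables}
    assert len(back) == len(orig)
    for t in back:
        o = orig[(t.query_id, t.locus, t.source_db, t.run_id)]
        assert len(t.records) == len(o.records)
        for a, b in zip(t.records, o.records):
            assert (a.subject_id, a.subject_label) == (b.subject_id, b.subject_label)
            assert a.percent_identity == b.percent_identity
            assert a.evalue == b.evalue
            assert a.bitscore == b.bitscore
            assert a.similarity == b.similarity


def test_reader_equivalence_between_dialects(tmp_path):
    """The same hits via a BLAST file and a BOLD file adjudicate identically
    when the tie policy sees the shared similarity statistic."""
    hits = [  # (subject, genus, epithet, pct)
        ("S1", "Aus", "bus", 99.8), ("S2", "Aus", "bus", 99.8),
        ("S3", "Aus", "cus", 99.8), ("S4", "Dus", "eus", 95.0),
    ]
    blast = tmp_path / "g.tsv"
    with open(blast, "w") as fh:
        for sid, g, e, pct in hits:
            # bit score and e-value constant: ties ride on percent identity
            fh.write(f"Q1\t{sid}\t{pct}\t600\t1\t0\t1\t600\t1\t600\t1e-50\t1000\t{g} {e}\n")
    bold = tmp_path / "b.csv"
    with open(bold, "w") as fh:
        fh.write("Query ID,Subject ID,Class,Order,Family,Genus,Species,Similarity\n")
        for sid, g, e, pct in hits:
            fh.write(f"Q1,{sid},,,,{g},{e},{pct}\n")

    truth_path = tmp_path / "truth.tsv"
    truth_path.write_text(
        "specimen_id\tlocus\tclass\torder\tfamily\tgenus\tspecies\n"
        "Q1\t\tInsecta\tDiptera\tAusidae\tAus\tAus bus\n"
    )
    truth = hit_io.TruthTable.from_tsv(truth_path)
    cls_g, _ = adjudicate_tables(hit_io.read_blast_tabular(blast), truth)
    cls_b, _ = adjudicate_tables(hit_io.read_bold_results(bold), truth)
    assert cls_g[0].status == cls_b[0].status == "ambiguous_correct"
    assert cls_g[0].tie_count == cls_b[0].tie_count == 3
    assert cls_g[0].ambiguity_categories == cls_b[0].ambiguity_categories


class TestArchivedWorkbook:
    """Synthetic stand-in workbook exercising the sheet-dialect adapter."""

    @staticmethod
    def _workbook(tmp_path, n_queries=17):
        wb = Workbook()
        ws = wb.active
        ws.title = "insects_genbank_COI"
        ws.append(["Sample", "Accession", "Top hit", "Identity", "E-value", "Score"])
        for q in range(n_queries):
            for h in range(3):
                ws.append([f"INS{q:02d}", f"ACC{q}{h}", f"Gen{q} sp{h}",
                           99.0 - h, 1e-50 * (h + 1), 1000 - h])
        ws2 = wb.create_sheet("fungi_bold_ITS")
        ws2.append(["Sample", "Best match", "Similarity"])
        ws2.append(["FUN01", "Amanita phalloides", 99.1])
        wb.create_sheet("notes")  # deliberately unmapped
        path = tmp_path / "synthetic_archive.xlsx"
        wb.save(path)
        return path

    DIALECT = {
        "sheets": {
            "insects_genbank_COI": {
                "source_db": "genbank", "locus": "COI", "run_id": "megablast",
                "columns": {"query_id": "Sample", "subject_id": "Accession",
                            "subject_label": "Top hit", "pident": "Identity",
                            "evalue": "E-value", "bitscore": "Score"},
            },
            "fungi_bold_ITS": {
                "source_db": "bold", "locus": "ITS", "run_id": "ids",
                "columns": {"query_id": "Sample", "subject_label": "Best match",
                            "similarity": "Similarity"},
            },
        }
    }

    def test_mapped_sheets_yield_tables(self, tmp_path, caplog):
        path = self._workbook(tmp_path)
        with caplog.at_level(logging.WARNING):
            tables = hit_io.read_archived_outputs(path, self.DIALECT)
        per_sheet = {}
        for t in tables:
            per_sheet.setdefault(t.locus, []).append(t)
        assert len(per_sheet["COI"]) == 17  # one table per query block
        assert all(t.source_db == "genbank" for t in per_sheet["COI"])
        assert per_sheet["ITS"][0].records[0].similarity == 99.1
        assert any("notes" in r.message for r in caplog.records)

    def test_absent_sheet_is_config_error(self, tmp_path):
        path = self._workbook(tmp_path)
        bad = {"sheets": {"missing_sheet": {"source_db": "genbank", "columns": {}}}}
        with pytest.raises(ConfigError, match="missing_sheet"):
            hit_io.read_archived_outputs(path, bad)

    def test_statistics_mismatching_source_db_rejected(self, tmp_path):
        path = self._workbook(tmp_path)
        bad = {"sheets": {"fungi_bold_ITS": {
            "source_db": "bold",
            "columns": {"query_id": "Sample", "subject_label": "Best match",
                        "pident": "Similarity"},
        }}}
        with pytest.raises(ConfigError, match="inconsistent"):
            hit_io.read_archived_outputs(path, bad)

    def test_empty_mapping_yields_empty_list(self, tmp_path, caplog):
        path = self._workbook(tmp_path)
        with caplog.at_level(logging.WARNING):
            assert hit_io.read_archived_outputs(path, {"sheets": {}}) == []
        assert caplog.records  # every sheet warned as unmapped


def test_truth_table_lookup_with_locus_fallback(tmp_path):
    p = tmp_path / "truth.tsv"
    p.write_text(
        "specimen_id\tlocus\tclass\torder\tfamily\tgenus\tspecies\n"
        "SP1\tCOI\tInsecta\tDiptera\tAusidae\tAus\tAus bus\n"
        "SP2\t*\tInsecta\tDiptera\tAusidae\tAus\tAus cus\n"
    )
    truth = hit_io.TruthTable.from_tsv(p)
    assert truth.lookup("SP1", "COI").species == "Aus bus"
    assert truth.lookup("SP2", "anything").species == "Aus cus"
    assert truth.lookup("SP3") is None


def test_record_invariants_enforced():
    with pytest.raises(ParseError):
        hit_io.HitRecord(query_id="Q", subject_id="S", subject_label="Aus bus",
                         source_db="bold", similarity=101.0)
    with pytest.raises(ParseError):
        hit_io.HitRecord(query_id="Q", subject_id="S", subject_label="Aus bus",
                         source_db="genbank", evalue=-1.0)
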