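"""Gene-table IO: fixtures, dialects, chrom.sizes, BED, round-trips."""

import pytest

from mutamatch import (
    GeneRecord,
    RowParseError,
    SchemaError,
    classify_cohort,
    read_chrom_sizes,
    read_gene_table,
    read_telomere_bed,
    write_results_table,
)


class TestFixtureIntegrity:
    def test_table1_has_11_rows_with_printed_values(self, table1):
        assert len(table1) == 11
        first = table1[0]
        assert first.symbol == "CACNA1C"
        assert first.drug == "Amlodipine"
        assert first.chromosome == 12
        assert first.proximity == 1.9
        assert (first.a_pct, first.t_pct) == (23, 25)
        assert first.a_plus_t == 48
        assert first.fl_size == 13744

    def test_table2_has_20_rows(self, table2):
        assert len(table2) == 20
        symbols = [r.symbol for r in table2]
        # alias cells ("NK1R or TACR1", printed "S1PR11") resolve to the
        # official symbol
        assert "TACR1" in symbols and "S1PR1" in symbols
        assert symbols.count("GLP1R") == 2  # two drugs target the same gene

    @pytest.mark.parametrize(
        "symbol, proximity, a_plus_t, fl_size",
        [
            ("KCNH2", 8, 35, 4292),
            ("CACNA1B", 0.1, 43, 9792),
            ("KCNJ6", 9, 60, 19659),
            ("KCNK4", 71, 34, 1829),
        ],
    )
    def test_table1_spot_cells(self, table1, symbol, proximity, a_plus_t, fl_size):
        rec = next(r for r in table1 if r.symbol == symbol)
        assert rec.proximity == proximity
        assert rec.a_plus_t == a_plus_t
        assert rec.fl_size == fl_size

    def test_fixture_classes(self, table1, table2):
        assert {r.protein_class for r in table1} == {"ion_channel"}
        assert {r.protein_class for r in table2} == {"gpcr"}


class TestReadGeneTable:
    def test_empty_file_with_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("drug\tgene\tchr\tproximity_mb\tat_pct\tfl_size_bp\n")
        assert read_gene_table(path, dialect="generic") == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("drug\tgene\tproximity_mb\nA\tG1\t5\n")
        with pytest.raises(SchemaError, match="chr"):
            read_gene_table(path, dialect="generic")

    def test_unparseable_cell_reports_row_index(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "gene\tchr\tproximity_mb\tat_pct\n"
            "G1\t1\t5\t40\n"
            "G2\t2\tnot_a_number\t50\n"
        )
        with pytest.raises(RowParseError, match="row 1"):
            read_gene_table(path, dialect="generic")

    def test_x_chromosome_maps_to_23_and_keeps_label(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("gene\tchr\tproximity_mb\tat_pct\nG1\tX\t5\t40\n")
        (rec,) = read_gene_table(path, dialect="generic")
        assert rec.chromosome == 23
        assert rec.chrom_label == "X"

    def test_csv_delimiter_sniffed(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("gene,chr,proximity_mb,at_pct\nG1,4,12,61\n")
        (rec,) = read_gene_table(path)
        assert rec.proximity == 12 and rec.a_plus_t == 61


class TestGeneRecordInvariants:
    def test_at_sum_slack_allows_printed_rounding(self):
        # 16 + 19 prints as 35 in the reference table
        GeneRecord(symbol="KCNH2", chromosome=7, a_pct=16, t_pct=19, a_plus_t=35)

    def test_at_sum_beyond_slack_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GeneRecord(symbol="G", chromosome=1, a_pct=10, t_pct=10, a_plus_t=30)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chromosome": 0},
            {"chromosome": 24},
            {"chromosome": 1, "proximity": -1},
            {"chromosome": 1, "a_plus_t": 101},
            {"chromosome": 1, "fl_size": 0},
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneRecord(symbol="G", **kwargs)


class TestChromSizes:
    def test_bp_to_mb_and_name_normalization(self, chrom_sizes_file):
        cmap = read_chrom_sizes(chrom_sizes_file)
        assert cmap[7] == pytest.approx(159.35)
        assert cmap[23] == pytest.approx(156.04)
        assert 12 in cmap and 99 not in cmap

    def test_duplicate_chromosome_rejected(self, tmp_path):
        path = tmp_path / "dup.sizes"
        path.write_text("chr7\t100\n7\t200\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_chrom_sizes(path)

    def test_non_positive_length_rejected(self, tmp_path):
        path = tmp_path / "zero.sizes"
        path.write_text("chr7\t0\n")
        with pytest.raises(ValueError, match="non-positive"):
            read_chrom_sizes(path)


class TestTelomereBed:
    def test_bed3_parsed_to_mb_intervals(self, tmp_path):
        path = tmp_path / "telo.bed"
        path.write_text("chr1\t0\t10000\nchr1\t248946000\t248956422\nchrX\t0\t5000\n")
        telo = read_telomere_bed(path)
        assert telo[1][0] == (0.0, 0.01)
        assert 23 in telo

    def test_invalid_interval_rejected(self, tmp_path):
        path = tmp_path / "telo.bed"
        path.write_text("chr1\t500\t500\n")
        with pytest.raises(ValueError):
            read_telomere_bed(path)


class TestResultsRoundTrip:
    def test_write_read_reclassify_identical(self, table1, tmp_path):
        calls = classify_cohort(table1)
        out = tmp_path / "results.tsv"
        write_results_table(table1, calls, out)
        back = read_gene_table(out, dialect="generic")
        assert [r.symbol for r in back] == [r.symbol for r in table1]
        assert [r.proximity for r in back] == [r.proximity for r in table1]
        assert [r.a_plus_t for r in back] == [r.a_plus_t for r in table1]
        assert [r.fl_size for r in back] == [r.fl_size for r in table1]
        recalls = classify_cohort(back)
        assert [c.category for c in recalls] == [c.category for c in calls]

    def test_none_rows_are_exactly_kcnk4_gabrb3(self, table1, tmp_path):
        calls = classify_cohort(table1)
        out = tmp_path / "results.tsv"
        write_results_table(table1, calls, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 12  # header + 11 genes
        none_genes = {l.split("\t")[1] for l in lines[1:] if l.split("\t")[-1] == "NONE"}
        assert none_genes == {"KCNK4", "GABRB3"}

    def test_empty_record_list_gives_header_only(self, tmp_path):
        out = tmp_path / "empty.tsv"
        write_results_table([], [], out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("drug\tgene")
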