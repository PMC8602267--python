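"""Allele-label conventions, panel/genotype I/O and gene counting."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strlink.data_model import (
    AlleleLabel,
    EmptyGroupError,
    MarkerKind,
    ParseError,
    ValidationError,
    canonical_pair,
    count_alleles,
    format_str_offset,
    parse_str_offset,
    read_genotypes,
    read_marker_panel,
    write_genotypes,
)

from conftest import make_gt, make_panel


class TestAlleleLabels:
    @given(st.integers(min_value=-30, max_value=30))
    @settings(deadline=None)
    def test_str_offset_round_trip(self, offset):
        assert parse_str_offset(format_str_offset(offset)) == offset

    def test_reference_symbol_is_offset_zero(self):
        assert parse_str_offset("R") == 0
        assert format_str_offset(0) == "R"

    def test_unicode_minus_normalised(self):
        assert parse_str_offset("−4") == -4
        assert parse_str_offset("− 4") == -4

    def test_bare_integer_accepted_for_str(self):
        # published tables print "2" for two extra repeats
        assert AlleleLabel.parse("2", MarkerKind.STR).raw == "+2"

    def test_str_ordering_by_offset(self):
        labels = ["+2", "R", "-4", "-1"]
        ordered = sorted(AlleleLabel.parse(l, MarkerKind.STR) for l in labels)
        assert [l.raw for l in ordered] == ["-4", "-1", "R", "+2"]

    def test_snp_ordering_lexicographic(self):
        ordered = sorted(AlleleLabel.parse(b, MarkerKind.SNP) for b in "TGCA")
        assert [l.raw for l in ordered] == ["A", "C", "G", "T"]

    def test_invalid_labels_rejected(self):
        with pytest.raises(ParseError):
            AlleleLabel.parse("+2", MarkerKind.SNP)
        with pytest.raises(ParseError):
            AlleleLabel.parse("Q", MarkerKind.STR)


class TestMarkerPanel:
    def test_reads_str_row_with_position_and_repeats(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "name\tchrom\tpos\tkind\trepeat_unit\tref_repeat_count\n"
            "STR9\tchr15\t28245567\tSTR\tCA\t18\n"
        )
        panel = read_marker_panel(p)
        assert panel[0].pos == 28245567
        assert panel[0].ref_repeat_count == 18
        assert panel[0].repeat_unit == "CA"

    def test_empty_file_yields_empty_panel(self, tmp_path, caplog):
        p = tmp_path / "panel.tsv"
        p.write_text("name\tchrom\tpos\tkind\trepeat_unit\tref_repeat_count\n")
        assert read_marker_panel(p) == []

    def test_same_position_sorted_stably_by_name(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "name\tchrom\tpos\tkind\trepeat_unit\tref_repeat_count\n"
            "B\tchr15\t100\tSTR\tCA\t10\n"
            "A\tchr15\t100\tSTR\tCA\t10\n"
            "C\tchr15\t50\tSTR\tCA\t10\n"
        )
        panel = read_marker_panel(p)
        assert [m.name for m in panel] == ["C", "A", "B"]

    def test_duplicate_name_rejected_naming_marker(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "name\tchrom\tpos\tkind\trepeat_unit\tref_repeat_count\n"
            "X\tchr15\t100\tSTR\tCA\t10\n"
            "X\tchr15\t200\tSTR\tCA\t10\n"
        )
        with pytest.raises(ValidationError, match="X"):
            read_marker_panel(p)

    def test_non_integer_pos_reports_line(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "name\tchrom\tpos\tkind\trepeat_unit\tref_repeat_count\n"
            "X\tchr15\tabc\tSTR\tCA\t10\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_marker_panel(p)


class TestGenotypeIO:
    def test_pairs_stored_canonically(self, mini_panel):
        gt = make_gt(mini_panel, {"STRX": ["R/-4"]})
        assert gt.calls["STRX"][0] == ("-4", "R")

    def test_snp_heterozygote(self, mini_panel):
        gt = make_gt(mini_panel, {"rsX": ["T/C"]})
        assert gt.calls["rsX"][0] == ("C", "T")

    def test_missing_call_sample_retained(self, mini_panel, tmp_path):
        p = tmp_path / "gt.tsv"
        p.write_text(
            "sample_id\tpopulation\tSTRX_A1\tSTRX_A2\n"
            "s0\tpop\t.\t.\n"
            "s1\tpop\tR\t-4\n"
        )
        gt = read_genotypes(p, mini_panel)
        assert gt.n_samples == 2
        assert gt.calls["STRX"][0] is None
        assert gt.calls["STRX"][1] == ("-4", "R")

    def test_half_call_rejected(self, mini_panel, tmp_path):
        p = tmp_path / "gt.tsv"
        p.write_text("sample_id\tSTRX_A1\tSTRX_A2\ns0\tR\t.\n")
        with pytest.raises(ParseError, match="half-call"):
            read_genotypes(p, mini_panel)

    def test_missing_partner_column_rejected(self, mini_panel, tmp_path):
        p = tmp_path / "gt.tsv"
        p.write_text("sample_id\tSTRX_A1\ns0\tR\n")
        with pytest.raises(ParseError, match="STRX"):
            read_genotypes(p, mini_panel)

    def test_str_label_on_snp_rejected(self, mini_panel, tmp_path):
        p = tmp_path / "gt.tsv"
        p.write_text("sample_id\trsX_A1\trsX_A2\ns0\t+2\tC\n")
        with pytest.raises(ParseError, match="rsX"):
            read_genotypes(p, mini_panel)

    def test_write_read_round_trip(self, mini_panel, tmp_path):
        gt = make_gt(
            mini_panel,
            {
                "STRX": ["R/-4", None, "+2/+2"],
                "rsX": ["C/T", "T/T", None],
                "STRY": ["-1/R", "R/R", "-6/-4"],
            },
            groups=["blue", None, "brown"],
        )
        path = tmp_path / "gt.tsv"
        write_genotypes(gt, path)
        back = read_genotypes(path, mini_panel)
        assert back.calls == gt.calls
        assert list(back.samples["group"]) == ["blue", None, "brown"]

    def test_allele_merge_map(self, mini_panel):
        gt = make_gt(mini_panel, {"STRX": ["-8/R", "-8/-8", "-4/-8"]})
        merged = gt.merge_alleles({"STRX": {"-8": "R"}})
        assert merged.calls["STRX"] == [("R", "R"), ("R", "R"), ("-4", "R")]


class TestCountAlleles:
    def test_hand_count(self, mini_panel):
        gt = make_gt(
            mini_panel,
            {"STRX": ["R/R", "R/R", "R/R", "R/-4", "R/-4"]},
            groups=["A", "A", "A", "B", "B"],
        )
        table = count_alleles(gt, "STRX", ("A", "B"))
        assert table.col_labels == ["-4", "R"]
        assert table.counts.tolist() == [[0, 6], [2, 2]]

    def test_missing_sample_excluded_from_its_row_only(self, mini_panel):
        gt = make_gt(
            mini_panel,
            {"STRX": ["R/R", None, "R/-4"]},
            groups=["A", "A", "B"],
        )
        table = count_alleles(gt, "STRX", ("A", "B"))
        assert table.row_totals.tolist() == [2, 2]

    def test_row_totals_are_twice_nonmissing_samples(self, mini_panel):
        calls = ["R/R", "R/-4", None, "-4/-4", "R/+2", "+2/+2", None, "R/R", "-4/+2", "R/R"]
        groups = ["A", "A", "A", "A", "B", "B", "B", "B", "B", "B"]
        gt = make_gt(mini_panel, {"STRX": calls}, groups=groups)
        table = count_alleles(gt, "STRX", ("A", "B"))
        non_missing = {
            g: sum(1 for c, gg in zip(calls, groups) if gg == g and c is not None)
            for g in "AB"
        }
        assert table.row_totals.tolist() == [2 * non_missing["A"], 2 * non_missing["B"]]

    def test_empty_group_raises(self, mini_panel):
        gt = make_gt(mini_panel, {"STRX": ["R/R", None]}, groups=["A", "B"])
        with pytest.raises(EmptyGroupError):
            count_alleles(gt, "STRX", ("A", "B"))
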