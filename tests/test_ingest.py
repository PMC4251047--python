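"""Parsers, report accounting, and the small numeric helpers."""

from __future__ import annotations

import math
import random

import pytest

from triomics import (
    allelic_frequency,
    average_probe_values,
    inner_mate_distance,
    parse_cuffdiff_genes,
    parse_cuffdiff_isoforms,
    parse_probe_table,
    parse_variants,
)
from triomics.ingest import ProbeMeasurement, CUFFDIFF_COLUMNS
from conftest import write_tsv


VARIANT_HEADER = [
    "chrom", "pos", "ref", "alt", "gene", "effect", "codon_change",
    "aa_change", "tumor_dp", "tumor_af", "normal_dp", "normal_af",
]


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def test_preset_vcf_yields_the_hotspot_variants(preset_bundle, preset_graph):
    records, report = parse_variants(preset_bundle.vcf, preset_graph)
    assert report.rows_rejected == 0
    by_gene = {r.gene.symbol: r for r in records}
    kras = by_gene["KRAS"]
    assert kras.tumor_depth == 113
    assert round(kras.tumor_af * 100) == 14
    assert kras.aa_change == "G13D"
    assert kras.effect == "NON_SYNONYMOUS_CODING"
    assert kras.gene.entrez_id == 3845
    tp53 = by_gene["TP53"]
    assert tp53.tumor_depth == 82
    assert round(tp53.tumor_af * 100) == 95


def test_af_out_of_range_rejected_with_rule(tmp_path, tiny_graph):
    table = write_tsv(
        tmp_path / "v.tsv",
        VARIANT_HEADER,
        [
            ("chr1", 150, "A", "G", "GENE_A", "NS", "Aaa/Gaa", "K1E", 50, 0.5, 40, 0.0),
            ("chr1", 151, "A", "G", "GENE_A", "NS", "Aaa/Gaa", "K1E", 50, 150.0, 40, 0.0),
        ],
    )
    records, report = parse_variants(table, tiny_graph)
    assert len(records) == 1
    assert report.rows_rejected == 1
    assert "tumor_af" in report.rejections[0][1]


def test_percent_af_autodetected(tmp_path, tiny_graph):
    table = write_tsv(
        tmp_path / "v.tsv",
        VARIANT_HEADER,
        [("chr1", 150, "A", "G", "GENE_A", "NS", "", "", 100, 14.0, 90, 0.0)],
    )
    records, report = parse_variants(table, tiny_graph)
    assert records[0].tumor_af == pytest.approx(0.14)
    assert any("percent" in note for note in report.notes)


def test_empty_variant_file_with_header(tmp_path, tiny_graph):
    table = write_tsv(tmp_path / "v.tsv", VARIANT_HEADER, [])
    records, report = parse_variants(table, tiny_graph)
    assert records == []
    assert report.rows_read == 0


def test_negative_depth_rejected(tmp_path, tiny_graph):
    table = write_tsv(
        tmp_path / "v.tsv",
        VARIANT_HEADER,
        [("chr1", 150, "A", "G", "GENE_A", "NS", "", "", -5, 0.2, 40, 0.0)],
    )
    records, report = parse_variants(table, tiny_graph)
    assert records == []
    assert report.rows_rejected == 1


def test_multiallelic_vcf_row_split_per_alt(tmp_path, tiny_graph):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
        '##INFO=<ID=EFF,Number=1,Type=String,Description="e">\n'
        '##INFO=<ID=TDP,Number=1,Type=Integer,Description="d">\n'
        '##INFO=<ID=TAF,Number=1,Type=Float,Description="f">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t150\t.\tA\tG,T\t100\tPASS\tGENE=GENE_A;EFF=NS;TDP=60;TAF=0.3\n"
    )
    records, report = parse_variants(vcf, tiny_graph)
    assert [r.alt_allele for r in records] == ["G", "T"]
    assert report.rows_accepted == 2


# ---------------------------------------------------------------------------
# Cuffdiff tables
# ---------------------------------------------------------------------------


def test_preset_gene_diff_has_significant_kras_and_tp53(preset_bundle):
    records, report = parse_cuffdiff_genes(preset_bundle.gene_diff)
    assert report.rows_rejected == 0
    flagged = {r.gene.symbol for r in records if r.significant}
    assert flagged == {"KRAS", "TP53"}


def test_negative_fpkm_rejected(tmp_path):
    row = ["g1", "X1", "G1", "chr1:1-100", "n", "t", "OK",
           "-0.1", "5", "1.0", "0", "0.5", "0.6", "no"]
    table = write_tsv(tmp_path / "g.diff", CUFFDIFF_COLUMNS, [row])
    records, report = parse_cuffdiff_genes(table)
    assert records == []
    assert report.rows_rejected == 1


def test_missing_column_is_file_level_error(tmp_path):
    table = write_tsv(tmp_path / "g.diff", CUFFDIFF_COLUMNS[:-1], [])
    with pytest.raises(ValueError, match="missing Cuffdiff columns"):
        parse_cuffdiff_genes(table)


def test_infinite_fold_change_kept_as_signed_infinity(tmp_path):
    rows = [
        ["g1", "X1", "G1", "chr1:1-100", "n", "t", "OK", "0", "5", "inf", "0", "0.01", "0.02", "yes"],
        ["g2", "X2", "G2", "chr1:1-100", "n", "t", "OK", "5", "0", "-1.79769e+308", "0", "0.01", "0.02", "yes"],
    ]
    table = write_tsv(tmp_path / "g.diff", CUFFDIFF_COLUMNS, rows)
    records, _ = parse_cuffdiff_genes(table)
    assert records[0].log2_fold_change == math.inf
    assert records[1].log2_fold_change == -math.inf


def _random_gene_diff_rows(rng: random.Random, n: int):
    rows = []
    for i in range(n):
        v1 = round(rng.uniform(0, 500), 4)
        v2 = round(rng.uniform(0, 500), 4)
        p = round(rng.random(), 6)
        q = round(min(1.0, p * rng.uniform(1, 2)), 6)
        rows.append([
            f"g{i}", f"XLOC_{i}", f"GENE{i}", f"chr1:{100 * i + 1}-{100 * i + 90}",
            "n", "t", "OK", v1, v2, "0", "0", p, q,
            "yes" if rng.random() < 0.3 else "no",
        ])
    return rows


def test_gene_diff_roundtrip(tmp_path):
    """Write a random valid table, parse, re-serialize, parse again."""
    rng = random.Random(5)
    rows = _random_gene_diff_rows(rng, 30)
    table = write_tsv(tmp_path / "g.diff", CUFFDIFF_COLUMNS, rows)
    first, report = parse_cuffdiff_genes(table)
    assert report.rows_rejected == 0

    rewritten = [
        [r.gene.symbol, f"XLOC_{i}", r.gene.symbol, r.locus.display(), "n", "t", "OK",
         r.sample1_fpkm, r.sample2_fpkm, r.log2_fold_change, "0",
         r.p_value, r.q_value, "yes" if r.significant else "no"]
        for i, r in enumerate(first)
    ]
    table2 = write_tsv(tmp_path / "g2.diff", CUFFDIFF_COLUMNS, rewritten)
    second, _ = parse_cuffdiff_genes(table2)
    assert [
        (r.gene.symbol, r.sample1_fpkm, r.sample2_fpkm, r.p_value, r.q_value, r.significant)
        for r in first
    ] == [
        (r.gene.symbol, r.sample1_fpkm, r.sample2_fpkm, r.p_value, r.q_value, r.significant)
        for r in second
    ]


def test_isoform_novel_flag_follows_prefix(preset_bundle):
    records, report = parse_cuffdiff_isoforms(preset_bundle.isoform_diff)
    assert report.rows_rejected == 0
    by_id = {r.transcript_id: r for r in records}
    assert not by_id["ENST00000311936"].novel
    assert by_id["CUFF.19733.1"].novel
    assert by_id["ENST00000311936"].significant


def test_empty_transcript_id_rejected(tmp_path):
    row = ["", "X1", "G1", "chr1:1-100", "n", "t", "OK", "1", "2", "1", "0", "0.5", "0.6", "no"]
    table = write_tsv(tmp_path / "i.diff", CUFFDIFF_COLUMNS, [row])
    records, report = parse_cuffdiff_isoforms(table)
    assert records == []
    assert report.rows_rejected == 1


# ---------------------------------------------------------------------------
# probe tables
# ---------------------------------------------------------------------------


def test_probe_row_parsed(tmp_path):
    table = tmp_path / "p.tsv"
    table.write_text("GENE_A\t201_at\t6.25\n")
    records, report = parse_probe_table(table)
    assert records == [ProbeMeasurement("201_at", "GENE_A", 6.25)]
    assert report.rows_accepted == 1


def test_tab_and_comma_dialects_equivalent(tmp_path):
    tab = tmp_path / "p.tsv"
    tab.write_text("GENE_A\t201_at\t6.25\nGENE_B\t202_at\t7.5\n")
    comma = tmp_path / "p.csv"
    comma.write_text("GENE_A,201_at,6.25\nGENE_B,202_at,7.5\n")
    assert parse_probe_table(tab)[0] == parse_probe_table(comma)[0]


def test_nan_probe_value_rejected(tmp_path):
    table = tmp_path / "p.tsv"
    table.write_text("GENE_A\t201_at\tNaN\nGENE_A\t202_at\tbogus\n")
    records, report = parse_probe_table(table)
    assert records == []
    assert report.rows_rejected == 2


def test_duplicate_probe_rows_both_kept(tmp_path):
    table = tmp_path / "p.tsv"
    table.write_text("GENE_A\t201_at\t5.0\nGENE_A\t201_at\t7.0\n")
    records, _ = parse_probe_table(table)
    assert len(records) == 2
    assert average_probe_values(records) == 6.0


# ---------------------------------------------------------------------------
# numeric helpers
# ---------------------------------------------------------------------------


def test_allelic_frequency_basic():
    assert allelic_frequency(0, 100) == 0.0
    assert allelic_frequency(100, 100) == 1.0
    assert allelic_frequency(16, 113) == pytest.approx(16 / 113)


def test_displayed_percentages_identify_unique_alt_counts():
    """At the worked example's depths, exactly one integer alt count rounds
    to each displayed whole-percent allelic frequency."""
    matches_14 = [a for a in range(114) if round(a / 113 * 100) == 14]
    assert matches_14 == [16]
    matches_95 = [a for a in range(83) if round(a / 82 * 100) == 95]
    assert matches_95 == [78]


def test_allelic_frequency_domain_errors():
    with pytest.raises(ValueError):
        allelic_frequency(1, 0)
    with pytest.raises(ValueError):
        allelic_frequency(11, 10)


def test_allelic_frequency_monotone_and_bounded():
    depth = 57
    values = [allelic_frequency(a, depth) for a in range(depth + 1)]
    assert all(0.0 <= v <= 1.0 for v in values)
    assert values == sorted(values)


def test_inner_mate_distance_standard_library():
    assert inner_mate_distance(300, 350, 101) == (98, 148)
    assert inner_mate_distance(202, 202, 101) == (0, 0)


def test_inner_mate_distance_overlapping_mates_error():
    with pytest.raises(ValueError, match="overlapping mates"):
        inner_mate_distance(150, 200, 101)


def test_average_probe_values():
    def mk(values):
        return [ProbeMeasurement(f"p{i}_at", "G", v) for i, v in enumerate(values)]

    assert average_probe_values(mk([5.0, 7.0])) == 6.0
    assert average_probe_values(mk([4.2])) == 4.2
    assert average_probe_values(mk([1, 2, 3, 4])) == 2.5
    assert average_probe_values([]) is None
    mixed = [ProbeMeasurement("a_at", "G1", 1.0), ProbeMeasurement("b_at", "G2", 2.0)]
    with pytest.raises(ValueError):
        average_probe_values(mixed)


# ---------------------------------------------------------------------------
# fuzzing: corrupted rows land in the report, never in records
# ---------------------------------------------------------------------------


def test_fuzzed_corrupt_rows_always_accounted(tmp_path, tiny_graph):
    rng = random.Random(99)
    corrupt_cells = ["", "NaN", "-1", "1.5", "abc", "1e309", "yes maybe"]
    for trial in range(20):
        rows = []
        for i in range(10):
            if rng.random() < 0.5:
                rows.append(
                    ("chr1", 150, "A", "G", "GENE_A", "NS", "", "", 50, 0.5, 40, 0.0)
                )
            else:
                row = ["chr1", 150, "A", "G", "GENE_A", "NS", "", "", 50, 0.5, 40, 0.0]
                row[rng.randrange(8, 12)] = rng.choice(corrupt_cells)
                rows.append(tuple(row))
        table = write_tsv(tmp_path / f"f{trial}.tsv", VARIANT_HEADER, rows)
        records, report = parse_variants(table, tiny_graph)
        assert report.rows_read == report.rows_accepted + report.rows_rejected
        assert report.rows_read == len(rows)
        assert len(records) == report.rows_accepted
        for record in records:
            assert 0.0 <= record.tumor_af <= 1.0
            assert record.tumor_depth >= 0
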