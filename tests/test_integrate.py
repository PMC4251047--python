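"""Association, the integrated grid, group filtering and membership."""

from __future__ import annotations

from itertools import chain, combinations

import pytest

from triomics import parse_probe_table
from triomics.idmap import GeneIdentity, GenomicLocus, resolve_row_identity
from triomics.ingest import ProbeMeasurement, VariantRecord
from triomics.integrate import (
    CORE_COLUMNS,
    GeneGroup,
    MEMBER_COLUMN,
    associate,
    build_view,
    filter_by_group,
    member_list,
)


# ---------------------------------------------------------------------------
# associate
# ---------------------------------------------------------------------------


def test_probes_with_same_gene_group_under_one_key(tiny_graph):
    measurements = [
        ProbeMeasurement("201_at", "GENE_A", 5.0),
        ProbeMeasurement("202_at", "gene_a", 7.0),
    ]
    dataset = associate(measurements, tiny_graph, "microarray")
    assert len(dataset.records) == 1
    (key, recs), = dataset.records.items()
    assert key == "entrez:101"
    assert len(recs) == 2


def test_locus_only_variant_keyed_to_overlapping_gene(tiny_graph):
    locus = GenomicLocus("chr1", 250, 251)
    variant = VariantRecord(
        locus=locus, ref_allele="A", alt_allele="G", effect="NS",
        codon_change=None, aa_change=None, tumor_depth=10, tumor_af=0.5,
        normal_depth=None, normal_af=None,
        gene=resolve_row_identity(None, None, locus, tiny_graph),
    )
    dataset = associate([variant], tiny_graph, "wes")
    assert list(dataset.records) == ["entrez:202"]  # GENE_B


def test_unresolved_records_preserved_in_bucket(tiny_graph):
    measurements = [
        ProbeMeasurement("201_at", "GENE_A", 5.0),
        ProbeMeasurement("999_at", "NOSUCHGENE", 1.0),
    ]
    dataset = associate(measurements, tiny_graph, "microarray")
    assert dataset.record_count == 2
    assert sum(len(v) for v in dataset.unresolved.values()) == 1


def test_unknown_modality_rejected(tiny_graph):
    with pytest.raises(ValueError):
        associate([], tiny_graph, "proteomics")


# ---------------------------------------------------------------------------
# build_view
# ---------------------------------------------------------------------------


def _nonempty_subsets(items):
    return chain.from_iterable(combinations(items, k) for k in range(1, len(items) + 1))


def test_outer_join_gene_only_in_microarray_gets_empty_cells(preset_datasets, preset_graph):
    table = build_view(
        [preset_datasets["wes"], preset_datasets["rnaseq_gene"],
         preset_datasets["microarray"]],
        preset_graph,
    )
    gapdh = table.frame[table.frame["Gene Symbol"] == "GAPDH"].iloc[0]
    assert gapdh["Effect"] == ""
    assert gapdh["Avg Probe Values"] != ""
    assert gapdh["Sample 2 FPKM"] != ""


def test_column_block_order_invariant_across_modality_subsets(preset_datasets, preset_graph):
    """First three columns, block order and last column never change."""
    for subset in _nonempty_subsets(["wes", "rnaseq_gene", "microarray"]):
        table = build_view([preset_datasets[m] for m in subset], preset_graph)
        assert table.columns[:3] == CORE_COLUMNS
        assert table.columns[-1] == MEMBER_COLUMN
        block_names = [name for name, _c, _cols in table.column_blocks]
        expected = ["core"]
        for slot in ("wes", "rnaseq", "microarray"):
            if (slot == "rnaseq" and "rnaseq_gene" in subset) or slot in subset:
                expected.append(slot)
        expected.append("member")
        assert block_names == expected


def test_block_colors_are_fixed(preset_datasets, preset_graph):
    table = build_view(
        [preset_datasets["wes"], preset_datasets["rnaseq_gene"],
         preset_datasets["microarray"]],
        preset_graph,
    )
    colors = {name: color for name, color, _ in table.column_blocks}
    assert colors == {
        "core": "grey", "wes": "green", "rnaseq": "light red",
        "microarray": "blue", "member": "grey",
    }


def test_record_conservation_across_all_subsets(preset_datasets, preset_graph):
    """Every input record is represented in the view or in the unresolved
    summary; nothing is silently lost."""
    for subset in _nonempty_subsets(["wes", "rnaseq_gene", "microarray"]):
        datasets = [preset_datasets[m] for m in subset]
        table = build_view(datasets, preset_graph)
        keys_in_view = set(table.frame["_key"])
        for ds in datasets:
            represented = sum(
                len(recs) for key, recs in ds.records.items() if key in keys_in_view
            ) + sum(
                len(recs) for key, recs in ds.unresolved.items() if key in keys_in_view
            )
            assert represented == ds.record_count
            assert table.record_counts[ds.modality] == ds.record_count


def test_outer_join_symmetric_in_dataset_order(preset_datasets, preset_graph):
    a = build_view(
        [preset_datasets["wes"], preset_datasets["microarray"]], preset_graph
    )
    b = build_view(
        [preset_datasets["microarray"], preset_datasets["wes"]], preset_graph
    )
    assert set(a.frame["_key"]) == set(b.frame["_key"])
    assert a.columns == b.columns


def test_two_datasets_in_same_slot_error(preset_datasets, preset_graph):
    with pytest.raises(ValueError, match="slot"):
        build_view(
            [preset_datasets["rnaseq_gene"], preset_datasets["rnaseq_isoform"]],
            preset_graph,
        )


def test_isoform_view_emits_one_row_per_isoform(preset_datasets, preset_graph):
    table = build_view(
        [preset_datasets["wes"], preset_datasets["rnaseq_isoform"],
         preset_datasets["microarray"]],
        preset_graph,
    )
    tp53 = table.frame[table.frame["Gene Symbol"] == "TP53"]
    assert len(tp53) == 7
    # gene-level WES cells repeat on every isoform row
    assert set(tp53["AA Change"]) == {"C277F"}
    kras = table.frame[table.frame["Gene Symbol"] == "KRAS"]
    assert len(kras) == 3


def test_minimal_mode_restricts_to_grid_columns(preset_datasets, preset_graph):
    minimal = build_view([preset_datasets["wes"]], preset_graph, mode="minimal")
    maximal = build_view([preset_datasets["wes"]], preset_graph, mode="maximal")
    assert set(minimal.columns) < set(maximal.columns)
    assert "Ref" in maximal.columns and "Ref" not in minimal.columns


def test_rows_are_in_genomic_order(preset_datasets, preset_graph):
    table = build_view([preset_datasets["rnaseq_gene"]], preset_graph)
    keys = list(table.frame["Gene Symbol"])
    # chr1: ACTB(2000) KRAS(10000) NRAS(30000) MYC(44000);
    # chr2: GAPDH(1000) TP53(20000) BRAF(40000)
    assert keys == ["ACTB", "KRAS", "NRAS", "MYC", "GAPDH", "TP53", "BRAF"]


def test_group_restriction_at_build_time(preset_datasets, preset_graph, preset_config):
    group = GeneGroup("Key Genes", "default",
                      frozenset(preset_config.groups["Key Genes"]))
    table = build_view(
        [preset_datasets["wes"], preset_datasets["rnaseq_gene"],
         preset_datasets["microarray"]],
        preset_graph, group=group,
    )
    assert set(table.frame["Gene Symbol"]) == {"KRAS", "TP53", "NRAS", "BRAF", "MYC"}
    assert set(table.frame[MEMBER_COLUMN]) == {"Key Genes"}


def test_tsv_export_carries_block_header(preset_datasets, preset_graph, tmp_path):
    table = build_view([preset_datasets["microarray"]], preset_graph)
    out = tmp_path / "view.tsv"
    table.to_tsv(out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("#blocks: core=grey;")
    assert lines[1].split("\t")[:3] == CORE_COLUMNS


# ---------------------------------------------------------------------------
# filter_by_group / member_list
# ---------------------------------------------------------------------------


def test_filter_by_group_set_intersection(preset_datasets, preset_graph, preset_config):
    table = build_view([preset_datasets["rnaseq_gene"]], preset_graph)
    group = GeneGroup("Key Genes", "default",
                      frozenset(preset_config.groups["Key Genes"]))
    filtered = filter_by_group(table, group, preset_graph)
    assert len(filtered.frame) == 5
    assert set(filtered.frame["_key"]) <= set(table.frame["_key"])


def test_filter_with_absent_members_yields_zero_rows(preset_datasets, preset_graph):
    table = build_view([preset_datasets["rnaseq_gene"]], preset_graph)
    group = GeneGroup("ghosts", "default", frozenset({"NOT1", "NOT2"}))
    assert len(filter_by_group(table, group, preset_graph).frame) == 0


def test_filter_idempotent(preset_datasets, preset_graph, preset_config):
    table = build_view([preset_datasets["rnaseq_gene"]], preset_graph)
    group = GeneGroup("Key Genes", "default",
                      frozenset(preset_config.groups["Key Genes"]))
    once = filter_by_group(table, group, preset_graph)
    twice = filter_by_group(once, group, preset_graph)
    assert once.frame.equals(twice.frame)


def test_filter_matches_members_in_other_namespaces(preset_datasets, preset_graph):
    # members given as Entrez IDs; the table keys are also Entrez-canonical,
    # but resolution must go through the graph either way
    table = build_view([preset_datasets["rnaseq_gene"]], preset_graph)
    group = GeneGroup("by-id", "default", frozenset({"3845", "7157"}))
    filtered = filter_by_group(table, group, preset_graph)
    assert set(filtered.frame["Gene Symbol"]) == {"KRAS", "TP53"}


def test_member_list_sorted_and_converted(tiny_graph):
    gene = resolve_row_identity(None, "GENE_A", None, tiny_graph)
    groups = [
        GeneGroup("zeta", "u", frozenset({"101"})),      # entrez id
        GeneGroup("alpha", "u", frozenset({"GENE_A"})),  # symbol
        GeneGroup("other", "u", frozenset({"GENE_B"})),
    ]
    assert member_list(gene, groups, tiny_graph) == ["alpha", "zeta"]
    stranger = GeneIdentity(symbol="NOPE")
    assert member_list(stranger, groups, tiny_graph) == []
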