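"""Shared fixtures: the worked-example bundle and small hand-built graphs."""

from __future__ import annotations

import pytest

from triomics import build_graph, fixtures
from triomics.integrate import associate
import triomics


@pytest.fixture(scope="session")
def preset_config():
    return fixtures.paper_preset()


@pytest.fixture(scope="session")
def preset_bundle(preset_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return fixtures.generate(preset_config, out)


@pytest.fixture(scope="session")
def preset_graph(preset_bundle):
    return build_graph(preset_bundle.association_tables)


@pytest.fixture(scope="session")
def preset_datasets(preset_bundle, preset_graph):
    """All four modality datasets of the worked-example bundle."""
    variants, _ = triomics.parse_variants(preset_bundle.vcf, preset_graph)
    genes, _ = triomics.parse_cuffdiff_genes(preset_bundle.gene_diff)
    isoforms, _ = triomics.parse_cuffdiff_isoforms(preset_bundle.isoform_diff)
    probes, _ = triomics.parse_probe_table(preset_bundle.probe_table)
    return {
        "wes": associate(variants, preset_graph, "wes"),
        "rnaseq_gene": associate(genes, preset_graph, "rnaseq_gene"),
        "rnaseq_isoform": associate(isoforms, preset_graph, "rnaseq_isoform"),
        "microarray": associate(probes, preset_graph, "microarray"),
    }


def write_tsv(path, header, rows):
    lines = ["\t".join(header)]
    lines += ["\t".join(str(c) for c in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tiny_graph(tmp_path):
    """symbol GENE_A <-> entrez 101 <-> genbank ACC001, plus loci for A and B."""
    assoc = write_tsv(
        tmp_path / "assoc.tsv",
        ["id_a", "ns_a", "id_b", "ns_b"],
        [
            ("GENE_A", "symbol", "101", "entrez"),
            ("101", "entrez", "ACC001", "genbank"),
            ("GENE_B", "symbol", "202", "entrez"),
        ],
    )
    loci = write_tsv(
        tmp_path / "loci.tsv",
        ["gene_id", "chrom", "start", "end", "strand", "gene_name"],
        [
            ("GENE_A", "chr1", 100, 200, "+", "gene alpha"),
            ("GENE_B", "chr1", 200, 300, "-", "gene beta"),
        ],
    )
    return build_graph([assoc, loci])
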