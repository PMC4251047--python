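"""Deterministic synthetic multi-modality study generator.

Produces a coherent bundle of files — identifier association tables,
an annotated somatic VCF, RNA and DNA SAM alignments, Cuffdiff-style
gene and isoform differential-expression tables, a microarray probe
table, and the annotation seed tables — in exactly the formats the
ingest and concordance modules consume.  Read sets are constructed so
that a pileup at each variant position recovers the configured ref/alt
counts, and the same seed always yields a byte-identical bundle.

``paper_preset`` encodes the single-patient multiple-myeloma scenario
used as the package's worked example: a KRAS G13D hotspot call at 113x
tumor depth and 14% allelic frequency that is absent from 200x RNA
coverage (the mutation is not transcribed), a TP53 C277F call at 82x
and 95% that the RNA supports, KRAS's two annotated tumor-expressed
isoforms plus one novel assembly transcript, seven TP53 isoforms, and
a five-gene user group.  The genome is a tiny invented two-contig
reference; no real genome coordinates are embedded.
"""

from __future__ import annotations

import random
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

READ_LENGTH = 40
BASES = "ACGT"


@dataclass(frozen=True)
class IsoformSpec:
    transcript_id: str
    tumor_fpkm: float
    normal_fpkm: float
    p_value: float
    significant: bool

    @property
    def novel(self) -> bool:
        return self.transcript_id.startswith("CUFF.")


@dataclass(frozen=True)
class VariantSpec:
    """One somatic SNV with its DNA and RNA read-level evidence.

    ``pos`` is 0-based; tumor/normal counts parameterise the DNA
    alignment and VCF row, rna counts the RNA alignment.
    """

    gene: str
    pos: int
    ref: str
    alt: str
    effect: str
    codon_change: str
    aa_change: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    rna_depth: int
    rna_alt: int


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    entrez: int
    ensembl_gene: str
    genbank: str
    name: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    protein_length: int
    gene_fpkm: tuple[float, float, float, float, bool]  # normal, tumor, p, q, sig
    probes: tuple[tuple[str, float], ...] = ()
    isoforms: tuple[IsoformSpec, ...] = ()


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int
    contigs: dict[str, int]
    genes: tuple[GeneSpec, ...]
    variants: tuple[VariantSpec, ...]
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def validate(self) -> None:
        symbols = {g.symbol for g in self.genes}
        for gene in self.genes:
            if gene.chrom not in self.contigs:
                raise ValueError(f"gene {gene.symbol} on unknown contig {gene.chrom}")
            if gene.end > self.contigs[gene.chrom]:
                raise ValueError(f"gene {gene.symbol} extends past its contig")
        for variant in self.variants:
            if variant.gene not in symbols:
                raise ValueError(f"variant references undefined gene {variant.gene}")
            for label, alt, depth in (
                ("tumor", variant.tumor_alt, variant.tumor_depth),
                ("normal", variant.normal_alt, variant.normal_depth),
                ("rna", variant.rna_alt, variant.rna_depth),
            ):
                if not 0 <= alt <= depth:
                    raise ValueError(
                        f"{variant.gene} {label} alt reads {alt} exceed depth {depth}"
                    )
        for name, members in self.groups.items():
            unknown = set(members) - symbols
            if unknown:
                raise ValueError(f"group {name!r} names undefined genes {unknown}")


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of one generated study bundle."""

    out_dir: Path
    associations: Path
    loci: Path
    vcf: Path
    rna_sam: Path
    dna_sam: Path
    gene_diff: Path
    isoform_diff: Path
    probe_table: Path
    domain_table: Path
    canonical_table: Path
    drug_table: Path
    config: ScenarioConfig

    @property
    def association_tables(self) -> list[Path]:
        return [self.associations, self.loci]


def generate(config: ScenarioConfig, out_dir) -> FixtureBundle:
    """Write the full bundle; same config and seed → byte-identical files."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = {g.symbol: g for g in config.genes}

    bundle = FixtureBundle(
        out_dir=out,
        associations=out / "associations.tsv",
        loci=out / "loci.tsv",
        vcf=out / "somatic.vcf",
        rna_sam=out / "rna.sam",
        dna_sam=out / "dna.sam",
        gene_diff=out / "gene_exp.diff",
        isoform_diff=out / "isoform_exp.diff",
        probe_table=out / "probes.tsv",
        domain_table=out / "protein_domains.tsv",
        canonical_table=out / "canonical_mutations.tsv",
        drug_table=out / "drug_gene.tsv",
        config=config,
    )

    _write_associations(bundle.associations, config)
    _write_loci(bundle.loci, config)
    _write_vcf(bundle.vcf, config, genes)
    _write_sam(
        bundle.rna_sam,
        config,
        genes,
        prefix="rna",
        counts=lambda v: (v.rna_depth, v.rna_alt),
    )
    _write_sam(
        bundle.dna_sam,
        config,
        genes,
        prefix="dna",
        counts=lambda v: (v.tumor_depth, v.tumor_alt),
    )
    _write_gene_diff(bundle.gene_diff, config)
    _write_isoform_diff(bundle.isoform_diff, config)
    _write_probe_table(bundle.probe_table, config)
    for name, target in (
        ("protein_domains.tsv", bundle.domain_table),
        ("canonical_mutations.tsv", bundle.canonical_table),
        ("drug_gene.tsv", bundle.drug_table),
    ):
        source = resources.files("triomics").joinpath("data", name)
        shutil.copyfile(str(source), target)
    return bundle


# ---------------------------------------------------------------------------
# individual writers
# ---------------------------------------------------------------------------


def _write_associations(path: Path, config: ScenarioConfig) -> None:
    lines = ["id_a\tns_a\tid_b\tns_b"]
    for gene in config.genes:
        lines.append(f"{gene.symbol}\tsymbol\t{gene.entrez}\tentrez")
        # Ensembl reachable only via Entrez: exercises indirect conversion.
        lines.append(f"{gene.entrez}\tentrez\t{gene.ensembl_gene}\tensembl_gene")
        lines.append(f"{gene.symbol}\tsymbol\t{gene.genbank}\tgenbank")
        for probe_id, _value in gene.probes:
            lines.append(f"{gene.symbol}\tsymbol\t{probe_id}\taffy_probeset")
        for isoform in gene.isoforms:
            if not isoform.novel:
                lines.append(
                    f"{gene.ensembl_gene}\tensembl_gene\t"
                    f"{isoform.transcript_id}\tensembl_transcript"
                )
    path.write_text("\n".join(lines) + "\n")


def _write_loci(path: Path, config: ScenarioConfig) -> None:
    lines = ["gene_id\tchrom\tstart\tend\tstrand\tgene_name"]
    for gene in config.genes:
        lines.append(
            f"{gene.symbol}\t{gene.chrom}\t{gene.start}\t{gene.end}\t"
            f"{gene.strand}\t{gene.name}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_vcf(path: Path, config: ScenarioConfig, genes: dict[str, GeneSpec]) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=triomics-fixtures",
    ]
    for contig, length in config.contigs.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    for field_def in (
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=EFF,Number=1,Type=String,Description="SnpEff effect">',
        '##INFO=<ID=CODON,Number=1,Type=String,Description="Codon change">',
        '##INFO=<ID=AA,Number=1,Type=String,Description="Amino acid change">',
        '##INFO=<ID=TDP,Number=1,Type=Integer,Description="Tumor depth">',
        '##INFO=<ID=TAF,Number=1,Type=Float,Description="Tumor allelic frequency">',
        '##INFO=<ID=NDP,Number=1,Type=Integer,Description="Normal depth">',
        '##INFO=<ID=NAF,Number=1,Type=Float,Description="Normal allelic frequency">',
    ):
        lines.append(field_def)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for variant in sorted(config.variants, key=lambda v: (genes[v.gene].chrom, v.pos)):
        gene = genes[variant.gene]
        taf = variant.tumor_alt / variant.tumor_depth
        naf = (
            variant.normal_alt / variant.normal_depth
            if variant.normal_depth
            else 0.0
        )
        info = (
            f"GENE={variant.gene};EFF={variant.effect};CODON={variant.codon_change};"
            f"AA={variant.aa_change};TDP={variant.tumor_depth};TAF={taf:.4f};"
            f"NDP={variant.normal_depth};NAF={naf:.4f}"
        )
        lines.append(
            f"{gene.chrom}\t{variant.pos + 1}\t.\t{variant.ref}\t{variant.alt}\t"
            f"100\tPASS\t{info}"
        )
    path.write_text("\n".join(lines) + "\n")


def _random_base(rng: random.Random, exclude: str) -> str:
    choices = [b for b in BASES if b != exclude]
    return rng.choice(choices)


def _write_sam(
    path: Path,
    config: ScenarioConfig,
    genes: dict[str, GeneSpec],
    prefix: str,
    counts,
) -> None:
    """Reads of length READ_LENGTH, CIGAR match-only, covering each variant.

    The first ``alt`` reads at a locus carry the alternate base, the
    rest the reference base; start positions are staggered so the
    pileup is not a stack of identical alignments.
    """
    rng = random.Random(config.seed * 7919 + (1 if prefix == "rna" else 2))
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for contig, length in config.contigs.items():
        lines.append(f"@SQ\tSN:{contig}\tLN:{length}")
    for variant in sorted(config.variants, key=lambda v: (genes[v.gene].chrom, v.pos)):
        gene = genes[variant.gene]
        depth, alt_count = counts(variant)
        for i in range(depth):
            offset = 3 + (i * 7) % (READ_LENGTH - 6)  # variant inside the read
            start = variant.pos - offset  # 0-based
            seq = [rng.choice(BASES) for _ in range(READ_LENGTH)]
            seq[offset] = variant.alt if i < alt_count else variant.ref
            lines.append(
                "\t".join(
                    (
                        f"{prefix}.{variant.gene}.{i}",
                        "0",
                        gene.chrom,
                        str(start + 1),  # SAM is 1-based
                        "60",
                        f"{READ_LENGTH}M",
                        "*",
                        "0",
                        "0",
                        "".join(seq),
                        "I" * READ_LENGTH,
                    )
                )
            )
    path.write_text("\n".join(lines) + "\n")


_CUFFDIFF_HEADER = (
    "test_id\tgene_id\tgene\tlocus\tsample_1\tsample_2\tstatus\tvalue_1\t"
    "value_2\tlog2(fold_change)\ttest_stat\tp_value\tq_value\tsignificant"
)


def _log2fc(normal: float, tumor: float) -> str:
    import math

    if normal == 0 and tumor == 0:
        return "0"
    if normal == 0:
        return "inf"
    if tumor == 0:
        return "-inf"
    return f"{math.log2(tumor / normal):.6f}"


def _locus_display(gene: GeneSpec) -> str:
    return f"{gene.chrom}:{gene.start + 1}-{gene.end}"


def _write_gene_diff(path: Path, config: ScenarioConfig) -> None:
    lines = [_CUFFDIFF_HEADER]
    for gene in sorted(config.genes, key=lambda g: g.symbol):
        normal, tumor, p, q, significant = gene.gene_fpkm
        lines.append(
            "\t".join(
                (
                    gene.symbol,
                    gene.ensembl_gene,
                    gene.symbol,
                    _locus_display(gene),
                    "normal_pool",
                    "tumor",
                    "OK",
                    f"{normal:g}",
                    f"{tumor:g}",
                    _log2fc(normal, tumor),
                    "0",
                    f"{p:g}",
                    f"{q:g}",
                    "yes" if significant else "no",
                )
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_isoform_diff(path: Path, config: ScenarioConfig) -> None:
    lines = [_CUFFDIFF_HEADER]
    for gene in sorted(config.genes, key=lambda g: g.symbol):
        for isoform in gene.isoforms:
            lines.append(
                "\t".join(
                    (
                        isoform.transcript_id,
                        gene.ensembl_gene,
                        gene.symbol,
                        _locus_display(gene),
                        "normal_pool",
                        "tumor",
                        "OK",
                        f"{isoform.normal_fpkm:g}",
                        f"{isoform.tumor_fpkm:g}",
                        _log2fc(isoform.normal_fpkm, isoform.tumor_fpkm),
                        "0",
                        f"{isoform.p_value:g}",
                        f"{min(1.0, isoform.p_value * 2):g}",
                        "yes" if isoform.significant else "no",
                    )
                )
            )
    path.write_text("\n".join(lines) + "\n")


def _write_probe_table(path: Path, config: ScenarioConfig) -> None:
    lines = ["gene\tprobeID\tvalue"]
    for gene in sorted(config.genes, key=lambda g: g.symbol):
        for probe_id, value in gene.probes:
            lines.append(f"{gene.symbol}\t{probe_id}\t{value:g}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# the worked-example preset
# ---------------------------------------------------------------------------


def paper_preset(seed: int = 20140326) -> ScenarioConfig:
    """The single-patient KRAS/TP53 worked-example scenario.

    KRAS carries a non-synonymous G13D hotspot SNV (tumor depth 113,
    16 alt reads → 14% allelic frequency when displayed) with zero alt
    reads in 200x RNA coverage — transcribed evidence contradicts the
    DNA call.  TP53 carries C277F (depth 82, 78 alt reads → 95%) that
    the RNA supports at 90/100 reads.  KRAS has two annotated isoforms
    with non-zero tumor FPKM (only ENST00000311936 significant) plus
    the novel assembly transcript CUFF.19733.1 seen in the normal
    pool; TP53 has seven isoforms.  Both genes are significant in the
    gene-level differential table, TP53 strongly overexpressed in the
    tumor.  The loci live on an invented two-contig mini-genome.
    """
    kras_isoforms = (
        IsoformSpec("ENST00000311936", 75.0, 20.0, 0.0004, True),
        IsoformSpec("ENST00000556131", 8.6, 7.9, 0.41, False),
        IsoformSpec("CUFF.19733.1", 0.0, 5.2, 0.23, False),
    )
    tp53_isoforms = (
        IsoformSpec("ENST00000269305", 60.0, 5.0, 0.0003, True),
        IsoformSpec("ENST00000359597", 22.0, 2.1, 0.004, True),
        IsoformSpec("ENST00000413465", 11.0, 1.4, 0.02, False),
        IsoformSpec("ENST00000420246", 8.5, 0.9, 0.03, False),
        IsoformSpec("ENST00000445888", 7.2, 0.8, 0.06, False),
        IsoformSpec("ENST00000455263", 4.4, 0.5, 0.11, False),
        IsoformSpec("ENST00000504290", 2.3, 0.4, 0.19, False),
    )
    genes = (
        GeneSpec(
            "KRAS", 3845, "ENSG00000133703", "NM_033360",
            "Kirsten rat sarcoma viral oncogene homolog",
            "chr1", 10000, 15000, "-", 189,
            (30.0, 95.0, 0.0008, 0.004, True),
            probes=(("214352_s_at", 9.1), ("1559204_x_at", 8.4)),
            isoforms=kras_isoforms,
        ),
        GeneSpec(
            "TP53", 7157, "ENSG00000141510", "NM_000546",
            "tumor protein p53",
            "chr2", 20000, 28000, "-", 393,
            (10.0, 120.0, 5e-05, 0.0005, True),
            probes=(("201746_at", 10.2),),
            isoforms=tp53_isoforms,
        ),
        GeneSpec(
            "NRAS", 4893, "ENSG00000213281", "NM_002524",
            "NRAS proto-oncogene, GTPase",
            "chr1", 30000, 33000, "+", 189,
            (20.0, 22.0, 0.6, 0.8, False),
            probes=(("202647_s_at", 7.7),),
        ),
        GeneSpec(
            "BRAF", 673, "ENSG00000157764", "NM_004333",
            "B-Raf proto-oncogene, serine/threonine kinase",
            "chr2", 40000, 44000, "-", 766,
            (15.0, 14.0, 0.7, 0.85, False),
            probes=(("206044_s_at", 6.9),),
        ),
        GeneSpec(
            "MYC", 4609, "ENSG00000136997", "NM_002467",
            "MYC proto-oncogene, bHLH transcription factor",
            "chr1", 44000, 46000, "+", 439,
            (40.0, 55.0, 0.2, 0.4, False),
            probes=(("202431_s_at", 11.5),),
        ),
        GeneSpec(
            "GAPDH", 2597, "ENSG00000111640", "NM_002046",
            "glyceraldehyde-3-phosphate dehydrogenase",
            "chr2", 1000, 3000, "+", 335,
            (500.0, 480.0, 0.8, 0.9, False),
            probes=(("212581_x_at", 13.1),),
        ),
        GeneSpec(
            "ACTB", 60, "ENSG00000075624", "NM_001101",
            "actin beta",
            "chr1", 2000, 4000, "-", 375,
            (700.0, 690.0, 0.9, 0.95, False),
            probes=(("200801_x_at", 13.4),),
        ),
    )
    variants = (
        # KRAS codes from the reverse strand: the coding-strand G>A of
        # G13D appears as C>T on the genomic forward strand.
        VariantSpec(
            gene="KRAS", pos=10449, ref="C", alt="T",
            effect="NON_SYNONYMOUS_CODING", codon_change="gGt/gAt",
            aa_change="G13D",
            tumor_depth=113, tumor_alt=16,
            normal_depth=100, normal_alt=0,
            rna_depth=200, rna_alt=0,
        ),
        # TP53 also reverse-strand: coding G>T appears as genomic C>A.
        VariantSpec(
            gene="TP53", pos=21499, ref="C", alt="A",
            effect="NON_SYNONYMOUS_CODING", codon_change="tGc/tTc",
            aa_change="C277F",
            tumor_depth=82, tumor_alt=78,
            normal_depth=90, normal_alt=0,
            rna_depth=100, rna_alt=90,
        ),
    )
    return ScenarioConfig(
        seed=seed,
        contigs={"chr1": 50000, "chr2": 50000},
        genes=genes,
        variants=variants,
        groups={"Key Genes": ("KRAS", "TP53", "NRAS", "BRAF", "MYC")},
    )
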