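"""DNA→RNA variant-expression concordance.

A somatic SNV called from tumor DNA may or may not appear in the tumor
transcriptome: a mutation that is not transcribed will not reach the
protein, which matters when the mutant protein is the drug target.
This module counts ref/alt alleles in RNA-seq alignments at the DNA
variant position and classifies the variant as expressed-concordant,
not-expressed, or insufficiently covered.  The thresholds are explicit
library parameters (the judgement is often made visually in a browser;
here it must be reproducible) and are echoed into every output header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pysam

from .idmap import GenomicLocus
from .ingest import VariantRecord

Source = Union[str, Path]

_EXCLUDED_FLAGS = (
    pysam.FUNMAP | pysam.FSECONDARY | pysam.FSUPPLEMENTARY | pysam.FQCFAIL
)


@dataclass(frozen=True)
class PileupAlleleCount:
    """Allele tally at one genomic base from an alignment pileup."""

    locus: GenomicLocus
    ref_count: int
    alt_count: int
    other_count: int

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.other_count) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count

    @property
    def rna_af(self) -> float | None:
        return None if self.depth == 0 else self.alt_count / self.depth


@dataclass(frozen=True)
class ConcordanceThresholds:
    """Minimum evidence required to call a variant expressed in RNA."""

    min_rna_depth: int = 10
    min_alt_reads: int = 2
    min_rna_af: float = 0.01

    def __post_init__(self) -> None:
        if self.min_rna_depth < 0 or self.min_alt_reads < 0 or self.min_rna_af < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class ConcordanceCall:
    status: str  # expressed_concordant | not_expressed | insufficient_coverage | no_rna_data
    evidence: PileupAlleleCount | None
    dna_af: float


STATUSES = (
    "expressed_concordant",
    "not_expressed",
    "insufficient_coverage",
    "no_rna_data",
)


def count_alleles(
    alignments: Source,
    locus: GenomicLocus,
    ref: str,
    alt: str,
    min_base_quality: int = 13,
    min_mapping_quality: int = 0,
    exclude_duplicates: bool = True,
) -> PileupAlleleCount:
    """Count ref/alt/other bases at a single genomic position.

    Bases are compared on the genomic forward strand (SAM stores
    reverse-strand reads already forward).  Unmapped, secondary,
    supplementary and QC-fail reads are skipped, duplicate-marked reads
    optionally so; reads below the mapping- or base-quality cutoffs do
    not contribute.  A deletion or reference skip spanning the position
    counts toward ``other_count``.  Overlapping mates of one fragment
    are counted once (the mate with the higher base quality wins).
    """
    if len(locus) != 1:
        raise ValueError("count_alleles operates on a single-base locus")
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("ref and alt must be single bases (SNV only)")
    pos = locus.start
    ref = ref.upper()
    alt = alt.upper()

    excluded = _EXCLUDED_FLAGS | (pysam.FDUP if exclude_duplicates else 0)
    # one vote per fragment: name -> (category, base quality at the locus)
    fragment_vote: dict[str, tuple[str, int]] = {}
    with pysam.AlignmentFile(str(alignments), check_sq=False) as sam:
        if locus.chrom not in sam.references:
            raise ValueError(
                f"locus chromosome {locus.chrom!r} not in alignment references"
            )
        for read in sam.fetch(until_eof=True):
            if read.flag & excluded:
                continue
            if read.reference_name != locus.chrom:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            if not (read.reference_start <= pos < (read.reference_end or -1)):
                continue
            category, quality = _read_vote(read, pos, ref, alt, min_base_quality)
            if category is None:
                continue
            name = read.query_name or ""
            previous = fragment_vote.get(name)
            if previous is None or quality > previous[1]:
                fragment_vote[name] = (category, quality)

    tally = {"ref": 0, "alt": 0, "other": 0}
    for category, _quality in fragment_vote.values():
        tally[category] += 1
    return PileupAlleleCount(
        locus=locus,
        ref_count=tally["ref"],
        alt_count=tally["alt"],
        other_count=tally["other"],
    )


def _read_vote(
    read, pos: int, ref: str, alt: str, min_base_quality: int
) -> tuple[str | None, int]:
    """Classify one read's base at ``pos``; None means no usable vote."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=False):
        if rpos != pos:
            continue
        if qpos is None:
            # deletion or reference skip spanning the locus
            return "other", 0
        base = (read.query_sequence or "")[qpos].upper()
        qualities = read.query_qualities
        quality = qualities[qpos] if qualities is not None else 0
        if quality < min_base_quality:
            return None, 0
        if base == ref:
            return "ref", quality
        if base == alt:
            return "alt", quality
        return "other", quality
    return None, 0


def classify(
    variant: VariantRecord,
    rna: PileupAlleleCount | None,
    thresholds: ConcordanceThresholds = ConcordanceThresholds(),
) -> ConcordanceCall:
    """Classify whether a DNA variant is expressed in the RNA evidence.

    Exactly one status is assigned: ``no_rna_data`` when no RNA
    experiment was supplied, ``insufficient_coverage`` below the depth
    threshold, ``expressed_concordant`` when both the alt-read and
    allele-frequency thresholds are met, ``not_expressed`` otherwise.
    """
    if not variant.is_snv:
        raise ValueError("concordance classification is defined for SNVs only")
    if rna is None:
        return ConcordanceCall("no_rna_data", None, variant.tumor_af)
    if rna.locus.chrom != variant.locus.chrom or rna.locus.start != variant.locus.start:
        raise ValueError(
            f"RNA pileup locus {rna.locus.display()} does not match variant "
            f"locus {variant.locus.display()}"
        )
    if rna.depth < thresholds.min_rna_depth:
        return ConcordanceCall("insufficient_coverage", rna, variant.tumor_af)
    if (
        rna.alt_count >= thresholds.min_alt_reads
        and (rna.rna_af or 0.0) >= thresholds.min_rna_af
    ):
        return ConcordanceCall("expressed_concordant", rna, variant.tumor_af)
    return ConcordanceCall("not_expressed", rna, variant.tumor_af)


def concordance_table(
    variants: Sequence[VariantRecord],
    alignments: Source,
    thresholds: ConcordanceThresholds = ConcordanceThresholds(),
    min_base_quality: int = 13,
    min_mapping_quality: int = 0,
) -> list[tuple[VariantRecord, ConcordanceCall]]:
    """Run count_alleles + classify over every SNV in a variant list."""
    results = []
    for variant in variants:
        if not variant.is_snv:
            continue
        pileup = count_alleles(
            alignments,
            variant.locus,
            variant.ref_allele,
            variant.alt_allele,
            min_base_quality=min_base_quality,
            min_mapping_quality=min_mapping_quality,
        )
        results.append((variant, classify(variant, pileup, thresholds)))
    return results


def write_concordance_tsv(
    results: Sequence[tuple[VariantRecord, ConcordanceCall]],
    path: Source,
    thresholds: ConcordanceThresholds = ConcordanceThresholds(),
) -> None:
    """Serialize concordance calls; thresholds are echoed in the header."""
    with open(path, "w") as handle:
        handle.write(
            f"# thresholds: min_rna_depth={thresholds.min_rna_depth} "
            f"min_alt_reads={thresholds.min_alt_reads} "
            f"min_rna_af={thresholds.min_rna_af}\n"
        )
        handle.write(
            "chrom\tpos\tref\talt\tdna_af\trna_depth\trna_alt\trna_af\tstatus\n"
        )
        for variant, call in results:
            ev = call.evidence
            rna_af = "" if ev is None or ev.rna_af is None else f"{ev.rna_af:.4f}"
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        variant.locus.chrom,
                        variant.locus.start + 1,
                        variant.ref_allele,
                        variant.alt_allele,
                        f"{variant.tumor_af:.4f}",
                        "" if ev is None else ev.depth,
                        "" if ev is None else ev.alt_count,
                        rna_af,
                        call.status,
                    )
                )
                + "\n"
            )
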