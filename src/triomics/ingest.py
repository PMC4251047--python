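"""Typed parsing, cleaning and validation of the three modality families.

One parser per file family: SnpEff-annotated somatic variants (VCF or a
tab-delimited export mirroring the variant-grid columns), Cuffdiff
``gene_exp.diff`` / ``isoform_exp.diff`` tables, and three-column
microarray probe tables (``gene, probeID, value``).  Each parser gives
the generic text an explicit type, applies range and set-membership
checks, and returns accepted records together with an ImportReport that
enumerates every rejected row — rows_read always equals accepted plus
rejected.

Small numeric helpers that belong to these file families (allelic
frequency, paired-end inner-mate distance, probe averaging) live here
too.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import pysam

from .idmap import GeneIdentity, GenomicLocus, IdGraph, resolve_row_identity
from .report import ImportReport

Source = Union[str, Path]

#: Cuffdiff 2.x column names, in file order.
CUFFDIFF_COLUMNS = [
    "test_id",
    "gene_id",
    "gene",
    "locus",
    "sample_1",
    "sample_2",
    "status",
    "value_1",
    "value_2",
    "log2(fold_change)",
    "test_stat",
    "p_value",
    "q_value",
    "significant",
]

#: Cufflinks prints this sentinel (DBL_MAX) for infinite fold changes.
_CUFFLINKS_INF_SENTINEL = 1.7976e308

#: Prefix the assembler gives novel (unannotated) transcripts.
NOVEL_TRANSCRIPT_PREFIX = "CUFF."


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/InDel call with functional annotation."""

    locus: GenomicLocus
    ref_allele: str
    alt_allele: str
    effect: str
    codon_change: str | None
    aa_change: str | None
    tumor_depth: int
    tumor_af: float
    normal_depth: int | None
    normal_af: float | None
    gene: GeneIdentity

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_af <= 1.0:
            raise ValueError(f"tumor_af {self.tumor_af} outside [0, 1]")
        if self.tumor_depth < 0:
            raise ValueError(f"tumor_depth {self.tumor_depth} negative")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class ExpressionDiffRecord:
    """Cuffdiff gene-level differential-expression result.

    ``sample1_fpkm`` is the pooled-normal FPKM, ``sample2_fpkm`` the
    tumor FPKM; ``significant`` is the file's own yes/no call and is
    never recomputed here.
    """

    gene: GeneIdentity
    locus: GenomicLocus | None
    sample1_fpkm: float
    sample2_fpkm: float
    log2_fold_change: float
    p_value: float
    q_value: float
    significant: bool

    def __post_init__(self) -> None:
        for name in ("p_value", "q_value"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} {value} outside [0, 1]")
        _check_fpkm(self.sample1_fpkm, self.sample2_fpkm)


@dataclass(frozen=True)
class IsoformRecord:
    """Cuffdiff transcript-level result; novel iff CUFF-prefixed."""

    transcript_id: str
    gene: GeneIdentity
    sample1_fpkm: float
    sample2_fpkm: float
    p_value: float
    significant: bool
    novel: bool

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("empty transcript id")
        if self.novel != self.transcript_id.startswith(NOVEL_TRANSCRIPT_PREFIX):
            raise ValueError("novel flag inconsistent with transcript id prefix")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        _check_fpkm(self.sample1_fpkm, self.sample2_fpkm)


def _check_fpkm(*values: float) -> None:
    for value in values:
        if not (math.isfinite(value) and value >= 0):
            raise ValueError(f"FPKM must be finite and non-negative, got {value}")


@dataclass(frozen=True)
class ProbeMeasurement:
    """A single microarray probe-set signal attributed to a gene symbol."""

    probe_id: str
    gene_symbol: str
    value: float

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValueError("empty probe id")
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite probe value {self.value}")


# ---------------------------------------------------------------------------
# numeric helpers
# ---------------------------------------------------------------------------


def allelic_frequency(alt_count: int, depth: int) -> float:
    """Fraction of reads supporting the alternate allele."""
    if depth <= 0:
        raise ValueError("allelic frequency undefined at zero depth")
    if not 0 <= alt_count <= depth:
        raise ValueError(f"alt_count {alt_count} outside [0, {depth}]")
    return alt_count / depth


def inner_mate_distance(
    fragment_min: int, fragment_max: int, read_length: int
) -> tuple[int, int]:
    """Unsequenced gap between paired-end mates: fragment − 2·read length.

    With 300–350 bp libraries and 101 bp paired-end reads this yields
    the 98–148 bp range used to parameterise spliced alignment.
    """
    if fragment_min > fragment_max:
        raise ValueError("fragment_min exceeds fragment_max")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    lo = fragment_min - 2 * read_length
    hi = fragment_max - 2 * read_length
    if lo < 0:
        raise ValueError(
            f"overlapping mates: fragment {fragment_min} bp shorter than "
            f"two {read_length} bp reads"
        )
    return lo, hi


def average_probe_values(measurements: Sequence[ProbeMeasurement]) -> float | None:
    """Arithmetic mean signal over one gene's probe sets; None if empty."""
    if not measurements:
        return None
    genes = {m.gene_symbol.upper() for m in measurements}
    if len(genes) > 1:
        raise ValueError(f"measurements span multiple genes: {sorted(genes)}")
    return sum(m.value for m in measurements) / len(measurements)


# ---------------------------------------------------------------------------
# variant parsing
# ---------------------------------------------------------------------------

#: Tab-delimited variant export columns (the variant-grid column set).
VARIANT_TAB_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "codon_change",
    "aa_change",
    "tumor_dp",
    "tumor_af",
    "normal_dp",
    "normal_af",
]


def parse_variants(
    source: Source, graph: IdGraph
) -> tuple[list[VariantRecord], ImportReport]:
    """Parse annotated somatic variants from VCF or tab-delimited export.

    Format is auto-detected: a ``##fileformat=VCF`` header (or ``.vcf``
    extension) selects the VCF path; otherwise the tab-delimited layout
    is assumed.  Multi-allelic VCF rows are split into one record per
    alternate allele.  Allelic frequencies greater than 1 are treated as
    percentages and divided by 100; the detection is noted in the report.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if _looks_like_vcf(path):
        return _parse_variants_vcf(path, graph)
    return _parse_variants_tab(path, graph)


def _looks_like_vcf(path: Path) -> bool:
    if path.suffix.lower() == ".vcf":
        return True
    with open(path) as handle:
        first = handle.readline()
    return first.startswith("##fileformat=VCF")


def _coerce_af(raw: float, report: ImportReport, context: str) -> float:
    # Callers emit fractions but displays use percent; values in (1, 100]
    # are unambiguously percentages.
    if 1.0 < raw <= 100.0:
        report.note(f"{context}: allelic frequency {raw} interpreted as percent")
        return raw / 100.0
    return raw


def _parse_variants_vcf(
    path: Path, graph: IdGraph
) -> tuple[list[VariantRecord], ImportReport]:
    report = ImportReport()
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        contigs = set(vcf.header.contigs)
        for row in vcf:
            info = row.info
            for alt in row.alts or ():
                line_no = row.pos  # VCF rows are best identified by position
                try:
                    if contigs and row.chrom not in contigs:
                        raise ValueError(f"unknown chromosome {row.chrom!r}")
                    locus = GenomicLocus(
                        row.chrom, row.start, row.start + len(row.ref)
                    )
                    tumor_af = _coerce_af(
                        float(_info_scalar(info, "TAF")), report, f"{row.chrom}:{row.pos}"
                    )
                    tumor_depth = int(_info_scalar(info, "TDP"))
                    normal_depth = _optional_int(_info_scalar(info, "NDP", None))
                    normal_af = _optional_float(_info_scalar(info, "NAF", None))
                    gene_hint = _info_scalar(info, "GENE", None)
                    record = VariantRecord(
                        locus=locus,
                        ref_allele=row.ref,
                        alt_allele=str(alt),
                        effect=str(_info_scalar(info, "EFF", "")),
                        codon_change=_optional_str(_info_scalar(info, "CODON", None)),
                        aa_change=_optional_str(_info_scalar(info, "AA", None)),
                        tumor_depth=tumor_depth,
                        tumor_af=tumor_af,
                        normal_depth=normal_depth,
                        normal_af=normal_af,
                        gene=resolve_row_identity(
                            None, _optional_str(gene_hint), locus, graph
                        ),
                    )
                except (KeyError, TypeError, ValueError) as exc:
                    report.reject(line_no, str(exc))
                    continue
                records.append(record)
                report.accept()
    return records, report


def _info_scalar(info, key: str, default="__required__"):
    if key in info:
        value = info[key]
        if isinstance(value, tuple):
            value = value[0]
        return value
    if default == "__required__":
        raise KeyError(f"missing INFO field {key}")
    return default


def _optional_int(value) -> int | None:
    return None if value in (None, "", ".") else int(value)


def _optional_float(value) -> float | None:
    return None if value in (None, "", ".") else float(value)


def _optional_str(value) -> str | None:
    if value is None:
        return None
    text = str(value).strip()
    return text or None


def _parse_variants_tab(
    path: Path, graph: IdGraph
) -> tuple[list[VariantRecord], ImportReport]:
    report = ImportReport()
    records: list[VariantRecord] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(VARIANT_TAB_COLUMNS[:10]) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing variant columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                pos = int(row["pos"])  # 1-based in the export
                locus = GenomicLocus(
                    row["chrom"], pos - 1, pos - 1 + len(row["ref"])
                )
                tumor_af = _coerce_af(
                    float(row["tumor_af"]), report, f"line {line_no}"
                )
                record = VariantRecord(
                    locus=locus,
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    effect=row["effect"],
                    codon_change=_optional_str(row.get("codon_change")),
                    aa_change=_optional_str(row.get("aa_change")),
                    tumor_depth=int(row["tumor_dp"]),
                    tumor_af=tumor_af,
                    normal_depth=_optional_int(row.get("normal_dp")),
                    normal_af=_optional_float(row.get("normal_af")),
                    gene=resolve_row_identity(
                        None, _optional_str(row.get("gene")), locus, graph
                    ),
                )
            except (KeyError, TypeError, ValueError) as exc:
                report.reject(line_no, str(exc))
                continue
            records.append(record)
            report.accept()
    return records, report


# ---------------------------------------------------------------------------
# Cuffdiff tables
# ---------------------------------------------------------------------------


def _read_cuffdiff(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CUFFDIFF_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing Cuffdiff columns {sorted(missing)}")
    return frame


def _parse_log2fc(raw) -> float:
    """Map Cufflinks' textual/sentinel infinities onto IEEE infinities."""
    text = str(raw).strip().lower()
    if text in ("", "nan"):
        raise ValueError("missing log2 fold change")
    if text in ("inf", "+inf", "infinity"):
        return math.inf
    if text in ("-inf", "-infinity"):
        return -math.inf
    value = float(raw)
    if abs(value) >= _CUFFLINKS_INF_SENTINEL:
        return math.copysign(math.inf, value)
    return value


def _parse_locus_cell(raw: str) -> GenomicLocus | None:
    try:
        return GenomicLocus.from_display(raw)
    except (ValueError, AttributeError):
        return None


def _parse_significant(raw: str) -> bool:
    text = raw.strip().lower()
    if text not in ("yes", "no"):
        raise ValueError(f"significant column must be yes/no, got {raw!r}")
    return text == "yes"


def parse_cuffdiff_genes(
    source: Source,
) -> tuple[list[ExpressionDiffRecord], ImportReport]:
    """Parse a ``gene_exp.diff``-style table into typed records.

    Gene identities are stubs carrying the file's symbol and locus; the
    integrate stage resolves them against the association graph.
    """
    frame = _read_cuffdiff(Path(source))
    report = ImportReport()
    records: list[ExpressionDiffRecord] = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2
        try:
            locus = _parse_locus_cell(row["locus"])
            record = ExpressionDiffRecord(
                gene=GeneIdentity(symbol=str(row["gene"]).upper(), locus=locus),
                locus=locus,
                sample1_fpkm=float(row["value_1"]),
                sample2_fpkm=float(row["value_2"]),
                log2_fold_change=_parse_log2fc(row["log2(fold_change)"]),
                p_value=float(row["p_value"]),
                q_value=float(row["q_value"]),
                significant=_parse_significant(row["significant"]),
            )
        except (TypeError, ValueError) as exc:
            report.reject(line_no, str(exc))
            continue
        records.append(record)
        report.accept()
    return records, report


def parse_cuffdiff_isoforms(
    source: Source,
) -> tuple[list[IsoformRecord], ImportReport]:
    """Parse an ``isoform_exp.diff``-style table; CUFF.* ids are novel."""
    frame = _read_cuffdiff(Path(source))
    report = ImportReport()
    records: list[IsoformRecord] = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2
        try:
            transcript_id = str(row["test_id"]).strip()
            if not transcript_id or transcript_id == "nan":
                raise ValueError("empty transcript id")
            locus = _parse_locus_cell(row["locus"])
            record = IsoformRecord(
                transcript_id=transcript_id,
                gene=GeneIdentity(symbol=str(row["gene"]).upper(), locus=locus),
                sample1_fpkm=float(row["value_1"]),
                sample2_fpkm=float(row["value_2"]),
                p_value=float(row["p_value"]),
                significant=_parse_significant(row["significant"]),
                novel=transcript_id.startswith(NOVEL_TRANSCRIPT_PREFIX),
            )
        except (TypeError, ValueError) as exc:
            report.reject(line_no, str(exc))
            continue
        records.append(record)
        report.accept()
    return records, report


# ---------------------------------------------------------------------------
# microarray probe tables
# ---------------------------------------------------------------------------


def parse_probe_table(
    source: Source,
) -> tuple[list[ProbeMeasurement], ImportReport]:
    """Parse a ``gene, probeID, value`` table (tab- or comma-separated).

    Duplicate (gene, probe) rows are all kept; averaging happens at view
    time.  Non-numeric or non-finite values reject the row.
    """
    path = Path(source)
    report = ImportReport()
    records: list[ProbeMeasurement] = []
    with open(path) as handle:
        sample = handle.readline()
        delimiter = "\t" if sample.count("\t") >= sample.count(",") else ","
        handle.seek(0)
        reader = csv.reader(handle, delimiter=delimiter)
        for line_no, cells in enumerate(reader, start=1):
            if not cells or not "".join(cells).strip():
                continue
            if line_no == 1 and _is_probe_header(cells):
                continue
            if len(cells) != 3:
                report.reject(line_no, "wrong column count")
                continue
            gene, probe_id, raw_value = (c.strip() for c in cells)
            try:
                record = ProbeMeasurement(
                    probe_id=probe_id, gene_symbol=gene.upper(), value=float(raw_value)
                )
            except ValueError as exc:
                report.reject(line_no, str(exc))
                continue
            records.append(record)
            report.accept()
    return records, report


def _is_probe_header(cells: Iterable[str]) -> bool:
    lowered = [c.strip().lower() for c in cells]
    return lowered[:1] == ["gene"] or "probeid" in lowered or "probe_id" in lowered
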