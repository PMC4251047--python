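"""Protein/gene annotation products built on the integrated data.

Covers domain containment of amino-acid changes (protein coordinates
are 1-based inclusive, never mixed with genomic half-open coordinates),
lolliplot input data (observed mutations in red, canonical/previously
reported ones in blue, domains in green), FPKM chart data (per-gene bar
charts and per-isoform donut rings for tumor vs pooled normal), and
drug–gene interaction lookup with a deterministic DGIdb query URL.

Domain, canonical-mutation and drug tables ship as editable TSV files
under ``triomics/data`` and can be replaced per deployment.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

from .idmap import GeneIdentity
from .ingest import ExpressionDiffRecord, IsoformRecord, VariantRecord

Source = Union[str, Path]

LOLLIPLOT_COLORS = {"observed": "red", "canonical": "blue", "domain": "green"}

_AA_CHANGE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein domain, 1-based inclusive amino-acid interval."""

    protein_symbol: str
    domain_name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not 1 <= self.start_aa <= self.end_aa:
            raise ValueError(
                f"domain interval must satisfy 1 <= start <= end, got "
                f"{self.start_aa}-{self.end_aa}"
            )


def in_domain(aa_pos: int, domain: DomainAnnotation) -> bool:
    """True iff the amino-acid position lies in the domain (both ends in)."""
    if aa_pos < 1:
        raise ValueError("amino-acid positions are 1-based")
    return domain.start_aa <= aa_pos <= domain.end_aa


def parse_aa_change(aa_change: str) -> tuple[str, int, str]:
    """Split a single-letter substitution like ``G13D`` into (G, 13, D)."""
    m = _AA_CHANGE.match(aa_change.strip())
    if m is None:
        raise ValueError(f"cannot parse amino-acid change {aa_change!r}")
    ref_aa, pos, alt_aa = m.groups()
    return ref_aa, int(pos), alt_aa


@dataclass(frozen=True)
class LolliplotData:
    """Plot-ready mutation/domain layout for one protein."""

    protein_symbol: str
    protein_length: int
    observed: tuple[tuple[int, str, str], ...]  # (aa position, label, category)
    canonical: tuple[tuple[int, str, str], ...]
    domains: tuple[tuple[DomainAnnotation, str], ...]  # (domain, color)
    colors: dict = field(default_factory=lambda: dict(LOLLIPLOT_COLORS))

    def to_json(self) -> str:
        return json.dumps(
            {
                "protein": self.protein_symbol,
                "length": self.protein_length,
                "observed": [
                    {"pos": p, "label": l, "category": c, "color": self.colors["observed"]}
                    for p, l, c in self.observed
                ],
                "canonical": [
                    {"pos": p, "label": l, "category": c, "color": self.colors["canonical"]}
                    for p, l, c in self.canonical
                ],
                "domains": [
                    {
                        "name": d.domain_name,
                        "start": d.start_aa,
                        "end": d.end_aa,
                        "color": color,
                    }
                    for d, color in self.domains
                ],
            },
            indent=2,
        )


def lolliplot_data(
    variants: Sequence[VariantRecord],
    canonical: Sequence[tuple[int, str]],
    domains: Sequence[DomainAnnotation],
    protein_length: int,
    protein_symbol: str | None = None,
) -> LolliplotData:
    """Assemble lolliplot data for one gene's protein.

    Observed mutations come from the variants' amino-acid changes and
    are tagged red; canonical (previously reported) mutations blue;
    domains green.  A variant whose aa_change cannot be parsed is
    excluded with a warning; a parsed position beyond the protein
    length is an error naming the variant.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be positive")
    symbol = protein_symbol or next(
        (v.gene.symbol for v in variants if v.gene.symbol), "protein"
    )
    observed: list[tuple[int, str, str]] = []
    for variant in variants:
        if not variant.aa_change:
            warnings.warn(f"variant at {variant.locus.display()} has no aa_change")
            continue
        try:
            _ref, pos, _alt = parse_aa_change(variant.aa_change)
        except ValueError:
            warnings.warn(
                f"unparseable aa_change {variant.aa_change!r} at "
                f"{variant.locus.display()}; excluded from lolliplot"
            )
            continue
        if pos > protein_length:
            raise ValueError(
                f"variant {variant.aa_change} position {pos} exceeds protein "
                f"length {protein_length}"
            )
        observed.append((pos, variant.aa_change, "observed"))
    canonical_entries = []
    for pos, label in canonical:
        if not 1 <= pos <= protein_length:
            raise ValueError(
                f"canonical mutation {label} position {pos} outside protein"
            )
        canonical_entries.append((pos, label, "canonical"))
    for domain in domains:
        if domain.end_aa > protein_length:
            raise ValueError(
                f"domain {domain.domain_name} extends past protein length"
            )
    return LolliplotData(
        protein_symbol=symbol,
        protein_length=protein_length,
        observed=tuple(observed),
        canonical=tuple(canonical_entries),
        domains=tuple((d, LOLLIPLOT_COLORS["domain"]) for d in domains),
    )


# ---------------------------------------------------------------------------
# FPKM chart data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChartData:
    """Numeric series shaped for a generic plotting front end."""

    kind: str  # bar | donut
    series: tuple  # bar: ((gene, normal, tumor), ...); donut: per-ring dicts

    def to_json(self) -> str:
        if self.kind == "bar":
            rows = [
                {"gene": g, "normal_fpkm": n, "tumor_fpkm": t}
                for g, n, t in self.series
            ]
            return json.dumps({"kind": "bar", "groups": rows}, indent=2)
        return json.dumps({"kind": "donut", "rings": list(self.series)}, indent=2)


def chart_data(
    records: Sequence[Union[ExpressionDiffRecord, IsoformRecord]],
) -> ChartData:
    """Build the automated FPKM chart for Cuffdiff records.

    Gene-level records produce a grouped bar chart (pooled-normal vs
    tumor FPKM per gene); isoform records of a single gene produce a
    two-ring donut (tumor and normal rings, one segment per isoform).
    """
    if not records:
        raise ValueError("chart_data needs at least one record")
    if all(isinstance(r, ExpressionDiffRecord) for r in records):
        series = tuple(
            (r.gene.symbol or "?", r.sample1_fpkm, r.sample2_fpkm) for r in records
        )
        return ChartData(kind="bar", series=series)
    if all(isinstance(r, IsoformRecord) for r in records):
        genes = {r.gene.symbol for r in records}
        if len(genes) > 1:
            raise ValueError(
                f"donut charts cover one gene; got records for {sorted(map(str, genes))}"
            )
        ordered = sorted(records, key=lambda r: r.transcript_id)
        tumor_ring = {
            "ring": "tumor",
            "segments": [
                {"transcript": r.transcript_id, "fpkm": r.sample2_fpkm}
                for r in ordered
            ],
        }
        normal_ring = {
            "ring": "normal",
            "segments": [
                {"transcript": r.transcript_id, "fpkm": r.sample1_fpkm}
                for r in ordered
            ],
        }
        return ChartData(kind="donut", series=(tumor_ring, normal_ring))
    raise ValueError("chart_data records must be all gene-level or all isoform-level")


# ---------------------------------------------------------------------------
# drug-gene interactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugGeneInteraction:
    gene: str
    drug: str
    interaction_type: str
    source: str


class DrugGeneTable:
    """Local drug–gene interaction lookup loaded from TSV."""

    def __init__(self, interactions: Sequence[DrugGeneInteraction]):
        self._by_gene: dict[str, list[DrugGeneInteraction]] = {}
        for row in interactions:
            self._by_gene.setdefault(row.gene.upper(), []).append(row)

    @classmethod
    def from_tsv(cls, source: Source) -> "DrugGeneTable":
        rows = []
        with open(source) as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            for row in reader:
                rows.append(
                    DrugGeneInteraction(
                        gene=row["gene"].strip(),
                        drug=row["drug"].strip(),
                        interaction_type=row.get("interaction_type", "").strip(),
                        source=row.get("source", "").strip(),
                    )
                )
        return cls(rows)

    def lookup(self, gene: Union[GeneIdentity, str]) -> list[DrugGeneInteraction]:
        """Interactions for a gene under any of its resolvable identifiers."""
        symbols: list[str] = []
        if isinstance(gene, GeneIdentity):
            if gene.symbol:
                symbols.append(gene.symbol)
        else:
            symbols.append(str(gene))
        hits: list[DrugGeneInteraction] = []
        for symbol in symbols:
            hits.extend(self._by_gene.get(symbol.upper(), []))
        return hits


def drug_interactions(
    gene: Union[GeneIdentity, str], table: DrugGeneTable
) -> list[DrugGeneInteraction]:
    return table.lookup(gene)


def dgidb_url(genes: Sequence[Union[GeneIdentity, str]]) -> str:
    """Deterministic DGIdb query URL for a gene list (no network access)."""
    symbols = []
    for gene in genes:
        symbol = gene.symbol if isinstance(gene, GeneIdentity) else str(gene)
        if symbol:
            symbols.append(symbol.upper())
    joined = ",".join(sorted(set(symbols)))
    return f"https://dgidb.org/results?searchType=gene&searchTerms={joined}"


# ---------------------------------------------------------------------------
# bundled seed tables
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("triomics").joinpath("data", name))


def load_domain_table(source: Source | None = None) -> list[DomainAnnotation]:
    """Protein-domain seed table (``protein, domain, start_aa, end_aa``)."""
    path = Path(source) if source else _data_path("protein_domains.tsv")
    domains = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            domains.append(
                DomainAnnotation(
                    protein_symbol=row["protein"].strip().upper(),
                    domain_name=row["domain"].strip(),
                    start_aa=int(row["start_aa"]),
                    end_aa=int(row["end_aa"]),
                )
            )
    return domains


def load_canonical_mutations(
    source: Source | None = None,
) -> dict[str, list[tuple[int, str]]]:
    """Previously reported mutations per protein (``protein, aa_change``)."""
    path = Path(source) if source else _data_path("canonical_mutations.tsv")
    table: dict[str, list[tuple[int, str]]] = {}
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            label = row["aa_change"].strip()
            _ref, pos, _alt = parse_aa_change(label)
            table.setdefault(row["protein"].strip().upper(), []).append((pos, label))
    return table


def load_drug_table(source: Source | None = None) -> DrugGeneTable:
    path = Path(source) if source else _data_path("drug_gene.tsv")
    return DrugGeneTable.from_tsv(path)
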