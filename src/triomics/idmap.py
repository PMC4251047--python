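"""Gene-identifier association graph: the system's switching center.

Gene-centric datasets name genes in incompatible namespaces (Entrez IDs,
Ensembl gene/transcript IDs, GenBank accessions, HGNC-style symbols,
Affymetrix probe-set IDs) or only by genomic coordinates.  This module
holds an undirected association graph over tagged identifiers, loaded
from plain TSV tables, and converts between namespaces either directly
(one edge) or indirectly (any path through identifier nodes).  Genes
that carry a genomic locus are additionally indexed in per-chromosome
interval trees so a coordinate range can be mapped to genes.

Coordinate convention: all in-memory loci are 0-based half-open.
Display strings (and the IGV module) render 1-based inclusive.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

from intervaltree import IntervalTree

from .report import ImportReport


class Namespace(str, Enum):
    """Closed set of identifier namespaces known to the system."""

    entrez = "entrez"
    ensembl_gene = "ensembl_gene"
    ensembl_transcript = "ensembl_transcript"
    genbank = "genbank"
    symbol = "symbol"
    affy_probeset = "affy_probeset"
    locus = "locus"


#: Namespaces an input file's "Gene ID" column may carry, tried in order.
_GENE_ID_NAMESPACES = (
    Namespace.entrez,
    Namespace.ensembl_gene,
    Namespace.ensembl_transcript,
    Namespace.genbank,
)

_STRANDS = ("+", "-", "?")

_LOCUS_STRING = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class GenomicLocus:
    """Half-open genomic interval (0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @classmethod
    def from_display(cls, text: str, strand: str = "?") -> "GenomicLocus":
        """Parse a 1-based inclusive ``chr:start-end`` string."""
        m = _LOCUS_STRING.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse locus string {text!r}")
        start = int(m.group("start"))
        end = int(m.group("end"))
        if start < 1:
            raise ValueError(f"1-based locus start must be >= 1, got {start}")
        return cls(m.group("chrom"), start - 1, end, strand)

    def display(self) -> str:
        """Render 1-based inclusive, the genomics display convention."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def overlaps(self, other: "GenomicLocus") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneIdentity:
    """A gene with every namespace identifier reachable in the graph."""

    entrez_id: int | None = None
    ensembl_gene_id: str | None = None
    symbol: str | None = None
    gene_name: str | None = None
    genbank_accessions: frozenset[str] = frozenset()
    affy_probesets: frozenset[str] = frozenset()
    locus: GenomicLocus | None = None
    resolved: bool = False

    def __post_init__(self) -> None:
        if not any(
            (
                self.entrez_id is not None,
                self.ensembl_gene_id,
                self.symbol,
                self.genbank_accessions,
                self.affy_probesets,
                self.locus,
            )
        ):
            raise ValueError("GeneIdentity requires at least one identifier field")

    @property
    def canonical_key(self) -> str:
        """Deterministic merge key: Entrez first, matching the UI's first column."""
        if self.entrez_id is not None:
            return f"entrez:{self.entrez_id}"
        if self.ensembl_gene_id:
            return f"ensembl_gene:{self.ensembl_gene_id}"
        if self.symbol:
            return f"symbol:{self.symbol.upper()}"
        if self.locus is not None:
            return f"locus:{self.locus.display()}"
        if self.genbank_accessions:
            return f"genbank:{sorted(self.genbank_accessions)[0]}"
        return f"affy:{sorted(self.affy_probesets)[0]}"


Node = tuple[Namespace, str]


def _normalise(namespace: Namespace, identifier: str) -> str:
    # Symbols are upper-cased at load so source-case drift cannot split genes.
    identifier = identifier.strip()
    if namespace is Namespace.symbol:
        return identifier.upper()
    return identifier


class IdGraph:
    """Undirected identifier-association graph plus a locus interval index."""

    def __init__(self) -> None:
        self._adj: dict[Node, set[Node]] = {}
        self._loci: dict[Node, GenomicLocus] = {}
        self._names: dict[Node, str] = {}
        self._trees: dict[str, IntervalTree] = {}
        self.report = ImportReport()

    # -- construction -------------------------------------------------

    def add_edge(self, id_a: str, ns_a: Namespace, id_b: str, ns_b: Namespace) -> None:
        a = (ns_a, _normalise(ns_a, id_a))
        b = (ns_b, _normalise(ns_b, id_b))
        if a == b:
            return
        self._adj.setdefault(a, set()).add(b)
        self._adj.setdefault(b, set()).add(a)

    def add_locus(
        self,
        gene_id: str,
        namespace: Namespace,
        locus: GenomicLocus,
        gene_name: str | None = None,
    ) -> None:
        node = (namespace, _normalise(namespace, gene_id))
        self._adj.setdefault(node, set())
        self._loci[node] = locus
        if gene_name:
            self._names[node] = gene_name
        if len(locus) > 0:
            self._trees.setdefault(locus.chrom, IntervalTree()).addi(
                locus.start, locus.end, node
            )

    # -- inspection ---------------------------------------------------

    def __contains__(self, node: Node) -> bool:
        return node in self._adj

    @property
    def nodes(self) -> set[Node]:
        return set(self._adj)

    @property
    def edges(self) -> set[frozenset[Node]]:
        return {
            frozenset((a, b)) for a, nbrs in self._adj.items() for b in nbrs
        }

    def neighbors(self, node: Node) -> set[Node]:
        return set(self._adj.get(node, ()))

    def component(self, node: Node) -> set[Node]:
        """All identifier nodes reachable from ``node`` (visited-set BFS)."""
        if node not in self._adj:
            return set()
        seen = {node}
        queue = deque([node])
        while queue:
            for nbr in self._adj[queue.popleft()]:
                if nbr not in seen:
                    seen.add(nbr)
                    queue.append(nbr)
        return seen

    def identity_for(self, node: Node) -> GeneIdentity:
        """Assemble the full GeneIdentity of the gene containing ``node``."""
        component = self.component(node)
        if not component:
            raise KeyError(f"unknown identifier {node}")
        entrez: int | None = None
        ensembl: str | None = None
        symbol: str | None = None
        genbank: set[str] = set()
        probes: set[str] = set()
        locus: GenomicLocus | None = None
        name: str | None = None
        for ns, ident in sorted(component, key=lambda n: (n[0].value, n[1])):
            if ns is Namespace.entrez and entrez is None:
                entrez = int(ident)
            elif ns is Namespace.ensembl_gene and ensembl is None:
                ensembl = ident
            elif ns is Namespace.symbol and symbol is None:
                symbol = ident
            elif ns is Namespace.genbank:
                genbank.add(ident)
            elif ns is Namespace.affy_probeset:
                probes.add(ident)
            if (ns, ident) in self._loci and locus is None:
                locus = self._loci[(ns, ident)]
            if (ns, ident) in self._names and name is None:
                name = self._names[(ns, ident)]
        return GeneIdentity(
            entrez_id=entrez,
            ensembl_gene_id=ensembl,
            symbol=symbol,
            gene_name=name,
            genbank_accessions=frozenset(genbank),
            affy_probesets=frozenset(probes),
            locus=locus,
            resolved=True,
        )


Source = Union[str, Path]

_ASSOC_HEADER = ["id_a", "ns_a", "id_b", "ns_b"]
_LOCUS_HEADER = ["gene_id", "chrom", "start", "end", "strand"]


def build_graph(association_tables: Iterable[Source]) -> IdGraph:
    """Load association and locus TSV tables into one IdGraph.

    Two table shapes are accepted, distinguished by header: association
    tables (``id_a, ns_a, id_b, ns_b``) and locus tables
    (``gene_id, chrom, start, end, strand[, gene_name]``).  Malformed
    rows are rejected individually and recorded in ``graph.report``;
    duplicate association rows collapse to one edge, so the load is
    idempotent.
    """
    graph = IdGraph()
    for table in association_tables:
        path = Path(table)
        with open(path) as handle:
            header_line = handle.readline()
            if not header_line.strip():
                continue  # empty input -> empty graph contribution
            header = [c.strip() for c in header_line.rstrip("\n").split("\t")]
            if header[:4] == _ASSOC_HEADER:
                _load_association_rows(graph, handle)
            elif header[:5] == _LOCUS_HEADER:
                _load_locus_rows(graph, handle)
            else:
                raise ValueError(
                    f"{path}: unrecognised header {header!r}; expected "
                    f"{_ASSOC_HEADER} or {_LOCUS_HEADER}"
                )
    return graph


def _load_association_rows(graph: IdGraph, handle) -> None:
    for line_no, line in enumerate(handle, start=2):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.rstrip("\n").split("\t")]
        if len(cells) != 4:
            graph.report.reject(line_no, "wrong column count")
            continue
        id_a, ns_a, id_b, ns_b = cells
        try:
            namespace_a = Namespace(ns_a)
            namespace_b = Namespace(ns_b)
        except ValueError:
            graph.report.reject(line_no, f"unknown namespace in {ns_a!r}/{ns_b!r}")
            continue
        if Namespace.locus in (namespace_a, namespace_b):
            graph.report.reject(line_no, "locus rows belong in the locus table")
            continue
        if not id_a or not id_b:
            graph.report.reject(line_no, "empty identifier")
            continue
        graph.add_edge(id_a, namespace_a, id_b, namespace_b)
        graph.report.accept()


def _load_locus_rows(graph: IdGraph, handle) -> None:
    for line_no, line in enumerate(handle, start=2):
        if not line.strip():
            continue
        cells = [c.strip() for c in line.rstrip("\n").split("\t")]
        if len(cells) < 5:
            graph.report.reject(line_no, "wrong column count")
            continue
        gene_id, chrom, start, end, strand = cells[:5]
        name = cells[5] if len(cells) > 5 else None
        try:
            locus = GenomicLocus(chrom, int(start), int(end), strand)
        except ValueError as exc:
            graph.report.reject(line_no, f"bad locus: {exc}")
            continue
        graph.add_locus(gene_id, _guess_gene_id_namespace(gene_id), locus, name)
        graph.report.accept()


def _guess_gene_id_namespace(identifier: str) -> Namespace:
    if identifier.isdigit():
        return Namespace.entrez
    if identifier.startswith("ENSG"):
        return Namespace.ensembl_gene
    if identifier.startswith("ENST"):
        return Namespace.ensembl_transcript
    return Namespace.symbol


def convert(
    identifier: str, src: Namespace, dst: Namespace, graph: IdGraph
) -> set[str]:
    """Convert an identifier between namespaces, directly or indirectly.

    Returns every ``dst`` identifier reachable from ``(identifier, src)``
    through the association graph; the result is a set because probe
    sets and symbols are legitimately one-to-many.  An unknown source
    identifier yields the empty set.
    """
    if not isinstance(src, Namespace) or not isinstance(dst, Namespace):
        raise TypeError("src and dst must be Namespace members")
    if src is Namespace.locus:
        raise ValueError("use map_locus_to_genes for locus queries")
    node = (src, _normalise(src, identifier))
    return {ident for ns, ident in graph.component(node) if ns is dst}


def map_locus_to_genes(locus: GenomicLocus, graph: IdGraph) -> set[GeneIdentity]:
    """All genes whose stored locus overlaps the query (strand ignored)."""
    tree = graph._trees.get(locus.chrom)
    if tree is None:
        return set()
    hits = tree.overlap(locus.start, locus.end)
    return {graph.identity_for(hit.data) for hit in hits}


def resolve_row_identity(
    gene_id: str | None,
    symbol: str | None,
    locus: GenomicLocus | None,
    graph: IdGraph,
) -> GeneIdentity:
    """Resolve an input row to a gene: by ID, then symbol, then locus.

    The first key that resolves in the graph populates all reachable
    namespace fields; when nothing resolves a stub identity carrying
    only the supplied fields is returned with ``resolved=False``.
    """
    if gene_id is None and symbol is None and locus is None:
        raise ValueError("at least one of gene_id, symbol, locus is required")
    if gene_id is not None:
        for namespace in _GENE_ID_NAMESPACES:
            node = (namespace, _normalise(namespace, str(gene_id)))
            if node in graph:
                identity = graph.identity_for(node)
                if identity.locus is None and locus is not None:
                    identity = replace(identity, locus=locus)
                return identity
    if symbol:
        node = (Namespace.symbol, _normalise(Namespace.symbol, symbol))
        if node in graph:
            return graph.identity_for(node)
    if locus is not None:
        overlapping = map_locus_to_genes(locus, graph)
        if overlapping:
            # deterministic pick: the gene whose locus starts first
            return min(
                overlapping,
                key=lambda g: (g.locus.start if g.locus else 0, g.canonical_key),
            )
    stub_ns = _guess_gene_id_namespace(str(gene_id)) if gene_id is not None else None
    return GeneIdentity(
        entrez_id=int(gene_id) if stub_ns is Namespace.entrez else None,
        ensembl_gene_id=str(gene_id) if stub_ns is Namespace.ensembl_gene else None,
        symbol=symbol.upper() if symbol else None,
        genbank_accessions=(
            frozenset({str(gene_id)})
            if gene_id is not None
            and stub_ns not in (Namespace.entrez, Namespace.ensembl_gene)
            else frozenset()
        ),
        locus=locus,
        resolved=False,
    )
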