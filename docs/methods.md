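# Methods

## The integration model

The unit of integration is the *gene identity*: the set of all
identifiers (Entrez ID, Ensembl gene ID, symbol, GenBank accessions,
Affymetrix probe sets) connected to one another in an undirected
association graph, plus an optional genomic locus. Conversion between
namespaces is reachability in this graph: a direct edge or any path
through identifier nodes (visited-set BFS; path choice is irrelevant
because only the reachable set matters, and cycles are handled by the
visited set). One-to-many conversions return the full set — probe sets
and symbols are legitimately multi-mapped, and collapsing them silently
would lose data; callers decide policy. Symbols are upper-cased at load
so source-case drift cannot split a gene, but no fuzzy or alias
matching is attempted.

Input rows are resolved to identities with a fixed precedence — gene
ID, then symbol, then locus overlap — mirroring the three-column input
convention (ID if known, symbol if known, chromosome+locus if known).
A row that resolves through none of its keys becomes a *stub* identity
carrying only the supplied fields, flagged unresolved; it is kept,
keyed by its stub, and placed at the end of any view. Nothing is ever
dropped: every parser and every join preserves the accounting
`rows_read = rows_accepted + rows_rejected` and each accepted record is
represented in exactly one row of a built view.

Coordinates are 0-based half-open everywhere in memory; display
strings, Cuffdiff `locus` cells and IGV `goto` commands are 1-based
inclusive. Protein (amino-acid) coordinates are a separate 1-based
inclusive system and are never mixed with genomic arithmetic.

The integrated grid is a full outer join over gene keys: a gene present
in any selected modality yields a row with empty cells elsewhere. The
paper-of-record UI convention for such grids does not specify the join
type; outer was chosen so that single-modality genes remain visible,
and the choice is observable (empty cells) rather than silent. The join
key is Entrez-first (then Ensembl gene, then upper-cased symbol, then
locus string), matching the grid's leading column and giving a
deterministic merge. Rows are ordered genomically (chromosome, then
start), unresolved rows last, which keeps the view aligned with IGV
navigation. Column *blocks* are fixed — core (grey), WES (green),
RNA-seq (light red), microarray (blue), member list (grey) — and
travel as metadata strings; this library renders nothing.

## Concordance

A somatic SNV called from DNA is checked against RNA alignments by
counting, at the variant base, reads supporting the reference allele,
the alternate allele, or anything else (including deletions and
reference skips spanning the base). Unmapped, secondary, supplementary
and QC-fail reads are excluded; duplicate-marked reads are excluded by
default (configurable — DNA pipelines typically deduplicate upstream,
RNA practice varies); bases below the base-quality cutoff (default 13)
or reads below the mapping-quality cutoff do not contribute. Mates of
one fragment that both overlap the base are counted once, the
higher-quality base winning, because short-insert paired-end libraries
(inner-mate distance ≈ fragment − 2×read length) routinely overlap.
All allele comparisons use genomic forward-strand bases; the
reverse-strand appearance of a variant in a browser is a display
concern only.

The call is a total, exclusive partition: `no_rna_data` (no RNA
experiment), `insufficient_coverage` (depth < 10 by default),
`expressed_concordant` (≥ 2 alternate reads *and* ≥ 1% RNA allele
frequency), else `not_expressed`. The numeric thresholds are this
package's own explicit stand-ins for what is otherwise a visual
browser judgement; they are deliberately permissive, configurable on
the CLI, and echoed into every output header so a call can always be
traced to its criteria.

## Synthetic studies and what they show

The fixture generator writes a complete, mutually consistent bundle:
association and locus tables, an annotated VCF, RNA and DNA SAM files,
Cuffdiff-style gene and isoform tables, a probe table, and the
annotation seed tables. Reads are 40 bp, match-only CIGARs, staggered
across each variant position so that a pileup recovers exactly the
configured ref/alt counts; all randomness (base content) comes from the
single config seed, so a bundle is byte-identical across runs.

The worked-example preset encodes the single-patient scenario the
package is demonstrated on: KRAS G13D at tumor depth 113 with 16
alternate reads — 16 is the only integer count at depth 113 that
displays as the reported 14% — absent from 200× RNA coverage; TP53
C277F at depth 82 with 78 alternate reads (the unique count displaying
as 95%) supported by 90 of 100 RNA reads; KRAS with two annotated
isoforms at non-zero tumor FPKM (only ENST00000311936 significant) plus
the novel assembly transcript CUFF.19733.1 seen in the normal pool;
seven TP53 isoform rows; and a five-gene user group (KRAS, TP53, NRAS,
BRAF, MYC — the membership beyond KRAS/TP53 is an invented but
plausible choice, as is every locus: the genome is two invented 50 kb
contigs, not real genome coordinates). Gene-level FPKMs make KRAS and
TP53 significant, TP53 strongly tumor-overexpressed, with five
unremarkable background genes.

What passing tests on this bundle show: the parsing, association,
join, pileup and classification machinery is correct under clean,
perfectly consistent inputs at realistic per-locus depths. What they
do not show: robustness to real alignment artifacts (soft-clip-heavy
reads, multi-mappers, strand bias), real annotation-release
inconsistencies between identifier tables, microarray normalization
effects, or performance at transcriptome scale. The oracle-equivalence
suites (graph conversion vs. brute-force transitive closure, interval
lookup vs. linear scan, pileup vs. a hand-rolled CIGAR walker over
randomized reads including insertions, deletions and soft clips) cover
the primitive operations well beyond what the bundle itself exercises.

## Numerical and design details

- Cuffdiff's infinite log2 fold changes (`inf`, `-inf`, or the DBL_MAX
  sentinel ≈ 1.7977e308) are stored as IEEE signed infinities, never as
  finite numbers; missing/NaN fold changes reject the row. FPKMs must
  be finite and non-negative; p/q values in [0, 1]. The file's own
  `significant` yes/no column is authoritative — no FDR recomputation.
- Variant allelic frequencies greater than 1 (and ≤ 100) are
  interpreted as percentages and divided by 100; the auto-detection is
  recorded in the import report. Displayed frequencies are rounded to
  whole percent, matching the grid convention.
- Multi-allelic VCF rows split into one record per alternate allele.
- Probe-table duplicate (gene, probe) rows are both kept; averaging
  (arithmetic mean) happens at view time, so nothing is lost upstream.
- The association-table namespace of a bare gene ID is inferred: all
  digits → Entrez, `ENSG`/`ENST` prefixes → Ensembl, otherwise
  symbol/GenBank probing against the graph.
- The store is a single-file SQLite database; the import queue is
  synchronous FIFO (`process_next`/`run-queue`), which trades the
  original system's background scheduler for testability. Staging rows
  are retained when an import fails, for inspection. Cascade delete
  removes records, staging rows and jobs before the study row and is
  verified by a full referential orphan scan.
- Problem sizes throughout the default test run are small by design
  (tens of genes, hundreds of reads, ≤ 50-node random graphs, 100–200
  oracle trials), chosen as the smallest sizes that still exercise
  every code path and boundary.

## Known limitations

- InDel concordance is out of scope; classification is SNV-only.
- No liftover between genome builds, no live Ensembl/NCBI/DGIdb
  queries; identifier and drug tables are deployment inputs (seeded
  with small editable TSVs).
- Isoform-level lolliplot labelling follows the selected transcript;
  when one genomic SNV has different amino-acid labels per isoform,
  one transcript's label is plotted at a time.
- The IGV command vocabulary is the standard batch set
  (new/genome/load/goto/snapshot); exotic viewer commands are not
  modelled.
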