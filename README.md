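# triomics

Gene-level integration of whole-exome sequencing (WES) variant calls,
Cuffdiff RNA-seq differential expression, and legacy microarray probe
data — with identifier cross-mapping, DNA→RNA variant-expression
concordance, chart/lolliplot data generation, drug–gene linkage, and
IGV batch automation.

## Who this is for

Cancer genomics groups that hold years of microarray studies and are
now producing NGS data for the same disease. A tumor's mutational
landscape (WES) is necessary but often not sufficient: a DNA hotspot
mutation that is never transcribed will not reach the protein, and a
therapy targeting that mutant protein is then misdirected. Deciding
this requires putting the variant call, the transcriptome evidence,
and the historical expression data side by side, per gene — the
"triple integration" this package automates.

## What it does

- **Identifier switching center** (`triomics.idmap`): an undirected
  association graph over gene namespaces (Entrez, Ensembl gene and
  transcript, GenBank, symbol, Affymetrix probe set), loaded from TSV
  tables. Conversion is direct (one edge) or indirect (any path), and
  genes with genomic loci are interval-indexed so a coordinate range
  maps to genes. Internal coordinates are 0-based half-open; display
  strings are 1-based inclusive.
- **Typed ingestion** (`triomics.ingest`): parsers for SnpEff-annotated
  somatic variants (VCF or tab-delimited export), Cuffdiff
  `gene_exp.diff` / `isoform_exp.diff` tables, and `gene, probeID,
  value` microarray tables. Every row is explicitly typed and
  range-checked; rejected rows are enumerated in an `ImportReport`
  (`rows_read = rows_accepted + rows_rejected`, always).
- **Integration** (`triomics.integrate`): records are keyed by resolved
  gene identity and joined with a full outer join into an ordered grid
  whose column layout never changes — `Entrez ID, Gene Symbol, Gene
  Name` first, `Member List` last, WES (green), RNA-seq (light red) and
  microarray (blue) blocks in between. Isoform-level views emit one row
  per transcript. Gene groups filter any view.
- **Concordance** (`triomics.concordance`): counts ref/alt alleles in
  RNA alignments at each DNA variant position (quality filters,
  duplicate exclusion, fragment-level counting of overlapping mates)
  and classifies the variant as `expressed_concordant`,
  `not_expressed`, `insufficient_coverage`, or `no_rna_data` under
  explicit, configurable thresholds.
- **Annotation products** (`triomics.annotate`): protein-domain
  containment (1-based inclusive amino-acid coordinates), lolliplot
  data (observed mutations red, canonical blue, domains green), FPKM
  bar/donut chart data, and drug–gene interaction lookup with a
  deterministic DGIdb query URL.
- **IGV automation** (`triomics.igv`): builds and sends `new / genome /
  load / goto / snapshot` batch scripts over IGV's TCP command port
  (default 60151), so one call loads all tracks and jumps to a gene.
- **Store + CLI** (`triomics.store`, `triomics.cli`): a single-file
  SQLite study store with a synchronous FIFO import queue, staging and
  associated record tables, cascading delete, and a `triomics` command
  with `import`, `run-queue`, `list`, `view`, `concordance`,
  `igv-send`, `fixtures generate`, `delete`, and `groups` subcommands.
- **Synthetic studies** (`triomics.fixtures`): a deterministic
  generator for coherent multi-modality bundles on a tiny invented
  two-contig genome, including the worked-example preset below.

## Worked example

The `paper` preset emulates a single-patient multiple-myeloma study:
a KRAS G13D hotspot mutation and a TP53 C277F mutation, both called
from tumor DNA, with RNA-seq and microarray data for the same patient.

```sh
triomics fixtures generate --preset paper --out bundle/
cd bundle
triomics --db study.db --associations associations.tsv --associations loci.tsv \
    import patient1 wes 2014-03-26 somatic.vcf
triomics --db study.db --associations associations.tsv --associations loci.tsv \
    import patient1 rnaseq_gene 2014-03-26 gene_exp.diff
triomics --db study.db --associations associations.tsv --associations loci.tsv \
    import patient1 microarray 2014-03-26 probes.tsv
triomics --db study.db --associations associations.tsv --associations loci.tsv run-queue
triomics --db study.db --associations associations.tsv --associations loci.tsv \
    view patient1 --wes --rna --array --out view.tsv
triomics --db study.db --associations associations.tsv --associations loci.tsv \
    concordance somatic.vcf rna.sam --out concordance.tsv
```

The integrated view (`view.tsv`) contains, among its seven gene rows:

```
Entrez ID  Gene Symbol  ...  Tumor DP  Tumor AF  Sample 1 FPKM  Sample 2 FPKM  ...  Avg Probe Values
3845       KRAS              113       14%       30.0           95.0                8.75
7157       TP53              82        95%       10.0           120.0               10.2
```

KRAS was called at 113 reads of tumor depth with a 14% allelic
frequency; TP53 at 82 reads and 95%. The concordance command prints:

```
KRAS    G13D     not_expressed
TP53    C277F    expressed_concordant
```

i.e. 200 RNA reads cover the KRAS position with zero alternate-allele
reads — the DNA mutation is not transcribed and will not reach the
protein, which argues against a therapy targeting mutant KRAS — while
the TP53 mutation is supported by 90 of 100 RNA reads, strengthening
that finding.

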