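# Methods

## Isoform identity

An isoform is identified by its intron chain: chromosome, strand, and
the ordered list of intron intervals (the gaps between consecutive
exons), serialized canonically as `chrom:strand:s1-e1,s2-e2,...`. All
coordinates are 0-based half-open internally (genePred's native
convention); GTF's 1-based inclusive coordinates are converted at the
read/write boundary, so a transcript round-trips between the two formats
with exact integer equality. Chains match exactly or not at all — there
is no ±n bp splice-site fuzz window; fuzzy collapsing is the job of the
upstream per-sample collapser, and adding a second, cross-sample fuzz
layer would make identity depend on ingestion history.

This identity is justified empirically: in a reference annotation the
overwhelming majority of intron chains correspond to exactly one
transcript. `gtf_stats.chain_uniqueness` quantifies this for any
annotation by populating a dictionary keyed by chain whose values are
the observed (start, end) pairs, then counting keys with more than one
*distinct* pair (exact integer comparison). In the human GENCODE v39
annotation this multi-ends fraction is about 1% of chains; the analysis
runs in minutes on one CPU but the ~50 MB GTF must be supplied by the
user (`data/gencode.v39.annotation.gtf`), as it cannot be
redistributed here.

**Monoexonic transcripts** have no introns, so a pure-coordinate key
would either merge every monoexonic transcript on a chromosome arm or
forbid ends variability entirely. They are instead keyed by
chromosome + strand + associated gene (the SQANTI3 gene assignment at
ingest; the transcript's own gene ID in annotation analyses), with their
(start, end) pairs stored as ends variants like any chain. The
uniqueness analysis exposes `--exclude-mono` to reconcile against counts
that handled monoexonic transcripts differently.

## The store

A single-file SQLite database (tables `isoform`, `ends`, `counts`,
`sc_counts`, `exp`, `sampleData`, `meta`, `ingest_log`; a
`schema_version` row in `meta` guards against foreign files). Isoform
IDs are positive integers assigned sequentially in ingestion order and
never renumbered; ends variants carry the derived ID `x_y_z` where `x`
is the isoform ID and `y`, `z` the start/end coordinates. Counts are
stored per (variant, experiment) — chain-level counts are always the sum
over a chain's variants — and single-cell samples additionally populate
per-(variant, experiment, cell type, barcode) counts.

Ingest semantics: each input isoform's chain is looked up; a hit updates
only the count tables under the new experiment, a miss creates the
isoform entry. Annotations (category, gene, reference transcript) are
written once, by the first experiment that introduces a chain; later
conflicting annotations (e.g. a chain called novel under one reference
release and a full-splice match under another) are recorded in the
ingest report rather than overwritten, keeping the isoform table stable.
Within-sample duplicates of one (chain, start, end) are summed with a
warning — upstream collapse is assumed but not required. Read totals are
conserved exactly and asserted on every ingest. Replacing an experiment
deletes only its count rows; chains and variants it introduced remain
(IDs stable) with zero counts.

For single-cell samples the per-isoform sum of barcode assignments must
equal the isoform's FL count (strict mode, default), which makes the
pseudobulk view equal the bulk counts by construction; `strict=False`
downgrades a mismatch to a report note for pipelines whose barcode
tables are filtered after quantification.

## Queries

- **Detection**: a chain is "detected" in an experiment when its
  chain-level reads reach a threshold, default 1 read (exposed as
  `detect_threshold` — the choice is a convention, not a statistic).
- **CPM** is the depth normalization: reads / experiment total x 1e6,
  with totals taken from the *pre-filter* matrix so that row filtering
  (`min_reads` detected in `min_experiments`) never rescales columns.
- **UpSet intersections** are exclusive: each chain is counted once,
  under the exact set of experiments detecting it, so sizes partition
  the detected chains. Rank ties at `top_n` break deterministically
  (larger size, then higher degree, then lexicographic member set).
- **Ends variability** marginalizes variant counts per experiment over
  starts and over ends separately; both tables row-sum to 1 and both
  margins total the isoform's per-experiment reads.
- **Gene-level proportions** label full-splice-match isoforms by their
  reference transcript ID and others by the store ID; `known_only`
  restricts the denominator to full-splice matches (the convention used
  when comparing known isoforms across cell types). Group read totals
  are returned alongside because proportions from a 12-read cell type
  and a 3,000-read cell type do not deserve equal visual weight.
- **Major-isoform switching**: a group (experiment or cell type)
  qualifies for a gene when its total gene reads reach `min_reads`
  (default 10 — below that, an argmax over reads is mostly noise); the
  major isoform is the within-group argmax; ties break to the
  lexicographically smallest label and are flagged. Only genes with at
  least two qualifying groups and at least two distinct majors are
  reported.
- **GTF export**: `longest` emits one record per chain spanning min
  start / max end over its variants — deliberately reproducing the
  information loss of merge-to-longest tools, for comparison and for
  re-annotation workflows; `all_variants` emits every ends variant.
  Exons are reconstructed from the chain plus the bounds, so exports
  re-read into exactly the original chains.

Differential isoform expression/usage testing is out of scope: the count
matrix is the hand-off point to dedicated tools.

## Synthetic data

`simulate` generates complete input bundles — classification TSV,
genePred, metadata configs, cell-type tables — plus a truth table that
exactly describes the files, so tests compare against construction
rather than sampling. Counts are written directly into the FL column (no
read-level simulation: the tool consumes counts) and each gene lives on
its own artificial chromosome, so no reference sequence or alignment
step is modelled.

The cohort defaults state the world the tool targets: 4 experiments of
one biological source; ~28% of chains novel (NIC+NNC) with 97.2% of them
private to a single experiment; full-splice matches detected in every
experiment at Poisson-distributed depths around 50 reads vs ~3 for novel
chains, so reads concentrate in known isoforms while novel isoforms
dominate chain counts' diversity; 30% of chain-experiment observations
carry a second jittered ends variant (offsets up to 80 bp, never
crossing a junction). Single-cell cohorts apportion each per-cell-type
read budget (200 reads) across a gene's isoforms by fixed weights
(0.55 / 0.25 / rest), identical in every cell type except in planted
switch genes, where the top two isoforms swap weights in half the cell
types — so exactly the planted genes, and no others, show a
major-isoform switch. Integer splitting uses largest-remainder
apportionment; index-ordered tie-breaks keep every bundle byte-identical
for a given seed.

What a green test does **not** establish: robustness to real SQANTI3
quirks (column drift across versions, degenerate categories), fuzzy
junction variation between samples (excluded by design), barcode
error/doublet structure, or statistical power of switch detection at
realistic noise — the generator plants effects far above the
`min_reads` threshold by construction.

## Numerical and degenerate-input choices

Proportions are exact ratios of integer counts (row sums equal 1 to
float rounding; tests assert 1e-9). Experiments with zero reads are
omitted from proportion tables with a warning rather than producing
0/0 rows. `NA` and the empty string both map to missing in
classification text columns; full-/incomplete-splice matches must carry
a reference transcript. Parsers are strict — wrong exon counts,
inverted coordinates, unknown categories, and overlapping exons are
errors naming the offending line, because a silently mis-keyed chain
would corrupt identities for every later sample.

## Known limitations

- No fuzzy chain matching; samples collapsed with different junction
  tolerances upstream may keep near-duplicate chains separate.
- Monoexonic identity inherits the quality of the upstream gene
  assignment; two monoexonic transcripts assigned different gene
  symbols never merge.
- The store tracks long-read counts only; short-read junction support is
  not integrated.
- Cell-type labels are inputs; no clustering or label transfer is
  performed.
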