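# isochaindb

Compare long-read RNA isoform profiles across many samples.

Long-read (PacBio / ONT) transcriptome pipelines end with per-sample
SQANTI3 annotation, but SQANTI3 is single-sample: its `PB.X.Y` isoform
IDs are not comparable between runs, so "do these four libraries share
this novel isoform?" has no direct answer. `isochaindb` consolidates
per-sample SQANTI3 outputs (classification TSV + genePred) into one
growing SQLite store in which an isoform is identified by its **intron
chain** — chromosome, strand, and the ordered intron intervals

    chain(t) = (chrom, strand, [(e1_end, e2_start), ..., (e(k-1)_end, ek_start)])

so that transcripts truncated at the 5′ or 3′ end (RNA degradation,
incomplete reverse transcription, partial sequencing) but sharing every
splice junction collapse onto one identity. The observed (start, end)
combinations are kept in a separate *ends* table as variants with IDs
`x_y_z` (isoform ID, start, end); the read count of a chain in an
experiment is the sum over its variants' counts. Monoexonic transcripts,
having no introns, are keyed by chromosome + strand + gene.

On top of the store, the package provides the comparative queries such
projects need: count matrices (raw or CPM), structural-category
proportions by isoform or by read, UpSet-style exclusive intersections
of detected chains, start/end variability profiles, novel-isoform
sample-sharing histograms, per-gene isoform read proportions (per
experiment or per cell type), major-isoform-switch detection, and GTF
export (one record per chain, or per ends variant). Single-cell samples
additionally carry per-barcode, per-cell-type counts whose pseudobulk
marginals equal the bulk counts by construction. A seeded synthetic
fixture generator (`isochaindb.simulate`) emits complete, parseable
sample bundles with known truth tables.

Intended users: anyone aggregating SQANTI3-annotated long-read samples —
across library preparations, sequencing platforms, conditions, or cell
types — who wants stable isoform identities and depth-aware comparisons
without re-collapsing all samples into one transcriptome.

## Worked example

Generate the two-sample truncation scenario (five transcripts, all
end-truncations of one two-exon transcript, 10 reads each) and add both
samples:

```bash
$ isochaindb simulate truncation --out trunc
$ isochaindb add --db iso.db \
    --classification trunc/trunc_sampleA_classification.txt \
    --genepred trunc/trunc_sampleA.genePred \
    --exp-config trunc/trunc_sampleA_exp.config \
    --sample-config trunc/trunc_sampleA_sample.config
{
  "exp_name": "trunc_sampleA",
  "n_input_isoforms": 3,
  "n_new_chains": 1,
  "n_matched_chains": 0,
  "n_new_variants": 3,
  "total_reads_in": 30,
  "total_reads_stored": 30,
  ...
}
```

Three input transcripts became **one** isoform (they share the intron
chain) with three ends variants; all 30 reads are conserved. After
adding sample B the same way, start-coordinate variability of isoform 1:

```bash
$ isochaindb ends --db iso.db --isoform 1 --out-prefix ends
$ cat ends.starts.tsv
exp_name        1000    1050
trunc_sampleA   0.6666666666666666      0.3333333333333333
trunc_sampleB   1.0     0.0
```

Two-thirds of sample A's reads support the full-length start (1000) and
one-third a start truncated by 50 bp; sample B only ever saw the
full-length start. Exporting with `--mode longest` reproduces what
merge-to-longest tools (e.g. gffcompare) would report — a single
full-length transcript, the truncation information discarded:

```bash
$ isochaindb export-gtf --db iso.db --out longest.gtf --mode longest
1 transcripts -> longest.gtf
$ cat longest.gtf
chrSim1  isochaindb  transcript  1001  5200  .  +  .  gene_id "LPAR3"; transcript_id "isoform_1";
chrSim1  isochaindb  exon        1001  1600  .  +  .  ...
chrSim1  isochaindb  exon        4001  5200  .  +  .  ...
```

(`--mode all_variants` instead writes one record per `x_y_z` ends
variant, preserving every observed start/end.) Other subcommands:
`matrix`, `summary`, `upset`, `sharing`, `gene-prop`, `switches`
(each with optional `--plot`), `gtf-stats` for the reference-annotation
chain-uniqueness analysis, and `add-sc` for single-cell samples.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the whole pipeline end to end on seed-derived synthetic inputs —
truncation-scenario ingest and longest-mode export, a four-experiment
bulk cohort through every query family, a single-cell cohort with
planted major-isoform switches, and the chain-uniqueness analysis on an
exported annotation — asserting internal conservation along the way,
and writes the results JSON to `--out`.
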