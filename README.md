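# atacprep

Preprocessing for single-cell ATAC-seq: from barcoded FASTQ reads (or a
barcode-tagged BAM) to a quality-controlled, cell-called, sparse
feature × cell matrix with per-barcode QC metrics and barcode-matched
multimodal integration.

scATAC-seq profiles open chromatin per cell: Tn5 transposase inserts into
accessible DNA and the resulting fragments, keyed by a per-cell DNA barcode,
are sequenced in bulk. Turning raw reads into an analysable matrix takes a
chain of small, error-prone steps — rescuing sequencing errors in barcodes,
converting read pairs into true insertion intervals, separating real cells
from ambient background DNA — and this package implements that chain as a
library of composable functions plus a thin CLI, for bioinformaticians who
want each step testable and every parameter logged.

## What it computes

- **Barcode demultiplexing.** Barcodes come from a separate index FASTQ or
  from positions inside the reads (CSV-declared). An observed barcode *b* is
  validated against a whitelist *W*; if *b* ∉ *W*, every *w* ∈ *W* with
  Hamming distance d(*b*, *w*) = 1 is a candidate, and with several
  candidates the one whose mismatch position carries the lowest base-call
  quality Q wins (a low-Q base is the one most plausibly miscalled); ties are
  discarded. Reads are partitioned into complete-match / partial-match /
  no-match streams plus their concatenation (full-data), with the assigned
  barcode prefixed to each read name.
- **Fragment generation.** After external alignment, read-name barcodes are
  moved into `CB:Z` tags and each proper pair becomes a fragment
  [*s* + 4, *e* − 5) in 0-based half-open coordinates, where *s*, *e* are the
  outermost alignment bounds — the +4/−5 correction recovers the true Tn5
  insertion sites from the 9 bp target-site duplication. Pairs failing MAPQ
  or size filters are rejected with a reason; PCR duplicates (same contig,
  start, end, barcode) collapse into one record whose count is the number of
  times the fragment was sequenced.
- **Feature counting.** Rows are fixed-width genome bins tiling every contig
  (default 2 kb) or a supplied peak BED; entry (*f*, *c*) counts distinct
  fragments of barcode *c* overlapping feature *f* by ≥ 1 bp. A binarized
  (presence/absence) twin is standard for scATAC.
- **QC and cell calling.** Per barcode: total fragments *n*, FRiP
  (fraction of fragments in peaks), optional TSS/promoter/enhancer and
  mitochondrial fractions. A barcode is called a cell iff
  *n* ≥ *n*₀ ∧ FRiP ≥ *f*₀ ∧ mito ≤ *m*₀ (all thresholds tunable and
  logged), then low-occupancy features and near-empty cells are dropped.
- **Bundles and integration.** The filtered matrix ships as
  MTX + TSV + JSON provenance (loadable into AnnData); bundles from
  different modalities (e.g. multiome ATAC + RNA) combine over the union of
  barcodes, with missing (modality, barcode) pairs marked in an explicit
  presence mask, never zero-filled.

A first-class synthetic-data module plants ground truth (true cell barcodes,
true fragments, known duplication and barcode-error rates) so that every
stage is tested against an independent oracle — no downloads required.

## Worked example

Simulate a small experiment and run the full pipeline from one config file:

```bash
atacprep simulate --outdir sim --n-cells 40 --n-ambient 150 --seed 7
```

```json
{
  "read_pairs": 13510,
  "true_fragments": 11272,
  "expected_partition": {
    "complete_match": 12871,
    "partial_match": 639,
    "no_match": 0
  }
}
```

13,510 read pairs were emitted for 11,272 distinct fragments (the excess is
PCR duplication); 639 reads carry a planted single-base barcode error that
Hamming-1 correction is expected to rescue. Then:

```yaml
# config.yaml
bam: sim/aligned.bam
chrom_sizes: sim/chrom.sizes
outdir: out
features: {bed: sim/peaks.bed}
fragments: {min_mapq: 30, max_fragment_size: 2000}
qc: {min_total_fragments: 80, min_frac_in_peaks: 0.3, mito_contigs: [chrM]}
binarize: true
```

```bash
atacprep pipeline --config config.yaml
```

```json
{
  "n_called_cells": 40,
  "filtered_shape": [60, 40],
  "bundle": "out/bundle"
}
```

All 40 planted cells were called out of 190 observed barcodes, and the
filtered binary matrix has 60 peak features × 40 cells. `out/` also contains
the sorted fragment BED (`chr1  33  270  ATGCTCCAGGCGTTAT  1` — chrom,
start, end, barcode, read support), the per-barcode QC table, a JSON summary
and the full parameter log.

Each stage is equally available as its own subcommand (`demux`, `tag-bam`,
`fragments`, `count`, `qc-call`, `integrate`) and as plain library functions
(`atacprep.demultiplex`, `atacprep.pair_to_fragment`, …).

## Scope

Read alignment (any paired-end aligner) and bulk peak calling (MACS-style)
are external: the pipeline consumes their outputs. Downstream analysis —
dimensionality reduction, clustering, motif enrichment — is deliberately
left to the single-cell ecosystem the bundles interoperate with. See
`docs/methods.md` for the model, parameter defaults and known limitations.
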