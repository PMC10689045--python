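# Methods

This note documents the procedures implemented in `atacprep`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical/design decisions made where the choice was
genuinely open.

## Barcode error correction

Observed barcodes are matched against a whitelist of valid sequences.
Matching is exact first; a miss triggers a Hamming-distance-1 search (one
substitution). `N` never equals any base, so an `N` inside the barcode can
at best yield a corrected match, never an exact one. When more than one
whitelist entry lies at distance 1, the candidates are ranked by the
base-call quality of the observed read at each candidate's mismatch
position: the *lowest* Q wins, because that position is the most plausible
sequencing error. Two situations are irreducibly ambiguous and send the read
to the no-match pool: equal minimal Q scores across candidates, and two
candidates mismatching at the same position (which forces equal Q). Ambiguity
is resolved by discarding rather than arbitrary choice — a conservative rule
that costs a small fraction of reads and never mis-assigns a cell.

Reverse-complement mode reverse-complements the observed barcode (and
reverses its quality string) before matching, so an index file sequenced in
the opposite orientation reproduces the forward partition exactly.

The four output streams are complete-match (valid as observed),
partial-match (rescued), no-match, and full-data (their concatenation);
downstream steps default to full-data. Partial-match reads store the
*corrected* barcode in their read name — the observed one is, by
construction, a sequencing error. The barcode/read-name separator is a
single configurable character, `#` by default, used identically by the BAM
tagging step.

Embedded-barcode layout: a CSV of rows `file,start,length`
(`file` ∈ {R1, R2}, 0-based start); multi-row specs concatenate segments in
row order into one barcode string, and the segments are spliced out of the
read before writing, so the output FASTQs are directly alignable.

## Fragments and the Tn5 shift

Tn5 inserts as a dimer and duplicates 9 bp of target sequence; the true
insertion sites are therefore +4 bp inside the leftmost alignment start and
−5 bp inside the rightmost alignment end. Fragments are stored in BED
convention (0-based, half-open), and BAM positions are converted to that
convention before the +4/−5 arithmetic. A pair is rejected — with a counted
reason, not an exception — when mates map to different contigs, the pair is
not proper, the CB tag is absent, the pair-minimum MAPQ is below threshold,
the post-shift span is ≤ 0 (raw spans of ≤ 9 bp are consumed by the shift),
or the span exceeds the maximum size.

Defaults: `min_mapq = 30` (confident unique alignments under the common
aligner conventions), `max_fragment_size = 2000` (beyond tri-nucleosomal
spacing; larger spans are almost always artefacts). The MAPQ filter applies
to the pair minimum: one unreliable mate makes the inferred span unreliable.
Both are flags and are logged.

Duplicate collapsing keys on (chrom, start, end, barcode) — the barcode is
part of the key because two cells can legitimately produce identical
coordinates — and records the multiplicity as the fragment's read-support
count. Duplicate removal at the BAM level is an optional external hook
(`samtools markdup` or similar); it is not reimplemented because
fragment-level collapsing already absorbs PCR duplicates.

## Feature counting

Two feature spaces: fixed-width genome bins (default 2000 bp, the last bin
truncated at the contig end; bins tile the genome exactly) or a user BED
(e.g. bulk peaks). Counting is any-overlap: a fragment contributes 1 to
every feature it overlaps by ≥ 1 bp, in half-open semantics (a fragment
starting exactly at a bin boundary belongs to the right bin only). An
alternative convention — counting the two Tn5 cut sites separately — is a
defensible choice we did not implement; with features much wider than
fragments the two agree almost everywhere, and any-overlap keeps the
fragment as the unit of evidence. Counts use *distinct* fragments, never the
read-support column: PCR duplicates carry no additional accessibility
evidence, which is exactly why collapsing exists. Overlapping input peaks
are kept as-is (with a warning), not merged, so feature ids remain traceable
to the caller's output.

Internally, disjoint sorted features (bins, non-overlapping peaks) are
counted by a vectorised binary search; overlapping feature sets fall back to
an interval tree. Both paths are tested against an O(n·m) brute-force
oracle.

## QC metrics and cell calling

Per barcode: total fragments; fraction of fragments overlapping peaks
(FRiP); fractions overlapping optional TSS/promoter/enhancer BEDs; fraction
on mitochondrial contigs; distinct features touched; total fragment-feature
overlaps. All fractions are exact count ratios. Missing annotations produce
*absent* columns, not zeros, so downstream thresholds cannot silently bind
to fabricated values.

Cell calling is a conjunction of thresholds: a barcode is a cell iff
`total_fragments >= min_total_fragments` and
`frac_in_peaks >= min_frac_in_peaks` and (when mitochondrial data exists)
`frac_mito <= max_frac_mito`. This threshold-conjunction rule is one
reading of multi-metric filter-based calling and is labelled as such in the
report metadata. Defaults — `min_total_fragments = 200`,
`min_frac_in_peaks = 0.1`, `max_frac_mito = 0.2`,
`min_features_per_cell = 10`, `min_cells_per_feature = 2` — are deliberately
permissive values at the boundary between ambient background and real cells
in droplet data; every one is a flag, appears in the JSON log, and should be
tuned per dataset from the QC plots. Matrix filtering is ordered: restrict
columns to called cells, then drop features below the cell-support floor,
then drop cells below the feature floor; the operation is idempotent at
fixed thresholds and monotone in each threshold.

"Read density" in the QC plots is `features_per_barcode / total_fragments`
— a measure of how spread a barcode's fragments are across the feature
space; the definition is recorded in the report metadata since conventions
vary.

## Bundles and integration

A bundle serialises the matrix (MatrixMarket coordinate integer), feature
and barcode TSVs, the per-cell QC table aligned 1:1 with matrix columns, and
a JSON provenance log; saves are byte-deterministic, and round trips are
lossless. Integration joins bundles of distinct modalities over the *union*
of barcodes. Missing (modality, barcode) pairs are represented by an
explicit boolean presence mask plus NaN metadata — a sparse integer matrix
has no honest "NA", and zero-filling would conflate "not measured" with
"closed chromatin". The combined object is invariant to bundle order, and an
optional two-column translation table maps chemistry-specific barcodes into
a common space before joining (constructing such a table is out of scope).

## The synthetic generator

The generator plants a complete experiment and keeps the truth: a random
genome, disjoint peaks (sorted-uniform-gap placement, widths within a given
range), cell barcodes versus ambient barcodes, fragments, duplication, and
barcode sequencing errors. Its defaults are the study conditions used
throughout the tests and the acceptance script: 500 cells at 500–2000
fragments each with FRiP 0.7, 5000 ambient barcodes at 1–50 fragments with
FRiP 0.05, 10% duplication, 16 bp barcodes, fragment sizes uniform in
100–400 bp. Fragment placement draws in-peak status per fragment as a
Bernoulli variable at the class FRiP, places in-peak fragments to overlap a
uniformly chosen peak by ≥ 1 bp, and places background fragments uniformly
outside all peaks (rejection sampling). The duplicated share of fragments
draws its read support uniformly from {2, 3, 4}. Whitelists are generated
with minimum pairwise Hamming distance 3, making single-error correction
unambiguous; a separate colliding-whitelist fixture builds distance-2 pairs
specifically to exercise the Q-score tie-break. Independently placed
fragments that collide on (chrom, start, end, barcode) are merged in the
truth table with summed read support, so the truth is exactly the fixed
point of duplicate collapsing.

Fragment coordinates are generated directly in BED convention and read/
alignment coordinates are derived by inverting the +4/−5 shift, which is
what makes bit-exact reconstruction a valid test oracle. The recorded
expected demultiplexing partition is computed by a brute-force Hamming scan
over the whitelist — code independent of the correction implementation under
test.

Deliberately not emulated: realistic sequence composition and GC bias,
doublets, alignment errors, chimeric or secondary alignments, variable read
lengths. Passing tests therefore demonstrate the correctness of the
*bookkeeping* — coordinate arithmetic, partitioning, counting, thresholding
— under clean mapping; they do not certify behaviour under mapping
ambiguity, contamination, or chemistry drift in real libraries. In
particular the planted cell/ambient separation is generous by construction,
so the cell-calling recovery figures characterise the filter's behaviour at
well-separated settings, not its discrimination power on marginal data.

## Problem sizes and numerical notes

Tests and the acceptance script run on deliberately compact instances —
10⁴ read pairs for demultiplexing, ≤ 10⁴ pairs for fragment reconstruction,
10³ × 10³ for the counting oracle, 5,500 barcodes / ~7.5 × 10⁵ fragments
for cell calling — chosen so the full chain, including brute-force oracles,
completes in seconds while still exercising every code path at realistic
per-barcode depths. All randomness flows from explicit seeds
(`numpy.random.default_rng`); identical seeds yield byte-identical emitted
files. Contig ordering follows the chrom.sizes file everywhere (fragment
sorting, feature ordering), with lexicographic fallback for contigs outside
it. Empty inputs (no reads, no barcodes, no fragments, empty whitelist,
empty filtered matrix) return empty-but-valid results rather than raising,
with the two documented exceptions: malformed records and inconsistent file
pairs are hard errors.

## Known limitations

- Combinatorial multi-round barcodes are accepted only as one concatenated
  barcode string; per-round correction is not modelled.
- No knee-point or model-based (EmptyDrops-style) cell calling; the filter
  conjunction is the only rule provided.
- No doublet detection.
- The BAM pairing buffer joins mates by query name and assumes primary,
  non-supplementary pairs; discordant-pair rescue is not attempted.
- Peak calling and alignment are consumed, never performed.
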