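"""Tn5 fragment generation from barcode-tagged paired alignments.

Tn5 inserts as a homodimer and duplicates 9 bp of its target, so the true
insertion sites sit +4 bp inside the leftmost alignment start and −5 bp
inside the rightmost alignment end.  A fragment is the interval between the
two shifted insertion sites, in BED convention (0-based, half-open), keyed by
the cell barcode.  PCR duplicates — read pairs reproducing the same
(contig, start, end, barcode) — are collapsed into one record whose ``count``
records how many times the fragment was sequenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

from ._utils import chrom_rank

TN5_SHIFT_LEFT = 4
TN5_SHIFT_RIGHT = 5

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1


@dataclass(frozen=True)
class Rejected:
    """A read pair excluded from the fragment file, with the filter that fired."""

    reason: str


@dataclass
class FragmentFilterConfig:
    """Pair-level filters. MAPQ applies to the pair minimum."""

    min_mapq: int = 30
    max_fragment_size: int = 2000
    include_contigs: list[str] | None = None
    exclude_contigs: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.max_fragment_size <= 0:
            raise ValueError("max_fragment_size must be positive")


def pair_to_fragment(r1, r2, cfg: FragmentFilterConfig) -> Fragment | Rejected:
    """Convert one mated pair of tagged alignments into a Tn5-shifted fragment.

    Rejections (with reasons) instead of exceptions: interchromosomal pairs,
    improper pairs, missing CB tag, sub-threshold MAPQ, degenerate post-shift
    span, over-long fragments and filtered contigs.
    """
    if r1.reference_name != r2.reference_name:
        return Rejected("interchromosomal")
    if not (r1.is_proper_pair and r2.is_proper_pair):
        return Rejected("improper_pair")
    barcode = None
    for r in (r1, r2):
        if r.has_tag("CB"):
            barcode = r.get_tag("CB")
            break
    if not barcode:
        return Rejected("no_barcode")
    if min(r1.mapping_quality, r2.mapping_quality) < cfg.min_mapq:
        return Rejected("low_mapq")
    chrom = r1.reference_name
    if cfg.include_contigs is not None and chrom not in cfg.include_contigs:
        return Rejected("contig_filtered")
    if chrom in cfg.exclude_contigs:
        return Rejected("contig_filtered")
    start = min(r1.reference_start, r2.reference_start) + TN5_SHIFT_LEFT
    end = max(r1.reference_end, r2.reference_end) - TN5_SHIFT_RIGHT
    if end - start <= 0:
        return Rejected("degenerate")
    if end - start > cfg.max_fragment_size:
        return Rejected("too_long")
    return Fragment(chrom, start, end, barcode)


def bam_to_fragments(
    bam_path, cfg: FragmentFilterConfig | None = None
) -> tuple[list[Fragment], dict[str, int]]:
    """Stream a tagged BAM into (uncollapsed) fragments plus per-reason counters.

    Secondary, supplementary, unmapped and unpaired records are skipped and
    tallied; mates are joined by query name with a bounded in-flight buffer,
    which works for any sort order.
    """
    cfg = cfg or FragmentFilterConfig()
    fragments: list[Fragment] = []
    stats = {
        "accepted_pairs": 0,
        "secondary_or_supplementary": 0,
        "unmapped": 0,
        "unpaired": 0,
        "mate_missing": 0,
    }
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for read in bam:
            if read.is_secondary or read.is_supplementary:
                stats["secondary_or_supplementary"] += 1
                continue
            if not read.is_paired:
                stats["unpaired"] += 1
                continue
            if read.is_unmapped or read.mate_is_unmapped:
                stats["unmapped"] += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            result = pair_to_fragment(mate, read, cfg)
            if isinstance(result, Rejected):
                stats[result.reason] = stats.get(result.reason, 0) + 1
            else:
                fragments.append(result)
                stats["accepted_pairs"] += 1
    stats["mate_missing"] = len(pending)
    return fragments, stats


def collapse(fragments: Iterable[Fragment]) -> list[Fragment]:
    """Deduplicate on (chrom, start, end, barcode); count accumulates multiplicity."""
    acc: dict[tuple, int] = {}
    for f in fragments:
        key = (f.chrom, f.start, f.end, f.barcode)
        acc[key] = acc.get(key, 0) + f.count
    return [Fragment(c, s, e, b, n) for (c, s, e, b), n in acc.items()]


def sort_fragments(
    fragments: Iterable[Fragment], chrom_order: list[str] | None = None
) -> list[Fragment]:
    key = chrom_rank(chrom_order)
    return sorted(fragments, key=lambda f: (key(f.chrom), f.start, f.end, f.barcode))


def write_fragments(
    fragments: Iterable[Fragment],
    path,
    chrom_order: list[str] | None = None,
    index: bool = False,
) -> str:
    """Write a sorted 5-column fragment BED; ``.gz`` paths get bgzip (+tabix).

    Columns: chrom, start, end, barcode, count. Returns the written path.
    """
    path = str(path)
    ordered = sort_fragments(fragments, chrom_order)
    plain = path[:-3] if path.endswith(".gz") else path
    with open(plain, "w") as fh:
        for f in ordered:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.barcode}\t{f.count}\n")
    if path.endswith(".gz"):
        pysam.tabix_compress(plain, path, force=True)
        Path(plain).unlink()
        if index:
            pysam.tabix_index(path, preset="bed", force=True)
    return path


def read_fragments(path) -> pd.DataFrame:
    """Load a fragment BED into a DataFrame (chrom, start, end, barcode, count)."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=FRAGMENT_COLUMNS,
            dtype={"chrom": str, "start": int, "end": int, "barcode": str, "count": int},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=FRAGMENT_COLUMNS)
    return df


def iter_fragments(df: pd.DataFrame) -> Iterator[Fragment]:
    for row in df.itertuples(index=False):
        yield Fragment(row.chrom, int(row.start), int(row.end), row.barcode, int(row.count))


def fragments_to_frame(fragments: Iterable[Fragment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.chrom, f.start, f.end, f.barcode, f.count) for f in fragments],
        columns=FRAGMENT_COLUMNS,
    )
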