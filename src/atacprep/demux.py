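"""Cell-barcode extraction, whitelist error correction and read partitioning.

Barcodes arrive either as the sequence of a separate index FASTQ or embedded
at declared positions inside the reads themselves.  Observed barcodes are
validated against a whitelist; a barcode that misses the whitelist is rescued
when it sits at Hamming distance 1 from exactly one valid barcode, or — when
several valid barcodes are one substitution away — when the mismatched
position's base-call quality singles one candidate out: the candidate whose
mismatch position carries the *lowest* Q score in the observed read wins,
because a low-quality base is the one most plausibly miscalled.  Ties are
ambiguous and the read is discarded to the no-match pool.

Reads are partitioned into four streams: ``complete_match`` (barcode valid as
observed), ``partial_match`` (rescued by correction), ``no_match`` and
``full_data`` (the concatenation of the three).  Surviving reads get the
assigned barcode prefixed to their name so that downstream BAM tagging can
recover it after alignment.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pysam

from ._utils import FastqWriter, encode_seqs, open_text, quals_to_ints, revcomp

DEFAULT_SEPARATOR = "#"

CATEGORIES = ("complete_match", "partial_match", "no_match")


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of matching one observed barcode against the whitelist."""

    status: str  # exact | corrected | unmatched | ambiguous
    barcode: str | None = None
    mismatch_position: int | None = None


@dataclass
class BarcodeSpec:
    """Where barcodes live in the input reads.

    ``mode`` is ``"index-fastq"`` (barcode = leading bases of a complementary
    index FASTQ) or ``"embedded-csv"`` (barcode spliced out of the reads at
    positions given by ``csv_rows``).  Each CSV row is ``(file, start, length)``
    with ``file`` in {"R1", "R2"} and a 0-based start; multi-row specs are
    concatenated in row order into one barcode string.
    """

    mode: str
    barcode_length: int
    csv_rows: list[tuple[str, int, int]] = field(default_factory=list)
    check_reverse_complement: bool = False

    def __post_init__(self):
        if self.mode not in ("index-fastq", "embedded-csv"):
            raise ValueError(f"unknown barcode mode: {self.mode!r}")
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")
        if self.mode == "embedded-csv" and not self.csv_rows:
            raise ValueError("embedded-csv mode requires csv_rows")

    @classmethod
    def from_csv(cls, path, check_reverse_complement: bool = False) -> "BarcodeSpec":
        rows: list[tuple[str, int, int]] = []
        with open_text(path) as fh:
            for rec in csv.reader(fh):
                if not rec or rec[0].lstrip().startswith("#"):
                    continue
                rows.append((rec[0].strip().upper(), int(rec[1]), int(rec[2])))
        total = sum(r[2] for r in rows)
        return cls("embedded-csv", total, rows, check_reverse_complement)


class Whitelist:
    """The set of valid cell barcodes, with Hamming-1 correction support.

    All barcodes must share one length.  Matching uses a packed byte matrix so
    per-read candidate search is a vectorised comparison; ``N`` never equals
    any base and therefore always counts as a mismatch.
    """

    def __init__(self, barcodes: Sequence[str]):
        seen = list(dict.fromkeys(b.strip().upper() for b in barcodes if b.strip()))
        if not seen:
            self.barcodes: list[str] = []
            self.length = 0
            self._set: set[str] = set()
            self._mat = np.empty((0, 0), dtype=np.uint8)
            return
        lengths = {len(b) for b in seen}
        if len(lengths) != 1:
            raise ValueError(f"whitelist barcodes have mixed lengths: {sorted(lengths)}")
        self.barcodes = seen
        self.length = lengths.pop()
        self._set = set(seen)
        self._mat = encode_seqs(seen, self.length)

    @classmethod
    def from_file(cls, path) -> "Whitelist":
        with open_text(path) as fh:
            return cls([line.strip() for line in fh])

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._set

    def correct(self, observed: str, quals: str | Sequence[int]) -> CorrectionResult:
        """Match one observed barcode (exact, then Hamming-1 with Q tie-break)."""
        q = quals_to_ints(quals)
        if len(observed) != self.length or len(q) != self.length:
            raise ValueError(
                f"barcode/quality length {len(observed)}/{len(q)} does not match "
                f"whitelist barcode length {self.length}"
            )
        if observed in self._set:
            return CorrectionResult("exact", observed)
        obs = encode_seqs([observed], self.length)[0]
        mism = self._mat != obs
        dist = mism.sum(axis=1)
        cand = np.flatnonzero(dist == 1)
        if cand.size == 0:
            return CorrectionResult("unmatched")
        positions = [int(np.flatnonzero(mism[i])[0]) for i in cand]
        qs = np.array([q[p] for p in positions])
        best = int(np.argmin(qs))
        if (qs == qs[best]).sum() > 1:
            return CorrectionResult("ambiguous")
        return CorrectionResult("corrected", self.barcodes[int(cand[best])], positions[best])

    def correct_batch(
        self, observed: Sequence[str], quals: Sequence[str | Sequence[int]]
    ) -> list[CorrectionResult]:
        """Vectorised batch correction; semantics identical to :meth:`correct`."""
        out: list[CorrectionResult | None] = [None] * len(observed)
        todo_idx = []
        for i, bc in enumerate(observed):
            if len(bc) != self.length:
                raise ValueError(
                    f"barcode length {len(bc)} does not match whitelist length {self.length}"
                )
            if bc in self._set:
                out[i] = CorrectionResult("exact", bc)
            else:
                todo_idx.append(i)
        if not todo_idx:
            return out  # type: ignore[return-value]
        chunk = max(1, 2**22 // max(1, len(self.barcodes) * self.length))
        for lo in range(0, len(todo_idx), chunk):
            idx = todo_idx[lo : lo + chunk]
            mat = encode_seqs([observed[i] for i in idx], self.length)
            # (reads, whitelist) Hamming distances via a broadcast byte compare
            dist = (mat[:, None, :] != self._mat[None, :, :]).sum(axis=2)
            for row, i in enumerate(idx):
                cand = np.flatnonzero(dist[row] == 1)
                if cand.size == 0:
                    out[i] = CorrectionResult("unmatched")
                    continue
                q = quals_to_ints(quals[i])
                mism = self._mat[cand] != mat[row]
                positions = [int(np.flatnonzero(m)[0]) for m in mism]
                qs = np.array([q[p] for p in positions])
                best = int(np.argmin(qs))
                if (qs == qs[best]).sum() > 1:
                    out[i] = CorrectionResult("ambiguous")
                else:
                    out[i] = CorrectionResult(
                        "corrected", self.barcodes[int(cand[best])], positions[best]
                    )
        return out  # type: ignore[return-value]


@dataclass
class DemuxPartition:
    """Counts, per-barcode frequencies and file handles of a demux run."""

    counts: dict[str, int]
    barcode_counts: Counter
    files: dict[str, tuple[str, str]]
    params: dict
    assignments: list[tuple[str, str, str]] | None = None

    @property
    def total(self) -> int:
        return sum(self.counts[c] for c in CATEGORIES)


def _read_ids_match(a: str, b: str) -> bool:
    sa = a.split()[0].removesuffix("/1").removesuffix("/2")
    sb = b.split()[0].removesuffix("/1").removesuffix("/2")
    return sa == sb


def _iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    with pysam.FastxFile(str(path)) as fh:
        for i, rec in enumerate(fh):
            if rec.sequence is None or rec.quality is None:
                raise ValueError(f"malformed FASTQ record #{i} in {path}")
            yield rec.name, rec.sequence, rec.quality


def _extract_embedded(spec: BarcodeSpec, r1: tuple[str, str, str], r2: tuple[str, str, str]):
    """Splice the barcode segments out of the reads; returns (bc, bq, r1', r2')."""
    seqs = {"R1": list(r1[1:]), "R2": list(r2[1:])}
    bc_parts, bq_parts = [], []
    cuts: dict[str, list[tuple[int, int]]] = {"R1": [], "R2": []}
    for fname, start, length in spec.csv_rows:
        seq, qual = seqs[fname]
        bc_parts.append(seq[start : start + length])
        bq_parts.append(qual[start : start + length])
        cuts[fname].append((start, start + length))
    for fname, spans in cuts.items():
        seq, qual = seqs[fname]
        for s, e in sorted(spans, reverse=True):
            seq = seq[:s] + seq[e:]
            qual = qual[:s] + qual[e:]
        seqs[fname] = [seq, qual]
    return (
        "".join(bc_parts),
        "".join(bq_parts),
        (r1[0], *seqs["R1"]),
        (r2[0], *seqs["R2"]),
    )


def demultiplex(
    r1_path,
    r2_path,
    outdir,
    *,
    index_fastq=None,
    barcode_spec: BarcodeSpec | None = None,
    whitelist: Whitelist | None = None,
    reverse_complement: bool = False,
    separator: str = DEFAULT_SEPARATOR,
    gzip_output: bool = False,
    record_assignments: bool = False,
) -> DemuxPartition:
    """Partition paired reads into complete/partial/no-match (+ full-data) FASTQs.

    Exactly one barcode source must be given: ``index_fastq`` or an
    embedded-csv ``barcode_spec``.  Without a whitelist every read passes
    through as complete-match with its observed barcode (frequency counting
    only).  With ``reverse_complement`` the observed barcode is
    reverse-complemented (and its qualities reversed) before matching, so an
    index file sequenced in the opposite orientation reproduces the forward
    partition.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if index_fastq is None and (barcode_spec is None or barcode_spec.mode != "embedded-csv"):
        raise ValueError("need an index FASTQ or an embedded-csv BarcodeSpec")
    if index_fastq is not None and barcode_spec is not None and barcode_spec.mode == "embedded-csv":
        raise ValueError("index FASTQ and embedded-csv spec are mutually exclusive")

    suffix = ".fastq.gz" if gzip_output else ".fastq"
    streams = CATEGORIES + ("full_data",)
    writers = {
        cat: (
            FastqWriter(outdir / f"{cat}_R1{suffix}"),
            FastqWriter(outdir / f"{cat}_R2{suffix}"),
        )
        for cat in streams
    }
    counts = {cat: 0 for cat in CATEGORIES}
    counts.update(exact=0, corrected=0, ambiguous=0, unmatched=0)
    barcode_counts: Counter = Counter()
    assignments: list[tuple[str, str, str]] | None = [] if record_assignments else None

    it1, it2 = _iter_fastq(r1_path), _iter_fastq(r2_path)
    it_idx = _iter_fastq(index_fastq) if index_fastq is not None else None
    bc_len = whitelist.length if whitelist is not None and len(whitelist) else (
        barcode_spec.barcode_length if barcode_spec is not None else None
    )

    def batches():
        n = 0
        while True:
            batch = []
            for _ in range(8192):
                rec1 = next(it1, None)
                rec2 = next(it2, None)
                if (rec1 is None) != (rec2 is None):
                    raise ValueError(
                        f"record count mismatch between {r1_path} and {r2_path}"
                    )
                if rec1 is None:
                    if it_idx is not None and next(it_idx, None) is not None:
                        raise ValueError(
                            f"record count mismatch between {r1_path} and {index_fastq}"
                        )
                    break
                if not _read_ids_match(rec1[0], rec2[0]):
                    raise ValueError(
                        f"read id mismatch at record {n}: {rec1[0]!r} vs {rec2[0]!r}"
                    )
                if it_idx is not None:
                    reci = next(it_idx, None)
                    if reci is None:
                        raise ValueError(
                            f"record count mismatch between {r1_path} and {index_fastq}"
                        )
                    bc, bq = reci[1], reci[2]
                    if bc_len is not None:
                        bc, bq = bc[:bc_len], bq[:bc_len]
                else:
                    bc, bq, rec1, rec2 = _extract_embedded(barcode_spec, rec1, rec2)
                if reverse_complement:
                    bc, bq = revcomp(bc), bq[::-1]
                batch.append((rec1, rec2, bc, bq))
                n += 1
            if not batch:
                return
            yield batch

    try:
        for batch in batches():
            if whitelist is None:
                results = [CorrectionResult("exact", bc) for (_, _, bc, _) in batch]
            elif len(whitelist) == 0:
                results = [CorrectionResult("unmatched") for _ in batch]
            else:
                results = whitelist.correct_batch(
                    [bc for (_, _, bc, _) in batch], [bq for (_, _, _, bq) in batch]
                )
            for (rec1, rec2, bc, _), res in zip(batch, results):
                counts[res.status] += 1
                if res.status == "exact":
                    cat, tag = "complete_match", res.barcode
                elif res.status == "corrected":
                    cat, tag = "partial_match", res.barcode
                else:
                    cat, tag = "no_match", bc
                counts[cat] += 1
                if cat != "no_match":
                    barcode_counts[tag] += 1
                name1 = f"{tag}{separator}{rec1[0]}"
                name2 = f"{tag}{separator}{rec2[0]}"
                for target in (cat, "full_data"):
                    writers[target][0].write(name1, rec1[1], rec1[2])
                    writers[target][1].write(name2, rec2[1], rec2[2])
                if assignments is not None:
                    assignments.append((rec1[0], cat, tag))
    finally:
        for w1, w2 in writers.values():
            w1.close()
            w2.close()

    with open(outdir / "barcode_stats.tsv", "w") as fh:
        fh.write("barcode\tcount\n")
        for bc, n in barcode_counts.most_common():
            fh.write(f"{bc}\t{n}\n")

    params = {
        "r1": str(r1_path),
        "r2": str(r2_path),
        "index_fastq": str(index_fastq) if index_fastq is not None else None,
        "barcode_mode": "index-fastq" if index_fastq is not None else "embedded-csv",
        "whitelist_size": len(whitelist) if whitelist is not None else None,
        "reverse_complement": reverse_complement,
        "separator": separator,
        "counts": dict(counts),
    }
    with open(outdir / "demux_log.json", "w") as fh:
        json.dump(params, fh, indent=2)

    files = {
        cat: (str(outdir / f"{cat}_R1{suffix}"), str(outdir / f"{cat}_R2{suffix}"))
        for cat in streams
    }
    return DemuxPartition(counts, barcode_counts, files, params, assignments)
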