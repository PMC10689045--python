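"""Ground-truth-annotated synthetic scATAC experiments.

Every downstream stage of the pipeline is testable against planted truth:
a random reference genome, disjoint planted peaks, a population of "cell"
barcodes (many fragments, high fraction of fragments in peaks) over an
ambient background (few fragments, low FRiP), PCR duplication, single-base
barcode sequencing errors, and reads emitted in both supported barcode
layouts (separate index FASTQ, or embedded in the reads at CSV-declared
positions).  Fragment coordinates are generated directly in BED convention
(0-based half-open); read coordinates are derived by *inverting* the +4/−5
Tn5 shift, so the fragment builder's output can be compared to the truth
table bit-exactly.

The expected demultiplexing partition recorded with emitted reads is computed
by a brute-force Hamming scan over the whitelist, independent of the
correction code under test.

Deliberately not simulated: realistic sequence content, GC bias, doublets,
alignment errors.  Reads are fixed-length proper pairs only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._utils import (
    FastqWriter,
    chrom_rank,
    encode_seqs,
    ints_to_quals,
    revcomp,
    write_chrom_sizes,
)
from .features import FeatureSet
from .fragments import TN5_SHIFT_LEFT, TN5_SHIFT_RIGHT

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Margin kept free at contig edges so the inverse Tn5 shift and a read
#: length of up to ~150 bp never run off the sequence.
_EDGE_PAD = 200


@dataclass
class Reference:
    """Random reference bundle: ordered contig sizes plus nucleotide sequences."""

    chrom_sizes: dict[str, int]
    sequences: dict[str, str]

    def write_chrom_sizes(self, path) -> None:
        write_chrom_sizes(self.chrom_sizes, path)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def make_reference(chrom_lengths: dict[str, int], seed: int) -> Reference:
    """Deterministic random genome with the requested contig lengths."""
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {name!r} has non-positive length {length}")
    rng = np.random.default_rng(seed)
    sequences = {
        name: _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        for name, length in chrom_lengths.items()
    }
    return Reference(dict(chrom_lengths), sequences)


def plant_peaks(
    reference: Reference,
    n_peaks: int,
    width_range: tuple[int, int],
    seed: int,
    min_gap: int = 1,
) -> FeatureSet:
    """Place ``n_peaks`` disjoint peaks with widths in ``width_range``.

    Peaks are distributed across contigs proportionally to length and placed
    by the sorted-uniform-gaps construction, which guarantees disjointness
    with at least ``min_gap`` bp between neighbours.  Contig edges keep a
    margin so simulated fragments overlapping a peak never leave the contig.
    """
    if n_peaks < 0:
        raise ValueError("n_peaks must be >= 0")
    wmin, wmax = width_range
    if not (0 < wmin <= wmax):
        raise ValueError("invalid width_range")
    chroms = list(reference.chrom_sizes)
    cols = ["chrom", "start", "end", "id"]
    if n_peaks == 0 or not chroms:
        if n_peaks > 0:
            raise ValueError("genome too small to place the requested peaks")
        return FeatureSet(pd.DataFrame(columns=cols), origin="external_peaks",
                          chrom_order=chroms)
    rng = np.random.default_rng(seed)
    usable = {
        c: max(0, reference.chrom_sizes[c] - 2 * min(_EDGE_PAD, reference.chrom_sizes[c] // 10))
        for c in chroms
    }
    cap = {c: max(0, (usable[c] + min_gap) // (wmax + min_gap)) for c in chroms}
    if sum(cap.values()) < n_peaks:
        raise ValueError(
            f"genome too small to place {n_peaks} disjoint peaks of width <= {wmax}"
        )
    total = sum(usable.values())
    alloc = {c: min(cap[c], int(n_peaks * usable[c] / total)) for c in chroms}
    leftover = n_peaks - sum(alloc.values())
    for c in sorted(chroms, key=lambda c: cap[c] - alloc[c], reverse=True):
        if leftover <= 0:
            break
        take = min(leftover, cap[c] - alloc[c])
        alloc[c] += take
        leftover -= take
    rows = []
    for c in chroms:
        k = alloc[c]
        if k == 0:
            continue
        pad = min(_EDGE_PAD, reference.chrom_sizes[c] // 10)
        widths = rng.integers(wmin, wmax + 1, size=k)
        slack = usable[c] - int(widths.sum()) - (k - 1) * min_gap
        if slack < 0:
            raise ValueError(f"contig {c} too small for its allocated peaks")
        offsets = np.sort(rng.integers(0, slack + 1, size=k))
        starts = pad + offsets + np.concatenate(([0], np.cumsum(widths[:-1]))) + \
            min_gap * np.arange(k)
        for s, w in zip(starts, widths):
            rows.append((c, int(s), int(s + w)))
    df = pd.DataFrame(rows, columns=cols[:3])
    df["id"] = df.chrom + ":" + df.start.astype(str) + "-" + df.end.astype(str)
    return FeatureSet(df, origin="external_peaks", chrom_order=chroms)


def random_barcodes(
    n: int, length: int, seed: int, min_distance: int = 3
) -> list[str]:
    """Unique random barcodes with a guaranteed minimum pairwise Hamming distance."""
    if n == 0:
        return []
    if length < 1:
        raise ValueError("barcode length must be >= 1")
    if n > 4**length:
        raise ValueError(f"cannot draw {n} distinct barcodes of length {length}")
    rng = np.random.default_rng(seed)
    acc = np.empty((n, length), dtype=np.uint8)
    count = 0
    attempts = 0
    while count < n:
        attempts += 1
        if attempts > 1000 * n + 1000:
            raise ValueError(
                f"failed to draw {n} barcodes of length {length} at min distance "
                f"{min_distance}; whitelist too dense"
            )
        cand = _BASES[rng.integers(0, 4, size=length)]
        if count and int((acc[:count] != cand).sum(axis=1).min()) < min_distance:
            continue
        acc[count] = cand
        count += 1
    return [row.tobytes().decode("ascii") for row in acc]


@dataclass
class TruthSet:
    """Planted ground truth of one simulated experiment."""

    cell_barcodes: set[str]
    ambient_barcodes: set[str]
    fragments: pd.DataFrame  # chrom, start, end, barcode, n_reads
    peaks: FeatureSet
    reference: Reference
    params: dict = field(default_factory=dict)
    barcode_errors: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.cell_barcodes & self.ambient_barcodes:
            raise ValueError("cell and ambient barcode sets overlap")
        if len(self.fragments):
            if not (self.fragments.start < self.fragments.end).all():
                raise ValueError("truth fragment with start >= end")
            for chrom, sub in self.fragments.groupby("chrom"):
                L = self.reference.chrom_sizes[chrom]
                if int(sub.start.min()) < 0 or int(sub.end.max()) > L:
                    raise ValueError(f"truth fragment outside contig {chrom}")

    @property
    def whitelist(self) -> list[str]:
        return sorted(self.cell_barcodes | self.ambient_barcodes)

    @property
    def n_read_pairs(self) -> int:
        return int(self.fragments.n_reads.sum()) if len(self.fragments) else 0

    def write_tables(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fragments.to_csv(outdir / "true_fragments.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "barcode": sorted(self.cell_barcodes) + sorted(self.ambient_barcodes),
                "kind": ["cell"] * len(self.cell_barcodes)
                + ["ambient"] * len(self.ambient_barcodes),
            }
        ).to_csv(outdir / "true_barcodes.tsv", sep="\t", index=False)
        self.peaks.to_bed(outdir / "planted_peaks.bed")


def _merged_peak_arrays(peaks: FeatureSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, (_, starts, ends, _) in peaks._by_chrom.items():
        out[chrom] = (starts, ends)
    return out


def simulate_experiment(
    reference: Reference,
    peaks: FeatureSet,
    n_cells: int = 500,
    n_ambient: int = 5000,
    frags_per_cell_range: tuple[int, int] = (500, 2000),
    frags_per_ambient_range: tuple[int, int] = (1, 50),
    frip_cell: float = 0.7,
    frip_ambient: float = 0.05,
    dup_rate: float = 0.1,
    barcode_len: int = 16,
    fragment_size_range: tuple[int, int] = (100, 400),
    seed: int = 0,
    whitelist_min_distance: int = 3,
) -> TruthSet:
    """Plant an experiment: cells vs ambient background over a peak landscape.

    Each barcode draws its fragment count uniformly from its class range; each
    fragment lands inside a peak with probability equal to its class FRiP
    (overlapping a uniformly chosen peak by >= 1 bp) and otherwise uniformly
    in peak-free genome.  A ``dup_rate`` share of fragments is sequenced 2-4
    times; the rest once.  Independently placed fragments that collide on
    (chrom, start, end, barcode) are merged in the truth table with summed
    read support, so the truth is the exact fixed point of duplicate
    collapsing.
    """
    if not (0 <= frip_cell <= 1 and 0 <= frip_ambient <= 1 and 0 <= dup_rate <= 1):
        raise ValueError("fractions must be within [0, 1]")
    if barcode_len < 4:
        raise ValueError("barcode_len must be >= 4")
    if n_cells + n_ambient > 4**barcode_len:
        raise ValueError(
            f"{n_cells + n_ambient} barcodes exceed the 4^{barcode_len} barcode space"
        )
    rng = np.random.default_rng(seed)
    barcodes = random_barcodes(
        n_cells + n_ambient, barcode_len, int(rng.integers(2**31)),
        min_distance=whitelist_min_distance,
    )
    cell_bcs, ambient_bcs = barcodes[:n_cells], barcodes[n_cells:]
    chroms = list(reference.chrom_sizes)
    lengths = np.array([reference.chrom_sizes[c] for c in chroms], dtype=np.int64)
    empty = pd.DataFrame(columns=["chrom", "start", "end", "barcode", "n_reads"])
    params = {
        "n_cells": n_cells, "n_ambient": n_ambient,
        "frags_per_cell_range": list(frags_per_cell_range),
        "frags_per_ambient_range": list(frags_per_ambient_range),
        "frip_cell": frip_cell, "frip_ambient": frip_ambient,
        "dup_rate": dup_rate, "barcode_len": barcode_len,
        "fragment_size_range": list(fragment_size_range), "seed": seed,
    }
    if n_cells + n_ambient == 0 or not chroms:
        return TruthSet(set(cell_bcs), set(ambient_bcs), empty, peaks, reference, params)

    n_frags = np.concatenate([
        rng.integers(frags_per_cell_range[0], frags_per_cell_range[1] + 1, n_cells),
        rng.integers(frags_per_ambient_range[0], frags_per_ambient_range[1] + 1, n_ambient),
    ])
    N = int(n_frags.sum())
    if N == 0:
        return TruthSet(set(cell_bcs), set(ambient_bcs), empty, peaks, reference, params)
    bc_idx = np.repeat(np.arange(n_cells + n_ambient), n_frags)
    frip = np.where(bc_idx < n_cells, frip_cell, frip_ambient)
    smin, smax = fragment_size_range
    sizes = rng.integers(smin, smax + 1, N)
    in_peak = rng.random(N) < frip
    if len(peaks) == 0:
        in_peak[:] = False

    chrom_code = np.empty(N, dtype=np.int64)
    starts = np.empty(N, dtype=np.int64)
    chrom_to_code = {c: i for i, c in enumerate(chroms)}

    # fragments planted inside peaks: pick a peak, then a start that overlaps it
    idx_in = np.flatnonzero(in_peak)
    if idx_in.size:
        p_chrom = peaks.df.chrom.map(chrom_to_code).to_numpy(np.int64)
        p_start = peaks.df.start.to_numpy(np.int64)
        p_end = peaks.df.end.to_numpy(np.int64)
        which = rng.integers(0, len(peaks), idx_in.size)
        sz = sizes[idx_in]
        L = lengths[p_chrom[which]]
        lo = np.maximum(TN5_SHIFT_LEFT, p_start[which] - sz + 1)
        hi = np.minimum(L - TN5_SHIFT_RIGHT - sz, p_end[which] - 1)
        hi = np.maximum(hi, lo)
        starts[idx_in] = lo + (rng.random(idx_in.size) * (hi - lo + 1)).astype(np.int64)
        chrom_code[idx_in] = p_chrom[which]

    # background fragments: uniform over the genome, rejected out of peaks
    idx_out = np.flatnonzero(~in_peak)
    if idx_out.size:
        cc = rng.choice(len(chroms), size=idx_out.size, p=lengths / lengths.sum())
        sz = sizes[idx_out]
        L = lengths[cc]
        span = np.maximum(L - TN5_SHIFT_LEFT - TN5_SHIFT_RIGHT - sz + 1, 1)
        st = TN5_SHIFT_LEFT + (rng.random(idx_out.size) * span).astype(np.int64)
        peak_arrays = _merged_peak_arrays(peaks)
        for _ in range(200):
            bad = np.zeros(idx_out.size, dtype=bool)
            for ci, c in enumerate(chroms):
                if c not in peak_arrays:
                    continue
                ps, pe = peak_arrays[c]
                m = cc == ci
                if not m.any():
                    continue
                s, e = st[m], st[m] + sz[m]
                first = np.searchsorted(pe, s, side="right")
                last = np.searchsorted(ps, e, side="left") - 1
                bad[m] = last >= first
            if not bad.any():
                break
            st[bad] = TN5_SHIFT_LEFT + (rng.random(int(bad.sum())) * span[bad]).astype(np.int64)
        starts[idx_out] = st
        chrom_code[idx_out] = cc

    n_reads = np.ones(N, dtype=np.int64)
    dup = rng.random(N) < dup_rate
    n_reads[dup] = rng.integers(2, 5, int(dup.sum()))

    bc_arr = np.array(barcodes, dtype=object)
    df = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[chrom_code],
            "start": starts,
            "end": starts + sizes,
            "barcode": bc_arr[bc_idx],
            "n_reads": n_reads,
        }
    )
    df = df.groupby(["chrom", "start", "end", "barcode"], as_index=False, sort=False)[
        "n_reads"
    ].sum()
    key = chrom_rank(chroms)
    df = df.sort_values(
        ["chrom", "start", "end", "barcode"],
        key=lambda col: col.map(key) if col.name == "chrom" else col,
    ).reset_index(drop=True)
    return TruthSet(set(cell_bcs), set(ambient_bcs), df, peaks, reference, params)


# ---------------------------------------------------------------------------
# independent brute-force demultiplexing oracle


def brute_force_partition(
    observed: list[str], quals: list[str], whitelist: list[str]
) -> list[tuple[str, str | None]]:
    """Expected (category, assigned barcode) per read, by exhaustive Hamming scan.

    Independent of the correction implementation under test: full distance
    matrix against the whitelist, Hamming-1 candidates enumerated explicitly,
    multi-candidate cases resolved by the lowest Q score at the mismatch
    position, ties discarded.  Categories: complete_match / partial_match /
    no_match.
    """
    if not whitelist:
        return [("no_match", None)] * len(observed)
    length = len(whitelist[0])
    wl_mat = encode_seqs(whitelist, length)
    out: list[tuple[str, str | None]] = []
    chunk = max(1, 2**22 // max(1, wl_mat.size))
    for lo in range(0, len(observed), chunk):
        obs = observed[lo : lo + chunk]
        mat = encode_seqs(obs, length)
        dist = (mat[:, None, :] != wl_mat[None, :, :]).sum(axis=2)
        for row, bc in enumerate(obs):
            d = dist[row]
            if d.min() == 0:
                out.append(("complete_match", bc))
                continue
            cand = np.flatnonzero(d == 1)
            if cand.size == 0:
                out.append(("no_match", None))
                continue
            q = np.frombuffer(quals[lo + row].encode(), dtype=np.uint8).astype(int) - 33
            best_bc, best_q, tie = None, None, False
            for ci in cand:
                pos = int(np.flatnonzero(wl_mat[ci] != mat[row])[0])
                qv = int(q[pos])
                if best_q is None or qv < best_q:
                    best_bc, best_q, tie = whitelist[int(ci)], qv, False
                elif qv == best_q:
                    tie = True
            if tie:
                out.append(("no_match", None))
            else:
                out.append(("partial_match", best_bc))
    return out


# ---------------------------------------------------------------------------
# read / alignment emission


@dataclass
class ReadEmission:
    """Paths and expectations for one emitted read set."""

    mode: str
    r1: str
    r2: str
    index_fastq: str | None
    barcode_csv: str | None
    whitelist: str
    expected: pd.DataFrame  # read_id, true/observed barcode, expected category

    @property
    def expected_counts(self) -> dict[str, int]:
        counts = self.expected.expected_category.value_counts().to_dict()
        return {
            c: int(counts.get(c, 0))
            for c in ("complete_match", "partial_match", "no_match")
        }


def _expand_reads(truth: TruthSet) -> pd.DataFrame:
    frs = truth.fragments
    reps = frs.n_reads.to_numpy()
    idx = np.repeat(np.arange(len(frs)), reps)
    copy_no = np.arange(idx.size) - np.repeat(np.cumsum(reps) - reps, reps)
    df = frs.iloc[idx].reset_index(drop=True)
    df["read_id"] = [f"frag{i:07d}:{j}" for i, j in zip(idx, copy_no)]
    return df


def emit_reads(
    truth: TruthSet,
    outdir,
    mode: str = "index-fastq",
    barcode_error_rate: float = 0.0,
    seed: int = 0,
    read_len: int = 50,
    gzip_output: bool = False,
    barcode_qual_range: tuple[int, int] = (20, 41),
) -> ReadEmission:
    """Emit FASTQ read pairs (plus whitelist and expected demux partition).

    Every true fragment yields ``n_reads`` identical read pairs whose
    alignment coordinates invert the +4/−5 Tn5 shift.  A
    ``barcode_error_rate`` share of reads carries exactly one substituted
    barcode base.  ``mode`` selects the barcode layout: a complementary index
    FASTQ, or the barcode spliced onto the front of R1 with a CSV describing
    the position.
    """
    if mode not in ("index-fastq", "embedded"):
        raise ValueError(f"unknown read-emission mode: {mode!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    reads = _expand_reads(truth)
    n = len(reads)
    bc_len = truth.params.get("barcode_len") or (
        len(next(iter(truth.whitelist))) if truth.whitelist else 0
    )

    true_bc = reads.barcode.tolist() if n else []
    observed = list(true_bc)
    err_pos = np.full(n, -1, dtype=int)
    if n:
        err = np.flatnonzero(rng.random(n) < barcode_error_rate)
        for i in err:
            pos = int(rng.integers(0, bc_len))
            old = observed[i][pos]
            new = "ACGT".replace(old, "")[int(rng.integers(0, 3))]
            observed[i] = observed[i][:pos] + new + observed[i][pos + 1 :]
            err_pos[i] = pos
            truth.barcode_errors[reads.read_id.iat[i]] = (true_bc[i], pos)

    qlo, qhi = barcode_qual_range
    bc_quals = [
        ints_to_quals(rng.integers(qlo, qhi, bc_len)) for _ in range(n)
    ]
    read_qual = "I" * read_len

    suffix = ".fastq.gz" if gzip_output else ".fastq"
    r1_path = str(outdir / f"reads_R1{suffix}")
    r2_path = str(outdir / f"reads_R2{suffix}")
    index_path = str(outdir / f"reads_index{suffix}") if mode == "index-fastq" else None
    csv_path = str(outdir / "barcode_positions.csv") if mode == "embedded" else None

    seqs = truth.reference.sequences
    writers = [FastqWriter(r1_path), FastqWriter(r2_path)]
    w_idx = FastqWriter(index_path) if index_path else None
    try:
        for i in range(n):
            chrom = reads.chrom.iat[i]
            start = int(reads.start.iat[i])
            end = int(reads.end.iat[i])
            raw_start = start - TN5_SHIFT_LEFT
            raw_end = end + TN5_SHIFT_RIGHT
            ref = seqs[chrom]
            s1 = ref[raw_start : raw_start + read_len]
            s2 = revcomp(ref[raw_end - read_len : raw_end])
            rid = reads.read_id.iat[i]
            if mode == "index-fastq":
                writers[0].write(rid, s1, read_qual)
                w_idx.write(rid, observed[i], bc_quals[i])
            else:
                writers[0].write(rid, observed[i] + s1, bc_quals[i] + read_qual)
            writers[1].write(rid, s2, read_qual)
    finally:
        for w in writers:
            w.close()
        if w_idx:
            w_idx.close()

    whitelist = truth.whitelist
    wl_path = str(outdir / "whitelist.txt")
    with open(wl_path, "w") as fh:
        fh.write("\n".join(whitelist) + ("\n" if whitelist else ""))
    if csv_path:
        with open(csv_path, "w") as fh:
            fh.write(f"R1,0,{bc_len}\n")

    oracle = brute_force_partition(observed, bc_quals, whitelist)
    expected = pd.DataFrame(
        {
            "read_id": reads.read_id if n else pd.Series(dtype=object),
            "true_barcode": true_bc,
            "observed_barcode": observed,
            "error_position": err_pos,
            "expected_category": [o[0] for o in oracle],
            "expected_barcode": [o[1] for o in oracle],
        }
    )
    expected.to_csv(outdir / "expected_partition.tsv", sep="\t", index=False)
    return ReadEmission(
        mode, r1_path, r2_path, index_path, csv_path, wl_path, expected
    )


def emit_bam(
    truth: TruthSet,
    path,
    read_len: int = 50,
    tagged: bool = False,
    separator: str = "#",
    seed: int = 0,
) -> str:
    """Write a coordinate-sorted BAM of proper pairs reconstructing the truth.

    Read names are barcode-prefixed (``BARCODE#fragNNN:i``), i.e. the state
    reads are in after demultiplexing and external alignment; with
    ``tagged=True`` the CB:Z tag is set as well, skipping the tagging step.
    """
    path = str(path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    reads = _expand_reads(truth)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": c, "LN": int(L)} for c, L in truth.reference.chrom_sizes.items()
        ],
    }
    tid = {c: i for i, c in enumerate(truth.reference.chrom_sizes)}
    unsorted = path + ".unsorted.bam"
    qual = pysam.qualitystring_to_array("I" * read_len)
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for row in reads.itertuples(index=False):
            raw_start = int(row.start) - TN5_SHIFT_LEFT
            raw_end = int(row.end) + TN5_SHIFT_RIGHT
            ref = truth.reference.sequences[row.chrom]
            name = f"{row.barcode}{separator}{row.read_id}"
            for is_r2 in (False, True):
                a = pysam.AlignedSegment()
                a.query_name = name
                a.reference_id = tid[row.chrom]
                a.mapping_quality = 60
                a.cigartuples = [(0, read_len)]
                if not is_r2:
                    a.flag = 99
                    a.reference_start = raw_start
                    a.next_reference_start = raw_end - read_len
                    a.template_length = raw_end - raw_start
                    a.query_sequence = ref[raw_start : raw_start + read_len]
                else:
                    a.flag = 147
                    a.reference_start = raw_end - read_len
                    a.next_reference_start = raw_start
                    a.template_length = -(raw_end - raw_start)
                    a.query_sequence = revcomp(ref[raw_end - read_len : raw_end])
                a.next_reference_id = tid[row.chrom]
                a.query_qualities = qual
                if tagged:
                    a.set_tag("CB", row.barcode, value_type="Z")
                bam.write(a)
    pysam.sort("-o", path, unsorted)
    Path(unsorted).unlink()
    pysam.index(path)
    return path


# ---------------------------------------------------------------------------
# colliding-whitelist fixture for the Q-score tie-break


@dataclass
class CollidingFixture:
    r1: str
    r2: str
    index_fastq: str
    whitelist: str
    whitelist_barcodes: list[str]
    expected: pd.DataFrame  # read_id, observed, quals, candidates, expectation


def make_colliding_fixture(
    outdir,
    n_pairs: int = 10,
    n_reads: int = 400,
    barcode_len: int = 12,
    tie_fraction: float = 0.3,
    seed: int = 0,
    read_len: int = 50,
) -> CollidingFixture:
    """Whitelist of distance-2 barcode pairs forcing two-candidate corrections.

    Each emitted read's observed barcode sits at Hamming distance 1 from both
    members of one pair, mismatching them at two *distinct* positions; the
    base-call qualities at those positions either differ (min-Q resolvable)
    or are equal (``tie_fraction`` of reads, expected ambiguous).  Pairs are
    kept at distance >= 4 from all other whitelist entries so no third
    candidate can appear.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries: list[str] = []
    pairs: list[tuple[str, str, int, int]] = []
    mat = np.empty((2 * n_pairs, barcode_len), dtype=np.uint8)
    count = 0
    while len(pairs) < n_pairs:
        a = _BASES[rng.integers(0, 4, barcode_len)]
        p1, p2 = sorted(rng.choice(barcode_len, size=2, replace=False).tolist())
        b = a.copy()
        for p in (p1, p2):
            b[p] = _BASES[(np.searchsorted(_BASES, b[p]) + 1 + rng.integers(0, 3)) % 4]
        if count:
            prev = mat[:count]
            if int((prev != a).sum(axis=1).min()) < 4 or int(
                (prev != b).sum(axis=1).min()
            ) < 4:
                continue
        mat[count], mat[count + 1] = a, b
        count += 2
        pairs.append((a.tobytes().decode(), b.tobytes().decode(), p1, p2))
        entries.extend(pairs[-1][:2])

    wl_path = str(outdir / "whitelist.txt")
    with open(wl_path, "w") as fh:
        fh.write("\n".join(entries) + "\n")

    rows = []
    r1_path, r2_path = str(outdir / "reads_R1.fastq"), str(outdir / "reads_R2.fastq")
    idx_path = str(outdir / "reads_index.fastq")
    with FastqWriter(r1_path) as w1, FastqWriter(r2_path) as w2, FastqWriter(
        idx_path
    ) as wi:
        for r in range(n_reads):
            a, b, p1, p2 = pairs[int(rng.integers(0, n_pairs))]
            # observed = a with position p1 flipped to b's base: distance 1
            # from a (mismatch at p1) and 1 from b (mismatch at p2)
            observed = a[:p1] + b[p1] + a[p1 + 1 :]
            q = rng.integers(20, 41, barcode_len)
            if rng.random() < tie_fraction:
                q[p2] = q[p1]
                expected_cat, expected_bc = "no_match", None
            else:
                while q[p1] == q[p2]:
                    q[p2] = rng.integers(20, 41)
                if q[p1] < q[p2]:
                    expected_cat, expected_bc = "partial_match", a
                else:
                    expected_cat, expected_bc = "partial_match", b
            quals = ints_to_quals(q)
            rid = f"read{r:05d}"
            seq = _BASES[rng.integers(0, 4, read_len)].tobytes().decode()
            w1.write(rid, seq, "I" * read_len)
            w2.write(rid, revcomp(seq), "I" * read_len)
            wi.write(rid, observed, quals)
            rows.append(
                (rid, observed, quals, a, b, p1, p2, expected_cat, expected_bc)
            )
    expected = pd.DataFrame(
        rows,
        columns=[
            "read_id", "observed", "quals", "candidate_a", "candidate_b",
            "mismatch_pos_a", "mismatch_pos_b", "expected_category",
            "expected_barcode",
        ],
    )
    expected.to_csv(outdir / "expected_tiebreak.tsv", sep="\t", index=False)
    return CollidingFixture(r1_path, r2_path, idx_path, wl_path, entries, expected)
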