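"""Feature spaces and fragment-by-feature counting.

The matrix rows are genomic intervals: either fixed-width genome bins tiling
every contig (sensitive to rare open regions at the cost of many features) or
a supplied peak/feature BED.  An entry counts the *distinct* deduplicated
fragments of a barcode overlapping a feature by at least one base, in 0-based
half-open coordinates; the read-support column of the fragment file never
inflates counts, since PCR duplicates carry no extra accessibility evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import chrom_rank, open_text


@dataclass
class FeatureSet:
    """Ordered genomic intervals defining the rows of the count matrix.

    ``df`` has columns chrom/start/end/id, sorted by (contig order, start,
    end); ids are unique.  ``origin`` records how the set was built
    (``genome_bin`` | ``bed`` | ``external_peaks``).
    """

    df: pd.DataFrame
    origin: str = "bed"
    bin_size: int | None = None
    chrom_order: list[str] | None = None
    _by_chrom: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        if len(df):
            key = chrom_rank(self.chrom_order)
            order = sorted(
                range(len(df)),
                key=lambda i: (key(df.chrom.iat[i]), df.start.iat[i], df.end.iat[i]),
            )
            df = df.iloc[order].reset_index(drop=True)
        if df.id.duplicated().any():
            dup = df.id.duplicated(keep=False)
            suffix = df.groupby("id").cumcount()
            df.loc[dup, "id"] = df.id[dup] + "." + suffix[dup].astype(str)
        self.df = df
        # per-chrom (row offset, starts, ends, disjoint?) cache for fast overlap
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub.start.to_numpy(np.int64)
            ends = sub.end.to_numpy(np.int64)
            disjoint = bool(np.all(starts[1:] >= ends[:-1])) if len(sub) > 1 else True
            self._by_chrom[chrom] = (int(sub.index[0]), starts, ends, disjoint)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df.id.tolist()

    def intervals(self):
        return list(self.df.itertuples(index=False, name=None))

    def to_bed(self, path) -> None:
        self.df[["chrom", "start", "end", "id"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def make_bins(chrom_sizes: dict[str, int], bin_size: int) -> FeatureSet:
    """Tile every contig with fixed-width bins; the last bin is truncated."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    df["id"] = df.chrom + ":" + df.start.astype(str) + "-" + df.end.astype(str)
    return FeatureSet(df, origin="genome_bin", bin_size=bin_size,
                      chrom_order=list(chrom_sizes))


def load_features(bed_path, chrom_sizes: dict[str, int]) -> FeatureSet:
    """Read a 3+ column BED as a FeatureSet, clipping intervals to contig bounds.

    Intervals on contigs absent from ``chrom_sizes`` are skipped (counted and
    warned about); overlapping peaks are kept as-is with a warning.
    """
    rows = []
    n_skipped = 0
    with open_text(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{bed_path}:{lineno}: start {start} >= end {end}")
            if chrom not in chrom_sizes:
                n_skipped += 1
                continue
            end = min(end, chrom_sizes[chrom])
            start = max(start, 0)
            if start < end:
                rows.append((chrom, start, end))
    if n_skipped:
        warnings.warn(f"{bed_path}: skipped {n_skipped} intervals on unknown contigs")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["id"] = df.chrom + ":" + df.start.astype(str) + "-" + df.end.astype(str)
    fs = FeatureSet(df, origin="bed", chrom_order=list(chrom_sizes))
    if any(not disjoint for (_, _, _, disjoint) in fs._by_chrom.values()):
        warnings.warn(f"{bed_path}: overlapping features kept as-is (not merged)")
    fs.n_skipped = n_skipped
    return fs


@dataclass
class SparseCountMatrix:
    """Feature × barcode sparse counts with explicit row/column labels."""

    matrix: sp.csr_matrix
    feature_ids: list[str]
    barcodes: list[str]
    binarized: bool = False
    n_skipped_fragments: int = 0

    @property
    def shape(self):
        return self.matrix.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def features_per_barcode(self) -> np.ndarray:
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()


def binarize(m: SparseCountMatrix) -> SparseCountMatrix:
    """Presence/absence view: entries > 0 become 1. Idempotent."""
    b = m.matrix.copy()
    b.data = (b.data > 0).astype(b.data.dtype)
    b.eliminate_zeros()
    return SparseCountMatrix(b, list(m.feature_ids), list(m.barcodes), binarized=True,
                             n_skipped_fragments=m.n_skipped_fragments)


def _overlap_ranges(starts: np.ndarray, ends: np.ndarray, s: np.ndarray, e: np.ndarray):
    """For disjoint sorted features, the index range [first, last] overlapping [s, e)."""
    first = np.searchsorted(ends, s, side="right")
    last = np.searchsorted(starts, e, side="left") - 1
    return first, last


def count_matrix(
    fragments,
    features: FeatureSet,
    barcodes: list[str] | None = None,
) -> SparseCountMatrix:
    """Overlap fragments against features into the raw feature × barcode matrix.

    ``fragments`` is a fragment DataFrame (chrom/start/end/barcode[/count]) or
    a path to a fragment BED.  A fragment overlapping k features contributes 1
    to each of the k entries in its barcode's column.  Fragments on contigs
    outside the feature universe are tallied as skipped, not errors.
    """
    from .fragments import read_fragments

    df = fragments if isinstance(fragments, pd.DataFrame) else read_fragments(fragments)
    if barcodes is None:
        barcodes = sorted(df.barcode.unique()) if len(df) else []
    bc_index = {b: i for i, b in enumerate(barcodes)}
    n_feat, n_bc = len(features), len(barcodes)

    rows_acc: list[np.ndarray] = []
    cols_acc: list[np.ndarray] = []
    n_skipped = 0
    chrom_universe = set(features._by_chrom)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in chrom_universe:
            n_skipped += len(sub)
            continue
        offset, f_starts, f_ends, disjoint = features._by_chrom[chrom]
        s = sub.start.to_numpy(np.int64)
        e = sub.end.to_numpy(np.int64)
        codes = np.array([bc_index[b] for b in sub.barcode], dtype=np.int64)
        if disjoint:
            first, last = _overlap_ranges(f_starts, f_ends, s, e)
            k = np.maximum(last - first + 1, 0)
            hit = k > 0
            tot = k[hit]
            if tot.size:
                base = np.repeat(first[hit], tot)
                within = np.arange(tot.sum()) - np.repeat(np.cumsum(tot) - tot, tot)
                rows_acc.append(offset + base + within)
                cols_acc.append(np.repeat(codes[hit], tot))
        else:
            from intervaltree import IntervalTree

            tree = IntervalTree()
            for i, (fs_, fe_) in enumerate(zip(f_starts, f_ends)):
                tree.addi(int(fs_), int(fe_), offset + i)
            r, c = [], []
            for si, ei, ci in zip(s, e, codes):
                for iv in tree.overlap(int(si), int(ei)):
                    r.append(iv.data)
                    c.append(int(ci))
            if r:
                rows_acc.append(np.asarray(r, dtype=np.int64))
                cols_acc.append(np.asarray(c, dtype=np.int64))

    if rows_acc:
        rows = np.concatenate(rows_acc)
        cols = np.concatenate(cols_acc)
        mat = sp.coo_matrix(
            (np.ones(rows.size, dtype=np.int64), (rows, cols)), shape=(n_feat, n_bc)
        ).tocsr()
        mat.sum_duplicates()
    else:
        mat = sp.csr_matrix((n_feat, n_bc), dtype=np.int64)
    return SparseCountMatrix(mat, features.ids, list(barcodes),
                             n_skipped_fragments=n_skipped)
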