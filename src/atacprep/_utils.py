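"""Small shared helpers: sequence encoding, FASTQ writing, chromosome ordering."""

from __future__ import annotations

import gzip
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Phred+33 offset used throughout (Illumina 1.8+ convention).
PHRED_OFFSET = 33


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seqs(seqs: Sequence[str], length: int) -> np.ndarray:
    """Pack equal-length sequences into a (n, length) uint8 byte matrix."""
    if len(seqs) == 0:
        return np.empty((0, length), dtype=np.uint8)
    buf = "".join(seqs).encode("ascii")
    if len(buf) != len(seqs) * length:
        raise ValueError(f"sequences are not all of length {length}")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(seqs), length)


def decode_seq(row: np.ndarray) -> str:
    return row.tobytes().decode("ascii")


def quals_to_ints(quals: str | Sequence[int]) -> np.ndarray:
    """Normalise a quality string (Phred+33) or integer sequence to an int array."""
    if isinstance(quals, str):
        return np.frombuffer(quals.encode("ascii"), dtype=np.uint8).astype(int) - PHRED_OFFSET
    return np.asarray(quals, dtype=int)


def ints_to_quals(q: Iterable[int]) -> str:
    return "".join(chr(int(v) + PHRED_OFFSET) for v in q)


def open_text(path, mode: str = "rt") -> IO[str]:
    """Open plain or gzip-compressed text transparently, based on the suffix."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class FastqWriter:
    """Minimal 4-line FASTQ record writer (gz-aware). Context manager."""

    def __init__(self, path):
        self.path = str(path)
        self._fh = open_text(path, "wt")

    def write(self, name: str, seq: str, qual: str) -> None:
        self._fh.write(f"@{name}\n{seq}\n+\n{qual}\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_chrom_sizes(path) -> dict[str, int]:
    """Load a 2-column chrom.sizes TSV into an ordered name -> length map."""
    sizes: dict[str, int] = {}
    with open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def chrom_rank(chrom_order: Sequence[str] | None):
    """Sort key for contig names: position in the declared order, else lexicographic.

    Contigs absent from the declared order sort after the known ones.
    """
    if chrom_order is None:
        return lambda c: (0, "", c)
    index = {c: i for i, c in enumerate(chrom_order)}
    n = len(index)

    def key(c: str):
        i = index.get(c)
        return (0, i, "") if i is not None else (1, n, c)

    return key
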