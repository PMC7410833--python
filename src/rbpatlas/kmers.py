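"""Integer-encoded RNA sequence pools and overlapping k-mer counting.

Sequences are stored as int8 arrays with A,C,G,U -> 0..3 and a sentinel
value (-1) for masked positions.  Overlapping k-mer occurrences are always
counted; any window containing a sentinel contributes to no k-mer, so a
masked stretch can never seed a chimeric k-mer across its boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

RNA_ALPHABET = "ACGU"
MASK = np.int8(-1)

_CHAR_TO_INT = {c: i for i, c in enumerate(RNA_ALPHABET)}
_CHAR_TO_INT["T"] = _CHAR_TO_INT["U"]


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string (T treated as U) to an int8 array."""
    try:
        return np.array([_CHAR_TO_INT[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-ACGT/U character in sequence: {exc}") from None


def decode(arr: np.ndarray) -> str:
    return "".join(RNA_ALPHABET[i] if i >= 0 else "N" for i in arr)


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for c in kmer.upper():
        idx = idx * 4 + _CHAR_TO_INT[c]
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(RNA_ALPHABET[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    return [index_to_kmer(i, k) for i in range(4**k)]


def window_codes(reads: np.ndarray, k: int) -> np.ndarray:
    """Per-window k-mer codes for a (n_reads, L) int8 array.

    Windows containing a masked position get code -1.
    Returns an (n_reads, L - k + 1) int64 array.
    """
    if reads.ndim != 2:
        raise ValueError("reads must be a 2-D (n_reads, L) array")
    n, L = reads.shape
    if L < k:
        return np.empty((n, 0), dtype=np.int64)
    codes = np.zeros((n, L - k + 1), dtype=np.int64)
    bad = np.zeros((n, L - k + 1), dtype=bool)
    for j in range(k):
        col = reads[:, j : j + L - k + 1]
        codes = codes * 4 + np.maximum(col, 0)
        bad |= col < 0
    codes[bad] = -1
    return codes


def count_kmers(reads: np.ndarray, k: int) -> np.ndarray:
    """Overlapping k-mer occurrence counts (length 4**k) for a read pool."""
    codes = window_codes(reads, k)
    flat = codes[codes >= 0]
    return np.bincount(flat, minlength=4**k).astype(np.int64)


def mask_kmer(reads: np.ndarray, kmer: str) -> int:
    """Mask (in place) every occurrence of ``kmer``; returns #occurrences masked."""
    k = len(kmer)
    codes = window_codes(reads, k)
    target = kmer_to_index(kmer)
    rows, cols = np.nonzero(codes == target)
    for j in range(k):
        reads[rows, cols + j] = MASK
    return len(rows)


class ReadPool:
    """A pool of equal-length reads held as an (n, L) int8 array."""

    def __init__(self, array: np.ndarray):
        array = np.asarray(array, dtype=np.int8)
        if array.ndim != 2:
            raise ValueError("ReadPool requires a 2-D array")
        self.array = array

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "ReadPool":
        """Build a pool; unequal lengths are right-padded with the mask sentinel."""
        rows = [encode(s) for s in seqs]
        if not rows:
            return cls(np.empty((0, 0), dtype=np.int8))
        width = max(len(r) for r in rows)
        arr = np.full((len(rows), width), MASK, dtype=np.int8)
        for i, r in enumerate(rows):
            arr[i, : len(r)] = r
        return cls(arr)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReadPool":
        from Bio import SeqIO

        return cls.from_sequences(str(r.seq) for r in SeqIO.parse(str(path), "fasta"))

    def __len__(self) -> int:
        return self.array.shape[0]

    @property
    def read_length(self) -> int:
        return self.array.shape[1]

    def sequences(self) -> Iterator[str]:
        for row in self.array:
            # trailing sentinel is length padding, not masked sequence
            end = len(row)
            while end > 0 and row[end - 1] == MASK:
                end -= 1
            yield decode(row[:end])

    def to_fasta(self, path: str | Path, prefix: str = "read") -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences()):
                fh.write(f">{prefix}_{i}\n{seq}\n")

    def copy(self) -> "ReadPool":
        return ReadPool(self.array.copy())

    def split_halves(self) -> tuple["ReadPool", "ReadPool"]:
        half = len(self) // 2
        return ReadPool(self.array[:half]), ReadPool(self.array[half:])
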