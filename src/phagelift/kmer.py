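"""Strand-aware k-mer counting over dense 4^k vectors.

Every k-mer over {A,C,G,T} is indexed lexicographically (A<C<G<T) by its
2-bit encoding, so counts live in dense numpy arrays of length 4**k. A
sequence window containing N contributes nothing. With double-strand
counting (the default throughout the package) every valid forward window w
also contributes its reverse complement, i.e. both strands of the molecule
are counted; palindromes are not down-weighted.

The practical ceiling is k <= 12 (4^12 dense entries); the classifier
sweeps k up to 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MAX_K = 12

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class KmerCountVector:
    """Occurrence counts of all 4^k k-mers for one sequence set.

    ``effective_positions`` is the number of valid k-mer windows counted
    (both strands, all sequences) and always equals ``counts.sum()``.
    """

    k: int
    counts: np.ndarray
    effective_positions: int
    n_sequences: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (4**self.k,):
            raise ValueError(f"counts must have 4^{self.k} entries")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if int(c.sum()) != self.effective_positions:
            raise ValueError("sum of counts must equal effective_positions")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class FrequencyVector:
    """Relative k-mer frequencies f_w = X_w / sum_w X_w."""

    k: int
    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4**self.k,):
            raise ValueError(f"freqs must have 4^{self.k} entries")
        if (f < 0).any():
            raise ValueError("frequencies must be non-negative")
        object.__setattr__(self, "freqs", f)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a sequence to integer codes; non-ACGT becomes -1."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer string (A<C<G<T)."""
    codes = encode_sequence(kmer)
    if (codes < 0).any():
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT characters")
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    """Inverse of :func:`kmer_index`."""
    bases = []
    for _ in range(k):
        bases.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(bases))


@lru_cache(maxsize=MAX_K)
def revcomp_permutation(k: int) -> np.ndarray:
    """Index permutation mapping each k-mer index to its reverse complement."""
    idx = np.arange(4**k, dtype=np.int64)
    out = np.zeros_like(idx)
    rem = idx
    for _ in range(k):
        out = out * 4 + (3 - rem % 4)
        rem = rem // 4
    return out


def _forward_window_counts(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Counts of valid (N-free) forward windows and their number."""
    n = codes.size
    counts = np.zeros(4**k, dtype=np.int64)
    if n < k:
        return counts, 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return counts, 0
    weights = (4 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    idx = windows[valid] @ weights
    counts = np.bincount(idx, minlength=4**k).astype(np.int64)
    return counts, int(valid.sum())


def count_kmers(sequence_or_record, k: int, double_strand: bool = True) -> KmerCountVector:
    """Count every length-k window containing no N.

    Accepts a :class:`~phagelift.sequence_io.SequenceRecord` or a plain
    string. With ``double_strand`` the reverse-complement strand is counted
    as well, doubling ``effective_positions`` for an N-free sequence. A
    sequence shorter than k gives an all-zero vector (not an error).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    seq = getattr(sequence_or_record, "sequence", sequence_or_record)
    codes = encode_sequence(seq)
    fwd, n_windows = _forward_window_counts(codes, k)
    if double_strand:
        # each valid forward window w also appears as rc(w) on the other strand
        counts = fwd + fwd[revcomp_permutation(k)]
        eff = 2 * n_windows
    else:
        counts, eff = fwd, n_windows
    return KmerCountVector(k=k, counts=counts, effective_positions=eff, n_sequences=1)


def count_kmers_pooled(
    records: Iterable, k: int, double_strand: bool = True
) -> KmerCountVector:
    """Count k-mers across many sequences into one pooled vector."""
    vectors = [count_kmers(r, k, double_strand) for r in records]
    if not vectors:
        return KmerCountVector(k, np.zeros(4**k, dtype=np.int64), 0, 0)
    return pool_counts(vectors)


def pool_counts(vectors: Sequence[KmerCountVector]) -> KmerCountVector:
    """Element-wise sum of count vectors sharing the same k."""
    if not vectors:
        raise ValueError("cannot pool an empty list of count vectors")
    k = vectors[0].k
    if any(v.k != k for v in vectors):
        raise ValueError("all pooled vectors must share the same k")
    counts = np.sum([v.counts for v in vectors], axis=0)
    return KmerCountVector(
        k=k,
        counts=counts,
        effective_positions=sum(v.effective_positions for v in vectors),
        n_sequences=sum(v.n_sequences for v in vectors),
    )


def to_frequencies(v: KmerCountVector) -> FrequencyVector:
    """Relative frequencies; undefined (error) on an empty vector."""
    if v.effective_positions == 0:
        raise ValueError("frequencies undefined: no k-mer windows counted")
    return FrequencyVector(k=v.k, freqs=v.counts / v.effective_positions)


def write_counts_tsv(v: KmerCountVector, path: str | Path) -> None:
    """Export a count vector as a two-column (kmer, count) TSV."""
    with open(path, "w") as fh:
        fh.write("kmer\tcount\n")
        for i, c in enumerate(v.counts):
            fh.write(f"{index_to_kmer(i, v.k)}\t{int(c)}\n")
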