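"""Sparse n-mer counting and frequency encoding of nucleotide sequences.

A sequence is scanned with a sliding window of length ``n`` and overlap
``n - 1`` (positions 1..n, then 2..n+1, and so on).  Each window made
solely of A, C, G, T maps to an integer index via big-endian 2-bit
packing (A=0, C=1, G=2, T=3), yielding a sparse vector of counts in a
:math:`4^n`-dimensional space.  Counts are either normalized by the
number of counted windows, or add-one smoothed — pretending every
possible word occurred at least once, ``(count + 1) / (total + 4^n)`` —
which keeps every implicit coordinate strictly positive so that the
Kullback-Leibler divergence is always defined.

Windows containing any non-ACGT character are skipped and tallied in
``skipped`` (a warning is logged); a sequence whose every window is
skipped cannot be encoded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KmerCounts",
    "FrequencyVector",
    "count_kmers",
    "normalize",
    "smooth_add_one",
    "encode",
    "MAX_N",
]

logger = logging.getLogger(__name__)

#: Largest supported word length; 4**10 ≈ 1.05M implicit dimensions.
MAX_N = 10

# Base-to-code lookup over all 256 byte values; non-ACGT bytes map to -1.
_CODE = np.full(256, -1, dtype=np.int64)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c
for _b, _c in zip(b"acgt", range(4)):
    _CODE[_b] = _c


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded (empty, or no valid window)."""


@dataclass(frozen=True)
class KmerCounts:
    """Sparse occurrence counts of the n-mers of one sequence.

    Attributes
    ----------
    n : int
        Word length, 1..10.
    indices : numpy.ndarray
        Sorted packed-integer indices (in ``[0, 4**n)``) of observed words.
    counts : numpy.ndarray
        Occurrence count for each index; same length as ``indices``.
    total : int
        Number of windows counted; equals ``sum(counts)``.
    skipped : int
        Number of windows skipped because they contained a non-ACGT
        character.  ``total + skipped == max(L - n + 1, 0)``.
    """

    n: int
    indices: np.ndarray
    counts: np.ndarray
    total: int
    skipped: int

    @property
    def dim(self) -> int:
        return 4 ** self.n

    def as_dict(self) -> dict[int, int]:
        """Counts as a plain ``{index: count}`` mapping."""
        return {int(i): int(c) for i, c in zip(self.indices, self.counts)}


@dataclass(frozen=True)
class FrequencyVector:
    """Sparse n-mer frequency vector, the representation compared by all
    similarity measures.

    Only positions with a nonzero raw count are stored in
    ``indices``/``values``; every other implicit coordinate holds
    ``zero_value`` (0 for unsmoothed vectors, ``1 / (total + 4**n)``
    after add-one smoothing).  The implicit dense vector always sums
    to 1.
    """

    n: int
    indices: np.ndarray
    values: np.ndarray
    smoothed: bool
    zero_value: float = 0.0

    @property
    def dim(self) -> int:
        return 4 ** self.n

    def dense(self) -> np.ndarray:
        """Materialize the full 4**n vector (small n only; test/debug aid)."""
        out = np.full(self.dim, self.zero_value, dtype=float)
        out[self.indices] = self.values
        return out

    def as_dict(self) -> dict[int, float]:
        return {int(i): float(v) for i, v in zip(self.indices, self.values)}


def _validate_n(n: int) -> None:
    if not isinstance(n, (int, np.integer)) or n < 1 or n > MAX_N:
        raise ValueError(f"word length n must be an integer in 1..{MAX_N}, got {n!r}")


def kmer_to_index(word: str) -> int:
    """Pack an ACGT word into its big-endian 2-bit integer index."""
    idx = 0
    for ch in word.upper():
        code = _CODE[ord(ch)]
        if code < 0:
            raise ValueError(f"non-ACGT character {ch!r} in word {word!r}")
        idx = (idx << 2) | int(code)
    return idx


def index_to_kmer(index: int, n: int) -> str:
    """Inverse of :func:`kmer_to_index`."""
    _validate_n(n)
    return "".join("ACGT"[(index >> (2 * (n - 1 - i))) & 3] for i in range(n))


def count_kmers(sequence: str, n: int) -> KmerCounts:
    """Count overlapping n-mers of ``sequence``.

    Windows are taken at every position (overlap ``n - 1``); windows
    containing a character outside A/C/G/T (case-insensitive) are
    skipped and reported in :attr:`KmerCounts.skipped`.

    Raises
    ------
    ValueError
        If ``n`` is outside 1..10.
    EncodingError
        If the sequence is empty.
    """
    _validate_n(n)
    if not sequence:
        raise EncodingError("cannot count n-mers of an empty sequence")

    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n_windows = max(len(codes) - n + 1, 0)
    if n_windows == 0:
        return KmerCounts(
            n=n,
            indices=np.empty(0, dtype=np.int64),
            counts=np.empty(0, dtype=np.int64),
            total=0,
            skipped=0,
        )

    bad = codes < 0
    if bad.any():
        # A window is invalid iff it covers any bad position.
        bad_in_window = np.convolve(bad.astype(np.int64), np.ones(n, dtype=np.int64), mode="valid") > 0
    else:
        bad_in_window = np.zeros(n_windows, dtype=bool)

    # Window value = sum codes[i+j] * 4**(n-1-j): a correlation of the code
    # track with descending powers of 4.  np.convolve flips its kernel, so
    # pass the powers in ascending order.
    powers = 4 ** np.arange(n, dtype=np.int64)
    vals = np.convolve(np.where(bad, 0, codes), powers, mode="valid")

    good_vals = vals[~bad_in_window]
    skipped = int(bad_in_window.sum())
    if skipped:
        logger.warning("skipped %d window(s) containing non-ACGT characters", skipped)

    indices, counts = np.unique(good_vals, return_counts=True)
    return KmerCounts(
        n=n,
        indices=indices.astype(np.int64),
        counts=counts.astype(np.int64),
        total=int(counts.sum()),
        skipped=skipped,
    )


def normalize(counts: KmerCounts) -> FrequencyVector:
    """Divide each count by the total number of counted windows.

    Raises :class:`EncodingError` when ``total == 0`` (every window was
    skipped): such a sequence has no defined composition.
    """
    if counts.total == 0:
        raise EncodingError("sequence has no countable window; cannot normalize")
    return FrequencyVector(
        n=counts.n,
        indices=counts.indices,
        values=counts.counts / counts.total,
        smoothed=False,
        zero_value=0.0,
    )


def smooth_add_one(counts: KmerCounts) -> FrequencyVector:
    """Add-one smoothed frequencies: ``(count_i + 1) / (total + 4**n)``.

    Every implicit coordinate is strictly positive; zero-count positions
    all share the scalar ``1 / (total + 4**n)`` stored in
    :attr:`FrequencyVector.zero_value`, so the representation stays
    sparse even at n = 10.
    """
    denom = counts.total + counts.dim
    return FrequencyVector(
        n=counts.n,
        indices=counts.indices,
        values=(counts.counts + 1) / denom,
        smoothed=True,
        zero_value=1.0 / denom,
    )


def encode(sequence: str, n: int, smoothed: bool = False) -> FrequencyVector:
    """Count and normalize in one step; ``smoothed`` selects add-one smoothing."""
    counts = count_kmers(sequence, n)
    return smooth_add_one(counts) if smoothed else normalize(counts)
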