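"""Shared k-mer machinery: alphabet, encoding, counting.

All counting in the package goes through these helpers so that the
overlapping, step-1, optionally both-strand convention is applied uniformly
to hexamer features, triplet pairs and the significance analysis.
"""

from __future__ import annotations

import itertools

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_CODE = {b: i for i, b in enumerate(BASES)}


def reverse_complement(residues: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    invalid = set(residues) - set(BASES)
    if invalid:
        raise ValueError(
            f"invalid DNA character(s) {sorted(invalid)} in reverse_complement input"
        )
    return residues.translate(_COMPLEMENT)[::-1]


def all_kmers(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic (A<C<G<T) order."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of a k-mer (row index into count matrices)."""
    idx = 0
    for b in kmer:
        idx = idx * 4 + _CODE[b]
    return idx


def encode(residues: str) -> np.ndarray:
    """Base codes A=0 C=1 G=2 T=3 as an int8 array."""
    out = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = np.full(out.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        codes[out == ord(base)] = code
    if (codes < 0).any():
        raise ValueError("sequence contains characters outside {A,C,G,T}")
    return codes


def _window_indices(codes: np.ndarray, k: int) -> np.ndarray:
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    return windows @ powers


def count_vector(residues: str, k: int, both_strands: bool) -> np.ndarray:
    """Counts of every k-mer (length 4**k vector) for one sequence.

    Overlapping windows with step 1; with ``both_strands`` the counts from the
    reverse complement are added into the same vector.
    """
    n = 4**k
    idx = _window_indices(encode(residues), k)
    counts = np.bincount(idx, minlength=n)
    if both_strands:
        idx_rc = _window_indices(encode(reverse_complement(residues)), k)
        counts = counts + np.bincount(idx_rc, minlength=n)
    return counts.astype(np.int64)


def count_matrix(sequences, k: int, both_strands: bool) -> np.ndarray:
    """Per-sequence k-mer counts, shape (n_sequences, 4**k).

    ``sequences`` is an iterable of objects with a ``residues`` attribute
    (or plain strings).
    """
    rows = []
    for seq in sequences:
        residues = seq if isinstance(seq, str) else seq.residues
        rows.append(count_vector(residues, k, both_strands))
    if not rows:
        return np.empty((0, 4**k), dtype=np.int64)
    return np.vstack(rows)
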