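"""Sequence I/O, validation, window extraction and cross-validation folds.

Datasets are two collections of equal-length DNA sequences, promoters and
non-promoters, with an optional stratified fold assignment.  The canonical
promoter convention is a 251 bp segment spanning -200..+51 around the
transcription start site; the length is a dataset property, not a constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO as _BioSeqIO

from ._kmers import BASES, reverse_complement as _rc

logger = logging.getLogger(__name__)

_VALID_WITH_N = set(BASES) | {"N"}


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class SequenceValidationError(ValueError):
    """Raised when a record contains characters outside the DNA alphabet."""


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over {A,C,G,T}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - set(BASES)
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def reverse_complement(residues: str) -> str:
    """Watson-Crick reverse complement; involution, preserves length."""
    return _rc(residues)


def read_fasta(path, drop_n: bool = False) -> list[Sequence]:
    """Read a multi-record FASTA file into validated sequences.

    Residues are uppercased.  Records containing ``N`` are rejected (exact
    k-mer counting does not admit ambiguity codes); with ``drop_n`` they are
    skipped with a warning instead.  Any other non-ACGT character raises
    :class:`SequenceValidationError` naming the record.
    """
    sequences: list[Sequence] = []
    try:
        records = list(_BioSeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # malformed record
        raise FastaParseError(f"{path}: {exc}") from exc
    for record in records:
        residues = str(record.seq).upper()
        bad = set(residues) - _VALID_WITH_N
        if bad:
            raise SequenceValidationError(
                f"record {record.id!r}: invalid residue(s) {sorted(bad)}"
            )
        if "N" in residues:
            if drop_n:
                logger.warning("dropping record %r: contains N", record.id)
                continue
            raise SequenceValidationError(
                f"record {record.id!r} contains ambiguous base N "
                "(use drop_n=True to skip such records)"
            )
        sequences.append(Sequence(id=record.id, residues=residues))
    return sequences


def write_fasta(sequences: list[Sequence], path) -> None:
    """Write sequences as plain multi-record FASTA."""
    with open(path, "w") as handle:
        for seq in sequences:
            handle.write(f">{seq.id}\n{seq.residues}\n")


def extract_window(seq: Sequence, length: int, rng: np.random.Generator) -> Sequence:
    """Extract a random fixed-length window from a longer sequence.

    Emulates trimming non-promoter source sequences to the promoter length by
    choosing a uniform random start position.  Deterministic given the
    generator state.
    """
    if length <= 0:
        raise ValueError("window length must be positive")
    if len(seq) < length:
        raise ValueError(
            f"record {seq.id!r}: length {len(seq)} shorter than window {length}"
        )
    start = int(rng.integers(0, len(seq) - length + 1))
    return Sequence(id=seq.id, residues=seq.residues[start : start + length])


@dataclass
class LabeledDataset:
    """Promoter / non-promoter sequence collections with optional CV folds.

    Invariants: all sequences share one length; ids are unique across both
    classes; when folds are assigned, every id is in exactly one fold and
    fold sizes within a class differ by at most one.
    """

    promoters: list[Sequence]
    nonpromoters: list[Sequence]
    fold_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.promoters or not self.nonpromoters:
            raise ValueError("both classes must be non-empty")
        lengths = {len(s) for s in self.promoters} | {len(s) for s in self.nonpromoters}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        ids = [s.id for s in self.promoters] + [s.id for s in self.nonpromoters]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique across both classes")

    @property
    def sequence_length(self) -> int:
        return len(self.promoters[0])

    @property
    def n_folds(self) -> int:
        if not self.fold_of:
            return 0
        return max(self.fold_of.values()) + 1

    def _split(self, fold: int, keep_test: bool) -> "LabeledDataset":
        if not self.fold_of:
            raise ValueError("dataset has no fold assignment; call make_folds first")
        if not 0 <= fold < self.n_folds:
            raise ValueError(f"fold {fold} out of range 0..{self.n_folds - 1}")

        def pick(seqs):
            return [
                s for s in seqs if (self.fold_of[s.id] == fold) == keep_test
            ]

        return LabeledDataset(
            promoters=pick(self.promoters),
            nonpromoters=pick(self.nonpromoters),
        )

    def training_split(self, fold: int) -> "LabeledDataset":
        """All sequences outside ``fold`` (the feature-selection/training set)."""
        return self._split(fold, keep_test=False)

    def test_split(self, fold: int) -> "LabeledDataset":
        """The held-out sequences of ``fold``."""
        return self._split(fold, keep_test=True)


def make_folds(
    promoters: list[Sequence],
    nonpromoters: list[Sequence],
    k: int,
    rng: np.random.Generator,
) -> LabeledDataset:
    """Assign stratified k-fold labels, shuffling each class independently.

    With 305 sequences per class and k=5 every fold holds 61 promoters and
    61 non-promoters.  Fold sizes within a class differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    for name, seqs in (("promoters", promoters), ("nonpromoters", nonpromoters)):
        if len(seqs) < k:
            raise ValueError(f"{name}: {len(seqs)} sequences is fewer than k={k}")
    fold_of: dict[str, int] = {}
    for seqs in (promoters, nonpromoters):
        order = rng.permutation(len(seqs))
        for pos, idx in enumerate(order):
            fold_of[seqs[idx].id] = pos % k
    return LabeledDataset(
        promoters=list(promoters), nonpromoters=list(nonpromoters), fold_of=fold_of
    )


def write_folds_tsv(dataset: LabeledDataset, path) -> None:
    """Two-column TSV (id, fold) of the fold assignment."""
    with open(path, "w") as handle:
        handle.write("id\tfold\n")
        for seq in dataset.promoters + dataset.nonpromoters:
            handle.write(f"{seq.id}\t{dataset.fold_of[seq.id]}\n")
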