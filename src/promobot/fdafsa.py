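"""Frequency Distribution Analyzed Feature Selection (FDAFSA).

Ranks all 4,096 hexamers by the absolute difference between their total
both-strand counts in promoters (CP) and in non-promoters (CNP), and selects
a top fraction (by default the top 25%, 1,024 hexamers) as classification
features.  Counting is overlapping, step 1, on both strands.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kmers import all_kmers, count_matrix, reverse_complement
from .seqio import LabeledDataset, Sequence


@dataclass(frozen=True)
class HexamerScore:
    """Class totals and absolute difference for one hexamer."""

    hexamer: str
    cp: int
    cnp: int

    @property
    def diff(self) -> int:
        return abs(self.cp - self.cnp)


def count_kmers(seq: Sequence | str, k: int, both_strands: bool = True) -> Counter:
    """Overlapping step-1 k-mer counts of one sequence.

    With ``both_strands`` the counts from the reverse complement are summed
    into the same map, so for a sequence of length L the counts total
    2*(L-k+1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    residues = seq if isinstance(seq, str) else seq.residues
    counts: Counter = Counter(
        residues[i : i + k] for i in range(len(residues) - k + 1)
    )
    if both_strands:
        rc = reverse_complement(residues)
        counts.update(rc[i : i + k] for i in range(len(rc) - k + 1))
    return counts


def compute_hexamer_scores(
    train: LabeledDataset, k: int = 6, both_strands: bool = True
) -> list[HexamerScore]:
    """Score every possible k-mer (4**k entries, zero-count ones included).

    CP sums the per-sequence both-strand counts over all promoters, CNP over
    all non-promoters; the score is |CP - CNP|.
    """
    cp = count_matrix(train.promoters, k, both_strands).sum(axis=0)
    cnp = count_matrix(train.nonpromoters, k, both_strands).sum(axis=0)
    kmers = all_kmers(k)
    return [
        HexamerScore(hexamer=kmers[i], cp=int(cp[i]), cnp=int(cnp[i]))
        for i in range(len(kmers))
    ]


def select_top_fraction(
    scores: list[HexamerScore], fraction: float = 0.25
) -> list[str]:
    """The top-``fraction`` hexamers ranked by descending diff.

    Ties are broken lexicographically (ascending on the hexamer string) so
    the selected feature set is reproducible.  The default fraction 0.25
    keeps 1,024 of the 4,096 hexamers.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    ranked = sorted(scores, key=lambda s: (-s.diff, s.hexamer))
    n_keep = int(np.floor(fraction * len(scores) + 0.5))
    return [s.hexamer for s in ranked[:n_keep]]


def scores_to_frame(scores: list[HexamerScore]) -> pd.DataFrame:
    """Ranked score table with columns hexamer, cp, cnp, diff, rank."""
    ranked = sorted(scores, key=lambda s: (-s.diff, s.hexamer))
    return pd.DataFrame(
        {
            "hexamer": [s.hexamer for s in ranked],
            "cp": [s.cp for s in ranked],
            "cnp": [s.cnp for s in ranked],
            "diff": [s.diff for s in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )


def write_scores_tsv(scores: list[HexamerScore], path) -> None:
    scores_to_frame(scores).to_csv(path, sep="\t", index=False)
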