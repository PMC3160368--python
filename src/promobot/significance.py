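"""RTP-versus-hexamer discrimination analysis with a permutation p-value.

For a triplet pair, the two candidate hexamers are the concatenations
t1+t2 and t2+t1.  The analysis asks whether the pair's min-frequency
statistic discriminates the classes better than either concatenated
hexamer does on its own:

    diff = FD_RTP - max(FD_hex1, FD_hex2)

where FD_RTP is the absolute difference between the pair's total frequency
in promoters and in non-promoters, and FD_hex is the same absolute count
difference for a candidate hexamer.  The observed average diff over a set
of selected pairs is compared against averages from sets of uniformly drawn
random pairs, yielding an empirical p-value (fraction of random averages at
least as large; no small-sample correction, so an observed value above every
random average reports exactly 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kmers import count_matrix, kmer_index
from .rtpfsga import N_CANONICAL_PAIRS, TripletPair, all_canonical_pairs
from .seqio import LabeledDataset

_MODES = ("max", "sum", "mean")


@dataclass(frozen=True)
class RtpHexamerDiff:
    """Components of the RTP-vs-hexamer comparison for one pair."""

    rtp: TripletPair
    fd_rtp: int
    fd_hex1: int
    fd_hex2: int
    diff: float


class DiffCalculator:
    """Precomputes count tables for fast diff evaluation over many pairs."""

    def __init__(
        self, data: LabeledDataset, both_strands: bool = True, mode: str = "max"
    ) -> None:
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
        self.mode = mode
        self._p3 = count_matrix(data.promoters, 3, both_strands)
        self._n3 = count_matrix(data.nonpromoters, 3, both_strands)
        hex_p = count_matrix(data.promoters, 6, both_strands).sum(axis=0)
        hex_n = count_matrix(data.nonpromoters, 6, both_strands).sum(axis=0)
        self._hex_diff = np.abs(hex_p - hex_n)

    def _fd_rtp(self, i: int, j: int) -> int:
        pro = np.minimum(self._p3[:, i], self._p3[:, j]).sum()
        non = np.minimum(self._n3[:, i], self._n3[:, j]).sum()
        return int(abs(pro - non))

    def diff(self, rtp: TripletPair) -> RtpHexamerDiff:
        i, j = kmer_index(rtp.t1), kmer_index(rtp.t2)
        fd_rtp = self._fd_rtp(i, j)
        fd_hex1 = int(self._hex_diff[kmer_index(rtp.t1 + rtp.t2)])
        fd_hex2 = int(self._hex_diff[kmer_index(rtp.t2 + rtp.t1)])
        if self.mode == "max":
            penalty = max(fd_hex1, fd_hex2)
        elif self.mode == "sum":
            penalty = fd_hex1 + fd_hex2
        else:
            penalty = (fd_hex1 + fd_hex2) / 2.0
        return RtpHexamerDiff(
            rtp=rtp, fd_rtp=fd_rtp, fd_hex1=fd_hex1, fd_hex2=fd_hex2,
            diff=fd_rtp - penalty,
        )

    def diff_table(self) -> np.ndarray:
        """diff values for all 2,080 canonical pairs, in canonical order."""
        return np.array(
            [self.diff(TripletPair(t1, t2)).diff for t1, t2 in all_canonical_pairs()]
        )


def diff_rtp_hexamer(
    rtp: TripletPair,
    data: LabeledDataset,
    both_strands: bool = True,
    mode: str = "max",
) -> RtpHexamerDiff:
    """Discrimination-power difference between a pair and its concatenations."""
    return DiffCalculator(data, both_strands, mode).diff(rtp)


def average_diff(
    rtps: list[TripletPair],
    data: LabeledDataset,
    both_strands: bool = True,
    mode: str = "max",
) -> tuple[float, list[RtpHexamerDiff]]:
    """Mean diff over a set of pairs, with the per-pair components."""
    if not rtps:
        raise ValueError("need at least one triplet pair")
    calc = DiffCalculator(data, both_strands, mode)
    diffs = [calc.diff(r) for r in rtps]
    return float(np.mean([d.diff for d in diffs])), diffs


def empirical_pvalue(
    observed_avg: float,
    data: LabeledDataset,
    n_pairs: int,
    n_random: int,
    rng: np.random.Generator,
    both_strands: bool = True,
    mode: str = "max",
) -> float:
    """Permutation p-value of an observed average diff.

    Draws ``n_random`` sets of ``n_pairs`` pairs uniformly over the 2,080
    canonical pairs and returns the fraction of set averages >= the observed
    average.  Always a multiple of 1/n_random and monotone non-increasing in
    the observed value.
    """
    if n_random < 1 or n_pairs < 1:
        raise ValueError("n_random and n_pairs must be >= 1")
    table = DiffCalculator(data, both_strands, mode).diff_table()
    draws = rng.integers(0, N_CANONICAL_PAIRS, size=(n_random, n_pairs))
    averages = table[draws].mean(axis=1)
    return float((averages >= observed_avg).sum() / n_random)


def diffs_to_frame(diffs: list[RtpHexamerDiff]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t1": [d.rtp.t1 for d in diffs],
            "t2": [d.rtp.t2 for d in diffs],
            "fd_rtp": [d.fd_rtp for d in diffs],
            "fd_hexamer1": [d.fd_hex1 for d in diffs],
            "fd_hexamer2": [d.fd_hex2 for d in diffs],
            "diff": [d.diff for d in diffs],
        }
    )
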