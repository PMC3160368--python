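"""Seeded synthetic DNA generator with plantable class-differential signal.

Generates two classes of equal-length sequences (promoter-shaped and
non-promoter-shaped) from an i.i.d. background, then overwrites planted
motifs — single motifs or gapped triplet pairs — at uniformly drawn
non-overlapping positions with per-class copy numbers.  It emulates the
compositional contrast between promoter and non-promoter sets (e.g. an
AT-rich hexamer enriched in promoters) so the whole feature-selection and
classification pipeline runs without any external database.

It plants exact motif copies; it does not model real promoter architecture
(TATA positioning relative to a TSS, Y patches, codon structure in mRNA).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from ._kmers import BASES
from .seqio import LabeledDataset, Sequence, make_folds, write_fasta

UNIFORM_BACKGROUND = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
# AT-rich preset mirroring the composition of real plant promoter segments.
AT_RICH_BACKGROUND = {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}

_PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class PlantedMotif:
    """One contiguous motif planted ``count_class1``/``count_class2`` times
    per sequence of each class."""

    motif: str
    count_class1: int
    count_class2: int

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - set(BASES):
            raise ValueError(f"invalid motif {self.motif!r}")
        if self.count_class1 < 0 or self.count_class2 < 0:
            raise ValueError("planting counts must be non-negative")


@dataclass(frozen=True)
class PlantedPair:
    """A gapped triplet pair: t1 and t2 separated by a uniform random gap.

    The gap is at least 1 so a planted copy never forms the concatenated
    hexamer t1+t2; the gap bases stay background.
    """

    t1: str
    t2: str
    gap_min: int
    gap_max: int
    count_class1: int
    count_class2: int

    def __post_init__(self) -> None:
        for t in (self.t1, self.t2):
            if len(t) != 3 or set(t) - set(BASES):
                raise ValueError(f"invalid triplet {t!r}")
        if self.gap_min < 1 or self.gap_max < self.gap_min:
            raise ValueError("need gap_max >= gap_min >= 1 (non-adjacent triplets)")
        if self.count_class1 < 0 or self.count_class2 < 0:
            raise ValueError("planting counts must be non-negative")


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters: sizes, background composition, planted signal."""

    n_per_class: int
    length: int = 251
    background: dict[str, float] = field(
        default_factory=lambda: dict(UNIFORM_BACKGROUND)
    )
    planted_motifs: tuple[PlantedMotif, ...] = ()
    planted_pairs: tuple[PlantedPair, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.length < 1:
            raise ValueError("n_per_class and length must be positive")
        probs = [self.background.get(b, 0.0) for b in BASES]
        if sorted(self.background) != sorted(BASES) or not np.isclose(sum(probs), 1.0):
            raise ValueError("background must assign A,C,G,T probabilities summing to 1")
        for cls_attr in ("count_class1", "count_class2"):
            occupied = sum(
                len(m.motif) * getattr(m, cls_attr) for m in self.planted_motifs
            ) + sum(
                (6 + p.gap_min) * getattr(p, cls_attr) for p in self.planted_pairs
            )
            if occupied > self.length:
                raise ValueError(
                    f"planted material ({occupied} bp, {cls_attr}) exceeds "
                    f"sequence length {self.length}"
                )


# Core-promoter-style elements planted once per promoter sequence.  The
# eight hexamers are chosen so their triplet windows fall in pairwise
# disjoint reverse-complement classes (and none in the classes of the
# study's planted triplet pair), so each element contributes an independent
# hexamer feature without compounding triplet-level signal.
STUDY_MOTIFS: tuple[str, ...] = (
    "TATAAA",  # TATA box
    "TTCTCC",  # Y-patch-like pyrimidine run
    "CCAATC",  # CAAT-box-like
    "GGGCGG",  # GC-box-like
    "CACGTG",  # G-box
    "AGCTAG",
    "CATGCA",
    "AACCGG",
)

STUDY_RTP = ("CAG", "GTC")


def promoter_study_spec(
    seed: int, n_per_class: int = 100, length: int = 251
) -> SynthSpec:
    """The package's reference study conditions.

    Promoters carry one copy of each of the eight core-promoter-style
    elements in :data:`STUDY_MOTIFS` plus four copies of the gapped triplet
    pair :data:`STUDY_RTP` (gap 4-10 bp); non-promoters are pure background.
    Single-copy elements mirror how real core-promoter motifs occur, while
    the paired triplets carry a signal that only the min-frequency pair
    statistic, not any single hexamer, can see.
    """
    spec = SynthSpec(
        n_per_class=n_per_class,
        length=length,
        seed=seed,
        planted_motifs=tuple(PlantedMotif(m, 1, 0) for m in STUDY_MOTIFS),
    )
    return plant_rtp_signal(spec, *STUDY_RTP, (4, 10), 4, 0)


def plant_rtp_signal(
    spec: SynthSpec,
    t1: str,
    t2: str,
    gap_range: tuple[int, int],
    count_class1: int,
    count_class2: int,
) -> SynthSpec:
    """Return a spec augmented with a gapped triplet-pair signal."""
    pair = PlantedPair(
        t1=t1,
        t2=t2,
        gap_min=gap_range[0],
        gap_max=gap_range[1],
        count_class1=count_class1,
        count_class2=count_class2,
    )
    return dataclasses.replace(spec, planted_pairs=spec.planted_pairs + (pair,))


def _place(
    residues: np.ndarray,
    segments: list[str],
    gap: int,
    occupied: list[tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    """Overwrite segments (with the given gap between two of them) at a
    uniform non-overlapping start; bounded retries."""
    span = sum(len(s) for s in segments) + gap
    if span > residues.size:
        raise ValueError(f"motif span {span} exceeds sequence length {residues.size}")
    # Written intervals only; the gap stays background and may host others.
    for _ in range(_PLACEMENT_RETRIES):
        start = int(rng.integers(0, residues.size - span + 1))
        intervals = []
        pos = start
        for seg in segments:
            intervals.append((pos, pos + len(seg)))
            pos += len(seg) + gap
        if all(
            hi <= lo2 or hi2 <= lo
            for lo, hi in intervals
            for lo2, hi2 in occupied
        ):
            pos = start
            for seg in segments:
                residues[pos : pos + len(seg)] = list(seg)
                pos += len(seg) + gap
            occupied.extend(intervals)
            return
    raise RuntimeError(
        f"could not place motif {'-'.join(segments)} after "
        f"{_PLACEMENT_RETRIES} attempts; sequence too crowded"
    )


def _make_sequence(
    spec: SynthSpec, class1: bool, seq_id: str, rng: np.random.Generator
) -> Sequence:
    probs = [spec.background[b] for b in BASES]
    residues = rng.choice(list(BASES), size=spec.length, p=probs)
    occupied: list[tuple[int, int]] = []
    for pair in spec.planted_pairs:
        count = pair.count_class1 if class1 else pair.count_class2
        for _ in range(count):
            gap = int(rng.integers(pair.gap_min, pair.gap_max + 1))
            _place(residues, [pair.t1, pair.t2], gap, occupied, rng)
    for motif in spec.planted_motifs:
        count = motif.count_class1 if class1 else motif.count_class2
        for _ in range(count):
            _place(residues, [motif.motif], 0, occupied, rng)
    return Sequence(id=seq_id, residues="".join(residues))


def generate(spec: SynthSpec, k_folds: int | None = None) -> LabeledDataset:
    """Draw the dataset; class 1 becomes promoters, class 2 non-promoters.

    Fully reproducible from ``spec.seed``.  When ``k_folds`` is given a
    stratified fold assignment (seeded from the same stream) is attached.
    """
    rng = np.random.default_rng(spec.seed)
    promoters = [
        _make_sequence(spec, True, f"prom_{i:04d}", rng)
        for i in range(spec.n_per_class)
    ]
    nonpromoters = [
        _make_sequence(spec, False, f"nonprom_{i:04d}", rng)
        for i in range(spec.n_per_class)
    ]
    if k_folds is not None:
        return make_folds(promoters, nonpromoters, k_folds, rng)
    return LabeledDataset(promoters=promoters, nonpromoters=nonpromoters)


def spec_to_dict(spec: SynthSpec) -> dict:
    return dataclasses.asdict(spec)


def spec_from_dict(payload: dict) -> SynthSpec:
    payload = dict(payload)
    payload["planted_motifs"] = tuple(
        PlantedMotif(**m) for m in payload.get("planted_motifs", ())
    )
    payload["planted_pairs"] = tuple(
        PlantedPair(**p) for p in payload.get("planted_pairs", ())
    )
    return SynthSpec(**payload)


def export(spec: SynthSpec, data: LabeledDataset, out_dir) -> dict[str, str]:
    """Write promoters.fasta, nonpromoters.fasta and a JSON spec sidecar."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "promoters": os.path.join(out_dir, "promoters.fasta"),
        "nonpromoters": os.path.join(out_dir, "nonpromoters.fasta"),
        "spec": os.path.join(out_dir, "spec.json"),
    }
    write_fasta(data.promoters, paths["promoters"])
    write_fasta(data.nonpromoters, paths["nonpromoters"])
    with open(paths["spec"], "w") as handle:
        json.dump(spec_to_dict(spec), handle, indent=2)
    return paths
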