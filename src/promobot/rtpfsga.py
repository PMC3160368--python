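"""Random Triplet Pair Feature Selecting Genetic Algorithm (RTPFSGA).

A random triplet pair (RTP) is an unordered pair of 3-mers, not required to
be adjacent in the sequence; its frequency in a sequence is the minimum of
the two triplets' counts.  The GA evolves a population of RTPs, scoring each
by a two-tailed pooled-variance t-test comparing its per-sequence frequency
across promoters versus non-promoters, and finally returns the pairs whose
p-value beats a significance level alpha.

Operators follow the classical recipe: binary tournament parent selection,
triplet-swapping crossover, single-slot mutation with a uniqueness retry,
and elitist (mu + lambda) survival selection on p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._kmers import all_kmers, count_matrix, kmer_index
from .seqio import LabeledDataset, Sequence

logger = logging.getLogger(__name__)

TRIPLETS: list[str] = all_kmers(3)
N_TRIPLETS = 64
N_CANONICAL_PAIRS = N_TRIPLETS * (N_TRIPLETS + 1) // 2  # 2080

_MUTATION_RETRIES = 100


class TripletPair:
    """An unordered pair of 3-mers with an optional fitness p-value.

    Pairs are canonicalized at construction (t1 <= t2 lexicographically);
    equality and hashing ignore the fitness fields.  t1 == t2 is allowed.
    """

    __slots__ = ("t1", "t2", "t_value", "pvalue", "generation_found")

    def __init__(
        self,
        t1: str,
        t2: str,
        t_value: float | None = None,
        pvalue: float | None = None,
        generation_found: int | None = None,
    ) -> None:
        for t in (t1, t2):
            if t not in _TRIPLET_SET:
                raise ValueError(f"{t!r} is not a valid 3-mer over ACGT")
        if t2 < t1:
            t1, t2 = t2, t1
        self.t1 = t1
        self.t2 = t2
        self.t_value = t_value
        self.pvalue = pvalue
        self.generation_found = generation_found

    @property
    def key(self) -> tuple[str, str]:
        return (self.t1, self.t2)

    def __eq__(self, other) -> bool:
        return isinstance(other, TripletPair) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:
        p = f", p={self.pvalue:.3g}" if self.pvalue is not None else ""
        return f"TripletPair({self.t1}-{self.t2}{p})"


_TRIPLET_SET = frozenset(TRIPLETS)


def all_canonical_pairs() -> list[tuple[str, str]]:
    """All 2,080 unordered triplet pairs (t1 <= t2), lexicographic order."""
    return [
        (TRIPLETS[i], TRIPLETS[j])
        for i in range(N_TRIPLETS)
        for j in range(i, N_TRIPLETS)
    ]


@dataclass(frozen=True)
class FrequencySamples:
    """Per-sequence RTP frequencies in promoters (x1) and non-promoters (x2)."""

    x1: np.ndarray
    x2: np.ndarray


@dataclass(frozen=True)
class GAConfig:
    """GA parameters.  Defaults are the full-scale configuration: population
    1000, 500 reproductions and at most 500 new children per generation,
    1000 generations, crossover probability 0.8, mutation probability 0.05,
    significance level 1e-6."""

    population_size: int = 1000
    reproductions_per_generation: int = 500
    max_children_per_generation: int = 500
    max_generations: int = 1000
    crossover_probability: float = 0.8
    mutation_probability: float = 0.05
    alpha: float = 1e-6
    seed: int = 0
    both_strands: bool = True

    def __post_init__(self) -> None:
        for name in ("crossover_probability", "mutation_probability"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0,1], got {self.alpha}")
        for name in (
            "population_size",
            "reproductions_per_generation",
            "max_children_per_generation",
            "max_generations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.population_size > N_CANONICAL_PAIRS:
            raise ValueError(
                f"population_size {self.population_size} exceeds the "
                f"{N_CANONICAL_PAIRS} distinct canonical pairs"
            )

    @classmethod
    def scaled_down(cls, **overrides) -> "GAConfig":
        """A desk-scale configuration: population 50, 20 generations.

        The pair space (2,080) does not shrink with the population, so the
        reproduction budget is kept at ~5% of the space per generation
        (the full-scale configuration reproduces ~24% of it).
        """
        defaults = dict(
            population_size=50,
            reproductions_per_generation=100,
            max_children_per_generation=100,
            max_generations=20,
        )
        defaults.update(overrides)
        return cls(**defaults)


def rtp_frequency(
    seq: Sequence | str, rtp: TripletPair, both_strands: bool = True
) -> int:
    """min(count of t1, count of t2) with overlapping step-1 counting."""
    from .fdafsa import count_kmers

    counts = count_kmers(seq, 3, both_strands)
    return min(counts.get(rtp.t1, 0), counts.get(rtp.t2, 0))


def collect_samples(
    rtp: TripletPair, train: LabeledDataset, both_strands: bool = True
) -> FrequencySamples:
    """Per-sequence RTP frequencies over both classes, in dataset order."""
    return FitnessEvaluator(train, both_strands).samples(rtp)


def t_test_pvalue(samples: FrequencySamples) -> tuple[float, float]:
    """Pooled-variance two-sample t statistic and two-tailed p-value.

    Degrees of freedom are n1 + n2 - 2.  When the pooled variance is zero
    the test degenerates: equal means give (t=0, p=1); unequal means give
    p=0 by convention (the samples are perfectly separated).
    """
    x1 = np.asarray(samples.x1, dtype=float)
    x2 = np.asarray(samples.x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    delta = x1.mean() - x2.mean()
    if sp2 == 0.0:
        if delta == 0.0:
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means; p = 0")
        return math.copysign(math.inf, delta), 0.0
    t = delta / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, float(min(p, 1.0))


class FitnessEvaluator:
    """Caches triplet count matrices and per-pair fitness for one dataset.

    Fitness is deterministic given the training data, so caching by canonical
    pair cannot change GA results — it only avoids recounting.
    """

    def __init__(self, train: LabeledDataset, both_strands: bool = True) -> None:
        self._p = count_matrix(train.promoters, 3, both_strands)
        self._n = count_matrix(train.nonpromoters, 3, both_strands)
        self._cache: dict[tuple[str, str], tuple[float, float]] = {}

    def samples(self, rtp: TripletPair) -> FrequencySamples:
        i, j = kmer_index(rtp.t1), kmer_index(rtp.t2)
        return FrequencySamples(
            x1=np.minimum(self._p[:, i], self._p[:, j]),
            x2=np.minimum(self._n[:, i], self._n[:, j]),
        )

    def score(self, rtp: TripletPair) -> TripletPair:
        """Attach (t, p) to the pair, computing at most once per pair."""
        if rtp.key not in self._cache:
            self._cache[rtp.key] = t_test_pvalue(self.samples(rtp))
        rtp.t_value, rtp.pvalue = self._cache[rtp.key]
        return rtp


def initialize_population(
    config: GAConfig, rng: np.random.Generator, evaluator: FitnessEvaluator
) -> list[TripletPair]:
    """Uniform sample of distinct canonical pairs, scored before generation 1."""
    pairs = all_canonical_pairs()
    chosen = rng.choice(len(pairs), size=config.population_size, replace=False)
    population = [
        TripletPair(*pairs[i], generation_found=0) for i in chosen
    ]
    for rtp in population:
        evaluator.score(rtp)
    return population


def tournament_select(
    population: list[TripletPair], rng: np.random.Generator
) -> TripletPair:
    """Binary tournament: the lower p-value of two distinct uniform draws wins."""
    if not population:
        raise ValueError("population is empty")
    if len(population) == 1:
        contenders = [population[0]]
    else:
        idx = rng.choice(len(population), size=2, replace=False)
        contenders = [population[idx[0]], population[idx[1]]]
    for c in contenders:
        if c.pvalue is None:
            raise ValueError(f"unscored individual {c!r} in tournament")
    if len(contenders) == 1 or contenders[0].pvalue != contenders[1].pvalue:
        return min(contenders, key=lambda c: c.pvalue)
    return contenders[int(rng.integers(0, 2))]


def crossover(
    p1: TripletPair,
    p2: TripletPair,
    rng: np.random.Generator,
    probability: float,
) -> tuple[TripletPair, TripletPair]:
    """Swap triplets between the parents with the given probability.

    When the crossover fires, the offspring are the canonicalized cross
    pairs (p1.t1, p2.t2) and (p2.t1, p1.t2); otherwise they are unscored
    copies of the parents.
    """
    if rng.random() < probability:
        return TripletPair(p1.t1, p2.t2), TripletPair(p2.t1, p1.t2)
    return TripletPair(p1.t1, p1.t2), TripletPair(p2.t1, p2.t2)


def mutate(
    child: TripletPair,
    population: list[TripletPair] | set[tuple[str, str]],
    rng: np.random.Generator,
    probability: float,
) -> TripletPair:
    """Replace one triplet of the child with a uniform 3-mer.

    A mutated pair already present in the population is discarded and the
    draw retried (bounded); if no novel pair is found the child is returned
    unmutated with a warning.
    """
    if rng.random() >= probability:
        return child
    existing = (
        population
        if isinstance(population, set)
        else {p.key for p in population}
    )
    for _ in range(_MUTATION_RETRIES):
        slot = int(rng.integers(0, 2))
        new_triplet = TRIPLETS[int(rng.integers(0, N_TRIPLETS))]
        t1, t2 = (new_triplet, child.t2) if slot == 0 else (child.t1, new_triplet)
        mutant = TripletPair(t1, t2)
        if mutant.key not in existing:
            return mutant
    logger.warning("mutation failed to find a novel pair; child kept as-is")
    return child


def _survival_key(rtp: TripletPair) -> tuple:
    # p-values of strongly separated pairs underflow to 0.0; |t| descending
    # resolves those ties by effect size before the lexicographic fallback.
    return (rtp.pvalue, -abs(rtp.t_value), rtp.t1, rtp.t2)


def run_ga(
    train: LabeledDataset,
    config: GAConfig,
    evaluator: FitnessEvaluator | None = None,
) -> list[TripletPair]:
    """Evolve RTPs and return those significant at ``config.alpha``.

    Each generation performs ``reproductions_per_generation`` parent
    selections with crossover and mutation, accumulates at most
    ``max_children_per_generation`` distinct new children, scores them, and
    keeps the best ``population_size`` individuals from parents plus
    children (elitist mu+lambda).  The returned pairs are the final
    population members with p-value below alpha, sorted ascending by
    p-value then lexicographically.
    """
    if evaluator is None:
        evaluator = FitnessEvaluator(train, config.both_strands)
    rng = np.random.default_rng(config.seed)
    population = initialize_population(config, rng, evaluator)

    for generation in range(1, config.max_generations + 1):
        pop_keys = {p.key for p in population}
        children: list[TripletPair] = []
        child_keys: set[tuple[str, str]] = set()
        for _ in range(config.reproductions_per_generation):
            if len(children) >= config.max_children_per_generation:
                break
            parent1 = tournament_select(population, rng)
            parent2 = tournament_select(population, rng)
            for child in crossover(
                parent1, parent2, rng, config.crossover_probability
            ):
                child = mutate(
                    child, pop_keys | child_keys, rng, config.mutation_probability
                )
                if (
                    child.key not in pop_keys
                    and child.key not in child_keys
                    and len(children) < config.max_children_per_generation
                ):
                    child.generation_found = generation
                    children.append(child)
                    child_keys.add(child.key)
        for child in children:
            evaluator.score(child)
        merged = sorted(population + children, key=_survival_key)
        population = merged[: config.population_size]

    # alpha = 1 disables the filter (p-values of exactly 1 are kept too)
    significant = [
        r for r in population if config.alpha >= 1.0 or r.pvalue < config.alpha
    ]
    return sorted(significant, key=lambda r: (r.pvalue, r.t1, r.t2))


def exhaustive_scan(
    train: LabeledDataset,
    alpha: float,
    both_strands: bool = True,
) -> list[TripletPair]:
    """Brute-force significance scan of all 2,080 canonical pairs.

    The GA with an all-pairs population and one generation must agree with
    this scan; it is also a practical alternative when exhaustive search is
    affordable.
    """
    evaluator = FitnessEvaluator(train, both_strands)
    hits = []
    for t1, t2 in all_canonical_pairs():
        rtp = evaluator.score(TripletPair(t1, t2))
        if rtp.pvalue < alpha:
            hits.append(rtp)
    return sorted(hits, key=lambda r: (r.pvalue, r.t1, r.t2))


def rtps_to_frame(rtps: list[TripletPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t1": [r.t1 for r in rtps],
            "t2": [r.t2 for r in rtps],
            "t_value": [r.t_value for r in rtps],
            "p_value": [r.pvalue for r in rtps],
            "generation_found": [r.generation_found for r in rtps],
        }
    )


def write_rtps_tsv(rtps: list[TripletPair], path) -> None:
    rtps_to_frame(rtps).to_csv(path, sep="\t", index=False)


def read_rtps_tsv(path) -> list[TripletPair]:
    frame = pd.read_csv(path, sep="\t")
    return [
        TripletPair(row.t1, row.t2)
        for row in frame.itertuples(index=False)
    ]
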