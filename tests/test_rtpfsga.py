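import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import promobot as pb
from promobot.rtpfsga import (
    N_CANONICAL_PAIRS,
    TRIPLETS,
    FitnessEvaluator,
    FrequencySamples,
    GAConfig,
    all_canonical_pairs,
    crossover,
    initialize_population,
    mutate,
    tournament_select,
)

triplet = st.sampled_from(TRIPLETS)


class TestTripletPair:
    def test_canonicalization(self):
        assert pb.TripletPair("TTT", "AAA").key == ("AAA", "TTT")
        assert pb.TripletPair("AAA", "AAA").key == ("AAA", "AAA")

    def test_equality_ignores_fitness(self):
        assert pb.TripletPair("AAA", "CCC", pvalue=0.1) == pb.TripletPair("CCC", "AAA")

    def test_invalid_triplet(self):
        with pytest.raises(ValueError):
            pb.TripletPair("AAAA", "CCC")

    def test_enumeration_sizes(self):
        assert len(TRIPLETS) == 64
        assert len(all_canonical_pairs()) == N_CANONICAL_PAIRS == 2080


class TestRtpFrequency:
    def test_min_rule_plus_strand(self):
        rtp = pb.TripletPair("AAA", "TTT")
        assert pb.rtp_frequency("AAAAAA", rtp, both_strands=False) == 0

    def test_min_rule_both_strands(self):
        rtp = pb.TripletPair("AAA", "TTT")
        assert pb.rtp_frequency("AAAAAA", rtp, both_strands=True) == 4

    @staticmethod
    def _brute_count(residues, kmer, both):
        strands = [residues]
        if both:
            strands.append(pb.reverse_complement(residues))
        return sum(
            s[i : i + 3] == kmer for s in strands for i in range(len(s) - 2)
        )

    @given(
        st.text(alphabet="ACGT", min_size=3, max_size=50), triplet, triplet,
        st.booleans(),
    )
    def test_matches_brute_force(self, residues, t1, t2, both):
        rtp = pb.TripletPair(t1, t2)
        expected = min(
            self._brute_count(residues, rtp.t1, both),
            self._brute_count(residues, rtp.t2, both),
        )
        assert pb.rtp_frequency(residues, rtp, both) == expected


class TestCollectSamples:
    def test_lengths_and_order(self, toy_dataset):
        samples = pb.collect_samples(pb.TripletPair("ACG", "CGT"), toy_dataset)
        assert len(samples.x1) == len(toy_dataset.promoters)
        assert len(samples.x2) == len(toy_dataset.nonpromoters)
        for j, seq in enumerate(toy_dataset.promoters):
            assert samples.x1[j] == pb.rtp_frequency(seq, pb.TripletPair("ACG", "CGT"))

    def test_identical_classes_identical_samples(self, toy_dataset):
        mirrored = pb.LabeledDataset(
            promoters=toy_dataset.promoters,
            nonpromoters=[
                pb.Sequence("m" + s.id, s.residues) for s in toy_dataset.promoters
            ],
        )
        s = pb.collect_samples(pb.TripletPair("AAA", "CCC"), mirrored)
        assert np.array_equal(s.x1, s.x2)


class TestTTest:
    def test_identical_samples_null(self):
        s = FrequencySamples(np.array([1, 2, 3]), np.array([1, 2, 3]))
        assert pb.t_test_pvalue(s) == (0.0, 1.0)

    def test_strong_separation(self):
        s = FrequencySamples(np.array([0, 0, 0, 0]), np.array([5, 5, 5, 6]))
        t, p = pb.t_test_pvalue(s)
        assert p < 0.001 and t < 0

    def test_zero_variance_unequal_means(self):
        s = FrequencySamples(np.array([1, 1]), np.array([3, 3]))
        t, p = pb.t_test_pvalue(s)
        assert p == 0.0 and t == -np.inf

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            pb.t_test_pvalue(FrequencySamples(np.array([1]), np.array([1, 2])))

    @given(
        st.lists(st.integers(0, 20), min_size=2, max_size=30),
        st.lists(st.integers(0, 20), min_size=2, max_size=30),
    )
    def test_matches_reference_implementation(self, x1, x2):
        """Pooled t-test agrees with the independent reference to 1e-10."""
        s = FrequencySamples(np.array(x1), np.array(x2))
        t, p = pb.t_test_pvalue(s)
        ref = stats.ttest_ind(x1, x2, equal_var=True)
        if np.isnan(ref.pvalue):  # reference emits nan on zero variance
            return
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestOperators:
    def test_initialize_population_distinct_and_scored(self, toy_dataset):
        ev = FitnessEvaluator(toy_dataset)
        cfg = GAConfig.scaled_down(population_size=100)
        pop = initialize_population(cfg, np.random.default_rng(0), ev)
        assert len(pop) == len(set(pop)) == 100
        assert all(p.pvalue is not None for p in pop)

    def test_initialize_population_exhaustive(self, toy_dataset):
        ev = FitnessEvaluator(toy_dataset)
        cfg = GAConfig.scaled_down(population_size=2080)
        pop = initialize_population(cfg, np.random.default_rng(0), ev)
        assert {p.key for p in pop} == set(all_canonical_pairs())

    def test_initialize_population_deterministic(self, toy_dataset):
        ev = FitnessEvaluator(toy_dataset)
        cfg = GAConfig.scaled_down(population_size=30, seed=5)
        a = initialize_population(cfg, np.random.default_rng(5), ev)
        b = initialize_population(cfg, np.random.default_rng(5), ev)
        assert a == b

    def test_population_size_cap(self):
        with pytest.raises(ValueError, match="2080"):
            GAConfig(population_size=3000)

    def test_tournament_picks_better(self, rng):
        pop = [
            pb.TripletPair("AAA", "CCC", t_value=3.0, pvalue=0.01),
            pb.TripletPair("GGG", "TTT", t_value=0.5, pvalue=0.5),
        ]
        for _ in range(20):
            assert tournament_select(pop, rng).pvalue == 0.01

    def test_tournament_singleton_and_unscored(self, rng):
        lone = pb.TripletPair("AAA", "CCC", pvalue=0.3)
        assert tournament_select([lone], rng) is lone
        with pytest.raises(ValueError, match="unscored"):
            tournament_select([pb.TripletPair("AAA", "CCC")] * 2, rng)

    def test_tournament_win_frequency_matches_combinatorics(self):
        """In a 3-individual population the best wins 2 of the 3 possible
        tournaments, the middle 1 of 3, the worst none."""
        pop = [
            pb.TripletPair("AAA", "AAC", pvalue=0.1),
            pb.TripletPair("AAA", "AAG", pvalue=0.2),
            pb.TripletPair("AAA", "AAT", pvalue=0.3),
        ]
        rng = np.random.default_rng(0)
        wins = {p.key: 0 for p in pop}
        n = 6000
        for _ in range(n):
            wins[tournament_select(pop, rng).key] += 1
        assert wins[("AAA", "AAC")] / n == pytest.approx(2 / 3, abs=0.03)
        assert wins[("AAA", "AAG")] / n == pytest.approx(1 / 3, abs=0.03)
        assert wins[("AAA", "AAT")] == 0

    def test_crossover_swaps_and_canonicalizes(self, rng):
        p1, p2 = pb.TripletPair("AAA", "CCC"), pb.TripletPair("GGG", "TTT")
        c1, c2 = crossover(p1, p2, rng, probability=1.0)
        assert {c1.key, c2.key} == {("AAA", "TTT"), ("CCC", "GGG")}
        assert c1.pvalue is None and c2.pvalue is None

    def test_crossover_probability_zero_clones(self, rng):
        p1, p2 = pb.TripletPair("AAA", "CCC"), pb.TripletPair("GGG", "TTT")
        c1, c2 = crossover(p1, p2, rng, probability=0.0)
        assert (c1, c2) == (p1, p2)

    def test_crossover_identical_parents(self, rng):
        p = pb.TripletPair("ACG", "TGA")
        c1, c2 = crossover(p, p, rng, probability=1.0)
        assert c1 == c2 == p

    def test_mutate_probability_zero_is_identity(self, rng):
        child = pb.TripletPair("AAA", "CCC")
        assert mutate(child, [], rng, probability=0.0) is child

    def test_mutate_output_canonical_and_novel(self, rng):
        population = {p for p in all_canonical_pairs()} - {("AAA", "TTT")}
        child = pb.TripletPair("AAA", "AAA")
        for _ in range(50):
            out = mutate(child, population, rng, probability=1.0)
            assert out.t1 <= out.t2
            assert out.key in {("AAA", "TTT"), ("AAA", "AAA")}

    def test_mutate_gives_up_when_space_full(self, rng, caplog):
        population = set(all_canonical_pairs())
        child = pb.TripletPair("AAA", "AAA")
        out = mutate(child, population, rng, probability=1.0)
        assert out is child


class TestRunGA:
    def test_exhaustive_population_equals_brute_force(self, toy_dataset):
        cfg = GAConfig(
            population_size=2080,
            max_generations=1,
            reproductions_per_generation=50,
            max_children_per_generation=50,
            alpha=0.05,
            seed=0,
        )
        ga = pb.run_ga(toy_dataset, cfg)
        scan = pb.exhaustive_scan(toy_dataset, alpha=0.05)
        assert {r.key for r in ga} == {r.key for r in scan}

    def test_alpha_one_returns_whole_population(self, toy_dataset):
        cfg = GAConfig.scaled_down(
            population_size=40, max_generations=2, alpha=1.0, seed=1
        )
        out = pb.run_ga(toy_dataset, cfg)
        assert len(out) == 40

    def test_reproducible_given_seed(self, study_dataset):
        cfg = GAConfig.scaled_down(alpha=1e-3, seed=9, max_generations=5)
        a = pb.run_ga(study_dataset, cfg)
        b = pb.run_ga(study_dataset, cfg)
        assert [(r.key, r.pvalue) for r in a] == [(r.key, r.pvalue) for r in b]

    def test_population_cache_does_not_change_results(self, study_dataset):
        cfg = GAConfig.scaled_down(alpha=1e-3, seed=3, max_generations=5)
        fresh = pb.run_ga(study_dataset, cfg)
        warm = FitnessEvaluator(study_dataset)
        for t1, t2 in all_canonical_pairs():
            warm.score(pb.TripletPair(t1, t2))
        cached = pb.run_ga(study_dataset, cfg, evaluator=warm)
        assert [r.key for r in fresh] == [r.key for r in cached]

    def test_elitism_best_pvalue_non_increasing(self, study_dataset):
        """Across generations the best fitness can only improve (mu+lambda).

        With a shared seed, runs for 1..g generations replay the same
        evolution, so the best p-value after g generations is a monotone
        trace of one run.
        """
        ev = FitnessEvaluator(study_dataset)
        for seed in range(3):
            best = []
            for gens in range(1, 7):
                out = pb.run_ga(
                    study_dataset,
                    GAConfig.scaled_down(seed=seed, max_generations=gens, alpha=1.0),
                    evaluator=ev,
                )
                best.append(min(r.pvalue for r in out))
            assert all(b1 >= b2 for b1, b2 in zip(best, best[1:]))
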