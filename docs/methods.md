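# Methods

## Sequence model and conventions

Inputs are two collections of equal-length DNA sequences over {A,C,G,T}:
promoters (positive class) and non-promoters (negative class). The
canonical segment length is 251 bp (−200..+51 relative to the TSS), but
length is validated as a dataset-level invariant, not hard-coded. Records
containing the ambiguity code N are rejected by default (exact k-mer
counting does not admit ambiguity codes); `read_fasta(..., drop_n=True)`
skips them with a warning instead. Longer non-promoter source sequences are
trimmed to the target length with `extract_window`, which draws a uniform
random start once per sequence at dataset construction time.

All k-mer counting is overlapping with step 1. "Both strands" counting adds
the counts of the reverse complement into the same map, so a both-strand
count of k-mer *w* in sequence *s* equals `#w(s) + #rc(w)(s)`. Both-strand
counting is the default everywhere — for hexamer scores, triplet pairs and
the significance analysis — for internal consistency; every counting
function exposes a `both_strands` flag.

One consequence worth stating explicitly: under both-strand counting a
k-mer and its reverse complement have identical count vectors across any
dataset. Triplet pairs therefore come in identifiability classes of up to
four equivalent spellings ((t1,t2), (rc(t1),t2), (t1,rc(t2)),
(rc(t1),rc(t2)) after canonicalization), with exactly equal fitness. No
selection procedure can distinguish members of a class, and tests that
assert recovery of a planted pair do so at the class level.

## FDAFSA: hexamer frequency-difference ranking

For each of the 4,096 hexamers, `CP` sums both-strand counts over all
promoter training sequences and `CNP` over all non-promoter training
sequences; the score is `Diff = |CP − CNP|`. Hexamers are ranked by
descending Diff with ties broken lexicographically (determinism), and the
top fraction — default 0.25, i.e. 1,024 features — is selected. Zero-count
hexamers are retained in the full ranked list so the 4,096-length contract
is unconditional. `k` is a parameter (default 6) so shorter-word variants
of the analysis can be run; only k = 6 is exercised by the main pipeline.

## RTPFSGA: genetic algorithm over triplet pairs

A triplet pair is canonicalized to `t1 <= t2`; `t1 == t2` is allowed; there
are 64·65/2 = 2,080 canonical pairs. The pair's per-sequence frequency is
`min(count(t1), count(t2))`. "Non-adjacency" is conceptual: each triplet's
total frequency is counted with no positional constraint.

Fitness is the two-tailed p-value of the pooled-variance two-sample
Student t-test comparing the pair's per-sequence frequencies in promoters
(X₁) versus non-promoters (X₂), with df = n₁+n₂−2. Degenerate inputs are
handled by convention: zero pooled variance with equal means gives (t=0,
p=1); with unequal means, p=0 (perfectly separated constant samples must
not crash the search). Fitness is deterministic given the training data, so
per-pair caching is sound; a test verifies a pre-warmed cache changes
nothing.

GA operators: uniform initialization without replacement; binary tournament
parent selection (p-value ties resolved by a fair coin); crossover with
probability 0.8 swapping triplets across parents (offspring are the
canonicalized cross pairs); mutation with probability 0.05 replacing one
uniformly chosen slot with a uniform triplet, retried up to 100 times if
the mutant already exists in the population (then the child is kept
unmutated with a warning); elitist (μ+λ) survival keeping the best
`population_size` individuals from parents and children. Children that
duplicate a population member or an earlier sibling are discarded before
scoring. The returned set is every final-population pair with p < α
(α = 1 disables the filter), sorted by p-value then lexicographically.

Numerical detail: p-values of strongly separated pairs underflow to 0.0 in
double precision. Survival selection therefore breaks p-value ties by |t|
descending before falling back to lexicographic order, so underflow cannot
evict genuinely stronger pairs alphabetically.

Full-scale defaults follow the method's published configuration: population
1,000, 500 reproductions and at most 500 new children per generation, 1,000
generations, α = 10⁻⁶. `GAConfig.scaled_down()` is the desk-scale
configuration used in tests: population 50, 20 generations, with 100
reproductions/children per generation. The reproduction budget is *not*
scaled with the population because the search space (2,080 pairs) does not
shrink: 100 per generation is ~5% of the space, versus ~24% at full scale.
With the population covering the whole space (2,080) and one generation,
`run_ga` reduces exactly to a brute-force significance scan
(`exhaustive_scan`), which tests verify.

## Combining features, SVM, cross-validation

For every selected pair, both concatenated hexamers t1+t2 and t2+t1 are
removed from the selected hexamer list (survivor order preserved); the
feature vector is hexamer both-strand counts followed by pair
min-frequencies. Features are min–max scaled to [0,1] on the training data
(the standard LIBSVM workflow; a feature constant in training scales to 0
and is kept, logged), then fed to an RBF-kernel SVM with C = 1 and
γ = 1/#features — the library defaults, since nothing else is specified by
the method — via scikit-learn's LIBSVM binding. Promoter is the positive
class (+1).

Cross-validation is stratified: each class is shuffled and dealt
round-robin into k folds (sizes differ by ≤1; 305 per class and k=5 give
61+61 test, 244+244 training per fold). Feature selection runs on the
training folds only; a sentinel-leakage test verifies that a hexamer
dominating only the held-out fold does not dominate the training ranking.
Per-fold GA seeds are `config.ga.seed + fold`.

Metrics are integer percentages with round-half-up (56/61 → 92), and fold
averages are round-half-up means of the per-fold integers — this is the
arithmetic that reproduces the reference table (sensitivities 92, 89, 89,
85, 90 → 89; specificities 85, 85, 90, 84, 84 → 85.6 → 86).

## RTP-vs-hexamer significance

For a pair, `FD_RTP` is the absolute difference between its total
min-frequency in promoters and in non-promoters; `FD_hex1`/`FD_hex2` are
the Diff-style count differences of the two concatenated hexamers. The
statistic is `diff = FD_RTP − max(FD_hex1, FD_hex2)`: the pair must beat
its *better* concatenation. The max is a design choice where the definition
was genuinely open; `sum` and `mean` penalties are available via a `mode`
option. The empirical p-value of an observed average diff over n pairs is
the fraction of N random cases (default N = 1,000; each case draws n pairs
uniformly from the 2,080 canonical pairs) whose average is at least the
observed value. No +1 small-sample correction is applied, so an observed
value above every resample reports exactly 0. The implementation
precomputes the 2,080-entry diff table once, so resampling is a table
lookup; a test checks the table against the direct per-pair path.

## Synthetic data generator

`synth.generate` draws each sequence i.i.d. from a background composition
(default uniform; an AT-rich preset A=T=0.3 is provided), then overwrites
planted motifs at uniformly drawn non-overlapping positions (bounded
retries, default 100, with a loud failure when placement is infeasible).
`plant_rtp_signal` plants a triplet pair with a uniform random gap (≥1, so
the concatenated hexamer is never formed at planted sites); the gap bases
stay background.

The reference study conditions (`promoter_study_spec`) are: 100 sequences
per class (305 in the acceptance script), 251 bp, uniform background;
promoters carry one copy each of eight core-promoter-style hexamer elements
(TATA box, Y-patch-like, CAAT-box-like, GC-box-like, G-box, and three
further elements) plus four copies of the gapped pair CAG...GTC (gap
4–10 bp). These choices encode how real promoter signal is structured:
individual core elements occur about once per promoter, and discrimination
comes from many weakly informative words rather than one dominant one. The
eight elements are chosen with pairwise disjoint triplet
reverse-complement classes (and disjoint from the planted pair's classes)
so each contributes an independent hexamer feature without compounding
triplet-level signal.

What the generator does *not* model: positional structure (TATA placement
relative to a TSS), degenerate/IUPAC motifs, codon bias in mRNA negatives,
conservation structure in rRNA, and length variation. Passing tests on this
generator therefore demonstrate that the pipeline recovers compositional
and paired-word signal of realistic strength at realistic sample sizes —
not that it attains any particular accuracy on real promoter databases.

## Problem sizes and tolerances in the test suite

Unit and property tests run on toy datasets (2–40 sequences, 18–100 bp).
End-to-end checks use the study conditions at 100/class × 251 bp and the
desk-scale GA; the acceptance script uses 305/class. Null-calibration
checks assert chance-level CV accuracy within ±10 percentage points and a
non-small permutation p-value (>0.01); planted-signal checks assert ≥95%
average sensitivity and specificity. The pooled t-test is required to agree
with an independent reference implementation to 1e-10.

## Known limitations

- The GA at desk scale explores a 2,080-pair space with a 50-slot
  population; recovery of a specific planted pair is reliable under the
  reference conditions but degrades when a planted hexamer floods the
  population with correlated significant pairs (several copies of the same
  element per sequence).
- The min-frequency statistic couples a strongly elevated triplet to every
  partner, so single-triplet signal produces a halo of significant pairs;
  selected RTP sets should be read as identifiability classes, not
  individual spellings.
- Model artifacts are serialized with joblib and are not portable across
  major scikit-learn versions (a versioned header gives a clear error).
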