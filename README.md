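# promobot

Classification of plant promoter sequences from k-mer composition, using two
complementary feature-selection methods and a support vector machine.

Promoters — the regulatory regions upstream of transcription start sites —
differ from coding and structural-RNA sequence in their short-word
composition: plant core promoters are rich in elements such as the TATA box
and pyrimidine (Y) patches. This package implements a classifier for
fixed-length DNA segments (canonically 251 bp, −200..+51 around the TSS)
that separates promoters from non-promoters using two kinds of features:

- **FDAFSA** (Frequency Distribution Analyzed Feature Selection): every
  hexamer *i* is scored by `Diff_i = |CP_i − CNP_i|`, where `CP_i` and
  `CNP_i` are its total counts over all promoter and non-promoter training
  sequences (overlapping windows, both strands). The top 25% of the 4,096
  hexamers (1,024 features) are kept.
- **RTPFSGA** (Random Triplet Pair Feature Selecting Genetic Algorithm): a
  *random triplet pair* (RTP) is an unordered pair of 3-mers, not required
  to be adjacent; its per-sequence frequency is `min(count(t1), count(t2))`.
  A genetic algorithm (binary tournament selection, triplet-swap crossover
  with probability 0.8, mutation with probability 0.05, elitist μ+λ
  survival) evolves pairs toward small p-values of the pooled two-sample
  t-test (df = n₁+n₂−2) comparing per-sequence frequencies between classes;
  pairs with p < α (default 10⁻⁶) are selected. Non-adjacent pairs capture
  distal sequence elements that no single hexamer can represent.

The two sets are merged after removing any hexamer equal to a concatenation
(t1+t2 or t2+t1) of a selected pair; sequences are vectorized by feature
counts, min–max scaled to [0,1], and classified with an RBF-kernel SVM
(LIBSVM defaults: C = 1, γ = 1/#features). Performance is reported by
stratified k-fold cross-validation as integer-percent sensitivity
(TP/(TP+FN)) and specificity (TN/(TN+FP)), with feature selection repeated
inside every fold. A permutation analysis quantifies how much an RTP
out-discriminates its two concatenated "candidate hexamers"
(`diff = FD_RTP − max(FD_hex1, FD_hex2)`), comparing the observed average
against 1,000 random pair sets.

A seeded synthetic-data generator plants core-promoter-style motifs and
gapped triplet pairs into background sequence, so the entire pipeline runs
and is tested without any external database.

## Worked example

```python
import promobot as pb
from promobot.rtpfsga import GAConfig
from promobot.synth import promoter_study_spec

# 100 promoters (8 planted single-copy elements + a gapped CAG...GTC pair)
# and 100 background sequences, 251 bp, 5 folds
data = pb.generate(promoter_study_spec(seed=7), k_folds=5)

config = pb.PipelineConfig(ga=GAConfig.scaled_down(alpha=1e-3, seed=0))
report = pb.cross_validate(data, config)
print(report.to_frame().to_string(index=False))
```

```
   fold TP FN TN FP  sensitivity  specificity
      0 20  0 20  0          100          100
      1 20  0 19  1          100           95
      2 20  0 19  1          100           95
      3 20  0 20  0          100          100
      4 20  0 20  0          100          100
average                      100           98
```

Each fold holds out 20 promoters and 20 non-promoters; features are
selected on the other 80+80 only. The averages are round-half-up means of
the per-fold integer percentages. The GA recovers the planted pair — under
both-strand counting a triplet and its reverse complement are
indistinguishable, so the pair surfaces as its four equivalent spellings:

```python
rtps = pb.run_ga(data, GAConfig.scaled_down(alpha=1e-3, seed=0))
print([(r.t1, r.t2) for r in rtps[:4]])
# [('CAG', 'GAC'), ('CAG', 'GTC'), ('CTG', 'GAC'), ('CTG', 'GTC')]  p = 2.2e-17
```

The same workflow is available from the shell via the `promobot` command
(subcommands `simulate`, `select-features`, `train`, `predict`, `cv`,
`significance`); run `promobot --help`.

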