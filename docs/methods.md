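# Methods

## Problem and model

A CTCF binding site is represented by the best occurrence of the 19-bp CTCF
core motif inside its ChIP-seq peak, and the classification target is
whether that site overlaps a ChIA-PET loop anchor. The classifier input per
site is a 237-dimensional vector: a 59-position one-hot block (motif plus
20-bp flanks, read in motif orientation) and one continuous binding
intensity. The pipeline makes three substantive modelling commitments:

* **One best motif per peak.** Scanning maximizes the log2-odds score over
  all offsets and both strands and keeps a single hit; peaks with no
  scoreable window (all-N, too short) are dropped with a logged count.
  Scores are log2 odds against a background distribution (uniform by
  default); the base of the logarithm only rescales scores, so group
  comparisons and rankings are unaffected by that choice. Ties break
  deterministically: smaller start first, then + before −.
* **Anchor overlap means ≥ 1 shared base.** Coordinates are uniformly
  0-based half-open (the BED convention, never converted), so intervals
  [100,119) and [118,200) overlap and [100,119)/[119,200) do not. This is
  the weakest defensible reading of "overlap"; it is stated explicitly and
  tested at the boundary. Anchors are unstranded, and the loop FDR filter
  is strict (< 0.05, so FDR = 0.05 is dropped).
* **The one-hot channel order is A, T, C, G.** This non-alphabetical order
  is the published convention for this encoding and is preserved verbatim;
  every consumer of the feature matrix assumes it. N encodes as all zeros,
  and other IUPAC ambiguity codes are collapsed to N on input with a
  warning.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| PWM width | 19 bp | length of the CTCF core motif |
| flank | 20 bp | context added on each side → 59-bp window |
| pseudocount | 0.8 | added per cell when converting counts to probabilities |
| FDR threshold | 0.05 | strict upper bound for loops that count as real |
| score threshold | 0.5 | classification cut-off (score ≥ threshold → positive) |
| k, test fraction | 10, 0.1 | folds and held-out share of the split protocol |

Intensity normalization is a bare log2 of the narrowPeak signalValue:
values ≤ 0 are a hard error, values in (0,1) give negative features and are
kept without clipping. Sites whose 59-bp window would cross a chromosome
end are dropped, never padded — padding would invent sequence; the dropped
count is logged.

## Split protocol and models

`make_split` draws a stratified held-out test set (one tenth) and
stratified 10 folds over the remaining training pool, all determined by one
seed; every downstream comparison (model table, ablation) reuses the same
frozen plan, so differences between rows of a table cannot come from
re-splitting. Fold models train only on their 9 training folds; the final
model refits on the whole training pool and is scored once on the test set.

Model hyperparameters are standard defaults, recorded in every run log:
SVM C=1 with RBF kernel and gamma = 1/(d·Var(X)); random forest with 500
trees; logistic regression with L2 regularization; SGD with logistic loss;
Gaussian naive Bayes and LDA over the full merged matrix. The continuous
intensity column is z-scored with training-set statistics for the
scale-sensitive models (SVM, LR, SGD, LDA, NB, CNN); the one-hot block is
left as 0/1; the random forest sees raw features. Scores are P(label = 1)
where the estimator is probabilistic; for the margin-only SVM the decision
value is min-max rescaled into [0,1] — AUROC/AUPRC are rank-based, so this
rescaling cannot change them.

The CNN is a deliberately minimal reference architecture — one 1-D
convolution (16 filters, width 9, 4 input channels) over the one-hot
window, ReLU, global max pooling, the intensity concatenated at the dense
logistic head — trained full-batch with Adam (150 steps, lr 0.01) in numpy.
It is seeded and deterministic, included so the full model family can be
compared, and excluded from default acceptance runs; no claim is made that
a deeper architecture would not do better.

## Metrics

Sn, Sp, Pre, Acc, F1 and MCC are computed from the TP/FP/TN/FN tally at the
score threshold (≥, inclusive). Degenerate denominators return 0 with a
logged warning so the functions are total; real runs do not hit these
cases. AUROC is computed from the Mann–Whitney rank statistic U/(n₁n₀) with
average ranks for ties — this equals the trapezoidal area under the ROC
with grouped thresholds, and the trapezoidal form (scikit-learn) serves as
an independent cross-check in the tests, not as the implementation. AUPRC
is step-interpolated average precision.

## Synthetic data: what it emulates, what it does not

The generator plants one motif (sampled from an informative PWM, consensus
probability 0.85 per position) per site slot in an i.i.d. uniform-ACGT
background, assigns a chosen fraction of sites to be true anchors, and
gives positives two signals: signalValue = 2^N(μ₊, σ) versus 2^N(μ₋, σ)
for negatives — log-normal on the natural scale so the log2-normalized
intensities are exactly normal and t-test behaviour is analytically
checkable — and flank bases drawn with a per-position preferred-base tilt
(+0.15 probability by default). Loops are generated anchor-first from the
positive sites' peak intervals with FDR ~ U(0.001, 0.049), each anchor
shared cyclically between two loops so duplicate anchors occur and
deduplication is exercised; decoy loops with FDR ≥ 0.05 anchored on
negative sites are always present so the FDR filter is load-bearing in
every end-to-end test.

The default ("strong") conditions are 2000 sites, 45% positive,
μ₊ − μ₋ = 2 log2 units with σ = 1, flank bias 0.15; the null conditions
zero both effects. These sizes keep a full SVM cross-validation in seconds
while leaving sampling error on a held-out AUROC near ±0.04. What passing
tests on this data shows: the pipeline recovers planted labels exactly,
finds planted motifs, measures the planted effect size, and its classifiers
detect signal when present and none when absent. What it does not show:
performance on real genomes — real CTCF sites cluster, flank signal is not
i.i.d. per position, intensity distributions are heavier-tailed, and loop
anchors are not a deterministic function of peak intervals. Real-data
accuracy claims require real data.

One consequence of the strong defaults worth knowing: a 0.15 tilt at each
of 40 flank positions is, in aggregate, as discriminative as the 2-unit
intensity shift, so flank-only and intensity-only classifiers score
similarly there. The ablation ordering check (intensity-only beating
flank-only) therefore runs on an intensity-dominated variant (flank bias
0.02, all else equal), which is the regime that ordering claim is about.

## Numerical and degenerate-input choices

* Windows containing N score −∞ in scanning; an all-N region yields a
  no-hit sentinel (dropped, counted, logged).
* PWM probabilities must be strictly positive (enforce via pseudocount);
  an all-zero count row with pseudocount 0 is an error.
* Information content excludes N from a position's counts; a position with
  no informative bases reports 0 bits. Values are clamped to [0, 2] against
  floating-point drift. No small-sample correction is applied.
* Group comparisons use Welch's (unequal-variance) two-sided t-test: the
  positive and negative intensity variances are not assumed equal.
* Feature importance defaults to random-forest impurity importance, with
  permutation importance available; impurity importance is known to favour
  continuous features, which is acceptable here because the intensity
  column genuinely carries the dominant signal in the conditions tested.

## Known limitations

* One hit per peak discards secondary motifs; peaks with two true sites
  are under-represented.
* The loop-file dialect is a minimal 7-column TSV (chromA startA endA
  chromB startB endB fdr); richer interaction formats must be projected
  onto it.
* The CNN is a floor, not a ceiling, for sequence-model performance.
* Min-max rescaling of SVM decision values is batch-dependent; threshold
  metrics at 0.5 for the SVM are therefore less interpretable than its
  rank metrics (AUROC/AUPRC), which are unaffected.
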