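# loopanchor

Predicts whether a single CTCF binding site acts as a chromatin-loop
anchor, from its DNA sequence context and ChIP-seq binding intensity.

CTCF, an 11-zinc-finger DNA-binding protein, marks the boundaries of
chromatin loops: where bound CTCF halts cohesin-driven loop extrusion, a
loop anchor forms. But only a fraction of the tens of thousands of CTCF
sites in a genome actually anchor loops. `loopanchor` frames this as a
binary classification problem and provides the full pipeline for it, for
researchers in regulatory genomics who have CTCF ChIP-seq peaks and
ChIA-PET loop calls for the same cell type:

1. **Motif scanning** — each peak is scanned on both strands with a 19-bp
   CTCF position weight matrix; the best log2-odds occurrence
   `max_{offset, strand} Σᵢ log₂(pᵢ[bᵢ]/q[bᵢ])` and its strand are kept.
2. **Labeling** — ChIA-PET interactions are filtered at FDR < 0.05, their
   anchors pooled and deduplicated; a site is a positive example iff its
   motif interval overlaps (≥ 1 bp, half-open coordinates) any anchor.
3. **Features** — the motif plus 20 bp of flank on each side gives a 59-bp
   window, read in motif orientation (minus-strand sites are
   reverse-complemented). One-hot encoding with channel order **A, T, C, G**
   (A=(1,0,0,0), T=(0,1,0,0), C=(0,0,1,0), G=(0,0,0,1) — deliberately not
   alphabetical) yields 236 binary columns, merged with one continuous
   column, log₂(signalValue), the normalized binding intensity.
4. **Models & metrics** — SVM (RBF), random forest, LDA, Gaussian naive
   Bayes, logistic regression, SGD-logistic and a minimal 1-D CNN, all
   evaluated as: hold out one tenth as an independent test set, run
   stratified 10-fold cross-validation on the rest, refit on the full
   training set, score once on the test set. Metrics: Sn = TP/(TP+FN),
   Sp = TN/(TN+FP), Pre = TP/(TP+FP), Acc, F1 = 2·Pre·Sn/(Pre+Sn),
   MCC = (TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), AUROC (rank
   statistic), AUPRC (average precision).
5. **Feature analysis** — per-position information content
   (2 + Σ_b f·log₂f bits), Welch t-tests between positive and negative
   intensities and motif scores, random-forest importance ranking, and an
   ablation over six feature sets (core motif / flanks / intensity and
   combinations) under one frozen split.

A synthetic-data generator (`loopanchor.simulate`) produces all four input
file types with planted ground truth, so the whole pipeline runs and is
tested without any download.

## Worked example

```python
from loopanchor import (ModelSpec, build_feature_rows, cross_validate,
                        default_strong_config, make_split, simulate)
from loopanchor.metrics import report_table

result = simulate(default_strong_config(seed=7), "dataset")
pipe = build_feature_rows(result.fasta_path, result.narrowpeak_path,
                          result.loops_path, result.pwm_path)
plan = make_split(len(pipe.rows), [r.label for r in pipe.rows], k=10, seed=7)
res = cross_validate(ModelSpec("SVM", seed=7), pipe.rows, plan)
print(report_table({"SVM": res.test_report}))
```

prints

```
model      Sn      Sp     Pre     Acc     MCC      F1   AUROC   AUPRC
SVM    0.8444  0.9455  0.9268  0.9000  0.7990  0.8837  0.9625  0.9632
```

i.e. on 2000 synthetic sites (900 true anchors) the held-out SVM recovers
the planted signal — a 2-unit log₂ intensity shift plus a flank-composition
tilt — with AUROC 0.96 and a balanced error profile (Sn 0.84 at Sp 0.95).
The same dataset is generated by `examples/01_simulate_dataset.py`; the
other `examples/` scripts walk through scanning/labeling, model comparison
and the feature analyses, each printing its numbers with a note on what
they mean.

The pipeline is also available as shell subcommands
(`loopanchor simulate | scan | label | featurize | train | evaluate |
ablate | analyze`); each stage reads the previous stage's files and writes
a resolved-config JSON for reproducibility.

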