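"""Train several classifiers under the held-out + 10-fold protocol.

One tenth of the sites is set aside as an independent test set; the rest is
the training set, on which 10-fold cross-validation runs; the final model
is refit on the full training set and scored once on the test set. The
table prints the held-out metrics: Sn, Sp, Pre, Acc, MCC, F1, AUROC, AUPRC.
"""

from loopanchor import (
    ModelSpec,
    build_feature_rows,
    cross_validate,
    default_strong_config,
    make_split,
    simulate,
)
from loopanchor.metrics import report_table

result = simulate(default_strong_config(seed=7), "example_output/dataset")
pipe = build_feature_rows(result.fasta_path, result.narrowpeak_path,
                          result.loops_path, result.pwm_path)

rows = pipe.rows
plan = make_split(len(rows), [r.label for r in rows], k=10,
                  test_fraction=0.1, seed=7)

reports = {}
for name in ("SVM", "LR", "LDA", "NB", "SGD"):
    res = cross_validate(ModelSpec(name, seed=7), rows, plan)
    reports[name] = res.test_report
    print(f"{name}: mean fold AUROC {res.mean_fold('auroc'):.4f}")

print()
print(report_table(reports))
# Every model sees the identical frozen split, so the columns are directly
# comparable; AUROC well above 0.9 reflects the planted intensity shift
# plus the flanking-sequence tilt of the synthetic anchors.
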