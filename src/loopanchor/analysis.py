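"""Downstream feature analyses.

Covers four questions about the assembled feature matrix:

* which window positions are informative (per-position information content,
  2 − Shannon entropy in bits, as drawn in a sequence logo);
* do positives and negatives differ in binding intensity / motif score
  (Welch two-sided t-test — intensity variances visibly differ between the
  groups, so the unequal-variance form is used);
* which features drive the classifier (random-forest impurity importance by
  default, permutation importance optionally);
* how much each feature block contributes (ablation over the six feature
  sets — core motif, flanks, intensity, and their combinations — under one
  frozen train/test split).

Window indexing (flank = 20, core width 19): positions 0–19 are the
upstream flank, 20–38 the core motif, 39–58 the downstream flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .features import ONEHOT_BASES, feature_names
from .metrics import MetricsReport
from .models import ModelSpec, SplitPlan, cross_validate, fit_arrays, _rows_to_xy


@dataclass(frozen=True)
class PositionProfile:
    position: int
    base_freqs: np.ndarray  # order A,T,C,G (one-hot channel order)
    info_content: float

    def __post_init__(self):
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or not np.isclose(freqs.sum(), 1.0, atol=1e-9):
            raise ValueError("base_freqs must be 4 values summing to 1")
        if not (-1e-12 <= self.info_content <= 2 + 1e-12):
            raise ValueError("info_content must lie in [0, 2] bits")
        object.__setattr__(self, "base_freqs", freqs)


def information_content(windows) -> list[PositionProfile]:
    """Per-position information content of a set of equal-length windows.

    IC_j = 2 + sum_b f_jb * log2(f_jb), with 0*log(0) = 0 and N bases
    excluded from the position's counts. No small-sample correction.
    """
    windows = list(windows)
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError("windows must have equal length")
    (L,) = lengths
    arr = np.array([list(w.upper()) for w in windows])
    profiles = []
    for j in range(L):
        col = arr[:, j]
        counts = np.array([(col == b).sum() for b in ONEHOT_BASES], dtype=float)
        total = counts.sum()  # excludes N
        if total == 0:
            freqs = np.full(4, 0.25)
            ic = 0.0
        else:
            freqs = counts / total
            nz = freqs[freqs > 0]
            ic = float(2.0 + (nz * np.log2(nz)).sum())
        profiles.append(PositionProfile(j, freqs, max(0.0, min(2.0, ic))))
    return profiles


def compare_groups(values_pos, values_neg) -> dict[str, float]:
    """Welch two-sided t-test between positive- and negative-set values;
    the group means are reported so the direction is explicit."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(pos, neg, equal_var=False)
    return {
        "t_statistic": float(t),
        "p_value": float(p),
        "mean_pos": float(pos.mean()),
        "mean_neg": float(neg.mean()),
    }


def rank_features(rows, method: str = "impurity", seed: int = 0,
                  n_estimators: int = 500) -> list[tuple[str, float]]:
    """Descending feature-importance ranking over the merged matrix.

    Feature ids name their origin (``pos12_T`` = window position 12, channel
    T; ``intensity``). ``method`` is ``"impurity"`` (random-forest Gini
    importance) or ``"permutation"``.
    """
    X, y = _rows_to_xy(rows)
    if np.unique(y).size < 2:
        raise ValueError("labels are constant; importance is undefined")
    names = feature_names((X.shape[1] - 1) // 4)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1)
    rf.fit(X, y)
    if method == "impurity":
        importances = rf.feature_importances_
    elif method == "permutation":
        importances = permutation_importance(
            rf, X, y, n_repeats=5, random_state=seed
        ).importances_mean
    else:
        raise ValueError(f"unknown importance method {method!r}")
    order = np.argsort(importances)[::-1]
    return [(names[i], float(importances[i])) for i in order]


# ---------------------------------------------------------------------------
# ablation over feature blocks
# ---------------------------------------------------------------------------

FEATURE_SETS = (
    "core_motif", "flank", "intensity",
    "core+intensity", "flank+intensity", "all",
)


def _block_columns(window_length: int, core_start: int, core_end: int):
    core = [4 * p + c for p in range(core_start, core_end) for c in range(4)]
    flank = [
        4 * p + c
        for p in list(range(0, core_start)) + list(range(core_end, window_length))
        for c in range(4)
    ]
    return np.array(core), np.array(flank)


def feature_set_columns(name: str, window_length: int = 59,
                        core_start: int = 20, core_end: int = 39):
    """Column indices (into the merged matrix, intensity last) of one named
    feature set, plus which of those columns are continuous."""
    core, flank = _block_columns(window_length, core_start, core_end)
    intensity = np.array([4 * window_length])
    sets = {
        "core_motif": core,
        "flank": flank,
        "intensity": intensity,
        "core+intensity": np.concatenate([core, intensity]),
        "flank+intensity": np.concatenate([flank, intensity]),
        "all": np.arange(4 * window_length + 1),
    }
    if name not in sets:
        raise ValueError(f"unknown feature set {name!r}")
    cols = sets[name]
    continuous = np.nonzero(np.isin(cols, intensity))[0]
    return cols, continuous


@dataclass(frozen=True)
class AblationResult:
    feature_set: str
    acc: float
    auroc: float
    auprc: float
    report: MetricsReport


def run_ablation(rows, spec: ModelSpec, plan: SplitPlan,
                 window_length: int = 59) -> list[AblationResult]:
    """Train/evaluate one model on each of the six feature sets under the
    same frozen split plan (no re-splitting between sets)."""
    X, y = _rows_to_xy(rows)
    results = []
    for name in FEATURE_SETS:
        cols, cont = feature_set_columns(name, window_length)
        res = cross_validate(spec, (X[:, cols], y), plan,
                             continuous_cols=tuple(cont))
        rep = res.test_report
        results.append(AblationResult(name, rep.acc, rep.auroc, rep.auprc, rep))
    return results


def write_ablation_tsv(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_set\tAcc\tAUROC\tAUPRC\n")
        for r in results:
            fh.write(f"{r.feature_set}\t{r.acc:.6f}\t{r.auroc:.6f}\t{r.auprc:.6f}\n")


def write_ic_tsv(profiles, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tfreq_A\tfreq_T\tfreq_C\tfreq_G\tinfo_content\n")
        for p in profiles:
            freqs = "\t".join(f"{f:.6f}" for f in p.base_freqs)
            fh.write(f"{p.position}\t{freqs}\t{p.info_content:.6f}\n")
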