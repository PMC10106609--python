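"""Classifier training and evaluation under the held-out + K-fold protocol.

The split protocol: one tenth of the samples is set aside as an independent
test set; the remaining nine tenths are the training set, on which 10-fold
cross-validation is run (each fold serving as validation once); the final
model is refit on the whole training set and scored once on the test set.
Splits are stratified and fully determined by a seed.

Seven model families are supported: SVM (RBF), random forest, a minimal
1-D CNN, linear discriminant analysis, Gaussian naive Bayes, logistic
regression and an SGD-trained logistic model. Continuous columns (the
intensity) are z-scored with training-set statistics for the scale-sensitive
models; the one-hot block is left as 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from ._cnn import ConvNet
from .features import FeatureRow, design_matrix
from .metrics import MetricsReport, evaluate

MODEL_NAMES = ("SVM", "RF", "CNN", "LDA", "NB", "LR", "SGD")

#: models whose continuous columns are z-scored with train statistics
_SCALED = frozenset({"SVM", "LR", "SGD", "LDA", "NB", "CNN"})

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "SVM": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
    "RF": {"n_estimators": 500},
    "CNN": {"n_filters": 16, "kernel": 9, "epochs": 150, "lr": 0.01},
    "LDA": {},
    "NB": {},
    "LR": {"max_iter": 2000},  # sklearn's default L2 regularization
    "SGD": {"loss": "log_loss", "max_iter": 2000},
}


@dataclass(frozen=True)
class ModelSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unsupported model {self.name!r}; choose from {MODEL_NAMES}"
            )

    def resolved_hyperparameters(self) -> dict:
        hp = dict(DEFAULT_HYPERPARAMETERS[self.name])
        hp.update(self.hyperparameters)
        return hp


@dataclass(frozen=True)
class SplitPlan:
    """Frozen index sets: held-out test, training pool, and K folds that
    partition the training pool."""

    test_indices: np.ndarray
    train_indices: np.ndarray
    folds: tuple[np.ndarray, ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


def make_split(n: int, labels, k: int = 10, test_fraction: float = 0.1,
               seed: int = 0) -> SplitPlan:
    """Stratified held-out + K-fold plan, deterministic per seed."""
    labels = np.asarray(labels, dtype=int)
    if labels.size != n:
        raise ValueError("labels length must equal n")
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for k={k}")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    splitter = StratifiedShuffleSplit(
        n_splits=1, test_size=test_fraction, random_state=seed
    )
    train_idx, test_idx = next(splitter.split(np.zeros(n), labels))
    kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(
        train_idx[val] for _, val in kf.split(np.zeros(train_idx.size),
                                              labels[train_idx])
    )
    return SplitPlan(
        test_indices=np.sort(test_idx),
        train_indices=np.sort(train_idx),
        folds=folds,
        seed=seed,
    )


def _build_estimator(spec: ModelSpec):
    hp = spec.resolved_hyperparameters()
    if spec.name == "SVM":
        return SVC(random_state=spec.seed, **hp)
    if spec.name == "RF":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.name == "CNN":
        return ConvNet(seed=spec.seed, **hp)
    if spec.name == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if spec.name == "NB":
        return GaussianNB(**hp)
    if spec.name == "LR":
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.name == "SGD":
        return SGDClassifier(random_state=spec.seed, **hp)
    raise ValueError(spec.name)  # unreachable; guarded by ModelSpec


class FittedModel:
    """A trained estimator plus the training-set scaling of its continuous
    columns; exposes :meth:`predict_scores` in [0, 1]."""

    def __init__(self, spec: ModelSpec, estimator, continuous_cols, mean, std,
                 n_features: int):
        self.spec = spec
        self.estimator = estimator
        self.continuous_cols = continuous_cols
        self.mean = mean
        self.std = std
        self.n_features = n_features

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None or len(self.continuous_cols) == 0:
            return X
        X = X.astype(float, copy=True)
        X[:, self.continuous_cols] = (X[:, self.continuous_cols] - self.mean) / self.std
        return X

    def predict_scores(self, X) -> np.ndarray:
        """Anchor-likeness score per row, in [0, 1]; higher = more anchor-like.

        Probabilistic models report P(label=1); margin-only models (SVM)
        report a min-max rescaled decision value — AUROC/AUPRC are rank
        based, so the rescaling is harmless.
        """
        X = _as_array(X)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension "
                f"{self.n_features}"
            )
        Xs = self._transform(X)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(Xs)[:, 1]
        d = est.decision_function(Xs)
        lo, hi = d.min(), d.max()
        if hi == lo:
            return np.full(d.shape, 0.5)
        return (d - lo) / (hi - lo)


def _as_array(rows) -> np.ndarray:
    if isinstance(rows, np.ndarray):
        return rows
    if len(rows) and isinstance(rows[0], FeatureRow):
        return design_matrix(list(rows))[0]
    return np.asarray(rows, dtype=float)


def _rows_to_xy(rows) -> tuple[np.ndarray, np.ndarray]:
    """Accept either a list of FeatureRows or an (X, y) pair."""
    if isinstance(rows, tuple) and len(rows) == 2:
        return np.asarray(rows[0], dtype=float), np.asarray(rows[1], dtype=int)
    return design_matrix(list(rows))


def fit_arrays(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
               continuous_cols=(-1,)) -> FittedModel:
    """Train on a raw design matrix; ``continuous_cols`` names the columns to
    z-score (training statistics) for the scale-sensitive models."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    cols = np.array([c % X.shape[1] for c in continuous_cols], dtype=int)
    if spec.name in _SCALED and cols.size:
        mean = X[:, cols].mean(axis=0)
        std = X[:, cols].std(axis=0)
        std = np.where(std == 0, 1.0, std)
    else:
        mean = std = None
        cols = np.array([], dtype=int)
    model = FittedModel(spec, _build_estimator(spec), cols, mean, std,
                        n_features=X.shape[1])
    model.estimator.fit(model._transform(X), y)
    return model


def train(spec: ModelSpec, rows) -> FittedModel:
    """Train on FeatureRows (one-hot block + intensity as last column)."""
    X, y = design_matrix(list(rows))
    return fit_arrays(spec, X, y, continuous_cols=(-1,))


@dataclass(frozen=True)
class CVResult:
    fold_reports: tuple[MetricsReport, ...]
    test_report: MetricsReport
    spec: ModelSpec
    plan_seed: int

    def mean_fold(self, metric: str) -> float:
        return float(np.mean([getattr(r, metric) for r in self.fold_reports]))


def cross_validate(spec: ModelSpec, rows, plan: SplitPlan,
                   continuous_cols=(-1,)) -> CVResult:
    """K fold reports (models trained on the other K-1 folds) plus one
    held-out test report from the model refit on the full training pool."""
    X, y = _rows_to_xy(rows)
    if X.shape[0] != y.size:
        raise ValueError("rows and labels inconsistent")
    fold_reports = []
    train_set = set(plan.train_indices.tolist())
    for fold in plan.folds:
        fold_set = set(fold.tolist())
        tr = np.array(sorted(train_set - fold_set), dtype=int)
        model = fit_arrays(spec, X[tr], y[tr], continuous_cols)
        fold_reports.append(evaluate(y[fold], model.predict_scores(X[fold])))
    final = fit_arrays(spec, X[plan.train_indices], y[plan.train_indices],
                       continuous_cols)
    test_report = evaluate(
        y[plan.test_indices], final.predict_scores(X[plan.test_indices])
    )
    return CVResult(
        fold_reports=tuple(fold_reports),
        test_report=test_report,
        spec=spec,
        plan_seed=plan.seed,
    )
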