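"""Datasets, the evaluation protocol and metrics.

Every candidate model is scored with the same protocol: one stratified
70/30 split fixed by the run-level seed; the genetic algorithms' fitness is
the mean AUC over a stratified 4-fold cross-validation *inside* the 70%
training part, and the final reported metrics come from refitting on the
whole 70% and scoring the untouched 30% hold-out.  Fixing the split once
per run makes fitness values comparable across individuals and generations.

"cancer" is the positive class for sensitivity, specificity and F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import f_classif
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import NuSVC

from .params import ModelConfig
from .roi import LABEL_CANCER, LABEL_NO_CANCER, LABELS

POSITIVE_LABEL = LABEL_CANCER
MIN_SAMPLES = 8
DEFAULT_HOLDOUT_FRACTION = 0.3
DEFAULT_CV_FOLDS = 4
# Cap on libsvm iterations: well-behaved fits at study sizes converge in
# well under a thousand iterations, while degenerate hyperparameter
# combinations (e.g. tolerance 1e-8 on an inseparable column subset) can
# otherwise spin for minutes.  A capped non-converged fit either still
# yields usable decision scores or fails and scores fitness 0.
SVM_MAX_ITER = 100_000


@dataclass(frozen=True)
class Dataset:
    """An n x d feature matrix with binary diagnosis labels.

    ``y`` holds 1 for cancer and 0 for no_cancer.
    """

    features: np.ndarray
    y: np.ndarray
    column_names: tuple
    exam_ids: tuple = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2:
            raise ValueError("features must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and labels disagree on n")
        if X.shape[1] != len(self.column_names):
            raise ValueError("column_names length != number of feature columns")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("both classes must be present")
        ids = tuple(self.exam_ids) if self.exam_ids else tuple(
            f"exam_{i}" for i in range(X.shape[0])
        )
        if len(ids) != X.shape[0]:
            raise ValueError("exam_ids length != n")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "column_names", tuple(self.column_names))
        object.__setattr__(self, "exam_ids", ids)

    @classmethod
    def from_labels(
        cls,
        features: np.ndarray,
        labels: Sequence[str],
        column_names: Sequence[str],
        exam_ids: Sequence[str] = (),
    ) -> "Dataset":
        y = []
        for lab in labels:
            if lab not in LABELS:
                raise ValueError(
                    f"unknown class token {lab!r}; allowed: {LABELS}"
                )
            y.append(1 if lab == POSITIVE_LABEL else 0)
        return cls(
            features=np.asarray(features, dtype=float),
            y=np.asarray(y, dtype=int),
            column_names=tuple(column_names),
            exam_ids=tuple(exam_ids),
        )

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def labels(self) -> List[str]:
        return [LABEL_CANCER if v else LABEL_NO_CANCER for v in self.y]


@dataclass(frozen=True)
class EvaluationResult:
    """The five diagnosis metrics plus the protocol that produced them."""

    auc: float
    f1: float
    acc: float
    sens: float
    spec: float
    cv_auc: float
    protocol: dict = field(default_factory=dict)

    def as_percentages(self, ndigits: int = 2) -> dict:
        # round-half-even, matching the usual table style
        return {
            m: round(100.0 * getattr(self, m), ndigits)
            for m in ("auc", "f1", "acc", "sens", "spec")
        }


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """ACC / SENS / SPEC / F1 with class 1 (cancer) positive."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(y_true)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {"acc": acc, "sens": sens, "spec": spec, "f1": f1}


def _make_svm(config: ModelConfig) -> NuSVC:
    return NuSVC(
        nu=config.nu,
        kernel=config.kernel,
        gamma=config.gamma,
        coef0=config.coef0,
        degree=config.degree,
        tol=config.tolerance,
        max_iter=SVM_MAX_ITER,
    )


class Evaluator:
    """Evaluation protocol bound to one dataset and one seed.

    The 70/30 split and the 4 folds inside the training part are drawn once
    at construction; every configuration is then scored against the same
    partitions.  Failed fits (e.g. an infeasible ``nu`` for the class
    balance of a fold) score fitness 0 instead of raising, so a genetic
    search can discard such individuals and move on.
    """

    def __init__(
        self,
        data: Dataset,
        seed: int,
        holdout_fraction: float = DEFAULT_HOLDOUT_FRACTION,
        cv_folds: int = DEFAULT_CV_FOLDS,
    ) -> None:
        if data.n < MIN_SAMPLES:
            raise ValueError(
                f"need at least {MIN_SAMPLES} samples to split and cross-validate"
            )
        self.data = data
        self.seed = int(seed)
        self.holdout_fraction = float(holdout_fraction)
        self.cv_folds = int(cv_folds)
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=holdout_fraction, random_state=self.seed
        )
        train_idx, test_idx = next(splitter.split(data.features, data.y))
        self.train_idx = np.sort(train_idx)
        self.test_idx = np.sort(test_idx)
        y_train = data.y[self.train_idx]
        if len(np.unique(y_train)) < 2 or len(np.unique(data.y[self.test_idx])) < 2:
            raise ValueError("protocol error: a split part has a single class")
        kf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=self.seed)
        self.folds = []
        X_train = data.features[self.train_idx]
        for fit_rel, val_rel in kf.split(X_train, y_train):
            if len(np.unique(y_train[fit_rel])) < 2:
                raise ValueError("protocol error: single-class fold")
            self.folds.append((fit_rel, val_rel))
        self._X_train = X_train
        self._y_train = y_train
        self._X_test = data.features[self.test_idx]
        self._y_test = data.y[self.test_idx]

    # -- protocol descriptor -------------------------------------------------
    def protocol(self) -> dict:
        return {
            "holdout_fraction": self.holdout_fraction,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
        }

    def _columns(self, mask) -> np.ndarray:
        if mask is None:
            return np.arange(self.data.d)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.data.d,):
            raise ValueError("feature mask length != number of columns")
        cols = np.flatnonzero(mask)
        if cols.size == 0:
            raise ValueError("feature mask selects no columns")
        return cols

    def fitness(self, config: ModelConfig, mask=None) -> float:
        """Mean AUC over the stratified CV folds of the training part.

        Returns 0.0 when any fold's fit fails (infeasible configuration).
        """
        cols = self._columns(mask)
        aucs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for fit_rel, val_rel in self.folds:
                try:
                    model = _make_svm(config)
                    model.fit(
                        self._X_train[np.ix_(fit_rel, cols)],
                        self._y_train[fit_rel],
                    )
                    scores = model.decision_function(
                        self._X_train[np.ix_(val_rel, cols)]
                    )
                except (ValueError, ArithmeticError):
                    return 0.0
                if not np.all(np.isfinite(scores)):
                    return 0.0
                aucs.append(roc_auc_score(self._y_train[val_rel], scores))
        return float(np.mean(aucs))

    def holdout(self, config: ModelConfig, mask=None) -> EvaluationResult:
        """Refit on the 70% part and score the 30% hold-out."""
        cols = self._columns(mask)
        cv_auc = self.fitness(config, mask)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = _make_svm(config)
                model.fit(self._X_train[:, cols], self._y_train)
                scores = model.decision_function(self._X_test[:, cols])
                preds = model.predict(self._X_test[:, cols])
        except (ValueError, ArithmeticError):
            return EvaluationResult(
                auc=0.0, f1=0.0, acc=0.0, sens=0.0, spec=0.0,
                cv_auc=cv_auc, protocol=self.protocol(),
            )
        auc = float(roc_auc_score(self._y_test, scores))
        cm = confusion_metrics(self._y_test, preds)
        return EvaluationResult(
            auc=auc, f1=cm["f1"], acc=cm["acc"], sens=cm["sens"],
            spec=cm["spec"], cv_auc=cv_auc, protocol=self.protocol(),
        )


def evaluate(
    config: ModelConfig,
    data: Dataset,
    mask=None,
    seed: int = 0,
    holdout_fraction: float = DEFAULT_HOLDOUT_FRACTION,
    cv_folds: int = DEFAULT_CV_FOLDS,
) -> EvaluationResult:
    """One-shot evaluation of a configuration under the standard protocol."""
    ev = Evaluator(data, seed, holdout_fraction, cv_folds)
    return ev.holdout(config, mask)


def percentile_baseline(
    data: Dataset, percentile: float
) -> np.ndarray:
    """Filter baseline: activate the top-scoring fraction of columns.

    Columns are ranked by the ANOVA-F statistic of class association and the
    top ``ceil(percentile * d)`` are activated; returns a boolean mask.
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must be in (0, 1]")
    k = int(np.ceil(percentile * data.d))
    if k == 0:
        raise ValueError("percentile selects zero columns")
    scores, _ = f_classif(data.features, data.y)
    scores = np.nan_to_num(scores, nan=0.0)
    order = np.argsort(-scores, kind="stable")
    mask = np.zeros(data.d, dtype=bool)
    mask[order[:k]] = True
    return mask
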