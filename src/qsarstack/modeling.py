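"""Nested cross-validation, performance metrics, model gating, y-scrambling.

Each model configuration is a (classifier, feature-selection method, number
of features) triple. Performance is estimated by stratified nested CV —
feature selection happens inside each outer training fold only — and the
confusion counts are pooled over outer folds. Models pass the quality gate
only with balanced accuracy AND positive predictive value strictly above
70%. Y-scrambling reruns the identical pipeline on permuted labels; honest
models should collapse to chance-level balanced accuracy (~50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from qsarstack import feature_select
from qsarstack.synthetic import LabeledDataset

#: default model-quality gate (percent); strict inequalities
BA_GATE = 70.0
PPV_GATE = 70.0

CLASSIFIERS = ("rf", "svm", "adaboost_m1", "logistic", "c50_like", "bart_like")


def make_classifier(name: str, seed: int = 0, params: dict | None = None):
    """Instantiate a classifier by short name with library defaults.

    ``c50_like`` and ``bart_like`` are boosted-tree approximations of the
    C5.0 and Bayesian-additive-regression-trees learners.
    """
    params = dict(params or {})
    if name == "rf":
        params.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=seed, **params)
    if name == "svm":
        return SVC(random_state=seed, **params)
    if name == "adaboost_m1":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "logistic":
        params.setdefault("max_iter", 1000)
        return LogisticRegression(**params)
    if name == "c50_like":
        return GradientBoostingClassifier(random_state=seed, **params)
    if name == "bart_like":
        return HistGradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}; available: {CLASSIFIERS}")


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration: classifier x feature selection x k."""

    classifier: str
    fs_method: str
    k: int
    params: dict = field(default_factory=dict, hash=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; available: {CLASSIFIERS}"
            )
        if self.fs_method not in feature_select.AVAILABLE_METHODS:
            raise ValueError(f"unknown feature-selection method {self.fs_method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.classifier}_{self.fs_method}_{self.k}"


class QSARModel(ClassifierMixin, BaseEstimator):
    """Feature selection + classifier as one sklearn estimator.

    ``fit`` ranks the training columns with ``fs_method``, keeps the top
    ``k`` and fits ``classifier`` on them, so cross-validating this
    estimator automatically keeps selection inside the training folds.
    """

    def __init__(
        self,
        classifier: str = "rf",
        fs_method: str = "anova",
        k: int = 10,
        seed: int = 0,
        classifier_params: dict | None = None,
    ):
        self.classifier = classifier
        self.fs_method = fs_method
        self.k = k
        self.seed = seed
        self.classifier_params = classifier_params

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        ranking = feature_select.rank_features(
            LabeledDataset(X=X, y=y), self.fs_method, seed=self.seed
        )
        k = min(self.k, X.shape[1])
        self.selected_features_ = ranking.top_k(k)
        self.model_ = make_classifier(
            self.classifier, seed=self.seed, params=self.classifier_params
        )
        self.model_.fit(X[self.selected_features_], y)
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.model_.predict(pd.DataFrame(X)[self.selected_features_])

    def decision_scores(self, X):
        """Continuous activity scores for ROC analysis."""
        check_is_fitted(self)
        Xs = pd.DataFrame(X)[self.selected_features_]
        if hasattr(self.model_, "predict_proba"):
            return self.model_.predict_proba(Xs)[:, 1]
        return self.model_.decision_function(Xs)


@dataclass
class CVPerformance:
    """Pooled outer-fold confusion counts and derived metrics (percent)."""

    model_name: str
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None
    q2_rnd: float | None = None
    fold_predictions: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def ba(self) -> float:
        return (self.tpr + self.tnr) / 2.0

    @property
    def ppv(self) -> float | None:
        """None (not 0) when no compound was predicted active."""
        if self.tp + self.fp == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def mmce(self) -> float:
        return 100.0 * (self.fp + self.fn) / self.n

    @property
    def q2(self) -> float:
        return 100.0 - self.mmce

    @property
    def q2_minus_q2rnd(self) -> float | None:
        if self.q2_rnd is None:
            return None
        return self.q2 - self.q2_rnd

    def as_row(self) -> dict:
        return {
            "model": self.model_name,
            "BA": self.ba,
            "PPV": self.ppv,
            "MMCE": self.mmce,
            "AUC": self.auc,
            "TPR": self.tpr,
            "TNR": self.tnr,
            "Q2_minus_Q2rnd": self.q2_minus_q2rnd,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
        }


def confusion_metrics(
    tp: int, fp: int, tn: int, fn: int, model_name: str = ""
) -> CVPerformance:
    """Metric suite from confusion counts (all values in percent)."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be represented")
    return CVPerformance(model_name=model_name, tp=tp, fp=fp, tn=tn, fn=fn)


def random_accuracy(n_pos: int, n_neg: int) -> float:
    """Most probable random accuracy (percent): (n+^2 + n-^2) / N^2.

    The accuracy a classifier matching the label frequencies attains by
    chance; for the 286/752 class split this is 60.08%.
    """
    n = n_pos + n_neg
    if n <= 0:
        raise ValueError("need at least one compound")
    return 100.0 * (n_pos**2 + n_neg**2) / n**2


def nested_cv(
    dataset: LabeledDataset,
    spec: ModelSpec,
    outer_folds: int | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVPerformance:
    """Stratified nested cross-validation of one model configuration.

    Feature selection runs inside each outer training fold only; the inner
    folds are reserved for hyperparameter tuning (library defaults are used,
    so the inner loop is a no-op unless ``spec.params`` requests tuning).
    Outer-fold confusion counts are pooled; per-fold out-of-sample
    predictions and the per-fold selected features are retained.

    The slow ``bart_like`` learner defaults to 5 outer folds, all others
    to 10. Explicit ``folds`` (train_idx, test_idx) override stratification.
    """
    if outer_folds is None:
        outer_folds = 5 if spec.classifier == "bart_like" else 10
    X, y = dataset.X, np.asarray(dataset.y)
    if folds is None:
        skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    preds, fold_features = [], []
    for fold_no, (train_idx, test_idx) in enumerate(folds):
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError(
                "a fold lost one class entirely; dataset too small or "
                "imbalanced for this fold count"
            )
        est = QSARModel(
            classifier=spec.classifier,
            fs_method=spec.fs_method,
            k=spec.k,
            seed=spec.seed,
            classifier_params=spec.params or None,
        )
        est.fit(X.iloc[train_idx], y_train)
        fold_features.append(list(est.selected_features_))
        y_pred = est.predict(X.iloc[test_idx])
        scores = est.decision_scores(X.iloc[test_idx])
        preds.append(
            pd.DataFrame(
                {
                    "index": test_idx,
                    "fold": fold_no,
                    "y_true": y[test_idx],
                    "y_pred": y_pred,
                    "score": scores,
                }
            )
        )
    pred_df = pd.concat(preds, ignore_index=True)
    tp = int(((pred_df.y_true == 1) & (pred_df.y_pred == 1)).sum())
    fp = int(((pred_df.y_true == 0) & (pred_df.y_pred == 1)).sum())
    tn = int(((pred_df.y_true == 0) & (pred_df.y_pred == 0)).sum())
    fn = int(((pred_df.y_true == 1) & (pred_df.y_pred == 0)).sum())
    auc = 100.0 * roc_auc_score(pred_df.y_true, pred_df.score)
    perf = CVPerformance(
        model_name=spec.name,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auc=auc,
        q2_rnd=random_accuracy(int(y.sum()), int((1 - y).sum())),
        fold_predictions=pred_df,
    )
    perf.fold_features_ = fold_features  # instrumentation for leak checks
    return perf


def gate_models(
    perfs: list[CVPerformance], ba_min: float = BA_GATE, ppv_min: float = PPV_GATE
) -> list[CVPerformance]:
    """Keep models with BA > ba_min AND PPV > ppv_min (strict)."""
    return [
        p
        for p in perfs
        if p.ppv is not None and p.ba > ba_min and p.ppv > ppv_min
    ]


def best_variant(perfs: list[CVPerformance]) -> CVPerformance:
    """Best of several k-variants of one classifier+selection pair.

    Argmax of mean(BA, PPV); ties go to the higher PPV.
    """
    if not perfs:
        raise ValueError("empty group")
    def key(p: CVPerformance):
        ppv = -np.inf if p.ppv is None else p.ppv
        return ((p.ba + ppv) / 2.0, ppv)
    return max(perfs, key=key)


@dataclass
class YScrambleResult:
    """Performances of pipeline reruns on label-permuted data."""

    perfs: list[list[CVPerformance]]  # [repeat][spec]

    def metric_values(self, metric: str) -> np.ndarray:
        vals = []
        for repeat in self.perfs:
            for p in repeat:
                v = getattr(p, metric)
                if v is not None:
                    vals.append(v)
        return np.asarray(vals, float)

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in ("ba", "ppv"):
            v = self.metric_values(metric)
            rows.append(
                {
                    "metric": metric.upper(),
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                    "min": v.min(),
                    "max": v.max(),
                }
            )
        return pd.DataFrame(rows)


def y_scramble(
    dataset: LabeledDataset,
    specs: Sequence[ModelSpec],
    n_repeats: int = 10,
    seed: int = 0,
    permutations: Sequence[np.ndarray] | None = None,
) -> YScrambleResult:
    """Rerun the full modeling pipeline on label-permuted copies.

    Each repeat draws a fresh uniform label permutation (or takes one from
    ``permutations``, e.g. the identity to recover unscrambled results) and
    reruns nested CV for every spec under identical conditions. Real signal
    should vanish: mean scrambled balanced accuracy sits at chance (~50%).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(dataset.y)
    all_perfs = []
    for rep in range(n_repeats):
        if permutations is not None:
            perm = np.asarray(permutations[rep])
        else:
            perm = rng.permutation(len(y))
        scrambled = LabeledDataset(
            X=dataset.X, y=y[perm], ids=dataset.ids,
            column_roles=dataset.column_roles,
        )
        rep_perfs = [
            nested_cv(scrambled, spec, seed=seed + rep) for spec in specs
        ]
        all_perfs.append(rep_perfs)
    return YScrambleResult(perfs=all_perfs)


def results_table(perfs: list[CVPerformance]) -> pd.DataFrame:
    """Model-per-row metric table (BA, PPV, MMCE, AUC, TPR, TNR, Q2-Q2rnd)."""
    return pd.DataFrame([p.as_row() for p in perfs])
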