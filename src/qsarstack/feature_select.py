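"""Descriptor relevance ranking under a common multi-method interface.

Filter scores (ANOVA F, Kruskal-Wallis H, per-column AUC, variance,
quantile-binned chi-square, information gain, gain ratio, symmetrical
uncertainty, ReliefF, OneR) and model-based importances (random-forest
impurity and permutation importance, univariate CV score) all return a
full ranking over the current columns. The cross-method frequency of the
top-k descriptors summarises which features the methods agree on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestNeighbors

N_BINS = 10  # decile discretisation for contingency-based filters
RELIEF_K = 10  # neighbors per class in ReliefF


@dataclass
class FeatureRanking:
    """Ordered descriptor relevance scores for one method (higher = better)."""

    method: str
    names: list[str]  # sorted by decreasing score, ties by column order
    scores: np.ndarray  # aligned with names
    higher_is_better: bool = True

    def top_k(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.names):
            raise ValueError(
                f"k={k} out of range [1, {len(self.names)}] for {self.method}"
            )
        return self.names[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "rank": np.arange(1, len(self.names) + 1),
                "descriptor": self.names,
                "score": self.scores,
            }
        )


def _binned(x: np.ndarray) -> np.ndarray:
    """Decile-bin a column; constant columns collapse to one bin."""
    try:
        return pd.qcut(x, N_BINS, labels=False, duplicates="drop")
    except ValueError:
        return np.zeros(len(x), dtype=int)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _information_gain(x_binned: np.ndarray, y: np.ndarray) -> float:
    h_y = _entropy(y)
    n = len(y)
    h_cond = 0.0
    for b in np.unique(x_binned):
        mask = x_binned == b
        h_cond += mask.sum() / n * _entropy(y[mask])
    return h_y - h_cond


def _score_anova(X, y, rng):
    return np.array(
        [stats.f_oneway(col[y == 1], col[y == 0]).statistic for col in X.T]
    )


def _score_kruskal(X, y, rng):
    return np.array(
        [stats.kruskal(col[y == 1], col[y == 0]).statistic for col in X.T]
    )


def _score_auc(X, y, rng):
    # direction-free: a perfectly anti-correlated column is as informative
    aucs = np.array([roc_auc_score(y, col) for col in X.T])
    return np.maximum(aucs, 1.0 - aucs)


def _score_variance(X, y, rng):
    return X.var(axis=0, ddof=1)


def _score_chi_sq(X, y, rng):
    out = []
    for col in X.T:
        tab = pd.crosstab(_binned(col), y)
        if tab.shape[0] < 2:
            out.append(0.0)
        else:
            out.append(float(stats.chi2_contingency(tab).statistic))
    return np.array(out)


def _score_information_gain(X, y, rng):
    return np.array([_information_gain(_binned(col), y) for col in X.T])


def _score_gain_ratio(X, y, rng):
    out = []
    for col in X.T:
        xb = _binned(col)
        h_x = _entropy(xb)
        out.append(_information_gain(xb, y) / h_x if h_x > 0 else 0.0)
    return np.array(out)


def _score_sym_uncertainty(X, y, rng):
    h_y = _entropy(y)
    out = []
    for col in X.T:
        xb = _binned(col)
        h_x = _entropy(xb)
        denom = h_x + h_y
        out.append(2.0 * _information_gain(xb, y) / denom if denom > 0 else 0.0)
    return np.array(out)


def _score_relief(X, y, rng):
    """ReliefF with all n instances and k neighbors per class.

    Features are range-normalised so weight updates are comparable; the
    weight of a feature rises when near-misses differ on it and falls when
    near-hits do.
    """
    n, p = X.shape
    rng_span = X.max(axis=0) - X.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    Xn = (X - X.min(axis=0)) / rng_span
    w = np.zeros(p)
    for cls in (0, 1):
        same = Xn[y == cls]
        other = Xn[y != cls]
        k_hit = min(RELIEF_K, len(same) - 1)
        k_miss = min(RELIEF_K, len(other))
        if k_hit < 1 or k_miss < 1:
            raise ValueError("each class needs at least 2 members for ReliefF")
        nn_hit = NearestNeighbors(n_neighbors=k_hit + 1).fit(same)
        nn_miss = NearestNeighbors(n_neighbors=k_miss).fit(other)
        _, hit_idx = nn_hit.kneighbors(same)
        _, miss_idx = nn_miss.kneighbors(same)
        for i in range(len(same)):
            hits = same[hit_idx[i, 1:]]  # drop self
            misses = other[miss_idx[i]]
            w += np.abs(misses - same[i]).mean(axis=0)
            w -= np.abs(hits - same[i]).mean(axis=0)
    return w / n


def _score_oneR(X, y, rng):
    """Accuracy of a one-rule classifier per decile-binned feature."""
    out = []
    n = len(y)
    for col in X.T:
        xb = _binned(col)
        correct = 0
        for b in np.unique(xb):
            labels = y[xb == b]
            correct += max((labels == 0).sum(), (labels == 1).sum())
        out.append(correct / n)
    return np.array(out)


def _fit_rf(X, y, seed):
    return RandomForestClassifier(
        n_estimators=200, random_state=seed, n_jobs=1
    ).fit(X, y)


def _score_rf_impurity(X, y, rng):
    return _fit_rf(X, y, rng).feature_importances_


def _score_rf_permutation(X, y, rng):
    rf = _fit_rf(X, y, rng)
    return permutation_importance(
        rf, X, y, n_repeats=5, random_state=rng, n_jobs=1
    ).importances_mean


def _score_univariate(X, y, rng):
    """Mean 3-fold CV accuracy of a one-feature logistic model."""
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=rng)
    out = []
    for col in X.T:
        clf = LogisticRegression(max_iter=200)
        out.append(cross_val_score(clf, col[:, None], y, cv=cv).mean())
    return np.array(out)


_METHODS = {
    "anova": _score_anova,
    "kruskal": _score_kruskal,
    "auc": _score_auc,
    "variance": _score_variance,
    "chi.sq": _score_chi_sq,
    "information_gain": _score_information_gain,
    "gain_ratio": _score_gain_ratio,
    "sym_uncertainty": _score_sym_uncertainty,
    "relief": _score_relief,
    "oneR": _score_oneR,
    "rf_impurity": _score_rf_impurity,
    "rf_permutation": _score_rf_permutation,
    "univariate": _score_univariate,
}

AVAILABLE_METHODS = tuple(_METHODS)


def rank_features(dataset, method: str, seed: int = 0) -> FeatureRanking:
    """Rank all descriptor columns of a labeled dataset by one method.

    ``dataset`` is a LabeledDataset (or any object with ``X`` DataFrame and
    ``y`` binary vector). Stochastic methods (relief, rf_*) are fully
    determined by ``seed``.
    """
    if method not in _METHODS:
        raise ValueError(
            f"unknown method {method!r}; available: {sorted(_METHODS)}"
        )
    X = dataset.X.to_numpy(dtype=float)
    y = np.asarray(dataset.y)
    names = list(dataset.X.columns)
    scores = np.nan_to_num(_METHODS[method](X, y, seed), nan=0.0)
    # stable sort: decreasing score, ties by original column order
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(
        method=method,
        names=[names[i] for i in order],
        scores=scores[order],
    )


def top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """The k best descriptors under the ranking's direction."""
    return ranking.top_k(k)


def top_k_frequency(
    rankings: list[FeatureRanking], k: int = 5
) -> pd.DataFrame:
    """How often each descriptor appears among a method's first k features.

    Mirrors the cross-method agreement table: one row per descriptor that
    is top-k for at least one method, sorted by decreasing frequency.
    """
    counts: dict[str, int] = {}
    for r in rankings:
        for name in r.top_k(k):
            counts[name] = counts.get(name, 0) + 1
    out = pd.DataFrame(
        {"descriptor": list(counts), "frequency": list(counts.values())}
    )
    return out.sort_values(
        ["frequency", "descriptor"], ascending=[False, True]
    ).reset_index(drop=True)


def rank_all_methods(
    dataset, methods=AVAILABLE_METHODS, seed: int = 0
) -> list[FeatureRanking]:
    return [rank_features(dataset, m, seed=seed) for m in methods]
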