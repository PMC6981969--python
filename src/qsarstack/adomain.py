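"""Applicability-domain (AD) estimation for screening predictions.

A QSAR model can only be trusted inside the descriptor-space region its
training set covers. Four algorithms decide, per screening compound and
per model training set, whether a prediction is in-domain:

* Roy standardization: a 3-SD rule on training-standardised descriptors;
* Sahigara kNN: per-training-point distance thresholds derived from the
  distribution of mean k-nearest-neighbour distances;
* KDEOS: Gaussian-kernel density z-scores averaged over a neighbour range
  (higher = more outlying);
* INFLO: influence-space (kNN plus reverse-kNN) density ratio
  (~1 for inliers, >> 1 for outliers).

Distances are Euclidean in the model's own preprocessed feature space.
KDEOS and INFLO return scores; the verdict thresholds (KDEOS z > 2,
INFLO > 1.5) are configurable defaults, while Roy and Sahigara carry
their published decision rules.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

#: distance floor guarding against zero k-distances from duplicate points
EPS = 1e-12

#: default score thresholds for the two density methods (outside if above)
KDEOS_Z_THRESHOLD = 2.0
INFLO_THRESHOLD = 1.5


def _as_array(X) -> np.ndarray:
    return np.asarray(pd.DataFrame(X), dtype=float)


class RoyStandardizationAD(BaseEstimator):
    """Standardization-based AD with the 3-SD decision tree.

    Test descriptors are standardised by training mean/SD. A compound with
    every |s| <= 3 is inside; with every |s| > 3 it is outside; otherwise
    it is inside iff mean(|s|) + 1.28 * SD(|s|) <= 3 (the 90th percentile
    of its standardised profile stays within 3 SD).
    """

    def __init__(self, sd_limit: float = 3.0, snedecor: float = 1.28):
        self.sd_limit = sd_limit
        self.snedecor = snedecor

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        sds = X.std(ddof=1)
        zero = list(sds.index[sds <= 0])
        if zero:
            warnings.warn(
                f"zero-variance training columns excluded from AD: {zero}",
                stacklevel=2,
            )
        self.columns_ = [c for c in X.columns if c not in zero]
        self.mean_ = X[self.columns_].mean()
        self.scale_ = sds[self.columns_]
        return self

    def scores(self, X) -> np.ndarray:
        """mean(|s|) + snedecor * SD(|s|) per compound (the tie-break score)."""
        check_is_fitted(self)
        s = self._abs_standardized(X)
        mean = s.mean(axis=1)
        sd = s.std(axis=1, ddof=1) if s.shape[1] > 1 else np.zeros(len(s))
        return mean + self.snedecor * sd

    def _abs_standardized(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise ValueError(f"columns missing from input: {missing}")
        return np.abs(
            ((X[self.columns_] - self.mean_) / self.scale_).to_numpy(float)
        )

    def predict(self, X) -> np.ndarray:
        """Boolean inside-domain verdict per test compound."""
        s = self._abs_standardized(X)
        inside = np.empty(len(s), dtype=bool)
        all_below = (s <= self.sd_limit).all(axis=1)
        all_above = (s > self.sd_limit).all(axis=1)
        mixed = ~all_below & ~all_above
        inside[all_below] = True
        inside[all_above] = False
        if mixed.any():
            inside[mixed] = self.scores_of(s[mixed], self.snedecor) <= self.sd_limit
        return inside

    @staticmethod
    def scores_of(s: np.ndarray, snedecor: float = 1.28) -> np.ndarray:
        mean = s.mean(axis=1)
        sd = s.std(axis=1, ddof=1) if s.shape[1] > 1 else np.zeros(len(s))
        return mean + snedecor * sd


class SahigaraKNNAD(BaseEstimator):
    """kNN applicability domain with per-training-point thresholds.

    Fitting derives a global reference distance from the distribution of
    mean k-nearest-neighbour distances among training points (Q3 + 1.5*IQR),
    counts for each training point the neighbours within that reference
    (Ki), and sets its individual admission threshold to the mean distance
    of its Ki nearest neighbours (0 when isolated). A test compound is
    inside the domain iff it lies within at least one training point's
    threshold.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y=None):
        X = _as_array(X)
        n = len(X)
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.k >= n:
            raise ValueError(f"k={self.k} must be < n_train={n}")
        D = cdist(X, X)
        np.fill_diagonal(D, np.inf)
        D_sorted = np.sort(D, axis=1)
        mean_knn = D_sorted[:, : self.k].mean(axis=1)
        q1, q3 = np.percentile(mean_knn, [25, 75])
        self.reference_ = q3 + 1.5 * (q3 - q1)
        thresholds = np.zeros(n)
        for i in range(n):
            ki = int((D[i] <= self.reference_).sum())
            if ki > 0:
                thresholds[i] = D_sorted[i, :ki].mean()
        self.train_ = X
        self.thresholds_ = thresholds
        return self

    def predict(self, X) -> np.ndarray:
        """True where a test compound falls within any training threshold."""
        check_is_fitted(self)
        D = cdist(_as_array(X), self.train_)
        return (D <= self.thresholds_[None, :]).any(axis=1)


def _kdist_and_neighbors(D: np.ndarray, k: int):
    """Distance to the k-th neighbour and indices of the k nearest, per row."""
    order = np.argsort(D, axis=1, kind="stable")
    knn = order[:, :k]
    kdist = np.take_along_axis(D, knn[:, -1:], axis=1)[:, 0]
    return np.maximum(kdist, EPS), knn


def _gauss_density(D: np.ndarray, k: int) -> np.ndarray:
    """Gaussian-kernel density from the k nearest reference points per row.

    Bandwidth is the row's own k-distance (floored); the kernel is applied
    to the scalar distances, so densities compare within one feature space.
    """
    h, knn = _kdist_and_neighbors(D, k)
    d_nn = np.take_along_axis(D, knn, axis=1)
    kern = np.exp(-0.5 * (d_nn / h[:, None]) ** 2) / (h[:, None] * np.sqrt(2 * np.pi))
    return kern.mean(axis=1)


def kdeos_scores(
    train_X, test_X, k_min: int = 3, k_max: int = 10
) -> np.ndarray:
    """Kernel Density Estimation Outlier Score per test compound.

    For each neighbourhood size k in [k_min, k_max] the Gaussian-kernel
    density at the test point is z-scored against the densities of its k
    nearest training points; scores are averaged over the k range. Higher
    means more outlying.
    """
    train = _as_array(train_X)
    test = _as_array(test_X)
    n = len(train)
    if not 1 <= k_min <= k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be < n_train={n}")
    D_tt = cdist(train, train)
    np.fill_diagonal(D_tt, np.inf)
    if not np.isfinite(D_tt).any() or np.nanmax(np.where(np.isinf(D_tt), np.nan, D_tt)) <= EPS:
        raise ValueError("degenerate training set: all points identical")
    D_qt = cdist(test, train)
    z_sum = np.zeros(len(test))
    for k in range(k_min, k_max + 1):
        dens_train = _gauss_density(D_tt, k)
        dens_test = _gauss_density(D_qt, k)
        _, knn_q = _kdist_and_neighbors(D_qt, k)
        nb_dens = dens_train[knn_q]
        mu = nb_dens.mean(axis=1)
        sd = np.maximum(nb_dens.std(axis=1, ddof=1), EPS)
        z_sum += (mu - dens_test) / sd
    return z_sum / (k_max - k_min + 1)


def inflo_scores(train_X, test_X, k: int = 5) -> np.ndarray:
    """Influenced Outlierness score per test compound.

    Density is the reciprocal k-distance (floored at a small epsilon for
    duplicate points). The influence space of a test point is the union of
    its k nearest training points and the training points that would count
    it among their own k nearest (reverse neighbours). The score is the
    mean influence-space density over the point's own density: ~1 inside
    homogeneous regions, >> 1 for outliers.
    """
    train = _as_array(train_X)
    test = _as_array(test_X)
    n = len(train)
    if not 0 < k < n:
        raise ValueError(f"need 0 < k < n_train={n}")
    D_tt = cdist(train, train)
    np.fill_diagonal(D_tt, np.inf)
    kdist_train, _ = _kdist_and_neighbors(D_tt, k)
    dens_train = 1.0 / kdist_train
    D_qt = cdist(test, train)
    kdist_test, knn_q = _kdist_and_neighbors(D_qt, k)
    dens_test = 1.0 / kdist_test
    scores = np.empty(len(test))
    for i in range(len(test)):
        members = set(knn_q[i].tolist())
        members |= set(np.flatnonzero(D_qt[i] <= kdist_train).tolist())
        scores[i] = dens_train[list(members)].mean() / dens_test[i]
    return scores


def ad_report(
    train_X,
    test_X,
    compound_ids=None,
    sahigara_k: int = 5,
    kdeos_k: tuple[int, int] = (3, 10),
    inflo_k: int = 5,
    kdeos_threshold: float = KDEOS_Z_THRESHOLD,
    inflo_threshold: float = INFLO_THRESHOLD,
) -> pd.DataFrame:
    """Long-form verdict table: compound x method -> score, inside flag."""
    test = pd.DataFrame(test_X)
    ids = list(compound_ids) if compound_ids is not None else list(test.index)
    roy = RoyStandardizationAD().fit(train_X)
    sahigara = SahigaraKNNAD(k=sahigara_k).fit(train_X)
    kdeos = kdeos_scores(train_X, test_X, *kdeos_k)
    inflo = inflo_scores(train_X, test_X, k=inflo_k)
    frames = [
        pd.DataFrame(
            {"compound_id": ids, "method": "roy",
             "score": roy.scores(test_X), "inside": roy.predict(test_X)}
        ),
        pd.DataFrame(
            {"compound_id": ids, "method": "sahigara_knn",
             "score": np.nan, "inside": sahigara.predict(test_X)}
        ),
        pd.DataFrame(
            {"compound_id": ids, "method": "kdeos",
             "score": kdeos, "inside": kdeos <= kdeos_threshold}
        ),
        pd.DataFrame(
            {"compound_id": ids, "method": "inflo",
             "score": inflo, "inside": inflo <= inflo_threshold}
        ),
    ]
    return pd.concat(frames, ignore_index=True)


def sahigara_mask(
    model_features: dict[str, list[str]],
    train_X: pd.DataFrame,
    test_X: pd.DataFrame,
    k: int = 5,
) -> pd.DataFrame:
    """Compounds x models inside-AD mask in each model's own feature space.

    The ensemble uses these verdicts when limiting votes to in-domain
    models, matching the published choice of the kNN method for the final
    hit list.
    """
    cols = {}
    for name, feats in model_features.items():
        ad = SahigaraKNNAD(k=k).fit(train_X[feats])
        cols[name] = ad.predict(test_X[feats])
    return pd.DataFrame(cols, index=test_X.index)


def outlier_fraction_summary(mask: pd.DataFrame) -> pd.DataFrame:
    """Per-model fraction of screening compounds outside the domain."""
    frac = 100.0 * (~mask.astype(bool)).mean(axis=0)
    out = frac.describe().to_frame(name="outside_percent").T
    return out
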