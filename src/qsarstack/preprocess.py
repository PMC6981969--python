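"""Descriptor-matrix cleaning and scaling, plus Gower diversity analysis.

The fixed preprocessing order is: quasi-constant removal (columns where
fewer than 1% of observations differ from the mode), correlation removal
(no surviving pair with |Pearson r| above 0.9), then standardisation with
symmetric clipping of z-scores at +/-2 SD. All statistics are fitted on
training data only and frozen in a recipe for reuse on screening libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_is_fitted


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def quasi_constant_mask(X: pd.DataFrame, min_variant_fraction: float = 0.01):
    """Fraction of entries differing from the per-column mode; drop if < rule."""
    n = len(X)
    frac_off_mode = {}
    for col in X.columns:
        counts = X[col].value_counts(dropna=False)
        frac_off_mode[col] = 1.0 - counts.iloc[0] / n
    return pd.Series(frac_off_mode) >= min_variant_fraction


class QuasiConstantFilter(TransformerMixin, BaseEstimator):
    """Drop constant and quasi-constant descriptor columns.

    A column is dropped iff the fraction of entries differing from its mode
    is below ``min_variant_fraction`` (default 1%).
    """

    def __init__(self, min_variant_fraction: float = 0.01):
        self.min_variant_fraction = min_variant_fraction

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.empty:
            raise ValueError("X must be non-empty")
        keep = quasi_constant_mask(X, self.min_variant_fraction)
        self.kept_columns_ = [c for c in X.columns if keep[c]]
        self.dropped_columns_ = [c for c in X.columns if not keep[c]]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        return _as_frame(X)[self.kept_columns_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self)
        return np.asarray(self.kept_columns_, dtype=object)


class CorrelationFilter(TransformerMixin, BaseEstimator):
    """Remove columns until no pair has |Pearson r| above ``r_cutoff``.

    While an offending pair remains, the column with the highest mean
    absolute correlation to all other remaining columns is dropped; ties
    break by column order, so removal is deterministic.
    """

    def __init__(self, r_cutoff: float = 0.9):
        self.r_cutoff = r_cutoff

    def fit(self, X, y=None):
        X = _as_frame(X)
        cols = list(X.columns)
        corr = X.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        active = np.ones(len(cols), dtype=bool)
        dropped = []
        while True:
            sub = corr[np.ix_(active, active)]
            if sub.size == 0 or sub.max() <= self.r_cutoff:
                break
            idx_active = np.flatnonzero(active)
            offending = np.flatnonzero((sub > self.r_cutoff).any(axis=1))
            mean_abs = sub[offending].mean(axis=1)
            # argmax keeps the first (column-order) index on ties
            victim = idx_active[offending[int(np.argmax(mean_abs))]]
            active[victim] = False
            dropped.append(cols[victim])
        self.kept_columns_ = [c for c, a in zip(cols, active) if a]
        self.dropped_columns_ = dropped
        self.n_features_in_ = len(cols)
        return self

    def transform(self, X):
        check_is_fitted(self)
        return _as_frame(X)[self.kept_columns_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self)
        return np.asarray(self.kept_columns_, dtype=object)


class ClippedStandardScaler(TransformerMixin, BaseEstimator):
    """Center and scale by training mean/SD, clipping z-scores at +/-clip_limit.

    SDs use ddof=1 (sample SD). Clipping is symmetric: values beyond
    ``clip_limit`` standard deviations on either side are capped.
    """

    def __init__(self, clip_limit: float = 2.0):
        self.clip_limit = clip_limit

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.mean_ = X.mean()
        self.scale_ = X.std(ddof=1)
        if (self.scale_ <= 0).any():
            bad = list(self.scale_.index[self.scale_ <= 0])
            raise ValueError(
                f"zero-variance columns cannot be scaled: {bad}; "
                "apply the quasi-constant filter first"
            )
        self.columns_ = list(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = _as_frame(X)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise ValueError(f"columns missing from input: {missing}")
        Z = (X[self.columns_] - self.mean_) / self.scale_
        return Z.clip(-self.clip_limit, self.clip_limit)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self)
        return np.asarray(self.columns_, dtype=object)


@dataclass
class PreprocessRecipe:
    """Frozen preprocessing parameters, serialisable for screening reuse."""

    kept_columns: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    clip_limit: float = 2.0
    quasi_constant_fraction: float = 0.01
    correlation_cutoff: float = 0.9
    dropped_quasi_constant: list[str] = field(default_factory=list)
    dropped_correlated: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "kept_columns": list(self.kept_columns),
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
            "clip_limit": float(self.clip_limit),
            "quasi_constant_fraction": float(self.quasi_constant_fraction),
            "correlation_cutoff": float(self.correlation_cutoff),
            "dropped_quasi_constant": list(self.dropped_quasi_constant),
            "dropped_correlated": list(self.dropped_correlated),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessRecipe":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PreprocessRecipe":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def apply(self, X) -> pd.DataFrame:
        """Apply the frozen recipe; never re-estimates any parameter."""
        X = _as_frame(X)
        missing = [c for c in self.kept_columns if c not in X.columns]
        if missing:
            raise ValueError(f"columns missing from input: {missing}")
        mu = pd.Series(self.means)[self.kept_columns]
        sd = pd.Series(self.sds)[self.kept_columns]
        Z = (X[self.kept_columns] - mu) / sd
        return Z.clip(-self.clip_limit, self.clip_limit)


def make_preprocess_pipeline(
    min_variant_fraction: float = 0.01,
    r_cutoff: float = 0.9,
    clip_limit: float = 2.0,
) -> Pipeline:
    """Quasi-constant filter -> correlation filter -> clipped scaler."""
    return Pipeline(
        [
            ("quasi_constant", QuasiConstantFilter(min_variant_fraction)),
            ("correlation", CorrelationFilter(r_cutoff)),
            ("scaler", ClippedStandardScaler(clip_limit)),
        ]
    )


def drop_quasi_constant(X, min_variant_fraction: float = 0.01) -> list[str]:
    """Column names surviving the quasi-constant rule."""
    return QuasiConstantFilter(min_variant_fraction).fit(X).kept_columns_


def drop_correlated(X, r_cutoff: float = 0.9) -> list[str]:
    """Column names surviving the pairwise-correlation rule."""
    return CorrelationFilter(r_cutoff).fit(X).kept_columns_


def fit_scaler(
    X_train,
    min_variant_fraction: float = 0.01,
    r_cutoff: float = 0.9,
    clip_limit: float = 2.0,
) -> PreprocessRecipe:
    """Fit the full cleaning + scaling recipe on training data."""
    pipe = make_preprocess_pipeline(min_variant_fraction, r_cutoff, clip_limit)
    pipe.fit(_as_frame(X_train))
    scaler: ClippedStandardScaler = pipe.named_steps["scaler"]
    return PreprocessRecipe(
        kept_columns=list(scaler.columns_),
        means=scaler.mean_.to_dict(),
        sds=scaler.scale_.to_dict(),
        clip_limit=clip_limit,
        quasi_constant_fraction=min_variant_fraction,
        correlation_cutoff=r_cutoff,
        dropped_quasi_constant=pipe.named_steps["quasi_constant"].dropped_columns_,
        dropped_correlated=pipe.named_steps["correlation"].dropped_columns_,
    )


def apply_scaler(recipe: PreprocessRecipe, X) -> pd.DataFrame:
    return recipe.apply(X)


def gower_matrix(
    X,
    rescale: bool = False,
    binary_columns: list[str] | None = None,
) -> np.ndarray:
    """Gower dissimilarity matrix for mixed continuous/binary descriptors.

    Continuous features contribute |xi - xj| / range (range taken from the
    data; zero-range features are skipped). Binary features use simple
    matching (0 if equal, 1 otherwise) — this is why Gower tends to weight
    binary variables more heavily than range-normalised continuous ones.
    Features are equally weighted. With ``rescale`` the matrix is divided
    by its maximum off-diagonal value so the most dissimilar pair is 1.
    """
    X = _as_frame(X)
    n = len(X)
    if binary_columns is None:
        binary_columns = [
            c for c in X.columns if set(pd.unique(X[c].dropna())) <= {0, 1}
        ]
    binary_set = set(binary_columns)
    D = np.zeros((n, n))
    n_used = 0
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if col in binary_set:
            d = (v[:, None] != v[None, :]).astype(float)
        else:
            rng = v.max() - v.min()
            if rng == 0:
                continue
            d = np.abs(v[:, None] - v[None, :]) / rng
        D += d
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable features for the Gower matrix")
    D /= n_used
    if rescale:
        off = D[~np.eye(n, dtype=bool)]
        dmax = off.max() if off.size else 0.0
        if dmax == 0:
            warnings.warn(
                "all rows identical; Gower rescaling skipped to avoid "
                "division by zero",
                stacklevel=2,
            )
        else:
            D /= dmax
    return D
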