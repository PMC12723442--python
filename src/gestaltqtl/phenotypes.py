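"""Cuticular-hydrocarbon trait preparation.

Raw GC/FID peak areas become relative amounts (row-normalized), per-trait
outliers are removed by Tukey fences (1.5 x IQR beyond the quartiles),
each trait is normalized by the best-fitting candidate transform selected
on a Pearson chi-squared normality statistic (the bestNormalize selection
rule), nestmate values are averaged into colony profiles, and trait-space
PCA summarizes shared variation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "relative_amounts",
    "remove_outliers_iqr",
    "normalize_best_fit",
    "colony_average",
    "trait_pca",
    "IQROutlierFilter",
    "BestNormalizer",
    "NormalizationChoice",
]


class PhenotypeError(ValueError):
    pass


def relative_amounts(peak_areas: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's peak areas by its row total (missing excluded)."""
    values = peak_areas.to_numpy(float)
    if np.nanmin(values) < 0:
        raise PhenotypeError("peak areas must be non-negative")
    totals = np.nansum(values, axis=1)
    zero = totals <= 0
    if zero.any():
        bad = peak_areas.index[zero].tolist()
        raise PhenotypeError(f"all-zero peak areas for samples: {bad}")
    return peak_areas.div(totals, axis=0)


def _tukey_fences(x: np.ndarray, k: float) -> tuple[float, float]:
    q1, q3 = np.percentile(x, [25, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


class IQROutlierFilter(BaseEstimator, TransformerMixin):
    """Set values outside the Tukey fences [Q1 - k*IQR, Q3 + k*IQR] to NaN.

    Quartiles use linear interpolation.  A trait with zero IQR is left
    untouched (with a warning): the fences would collapse onto the data.
    """

    def __init__(self, k: float = 1.5):
        self.k = k

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        fences = {}
        for col in X.columns:
            x = X[col].to_numpy(float)
            x = x[~np.isnan(x)]
            if x.size < 4:
                raise PhenotypeError(f"trait {col!r}: need >= 4 non-missing values")
            lo, hi = _tukey_fences(x, self.k)
            if hi - lo <= 0:
                warnings.warn(f"trait {col!r}: IQR is 0, no outlier removal")
                lo, hi = -np.inf, np.inf
            fences[col] = (lo, hi)
        self.fences_ = fences
        return self

    def transform(self, X):
        X = pd.DataFrame(X).copy()
        for col in X.columns:
            lo, hi = self.fences_[col]
            vals = X[col].to_numpy(float)
            out = (vals < lo) | (vals > hi)
            X.loc[out, col] = np.nan
        return X


def remove_outliers_iqr(values: pd.DataFrame, k: float = 1.5) -> pd.DataFrame:
    """Per-trait Tukey-fence outlier removal (outliers set missing)."""
    return IQROutlierFilter(k=k).fit_transform(values)


# ---------------------------------------------------------------------------
# best-fit normalization


@dataclass
class NormalizationChoice:
    transform: str
    params: dict
    statistic: float
    candidates: dict


def _pearson_normality(z: np.ndarray) -> float:
    """Pearson chi-squared statistic on standardized values.

    Equal-probability normal bins, ceil(n/5) bins capped at 30; the
    statistic is sum (O - E)^2 / E.  Smaller means closer to normal.
    """
    z = z[~np.isnan(z)]
    n = z.size
    sd = z.std(ddof=1)
    if sd <= 0:
        return np.inf
    z = (z - z.mean()) / sd
    n_bins = min(30, max(2, math.ceil(n / 5)))
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1))
    observed, _ = np.histogram(z, bins=edges)
    expected = n / n_bins
    return float(((observed - expected) ** 2 / expected).sum())


def _fit_candidate(name: str, x: np.ndarray):
    """Return (transformed, params) or None when inapplicable."""
    if name == "identity":
        return x.copy(), {}
    if name == "log":
        c = 0.0 if x.min() > 0 else float(-x.min() + np.ptp(x) * 1e-3 + 1e-12)
        return np.log(x + c), {"shift": c}
    if name == "sqrt":
        c = 0.0 if x.min() >= 0 else float(-x.min())
        return np.sqrt(x + c), {"shift": c}
    if name == "arcsinh":
        return np.arcsinh(x), {}
    if name == "boxcox":
        if x.min() <= 0:
            return None
        y, lam = stats.boxcox(x)
        return y, {"lambda": float(lam)}
    if name == "yeojohnson":
        y, lam = stats.yeojohnson(x)
        return y, {"lambda": float(lam)}
    if name == "ordered_quantile":
        ranks = stats.rankdata(x, method="average")
        y = stats.norm.ppf((ranks - 0.5) / x.size)
        return y, {}
    raise ValueError(name)


#: candidate order doubles as the tie-break priority (identity first)
CANDIDATE_TRANSFORMS = (
    "identity", "log", "sqrt", "arcsinh", "boxcox", "yeojohnson", "ordered_quantile",
)


class BestNormalizer(BaseEstimator, TransformerMixin):
    """Per-trait best-fitting normalization, bestNormalize-style.

    Each candidate transform is fitted per column; the one minimizing the
    Pearson chi-squared normality statistic wins (ties resolved by
    candidate order, identity first).  ``transform`` returns standardized
    (zero-mean, unit-variance) transformed values; missing cells propagate.
    """

    def __init__(self, candidates: tuple = CANDIDATE_TRANSFORMS, min_values: int = 10):
        self.candidates = candidates
        self.min_values = min_values

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self.choices_ = {}
        for col in X.columns:
            x = X[col].to_numpy(float)
            x = x[~np.isnan(x)]
            if x.size < self.min_values:
                raise PhenotypeError(
                    f"trait {col!r}: need >= {self.min_values} non-missing values"
                )
            scores = {}
            fits = {}
            for name in self.candidates:
                res = _fit_candidate(name, x)
                if res is None:
                    continue
                yv, params = res
                scores[name] = _pearson_normality(yv)
                fits[name] = params
            best = min(scores, key=lambda k: (scores[k], self.candidates.index(k)))
            self.choices_[col] = NormalizationChoice(
                transform=best, params=fits[best], statistic=scores[best],
                candidates=scores,
            )
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        out = {}
        for col in X.columns:
            choice = self.choices_[col]
            x = X[col].to_numpy(float)
            mask = ~np.isnan(x)
            res = _apply_transform(choice.transform, choice.params, x[mask])
            z = np.full_like(x, np.nan)
            z[mask] = (res - res.mean()) / max(res.std(ddof=1), 1e-12)
            out[col] = z
        return pd.DataFrame(out, index=X.index)


def _apply_transform(name: str, params: dict, x: np.ndarray) -> np.ndarray:
    if name == "identity":
        return x.copy()
    if name == "log":
        return np.log(x + params["shift"])
    if name == "sqrt":
        return np.sqrt(x + params["shift"])
    if name == "arcsinh":
        return np.arcsinh(x)
    if name == "boxcox":
        return stats.boxcox(x, lmbda=params["lambda"])
    if name == "yeojohnson":
        return stats.yeojohnson(x, lmbda=params["lambda"])
    if name == "ordered_quantile":
        ranks = stats.rankdata(x, method="average")
        return stats.norm.ppf((ranks - 0.5) / x.size)
    raise ValueError(name)


def normalize_best_fit(values: pd.DataFrame):
    """Fit-and-apply the best normalization per trait.

    Returns ``(normalized DataFrame, {trait: NormalizationChoice})``.
    """
    norm = BestNormalizer().fit(values)
    return norm.transform(values), norm.choices_


def colony_average(tm: pd.DataFrame, colony_map: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of nestmate trait values per colony (missing excluded)."""
    cmap = colony_map.set_index("sample_id")["colony_id"]
    missing = [s for s in tm.index if s not in cmap.index]
    if missing:
        raise PhenotypeError(f"samples without colony assignment: {missing}")
    grouped = tm.groupby(tm.index.map(cmap)).mean()
    all_missing = grouped.isna()
    if all_missing.to_numpy().any():
        warnings.warn("some colony x trait cells have no non-missing members")
    grouped.index.name = "colony_id"
    return grouped


def trait_pca(tm: pd.DataFrame, min_explained: float = 0.04, standardize: bool = False,
              min_components: int = 0):
    """Centered PCA of the trait matrix; missing cells mean-imputed per trait.

    Returns ``(scores, explained)`` where ``scores`` holds all components
    whose explained-variance fraction is at least ``min_explained`` (at
    least ``min_components`` of them), in decreasing order, and
    ``explained`` the full explained-fraction vector.
    """
    if tm.shape[1] < 2:
        raise PhenotypeError("trait PCA needs at least two traits")
    X = tm.to_numpy(float).copy()
    col_means = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_means, nan_idx[1])
    if standardize:
        X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    explained = pca.explained_variance_ratio_
    n_keep = max(int((explained >= min_explained).sum()), min_components)
    cols = [f"PC{i + 1}" for i in range(n_keep)]
    return (
        pd.DataFrame(scores[:, :n_keep], index=tm.index, columns=cols),
        explained,
    )
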