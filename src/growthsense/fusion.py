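"""PCA fusion of E-nose and E-tongue responses.

The two sensor arrays live on incommensurate scales, so the per-time
mean responses are z-standardised channel-wise before a joint PCA.
The retained component scores are collapsed into a single per-time
*composite score* — the variance-fraction-weighted sum of the scores
— which falls as spoilage progresses; its negation is a growth-like
series suitable for primary-model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FusionResult",
    "SensorFusionPCA",
    "standardize",
    "fuse_pca",
    "composite_score",
    "orient_for_fitting",
]


@dataclass(frozen=True)
class FusionResult:
    """Retained components of the fused sensor PCA.

    ``component_scores`` is time × component, ``loadings`` channel ×
    component (orthonormal columns), ``variance_fractions`` the
    explained-variance proportions of the retained components (non-
    increasing, summing to ≤ 1), ``composite`` the weighted score.
    """

    component_scores: pd.DataFrame
    variance_fractions: np.ndarray
    loadings: pd.DataFrame
    composite: pd.Series
    k: int


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each channel to mean 0 and scale to sample sd 1."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to standardize")
    sd = matrix.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance channel(s): {', '.join(map(str, zero.index))}")
    return (matrix - matrix.mean()) / sd


class SensorFusionPCA(TransformerMixin, BaseEstimator):
    """Variance-weighted PCA fusion of a time × channel mean matrix.

    Parameters
    ----------
    min_cum_variance : float, default 0.90
        Retain the smallest number of components whose cumulative
        explained-variance fraction reaches this threshold.
    scale : bool, default True
        z-standardise channels before the PCA (E-nose and E-tongue
        units are incommensurate).
    orient_decreasing : bool, default True
        Flip component signs so each score series correlates
        negatively with time, matching the convention that spoilage
        drives the fused score downward.

    Attributes
    ----------
    loadings_ : pd.DataFrame
        channel × component orthonormal loadings.
    variance_fractions_ : np.ndarray
        Explained-variance proportions of the retained components.
    k_ : int
        Number of retained components.
    """

    def __init__(
        self,
        min_cum_variance: float = 0.90,
        scale: bool = True,
        orient_decreasing: bool = True,
    ):
        self.min_cum_variance = min_cum_variance
        self.scale = scale
        self.orient_decreasing = orient_decreasing

    def fit(self, X: pd.DataFrame, y=None):
        if not (0.0 < self.min_cum_variance <= 1.0):
            raise ValueError("min_cum_variance must be in (0, 1]")
        X = pd.DataFrame(X)
        Z = standardize(X) if self.scale else X - X.mean()
        times = np.asarray(Z.index, dtype=float)
        A = Z.to_numpy(dtype=float)
        n = A.shape[0]
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        var = s ** 2 / (n - 1)
        fractions = var / var.sum()
        k = int(np.searchsorted(np.cumsum(fractions), self.min_cum_variance) + 1)
        k = min(k, len(fractions))
        V = Vt[:k].T
        scores = A @ V
        if self.orient_decreasing:
            tc = times - times.mean()
            for j in range(k):
                if float(scores[:, j] @ tc) > 0:
                    V[:, j] *= -1.0
                    scores[:, j] *= -1.0
        self.columns_ = list(X.columns)
        self.mean_ = X.mean()
        self.scale_ = X.std(ddof=1) if self.scale else None
        self.loadings_ = pd.DataFrame(
            V, index=X.columns, columns=[f"PC{j + 1}" for j in range(k)]
        )
        self.variance_fractions_ = fractions[:k]
        self.k_ = k
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)[self.columns_]
        Z = X - self.mean_
        if self.scale_ is not None:
            Z = Z / self.scale_
        scores = Z.to_numpy(dtype=float) @ self.loadings_.to_numpy()
        return pd.DataFrame(scores, index=X.index, columns=self.loadings_.columns)

    def fusion_result(self, X: pd.DataFrame) -> FusionResult:
        """Scores, loadings and composite for the fitted matrix."""
        scores = self.transform(X)
        result = FusionResult(
            component_scores=scores,
            variance_fractions=self.variance_fractions_,
            loadings=self.loadings_,
            composite=pd.Series(dtype=float),
            k=self.k_,
        )
        comp = composite_score(result)
        return FusionResult(
            component_scores=scores,
            variance_fractions=self.variance_fractions_,
            loadings=self.loadings_,
            composite=comp,
            k=self.k_,
        )


def fuse_pca(z: pd.DataFrame, min_cum_variance: float = 0.90) -> FusionResult:
    """PCA-fuse an already standardised time × channel matrix."""
    est = SensorFusionPCA(min_cum_variance=min_cum_variance, scale=False).fit(z)
    return est.fusion_result(z)


def composite_score(fusion: FusionResult) -> pd.Series:
    """Variance-weighted composite: ``score_t = Σ_j fraction_j · pc_{t,j}``.

    The weights are the explained-variance proportions of the
    retained components (not renormalised), so components carrying
    more of the arrays' variation contribute proportionally more.
    """
    w = np.asarray(fusion.variance_fractions, dtype=float)
    S = fusion.component_scores.to_numpy(dtype=float)
    if S.shape[1] != len(w):
        raise ValueError("score columns and variance fractions disagree")
    return pd.Series(S @ w, index=fusion.component_scores.index, name="score")


def orient_for_fitting(composite: pd.Series) -> tuple[pd.Series, int]:
    """Negate the composite into a growth-like increasing series.

    Returns the negated series and the applied sign (−1) so the
    transformation stays traceable in reports.
    """
    composite = pd.Series(composite)
    if composite.empty:
        raise ValueError("composite is empty")
    return -composite, -1
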