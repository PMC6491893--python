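"""PCA ordination of core-genus abundances and a one-way MANOVA on the
score space.

The ordination is plain mean-centred PCA (no unit-variance scaling), which is
the decomposition implied by Euclidean distances between relative-abundance
profiles.  Class separation in the score plot is tested with one-way MANOVA
on the first k components: Wilks' lambda = det(W) / det(W + B) with Bartlett's
chi-square approximation chi2 = -(n - 1 - (k + g)/2) ln(lambda) on k(g - 1)
degrees of freedom.  k defaults to 2 to match two-dimensional score plots and
because small cohorts cannot support a full-rank MANOVA over all genera.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = ["OrdinationResult", "ManovaResult", "pca", "manova_test", "CoreOrdination"]


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genera x components
    explained_variance_ratio: np.ndarray
    mean: pd.Series  # centering vector

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class ManovaResult:
    wilks_lambda: float
    statistic: float  # Bartlett chi-square
    df: int
    p: float
    n_components: int


def pca(X, n_components: int | None = None) -> OrdinationResult:
    """Mean-centred SVD-based PCA of a samples x genera matrix.

    Sign convention: each loading vector's largest-magnitude entry is made
    positive, so results are reproducible across SVD implementations.
    """
    if not isinstance(X, pd.DataFrame):
        X = np.asarray(X, dtype=float)
        X = pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    n_components = min(n_components, max_comp)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X.to_numpy(dtype=float))
    loadings = model.components_.T.copy()  # p x k
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comps = [f"PC{j + 1}" for j in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comps),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comps),
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        mean=pd.Series(model.mean_, index=X.columns),
    )


def _scatter_matrices(S: np.ndarray, labels: np.ndarray):
    classes = np.unique(labels)
    grand = S.mean(axis=0)
    k = S.shape[1]
    W = np.zeros((k, k))
    B = np.zeros((k, k))
    for c in classes:
        sub = S[labels == c]
        mu = sub.mean(axis=0)
        dev = sub - mu
        W += dev.T @ dev
        dm = (mu - grand)[:, None]
        B += len(sub) * (dm @ dm.T)
    return W, B, len(classes)


def manova_test(ordination, labels, k: int = 2) -> ManovaResult:
    """One-way MANOVA (Wilks' lambda, Bartlett chi-square) on the first k
    principal-component scores.

    `ordination` may be an OrdinationResult or a bare samples x components
    score matrix.  If W is numerically singular, k is reduced one component
    at a time (logged) until the test is well posed.
    """
    if isinstance(ordination, OrdinationResult):
        S_full = ordination.scores.to_numpy(dtype=float)
    elif isinstance(ordination, pd.DataFrame):
        S_full = ordination.to_numpy(dtype=float)
    else:
        S_full = np.asarray(ordination, dtype=float)
    labels = np.asarray(labels)
    n = S_full.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must align with the score rows")
    classes, counts = np.unique(labels, return_counts=True)
    g = len(classes)
    if g < 2:
        raise ValueError("MANOVA needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    k = min(k, S_full.shape[1], n - g - 1)
    if k < 1:
        raise ValueError("not enough samples for even one component")

    while k >= 1:
        S = S_full[:, :k]
        W, B, _ = _scatter_matrices(S, labels)
        sign_w, logdet_w = np.linalg.slogdet(W)
        sign_t, logdet_t = np.linalg.slogdet(W + B)
        if sign_w > 0 and sign_t > 0:
            lam = float(np.exp(logdet_w - logdet_t))
            break
        logger.warning("singular within-class scatter at k=%d; reducing", k)
        k -= 1
    else:
        raise ValueError("within-class scatter singular for every k")

    lam = min(lam, 1.0)
    chi2 = -(n - 1 - (k + g) / 2.0) * np.log(lam) if lam > 0 else np.inf
    df = k * (g - 1)
    p = float(stats.chi2.sf(chi2, df))
    return ManovaResult(
        wilks_lambda=lam, statistic=float(chi2), df=df, p=p, n_components=k
    )


class CoreOrdination(TransformerMixin, BaseEstimator):
    """scikit-learn transformer wrapping the centred PCA with the fixed sign
    convention.

    Attributes after fit: ``ordination_`` (OrdinationResult), plus the usual
    ``components_`` / ``explained_variance_ratio_`` aliases.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.ordination_ = pca(X, n_components=self.n_components)
        self.components_ = self.ordination_.loadings.to_numpy().T
        self.explained_variance_ratio_ = self.ordination_.explained_variance_ratio
        self.mean_ = self.ordination_.mean.to_numpy()
        self.feature_names_in_ = np.asarray(self.ordination_.mean.index, dtype=object)
        self.n_features_in_ = len(self.feature_names_in_)
        return self

    def transform(self, X):
        check_is_fitted(self, "ordination_")
        if isinstance(X, pd.DataFrame):
            idx = X.index
            X = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        else:
            idx = None
            X = np.asarray(X, dtype=float)
        scores = (X - self.mean_) @ self.components_.T
        if idx is not None:
            return pd.DataFrame(
                scores, index=idx, columns=list(self.ordination_.scores.columns)
            )
        return scores

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.ordination_.scores

    def score_test(self, labels, k: int = 2) -> ManovaResult:
        """MANOVA on the fitted scores against per-sample class labels."""
        check_is_fitted(self, "ordination_")
        return manova_test(self.ordination_, labels, k=k)
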