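"""Standardized PCA over the selected descriptor panel.

The analysis runs on z-scored columns, so the decomposition is of the
correlation structure: eigenvalues sum to the number of variables, and the
percent variance of a component is 100·λ/p.  Loadings are the orthonormal
eigenvectors with a fixed sign convention (the largest-magnitude entry of
each column is positive), which makes the output reproducible where raw
eigenvector signs are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocessing import zscore_standardize

__all__ = ["PCAResult", "pca_standardized", "explained_variance"]


@dataclass
class PCAResult:
    feature_names: List[str]
    loadings: np.ndarray          # descriptors x components, orthonormal cols
    eigenvalues: np.ndarray       # all p eigenvalues, non-increasing
    pct_variance: np.ndarray      # per reported component, %
    cumulative_pct: np.ndarray
    scores: np.ndarray            # samples x components
    ncomp: int

    def loadings_table(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.ncomp)]
        return pd.DataFrame(self.loadings, index=self.feature_names,
                            columns=cols)


def explained_variance(eigenvalues: Sequence[float],
                       p: int) -> Tuple[np.ndarray, np.ndarray]:
    """Percent and cumulative percent of total variance per component.

    For standardized variables the total variance is p, so
    pct_i = 100·λ_i / p.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size > p:
        raise ValueError("more eigenvalues than variables")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    pct = 100.0 * lam / p
    return pct, np.cumsum(pct)


def pca_standardized(X: pd.DataFrame, ncomp: int = 3) -> PCAResult:
    """PCA of z-scored data via eigendecomposition of the correlation matrix.

    ``X`` is samples x descriptors with more samples than descriptors;
    standardization (sample SD) is applied internally, so constant columns
    are rejected.  ``scores`` and ``loadings`` cover the first ``ncomp``
    components; ``eigenvalues`` covers all p.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples than descriptors, got {n} x {p}")
    ncomp = min(ncomp, p)
    Z = zscore_standardize(X)
    corr = np.asarray(Z.cov())  # correlation matrix of the raw data
    lam, vec = np.linalg.eigh(corr)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(p):
        k = int(np.argmax(np.abs(vec[:, j])))
        if vec[k, j] < 0:
            vec[:, j] = -vec[:, j]
    pct, cum = explained_variance(lam[:ncomp], p)
    scores = Z.to_numpy() @ vec[:, :ncomp]
    return PCAResult(feature_names=[str(c) for c in X.columns],
                     loadings=vec[:, :ncomp], eigenvalues=lam,
                     pct_variance=pct, cumulative_pct=cum,
                     scores=scores, ncomp=ncomp)
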