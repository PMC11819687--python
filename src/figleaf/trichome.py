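"""Poisson modelling of trichome length-class distributions.

Non-glandular trichome lengths (µm) are binned into 11 size classes; the
class index minus one is treated as the Poisson support (classes 1..11 map
to x = 0..10), so a cultivar's class-frequency histogram is summarized by a
single rate λ fitted by maximum likelihood (the sample mean of x).  Cultivar
pairs are compared with a likelihood-ratio test: the null refits a common λ
on the pooled histogram, the alternative sums the two separate fits, and
2·(loglik_alt − loglik_null) is referred to a chi-squared upper tail
(df = 2 by default, following the source protocol; the nested models differ
by one free parameter, so df = 1 is available as a knob).  Densities
(trichomes per mm²) and the λ+density Ward dendrogram complete the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from .cluster_bootstrap import DendrogramNode, ward_tree

__all__ = [
    "N_CLASSES", "CLASS_BOUNDS", "TrichomeHistogram", "PoissonFit",
    "LRTResult", "bin_trichome_lengths", "poisson_pmf", "fit_lambda_mle",
    "lrt_poisson", "significance_matrix", "trichome_density",
    "lambda_density_dendrogram",
]

#: Printed class intervals [lower, upper] in µm, classes 1..11.
CLASS_BOUNDS: List[tuple] = [
    (0.1, 99.0), (100.0, 140.0), (140.1, 159.0), (160.0, 239.0),
    (240.0, 299.0), (300.0, 319.0), (320.0, 332.0), (334.0, 358.0),
    (360.0, 398.0), (412.0, 438.0), (450.0, 477.0),
]
N_CLASSES = len(CLASS_BOUNDS)
MAX_LENGTH_UM = CLASS_BOUNDS[-1][1]

# Gapless half-open edges: class i covers [lower_i, lower_{i+1}), the last
# class closes at the printed maximum.  The printed boundaries leave gaps
# (99->100, 332->334, ...); the default extends each class up to the next
# lower bound so every length in (0, 477] is assignable.
_EDGES = [b[0] for b in CLASS_BOUNDS] + [MAX_LENGTH_UM]


@dataclass
class TrichomeHistogram:
    """Class counts for one cultivar x leaf surface."""
    cultivar: str
    surface: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES,):
            raise ValueError(f"counts must have length {N_CLASSES}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class PoissonFit:
    lam: float
    loglik: float
    n: int


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float
    tier: str


def bin_trichome_lengths(lengths: Sequence[float], cultivar: str = "",
                         surface: str = "lower",
                         strict: bool = False) -> TrichomeHistogram:
    """Assign each length (µm) to its size class and count.

    Lengths must lie in (0, 477].  With ``strict=True`` the literal printed
    intervals are used and lengths falling in a between-class gap are
    rejected.
    """
    counts = np.zeros(N_CLASSES, dtype=int)
    for v in lengths:
        if not math.isfinite(v) or v <= 0 or v > MAX_LENGTH_UM:
            raise ValueError(f"length {v} outside (0, {MAX_LENGTH_UM}] µm")
        if strict:
            for c, (lo, hi) in enumerate(CLASS_BOUNDS):
                if lo <= v <= hi:
                    counts[c] += 1
                    break
            else:
                raise ValueError(f"length {v} falls in a between-class gap")
        else:
            c = int(np.searchsorted(_EDGES[1:-1], v, side="right"))
            counts[c] += 1
    return TrichomeHistogram(cultivar=cultivar, surface=surface, counts=counts)


def poisson_pmf(lam: float, x: int) -> float:
    """P(X = x) = e^(-λ) λ^x / x! for X ~ Poisson(λ)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if x < 0 or x != int(x):
        raise ValueError("x must be a non-negative integer")
    return float(stats.poisson.pmf(int(x), lam))


def _loglik(counts: np.ndarray, lam: float) -> float:
    x = np.arange(N_CLASSES)
    mask = counts > 0
    logp = stats.poisson.logpmf(x[mask], lam)
    return float(np.sum(counts[mask] * logp))


def fit_lambda_mle(hist: TrichomeHistogram) -> PoissonFit:
    """Maximum-likelihood λ for the class histogram (support x = class - 1).

    The Poisson MLE is the sample mean of x; the log-likelihood is evaluated
    at the estimate.
    """
    n = hist.n
    if n < 1:
        raise ValueError("empty histogram")
    x = np.arange(N_CLASSES)
    lam = float(np.dot(hist.counts, x) / n)
    return PoissonFit(lam=lam, loglik=_loglik(hist.counts, lam), n=n)


def _tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def lrt_poisson(histA: TrichomeHistogram, histB: TrichomeHistogram,
                df: int = 2) -> LRTResult:
    """Likelihood-ratio test of a common λ against separate per-cultivar λs."""
    fitA = fit_lambda_mle(histA)
    fitB = fit_lambda_mle(histB)
    pooled = TrichomeHistogram(cultivar="pooled", surface=histA.surface,
                               counts=histA.counts + histB.counts)
    fit0 = fit_lambda_mle(pooled)
    stat = 2.0 * (fitA.loglik + fitB.loglik - fit0.loglik)
    stat = max(stat, 0.0)  # clip tiny negative rounding noise
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, p=p, tier=_tier(p))


def significance_matrix(hists: Sequence[TrichomeHistogram],
                        df: int = 2) -> List[List[str]]:
    """Symmetric matrix of LRT significance tiers; diagonal NS."""
    if len(hists) < 2:
        raise ValueError("need at least 2 histograms")
    n = len(hists)
    M = [["NS"] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            tier = lrt_poisson(hists[i], hists[j], df=df).tier
            M[i][j] = M[j][i] = tier
    return M


def trichome_density(count: float, area_mm2: float) -> float:
    """Trichomes per mm² of leaf surface."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / area_mm2


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def lambda_density_dendrogram(lambdas: Dict[str, float],
                              densities: Dict[str, float]) -> DendrogramNode:
    """Ward/Euclidean tree of cultivars on (λ, density), min-max scaled.

    Both features are scaled to [0, 1] so the rate (order 0.1-3) and the
    density (order 20-90 per mm²) contribute comparably to the distances.
    """
    if set(lambdas) != set(densities):
        raise ValueError("cultivar sets of lambdas and densities differ")
    names = sorted(lambdas)
    lam = _minmax(np.array([lambdas[c] for c in names], dtype=float))
    den = _minmax(np.array([densities[c] for c in names], dtype=float))
    return ward_tree({c: (lam[i], den[i]) for i, c in enumerate(names)})
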