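"""Univariate and pairwise inference across cultivars.

One-way ANOVA (F statistic with the explicit between/within sum-of-squares
decomposition), Tukey HSD post hoc with a compact letter display, and the
pairwise panel: pooled-variance Student t test, 95% CI for the mean
difference, Cohen's d with the Sawilowsky-extended class labels, the JZS
two-sample Bayes factor (Cauchy prior, scale 0.707 by default) and post hoc
power of the two-sided two-sample t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import integrate, stats

__all__ = [
    "anova_oneway", "tukey_hsd", "compact_letter_display", "pairwise_t",
    "cohens_d", "classify_effect", "bayes_factor10", "posthoc_power",
    "pairwise_panel", "PairwiseComparison",
]

#: Effect-size class thresholds on |d| (Cohen extended by Sawilowsky).
EFFECT_CLASSES: List[Tuple[float, str]] = [
    (0.01, "Negligible"),
    (0.2, "Very small"),
    (0.5, "Small"),
    (0.8, "Medium"),
    (1.2, "Large"),
    (2.0, "Very large"),
    (math.inf, "Huge"),
]


@dataclass(frozen=True)
class PairwiseComparison:
    descriptor: str
    pair: Tuple[str, str]
    T: float
    p: float
    ci95: Tuple[float, float]
    effect_size: float
    bf10: float
    power: float
    effect_class: str


def _check_groups(groups: Sequence[np.ndarray]) -> List[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for i, a in enumerate(arrs):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {i} contains non-finite values")
    return arrs


def anova_oneway(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, p).

    Degenerate case: zero within-group variance with equal group means is
    reported as F = 0, p = 1 rather than 0/0.
    """
    arrs = _check_groups(groups)
    F, p, *_ = anova_decomposition(arrs)
    return F, p


def anova_decomposition(groups: Sequence[Sequence[float]]):
    """(F, p, SSB, SSW, df_between, df_within) for the one-way layout."""
    arrs = _check_groups(groups)
    allv = np.concatenate(arrs)
    grand = allv.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    dfb = len(arrs) - 1
    dfw = allv.size - len(arrs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0, ssb, ssw, dfb, dfw
        return math.inf, 0.0, ssb, ssw, dfb, dfw
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return float(F), p, float(ssb), float(ssw), dfb, dfw


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> np.ndarray:
    """All-pairs Tukey HSD; returns the symmetric adjusted-p matrix.

    Built on the studentized-range distribution (scipy); the diagonal is 1.
    """
    arrs = _check_groups(groups)
    res = stats.tukey_hsd(*arrs)
    p = np.asarray(res.pvalue, dtype=float).copy()
    np.fill_diagonal(p, 1.0)
    # enforce exact symmetry against tiny numeric drift
    p = (p + p.T) / 2.0
    return np.clip(p, 0.0, 1.0)


def compact_letter_display(pmatrix: np.ndarray, means: Sequence[float],
                           alpha: float = 0.05) -> List[str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups are lettered in descending order of ``means``; two groups share a
    letter iff their adjusted p-value is >= ``alpha``.  Returns one letter
    string per group, in the input order.
    """
    P = np.asarray(pmatrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("p matrix must be square")
    if not np.allclose(P, P.T, atol=1e-12):
        raise ValueError("p matrix must be symmetric")
    n = P.shape[0]
    if len(means) != n:
        raise ValueError("means length must match matrix size")
    order = np.argsort(-np.asarray(means, dtype=float), kind="stable")
    rank = {int(g): r for r, g in enumerate(order)}

    columns: List[set] = [set(range(n))]
    for a in range(n):
        for b in range(a + 1, n):
            if P[a, b] < alpha:
                for col in [c for c in columns if a in c and b in c]:
                    columns.remove(col)
                    columns.extend([col - {a}, col - {b}])
                # absorb columns that are subsets of others
                columns = [c for c in columns
                           if not any(c < d for d in columns)]
    # dedupe while keeping content
    uniq: List[set] = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    uniq.sort(key=lambda c: min(rank[g] for g in c))
    letters = ["" for _ in range(n)]
    for i, col in enumerate(uniq):
        ch = chr(ord("a") + i)
        for g in sorted(col, key=lambda g: rank[g]):
            letters[g] += ch
    return letters


def pairwise_t(groupA: Sequence[float], groupB: Sequence[float],
               welch: bool = False) -> Tuple[float, float, Tuple[float, float]]:
    """Two-sided two-sample t test with a 95% CI for mean(A) - mean(B).

    Pooled-variance Student t by default; Welch behind a flag.  A degenerate
    pair (zero pooled variance) returns T = 0, p = 1 when the means agree and
    is rejected otherwise.
    """
    a, b = _check_groups([groupA, groupB])
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if diff == 0:
            return 0.0, 1.0, (0.0, 0.0)
        raise ValueError("zero pooled variance with unequal means")
    if welch:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    T = diff / se
    p = 2 * float(stats.t.sf(abs(T), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return float(T), p, (float(diff - tcrit * se), float(diff + tcrit * se))


def cohens_d(groupA: Sequence[float], groupB: Sequence[float]) -> float:
    """|mean(A) - mean(B)| / pooled SD (always reported as a magnitude)."""
    a, b = _check_groups([groupA, groupB])
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD; effect size undefined")
    return abs(a.mean() - b.mean()) / math.sqrt(sp2)


def classify_effect(d: float) -> str:
    """Effect-size class label for |d| (Negligible ... Huge)."""
    if d < 0 or not math.isfinite(d):
        raise ValueError(f"effect size must be a finite magnitude, got {d}")
    for threshold, label in EFFECT_CLASSES:
        if d < threshold:
            return label
    raise AssertionError("unreachable")


def bayes_factor10(T: float, nA: int, nB: int, r: float = 0.707) -> float:
    """JZS two-sample Bayes factor BF10 (Cauchy prior on effect size, scale r).

    Computed by numerical quadrature of the Rouder et al. (2009) integral:
    the Cauchy prior is expressed as a normal mixture over a prior variance g
    with an inverse-gamma(1/2, r^2/2) mixing density.
    """
    if nA < 2 or nB < 2:
        raise ValueError("need at least 2 observations per group")
    if not math.isfinite(T):
        raise ValueError("T must be finite")
    n_eff = nA * nB / (nA + nB)
    nu = nA + nB - 2
    t2 = T * T

    def integrand(g: float) -> float:
        om = 1.0 + n_eff * g
        marg = om ** -0.5 * (1.0 + t2 / (om * nu)) ** (-(nu + 1) / 2.0)
        prior = (r / math.sqrt(2 * math.pi)) * g ** -1.5 * math.exp(-r * r / (2 * g))
        return marg * prior

    num, _ = integrate.quad(integrand, 0, math.inf, limit=200)
    den = (1.0 + t2 / nu) ** (-(nu + 1) / 2.0)
    return float(num / den)


def posthoc_power(d: float, nA: int, nB: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test at the observed effect size.

    Computed from the noncentral t distribution with noncentrality
    d * sqrt(nA*nB/(nA+nB)); at d = 0 this reduces to alpha.
    """
    if d < 0:
        raise ValueError("effect size must be non-negative")
    df = nA + nB - 2
    nc = d * math.sqrt(nA * nB / (nA + nB))
    tcrit = float(stats.t.ppf(1 - alpha / 2, df))
    power = float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    return min(max(power, 0.0), 1.0)


def pairwise_panel(samples: Dict[str, Sequence[float]], descriptor: str,
                   bf_scale: float = 0.707,
                   alpha: float = 0.05) -> List[PairwiseComparison]:
    """The full pairwise table for one descriptor across all cultivar pairs.

    Each entry reports T, p, CI95, Cohen's d with its class label, BF10 and
    post hoc power.  p-values are unadjusted; Tukey HSD is the only
    multiplicity adjustment used elsewhere in the pipeline.
    """
    names = sorted(samples)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ga = np.asarray(samples[a], dtype=float)
            gb = np.asarray(samples[b], dtype=float)
            T, p, ci = pairwise_t(ga, gb)
            d = cohens_d(ga, gb)
            out.append(PairwiseComparison(
                descriptor=descriptor, pair=(a, b), T=T, p=p, ci95=ci,
                effect_size=d,
                bf10=bayes_factor10(T, ga.size, gb.size, r=bf_scale),
                power=posthoc_power(d, ga.size, gb.size, alpha=alpha),
                effect_class=classify_effect(d)))
    return out
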