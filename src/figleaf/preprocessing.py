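"""Outlier Winsorization on IQR fences and z-score standardization.

Out-of-fence values are replaced (never dropped) with the fence value, per
cultivar and per descriptor, so each cultivar's own spread defines what
counts as extreme.  Quartiles use linear interpolation between order
statistics; standardization uses the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["QuartileSummary", "iqr_fences", "winsorize", "winsorize_table",
           "zscore_standardize"]


@dataclass(frozen=True)
class QuartileSummary:
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float


def iqr_fences(values: Sequence[float], k: float = 1.5) -> QuartileSummary:
    """Quartiles and Tukey fences q1 - k*IQR, q3 + k*IQR."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError(f"need at least 4 values for quartiles, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in input")
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return QuartileSummary(q1=float(q1), q3=float(q3), iqr=float(iqr),
                           lower_fence=float(q1 - k * iqr),
                           upper_fence=float(q3 + k * iqr))


def winsorize(values: Sequence[float], k_detect: float = 1.5,
              k_replace: float = 1.5,
              k_detect_lower: float | None = None) -> np.ndarray:
    """Replace out-of-fence values with the replacement fence.

    Values below ``q1 - k_detect_lower*IQR`` become ``q1 - k_replace*IQR``;
    values above ``q3 + k_detect*IQR`` become ``q3 + k_replace*IQR``.
    ``k_detect_lower`` defaults to ``k_detect`` (symmetric rule); passing 3.5
    reproduces the literal asymmetric variant of the printed rule.
    Length and order are preserved.
    """
    if k_detect_lower is None:
        k_detect_lower = k_detect
    arr = np.asarray(values, dtype=float).copy()
    fs = iqr_fences(arr, k=1.0)  # raw quartiles; fences built per rule below
    lo_detect = fs.q1 - k_detect_lower * fs.iqr
    hi_detect = fs.q3 + k_detect * fs.iqr
    lo_replace = fs.q1 - k_replace * fs.iqr
    hi_replace = fs.q3 + k_replace * fs.iqr
    arr[arr < lo_detect] = lo_replace
    arr[arr > hi_detect] = hi_replace
    return arr


def winsorize_table(df: pd.DataFrame, value_cols: Sequence[str],
                    group_by: Sequence[str] = ("cultivar",),
                    k_detect: float = 1.5, k_replace: float = 1.5) -> pd.DataFrame:
    """Winsorize each descriptor within each group (default: per cultivar).

    Cells that are missing, or groups with fewer than 4 finite values for a
    column, are left untouched.
    """
    out = df.copy()
    for _, idx in df.groupby(list(group_by)).groups.items():
        for col in value_cols:
            vals = out.loc[idx, col]
            finite = vals.dropna()
            if finite.size < 4:
                continue
            wz = winsorize(finite.to_numpy(), k_detect=k_detect,
                           k_replace=k_replace)
            out.loc[finite.index, col] = wz
    return out


def zscore_standardize(X: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Center each column to mean 0 and scale to unit sample (n-1) SD."""
    if isinstance(X, pd.DataFrame):
        sd = X.std(ddof=1)
        bad = sd.index[(sd == 0) | sd.isna()].tolist()
        if bad:
            raise ValueError(f"constant column(s) cannot be standardized: {bad}")
        return (X - X.mean()) / sd
    arr = np.asarray(X, dtype=float)
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        bad = list(np.flatnonzero((sd == 0) | ~np.isfinite(sd)))
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    return (arr - arr.mean(axis=0)) / sd
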