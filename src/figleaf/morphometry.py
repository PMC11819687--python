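"""Geometric leaf-morphometry descriptors for fig (*Ficus carica*) leaves.

Each leaf is measured on its right half, laid on a Cartesian plane with the
origin at the vein-divergence point and the y-axis along the midrib, so the
central-lobe apex sits at (0, L1).  From the direct measurements (petiole
length/diameter, lamina width/length, central-lobe length, basal angle, vein
angles) and the half-leaf landmark coordinates (lobe apices L2/L3, sinuses
I2/I3, central-lobe maximum-width point Z) the module derives the full
quantitative descriptor panel: the rectangular area proxy ``WxH``, Euclidean
landmark distances from the origin (``*_TP``, via the Pythagorean theorem),
and the shape ratios ``I2/L2``, ``L2/L1``, ``I3/L3``, ``L3/L1``, ``R``,
``PL/H``, ``PL/L1``, ``CLL/H``.

Three-lobed leaves carry 23 descriptors, five-lobed leaves 33 (the extra
third-lobe landmarks I3/L3, the angle beta, and the ratios built on them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "LeafLandmarks",
    "pythag_distance",
    "angle_between_deg",
    "r_statistic",
    "area_category",
    "compute_descriptors",
    "compute_descriptor_table",
    "read_leaf_csv",
    "THREE_LOBED_DESCRIPTORS",
    "FIVE_LOBED_DESCRIPTORS",
]

Point = Tuple[float, float]

#: Leaf-level CSV columns holding direct measurements and landmark coordinates.
LEAF_CSV_COLUMNS = [
    "leaf_id", "cultivar", "lobe_class",
    "PL", "PLO", "L1", "W", "H", "CLL", "BAC", "alpha", "beta",
    "I2x", "I2y", "L2x", "L2y", "I3x", "I3y", "L3x", "L3y", "Zx", "Zy",
]

#: Descriptor column set for three-lobed leaves (the Table-3 panel), 23 names.
THREE_LOBED_DESCRIPTORS = [
    "PL", "PLO", "L1",
    "I2x", "I2y", "I2_TP",
    "L2x", "L2y", "L2_TP",
    "Zx", "Zy", "Z_TP",
    "CLL", "W", "H", "BAC", "alpha",
    "CLL_H", "PL_H", "WxH", "PL_L1", "L2_L1", "I2_L2",
]

#: Descriptor column set for five-lobed leaves (the Table-4 panel), 33 names.
FIVE_LOBED_DESCRIPTORS = THREE_LOBED_DESCRIPTORS + [
    "I3x", "I3y", "I3_TP",
    "L3x", "L3y", "L3_TP",
    "beta", "L3_L1", "I3_L3", "R",
]


@dataclass
class LeafLandmarks:
    """Raw per-leaf measurements and right-half landmark coordinates.

    Lengths are in cm, angles in degrees.  ``I3``, ``L3pt`` and ``beta``
    exist only for five-lobed leaves (``lobe_class == 5``).
    """

    leaf_id: str
    cultivar: str
    lobe_class: int
    PL: float
    PLdiam: float
    W: float
    H: float
    CLL: float
    L1: float
    BAC: float
    alpha: float
    I2: Point
    L2pt: Point
    Z: Point
    beta: Optional[float] = None
    I3: Optional[Point] = None
    L3pt: Optional[Point] = None

    def __post_init__(self) -> None:
        if self.lobe_class not in (3, 5):
            raise ValueError(f"lobe_class must be 3 or 5, got {self.lobe_class}")
        for name in ("PL", "PLdiam", "W", "H", "CLL", "L1"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not 0 < self.BAC < 360:
            raise ValueError(f"BAC must lie in (0, 360), got {self.BAC}")
        if not 0 < self.alpha < 180:
            raise ValueError(f"alpha must lie in (0, 180), got {self.alpha}")
        for pname in ("I2", "L2pt", "Z"):
            self._check_point(pname)
        if self.lobe_class == 5:
            if self.I3 is None or self.L3pt is None or self.beta is None:
                raise ValueError("five-lobed leaf requires I3, L3pt and beta")
            if not 0 < self.beta < 180:
                raise ValueError(f"beta must lie in (0, 180), got {self.beta}")
            self._check_point("I3")
            self._check_point("L3pt")
        else:
            if self.I3 is not None or self.L3pt is not None or self.beta is not None:
                raise ValueError("three-lobed leaf must not carry I3, L3pt or beta")

    def _check_point(self, name: str) -> None:
        x, y = getattr(self, name)
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"{name} coordinates must be finite")
        if x < 0:
            raise ValueError(f"{name}.x must be >= 0 (right half-leaf), got {x}")


def pythag_distance(x: float, y: float) -> float:
    """Euclidean distance of the landmark (x, y) from the coordinate origin."""
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("pythag_distance requires finite coordinates")
    return math.sqrt(x * x + y * y)


def angle_between_deg(u: Sequence[float], v: Sequence[float]) -> float:
    """Unsigned angle between two plane vectors, in degrees (0..180).

    The field angles alpha and beta are measured directly on the leaf; this
    function exists for synthetic-geometry consistency checks.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("angle undefined for a zero vector")
    cosang = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def r_statistic(i2_tp: float, i3_tp: float, l2_tp: float, l3_tp: float) -> float:
    """Sinus-to-apex depth ratio R = (I2_TP + I3_TP) / (L2_TP + L3_TP)."""
    if min(i2_tp, i3_tp, l2_tp, l3_tp) <= 0:
        raise ValueError("r_statistic requires strictly positive distances")
    return (i2_tp + i3_tp) / (l2_tp + l3_tp)


def area_category(area: float) -> str:
    """IPGRI leaf-area class from the WxH area proxy (cm^2).

    Classes: medium (250, 400], large (400, 550], very large (> 550).
    Areas at or below 250 cm^2 fall outside the catalogue and are labelled
    ``below-medium`` so small synthetic leaves do not abort the pipeline.
    """
    if not math.isfinite(area) or area <= 0:
        raise ValueError(f"leaf area must be positive, got {area}")
    if area > 550:
        return "very large"
    if area > 400:
        return "large"
    if area > 250:
        return "medium"
    return "below-medium"


def compute_descriptors(leaf: LeafLandmarks) -> dict:
    """Full descriptor row for one leaf: 23 values if three-lobed, 33 if five.

    Distances come from :func:`pythag_distance`; ratios follow the standard
    definitions (I2/L2 = I2_TP / L2_TP, L2/L1 = L2_TP / L1, PL/H, PL/L1,
    CLL/H elementwise; for five-lobed leaves additionally I3/L3, L3/L1 and R).
    """
    i2_tp = pythag_distance(*leaf.I2)
    l2_tp = pythag_distance(*leaf.L2pt)
    z_tp = pythag_distance(*leaf.Z)
    if l2_tp == 0:
        raise ValueError("L2_TP is zero; shape ratios undefined")
    row = {
        "PL": leaf.PL, "PLO": leaf.PLdiam, "L1": leaf.L1,
        "I2x": leaf.I2[0], "I2y": leaf.I2[1], "I2_TP": i2_tp,
        "L2x": leaf.L2pt[0], "L2y": leaf.L2pt[1], "L2_TP": l2_tp,
        "Zx": leaf.Z[0], "Zy": leaf.Z[1], "Z_TP": z_tp,
        "CLL": leaf.CLL, "W": leaf.W, "H": leaf.H,
        "BAC": leaf.BAC, "alpha": leaf.alpha,
        "CLL_H": leaf.CLL / leaf.H,
        "PL_H": leaf.PL / leaf.H,
        "WxH": leaf.W * leaf.H,
        "PL_L1": leaf.PL / leaf.L1,
        "L2_L1": l2_tp / leaf.L1,
        "I2_L2": i2_tp / l2_tp,
    }
    if leaf.lobe_class == 5:
        i3_tp = pythag_distance(*leaf.I3)
        l3_tp = pythag_distance(*leaf.L3pt)
        if l3_tp == 0:
            raise ValueError("L3_TP is zero; shape ratios undefined")
        row.update({
            "I3x": leaf.I3[0], "I3y": leaf.I3[1], "I3_TP": i3_tp,
            "L3x": leaf.L3pt[0], "L3y": leaf.L3pt[1], "L3_TP": l3_tp,
            "beta": leaf.beta,
            "L3_L1": l3_tp / leaf.L1,
            "I3_L3": i3_tp / l3_tp,
            "R": r_statistic(i2_tp, i3_tp, l2_tp, l3_tp),
        })
    expected = FIVE_LOBED_DESCRIPTORS if leaf.lobe_class == 5 else THREE_LOBED_DESCRIPTORS
    assert set(row) == set(expected)
    return row


def _leaf_from_record(rec: pd.Series) -> LeafLandmarks:
    lobe = int(rec["lobe_class"])
    five = lobe == 5

    def pt(name: str) -> Point:
        return (float(rec[f"{name}x"]), float(rec[f"{name}y"]))

    return LeafLandmarks(
        leaf_id=str(rec["leaf_id"]),
        cultivar=str(rec["cultivar"]),
        lobe_class=lobe,
        PL=float(rec["PL"]), PLdiam=float(rec["PLO"]),
        W=float(rec["W"]), H=float(rec["H"]), CLL=float(rec["CLL"]),
        L1=float(rec["L1"]), BAC=float(rec["BAC"]), alpha=float(rec["alpha"]),
        I2=pt("I2"), L2pt=pt("L2"), Z=pt("Z"),
        beta=float(rec["beta"]) if five else None,
        I3=pt("I3") if five else None,
        L3pt=pt("L3") if five else None,
    )


def compute_descriptor_table(leaves: pd.DataFrame) -> pd.DataFrame:
    """Derive all descriptors for a leaf table (one row per leaf).

    The input follows the leaf CSV dialect (``LEAF_CSV_COLUMNS``); the output
    keeps ``leaf_id``, ``cultivar``, ``lobe_class`` and appends every derived
    column.  Columns meaningless for a lobe class stay empty (NaN).
    """
    rows = []
    for _, rec in leaves.iterrows():
        leaf = _leaf_from_record(rec)
        row = {"leaf_id": leaf.leaf_id, "cultivar": leaf.cultivar,
               "lobe_class": leaf.lobe_class}
        row.update(compute_descriptors(leaf))
        rows.append(row)
    cols = ["leaf_id", "cultivar", "lobe_class"] + FIVE_LOBED_DESCRIPTORS
    return pd.DataFrame(rows).reindex(columns=cols)


def read_leaf_csv(path) -> pd.DataFrame:
    """Read a leaf-landmark CSV (empty cells are missing values)."""
    df = pd.read_csv(path)
    missing = [c for c in LEAF_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"leaf CSV missing columns: {missing}")
    return df
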