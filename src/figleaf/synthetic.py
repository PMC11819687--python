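"""Synthetic study data with the distributional skeleton of the field survey.

The raw leaf measurements behind the fifteen-cultivar study are not publicly
deposited, so this module generates stand-in data carrying the published
statistical structure: per-cultivar means and SDs of every directly measured
trait and landmark coordinate, the 287-leaf sampling design (80 five-lobed +
207 three-lobed), per-cultivar lower-surface trichome rates λ, and trichome
densities per leaf surface.  Direct measurements and coordinates are drawn
from truncated normals (floored at 5% of the trait mean; angles additionally
capped at their geometric maxima); every *derived* descriptor is then
produced only through :func:`figleaf.morphometry.compute_descriptors`, so
rows are internally consistent by construction.

What the generator deliberately does not emulate: trait covariance beyond
that induced by deriving descriptors from sampled coordinates, and any
attempt to forge the study's exact raw dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from .trichome import CLASS_BOUNDS, N_CLASSES

__all__ = [
    "CultivarSpec", "SyntheticConfig", "default_study_config",
    "generate_leaves", "generate_trichome_lengths", "generate_trichome_table",
    "generate_density_table", "load_config", "save_config",
]

MeanSD = Tuple[float, float]

# Per-cultivar (mean, sd) of the directly measured traits.  Three-lobed
# cultivars carry 14 fields; five-lobed add I3/L3 coordinates and beta.
_THREE_LOBED_PARAMS: Dict[str, Dict[str, MeanSD]] = {
    "BC": {"PL": (7.44, 1.2), "PLO": (0.55, 0.1), "L1": (19.6, 2.5),
           "I2x": (2.83, 0.8), "I2y": (7.76, 1.1), "L2x": (8.69, 1.4),
           "L2y": (11.6, 2.2), "Zx": (4.27, 0.6), "Zy": (14.2, 2.4),
           "CLL": (11.8, 2.1), "W": (18.3, 1.9), "H": (21.2, 2.7),
           "BAC": (140.5, 45.0), "alpha": (40.1, 4.1)},
    "BB": {"PL": (9.57, 1.7), "PLO": (0.51, 0.06), "L1": (24.0, 2.2),
           "I2x": (2.89, 0.4), "I2y": (8.94, 1.2), "L2x": (10.5, 1.2),
           "L2y": (15.0, 2.0), "Zx": (5.11, 0.7), "Zy": (13.5, 1.6),
           "CLL": (15.1, 1.3), "W": (22.7, 3.4), "H": (25.5, 3.5),
           "BAC": (113.6, 36.0), "alpha": (41.3, 4.2)},
    "BN": {"PL": (9.54, 1.9), "PLO": (0.53, 0.07), "L1": (19.8, 2.8),
           "I2x": (4.39, 1.1), "I2y": (9.38, 2.1), "L2x": (9.26, 1.2),
           "L2y": (12.3, 2.0), "Zx": (5.09, 0.6), "Zy": (14.5, 2.3),
           "CLL": (10.4, 2.2), "W": (19.3, 2.6), "H": (22.0, 2.9),
           "BAC": (100.0, 37.0), "alpha": (41.9, 6.7)},
    "DO": {"PL": (8.52, 1.5), "PLO": (0.64, 0.1), "L1": (22.8, 1.8),
           "I2x": (3.88, 0.6), "I2y": (10.9, 1.3), "L2x": (9.94, 1.2),
           "L2y": (15.9, 1.8), "Zx": (4.31, 0.5), "Zy": (13.4, 2.0),
           "CLL": (11.8, 1.7), "W": (21.5, 3.2), "H": (25.6, 3.0),
           "BAC": (98.7, 36.0), "alpha": (36.6, 4.3)},
    "FI": {"PL": (6.95, 1.5), "PLO": (0.49, 0.1), "L1": (18.4, 1.9),
           "I2x": (3.25, 0.8), "I2y": (9.37, 1.5), "L2x": (7.52, 0.9),
           "L2y": (11.6, 1.7), "Zx": (5.05, 0.6), "Zy": (15.7, 1.8),
           "CLL": (8.99, 1.1), "W": (16.9, 2.5), "H": (19.7, 3.1),
           "BAC": (110.4, 42.0), "alpha": (38.4, 6.2)},
    "GI": {"PL": (8.74, 1.0), "PLO": (0.54, 0.09), "L1": (21.8, 2.7),
           "I2x": (3.42, 1.1), "I2y": (9.75, 2.3), "L2x": (9.39, 1.7),
           "L2y": (12.3, 2.2), "Zx": (4.69, 0.9), "Zy": (13.4, 2.4),
           "CLL": (12.1, 1.9), "W": (21.7, 3.4), "H": (23.7, 3.0),
           "BAC": (120.2, 37.0), "alpha": (42.5, 7.5)},
    "PA": {"PL": (9.49, 1.5), "PLO": (0.60, 0.1), "L1": (19.6, 2.3),
           "I2x": (3.31, 0.7), "I2y": (8.82, 1.6), "L2x": (8.21, 1.1),
           "L2y": (12.3, 2.0), "Zx": (4.37, 0.7), "Zy": (13.0, 2.44),
           "CLL": (10.8, 1.4), "W": (18.6, 2.5), "H": (21.7, 2.8),
           "BAC": (91.4, 18.0), "alpha": (39.6, 4.7)},
    "PO": {"PL": (8.52, 1.9), "PLO": (0.50, 0.1), "L1": (20.7, 1.8),
           "I2x": (3.27, 0.4), "I2y": (11.3, 1.1), "L2x": (7.89, 1.3),
           "L2y": (13.7, 1.8), "Zx": (4.48, 0.7), "Zy": (13.0, 1.2),
           "CLL": (9.46, 1.4), "W": (18.3, 2.1), "H": (21.1, 2.0),
           "BAC": (183.3, 17.0), "alpha": (31.4, 3.1)},
    "PB": {"PL": (8.02, 1.4), "PLO": (0.70, 0.08), "L1": (21.6, 2.9),
           "I2x": (3.26, 1.2), "I2y": (7.91, 1.3), "L2x": (10.5, 1.4),
           "L2y": (12.7, 2.6), "Zx": (4.89, 0.6), "Zy": (12.5, 2.7),
           "CLL": (13.7, 2.6), "W": (21.6, 3.2), "H": (23.9, 4.0),
           "BAC": (103.1, 25.0), "alpha": (49.4, 6.3)},
    "SP": {"PL": (8.62, 1.4), "PLO": (0.51, 0.09), "L1": (22.1, 2.3),
           "I2x": (3.98, 1.1), "I2y": (11.4, 1.3), "L2x": (8.65, 1.6),
           "L2y": (13.4, 1.7), "Zx": (4.88, 0.4), "Zy": (14.2, 0.8),
           "CLL": (10.8, 1.6), "W": (19.3, 3.0), "H": (22.6, 2.4),
           "BAC": (226.1, 32.0), "alpha": (29.0, 6.4)},
    "VE": {"PL": (8.93, 1.8), "PLO": (0.47, 0.08), "L1": (20.1, 2.0),
           "I2x": (4.05, 0.9), "I2y": (10.9, 1.0), "L2x": (8.04, 1.2),
           "L2y": (13.0, 1.1), "Zx": (4.73, 0.7), "Zy": (11.1, 1.9),
           "CLL": (9.22, 1.8), "W": (17.8, 3.3), "H": (21.4, 2.6),
           "BAC": (145.8, 39.0), "alpha": (36.0, 5.2)},
}

_FIVE_LOBED_PARAMS: Dict[str, Dict[str, MeanSD]] = {
    "AL": {"PL": (9.07, 1.7), "PLO": (0.70, 0.09), "L1": (23.1, 2.4),
           "I2x": (3.29, 1.5), "I2y": (8.68, 1.9), "L2x": (9.34, 1.89),
           "L2y": (14.3, 3.7), "I3x": (7.31, 1.6), "I3y": (3.21, 1.8),
           "L3x": (10.9, 2.4), "L3y": (2.76, 3.9), "Zx": (4.79, 1.4),
           "Zy": (15.1, 2.7), "CLL": (14.3, 2.4), "W": (23.7, 3.2),
           "H": (26.1, 2.7), "BAC": (91.5, 13.0), "alpha": (44.1, 8.0),
           "beta": (41.4, 4.0)},
    "CO": {"PL": (11.6, 1.6), "PLO": (0.72, 0.13), "L1": (24.9, 2.6),
           "I2x": (3.40, 0.9), "I2y": (10.5, 2.9), "L2x": (10.7, 1.7),
           "L2y": (16.4, 2.5), "I3x": (8.01, 1.0), "I3y": (3.60, 0.6),
           "L3x": (12.2, 1.7), "L3y": (2.95, 1.3), "Zx": (5.17, 0.8),
           "Zy": (16.3, 2.3), "CLL": (14.4, 2.4), "W": (24.6, 4.4),
           "H": (30.5, 3.9), "BAC": (34.5, 12.8), "alpha": (44.6, 4.0),
           "beta": (45.4, 2.3)},
    "PN": {"PL": (8.01, 1.3), "PLO": (0.46, 0.07), "L1": (18.9, 2.6),
           "I2x": (2.21, 0.5), "I2y": (5.91, 0.64), "L2x": (8.43, 1.3),
           "L2y": (12.9, 2.8), "I3x": (4.89, 0.9), "I3y": (2.88, 0.7),
           "L3x": (9.31, 1.5), "L3y": (2.88, 1.0), "Zx": (3.81, 0.7),
           "Zy": (13.7, 2.0), "CLL": (12.9, 2.3), "W": (18.5, 2.5),
           "H": (20.5, 2.7), "BAC": (113.4, 37.0), "alpha": (39.7, 5.3),
           "beta": (42.0, 5.2)},
    "PE": {"PL": (7.58, 1.3), "PLO": (0.47, 0.09), "L1": (20.3, 2.8),
           "I2x": (2.41, 0.7), "I2y": (7.82, 2.1), "L2x": (8.56, 1.4),
           "L2y": (13.9, 2.7), "I3x": (5.95, 1.2), "I3y": (4.28, 1.2),
           "L3x": (10.9, 2.2), "L3y": (4.12, 1.6), "Zx": (4.46, 0.5),
           "Zy": (14.0, 1.9), "CLL": (12.5, 2.0), "W": (20.7, 3.7),
           "H": (22.4, 3.3), "BAC": (114.8, 23.0), "alpha": (37.9, 4.5),
           "beta": (37.5, 4.1)},
}

# Trichome densities per mm^2 (mean, sd), upper / lower epidermis.
_DENSITY_PARAMS: Dict[str, Dict[str, MeanSD]] = {
    "AL": {"upper": (26.3, 3.26), "lower": (48.5, 2.38)},
    "BB": {"upper": (2.02, 0.77), "lower": (71.5, 2.65)},
    "BC": {"upper": (7.52, 1.5), "lower": (64.7, 2.78)},
    "BN": {"upper": (3.50, 0.51), "lower": (64.5, 2.88)},
    "CO": {"upper": (4.25, 0.35), "lower": (32.2, 2.18)},
    "DO": {"upper": (7.48, 1.02), "lower": (63.2, 1.90)},
    "FI": {"upper": (5.02, 0.76), "lower": (23.2, 2.91)},
    "GI": {"upper": (2.04, 0.89), "lower": (54.2, 2.65)},
    "PA": {"upper": (3.26, 0.46), "lower": (93.8, 1.79)},
    "PB": {"upper": (2.50, 0.35), "lower": (77.0, 1.86)},
    "PE": {"upper": (5.53, 0.58), "lower": (87.5, 1.10)},
    "PN": {"upper": (3.01, 0.36), "lower": (55.8, 1.56)},
    "PO": {"upper": (3.02, 0.32), "lower": (61.5, 2.41)},
    "SP": {"upper": (2.76, 0.28), "lower": (39.7, 0.68)},
    "VE": {"upper": (1.02, 0.12), "lower": (48.2, 1.14)},
}

# Published lower-surface Poisson rates; the remaining cultivars default to
# 1.0 (a documented free choice — no rate is printed for them).
_PRINTED_LAMBDAS = {"FI": 0.3, "VE": 0.1, "PO": 3.0, "PA": 1.8, "PE": 1.8}
_DEFAULT_LAMBDA = 1.0

# Angular traits and their geometric caps (degrees).
_ANGLE_CAPS = {"BAC": 360.0, "alpha": 180.0, "beta": 180.0}

#: Sampled ESEM leaf area per cultivar used to size trichome samples
#: (mm^2); three tissue pieces of roughly 0.65 mm^2 imaged area each.
DEFAULT_SAMPLED_AREA_MM2 = 2.0


@dataclass
class CultivarSpec:
    code: str
    lobe_class: int
    n_leaves: int
    measurements: Dict[str, MeanSD]
    trichome_lambda: float
    density: Dict[str, MeanSD]  # surface -> (mean, sd)

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.trichome_lambda < 0:
            raise ValueError("trichome lambda must be >= 0")
        for name, (_, sd) in self.measurements.items():
            if sd < 0:
                raise ValueError(f"negative sd for {name}")


@dataclass
class SyntheticConfig:
    cultivars: List[CultivarSpec]
    seed: int = 0
    sampled_area_mm2: float = DEFAULT_SAMPLED_AREA_MM2

    def total_leaves(self) -> int:
        return sum(c.n_leaves for c in self.cultivars)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sampled_area_mm2": self.sampled_area_mm2,
            "cultivars": [
                {"code": c.code, "lobe_class": c.lobe_class,
                 "n_leaves": c.n_leaves,
                 "measurements": {k: list(v) for k, v in c.measurements.items()},
                 "trichome_lambda": c.trichome_lambda,
                 "density": {k: list(v) for k, v in c.density.items()}}
                for c in self.cultivars],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        cultivars = [CultivarSpec(
            code=c["code"], lobe_class=int(c["lobe_class"]),
            n_leaves=int(c["n_leaves"]),
            measurements={k: tuple(v) for k, v in c["measurements"].items()},
            trichome_lambda=float(c["trichome_lambda"]),
            density={k: tuple(v) for k, v in c["density"].items()},
        ) for c in d["cultivars"]]
        return cls(cultivars=cultivars, seed=int(d.get("seed", 0)),
                   sampled_area_mm2=float(
                       d.get("sampled_area_mm2", DEFAULT_SAMPLED_AREA_MM2)))


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """The study-design configuration: 15 cultivars, 287 leaves.

    Eleven three-lobed cultivars at 19 leaves each would give 209; the two
    last codes in sorted order (SP, VE) get 18 so the trilobate total is the
    stated 207.  The four five-lobed cultivars get 20 leaves each (80).
    """
    cultivars: List[CultivarSpec] = []
    three_codes = sorted(_THREE_LOBED_PARAMS)
    short = set(three_codes[-2:])  # SP, VE
    for code in three_codes:
        cultivars.append(CultivarSpec(
            code=code, lobe_class=3,
            n_leaves=18 if code in short else 19,
            measurements=dict(_THREE_LOBED_PARAMS[code]),
            trichome_lambda=_PRINTED_LAMBDAS.get(code, _DEFAULT_LAMBDA),
            density={k: tuple(v) for k, v in _DENSITY_PARAMS[code].items()}))
    for code in sorted(_FIVE_LOBED_PARAMS):
        cultivars.append(CultivarSpec(
            code=code, lobe_class=5, n_leaves=20,
            measurements=dict(_FIVE_LOBED_PARAMS[code]),
            trichome_lambda=_PRINTED_LAMBDAS.get(code, _DEFAULT_LAMBDA),
            density={k: tuple(v) for k, v in _DENSITY_PARAMS[code].items()}))
    cfg = SyntheticConfig(cultivars=cultivars, seed=seed)
    assert cfg.total_leaves() == 287
    return cfg


def _draw_trait(rng: np.random.Generator, mean: float, sd: float, n: int,
                upper: float | None = None) -> np.ndarray:
    """Truncated-normal draws floored at 5% of the mean (rejection)."""
    if sd == 0:
        return np.full(n, mean)
    floor = 0.05 * mean
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = rng.normal(mean, sd, size=2 * (n - filled))
        ok = cand > floor
        if upper is not None:
            ok &= cand < upper
        cand = cand[ok]
        take = min(cand.size, n - filled)
        out[filled:filled + take] = cand[:take]
        filled += take
    return out


def generate_leaves(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Leaf-landmark table (one row per leaf, leaf CSV dialect).

    Reproducible for a fixed seed; ``seed=None`` uses the config seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    for cult in config.cultivars:
        n = cult.n_leaves
        cols = {}
        for name, (mean, sd) in cult.measurements.items():
            cols[name] = _draw_trait(rng, mean, sd, n,
                                     upper=_ANGLE_CAPS.get(name))
        df = pd.DataFrame(cols)
        df.insert(0, "lobe_class", cult.lobe_class)
        df.insert(0, "cultivar", cult.code)
        df.insert(0, "leaf_id", [f"{cult.code}_{i + 1:03d}" for i in range(n)])
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for col in ("beta", "I3x", "I3y", "L3x", "L3y"):
        if col not in out.columns:
            out[col] = np.nan
    order = ["leaf_id", "cultivar", "lobe_class", "PL", "PLO", "L1", "W", "H",
             "CLL", "BAC", "alpha", "beta", "I2x", "I2y", "L2x", "L2y",
             "I3x", "I3y", "L3x", "L3y", "Zx", "Zy"]
    return out[order]


def generate_trichome_lengths(lam: float, n: int,
                              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Synthetic trichome lengths (µm) whose class histogram is Poisson(λ).

    Class indices x are Poisson(λ) draws rejection-resampled into 0..10
    (rejection keeps the MLE unbiased at small λ, unlike clamping); each
    length is then uniform within the printed bounds of class x+1, so
    binning recovers the drawn class exactly.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    xs = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        cand = rng.poisson(lam, size=max(2 * (n - filled), 16))
        cand = cand[cand < N_CLASSES]
        take = min(cand.size, n - filled)
        xs[filled:filled + take] = cand[:take]
        filled += take
    lows = np.array([b[0] for b in CLASS_BOUNDS])
    highs = np.array([b[1] for b in CLASS_BOUNDS])
    return rng.uniform(lows[xs], highs[xs])


def generate_trichome_table(config: SyntheticConfig,
                            seed: int | None = None) -> pd.DataFrame:
    """Raw lower-surface trichome lengths for every cultivar.

    Sample sizes follow n = round(lower density x sampled area); the study
    never states the per-cultivar counts behind its histograms, so the
    sampled area is a documented assumption of the generator.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 101)
    rows = []
    for cult in config.cultivars:
        mean_density = cult.density["lower"][0]
        n = max(int(round(mean_density * config.sampled_area_mm2)), 1)
        lengths = generate_trichome_lengths(cult.trichome_lambda, n, rng)
        rows.append(pd.DataFrame({"cultivar": cult.code, "surface": "lower",
                                  "length_um": lengths}))
    return pd.concat(rows, ignore_index=True)


def generate_density_table(config: SyntheticConfig,
                           seed: int | None = None) -> pd.DataFrame:
    """Per-cultivar, per-surface trichome counts over the sampled area."""
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 202)
    rows = []
    for cult in config.cultivars:
        for surface, (mean, sd) in cult.density.items():
            density = max(float(rng.normal(mean, sd)), 0.0)
            rows.append({"cultivar": cult.code, "surface": surface,
                         "count": int(round(density * config.sampled_area_mm2)),
                         "area_mm2": config.sampled_area_mm2})
    return pd.DataFrame(rows)


def load_config(path) -> SyntheticConfig:
    """Read a SyntheticConfig from YAML or JSON."""
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
        else json.loads(text)
    return SyntheticConfig.from_dict(data)


def save_config(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        if str(path).endswith((".yaml", ".yml")):
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        else:
            json.dump(config.to_dict(), fh, indent=2)
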