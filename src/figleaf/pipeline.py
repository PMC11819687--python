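"""End-to-end orchestration of the analysis stages.

Stages run in a fixed order -- simulate, descriptors, winsorize, anova,
select, classify, cluster, pca, trichomes, report -- each consuming the
previous stage's on-disk output and writing machine-readable tables
(CSV/JSON/Newick) into the output directory, so any stage can be rerun from
intermediates.  A RunManifest records the config hash, the seed, and every
stage's outputs with row counts; deterministic stages are byte-identical
across reruns with the same manifest inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster_bootstrap import bootstrap_support, to_newick
from .inferential import anova_oneway, compact_letter_display, pairwise_panel, tukey_hsd
from .ml_selection import (COMMON_SIX_DESCRIPTORS, accuracy_vs_topk,
                           common_top_features, rank_features_mdi, train_rf)
from .morphometry import (FIVE_LOBED_DESCRIPTORS, THREE_LOBED_DESCRIPTORS,
                          compute_descriptor_table, read_leaf_csv)
from .pca import pca_standardized
from .preprocessing import winsorize_table
from .synthetic import (SyntheticConfig, generate_density_table,
                        generate_leaves, generate_trichome_table)
from .trichome import (bin_trichome_lengths, fit_lambda_mle,
                       lambda_density_dendrogram, significance_matrix,
                       trichome_density)

__all__ = ["STAGES", "RunManifest", "run_pipeline"]

STAGES = ["simulate", "descriptors", "winsorize", "anova", "select",
          "classify", "cluster", "pca", "trichomes", "report"]

# files each stage needs from upstream
_REQUIRES: Dict[str, List[str]] = {
    "simulate": [],
    "descriptors": ["leaves.csv"],
    "winsorize": ["descriptors.csv"],
    "anova": ["descriptors_winsorized.csv"],
    "select": ["descriptors_winsorized.csv"],
    "classify": ["descriptors_winsorized.csv"],
    "cluster": ["descriptors_winsorized.csv"],
    "pca": ["descriptors_winsorized.csv"],
    "trichomes": ["trichome_lengths.csv", "trichome_density.csv"],
    "report": [],
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: List[dict] = field(default_factory=list)

    def record(self, stage: str, outputs: Dict[str, int],
               inputs: Sequence[str] = ()) -> None:
        self.stages.append({"stage": stage, "inputs": list(inputs),
                            "outputs": outputs})

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "version": self.version, "stages": self.stages}


def _hash_config(config: SyntheticConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _rows(path: Path) -> int:
    if path.suffix == ".csv":
        return int(pd.read_csv(path).shape[0])
    return 1


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False)
    return int(df.shape[0])


def _descriptor_cols(lobe_class: int) -> List[str]:
    return FIVE_LOBED_DESCRIPTORS if lobe_class == 5 else THREE_LOBED_DESCRIPTORS


def _stage_simulate(out: Path, config: SyntheticConfig, seed: int) -> Dict[str, int]:
    leaves = generate_leaves(config, seed=seed)
    lengths = generate_trichome_table(config, seed=seed)
    density = generate_density_table(config, seed=seed)
    return {
        "leaves.csv": _write_csv(leaves, out / "leaves.csv"),
        "trichome_lengths.csv": _write_csv(lengths, out / "trichome_lengths.csv"),
        "trichome_density.csv": _write_csv(density, out / "trichome_density.csv"),
    }


def _stage_descriptors(out: Path) -> Dict[str, int]:
    leaves = read_leaf_csv(out / "leaves.csv")
    desc = compute_descriptor_table(leaves)
    return {"descriptors.csv": _write_csv(desc, out / "descriptors.csv")}


def _stage_winsorize(out: Path) -> Dict[str, int]:
    desc = pd.read_csv(out / "descriptors.csv")
    value_cols = [c for c in FIVE_LOBED_DESCRIPTORS if c in desc.columns]
    wz = winsorize_table(desc, value_cols, group_by=["cultivar"])
    return {"descriptors_winsorized.csv":
            _write_csv(wz, out / "descriptors_winsorized.csv")}


def _stage_anova(out: Path) -> Dict[str, int]:
    desc = pd.read_csv(out / "descriptors_winsorized.csv")
    outputs: Dict[str, int] = {}
    for lobe, tag in ((3, "three"), (5, "five")):
        sub = desc[desc["lobe_class"] == lobe]
        rows = []
        for col in _descriptor_cols(lobe):
            groups = {c: g[col].dropna().to_numpy()
                      for c, g in sub.groupby("cultivar")}
            groups = {c: v for c, v in groups.items() if v.size >= 2}
            if len(groups) < 2:
                continue
            names = sorted(groups)
            samples = [groups[c] for c in names]
            F, p = anova_oneway(samples)
            pmat = tukey_hsd(samples)
            letters = compact_letter_display(
                pmat, [s.mean() for s in samples])
            for name, s, let in zip(names, samples, letters):
                rows.append({"descriptor": col, "cultivar": name,
                             "mean": s.mean(), "sd": s.std(ddof=1),
                             "F": F, "p": p, "letters": let})
        fname = f"anova_{tag}.csv"
        outputs[fname] = _write_csv(pd.DataFrame(rows), out / fname)
    # pairwise panel on the pooled six-descriptor set
    rows = []
    for col in COMMON_SIX_DESCRIPTORS:
        samples = {c: g[col].dropna().to_numpy()
                   for c, g in desc.groupby("cultivar")}
        for cmp_ in pairwise_panel(samples, col):
            rows.append({"descriptor": col,
                         "pair": f"{cmp_.pair[0]}||{cmp_.pair[1]}",
                         "T": cmp_.T, "p_val": cmp_.p,
                         "ci_low": cmp_.ci95[0], "ci_high": cmp_.ci95[1],
                         "effect_size": cmp_.effect_size, "bf10": cmp_.bf10,
                         "power": cmp_.power,
                         "effect_class": cmp_.effect_class})
    outputs["pairwise_panel.csv"] = _write_csv(
        pd.DataFrame(rows), out / "pairwise_panel.csv")
    return outputs


def _stage_select(out: Path, seed: int) -> Dict[str, int]:
    desc = pd.read_csv(out / "descriptors_winsorized.csv")
    outputs: Dict[str, int] = {}
    rankings = {}
    for lobe, tag in ((3, "three"), (5, "five")):
        sub = desc[desc["lobe_class"] == lobe]
        X = sub[_descriptor_cols(lobe)]
        y = sub["cultivar"].to_numpy()
        ranking = rank_features_mdi(X, y, seed=seed)
        rankings[tag] = ranking
        rk = pd.DataFrame({"descriptor": ranking.features,
                           "importance": ranking.importances,
                           "importance_sd": ranking.importance_sds})
        outputs[f"ranking_{tag}.csv"] = _write_csv(rk, out / f"ranking_{tag}.csv")
        curve = accuracy_vs_topk(X, y, ranking, seed=seed)
        cv = pd.DataFrame(curve, columns=["k", "accuracy"])
        outputs[f"topk_{tag}.csv"] = _write_csv(cv, out / f"topk_{tag}.csv")
    common = sorted(common_top_features(rankings["three"], rankings["five"], k=10))
    payload = {
        "top10_three": rankings["three"].top(10),
        "top10_five": rankings["five"].top(10),
        "common_top10": common,
        "selected_six": COMMON_SIX_DESCRIPTORS,
        "note": ("selected_six is the configured downstream panel; when the "
                 "top-10 intersection differs from it, both are reported"),
    }
    (out / "common_features.json").write_text(json.dumps(payload, indent=2))
    outputs["common_features.json"] = 1
    return outputs


def _stage_classify(out: Path, seed: int) -> Dict[str, int]:
    desc = pd.read_csv(out / "descriptors_winsorized.csv")
    X = desc[COMMON_SIX_DESCRIPTORS]
    y = desc["cultivar"].to_numpy()
    _, report = train_rf(X, y, seed=seed)
    conf = pd.DataFrame(report.confusion, index=report.labels,
                        columns=report.labels)
    conf.index.name = "true"
    conf.to_csv(out / "confusion.csv")
    (out / "classification_report.json").write_text(
        json.dumps(report.to_dict(), indent=2))
    return {"confusion.csv": len(report.labels),
            "classification_report.json": 1}


def _stage_cluster(out: Path, seed: int, B: int = 100) -> Dict[str, int]:
    desc = pd.read_csv(out / "descriptors_winsorized.csv")
    tree = bootstrap_support(desc, COMMON_SIX_DESCRIPTORS, B=B, seed=seed)
    (out / "dendrogram.nwk").write_text(to_newick(tree) + "\n")
    (out / "dendrogram.json").write_text(json.dumps(tree.to_dict(), indent=2))
    return {"dendrogram.nwk": 1, "dendrogram.json": 1}


def _stage_pca(out: Path) -> Dict[str, int]:
    desc = pd.read_csv(out / "descriptors_winsorized.csv")
    res = pca_standardized(desc[COMMON_SIX_DESCRIPTORS], ncomp=3)
    table = res.loadings_table()
    table.loc["Eigenvalues"] = res.eigenvalues[:res.ncomp]
    table.loc["% of variance"] = res.pct_variance
    table.loc["Cumulative variance (%)"] = res.cumulative_pct
    table.index.name = "trait"
    table.to_csv(out / "pca_loadings.csv")
    scores = pd.DataFrame(res.scores, columns=[f"PC{i+1}" for i in range(res.ncomp)])
    scores.insert(0, "cultivar", desc["cultivar"].to_numpy())
    return {"pca_loadings.csv": int(table.shape[0]),
            "pca_scores.csv": _write_csv(scores, out / "pca_scores.csv")}


def _stage_trichomes(out: Path, seed: int) -> Dict[str, int]:
    lengths = pd.read_csv(out / "trichome_lengths.csv")
    density = pd.read_csv(out / "trichome_density.csv")
    hists, lam_rows = [], []
    for cult, g in lengths[lengths["surface"] == "lower"].groupby("cultivar"):
        hist = bin_trichome_lengths(g["length_um"].to_numpy(),
                                    cultivar=str(cult), surface="lower")
        fit = fit_lambda_mle(hist)
        hists.append(hist)
        lam_rows.append({"cultivar": cult, "lambda": fit.lam,
                         "loglik": fit.loglik, "n": fit.n})
    lam_df = pd.DataFrame(lam_rows)
    outputs = {"lambda_table.csv": _write_csv(lam_df, out / "lambda_table.csv")}
    tiers = significance_matrix(hists)
    names = [h.cultivar for h in hists]
    tier_df = pd.DataFrame(tiers, index=names, columns=names)
    tier_df.index.name = "cultivar"
    tier_df.to_csv(out / "lrt_tiers.csv")
    outputs["lrt_tiers.csv"] = len(names)
    dens = density[density["surface"] == "lower"]
    densities = {str(r["cultivar"]): trichome_density(r["count"], r["area_mm2"])
                 for _, r in dens.iterrows()}
    lambdas = dict(zip(lam_df["cultivar"].astype(str), lam_df["lambda"]))
    tree = lambda_density_dendrogram(lambdas, densities)
    (out / "trichome_tree.nwk").write_text(to_newick(tree) + "\n")
    outputs["trichome_tree.nwk"] = 1
    return outputs


def run_pipeline(config: SyntheticConfig, stages: Sequence[str] | None = None,
                 seed: int | None = None, outdir: str | Path = "results/run",
                 bootstrap_B: int = 100) -> RunManifest:
    """Run the requested stages in order; returns the RunManifest.

    ``stages`` defaults to all of :data:`STAGES`; a stage whose upstream
    output is absent from ``outdir`` raises, naming the stage and the file.
    """
    stages = list(STAGES if stages is None else stages)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    stages.sort(key=STAGES.index)
    seed = config.seed if seed is None else seed
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_hash_config(config), seed=seed,
                           version=__version__)
    for stage in stages:
        needed = _REQUIRES[stage]
        for f in needed:
            if not (out / f).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' requires missing upstream output {f}")
        if stage == "simulate":
            outputs = _stage_simulate(out, config, seed)
        elif stage == "descriptors":
            outputs = _stage_descriptors(out)
        elif stage == "winsorize":
            outputs = _stage_winsorize(out)
        elif stage == "anova":
            outputs = _stage_anova(out)
        elif stage == "select":
            outputs = _stage_select(out, seed)
        elif stage == "classify":
            outputs = _stage_classify(out, seed)
        elif stage == "cluster":
            outputs = _stage_cluster(out, seed, B=bootstrap_B)
        elif stage == "pca":
            outputs = _stage_pca(out)
        elif stage == "trichomes":
            outputs = _stage_trichomes(out, seed)
        elif stage == "report":
            outputs = {"manifest.json": 1}
        manifest.record(stage, outputs, inputs=needed)
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest
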