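# figleaf

Leaf geometric morphometrics and trichome statistics for discriminating fig
(*Ficus carica*) cultivars.

Characterizing fig germplasm from leaf shape is a standard first step in
cataloguing cultivars, but it hinges on extracting a reproducible
quantitative descriptor panel and on defensible statistics over many
correlated traits.  This package implements that chain as a tested library
for plant-phenomics work: descriptor extraction from half-leaf landmark
coordinates, per-cultivar outlier Winsorization, ANOVA/Tukey inference with
compact letter displays and a pairwise effect-size/Bayes-factor panel,
Random-Forest (Gini/MDI) feature ranking and cultivar classification,
Ward/Euclidean clustering with bootstrap node support, standardized PCA,
and Poisson modelling of trichome length-class histograms with pairwise
likelihood-ratio tests.  A synthetic-data generator reproduces the
fifteen-cultivar study design (287 leaves = 207 three-lobed + 80
five-lobed) from published per-cultivar means/SDs, so the whole pipeline is
runnable and testable without the unreleased raw measurements.

## The core quantities

- Each leaf is measured on its right half on a Cartesian plane (origin at
  the vein-divergence point, y-axis up the midrib).  Landmark distances are
  `*_TP = √(x² + y²)`; shape ratios include I2/L2, L2/L1, PL/H, PL/L1,
  CLL/H and, for five-lobed leaves, R = (I2_TP + I3_TP)/(L2_TP + L3_TP).
  Three-lobed leaves carry 23 descriptors, five-lobed 33.
- Trichome lengths (µm) bin into 11 size classes; with support x = class − 1
  a cultivar's histogram is summarized by the Poisson rate λ (MLE = mean x).
  Cultivar pairs are compared by LRT = 2·(ℓ_A + ℓ_B − ℓ_pooled), referred
  to a χ² upper tail.
- Dendrogram node support = percentage of within-cultivar bootstrap
  replicates containing a node whose leaf set matches at Jaccard ≥ 0.8.

See `docs/methods.md` for the full model description, parameter defaults
and known limitations.

## Worked example

```python
from figleaf.synthetic import generate_trichome_lengths
from figleaf.trichome import bin_trichome_lengths, fit_lambda_mle, lrt_poisson

# recover the published PO rate from a synthetic histogram
lengths = generate_trichome_lengths(3.0, 20_000, seed=42)
fit = fit_lambda_mle(bin_trichome_lengths(lengths))
print(round(fit.lam, 3))          # 3.014

# contrast a sparse-trichome cultivar (FI-like) against it
fi = bin_trichome_lengths(generate_trichome_lengths(0.3, 500, seed=1))
po = bin_trichome_lengths(generate_trichome_lengths(3.0, 500, seed=2))
res = lrt_poisson(fi, po)
print(res.tier, round(res.statistic, 1))   # *** 1284.8
```

The recovered rate 3.014 sits within sampling error (SE ≈ 0.012) of the
generator's λ = 3.0, and the likelihood-ratio statistic of ~1285 on two
histograms of 500 trichomes each marks the FI/PO contrast as significant
far beyond the 0.001 tier — the same qualitative separation the sparse- and
dense-trichome cultivars show.

The full analysis sequence lives under `analysis/` as numbered drivers
(simulate → morphometry/statistics → feature selection/classification →
clustering/PCA → trichomes), each writing its tables to `results/study/`
and printing a one-paragraph summary.  Run them in order, e.g.:

```
python analysis/01_simulate.py --seed 0
python analysis/02_morphometry_stats.py --seed 0
```

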