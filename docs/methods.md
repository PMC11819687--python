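# Methods

## Scope and data model

The package re-implements, as a tested pipeline, the statistical chain used
to discriminate fifteen fig (*Ficus carica*) cultivars from leaf geometric
morphometry and trichome size distributions.  The raw field measurements
behind the study are not publicly deposited, so a first-class synthetic
generator (`figleaf.synthetic`) reproduces the study's *distributional
skeleton* — per-cultivar trait means and SDs, the 287-leaf design, trichome
rates and densities — and every downstream stage operates on that or on any
user-supplied table in the same CSV dialect.

A leaf record holds the direct measurements (petiole length PL and diameter
PLØ, lamina width W and length H, central-lobe length CLL, midrib length L1,
basal angle BAC, vein angles α and, for five-lobed leaves, β) plus right-half
landmark coordinates on a Cartesian plane with the origin at the
vein-divergence point and the y-axis up the midrib: the sinus points I2 (and
I3), the lobe apices L2 (and L3), and Z, the central lobe's maximum-width
point.  All coordinates satisfy x ≥ 0 (right half-leaf); the axis convention
is fixed for determinism (the measurement protocol fixes only the y-axis).

## Descriptor panel

From each record `figleaf.morphometry` derives the area proxy `WxH = W·H`,
the landmark distances from the origin `*_TP = √(x² + y²)`, and the ratios
I2/L2 (= I2_TP/L2_TP), L2/L1, I3/L3, L3/L1, R = (I2_TP + I3_TP)/(L2_TP +
L3_TP), PL/H, PL/L1, CLL/H.  Three-lobed leaves yield exactly 23
descriptors, five-lobed leaves 33.  Note that L3/L1 is included in the
five-lobed panel — the published per-cultivar descriptor tables carry it
even though it is missing from the abbreviation catalogue, and the
33-descriptor count is only reachable with it.  IPGRI leaf-area classes are
assigned from WxH with left-open/right-closed intervals as printed
(medium (250, 400], large (400, 550], very large > 550 cm²); areas ≤ 250 cm²
get a distinct `below-medium` label rather than an error so synthetic tails
cannot abort a run.

Because `x ↦ √(x² + y²)` is convex, the mean of the `*_TP` values of a
population exceeds the `*_TP` of the mean coordinates (Jensen); per-cultivar
mean distance tables therefore do not exactly equal distances of mean
coordinates, and cross-table consistency checks use a loose ±0.05 cm band.

## Outlier handling and standardization

Winsorization runs per (cultivar, descriptor) cell: with quartiles Q1/Q3
(linear interpolation between order statistics, the mainstream numerical
default, fixed for reproducibility) and IQR = Q3 − Q1, values outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] are *replaced* by the corresponding fence.  The
detection multiplier is configurable per side; an asymmetric lower rule
(detect at 3.5·IQR, replace at 1.5·IQR) can be requested to reproduce the
literal printed variant, but the symmetric 1.5/1.5 rule is the default
because the asymmetry reads as a typographical slip.  Winsorization is
idempotent, preserves length, order, and the ranks of in-fence values, and
never widens the sample range.  Standardization is z-scoring with the
sample (n − 1) SD; constant columns are rejected by name.

## Univariate and pairwise inference

One-way fixed-effects ANOVA is computed from the explicit SSB/SSW
decomposition (conserving total SS to 1e-9 relative); the degenerate
all-constant layout reports F = 0, p = 1.  Post hoc contrasts use Tukey's
HSD on the studentized-range distribution, summarized as a compact letter
display by the insert-and-absorb algorithm with letters assigned in
descending group-mean order: two groups share a letter iff their adjusted
p ≥ α.

The pairwise panel reports, per cultivar pair and descriptor: the
pooled-variance Student t statistic (Welch behind a flag), the two-sided p,
a 95% CI for the mean difference, Cohen's d = |Δmean|/pooled SD with class
labels on the Sawilowsky-extended scale (Negligible < 0.01 ≤ Very small
< 0.2 ≤ Small < 0.5 ≤ Medium < 0.8 ≤ Large < 1.2 ≤ Very large < 2.0 ≤ Huge),
the JZS two-sample Bayes factor, and post hoc power.  The Bayes factor is
computed in-package by numerical quadrature of the Rouder (2009) integral —
Cauchy prior on the standardized effect (default scale r = 0.707) expressed
as a normal mixture over an inverse-gamma(1/2, r²/2) prior variance — and is
cross-checked in the tests against an independent library implementation.
Power comes directly from the noncentral t distribution with noncentrality
d·√(n_A·n_B/(n_A+n_B)); at d = 0 it reduces to α = 0.05.  The panel is
deliberately unadjusted for multiplicity; Tukey HSD is the only adjustment
in the pipeline.

## Random-Forest selection and classification

Forests use 100 trees, Gini criterion, unlimited depth, √p feature
subsampling and bootstrap resampling (all exposed in config).  Importance is
Mean Decrease in Impurity, normalized to sum to 1, with ties broken by
importance descending then descriptor name ascending.  The saturation curve
refits the forest on the top-k ranked descriptors for every k under one
fixed 80/20 split (no cross-validation — matching the protocol's single
split).  The split is stratified by cultivar by default: with 15 classes of
~19 leaves, an unstratified 20% test fold can miss classes entirely (the
published per-class zeros are consistent with exactly that); the
unstratified mode is available to reproduce that behaviour.  Metrics follow
the standard confusion-matrix definitions with the return-0 convention on
empty denominators; weighted averages weight by true-class counts, which
makes weighted recall equal accuracy identically.

The per-lobe-class top-10 rankings published for this system intersect in
only four descriptors (BAC, I2y, I2_TP, PL/L1), while the downstream
analyses use a six-descriptor panel (WxH, PL, I2_TP, I2y, PL/L1, BAC).  The
pipeline treats the six-descriptor panel as an explicit config default and
reports both its own top-10 intersection and the configured panel side by
side rather than silently reconciling them.

## Clustering with bootstrap support

Per-cultivar mean vectors are clustered by Ward linkage on Euclidean
distances.  Node stability uses a plain bootstrap (no multiscale
correction): leaf-level rows are resampled with replacement *within
cultivar* (the only resampling unit consistent with clustering cultivar
means while leaving something to resample), means recomputed, the tree
rebuilt, and a reference node counts as reproduced when some replicate
node's leaf set reaches Jaccard similarity ≥ 0.8 with it.  Support is the
percentage over B = 100 replicates; the root is always 100%.  Supports are
therefore exact multiples of 100/B — published values like 56.2% cannot
arise at B = 100 and are reported here as the exact k/B percentage instead.
Trees export to Newick with branch lengths from merge heights and node
labels carrying the support, round-tripping through standard parsers.

## Trichome Poisson model

Trichome lengths bin into 11 published classes.  The printed boundaries
leave gaps (99→100, 332→334, 358→360, 398→412, 438→450 µm); the default
binning extends each class half-open up to the next class's lower bound so
every length in (0, 477] is assignable, with a strict mode that enforces
the literal intervals.  The Poisson support is x = class − 1 (classes 1–11 ↦
x = 0–10); this mapping is forced by the published rates — λ of 0.1–0.3 for
cultivars whose trichomes sit in classes 1–4 requires probability mass at
x = 0.  The MLE is the sample mean of x (verified against a grid-search
argmax of the log-likelihood in tests).

The pairwise likelihood-ratio test refits a common rate on the pooled
histogram (null) against the sum of separate fits (alternative);
LRT = 2·(ℓ_alt − ℓ_null) ≥ 0 is referred to the upper χ² tail with df = 2 by
default, following the source protocol, although the nested models differ by
a single free parameter (df = 1, the statistically standard choice, is a
config knob).  Significance tiers are NS / * / ** / *** at 0.05/0.01/0.001.
Cultivars are finally clustered on (λ, density) with both features min–max
scaled to [0, 1] so a rate of order 1 and a density of order 10–100 per mm²
contribute comparably.

## Synthetic generator

Direct measurements and coordinates are drawn independently per trait from
truncated normals with the published per-cultivar means/SDs (floored at 5%
of the trait mean by rejection; angles additionally capped at 360° for BAC
and 180° for α/β).  Derived descriptors are then computed only through the
morphometry module, so rows are internally consistent by construction; no
trait covariance is imposed beyond what that derivation induces, and that
is the main respect in which synthetic data are easier to classify or
harder to cluster than real leaves — passing tests demonstrate the
correctness of the computations, not field-level effect sizes.

Design counts: 4 five-lobed cultivars × 20 leaves = 80; eleven three-lobed
cultivars at 19 leaves would give 209 against the stated total of 207, so
the last two codes in sorted order (SP, VE) get 18 (deterministic and
config-visible).  Trichome rates use the published values (PO 3.0, FI 0.3,
VE 0.1, PA/PE 1.8) and λ = 1.0 for the ten cultivars with no published rate
(a documented free choice).  Trichome class indices are Poisson draws
rejection-resampled into 0–10 — rejection, not clamping, keeps the MLE
unbiased at small λ — and each length is uniform within its class's printed
bounds, so binning recovers the drawn class exactly.  Per-cultivar sample
sizes follow n = round(lower-surface density × sampled area) with a default
sampled area of 2 mm² (three ESEM tissue pieces of roughly 0.65 mm² imaged
area each; the study does not state its counts).  The density table notes
an internal inconsistency of the source: its text calls VE the lowest
lower-surface density while its table prints FI lower (23.2 vs 48.2 per
mm²); the generator follows the table, so FI is the sparsest cultivar in
synthetic runs.

## Numerical choices and problem sizes

Quantiles: linear interpolation.  Standardization: sample SD.  Tukey p
matrices are symmetrized and clipped to [0, 1] against solver drift; LRT
statistics are clipped at 0 against rounding noise.  PCA uses the
eigendecomposition of the correlation matrix with the sign of each loading
column fixed so its largest-magnitude entry is positive.  Random state: a
single integer seed governs each stage; the bootstrap derives its replicate
stream from one `numpy` Generator.

Default problem sizes, chosen as the package's own test/demo scale: the
full 287-leaf design everywhere; B = 100 bootstrap replicates in the
analysis scripts (smaller in unit tests); n = 20 000 trichome draws for
rate-recovery checks, where the MLE's standard error √(λ/n) ≤ 0.013 makes
the ±0.1 recovery band comfortable.

## Known limitations

- No trait covariance model and no left/right asymmetry (half-leaf
  symmetry is assumed by the measurement protocol).
- Published per-cultivar test statistics (T, p, BF) depend on the
  unavailable raw data; the pipeline reproduces the *procedures* and the
  worked values that are data-independent, not those table entries.
- The qualitative IPGRI descriptors are carried as metadata only; no
  image-based landmarking.
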