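# Methods

`embryochron` implements temporal inference for single-nucleus atlases
collected in overlapping timed windows, together with a synthetic-atlas
generator that plants every quantity the pipeline is supposed to
recover.  This note documents the models, their assumptions, the
defaults, and the choices made where the design was genuinely open.

## The synthetic atlas

**Collection design.**  The default schedule has 11 overlapping windows
covering 0–20 h of embryogenesis: 0–2, 1–3, 2–4 (2-h windows capturing
the rapid early transitions), then 3–7, 5–9, 7–11, 9–13, 11–15, 13–17,
15–19, 16–20 (4-h windows).  Exact boundaries are configurable; a
window's *center hour* is the midpoint and is the only age supervision a
model sees.  Within a window, true ages are uniform; an optional
contamination fraction (default 3% in the 0–2 h window only) draws
"stuck" old embryos uniformly from beyond the window's end, emulating
the over-representation of older embryos, which contain vastly more
nuclei.

**Gene kinetics.**  Each gene belongs to one of four classes with
closed-form mean expression µ(t) at age *t*:

| class | µ(t) | emulates |
|---|---|---|
| maternal | A·e^(−rt) | deposited transcripts decaying after fertilization |
| zygotic | A / (1 + e^(−r(t−t₀))) | switch-like activation at onset t₀ |
| transient | A·e^(−((t−t₀)r)²/2) | pulses of stage-specific expression |
| constant | A | housekeeping background |

Amplitudes A are log-normal; onsets t₀ uniform on a configurable range;
rates r in units of 1/h.  A feature may carry a `lineage_mask`
restricting it to a subtree of the planted lineage (cell-type markers).
Accessibility uses the same functional form with the onset advanced by
`access_lead_h ≥ 0` (floored at age 0): this plants pioneer-factor
behaviour, where a gene's linked regions open before the transcript
rises.  Default lead 0.5 h for 20% of zygotic genes.

**Lineage.**  A planted tree assigns branching cell states to age
epochs; a cell's state is drawn uniformly among the states of its age's
epoch.  Marker genes active in a state's descendant closure make states
separable and ancestrally nested, which is what the cross-window linker
must recover.

**Counts.**  Per cell, the kinetic mean vector is scaled to a target
library size (log-normal spread σ = 0.35) and drawn negative-binomially
(gamma–Poisson, dispersion 0.5; dispersion 0 gives the exact Poisson
limit used by closed-form checks).  The RNA depth target is 399 UMIs per
cell — the sparse regime of combinatorial-indexing RNA data.  The ATAC
depth target preserves the *per-peak* read density of real data (5206
reads over ~110k peaks ≈ 0.05 reads/peak) at the toy peak count;
matching the absolute per-cell read total over a few hundred peaks would
saturate every peak and destroy the binary character of accessibility
data.  chrX read fractions are Normal(0.04, 0.004) for XX cells and
Normal(0.02, 0.004) for XY, truncated to [0, 1] — bimodal and separable
at an arbitrary but realistic scale.

**What the generator does not emulate:** genomic sequence (motif hits
are an input table), read-level effects, doublets, batch effects,
realistic gene–gene covariance beyond shared kinetics, or cell-number
growth over development.  Recovery results on it demonstrate the
pipeline's correctness and statistical behaviour under its stated noise
model, not performance on real sci-RNA/ATAC data.

## Age inference

Profiles are preprocessed with a frozen recipe: per-cell depth
normalization to 10⁴ counts, +1 pseudocount, natural log; ATAC-like
matrices are binarized first.  Candidate features are ranked by
|Pearson r| between the preprocessed value and the training cells'
window centers (zero-variance features excluded; ties by feature id);
the default keeps the strongest 300 on the toy gene panels
(configurable; on genome-scale panels, thousands).

Two regressor families are fit on center-hour targets, with seeded
cross-validation stratified by window:

- **lasso**: L1-penalized linear regression, λ selected on a grid
  (10⁻³…1, 7 points) by 10-fold CV, warm-started along the path;
- **NN**: feedforward network, two hidden layers (h, 64) with
  h ∈ {64, 128}, ReLU, Adam at learning rate {10⁻², 10⁻³}, squared-error
  loss, early stopping on a 10% validation split.  The hyperparameter
  search runs on a window-stratified subsample of ≤ 5000 cells to keep
  the 40 CV fits cheap; the winner is refit on all training cells.

Predictions are clipped to [0, 20] h (ages outside embryogenesis are
meaningless).

**Calibration.**  With overlapping windows, the expected label given a
true age is an average over the windows covering that age, so even a
perfect regressor of E[center | profile] under-ages the last window and
over-ages the first (edge compression; its empirical signature is a
depletion of very early and very late inferred ages).  A calibration
step therefore estimates a smooth correction curve g on 40 age bins by
ridge-regularized least squares (second-difference roughness penalty,
weight 0.3, identity prior) such that per-window means of g(prediction)
match the window centers on the training cells; `predict_age` applies g
automatically.  The penalty weight trades window-mean fidelity against
overfitting the training histogram; 0.3 keeps held-out per-window means
within ±0.5 h on the default atlas while changing overall MSE by < 10%.

**Evaluation.**  MSE against window centers, and *proportion correct*.
The latter is not uniquely defined by interval-level supervision; the
default counts a prediction correct when it falls inside the
originating collection window (bounds inclusive), because window
membership is the only ground truth available on real data.  A
nearest-window-center variant is provided.  Contamination of a window is
the fraction of its cells with predicted age ≥ 4 h; cells predicted
older than 18 h are excluded from windowed downstream analyses (model
edge effects dominate there).  Sex is classified from the chrX read
fraction by a two-component 1-D Gaussian mixture, the higher-mean
component labelled XX; the classifier needs ≥ 2 distinct values and is
invariant to a common shift.

## Fine-time pseudobulk

Cells are assigned to uniform bins of predicted age
(bin = ⌊(age − start)·60/increment⌋, the range end closing into the last
bin).  Per bin, counts are summed over member cells, normalized to 10⁴
per bin total, and log-transformed (+1 pseudocount).  **Empty bins are
missing, not zero** — sparse early collections routinely leave 1-min
bins empty, and treating them as zero would fabricate silencing;
smoothing (centered moving average, default 5 bins) skips missing
values.  Onset is the left edge of the first bin reaching half the
profile's maximum, on the smoothed profile; it is monotone-equivariant,
which is all the ZGA ordering analysis needs.  Temporal k-means clusters
operate on smoothed, per-feature z-scored profiles and are renumbered by
ascending median onset.  Per-gene accessibility aggregates the
normalized pseudobulk of the gene's linked regions (sum before log).

Depth normalization makes all dynamics *relative*: absolute per-gene
trajectories are only interpretable against a roughly stable total
pool.  Real early embryos provide this through dominant maternal
transcripts; targeted ZGA simulations must include such a constant
background pool, or per-bin renormalization inverts the dynamics.

## Lineage graphs

Cells are partitioned into non-overlapping windows of predicted age
(default 2 h up to 18 h, left-closed).  Per window: PCA on log-normalized
counts (RNA) or TF-IDF + truncated SVD on binarized counts (ATAC), a
kNN graph, and Leiden modularity clustering (seeded).  Adjacent windows
are co-embedded by the same reduction on the concatenated cells (30
components; no batch correction — the synthetic data have none).  For
each child-window cell, its k = 30 nearest parent-window cells
(Euclidean, ties broken by ascending cell index) yield per-parent-state
proportions; the edge weight parent → child state is the **median** (not
mean) of those proportions over the child state's cells.  States with
< 20 cells are excluded (medians over fewer cells are unstable).  Per
child state only the maximum-weight incoming edge survives, and only if
strictly > 0.2; edges always point forward in time, so the graph is
acyclic with in-degree ≤ 1 by construction.  k, the embedding
dimensionality, and the minimum state size are explicit stand-in
defaults.

## RNA–ATAC linkage

Gene activity = sum of ATAC reads over peaks overlapping
(gene body) ∪ [TSS − 2 kb, TSS + 2 kb), with TSS at the interval start
on + strands and end − 1 on − strands (0-based half-open throughout).  A
peak overlapping the region by any amount is counted in full: read-level
truncation is not available from a peak-count matrix.  Cluster profiles
(summed, depth-normalized to 10⁴, logged) are decomposed per target row
by NNLS over the other modality's profiles, restricted to shared genes
with nonzero variance; coefficients are rescaled to sum to 1 per target,
making the 0.1 linkage threshold a mixture proportion.  Linkage requires
both directional coefficients > 0.1 (strict); a single-direction mode
exists because the combination rule is genuinely open.  The best partner
of a cluster is the maximum of the combined (mean of both directions)
score.

## TF motif activity

The deviation statistic is a simplified chromVAR: per motif and cluster,
observed = fraction of the cluster's reads in motif-hit peaks,
expected = the same under the all-cluster mean profile,
raw = (obs − exp)/exp, z-scored against 50 random peak sets matched on
mean-accessibility decile (seeded).  Sequence-composition (GC) matching
is deliberately absent — synthetic peaks have no sequence — and the
interface leaves room for a drop-in full implementation.  A motif
hitting every peak has deviation exactly 0 (its background sets are the
full peak universe).

Activator/repressor calls: Pearson (default; Spearman optional)
correlation between a TF's expression and its motif deviation across
≥ 3 linked cluster pairs; positive for activators, negative for
repressors.

Stage/layer nomination: per window with ≥ 4 clusters and ≥ 2 germ
layers, OLS of deviation on [1, expression, expression·1(layer = g)]
across the window's clusters; the interaction coefficient is the
layer-specific activity effect, tested by its t statistic (the OLS and
t-test are computed directly with numpy/scipy for speed over thousands
of 3-parameter fits; agreement with statsmodels is covered by a test).
BH correction is applied **once over all (TF, layer, window) tests**;
significance at adjusted p < 10⁻³.  TFs are displayed when a layer shows
≥ 3 consecutive significant, sign-consistent windows, and the run's
start window is reported as the onset of activity.  Windows with few
clusters are skipped because interaction estimates there are driven by
single outlying clusters.

## Temporal modules (DTW)

Top-n most variable genes (default 2000 on genome-scale data), min-max
scaled to [0, 1] per gene over time bins (constant genes dropped).
DTW uses the classic dynamic program with absolute-difference local cost
and unit match/insert/delete steps; the distance function itself is
unconstrained by default and checked against exhaustive path
enumeration.  For *clustering*, a Sakoe–Chiba band of 10% of the series
length is applied by default: unbounded warping makes DTW nearly blind
to pure time shifts between monotone curves, whereas successive
expression waves differ precisely in timing; the band keeps warping
local so onset differences still cost.  Pairwise distances feed
average-linkage hierarchical clustering cut at k = 4; modules are
renumbered by ascending median onset.  The expression/activity lag is
the cross-correlation argmax over integer shifts of the two min-max
scaled curves on 100 equal-count age bins (positive = accessibility
precedes expression); half-max-difference is available as an
alternative via the onset estimator.  A peak correlation < 0.5 flags the
lag as low-confidence.

## Validation experiments and problem sizes

`embryochron.benchmarks` runs each stage end to end on planted truth;
`scripts/acceptance.py` reports the numbers and the test suite asserts
them.  Sizes were chosen once as the smallest at which the statistics
are stable: default atlas 11 × 1820 ≈ 20k RNA cells / 500 genes;
nonlinear comparison 11 × 900 cells / 300 switch-like genes; ZGA 15k RNA
+ 12k ATAC cells over 0–3 h with 50 zygotic genes; lineage 4 × 600 cells
over a 12-state tree; NNLS 10 matched pairs × 300 genes; TF model 9
windows × 3 layers × 4 clusters with 5 + 5 + 10 TFs and 100 null
replicates; DTW 4 × 200 genes × 60 bins.  The TF scenario uses 4
clusters per germ layer because the per-window interaction test with 3
per layer leaves only 6 residual degrees of freedom and, with the narrow
within-layer expression spread, is structurally underpowered — real
windows carry tens of clusters.

## Known limitations

- The age model assumes profiles are informative about age throughout
  the range; in windows where dynamics plateau, predictions revert to
  the window mean and calibration cannot restore per-cell accuracy.
- The calibration curve matches window *means*; it does not correct
  per-cell conditional bias, and it is estimated on training data, so
  extreme distribution shift between fit and use would degrade it.
- Median-of-proportions edge weights are insensitive to minority
  ancestry: a child state with < 50% of cells near a second parent will
  never show that parent.  This matches the single-parent DAG contract
  but cannot represent convergence.
- The deviation background matches accessibility only; on real data a
  GC-matched background is preferable.
- DTW module recovery depends on the band: with unconstrained warping,
  onset-shifted monotone curves collapse into one cluster.
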