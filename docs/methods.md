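# Methods

`isletflow` re-implements, at desk scale, an analysis pipeline for studying
how a rare immature islet β-cell subpopulation expands and adapts into a
pathogenic hormone-expressing (CCK-high) state along an obesity time course:
trajectory-based cell-of-origin tracing with enrichment scoring, archetypal
analysis of β-cell states, Granger-causality regulatory inference on gene
trends, cross-dataset integration audits, and islet–lesion proximity
statistics. Every stage runs on synthetic data generated in-package, so the
whole analysis is testable without external sequencing data.

## The synthetic population

`synth.gen_population` draws cells for T ordered conditions (default 3:
lean → moderately obese → severely obese, 2,000 cells each, 200 genes).
Each cell's latent position is a convex combination of k archetype vertices
(default 4) in a d-dimensional latent space (default 6), with Dirichlet
commitment weights; condition-specific concentrations shift mass toward one
designated "CCK" vertex, whose occupancy grows from the `origin_fraction`
(5%) at the first condition to 50% at the last. The rare origin
subpopulation is the set of first-condition cells drawn from the
CCK-vertex-concentrated Dirichlet; these cells carry a planted proliferation
advantage in the sense that the population at their vertex grows, which is
what unbalanced optimal transport should detect. Counts are
negative-binomial in the mean–dispersion parameterization
(var = μ + μ²/θ, θ = 10) with a log-linear map from latent position to
per-gene mean. Named genes are planted with loadings aligned to vertices:
"Cck" (and the default TF "Jun") along the CCK vertex, "Ins1"/"Ins2" along
the mature vertex, so Cck rises and insulin falls across conditions in
expectation. A configurable block of `mt-` genes receives a 12× rate boost
in 3% of cells to exercise the mitochondrial filter. A single global seed
spawns independent `SeedSequence` sub-streams per operation; identical seeds
give bit-identical outputs.

What the generator does **not** emulate: real sequencing depth (library
sizes are hundreds, not thousands), doublets, ambient RNA, batch-specific
gene detection dropout, or realistic gene–gene correlation beyond the
low-rank latent structure. Passing tests therefore demonstrate that the
algorithms recover structure they are designed to detect, not that they are
robust to every artifact of real data.

`gen_trend_pair` provides the regulatory-harness signal: a smoothed,
standardized random walk as the TF trend and `target[t] = effect ·
tf[t − lag] + ε` as the target. `gen_batch_pair` creates a second "dataset"
by an affine perturbation (small rotation + translation, scaled by
`batch_shift`) of the latent positions followed by independent NB
re-sampling. `gen_spatial_scene` samples islet discs/spheres (radii
30–120 µm) uniformly in a 6,000 µm region and places lesion centers either
uniformly (`proximity_bias = 0`) or at 100 µm from a random islet center;
the region size is chosen so the unbiased proximal fraction sits well below
saturation (roughly 15–20% of lesions), leaving the biased/unbiased contrast
detectable.

## Preprocessing

QC follows the standard islet scRNA-seq recipe with a fixed order: genes
expressed in fewer than 15 cells are dropped, then cells with library size
above 15,000, then cells with more than 12.5% of counts in mitochondrial
genes (the percentage is computed on post-gene-filter counts; the threshold
is interpreted as a percentage of counts, the conventional QC meaning).
Cells are L1-normalized to the median library size and square-root
transformed. Highly variable genes use the binned-dispersion dialect:
dispersion = var/mean of the back-transformed values, z-scored within 20
mean-expression bins, flagged when z > 0.5 and the log-scale mean is inside
(0.0125, 3). Denoising is a kNN-graph diffusion: adaptive Gaussian kernel
(bandwidth = distance to the k-th neighbor, k = 15), symmetrized,
row-normalized, applied t = 3 steps. The embedding is mean-centered PCA on
the smoothed matrix with the very highly expressed hormone genes (Ins1,
Ins2, Sst, Ppy, Gcg) excluded from the fit; the decoder
(`coords @ loadings + mean`) is exactly linear, excluded genes decode to
their mean, and component signs are fixed by making each loading vector's
largest-magnitude entry positive. k-means clustering (k = 20) reports the
best-inertia labeling of five runs plus the mean pairwise adjusted Rand
index as a stability statistic. Differential expression is a two-sided
Wilcoxon rank-sum per gene with Benjamini–Hochberg control; the significance
call requires q < 0.05 **and** log2 fold-change > 0 (up-regulation only).

## Trajectory engine

The neural-ODE trajectory model of the original toolchain is replaced by a
deterministic stand-in: pairwise **unbalanced entropic optimal transport**
between consecutive conditions plus displacement interpolation. This is a
stand-in, not a re-implementation — it preserves the three properties the
downstream analyses consume (distribution matching between timepoints,
least-action straight-line paths under the squared-Euclidean cost, and
proliferation via relaxed source marginals) at a scale where every coupling
can be checked against a dense oracle.

Sinkhorn details: squared Euclidean cost; ε defaults to 0.05 × the median
pairwise squared distance in the first condition (scale-free); ε-scaling
warm starts (factor 4 per stage) with log-stabilized scaling iterations and
potential absorption; convergence at marginal violation < 1e-9 (L1 row
violation in balanced mode; max log-scaling movement in unbalanced mode) or
10⁴ iterations, which raises. Unbalanced mode fixes the target marginal and
relaxes the source with a KL penalty of strength α (default 2, the
proliferation-regularization setting), giving the scaling exponent
α/(α + ε). The growth rate of source cell i is `g_i = n_source ·
(row mass of the converged coupling)`; with target mass scaled by relative
population size, mean growth equals the population-size ratio, and g > 1
marks proliferation. Rank stability of g across α ∈ [0.01, 10] is exposed
as `growth_robustness` (pairwise Spearman ρ).

Paths: terminal cells (e.g. the top-5% Cck expressors at the last
condition) are traced backward by sampling an ancestor per condition from
the normalized incoming coupling column; each path is the piecewise-linear
interpolation through the matched cell coordinates on a uniform 101-point
s ∈ [0, 1] grid, so a lag of 10 steps is exactly 10% of the trajectory.
Two runs (differing only in the sampling stream) are averaged, matching the
two-run protocol. Gene trends decode every path point through the linear
decoder, clip negatives at zero (clipped fraction reported), and average
over paths within run, then over runs.

For pipeline runs each condition is subsampled to at most 1,000 cells
before coupling fitting; at the default ε the couplings are near the
unregularized limit and full-size fits converge slowly without changing the
downstream calls. The subsample size is a desk-scale problem-size choice,
recorded in the manifest.

## Cell-of-origin and enrichment

A trajectory's cell-of-origin is its s = 0 position. Origins are labeled by
the Euclidean nearest reference cell at the first condition (ties broken
toward the lowest reference index — a fixed convention shared by all 1-NN
transfers in the package). The enrichment score of class c is
`E(c) = p_query(c) / p_reference(c)`; classes absent from the query get
E = 0, and a query class absent from the reference is an error. The
weighted-mean identity Σ p_ref(c)·E(c) = 1 holds exactly. Per-segment
archetype enrichment splits the grid into per-condition intervals (thirds
for T = 3; configurable breakpoints), labels trajectory points by the
nearest assigned cell of that condition, and scores each segment against
the pooled archetype distribution; runs are reported separately and jointly.

## Archetypal analysis

The latent-space autoencoder of the published tool is replaced by convex
archetypal (principal-convex-hull) factorization in the PCA space:
X ≈ A·Z with the commitment rows of A on the probability simplex and the
archetypes Z constrained to the convex hull of the data. The A-block is
solved by FISTA with function-value restart (best-iterate tracking, exact
Lipschitz step); the Z-block takes the unconstrained optimum projected onto
the data hull (an exact sparse projection via penalty-NNLS), accepted only
when it lowers the loss, followed by guaranteed-descent projected-gradient
polish. The loss trace is non-increasing by construction. Initialization is
furthest-point sampling whose first pick is the point farthest from the
centroid; additional restarts use random first picks. Convergence: relative
loss change < 1e-8 or 500 alternations; best of 5 restarts by loss (fewer,
shallower fits inside the k-selection sweep, where only the MSE curve shape
matters).

Archetype count: per repeat (3), the training set is a density-balanced 80%
subsample (inclusion probability ∝ distance to the 15th neighbor, i.e.
inverse density, so simplex corners are preferentially kept), each
k ∈ 2..10 is fit with a warm start from the previous k (previous archetypes
plus the worst-reconstructed point, which makes train MSE non-increasing in
k), and held-out cells are projected onto the fitted simplex for their MSE.
The elbow is the k maximizing the second difference of the **log** mean-MSE
curve; the log scale makes the drop onto the noise floor dominate
regardless of absolute magnitudes (the linear-scale rule systematically
picks the first big drop and under-selects for larger planted k). A
`weak_elbow` flag (with warning) marks curves whose winning curvature is
small relative to the curve's range.

Commitment calls use the strict rule: a cell is committed to archetype j
iff A[i, j] > 0.5 (a tie at exactly 0.5 stays uncommitted). Cross-dataset
assignment is 1-NN label transfer. Archetype similarity between two models
decodes both archetype sets to the shared gene space, z-scores per gene
over the union, and reports pairwise cosine similarity with greedy
mutual-best grouping above a cutoff — a documented choice; the original
similarity formula is not public.

## Integration audit

The cross-dataset mapper is an entropic-OT **barycentric projection**
(mapped point = coupling-weighted mean of reference points), a stand-in for
the adversarial mapper whose audit metrics are the point of this module.
Metrics: the modified batch ASW — per cell type, mean of `1 − |silhouette|`
computed on batch labels (Euclidean), averaged over cell types; 1 = perfect
batch overlap, 0 = separation — and global distortion, the mean per-cell
cosine similarity between pre- and post-mapping features. The accept gate
passes iff batch ASW > 0.6 and distortion ∈ [0.2, 0.6] (bounds
configurable, defaults as printed in the protocol). The OT mapper typically
lands *above* the distortion band because barycentric projection preserves
cells almost perfectly; the gate reports this honestly rather than being
re-tuned to the stand-in.

Sample-level comparison: exact pairwise EMD (Wasserstein-1, Euclidean
ground cost, uniform weights) between condition point clouds, subsampled to
≤ 500 points per cloud; equal sizes reduce to an assignment problem
(Hungarian), unequal sizes solve the transport LP (HiGHS). The Fiedler
vector of the Gaussian-affinity graph Laplacian (bandwidth = median
off-diagonal distance unless given) provides a scalar ordering of samples
along the main axis of variation; its sign is anchored to a user statistic.

## Granger-causality network

For each TF–gene pair the restricted model regresses the target trend on
its own L lags (plus intercept) and the unrestricted model adds L lags of
the TF (L = 10 = 10% of the grid). Two chi-square variants are provided,
because no single statistic can be both faithful to score-threshold network
pruning and calibrated as a nominal-α test on ~100-point series:

* `ssr` (default): `n·(RSS_r − RSS_u)/RSS_u ~ χ²(L)` — the statistic
  standard Granger tooling computes, against which the −log p > 25 network
  threshold is calibrated. As an α-level test on G = 101, L = 10 series it
  is anti-conservative (≈19% rejection of white-noise nulls at α = 0.05);
  white-noise nulls nonetheless essentially never clear −log p > 25.
* `lr`: the degrees-of-freedom-corrected likelihood ratio
  `(n − 2L − 1)·log(RSS_r/RSS_u) ~ χ²(L)`, calibrated (≈3.5% at α = 0.05 on
  the same grid). Use it when p-values are interpreted at a nominal level.

The signed score is `sign(Pearson corr of the two full trends) · (−log p)`
(natural log; p floored at 1e-300 with the floor flagged). Degenerate
(zero-variance) trends return score 0 with a flag rather than raising;
rank-deficient lag matrices fall back to ridge (λ = 1e-8), flagged.
Network construction applies three rules in order: keep the top 100 TFs by
max |score| over all genes; keep only pairs present in the prior edge list
(TRRUST-dialect TSV); keep edges with −log p > 25. The "increasing"
subnetwork keeps edges whose TF and target both fall in the increasing
trend cluster and flags the largest weakly-connected component.

## Trend clusters and gene-set statistics

Gene trends are z-scored over the grid and split by k-means with k = 2
(best of 10 restarts); each cluster's direction is the sign of the Spearman
correlation of its centroid with grid time, and the public cluster ids are
stable (1 = increasing, 2 = decreasing). Over-representation uses the
one-sided hypergeometric tail with BH control across sets (retained at
q < 0.05); the universe defaults to the tested (HVG) genes, and gene-set
collections are user-supplied GMT-like files. `set_overlap_test` gives the
hypergeometric p for the overlap of two gene-set id lists from a catalogue
of stated size (the catalogue size is a required input).

## Spatial statistics

Islets are discs/spheres (center + radius, µm); lesions are boundary/
surface point sets. Two distance rules are deliberately kept distinct: the
2D proximity call (a lesion is proximal iff any boundary point lies
strictly within 400 µm of the center of an islet with diameter strictly
over 100 µm, islet filtering applied before distance ranking), and
surface-to-surface shortest distances (center distance minus radius,
floored at zero) reported in both directions for 3D reconstructions.
Group comparisons use the two-sample KS test on the empirical CDFs plus the
two-sided Mann–Whitney rank-sum; proximal/distant condition tables use the
two-sided Fisher exact test (zero-margin tables return p = 1 with a
warning).

## Pipeline and reproducibility

`pipeline.run(RunConfig())` executes the stages in dependency order with
the standard defaults (gene filter 15 cells, library cap 15,000, mito cap
12.5%, k-means 20, archetype k-range 2–10 × 3 repeats × 80% subsample,
commitment 0.5, two 101-point trajectory runs, lag 10, top 100 TFs,
−log p > 25, proximity 400 µm / >100 µm). The manifest records a config
hash, per-stage wall-clock, headline numbers, and SHA-256 checksums of the
key arrays; identical seeds reproduce identical checksums. Desk-scale
problem sizes used by the default run: 3 × 2,000 cells × 200 genes,
couplings on 1,000-cell condition subsamples, archetype sweeps on 600-cell
subsamples, EMD on 300-point subsamples. The full default run takes a few
minutes on one CPU.

## Known limitations

* The OT trajectory engine and the archetypal factorization are stand-ins:
  they preserve the downstream contracts (couplings, growth rates, simplex
  commitments, decoded trends) but make no claim of reproducing the
  published neural models' coordinates.
* Granger scores on decoded trends inherit the strong autocorrelation of
  smooth trajectories; the type-I calibration statements hold for
  white-noise nulls at the stated grid and lag, not for arbitrary smooth
  null trends.
* The proximity baseline expectation ignores region-edge effects and islet
  overlap; tests use generous Monte-Carlo tolerances accordingly.
* Exact EMD is O(n³)-ish in the subsample size; the 500-point default keeps
  the LP tractable and adds subsampling noise that the seeded subsample
  makes reproducible.
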