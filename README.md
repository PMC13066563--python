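# isletflow

Trajectory, archetype and regulatory-network analysis of islet β-cell state
transitions, with a built-in synthetic-data harness.

In obesity, a rare immature β-cell subpopulation can expand and adapt into
a pathogenic hormone-expressing (CCK-high) state. Testing the computational
story behind that claim requires several coupled analyses: inferring
per-cell trajectories across an ordered time course, tracing terminal cells
back to their **cells-of-origin**, describing β-cell heterogeneity as
mixtures of **archetypes** (extreme states), inferring lagged TF→target
regulation from gene trends with **Granger causality**, auditing
cross-dataset mappings, and quantifying islet–lesion **spatial proximity**.
`isletflow` implements this pipeline end-to-end at desk scale, for
computational biologists who want every step checkable against oracles and
planted ground truth.

## The core models

* **Trajectories** — unbalanced entropic optimal transport between
  consecutive conditions: the coupling π minimizes
  ⟨π, C⟩ + ε·KL(π | a⊗b) + α·KL(π1 | a) with the target marginal fixed,
  squared-Euclidean cost and growth regularization α = 2. Per-cell growth
  g_i = n·(row mass of π); g > 1 means proliferation. Terminal cells are
  traced backward through the couplings and linearly interpolated on a
  101-point grid; trends are decoded through an exactly linear PCA decoder
  and averaged over two runs.
* **Cell-of-origin enrichment** — origins (s = 0 positions) are labeled by
  the nearest first-condition cell; the enrichment of class c is
  E(c) = p_query(c)/p_reference(c), with E > 1 meaning over-representation
  among origins.
* **Archetypes** — principal-convex-hull factorization X ≈ A·Z with
  commitment rows of A on the probability simplex and archetypes Z inside
  the data hull; the archetype count is the held-out reconstruction-MSE
  elbow over k = 2..10; a cell is *committed* when one weight exceeds 0.5.
* **Granger regulatory network** — per TF→gene pair, an L = 10-lag
  two-regression chi-square test on the decoded trends, signed score
  sign(corr)·(−log p); the network keeps the top-100 TFs, prunes to
  prior-supported pairs, thresholds at −log p > 25, and extracts the
  increasing–increasing subnetwork's largest component.
* **Integration audit** — modified batch ASW (mean of 1 − |silhouette| on
  batch labels per cell type; 1 = mixed), global distortion (mean per-cell
  cosine pre vs post mapping), the accept gate (ASW > 0.6, distortion in
  [0.2, 0.6]), exact pairwise EMD between samples and Fiedler-vector sample
  ordering.
* **Spatial statistics** — lesions are islet-proximal when a boundary point
  lies strictly within 400 µm of the center of an islet with diameter
  > 100 µm; groups are compared with Fisher exact, Mann–Whitney and
  two-sample KS tests.

A synthetic generator (`isletflow.synth`) produces every input the pipeline
consumes — a 3-condition population with planted archetype mixtures, a rare
origin subpopulation, reciprocal hormone-gene trends, lagged TF→target
pairs, batch pairs and toy islet/lesion geometries — so all downstream
stages are testable without external data. See `docs/methods.md` for the
full model descriptions and design choices.

## Worked example

`examples/03_trajectories_and_origins.py` generates a 3 × 600-cell
population, fits the OT couplings, traces the high-Cck terminal cells
backward and scores their origins:

```
epsilon = 0.0529; mean growth rate = 0.981
 class  p_query  p_reference  enrichment
     0      0.0        0.811         0.0
     2      0.0        0.082         0.0
     1      0.0        0.060         0.0
     3      1.0        0.048        21.0
top origin class: archetype 3 (planted origin archetype: 3)
```

Archetype 3 is the planted rare origin state: it makes up only 4.8% of the
first-condition reference cells but 100% of the traced cells-of-origin —
an enrichment of 21 — while the dominant mature archetype (81% of the
reference) contributes none. This is the in-silico lineage-tracing readout:
the terminal CCK-high state descends from the rare immature subpopulation,
not from the bulk.

The other scripts in `examples/` each demonstrate one capability
(generation, QC/embedding, archetype-count selection, Granger networks,
integration audit, spatial statistics, the full pipeline) and print a short
interpretation with their numbers.

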