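"""Trace high-Cck terminal cells back to their cells-of-origin.

Unbalanced entropic OT couples consecutive conditions (growth regularization
alpha = 2); terminal cells are traced backward through the couplings, and
the origin cells' archetype distribution is scored against the reference
distribution (the enrichment score: > 1 means over-represented).
"""

import numpy as np

import isletflow as ifl
from isletflow import origin as om, preprocess as pp, synth, trajectory as tj

cfg = synth.SynthConfig(n_cells_per_condition=600, n_genes=120, seed=5)
counts, truth = synth.gen_population(cfg)
filtered, _ = pp.qc_filter(counts)
keep = counts.cell_meta.index.get_indexer(filtered.cell_meta.index)
emb = pp.embed_pca(pp.smooth(pp.normalize(filtered)), d=8)

cond = filtered.cell_meta["condition"].to_numpy()
arch = truth.commitment[keep].argmax(axis=1)  # ground-truth archetype calls
coords = [emb.coords[cond == c] for c in (1, 2, 3)]
labels = [arch[cond == c] for c in (1, 2, 3)]

couplings, growth = tj.fit_couplings(coords, alpha=2.0, mode="unbalanced")
print(f"epsilon = {couplings.epsilon:.4f}; mean growth rate = {growth.mean():.3f}")

planted = cfg.n_archetypes - 1  # the expanding Cck archetype
terminal = labels[2] == planted
paths = tj.sample_paths(couplings, terminal, G=101, runs=2, seed=5)
origins = om.trace_origins(paths, coords[0], labels[0])
enrichment = om.enrichment_score(origins["label"], labels[0])
print(enrichment.table.round(3).to_string(index=False))
print(f"top origin class: archetype {enrichment.top_class()} "
      f"(planted origin archetype: {planted})")
# An enrichment far above 1 for the planted archetype means the rare
# immature subpopulation is the inferred cell-of-origin of the terminal
# high-Cck state.
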