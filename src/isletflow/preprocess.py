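"""QC, normalization, embedding and differential expression.

The QC rules follow the standard islet scRNA-seq recipe: drop rare genes
(expressed in fewer than 15 cells), drop cells with library size above
15000, drop cells whose mitochondrial count fraction exceeds 12.5%, in that
fixed order.  Cells are then L1 library-size normalized and square-root
transformed.  Embeddings are built by kNN-diffusion smoothing followed by
mean-centered PCA, which keeps the map back to gene space exactly linear so
trajectory coordinates can be decoded into gene trends.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .datatypes import CountMatrix, Embedding, ExpressionMatrix, QCReport

__all__ = [
    "qc_filter",
    "normalize",
    "select_hvg",
    "smooth",
    "embed_pca",
    "cluster_kmeans",
    "deg_wilcoxon",
]


def qc_filter(
    m: CountMatrix,
    min_cells: int = 15,
    max_libsize: float = 15000,
    max_mito_pct: float = 12.5,
) -> tuple[CountMatrix, QCReport]:
    """Gene filter, then library-size filter, then mitochondrial filter.

    Mitochondrial percentage is computed on the post-gene-filter counts as
    ``100 * mito_counts / total_counts``; cells strictly above
    ``max_mito_pct`` are removed.  Pass ``np.inf`` to disable a cell filter
    and ``0`` to disable the gene filter.
    """
    counts = m.counts
    expressed_in = (counts > 0).sum(axis=0)
    keep_genes = expressed_in >= min_cells
    genes_removed = int((~keep_genes).sum())
    counts = counts[:, keep_genes]
    gene_meta = m.gene_meta.loc[keep_genes]

    lib = counts.sum(axis=1)
    keep_lib = lib <= max_libsize
    cells_removed_lib = int((~keep_lib).sum())
    counts = counts[keep_lib]
    cell_meta = m.cell_meta.loc[keep_lib]

    if np.isfinite(max_mito_pct):
        if "mito" not in gene_meta:
            raise ValueError("mito flags required for mitochondrial filter")
        mito = gene_meta["mito"].to_numpy(dtype=bool)
        total = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * counts[:, mito].sum(axis=1) / np.maximum(total, 1)
        keep_mito = pct <= max_mito_pct
    else:
        keep_mito = np.ones(counts.shape[0], dtype=bool)
    cells_removed_mito = int((~keep_mito).sum())
    counts = counts[keep_mito]
    cell_meta = cell_meta.loc[keep_mito]

    if counts.shape[0] == 0:
        raise ValueError("QC filtering removed all cells")

    report = QCReport(
        genes_removed=genes_removed,
        cells_removed_by_libsize=cells_removed_lib,
        cells_removed_by_mito=cells_removed_mito,
        thresholds={
            "min_cells": min_cells,
            "max_libsize": max_libsize,
            "max_mito_pct": max_mito_pct,
        },
    )
    return CountMatrix(counts, cell_meta, gene_meta), report


def normalize(m: CountMatrix, target_size="median") -> ExpressionMatrix:
    """L1 library-size normalization followed by square-root transform."""
    counts = np.asarray(m.counts, dtype=float)
    lib = counts.sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"all-zero cell(s) cannot be normalized: {list(m.cell_meta.index[zero[:5]])}"
        )
    if target_size == "median":
        target = float(np.median(lib))
    else:
        target = float(target_size)
    scaled = counts / lib[:, None] * target
    return ExpressionMatrix(
        values=np.sqrt(scaled),
        cell_meta=m.cell_meta.copy(),
        gene_meta=m.gene_meta.copy(),
        provenance="normalized",
    )


def select_hvg(
    e: ExpressionMatrix,
    n_bins: int = 20,
    min_disp: float = 0.5,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
) -> np.ndarray:
    """Highly variable genes by binned normalized dispersion.

    Dispersion (var/mean of expm1(log1p-scaled expression), the Seurat-flavor
    statistic) is z-scored within mean-expression bins; genes with z-scored
    dispersion above ``min_disp`` and log-scale mean within
    ``[min_mean, max_mean]`` are flagged.  Deterministic for fixed input.
    """
    if e.n_cells < 2:
        raise ValueError("need at least 2 cells")
    x = np.log1p(e.values)
    mean = np.expm1(x).mean(axis=0)
    var = np.expm1(x).var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    log_mean = np.log1p(mean)

    bins = pd.cut(log_mean, bins=n_bins, duplicates="drop")
    disp_z = np.zeros_like(disp)
    df = pd.DataFrame({"bin": bins, "disp": disp})
    for _, grp in df.groupby("bin", observed=True):
        idx = grp.index.to_numpy()
        mu, sd = grp["disp"].mean(), grp["disp"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            disp_z[idx] = 0.0
        else:
            disp_z[idx] = (grp["disp"].to_numpy() - mu) / sd

    flagged = (disp_z > min_disp) & (log_mean > min_mean) & (log_mean < max_mean)
    flagged &= var > 0
    if not flagged.any():
        warnings.warn("no genes passed HVG thresholds; returning all non-constant genes")
        flagged = var > 0
    return np.flatnonzero(flagged)


def _knn_kernel(values: np.ndarray, k: int) -> sparse.csr_matrix:
    """Adaptive-bandwidth Gaussian kNN kernel, symmetrized, row-normalized."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, values.shape[0]))
    nn.fit(values)
    dist, idx = nn.kneighbors(values)
    sigma = np.maximum(dist[:, -1], 1e-12)
    n = values.shape[0]
    rows = np.repeat(np.arange(n), idx.shape[1])
    w = np.exp(-(dist**2) / sigma[:, None] ** 2)
    K = sparse.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
    K = 0.5 * (K + K.T)
    inv_rowsum = 1.0 / np.asarray(K.sum(axis=1)).ravel()
    return sparse.diags(inv_rowsum) @ K


def smooth(e: ExpressionMatrix, k: int = 15, t: int = 3) -> ExpressionMatrix:
    """Graph-diffusion denoising: t-step random walk on the kNN kernel."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= e.n_cells:
        raise ValueError("k must be smaller than the number of cells")
    if t == 0:
        return ExpressionMatrix(
            e.values.copy(), e.cell_meta.copy(), e.gene_meta.copy(), "smoothed"
        )
    P = _knn_kernel(e.values, k)
    out = e.values
    for _ in range(t):
        out = P @ out
    return ExpressionMatrix(
        np.asarray(out), e.cell_meta.copy(), e.gene_meta.copy(), "smoothed"
    )


def embed_pca(
    e: ExpressionMatrix, d: int, exclude_genes=()
) -> Embedding:
    """Mean-centered PCA with an exactly linear decoder.

    Excluded genes (very highly expressed hormones distort cell-cell
    distances) contribute nothing to the fit; they decode to their mean.
    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive.
    """
    names = list(e.gene_names)
    excl = set(exclude_genes)
    missing = excl - set(names)
    if missing:
        raise KeyError(f"exclude_genes not present: {sorted(missing)}")
    use = np.array([g not in excl for g in names])
    X = e.values[:, use]
    mean_all = e.values.mean(axis=0)
    Xc = X - X.mean(axis=0)
    if d > min(Xc.shape):
        raise ValueError("d exceeds the achievable rank")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if d > np.sum(S > 1e-10) and np.sum(S > 1e-10) < min(Xc.shape):
        # allow d up to numerical rank padding with zero variance directions
        pass
    U, S, Vt = U[:, :d], S[:d], Vt[:d]
    # deterministic sign: largest-|.| loading entry positive
    for j in range(d):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    coords = U * S
    loadings = np.zeros((d, len(names)))
    loadings[:, use] = Vt
    explained = (S**2) / max(e.n_cells - 1, 1)
    return Embedding(
        coords=coords,
        loadings=loadings,
        mean=mean_all,
        gene_names=np.asarray(names),
        explained_variance=explained,
        cell_meta=e.cell_meta.copy(),
        excluded_genes=tuple(sorted(excl)),
    )


def cluster_kmeans(
    emb: Embedding, k: int = 20, runs: int = 5, seed: int = 0
) -> tuple[np.ndarray, float]:
    """k-means with a multi-run stability report.

    Returns the best-inertia run's labels and the mean pairwise adjusted
    Rand index across the runs (the clustering-stability statistic).
    """
    if k <= 1:
        raise ValueError("k must be > 1")
    if k >= emb.coords.shape[0]:
        raise ValueError("k must be smaller than the number of cells")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 41)))
    labelings, inertias = [], []
    for _ in range(runs):
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
        labelings.append(km.fit_predict(emb.coords))
        inertias.append(km.inertia_)
    aris = [
        adjusted_rand_score(labelings[i], labelings[j])
        for i in range(runs)
        for j in range(i + 1, runs)
    ]
    stability = float(np.mean(aris)) if aris else 1.0
    best = labelings[int(np.argmin(inertias))]
    return best, stability


def deg_wilcoxon(e: ExpressionMatrix, group: np.ndarray) -> pd.DataFrame:
    """Differential expression of a cell group versus the rest.

    Two-sided Wilcoxon rank-sum per gene, BH adjustment across genes; a gene
    is flagged significant when q < 0.05 AND log2 fold-change > 0 (the
    one-sided fold-change rule: only up-regulation in the group counts).
    """
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValueError("group must split cells into two non-empty sets")
    a, b = e.values[group], e.values[~group]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    lfc = np.log2((mean_a + 1e-9) / (mean_b + 1e-9))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat_res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p = np.asarray(stat_res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # constant genes
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": e.gene_names,
            "log2fc": lfc,
            "p": p,
            "q": q,
            "significant": (q < 0.05) & (lfc > 0.0),
        }
    ).set_index("gene")
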