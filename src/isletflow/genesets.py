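"""Trend clustering and hypergeometric gene-set statistics.

Gene trends along the trajectory grid are z-scored and split into exactly
two k-means clusters whose direction labels (increasing / decreasing) come
from the Spearman correlation of each cluster centroid with grid time.
Over-representation of gene sets is tested with the one-sided
hypergeometric tail and Benjamini-Hochberg control across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .trajectory import GeneTrend

__all__ = [
    "TrendClusters",
    "cluster_trends",
    "hypergeom_enrich",
    "set_overlap_test",
    "read_gmt",
]


@dataclass
class TrendClusters:
    labels: pd.Series  # gene -> cluster id in {1, 2}
    direction: dict  # cluster id -> "increasing" | "decreasing"
    scaled_trends: np.ndarray  # (n_genes, G) z-scored trends

    def gene_direction(self) -> dict:
        return {g: self.direction[c] for g, c in self.labels.items()}


def cluster_trends(
    trends: GeneTrend, hvg=None, seed: int = 0
) -> TrendClusters:
    """Two-way k-means split of z-scored gene trends.

    Cluster direction is the sign of the Spearman correlation of its
    centroid with the grid coordinate; ties between clusters of the same
    sign are broken by correlation magnitude (the stronger one keeps its
    sign, the other gets the opposite label).
    """
    genes = list(trends.genes) if hvg is None else [g for g in trends.genes if g in set(hvg)]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    idx = [list(trends.genes).index(g) for g in genes]
    M = trends.values[idx]
    sd = M.std(axis=1)
    if np.all(sd == 0):
        raise ValueError("all trends are constant; nothing to cluster")
    mu = M.mean(axis=1, keepdims=True)
    Z = (M - mu) / np.where(sd > 0, sd, 1.0)[:, None]
    km = KMeans(n_clusters=2, n_init=10, random_state=seed & 0x7FFFFFFF)
    raw = km.fit_predict(Z)
    s = trends.s_grid
    rho = [stats.spearmanr(km.cluster_centers_[c], s).statistic for c in range(2)]
    rho = [0.0 if not np.isfinite(r) else r for r in rho]
    if rho[0] == rho[1]:
        direction_raw = {0: "increasing", 1: "decreasing"}
    else:
        order = np.argsort(rho)  # ascending
        direction_raw = {int(order[1]): "increasing", int(order[0]): "decreasing"}
    # stable public ids: cluster 1 = increasing, cluster 2 = decreasing
    remap = {c: (1 if direction_raw[c] == "increasing" else 2) for c in (0, 1)}
    labels = pd.Series([remap[c] for c in raw], index=genes, name="cluster")
    return TrendClusters(
        labels=labels,
        direction={1: "increasing", 2: "decreasing"},
        scaled_trends=Z,
    )


def _hyper_p(overlap: int, set_size: int, query_size: int, universe: int) -> float:
    """One-sided upper-tail hypergeometric probability of the overlap."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query_size))


def hypergeom_enrich(query, collections: dict, universe) -> pd.DataFrame:
    """Over-representation of each gene set in the query, BH-adjusted.

    ``collections`` maps set id -> iterable of genes; sets are intersected
    with the universe before testing and the query must be a subset of the
    universe.  Retained = q < 0.05.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for set_id, genes in collections.items():
        gs = set(genes) & universe
        overlap = len(query & gs)
        p = _hyper_p(overlap, len(gs), len(query), len(universe))
        rows.append(
            {
                "set_id": set_id,
                "overlap": overlap,
                "set_size": len(gs),
                "query_size": len(query),
                "universe_size": len(universe),
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["retained"] = df["q"] < 0.05
    return df.set_index("set_id")


def set_overlap_test(sets_a, sets_b, catalogue_size: int) -> float:
    """Hypergeometric p for the overlap of two id lists from one catalogue."""
    a, b = set(sets_a), set(sets_b)
    overlap = len(a & b)
    if overlap > min(len(a), len(b)):
        raise ValueError("inconsistent input: overlap exceeds a list size")
    if max(len(a), len(b)) > catalogue_size:
        raise ValueError("list larger than the catalogue")
    return _hyper_p(overlap, len(a), len(b), catalogue_size)


def read_gmt(path) -> dict:
    """GMT-like TSV: set_id <tab> description <tab> gene1 <tab> gene2 ..."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out
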