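"""Core in-memory containers shared across the pipeline.

The pipeline operates on integer count matrices with per-cell condition /
batch annotations, square-root normalized expression matrices, and invertible
linear (PCA) embeddings whose decoder maps trajectory coordinates back to
smoothed gene space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "Embedding",
    "QCReport",
    "SpatialScene",
]


@dataclass
class CountMatrix:
    """Cell x gene integer counts with cell and gene annotations.

    ``cell_meta`` must carry a ``condition`` column (ordinal, contiguous from
    1) and a ``batch`` column; an optional ``label`` column holds cell-type
    annotations.  ``gene_meta`` is indexed by gene name and carries boolean
    ``mito`` and ``tf`` flags.
    """

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.cell_meta) != self.counts.shape[0]:
            raise ValueError("cell_meta length mismatch")
        if len(self.gene_meta) != self.counts.shape[1]:
            raise ValueError("gene_meta length mismatch")
        if "condition" in self.cell_meta:
            conds = np.unique(self.cell_meta["condition"].to_numpy())
            if len(conds) and not np.array_equal(conds, np.arange(1, len(conds) + 1)):
                raise ValueError("condition ordinals must be contiguous from 1")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_names(self) -> np.ndarray:
        return self.gene_meta.index.to_numpy()

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ExpressionMatrix:
    """Cell x gene real-valued expression with provenance tag."""

    values: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    provenance: str = "raw"  # raw | normalized | smoothed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def gene_names(self) -> np.ndarray:
        return self.gene_meta.index.to_numpy()


@dataclass
class Embedding:
    """Low-dimensional coordinates with an exactly linear decoder.

    ``decode(coords) = coords @ loadings + mean`` reconstructs smoothed
    expression up to PCA truncation error.  Genes excluded from the fit have
    zero loadings and decode to their mean.
    """

    coords: np.ndarray  # (n_cells, d)
    loadings: np.ndarray  # (d, n_genes)
    mean: np.ndarray  # (n_genes,)
    gene_names: np.ndarray
    explained_variance: np.ndarray
    cell_meta: pd.DataFrame | None = None
    excluded_genes: tuple = field(default_factory=tuple)

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def decode(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.loadings + self.mean

    def gene_index(self, genes) -> np.ndarray:
        names = list(self.gene_names)
        idx = []
        for g in genes:
            if g not in names:
                raise KeyError(f"gene {g!r} not in decoder gene space")
            idx.append(names.index(g))
        return np.asarray(idx, dtype=int)


@dataclass
class QCReport:
    genes_removed: int
    cells_removed_by_libsize: int
    cells_removed_by_mito: int
    thresholds: dict

    def to_dict(self) -> dict:
        return {
            "genes_removed": int(self.genes_removed),
            "cells_removed_by_libsize": int(self.cells_removed_by_libsize),
            "cells_removed_by_mito": int(self.cells_removed_by_mito),
            "thresholds": dict(self.thresholds),
        }


@dataclass
class SpatialScene:
    """Islet discs/spheres and lesion boundary point sets, in micrometres.

    ``islets``: columns id, x, y[, z], radius.
    ``lesions``: columns id, point_index, x, y[, z] (boundary/surface points).
    """

    islets: pd.DataFrame
    lesions: pd.DataFrame
    dim: int = 2

    def __post_init__(self) -> None:
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if len(self.islets) and np.any(self.islets["radius"].to_numpy() <= 0):
            raise ValueError("islet radii must be positive")
        if len(self.lesions) == 0:
            raise ValueError("lesion point sets must be non-empty")

    @property
    def coord_cols(self) -> list:
        return ["x", "y", "z"][: self.dim]

    def islet_centers(self) -> np.ndarray:
        return self.islets[self.coord_cols].to_numpy(dtype=float)

    def lesion_points(self, lesion_id) -> np.ndarray:
        sub = self.lesions[self.lesions["id"] == lesion_id]
        return sub[self.coord_cols].to_numpy(dtype=float)

    def lesion_ids(self) -> np.ndarray:
        return pd.unique(self.lesions["id"])
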