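"""Plain-text readers and writers for the pipeline's artifacts.

Counts go to/from MTX (+ features.tsv / barcodes.tsv) or dense CSV; ground
truth, QC reports and manifests are JSON; spatial scenes, labels and edge
lists are CSV/TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import CountMatrix, SpatialScene

__all__ = [
    "write_counts_mtx",
    "read_counts_mtx",
    "write_counts_csv",
    "read_counts_csv",
    "write_scene_csv",
    "read_scene_csv",
    "write_json",
    "read_json",
]


def write_counts_mtx(m: CountMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(m.counts.T))
    m.gene_meta.reset_index().to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    m.cell_meta.reset_index().to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=True
    )


def read_counts_mtx(indir) -> CountMatrix:
    indir = Path(indir)
    counts = np.asarray(spio.mmread(str(indir / "matrix.mtx")).todense()).T
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    cell_meta = pd.read_csv(indir / "barcodes.tsv", sep="\t")
    cell_meta = cell_meta.set_index(cell_meta.columns[0])
    gene_meta = features.set_index(0)
    gene_meta.index.name = "gene"
    gene_meta.columns = ["mito", "tf"][: len(gene_meta.columns)]
    for c in gene_meta.columns:
        gene_meta[c] = gene_meta[c].astype(bool)
    return CountMatrix(counts.astype(np.int64), cell_meta, gene_meta)


def write_counts_csv(m: CountMatrix, path) -> None:
    df = pd.DataFrame(m.counts, index=m.cell_meta.index, columns=m.gene_meta.index)
    df.to_csv(path)


def read_counts_csv(path, cell_meta: pd.DataFrame, gene_meta: pd.DataFrame) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(df.to_numpy(dtype=np.int64), cell_meta, gene_meta)


def write_scene_csv(scene: SpatialScene, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene.islets.to_csv(outdir / "islets.csv", index=False)
    scene.lesions.to_csv(outdir / "lesions.csv", index=False)


def read_scene_csv(indir) -> SpatialScene:
    indir = Path(indir)
    islets = pd.read_csv(indir / "islets.csv")
    lesions = pd.read_csv(indir / "lesions.csv")
    dim = 3 if "z" in islets.columns else 2
    return SpatialScene(islets=islets, lesions=lesions, dim=dim)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
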