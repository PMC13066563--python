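"""Cell-of-origin tracing and enrichment-score statistics.

A trajectory's cell-of-origin is its position at the first timepoint
(s = 0).  Origins are annotated by nearest-neighbor label transfer from the
first-condition reference cells, and the enrichment score of a class is the
ratio of its proportion among the query cells to its proportion in the
reference: E > 1 means the class is over-represented among the origins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import TrajectorySet

__all__ = [
    "EnrichmentTable",
    "nearest_label",
    "trace_origins",
    "enrichment_score",
    "timepoint_archetype_enrichment",
]


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # class, p_query, p_reference, enrichment
    run: int | None = None

    def enrichment(self, cls) -> float:
        row = self.table[self.table["class"] == cls]
        if row.empty:
            raise KeyError(f"class {cls!r} not in table")
        return float(row["enrichment"].iloc[0])

    def top_class(self):
        idx = self.table["enrichment"].idxmax()
        return self.table.loc[idx, "class"]


def nearest_label(
    query_coords: np.ndarray,
    reference_coords: np.ndarray,
    reference_labels,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean 1-NN label transfer; ties go to the lowest reference index.

    Returns (labels, distances).  Exhaustive argmin per chunk so the
    tie-break convention is deterministic.
    """
    query_coords = np.atleast_2d(np.asarray(query_coords, dtype=float))
    reference_coords = np.asarray(reference_coords, dtype=float)
    if reference_coords.shape[0] == 0:
        raise ValueError("reference is empty")
    if query_coords.shape[1] != reference_coords.shape[1]:
        raise ValueError("dimension mismatch between query and reference")
    reference_labels = np.asarray(reference_labels)
    if reference_labels.shape[0] != reference_coords.shape[0]:
        raise ValueError("labels must cover all reference cells")
    ref_sq = np.sum(reference_coords**2, axis=1)
    labels = np.empty(query_coords.shape[0], dtype=reference_labels.dtype)
    dists = np.empty(query_coords.shape[0])
    for start in range(0, query_coords.shape[0], chunk):
        q = query_coords[start : start + chunk]
        d2 = np.sum(q**2, axis=1)[:, None] + ref_sq[None, :] - 2.0 * q @ reference_coords.T
        idx = np.argmin(d2, axis=1)  # first minimum = lowest index on ties
        labels[start : start + chunk] = reference_labels[idx]
        dists[start : start + chunk] = np.sqrt(np.maximum(d2[np.arange(len(q)), idx], 0.0))
    return labels, dists


def trace_origins(
    ts: TrajectorySet,
    reference_coords: np.ndarray,
    reference_labels,
    run: int | None = None,
) -> pd.DataFrame:
    """Label each trajectory's s=0 position by its nearest reference cell.

    With ``run=None`` every run's origins are labeled and stacked (one row
    per trajectory per run, the protocol that reports runs separately).
    """
    frames = []
    run_ids = range(ts.runs) if run is None else [run]
    for r in run_ids:
        coords = ts.origins(run=r)
        labels, dists = nearest_label(coords, reference_coords, reference_labels)
        frames.append(
            pd.DataFrame(
                {
                    "terminal_index": ts.terminal_indices,
                    "label": labels,
                    "distance": dists,
                    "run": r,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def enrichment_score(query_labels, reference_labels, run=None) -> EnrichmentTable:
    """Class-proportion ratios query / reference.

    Every query class must be present in the reference (the ratio is
    undefined otherwise); reference classes absent from the query get E = 0.
    """
    q = pd.Series(list(query_labels))
    r = pd.Series(list(reference_labels))
    q_prop = q.value_counts(normalize=True)
    r_prop = r.value_counts(normalize=True)
    missing = set(q_prop.index) - set(r_prop.index)
    if missing:
        raise ValueError(
            f"query class(es) absent from reference: {sorted(map(str, missing))}"
        )
    classes = list(r_prop.index)
    rows = []
    for cls in classes:
        pq = float(q_prop.get(cls, 0.0))
        pr = float(r_prop[cls])
        rows.append({"class": cls, "p_query": pq, "p_reference": pr,
                     "enrichment": pq / pr})
    return EnrichmentTable(table=pd.DataFrame(rows), run=run)


def timepoint_archetype_enrichment(
    ts: TrajectorySet,
    condition_coords: list,
    condition_assignments: list,
    breakpoints=None,
    combine_runs: bool = True,
) -> list:
    """Archetype enrichment along the trajectory grid.

    The grid is split into per-condition segments (default: equal intervals,
    e.g. thirds for three conditions).  Points in a segment are labeled by
    the nearest assigned cell of that condition, and each segment's label
    distribution is scored against the pooled distribution of all archetype
    assignments.  Returns a list of per-segment EnrichmentTables in grid
    order; with ``combine_runs=False`` a list per run is returned.
    """
    T = len(condition_coords)
    if len(condition_assignments) != T:
        raise ValueError("need one assignment vector per condition")
    G = ts.G
    if breakpoints is None:
        breakpoints = np.linspace(0, G, T + 1).astype(int)
    pooled = np.concatenate([np.asarray(a) for a in condition_assignments])

    def per_run(r):
        tables = []
        for t in range(T):
            lo, hi = breakpoints[t], breakpoints[t + 1]
            if hi <= lo:
                tables.append(None)  # empty segment reported as missing
                continue
            pts = ts.paths[r][:, lo:hi, :].reshape(-1, ts.paths.shape[-1])
            labels, _ = nearest_label(
                pts, np.asarray(condition_coords[t]), condition_assignments[t]
            )
            tables.append(enrichment_score(labels, pooled, run=r))
        return tables

    all_runs = [per_run(r) for r in range(ts.runs)]
    if not combine_runs:
        return all_runs
    combined = []
    for t in range(T):
        segs = [runs[t] for runs in all_runs if runs[t] is not None]
        if not segs:
            combined.append(None)
            continue
        merged = segs[0].table.copy()
        for other in segs[1:]:
            merged = merged.merge(
                other.table, on=["class", "p_reference"], suffixes=("", "_r")
            )
            merged["p_query"] = (merged["p_query"] + merged["p_query_r"]) / 2
            merged["enrichment"] = merged["p_query"] / merged["p_reference"]
            merged = merged[["class", "p_query", "p_reference", "enrichment"]]
        combined.append(EnrichmentTable(table=merged, run=None))
    return combined
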