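"""Islet-proximity statistics for 2D sections and 3D reconstructions.

Islets are discs/spheres (center + radius, micrometres), lesions are
boundary/surface point sets.  Two distinct distance rules are kept apart by
name: the 2D proximity call measures lesion-edge to islet-center (a lesion
is proximal when that distance is strictly below 400 um, counting only
islets with diameter strictly above 100 um), while ``shortest_distances``
reports surface-to-surface minima (center distance minus radius, floored at
zero) in both directions, as in 3D reconstructions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SpatialScene

__all__ = [
    "ProximityTable",
    "classify_proximity",
    "shortest_distances",
    "compare_groups",
    "fisher_proximity",
]


@dataclass
class ProximityTable:
    lesions: pd.DataFrame  # id, min_center_distance, proximal
    threshold_um: float
    min_islet_diameter_um: float
    n_islets_considered: int

    @property
    def n_proximal(self) -> int:
        return int(self.lesions["proximal"].sum())

    @property
    def n_distant(self) -> int:
        return int((~self.lesions["proximal"]).sum())

    def counts(self) -> tuple[int, int]:
        return self.n_proximal, self.n_distant


def classify_proximity(
    scene: SpatialScene,
    threshold_um: float = 400.0,
    min_islet_diameter_um: float = 100.0,
) -> ProximityTable:
    """Proximal/distant call per lesion under the strict 400 um rule.

    Islets with diameter <= ``min_islet_diameter_um`` are removed first; a
    lesion is proximal iff the minimum distance from any of its boundary
    points to a retained islet center is strictly below ``threshold_um``.
    """
    radii = scene.islets["radius"].to_numpy(dtype=float)
    keep = 2.0 * radii > min_islet_diameter_um
    centers = scene.islet_centers()[keep]
    if centers.shape[0] == 0:
        warnings.warn("no islets pass the diameter filter; all lesions distant")
    rows = []
    for lid in scene.lesion_ids():
        pts = scene.lesion_points(lid)
        if centers.shape[0]:
            d = np.sqrt(
                ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            )
            dmin = float(d.min())
        else:
            dmin = np.inf
        rows.append({"id": lid, "min_center_distance": dmin,
                     "proximal": dmin < threshold_um})
    return ProximityTable(
        lesions=pd.DataFrame(rows),
        threshold_um=threshold_um,
        min_islet_diameter_um=min_islet_diameter_um,
        n_islets_considered=int(keep.sum()),
    )


def shortest_distances(scene: SpatialScene) -> dict:
    """Surface-to-surface nearest distances in both directions, plus radii.

    Islet surface distance to a lesion point is ``center distance - radius``
    floored at zero (points inside the sphere are at distance 0).
    """
    centers = scene.islet_centers()
    radii = scene.islets["radius"].to_numpy(dtype=float)
    lesion_ids = scene.lesion_ids()
    lesion_min = np.full(len(lesion_ids), np.inf)
    islet_min = np.full(len(centers), np.inf)
    for li, lid in enumerate(lesion_ids):
        pts = scene.lesion_points(lid)
        if centers.shape[0] == 0:
            continue
        d = np.sqrt(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
        surf = np.maximum(d - radii[None, :], 0.0)
        lesion_min[li] = surf.min()
        islet_min = np.minimum(islet_min, surf.min(axis=0))
    return {
        "lesion_to_islet": pd.Series(lesion_min, index=lesion_ids),
        "islet_to_lesion": pd.Series(islet_min, index=scene.islets["id"].to_numpy()),
        "islet_radii": pd.Series(radii, index=scene.islets["id"].to_numpy()),
    }


def compare_groups(dist_a, dist_b) -> dict:
    """Two-sample KS on the empirical CDFs plus two-sided rank-sum p."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    ks = stats.ks_2samp(a, b, method="auto")
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "ranksum_p": float(mw.pvalue),
    }


def fisher_proximity(table) -> float:
    """Two-sided Fisher exact p for a 2x2 proximal/distant condition table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in contingency table; p = 1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
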