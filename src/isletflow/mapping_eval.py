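"""Cross-dataset mapping and integration-audit metrics.

The mapper is an entropic-OT barycentric projection: each source cell is
moved to the coupling-weighted mean of reference cells.  The audit metrics
are the ones used to gate such mappings:

* modified batch ASW -- per cell type, the mean of ``1 - |silhouette|`` on
  batch labels, averaged over cell types; 0 = batches separate, 1 = batches
  perfectly mixed;
* global distortion -- mean per-cell cosine similarity between features
  before and after mapping;
* the accept gate: batch ASW > 0.6 and distortion within [0.2, 0.6];
* exact pairwise EMD between samples (Wasserstein-1, Euclidean ground cost)
  and Fiedler-vector ordering of the resulting sample graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, sparse
from sklearn.metrics import silhouette_samples

from .trajectory import sinkhorn

__all__ = [
    "MappingResult",
    "IntegrationReport",
    "baseline_map",
    "batch_asw",
    "global_distortion",
    "integration_gate",
    "emd",
    "pairwise_emd",
    "fiedler_ordering",
]


@dataclass
class MappingResult:
    mapped: np.ndarray  # (n_source, d) coordinates in reference space
    pre: np.ndarray
    post: np.ndarray
    per_cell_correlation: np.ndarray
    method: str = "ot_barycentric"


@dataclass
class IntegrationReport:
    batch_asw: float
    global_distortion: float
    params: dict

    def gate(self, asw_min: float = 0.6, dist_band=(0.2, 0.6)):
        return integration_gate(self, asw_min=asw_min, dist_band=dist_band)


def baseline_map(
    source_coords: np.ndarray,
    reference_coords: np.ndarray,
    epsilon: float,
    tol: float = 1e-5,
    max_iter: int = 20_000,
) -> MappingResult:
    """Entropic-OT barycentric projection of source cells onto the reference.

    Mapped points are coupling-weighted means of reference points, hence lie
    in the reference convex hull; as epsilon -> 0 with source == reference the
    map approaches the identity.
    """
    src = np.asarray(source_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if src.size == 0 or ref.size == 0:
        raise ValueError("empty input point set")
    if src.shape[1] != ref.shape[1]:
        raise ValueError("dimension mismatch")
    pi, _ = sinkhorn(src, ref, epsilon=epsilon, mode="balanced", tol=tol,
                     max_iter=max_iter)
    row = pi.sum(axis=1, keepdims=True)
    mapped = (pi @ ref) / np.maximum(row, 1e-300)
    corr = np.empty(src.shape[0])
    for i in range(src.shape[0]):
        a, b = src[i], mapped[i]
        sa, sb = a.std(), b.std()
        corr[i] = np.corrcoef(a, b)[0, 1] if sa > 0 and sb > 0 else 0.0
    return MappingResult(mapped=mapped, pre=src, post=mapped, per_cell_correlation=corr)


def batch_asw(
    joint_coords: np.ndarray,
    batch_labels,
    cell_type_labels=None,
) -> float:
    """Modified average silhouette width of batch, scaled to [0, 1].

    Per cell type, silhouettes are computed on batch labels and averaged as
    ``mean(1 - |s|)``; the score is the mean over cell types.  1 means
    perfect batch overlap, 0 means complete separation.  Cell types in which
    some batch has fewer than 2 cells are skipped with a warning.
    """
    X = np.asarray(joint_coords, dtype=float)
    batch = np.asarray(batch_labels)
    if len(np.unique(batch)) < 2:
        raise ValueError("need at least 2 batches")
    if cell_type_labels is None:
        cell_type_labels = np.zeros(X.shape[0], dtype=int)
    ctypes = np.asarray(cell_type_labels)
    scores = []
    for ct in np.unique(ctypes):
        mask = ctypes == ct
        b = batch[mask]
        uniq, counts = np.unique(b, return_counts=True)
        if len(uniq) < 2 or counts.min() < 2:
            warnings.warn(f"cell type {ct!r} skipped: a batch has < 2 cells")
            continue
        s = silhouette_samples(X[mask], b)
        scores.append(float(np.mean(1.0 - np.abs(s))))
    if not scores:
        raise ValueError("no cell type had >= 2 cells in >= 2 batches")
    return float(np.mean(scores))


def global_distortion(pre_features: np.ndarray, post_features: np.ndarray) -> float:
    """Mean per-cell cosine similarity between pre- and post-mapping features."""
    pre = np.asarray(pre_features, dtype=float)
    post = np.asarray(post_features, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post feature shapes differ")
    na = np.linalg.norm(pre, axis=1)
    nb = np.linalg.norm(post, axis=1)
    bad = np.flatnonzero((na == 0) | (nb == 0))
    if bad.size:
        raise ValueError(f"zero-norm feature vector for cell(s) {bad[:5].tolist()}")
    cos = np.sum(pre * post, axis=1) / (na * nb)
    return float(cos.mean())


def integration_gate(
    report: IntegrationReport,
    asw_min: float = 0.6,
    dist_band=(0.2, 0.6),
) -> tuple[bool, str]:
    """Printed accept gate: ASW > asw_min and distortion within the band."""
    if not report.batch_asw > asw_min:
        return False, f"batch integration {report.batch_asw:.3f} <= {asw_min}"
    lo, hi = dist_band
    if not (lo <= report.global_distortion <= hi):
        side = "below" if report.global_distortion < lo else "above"
        return False, (
            f"global distortion {report.global_distortion:.3f} {side} band [{lo}, {hi}]"
        )
    return True, "pass"


def emd(x: np.ndarray, y: np.ndarray) -> float:
    """Exact Wasserstein-1 distance between uniform point clouds.

    Equal sizes reduce to an assignment problem; unequal sizes solve the
    transport linear program (HiGHS).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 0 or y.shape[0] == 0:
        raise ValueError("empty point cloud")
    n, m = x.shape[0], y.shape[0]
    D = np.sqrt(
        np.maximum(
            np.sum(x**2, 1)[:, None] + np.sum(y**2, 1)[None, :] - 2 * x @ y.T, 0.0
        )
    )
    if n == m:
        r, c = optimize.linear_sum_assignment(D)
        return float(D[r, c].mean())
    a = np.full(n, 1.0 / n)
    b = np.full(m, 1.0 / m)
    # transport LP: min <D, P> s.t. P 1 = a, P^T 1 = b, P >= 0
    A_eq_rows = sparse.kron(sparse.eye(n), np.ones((1, m)))
    A_eq_cols = sparse.kron(np.ones((1, n)), sparse.eye(m))
    A_eq = sparse.vstack([A_eq_rows, A_eq_cols]).tocsc()[:-1]  # drop redundant row
    b_eq = np.concatenate([a, b])[:-1]
    res = optimize.linprog(D.ravel(), A_eq=A_eq, b_eq=b_eq, method="highs")
    if not res.success:
        raise RuntimeError(f"EMD linear program failed: {res.message}")
    return float(res.fun)


def pairwise_emd(
    samples, subsample_n: int = 500, seed: int = 0
) -> np.ndarray:
    """Symmetric matrix of exact EMDs between samples (point clouds).

    Each cloud is subsampled (without replacement) to at most
    ``subsample_n`` points to keep the linear program at desk scale.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    clouds = []
    for i, s in enumerate(samples):
        s = np.atleast_2d(np.asarray(s, dtype=float))
        if s.shape[0] == 0:
            raise ValueError(f"sample {i} is empty")
        if s.shape[0] > subsample_n:
            rng = np.random.default_rng(np.random.SeedSequence((seed, 71, i)))
            s = s[rng.choice(s.shape[0], size=subsample_n, replace=False)]
        clouds.append(s)
    k = len(clouds)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = emd(clouds[i], clouds[j])
    return D


def fiedler_ordering(
    D: np.ndarray,
    kernel_bandwidth: float | None = None,
    anchor: np.ndarray | None = None,
) -> np.ndarray:
    """Scalar sample coordinates from the Fiedler vector of the EMD graph.

    Affinity ``W = exp(-D^2 / sigma^2)`` (sigma defaults to the median
    off-diagonal distance), unnormalized Laplacian, eigenvector of the
    second-smallest eigenvalue.  The sign is fixed to correlate positively
    with ``anchor`` when given, else so the first sample has a non-positive
    coordinate.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("D must be a symmetric square matrix")
    off = D[np.triu_indices_from(D, k=1)]
    sigma = kernel_bandwidth if kernel_bandwidth is not None else float(np.median(off))
    if sigma <= 0:
        sigma = 1.0
    W = np.exp(-(D**2) / sigma**2)
    np.fill_diagonal(W, 0.0)
    L = np.diag(W.sum(axis=1)) - W
    vals, vecs = linalg.eigh(L)
    if vals[1] < 1e-12 * max(vals[-1], 1.0):
        raise ValueError(
            "affinity graph is numerically disconnected; increase kernel_bandwidth"
        )
    fiedler = vecs[:, 1]
    if anchor is not None:
        anchor = np.asarray(anchor, dtype=float)
        if np.dot(fiedler - fiedler.mean(), anchor - anchor.mean()) < 0:
            fiedler = -fiedler
    elif fiedler[0] > 0:
        fiedler = -fiedler
    return fiedler
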