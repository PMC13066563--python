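"""Archetypal analysis in the PCA latent space.

Cells are modeled as convex combinations of a small number of extreme
states ("archetypes"): X ~ A Z with the commitment rows of A on the
probability simplex and the archetypes Z themselves restricted to convex
combinations of data points (the convex hull of X), i.e. the
principal-convex-hull factorization.  The commitment block is solved by
restarted FISTA on the simplex; the archetype block takes the unconstrained
optimum projected exactly onto the data hull (sparse penalty-NNLS),
accepted only when it lowers the loss, plus guaranteed-descent projected
gradient polish -- so the reconstruction loss is non-increasing at every
half-step.

The archetype count is selected by the held-out reconstruction-error elbow:
fit on a density-balanced 80% subsample for each k in a range, project the
held-out cells onto the fitted simplex, and take the k maximizing the
discrete second difference of the mean MSE curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as optimize_nnls
from sklearn.neighbors import NearestNeighbors

from .origin import nearest_label

__all__ = [
    "ArchetypeModel",
    "KSelectionCurve",
    "project_simplex_rows",
    "simplex_lstsq",
    "fit_archetypes",
    "select_n_archetypes",
    "committed",
    "assign_by_neighbor",
    "archetype_similarity",
]


@dataclass
class ArchetypeModel:
    k: int
    Z: np.ndarray  # (k, d) archetype coordinates
    A: np.ndarray  # (n, k) simplex commitments
    loss_trace: list = field(default_factory=list)

    @property
    def loss(self) -> float:
        return self.loss_trace[-1] if self.loss_trace else np.inf

    def reconstruct(self) -> np.ndarray:
        return self.A @ self.Z


@dataclass
class KSelectionCurve:
    k_values: np.ndarray
    mean_mse: np.ndarray
    per_repeat_mse: np.ndarray  # (len(k_values), repeats)
    chosen_k: int
    weak_elbow: bool
    repeats: int
    subsample: float


def project_simplex_rows(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = V.shape
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = U - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1  # last true index
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(V - theta[:, None], 0.0)


def simplex_lstsq(
    X: np.ndarray, Z: np.ndarray, A0: np.ndarray | None = None,
    n_iter: int = 200, tol: float = 1e-12,
) -> np.ndarray:
    """min ||X - A Z||^2 over A with rows on the simplex (projected gradient).

    Gram-free so the dictionary Z may have many rows (e.g. when archetypes
    are regressed on the full data cloud).
    """
    n, k = X.shape[0], Z.shape[0]
    L = max(float(np.linalg.svd(Z, compute_uv=False)[0]) ** 2, 1e-12)
    A = np.full((n, k), 1.0 / k) if A0 is None else A0.copy()

    def obj(M):
        R = M @ Z - X
        return float(np.einsum("ij,ij->", R, R))

    # FISTA with function-value restart; the best iterate is returned so the
    # result never regresses below the warm start
    best_A, best_f = A.copy(), obj(A)
    Y = A.copy()
    t_mom = 1.0
    prev_f = best_f
    for _ in range(n_iter):
        grad = (Y @ Z - X) @ Z.T
        A_new = project_simplex_rows(Y - grad / L)
        f_new = obj(A_new)
        if f_new > prev_f:  # restart momentum
            Y = A.copy()
            t_mom = 1.0
            grad = (Y @ Z - X) @ Z.T
            A_new = project_simplex_rows(Y - grad / L)
            f_new = obj(A_new)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        Y = A_new + ((t_mom - 1.0) / t_next) * (A_new - A)
        A, t_mom = A_new, t_next
        if f_new < best_f:
            best_A, best_f = A_new.copy(), f_new
        if abs(prev_f - f_new) < tol * max(abs(prev_f), 1.0):
            break
        prev_f = f_new
    return best_A


def _fps_init(
    X: np.ndarray, k: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Furthest-point-sampling rows of a one-hot B (archetypes at data points).

    With ``rng=None`` the first pick is the point farthest from the centroid
    (deterministic, covers an extreme); a rng gives a random first pick for
    restart diversity.
    """
    n = X.shape[0]
    if rng is None:
        first = int(np.argmax(np.sum((X - X.mean(axis=0)) ** 2, axis=1)))
    else:
        first = int(rng.integers(n))
    idx = [first]
    d2 = np.sum((X - X[idx[0]]) ** 2, axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        idx.append(nxt)
        d2 = np.minimum(d2, np.sum((X - X[nxt]) ** 2, axis=1))
    B = np.zeros((k, n))
    B[np.arange(k), idx] = 1.0
    return B


def _project_to_hull(points: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Euclidean projection of each point onto conv(X) (penalty NNLS).

    The simplex constraint is enforced with a quadratic penalty row; the
    active-set solution is sparse (support <= d + 1), so this is exact to
    O(1/rho^2) and fast even for thousands of hull vertices.
    """
    scale = float(np.abs(X).max()) or 1.0
    rho = 1e4 * scale
    A_aug = np.vstack([X.T, np.full((1, X.shape[0]), rho)])
    out = np.empty_like(points)
    for i, z in enumerate(points):
        b, _ = optimize_nnls(A_aug, np.append(z, rho))
        s = b.sum()
        out[i] = (b / s) @ X if s > 0 else X.mean(axis=0)
    return out


def _fit_once(
    X: np.ndarray,
    k: int,
    B0: np.ndarray,
    max_iter: int,
    tol: float,
    inner: int = 60,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Alternating minimization with the archetypes kept inside conv(X).

    A-block: simplex least squares (FISTA).  Z-block: the unconstrained
    optimum projected onto the data hull, accepted only when it lowers the
    loss, followed by guaranteed-descent projected-gradient steps in
    coordinate space (step 1 / lambda_max(A^T A), projection onto conv(X)).
    The loss trace is non-increasing by construction.
    """
    Z = B0 @ X
    A = simplex_lstsq(X, Z, n_iter=2 * inner)

    def loss(A, Z):
        R = X - A @ Z
        return float(np.einsum("ij,ij->", R, R))

    trace = [loss(A, Z)]
    for _ in range(max_iter):
        AtA = A.T @ A
        Z_star = np.linalg.solve(AtA + 1e-10 * np.eye(k), A.T @ X)
        Z_cand = _project_to_hull(Z_star, X)
        if loss(A, Z_cand) < loss(A, Z):
            Z = Z_cand
        L_Z = max(float(np.linalg.eigvalsh(AtA).max()), 1e-12)
        for _ in range(1):
            grad_Z = AtA @ Z - A.T @ X
            Z_new = _project_to_hull(Z - grad_Z / L_Z, X)
            if loss(A, Z_new) <= loss(A, Z):
                Z = Z_new
            else:
                break
        A = simplex_lstsq(X, Z, A0=A, n_iter=inner)
        cur = loss(A, Z)
        trace.append(cur)
        if trace[-2] - cur < tol * max(abs(trace[-2]), 1.0):
            break
    return A, Z, trace


def fit_archetypes(
    coords: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-8,
    init_B: np.ndarray | None = None,
    inner: int = 60,
) -> ArchetypeModel:
    """Fit the k-archetype simplex model; best of ``restarts`` by loss.

    ``init_B`` adds one warm-start restart (rows on the simplex over data
    points), used by the k-selection sweep to keep train MSE non-increasing
    in k.
    """
    X = np.asarray(coords, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError("k cannot exceed the number of cells")
    if k == 1:
        Z = X.mean(axis=0, keepdims=True)
        A = np.ones((n, 1))
        R = X - A @ Z
        return ArchetypeModel(k=1, Z=Z, A=A, loss_trace=[float(np.einsum("ij,ij->", R, R))])
    rng = np.random.default_rng(np.random.SeedSequence((seed, 61, k)))
    inits = [_fps_init(X, k)]  # deterministic extreme-point start
    inits += [_fps_init(X, k, rng) for _ in range(restarts - 1)]
    if init_B is not None:
        inits.append(init_B)
    best = None
    for B0 in inits:
        A, Z, trace = _fit_once(X, k, B0, max_iter=max_iter, tol=tol, inner=inner)
        if best is None or trace[-1] < best[2][-1]:
            best = (A, Z, trace)
    A, Z, trace = best
    return ArchetypeModel(k=k, Z=Z, A=A, loss_trace=trace)


def _density_subsample(
    X: np.ndarray, fraction: float, rng: np.random.Generator, k_nn: int = 15
) -> np.ndarray:
    """Indices of a density-balanced subsample: inclusion prob ~ 1 / density.

    Local density is 1 / distance-to-kth-neighbor, so sparse regions (the
    simplex corners) are kept preferentially.
    """
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k_nn + 1, n)).fit(X)
    dist, _ = nn.kneighbors(X)
    w = np.maximum(dist[:, -1], 1e-12)  # inverse density
    p = w / w.sum()
    n_take = int(round(fraction * n))
    return rng.choice(n, size=n_take, replace=False, p=p)


def select_n_archetypes(
    coords: np.ndarray,
    k_range=range(2, 11),
    repeats: int = 3,
    holdout: float = 0.2,
    seed: int = 0,
    curvature_flag: float = 0.05,
    sweep_max_iter: int = 80,
    sweep_tol: float = 1e-7,
) -> KSelectionCurve:
    """Held-out reconstruction-error elbow over the archetype-count range.

    Per repeat: density-subsample 80% of cells for training, fit each k,
    project held-out cells onto the fitted simplex and record their MSE.
    Elbow = k maximizing the second difference of the mean-MSE curve; the
    ``weak_elbow`` flag is set when the winning curvature is below
    ``curvature_flag`` x the curve's range.
    """
    X = np.asarray(coords, dtype=float)
    ks = np.asarray(list(k_range), dtype=int)
    n = X.shape[0]
    if ks.min() < 1 or ks.max() >= int((1 - holdout) * n):
        raise ValueError("k_range outside [1, n_train]")
    mses = np.empty((len(ks), repeats))
    for rep in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 62, rep)))
        train_idx = _density_subsample(X, 1.0 - holdout, rng)
        test_mask = np.ones(n, dtype=bool)
        test_mask[train_idx] = False
        Xtr, Xte = X[train_idx], X[test_mask]
        prev_model = None
        for ki, k in enumerate(ks):
            init_B = None
            if prev_model is not None:
                # warm start: previous archetypes + the worst-reconstructed point
                resid = np.sum((Xtr - prev_model.A @ prev_model.Z) ** 2, axis=1)
                extra = np.zeros((1, Xtr.shape[0]))
                extra[0, int(np.argmax(resid))] = 1.0
                prev_B = _coords_to_B(prev_model.Z, Xtr)
                init_B = np.vstack([prev_B, extra])
            model = fit_archetypes(
                Xtr, int(k), seed=seed + rep, init_B=init_B,
                restarts=1, max_iter=sweep_max_iter, tol=sweep_tol, inner=30,
            )
            A_te = simplex_lstsq(Xte, model.Z)
            mses[ki, rep] = float(np.mean((Xte - A_te @ model.Z) ** 2))
            prev_model = model
    mean_mse = mses.mean(axis=1)
    if len(ks) >= 3:
        # curvature on the log curve: scale-free, so the drop onto the noise
        # floor dominates regardless of the absolute MSE magnitudes
        log_mse = np.log(np.maximum(mean_mse, 1e-300))
        curv = log_mse[:-2] - 2 * log_mse[1:-1] + log_mse[2:]
        best_i = int(np.argmax(curv)) + 1
        weak = curv[best_i - 1] < curvature_flag * max(
            log_mse.max() - log_mse.min(), 1e-300
        )
        if weak:
            warnings.warn("weak elbow: MSE curve has no pronounced curvature")
    else:
        best_i, weak = 0, True
    return KSelectionCurve(
        k_values=ks,
        mean_mse=mean_mse,
        per_repeat_mse=mses,
        chosen_k=int(ks[best_i]),
        weak_elbow=bool(weak),
        repeats=repeats,
        subsample=1.0 - holdout,
    )


def _coords_to_B(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Express archetype coordinates as simplex weights over data points."""
    return simplex_lstsq(Z, X)


def committed(model: ArchetypeModel, threshold: float = 0.5) -> np.ndarray:
    """Per-cell archetype call: AT_j iff commitment to j exceeds threshold.

    The strict-inequality rule means a cell at exactly the threshold stays
    uncommitted; threshold must exceed 1/k so at most one archetype can win.
    """
    if not (1.0 / model.k) <= threshold <= 1.0:
        # strict > labeling means threshold = 1/k still yields unique labels
        raise ValueError("threshold must lie in [1/k, 1] for unique labels")
    labels = np.full(model.A.shape[0], "uncommitted", dtype=object)
    winner = np.argmax(model.A, axis=1)
    val = model.A[np.arange(model.A.shape[0]), winner]
    mask = val > threshold
    labels[mask] = np.array([f"AT_{j + 1}" for j in winner[mask]], dtype=object)
    return labels


def assign_by_neighbor(
    query_coords: np.ndarray,
    reference_coords: np.ndarray,
    reference_archetype_labels,
) -> tuple[np.ndarray, np.ndarray]:
    """1-NN archetype label transfer (Euclidean; ties to lowest index)."""
    return nearest_label(query_coords, reference_coords, reference_archetype_labels)


def archetype_similarity(
    model_a: ArchetypeModel,
    model_b: ArchetypeModel,
    decoder_a,
    decoder_b,
    cutoff: float = 0.5,
) -> tuple[np.ndarray, list]:
    """Cosine similarity between decoded archetype gene profiles.

    Profiles are decoded through each model's decoder into the shared gene
    space, z-scored per gene over the union of archetypes, and compared by
    cosine.  Mutually-best pairs above ``cutoff`` are grouped greedily.
    """
    genes_a = list(decoder_a.gene_names)
    genes_b = list(decoder_b.gene_names)
    shared = [g for g in genes_a if g in set(genes_b)]
    if not shared:
        raise ValueError("decoders have disjoint gene spaces")
    Pa = decoder_a.decode(model_a.Z)[:, [genes_a.index(g) for g in shared]]
    Pb = decoder_b.decode(model_b.Z)[:, [genes_b.index(g) for g in shared]]
    pooled = np.vstack([Pa, Pb])
    mu, sd = pooled.mean(axis=0), pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Za = (Pa - mu) / sd
    Zb = (Pb - mu) / sd
    na = np.linalg.norm(Za, axis=1)
    nb = np.linalg.norm(Zb, axis=1)
    na = np.where(na > 0, na, 1.0)
    nb = np.where(nb > 0, nb, 1.0)
    S = (Za / na[:, None]) @ (Zb / nb[:, None]).T
    # greedy mutual-best grouping
    pairs = []
    used_a, used_b = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(S, axis=None)[::-1], S.shape))[0]
    for i, j in order:
        if S[i, j] < cutoff:
            break
        if i in used_a or j in used_b:
            continue
        if S[i, :].argmax() == j and S[:, j].argmax() == i:
            pairs.append((int(i), int(j), float(S[i, j])))
            used_a.add(int(i))
            used_b.add(int(j))
    return S, pairs
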