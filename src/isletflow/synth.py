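"""Synthetic data generator for the whole pipeline.

Emulates the structure of an obesity time course of islet endocrine cells:
three ordered conditions (lean -> moderate -> severe obesity) whose cells are
convex combinations of archetypal extreme states, a rare proliferative
immature origin subpopulation planted at the first condition that expands
into the high-``Cck`` archetype by the last condition, reciprocal
increasing / decreasing hormone-gene trends, lagged TF->target regulation,
batch effects between "datasets", and toy islet / lesion geometries.

Counts are drawn negative-binomially (mean--dispersion parameterization,
``var = mu + mu^2 / theta``) from a log-linear map of the latent simplex
position.  A single global seed spawns independent sub-streams per
operation so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, SpatialScene

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_population",
    "gen_trend_pair",
    "gen_batch_pair",
    "gen_spatial_scene",
]

# Named planted genes.  "Cck"-like rises across conditions, the insulin-like
# genes fall; the remaining hormone genes exist so the PCA exclusion rule has
# something to exclude.
_DEFAULT_TREND_GENES = (
    ("Cck", "increasing"),
    ("Ins1", "decreasing"),
    ("Ins2", "decreasing"),
)
_DEFAULT_TF_EDGES = (("Jun", "Cck", 10, 0.8),)


@dataclass
class SynthConfig:
    """Parameters of the synthetic population.

    Defaults define the standard study conditions used throughout the test
    suite: 3 ordered conditions x 2000 cells, 200 genes, 4 archetypes per
    condition, a 5% immature origin subpopulation with a 3x proliferation
    advantage.
    """

    n_conditions: int = 3
    n_cells_per_condition: int = 2000
    n_genes: int = 200
    n_archetypes: int = 4
    d_latent: int = 6
    origin_fraction: float = 0.05
    origin_growth: float = 3.0
    trend_genes: tuple = _DEFAULT_TREND_GENES
    tf_edges: tuple = _DEFAULT_TF_EDGES
    batch_shift: float = 1.0
    nb_dispersion: float = 10.0
    mito_fraction: float = 0.05
    mito_high_cell_fraction: float = 0.03
    latent_noise: float = 0.05
    vertex_scale: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_conditions < 1:
            raise ValueError("n_conditions must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0.0 <= self.origin_fraction <= 1.0:
            raise ValueError("origin_fraction must be in [0, 1]")
        if self.origin_growth < 1.0:
            raise ValueError("origin_growth must be >= 1")
        n_special = len(self.trend_genes) + len(
            {tf for tf, *_ in self.tf_edges}
        )
        if self.n_genes < n_special + 4:
            raise ValueError("n_genes too small for the planted special genes")
        for _, _, _, eff in self.tf_edges:
            if not np.isfinite(eff):
                raise ValueError("non-finite TF edge effect size")
        if 0 < self.origin_fraction and (
            self.origin_fraction * self.n_cells_per_condition < 5
        ):
            raise ValueError(
                "origin_fraction * n_cells_per_condition must be >= 5"
            )


@dataclass
class GroundTruth:
    """Planted structure returned alongside the generated counts."""

    commitment: np.ndarray  # (n_cells, k) simplex rows
    origin: np.ndarray  # (n_cells,) bool
    trend_direction: dict  # gene -> "increasing" | "decreasing"
    tf_edges: tuple  # (tf, target, lag, effect)
    batch: np.ndarray  # (n_cells,) int
    # generative internals, kept so batch pairs can re-sample counts from the
    # same latent model
    latent: np.ndarray = None
    vertices: np.ndarray = None  # (T, k, d)
    loadings: np.ndarray = None  # (d, n_genes)
    log_base: np.ndarray = None  # (n_genes,)
    dispersion: float = 10.0
    count_seed: int = 0
    mito_boost: np.ndarray = None  # per-cell multiplier on mito genes
    mito_mask: np.ndarray = None  # per-gene bool


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent child stream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def _gene_names(config: SynthConfig) -> list:
    special = [g for g, _ in config.trend_genes]
    for tf, *_ in config.tf_edges:
        if tf not in special:
            special.append(tf)
    n_mito = max(1, int(round(config.mito_fraction * config.n_genes)))
    names = list(special)
    names += [f"mt-G{i}" for i in range(n_mito)]
    i = 0
    while len(names) < config.n_genes:
        names.append(f"G{i}")
        i += 1
    return names[: config.n_genes]


def _simplex_vertices(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-condition archetype vertices: shared geometry + small drift."""
    k, d = config.n_archetypes, config.d_latent
    if d < k - 1:
        raise ValueError("d_latent must be >= n_archetypes - 1")
    raw = rng.normal(size=(d, d))
    q, _ = np.linalg.qr(raw)
    base = config.vertex_scale * q[:, :k].T  # (k, d) well-separated directions
    verts = np.empty((config.n_conditions, k, d))
    for t in range(config.n_conditions):
        drift = 0.05 * config.vertex_scale * rng.normal(size=(k, d))
        verts[t] = base + drift
    return verts


def _condition_mixture(config: SynthConfig, t: int) -> float:
    """Probability that a condition-t cell belongs to the Cck-vertex pool."""
    if config.n_conditions == 1:
        return config.origin_fraction
    frac0 = config.origin_fraction
    frac_last = 0.5
    w = t / (config.n_conditions - 1)
    return frac0 + w * (frac_last - frac0)


def _sample_counts(
    latent: np.ndarray,
    loadings: np.ndarray,
    log_base: np.ndarray,
    dispersion: float,
    mito_boost: np.ndarray,
    mito_mask: np.ndarray,
    seed: int,
) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 91)))
    log_mu = log_base[None, :] + latent @ loadings
    mu = np.exp(np.clip(log_mu, -20, 12))
    if mito_boost is not None:
        mu = mu.copy()
        mu[:, mito_mask] *= mito_boost[:, None]
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    return rng.poisson(lam).astype(np.int64)


def gen_population(config: SynthConfig) -> tuple[CountMatrix, GroundTruth]:
    """Generate the full synthetic population and its ground truth.

    Latent cell positions are convex combinations of condition-specific
    archetype vertices (Dirichlet weights).  A rare origin cluster sits at the
    Cck vertex of the first-condition simplex; the mass at that vertex grows
    monotonically across conditions, so backward trajectory tracing from the
    high-Cck terminal state should land on the planted origin cells.
    """
    config.validate()
    names = _gene_names(config)
    k, d, T = config.n_archetypes, config.d_latent, config.n_conditions
    n = config.n_cells_per_condition

    geom_rng = _rng(config.seed, 1)
    verts = _simplex_vertices(config, geom_rng)

    cck_vertex = k - 1  # planted expanding archetype
    mature_vertex = 0  # insulin-high archetype, shrinking

    commit_rng = _rng(config.seed, 2)
    commitments = np.empty((T * n, k))
    latent = np.empty((T * n, d))
    origin = np.zeros(T * n, dtype=bool)
    conditions = np.repeat(np.arange(1, T + 1), n)

    alpha_cck = np.full(k, 0.15)
    alpha_cck[cck_vertex] = 25.0
    alpha_bulk = np.full(k, 0.8)
    alpha_bulk[cck_vertex] = 0.05
    alpha_bulk[mature_vertex] = 3.0

    for t in range(T):
        sl = slice(t * n, (t + 1) * n)
        p_cck = _condition_mixture(config, t)
        n_cck = int(round(p_cck * n))
        in_cck = np.zeros(n, dtype=bool)
        in_cck[:n_cck] = True
        a = np.where(in_cck[:, None], alpha_cck[None, :], alpha_bulk[None, :])
        w = commit_rng.gamma(shape=a)
        w /= w.sum(axis=1, keepdims=True)
        commitments[sl] = w
        latent[sl] = w @ verts[t] + config.latent_noise * commit_rng.normal(
            size=(n, d)
        )
        if t == 0 and config.origin_fraction > 0:
            n_origin = int(round(config.origin_fraction * n))
            origin[t * n : t * n + n_origin] = True

    # gene model: log-linear map of latent position
    load_rng = _rng(config.seed, 3)
    loadings = 0.10 * load_rng.normal(size=(d, config.n_genes))
    log_base = np.log(load_rng.uniform(0.5, 4.0, size=config.n_genes))

    def align(gene: str, vertex: int, strength: float) -> None:
        j = names.index(gene)
        direction = verts[:, vertex].mean(axis=0)
        direction = direction / np.linalg.norm(direction)
        loadings[:, j] = strength * direction

    for gene, sense in config.trend_genes:
        if sense == "increasing":
            align(gene, cck_vertex, 0.9)
        else:
            align(gene, mature_vertex, 0.9)
    for tf, _target, _lag, effect in config.tf_edges:
        sign = 1.0 if effect >= 0 else -1.0
        align(tf, cck_vertex, 0.7 * sign)

    mito_mask = np.array([g.startswith("mt-") for g in names])
    boost_rng = _rng(config.seed, 4)
    n_cells = T * n
    mito_boost = np.ones(n_cells)
    n_high = int(round(config.mito_high_cell_fraction * n_cells))
    if n_high:
        high_idx = boost_rng.choice(n_cells, size=n_high, replace=False)
        mito_boost[high_idx] = 12.0

    count_seed_val = int(
        np.random.SeedSequence((config.seed, 5)).generate_state(1)[0] % (2**31)
    )
    counts = _sample_counts(
        latent, loadings, log_base, config.nb_dispersion,
        mito_boost, mito_mask, count_seed_val,
    )

    cell_meta = pd.DataFrame(
        {
            "condition": conditions,
            "batch": np.zeros(n_cells, dtype=int),
            "origin": origin,
        },
        index=[f"cell_{i}" for i in range(n_cells)],
    )
    tf_names = {tf for tf, *_ in config.tf_edges}
    gene_meta = pd.DataFrame(
        {
            "mito": mito_mask,
            "tf": np.array([g in tf_names for g in names]),
        },
        index=pd.Index(names, name="gene"),
    )
    cm = CountMatrix(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)
    truth = GroundTruth(
        commitment=commitments,
        origin=origin,
        trend_direction=dict(config.trend_genes),
        tf_edges=tuple(config.tf_edges),
        batch=np.zeros(n_cells, dtype=int),
        latent=latent,
        vertices=verts,
        loadings=loadings,
        log_base=log_base,
        dispersion=config.nb_dispersion,
        count_seed=count_seed_val,
        mito_boost=mito_boost,
        mito_mask=mito_mask,
    )
    return cm, truth


def gen_trend_pair(
    n_steps: int, lag: int, effect: float, noise_sd: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """A smooth TF trend and a target that follows it with a fixed lag.

    ``target[t] = effect * tf[t - lag] + eps_t`` (the first ``lag`` entries
    repeat ``tf[0]``); the TF is a smoothed standardized random walk.
    """
    if not 0 < lag < n_steps / 2:
        raise ValueError("require 0 < lag < n_steps / 2")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    steps = rng.normal(size=n_steps + 8)
    walk = np.cumsum(steps)
    kernel = np.ones(9) / 9.0
    smooth = np.convolve(walk, kernel, mode="valid")  # length n_steps
    tf = (smooth - smooth.mean()) / (smooth.std() + 1e-12)
    lagged = np.concatenate([np.full(lag, tf[0]), tf[:-lag]])
    noise_rng = np.random.default_rng(np.random.SeedSequence((seed, 12)))
    target = effect * lagged + noise_sd * noise_rng.normal(size=n_steps)
    return tf, target


def gen_batch_pair(
    base: CountMatrix,
    truth: GroundTruth,
    batch_shift: float,
    seed: int,
) -> tuple[CountMatrix, CountMatrix]:
    """Create a second "dataset": affine latent perturbation + NB re-noise.

    The returned pair shares cell correspondence row-by-row; the second
    matrix carries batch label 1.  With ``batch_shift = 0`` and ``seed``
    equal to the base's count stream, the matrices are identical.
    """
    if base.n_cells == 0:
        raise ValueError("empty base matrix")
    if truth.latent is None:
        raise ValueError("ground truth must carry the latent model")
    d = truth.latent.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 21)))
    # small random rotation + translation, scaled by batch_shift
    skew = rng.normal(size=(d, d))
    skew = 0.15 * batch_shift * (skew - skew.T) / 2.0
    rot = np.eye(d) + skew
    shift = batch_shift * rng.normal(size=d) * 0.5
    latent2 = truth.latent @ rot.T + shift

    counts2 = _sample_counts(
        latent2, truth.loadings, truth.log_base,
        dispersion=truth.dispersion,
        mito_boost=truth.mito_boost, mito_mask=truth.mito_mask,
        seed=seed,
    )
    meta1 = base.cell_meta.copy()
    meta1["batch"] = 0
    meta2 = base.cell_meta.copy()
    meta2["batch"] = 1
    meta2.index = [f"{b}_b1" for b in meta2.index]
    m1 = CountMatrix(base.counts.copy(), meta1, base.gene_meta.copy())
    m2 = CountMatrix(counts2, meta2, base.gene_meta.copy())
    return m1, m2


def gen_spatial_scene(
    n_islets: int,
    n_lesions: int,
    proximity_bias: float,
    seed: int,
    dim: int = 2,
    region_um: float = 6000.0,
    islet_radius_range: tuple = (30.0, 120.0),
    lesion_radius_um: float = 30.0,
    n_boundary_points: int = 16,
    bias_distance_um: float = 100.0,
) -> SpatialScene:
    """Toy islet/lesion geometry in micrometres.

    With ``proximity_bias = 0`` lesion centers are uniform over the region;
    with bias 1 every lesion center is placed ``bias_distance_um`` from a
    random islet center.  Boundary points are a circle (2D) or sphere point
    cloud (3D) of radius ``lesion_radius_um`` around each lesion center.
    """
    if islet_radius_range[0] <= 0:
        raise ValueError("islet radii must be positive")
    if not 0.0 <= proximity_bias <= 1.0:
        raise ValueError("proximity_bias must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 31)))
    centers = rng.uniform(0, region_um, size=(n_islets, dim))
    radii = rng.uniform(*islet_radius_range, size=n_islets)

    cols = ["x", "y", "z"][:dim]
    islets = pd.DataFrame(centers, columns=cols)
    islets.insert(0, "id", np.arange(n_islets))
    islets["radius"] = radii

    rows = []
    for li in range(n_lesions):
        if rng.uniform() < proximity_bias and n_islets > 0:
            host = rng.integers(n_islets)
            direction = rng.normal(size=dim)
            direction /= np.linalg.norm(direction)
            center = centers[host] + bias_distance_um * direction
        else:
            center = rng.uniform(0, region_um, size=dim)
        if dim == 2:
            ang = np.linspace(0, 2 * np.pi, n_boundary_points, endpoint=False)
            pts = center + lesion_radius_um * np.stack(
                [np.cos(ang), np.sin(ang)], axis=1
            )
        else:
            raw = rng.normal(size=(n_boundary_points, 3))
            raw /= np.linalg.norm(raw, axis=1, keepdims=True)
            pts = center + lesion_radius_um * raw
        for pi, p in enumerate(pts):
            rows.append([li, pi, *p])
    lesions = pd.DataFrame(rows, columns=["id", "point_index", *cols])
    return SpatialScene(islets=islets, lesions=lesions, dim=dim)
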