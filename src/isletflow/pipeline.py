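"""End-to-end orchestration of the analysis on synthetic or user data.

``run(RunConfig())`` executes synth -> preprocess -> trajectory ->
archetypes -> origin tracing -> GRN -> gene-set stats -> mapping audit ->
spatial stats with the standard defaults (gene filter 15 cells, library
cap 15000, mito cap 12.5%, k-means 20, archetype k in 2..10 with 3 repeats
on an 80% density subsample, commitment 0.5, 2 trajectory runs on a
101-point grid, Granger lag 10, top 100 TFs, -log p > 25, proximity
400 um / islet diameter > 100 um) and emits a reproducibility manifest with
per-stage seeds, wall-clock and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import archetypes as at
from . import genesets as gs
from . import grn as grnmod
from . import mapping_eval as me
from . import origin as om
from . import preprocess as pp
from . import spatial as sp
from . import synth
from . import trajectory as tj

__all__ = ["RunConfig", "RunManifest", "run"]

HORMONE_GENES = ("Ins1", "Ins2", "Sst", "Ppy", "Gcg")


@dataclass
class RunConfig:
    """Flat stage-parameter bundle; defaults are the standard protocol."""

    seed: int = 0
    # synth
    synth: synth.SynthConfig | None = None
    # preprocess
    min_cells: int = 15
    max_libsize: float = 15000.0
    max_mito_pct: float = 12.5
    smooth_k: int = 15
    smooth_t: int = 3
    pca_d: int = 8
    kmeans_k: int = 20
    kmeans_runs: int = 5
    # trajectory
    ot_alpha: float = 2.0
    ot_mode: str = "unbalanced"
    grid_G: int = 101
    traj_runs: int = 2
    traj_max_cells: int = 1000  # per-condition subsample for OT fitting
    terminal_gene: str = "Cck"
    terminal_percentile: float = 95.0
    # archetypes
    archetype_k: int | str = "auto"  # "auto" -> held-out MSE elbow
    k_range: tuple = (2, 10)
    k_repeats: int = 3
    k_subsample: float = 0.8
    commitment_threshold: float = 0.5
    fit_restarts: int = 3
    sweep_max_cells: int = 600  # per-condition subsample for the k sweep
    # grn
    granger_lag: int = 10
    top_n_tfs: int = 100
    min_neglogp: float = 25.0
    # mapping audit
    batch_shift: float = 0.6
    emd_subsample: int = 300
    # spatial
    proximity_threshold_um: float = 400.0
    min_islet_diameter_um: float = 100.0
    n_islets: int = 15
    n_lesions: int = 120
    proximity_bias: float = 0.6
    # stage toggles
    stages: tuple = (
        "synth", "preprocess", "trajectory", "archetypes", "origin",
        "grn", "genesets", "mapping", "spatial",
    )


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seconds: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    stage_info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stage_seconds": self.stage_seconds,
            "checksums": self.checksums,
            "stage_info": self.stage_info,
        }


def _checksum(arr) -> str:
    a = np.ascontiguousarray(np.asarray(arr, dtype=float))
    return hashlib.sha256(a.tobytes()).hexdigest()[:16]


def _config_hash(config: RunConfig) -> str:
    d = asdict(config)
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run(config: RunConfig | None = None) -> tuple[RunManifest, dict]:
    """Execute the configured stages in dependency order.

    Returns (manifest, artifacts); ``artifacts`` maps stage names to their
    in-memory results.  A stage failure raises with the stage name attached.
    """
    config = config or RunConfig()
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)
    art: dict = {}
    stage = None
    t_all = time.perf_counter()
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            _STAGES[stage](config, art, manifest)
            manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest.stage_seconds["total"] = round(time.perf_counter() - t_all, 3)
    return manifest, art


def _need(art: dict, key: str, stage: str):
    if key not in art:
        raise RuntimeError(
            f"missing upstream artifact {key!r}; run its stage before {stage!r}"
        )
    return art[key]


def _stage_synth(config, art, manifest):
    scfg = config.synth or synth.SynthConfig(seed=config.seed)
    cm, truth = synth.gen_population(scfg)
    art["counts"] = cm
    art["truth"] = truth
    art["synth_config"] = scfg
    manifest.checksums["counts"] = _checksum(cm.counts)
    manifest.stage_info["synth"] = {
        "n_cells": cm.n_cells, "n_genes": cm.n_genes,
        "n_conditions": scfg.n_conditions,
    }


def _stage_preprocess(config, art, manifest):
    cm = _need(art, "counts", "preprocess")
    filtered, report = pp.qc_filter(
        cm, config.min_cells, config.max_libsize, config.max_mito_pct
    )
    norm = pp.normalize(filtered)
    hvg_idx = pp.select_hvg(norm)
    smoothed = pp.smooth(norm, k=config.smooth_k, t=config.smooth_t)
    exclude = [g for g in HORMONE_GENES if g in smoothed.gene_names]
    emb = pp.embed_pca(smoothed, d=config.pca_d, exclude_genes=exclude)
    labels, stability = pp.cluster_kmeans(
        emb, k=min(config.kmeans_k, emb.coords.shape[0] - 1),
        runs=config.kmeans_runs, seed=config.seed,
    )
    art.update(
        filtered=filtered, qc_report=report, normalized=norm,
        hvg=smoothed.gene_names[hvg_idx], smoothed=smoothed, embedding=emb,
        kmeans_labels=labels,
    )
    # ground-truth rows surviving QC
    truth = art.get("truth")
    if truth is not None:
        keep = cm.cell_meta.index.get_indexer(filtered.cell_meta.index)
        art["truth_keep"] = keep
    manifest.checksums["embedding"] = _checksum(emb.coords)
    manifest.stage_info["preprocess"] = {
        **report.to_dict(), "kmeans_stability": round(float(stability), 4),
        "n_hvg": int(len(hvg_idx)),
    }


def _split_by_condition(emb, meta):
    conds = np.sort(meta["condition"].unique())
    out = []
    for c in conds:
        out.append(emb.coords[meta["condition"].to_numpy() == c])
    return conds, out


def _stage_trajectory(config, art, manifest):
    emb = _need(art, "embedding", "trajectory")
    meta = art["filtered"].cell_meta
    conds, coords = _split_by_condition(emb, meta)
    # desk-scale: subsample each condition for OT fitting
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 83)))
    sub_idx = [
        np.sort(rng.choice(c.shape[0], size=min(config.traj_max_cells, c.shape[0]),
                           replace=False))
        for c in coords
    ]
    coords_sub = [c[i] for c, i in zip(coords, sub_idx)]
    cs, growth = tj.fit_couplings(
        coords_sub, alpha=config.ot_alpha, mode=config.ot_mode
    )
    # terminal set: top expression of the terminal gene at the last condition
    sm = art["smoothed"]
    gmask = meta["condition"].to_numpy() == conds[-1]
    gi = list(sm.gene_names).index(config.terminal_gene)
    expr = sm.values[gmask, gi][sub_idx[-1]]
    thr = np.percentile(expr, config.terminal_percentile)
    terminal = expr > thr
    if terminal.sum() == 0:
        terminal = expr >= thr
    ts = tj.sample_paths(
        cs, terminal, G=config.grid_G, runs=config.traj_runs, seed=config.seed
    )
    trends = tj.decode_trends(ts, emb, genes=list(art["hvg"]))
    art.update(couplings=cs, growth=growth, trajectories=ts, trends=trends,
               condition_coords=coords, traj_indices=sub_idx,
               traj_coords=coords_sub)
    manifest.checksums["growth"] = _checksum(growth)
    manifest.checksums["trends"] = _checksum(trends.values)
    manifest.stage_info["trajectory"] = {
        "epsilon": cs.epsilon, "alpha": cs.alpha, "mode": cs.mode,
        "n_terminal": int(terminal.sum()), "runs": config.traj_runs,
        "mean_growth": float(np.mean(growth)),
    }


def _stage_archetypes(config, art, manifest):
    coords = _need(art, "condition_coords", "archetypes")
    models, chosen = [], []
    for ci, X in enumerate(coords):
        if config.archetype_k == "auto":
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, 84, ci)))
            X_sweep = X
            if X.shape[0] > config.sweep_max_cells:
                X_sweep = X[rng.choice(X.shape[0], size=config.sweep_max_cells,
                                       replace=False)]
            curve = at.select_n_archetypes(
                X_sweep, k_range=range(config.k_range[0], config.k_range[1] + 1),
                repeats=config.k_repeats, holdout=1.0 - config.k_subsample,
                seed=config.seed + ci,
            )
            k = curve.chosen_k
        else:
            k = int(config.archetype_k)
        chosen.append(k)
        models.append(at.fit_archetypes(X, k, seed=config.seed + ci,
                                        restarts=config.fit_restarts))
    labels = [
        at.committed(m, threshold=config.commitment_threshold) for m in models
    ]
    art.update(archetype_models=models, archetype_labels=labels,
               archetype_k=chosen)
    manifest.checksums["archetype_Z"] = _checksum(
        np.concatenate([m.Z.ravel() for m in models])
    )
    manifest.stage_info["archetypes"] = {
        "chosen_k": chosen,
        "committed_fraction": [float(np.mean(l != "uncommitted")) for l in labels],
    }


def _stage_origin(config, art, manifest):
    ts = _need(art, "trajectories", "origin")
    coords = art["condition_coords"]
    labels = art["archetype_labels"]
    origins = om.trace_origins(ts, coords[0], labels[0])
    enr = om.enrichment_score(origins["label"], labels[0])
    seg = om.timepoint_archetype_enrichment(
        ts, coords, [np.asarray(lab) for lab in labels]
    )
    art.update(origin_table=origins, origin_enrichment=enr,
               segment_enrichment=seg)
    manifest.stage_info["origin"] = {
        "top_origin_class": str(enr.top_class()),
        "n_origins": int(len(origins)),
    }


def _make_prior(truth, hvg, tfs, rng) -> pd.DataFrame:
    """Prior edge list: the planted edges plus decoy pairs."""
    rows = [
        {"tf": tf, "target": tgt, "mode": "activation" if eff >= 0 else "repression"}
        for tf, tgt, _lag, eff in truth.tf_edges
    ]
    pool = [g for g in hvg if g not in set(tfs)]
    for tf in tfs:
        decoys = rng.choice(pool, size=min(10, len(pool)), replace=False)
        rows += [{"tf": tf, "target": d, "mode": "unknown"} for d in decoys]
    return pd.DataFrame(rows).drop_duplicates()


def _stage_grn(config, art, manifest):
    trends = _need(art, "trends", "grn")
    truth = art["truth"]
    gene_meta = art["filtered"].gene_meta
    tfs = [g for g in trends.genes if g in set(gene_meta.index[gene_meta["tf"]])]
    scores = grnmod.score_all(trends, tfs, L=config.granger_lag)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 81)))
    prior = _make_prior(truth, list(trends.genes), tfs, rng)
    net = grnmod.build_network(
        scores, prior, top_n_tfs=config.top_n_tfs,
        min_neglogp=config.min_neglogp,
    )
    clusters = gs.cluster_trends(trends, seed=config.seed)
    directions = clusters.gene_direction()
    inc = grnmod.increasing_subnetwork(
        net, {n: directions.get(n, "decreasing") for n in net.nodes}
    )
    art.update(granger_scores=scores, prior_db=prior, network=net,
               increasing_network=inc, trend_clusters=clusters)
    manifest.stage_info["grn"] = {
        "n_edges": net.number_of_edges(),
        "n_increasing_edges": inc.number_of_edges(),
    }


def _stage_genesets(config, art, manifest):
    clusters = _need(art, "trend_clusters", "genesets")
    truth = art["truth"]
    directions = clusters.gene_direction()
    universe = list(clusters.labels.index)
    increasing = [g for g, d in directions.items() if d == "increasing"]
    planted_up = [
        g for g, d in truth.trend_direction.items()
        if d == "increasing" and g in set(universe)
    ]
    collections = {"planted_increasing": planted_up}
    enrich = gs.hypergeom_enrich(increasing, collections, universe)
    art["geneset_enrichment"] = enrich
    manifest.stage_info["genesets"] = {
        "n_increasing": len(increasing),
        "planted_up_p": float(enrich["p"].iloc[0]) if len(enrich) else None,
    }


def _stage_mapping(config, art, manifest):
    cm = _need(art, "counts", "mapping")
    truth = art["truth"]
    m1, m2 = synth.gen_batch_pair(cm, truth, config.batch_shift,
                                  seed=config.seed + 1)
    # joint embedding of the pair, subsampled for speed
    n = m1.n_cells
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 82)))
    sub = rng.choice(n, size=min(800, n), replace=False)
    joint = np.vstack(
        [np.sqrt(m1.counts[sub].astype(float)), np.sqrt(m2.counts[sub].astype(float))]
    )
    jc = joint - joint.mean(axis=0)
    U, S, _ = np.linalg.svd(jc, full_matrices=False)
    pcs = U[:, :config.pca_d] * S[:config.pca_d]
    batch = np.concatenate([np.zeros(len(sub)), np.ones(len(sub))])
    asw_before = me.batch_asw(pcs, batch)
    src, ref = pcs[batch == 1], pcs[batch == 0]
    eps = tj.default_epsilon(ref)
    mres = me.baseline_map(src, ref, epsilon=eps)
    joint_after = np.vstack([ref, mres.mapped])
    asw_after = me.batch_asw(joint_after, batch)
    distortion = me.global_distortion(src, mres.mapped)
    report = me.IntegrationReport(
        batch_asw=asw_after, global_distortion=distortion,
        params={"epsilon": eps, "batch_shift": config.batch_shift},
    )
    gate = report.gate()
    # sample-level EMD over conditions of the base population
    emb = art.get("embedding")
    if emb is not None:
        conds, coords = _split_by_condition(emb, art["filtered"].cell_meta)
        D = me.pairwise_emd(coords, subsample_n=config.emd_subsample,
                            seed=config.seed)
        anchor = np.arange(len(coords), dtype=float)
        fied = me.fiedler_ordering(D, anchor=anchor)
    else:
        D, fied = None, None
    art.update(mapping=mres, integration_report=report, integration_gate=gate,
               sample_emd=D, fiedler=fied, asw_before=asw_before)
    manifest.stage_info["mapping"] = {
        "asw_before": round(asw_before, 4),
        "asw_after": round(asw_after, 4),
        "distortion": round(distortion, 4),
        "gate": gate[0], "gate_reason": gate[1],
    }
    if D is not None:
        manifest.checksums["sample_emd"] = _checksum(D)


def _stage_spatial(config, art, manifest):
    biased = synth.gen_spatial_scene(
        config.n_islets, config.n_lesions, config.proximity_bias,
        seed=config.seed,
    )
    unbiased = synth.gen_spatial_scene(
        config.n_islets, config.n_lesions, 0.0, seed=config.seed + 1,
    )
    tab_b = sp.classify_proximity(
        biased, config.proximity_threshold_um, config.min_islet_diameter_um
    )
    tab_u = sp.classify_proximity(
        unbiased, config.proximity_threshold_um, config.min_islet_diameter_um
    )
    contingency = [
        [tab_b.n_proximal, tab_b.n_distant],
        [tab_u.n_proximal, tab_u.n_distant],
    ]
    p_fisher = sp.fisher_proximity(contingency)
    d_b = sp.shortest_distances(biased)["lesion_to_islet"].to_numpy()
    d_u = sp.shortest_distances(unbiased)["lesion_to_islet"].to_numpy()
    comp = sp.compare_groups(d_b, d_u)
    art.update(scene_biased=biased, scene_unbiased=unbiased,
               proximity_biased=tab_b, proximity_unbiased=tab_u,
               spatial_fisher_p=p_fisher, spatial_comparison=comp)
    manifest.stage_info["spatial"] = {
        "proximal_biased": tab_b.n_proximal,
        "proximal_unbiased": tab_u.n_proximal,
        "fisher_p": p_fisher,
        "ks_p": comp["ks_p"],
    }


_STAGES = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "trajectory": _stage_trajectory,
    "archetypes": _stage_archetypes,
    "origin": _stage_origin,
    "grn": _stage_grn,
    "genesets": _stage_genesets,
    "mapping": _stage_mapping,
    "spatial": _stage_spatial,
}
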