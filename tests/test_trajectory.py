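"""OT couplings vs a dense log-domain oracle; paths, trends, growth."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from isletflow import trajectory as tj
from isletflow.datatypes import Embedding


def oracle_sinkhorn_log(x, y, epsilon, a=None, b=None, n_iter=50_000, tol=1e-13):
    """Independent dense log-domain balanced Sinkhorn (squared Euclidean)."""
    n, m = len(x), len(y)
    a = np.full(n, 1.0 / n) if a is None else a
    b = np.full(m, 1.0 / m) if b is None else b
    C = np.sum((x[:, None, :] - y[None, :, :]) ** 2, axis=2)
    M = -C / epsilon
    f = np.zeros(n)
    g = np.zeros(m)
    for _ in range(n_iter):
        f_new = epsilon * (np.log(a) - logsumexp(M + g[None, :] / epsilon, axis=1))
        g = epsilon * (np.log(b) - logsumexp(M + f_new[:, None] / epsilon, axis=0))
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    return np.exp(M + f[:, None] / epsilon + g[None, :] / epsilon)


class TestSinkhorn:
    def test_identity_limit_small_epsilon(self, rng):
        x = rng.normal(size=(12, 3)) * 5  # well-separated points
        pi, _ = tj.sinkhorn(x, x, epsilon=1e-3, mode="balanced")
        off = pi - np.diag(np.diag(pi))
        assert off.sum() < 1e-6
        np.testing.assert_allclose(np.diag(pi), 1.0 / 12, atol=1e-6)

    @pytest.mark.parametrize("n,m", [(3, 3), (7, 5), (10, 10)])
    def test_matches_dense_log_domain_oracle(self, rng, n, m):
        x = rng.normal(size=(n, 3))
        y = rng.normal(size=(m, 3)) + 0.5
        eps = 2.0  # comparable to the cost scale so the fixed point is sharp
        pi, _ = tj.sinkhorn(x, y, epsilon=eps, mode="balanced", tol=1e-10)
        pi_oracle = oracle_sinkhorn_log(x, y, eps)
        np.testing.assert_allclose(pi, pi_oracle, atol=1e-8)

    def test_mass_conservation_balanced(self, rng):
        x, y = rng.normal(size=(8, 2)), rng.normal(size=(9, 2))
        pi, _ = tj.sinkhorn(x, y, epsilon=0.2, mode="balanced")
        assert abs(pi.sum() - 1.0) < 1e-9

    def test_empty_input_error(self, rng):
        with pytest.raises(ValueError):
            tj.sinkhorn(np.empty((0, 2)), rng.normal(size=(3, 2)), epsilon=0.1)

    def test_bad_epsilon(self, rng):
        x = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            tj.sinkhorn(x, x, epsilon=0.0)


class TestFitCouplings:
    def test_duplicated_target_point_growth(self, rng):
        # one source point appears twice in the target -> its growth ~ 2
        src = np.array([[0.0, 0], [10, 0], [0, 10], [10, 10]])
        tgt = np.vstack([src, src[1:2]])  # point 1 duplicated
        cs, g = tj.fit_couplings([src, tgt], epsilon=0.05, alpha=2.0,
                                 mode="unbalanced")
        assert abs(g[1] - 2.0) < 0.2
        for i in (0, 2, 3):
            assert abs(g[i] - 1.0) < 0.1

    def test_growth_mean_tracks_mass_ratio(self, rng):
        src = rng.normal(size=(30, 3))
        tgt = np.vstack([src, src[:15]]) + 0.01 * rng.normal(size=(45, 3))
        cs, g = tj.fit_couplings([src, tgt], epsilon=0.1, alpha=2.0)
        assert abs(g.mean() - 45 / 30) < 0.05

    def test_too_few_conditions(self, rng):
        with pytest.raises(ValueError):
            tj.fit_couplings([rng.normal(size=(5, 2))])


class TestSamplePaths:
    def _identity_couplings(self, coords):
        n = coords.shape[0]
        cs = tj.CouplingSet(
            couplings=[np.eye(n) / n, np.eye(n) / n],
            coords=[coords, coords, coords],
            epsilon=0.1, alpha=2.0, mode="balanced",
        )
        return cs

    def test_identity_couplings_constant_paths(self, rng):
        coords = rng.normal(size=(6, 2))
        cs = self._identity_couplings(coords)
        ts = tj.sample_paths(cs, np.ones(6, dtype=bool), G=11, runs=2, seed=0)
        for r in range(2):
            for i in range(6):
                assert np.allclose(ts.paths[r, i], ts.paths[r, i, 0])

    def test_permutation_couplings_seed_independent(self, rng):
        coords = rng.normal(size=(5, 2))
        perm = np.roll(np.eye(5), 1, axis=1) / 5
        cs = tj.CouplingSet(
            couplings=[perm], coords=[coords, coords + 1],
            epsilon=0.1, alpha=2.0, mode="balanced",
        )
        t1 = tj.sample_paths(cs, np.ones(5, dtype=bool), G=11, seed=1)
        t2 = tj.sample_paths(cs, np.ones(5, dtype=bool), G=11, seed=99)
        np.testing.assert_array_equal(t1.paths, t2.paths)

    def test_planted_ancestry_recovered(self, rng):
        # cluster b at t=1 is the only ancestor of cluster B at t=3
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(20, 2)) + 50
        t1 = np.vstack([a, b])
        t2 = t1 + 0.1
        t3 = t1 + 0.2
        cs, _ = tj.fit_couplings([t1, t2, t3], epsilon=0.05, alpha=2.0)
        terminal = np.zeros(40, dtype=bool)
        terminal[20:] = True  # cluster B
        ts = tj.sample_paths(cs, terminal, G=31, runs=2, seed=3)
        assert np.all(ts.ancestor_indices[..., 0] >= 20)

    def test_empty_terminal_error(self, rng):
        coords = rng.normal(size=(4, 2))
        cs = self._identity_couplings(coords)
        with pytest.raises(ValueError):
            tj.sample_paths(cs, np.zeros(4, dtype=bool))

    def test_path_continuity_bound(self, rng):
        coords = [rng.normal(size=(8, 2)), rng.normal(size=(8, 2)) + 2]
        cs, _ = tj.fit_couplings(coords, epsilon=0.2)
        ts = tj.sample_paths(cs, np.ones(8, dtype=bool), G=51, seed=0)
        steps = np.linalg.norm(np.diff(ts.paths, axis=2), axis=3)
        seg_len = np.linalg.norm(ts.paths[:, :, -1] - ts.paths[:, :, 0], axis=2)
        assert np.all(steps.max(axis=2) <= seg_len / 50 + 1e-9)


def _decoder(n_genes, d, rng):
    return Embedding(
        coords=np.zeros((1, d)),
        loadings=rng.normal(size=(d, n_genes)),
        mean=np.abs(rng.normal(size=n_genes)) + 1,
        gene_names=np.array([f"g{i}" for i in range(n_genes)]),
        explained_variance=np.ones(d),
    )


class TestDecodeTrends:
    def test_constant_paths_constant_trends(self, rng):
        dec = _decoder(5, 3, rng)
        paths = np.tile(rng.normal(size=(1, 4, 1, 3)), (2, 1, 21, 1))
        ts = tj.TrajectorySet(paths, np.linspace(0, 1, 21), np.arange(4),
                              np.zeros((2, 4, 2), dtype=int), 0, 0.1, 2.0)
        gt = tj.decode_trends(ts, dec)
        assert np.allclose(gt.values, gt.values[:, :1])

    def test_two_identical_runs_equal_single_run(self, rng):
        dec = _decoder(4, 2, rng)
        one = rng.normal(size=(1, 3, 11, 2))
        both = np.concatenate([one, one], axis=0)
        grid = np.linspace(0, 1, 11)
        ts1 = tj.TrajectorySet(one, grid, np.arange(3),
                               np.zeros((1, 3, 2), dtype=int), 0, 0.1, 2.0)
        ts2 = tj.TrajectorySet(both, grid, np.arange(3),
                               np.zeros((2, 3, 2), dtype=int), 0, 0.1, 2.0)
        np.testing.assert_allclose(
            tj.decode_trends(ts1, dec).values, tj.decode_trends(ts2, dec).values
        )

    def test_unknown_gene_error(self, rng):
        dec = _decoder(3, 2, rng)
        ts = tj.TrajectorySet(np.zeros((1, 2, 5, 2)), np.linspace(0, 1, 5),
                              np.arange(2), np.zeros((1, 2, 2), dtype=int),
                              0, 0.1, 2.0)
        with pytest.raises(KeyError):
            tj.decode_trends(ts, dec, genes=["nope"])


class TestGrowthRobustness:
    def test_duplicate_alpha_perfect_correlation(self, rng):
        src = rng.normal(size=(25, 2))
        tgt = np.vstack([src, src[:10]]) + 0.05 * rng.normal(size=(35, 2))
        out = tj.growth_robustness([src, tgt], epsilon=0.1,
                                   alpha_grid=(2.0, 2.0))
        assert out["rho"][0, 1] == pytest.approx(1.0)

    def test_smooth_growth_field_rank_stable(self, rng):
        src = rng.normal(size=(40, 2))
        extra = src[np.argsort(src[:, 0])[-15:]]
        tgt = np.vstack([src, extra]) + 0.05 * rng.normal(size=(55, 2))
        out = tj.growth_robustness(
            [src, tgt], epsilon=0.1, alpha_grid=(0.01, 0.1, 1.0, 2.0, 10.0)
        )
        off = out["rho"][np.triu_indices(5, k=1)]
        assert np.nanmin(off) >= 0.8

    def test_degenerate_growth_reported_not_crash(self, rng):
        src = np.array([[0.0, 0.0], [8.0, 0.0]])
        out = tj.growth_robustness([src, src], epsilon=0.05,
                                   alpha_grid=(1.0, 2.0))
        assert "degenerate" in out
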