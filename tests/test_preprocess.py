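"""QC, normalization, HVG, smoothing, PCA decoder, clustering, DE."""

import numpy as np
import pandas as pd
import pytest

from isletflow.datatypes import CountMatrix, ExpressionMatrix
from isletflow import preprocess as pp


def _cm(counts, mito=None, condition=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    cell_meta = pd.DataFrame(
        {
            "condition": condition if condition is not None else np.ones(n, dtype=int),
            "batch": np.zeros(n, dtype=int),
        },
        index=[f"c{i}" for i in range(n)],
    )
    gene_meta = pd.DataFrame(
        {
            "mito": mito if mito is not None else np.zeros(g, dtype=bool),
            "tf": np.zeros(g, dtype=bool),
        },
        index=pd.Index([f"g{j}" for j in range(g)], name="gene"),
    )
    return CountMatrix(counts, cell_meta, gene_meta)


def _em(values):
    m = _cm(np.asarray(values, dtype=int))
    return ExpressionMatrix(np.asarray(values, float), m.cell_meta, m.gene_meta)


class TestQCFilter:
    def test_rare_gene_dropped(self):
        counts = np.array([[1, 5], [0, 5], [0, 5], [0, 5]])
        out, rep = pp.qc_filter(_cm(counts), min_cells=2, max_libsize=np.inf,
                                max_mito_pct=np.inf)
        assert out.n_genes == 1
        assert rep.genes_removed == 1

    def test_high_mito_cell_dropped(self):
        # 20 of 100 counts mitochondrial: 20% > 12.5% threshold
        counts = np.array([[20, 80], [5, 95]])
        mito = np.array([True, False])
        out, rep = pp.qc_filter(_cm(counts, mito=mito), min_cells=0,
                                max_libsize=np.inf, max_mito_pct=12.5)
        assert out.n_cells == 1
        assert rep.cells_removed_by_mito == 1

    def test_libsize_cap(self):
        counts = np.array([[10, 10], [9000, 9000]])
        out, rep = pp.qc_filter(_cm(counts), min_cells=0, max_libsize=15000,
                                max_mito_pct=np.inf)
        assert out.n_cells == 1
        assert rep.cells_removed_by_libsize == 1

    def test_disabled_thresholds_identity(self):
        counts = np.array([[1, 2], [3, 4]])
        out, rep = pp.qc_filter(_cm(counts), min_cells=0, max_libsize=np.inf,
                                max_mito_pct=np.inf)
        assert np.array_equal(out.counts, counts)
        assert rep.genes_removed == 0

    def test_idempotent(self, rng):
        counts = rng.poisson(2.0, size=(60, 30))
        mito = np.zeros(30, dtype=bool)
        mito[:3] = True
        once, _ = pp.qc_filter(_cm(counts, mito=mito), min_cells=5,
                               max_libsize=80, max_mito_pct=12.5)
        twice, rep2 = pp.qc_filter(once, min_cells=5, max_libsize=80,
                                   max_mito_pct=12.5)
        assert np.array_equal(once.counts, twice.counts)
        assert rep2.genes_removed == 0
        assert rep2.cells_removed_by_libsize == 0
        assert rep2.cells_removed_by_mito == 0

    def test_all_cells_removed_is_explicit_error(self):
        counts = np.array([[100, 100], [200, 200]])
        with pytest.raises(ValueError, match="all cells"):
            pp.qc_filter(_cm(counts), min_cells=0, max_libsize=10,
                         max_mito_pct=np.inf)


class TestNormalize:
    def test_worked_arithmetic(self):
        # cell [1, 3] with target 4: L1 step -> [1, 3], sqrt -> [1, sqrt(3)]
        out = pp.normalize(_cm(np.array([[1, 3]])), target_size=4)
        np.testing.assert_allclose(out.values[0], [1.0, np.sqrt(3)])

    def test_identical_cells_identical_rows(self):
        out = pp.normalize(_cm(np.array([[2, 4], [2, 4], [2, 4]])))
        assert np.allclose(out.values, out.values[0])

    def test_presqrt_rows_sum_to_target(self, rng):
        counts = rng.poisson(3.0, size=(50, 20)) + 1
        out = pp.normalize(_cm(counts), target_size=100.0)
        np.testing.assert_allclose((out.values**2).sum(axis=1), 100.0, atol=1e-9)

    def test_zero_cell_error_names_cell(self):
        counts = np.array([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            pp.normalize(_cm(counts))


class TestHVG:
    def test_high_variance_gene_selected_constant_never(self, rng):
        base = rng.poisson(5.0, size=(300, 30)).astype(float)
        # same mean (~5) as the others but ~10x their variance
        base[:, 0] = rng.gamma(shape=0.5, scale=10.0, size=300)
        base[:, 1] = 7.0  # constant
        idx = pp.select_hvg(_em(base))
        assert 0 in idx
        assert 1 not in idx

    def test_planted_bimodal_recovery(self, rng):
        # bimodal genes scattered across the mean range so each competes
        # against expression-matched unimodal genes in its bin
        n, g = 400, 60
        lam = rng.uniform(2.0, 25.0, size=g)
        lam[:12] = rng.uniform(2.0, 7.0, size=12)  # planted start low
        vals = rng.poisson(lam, size=(n, g)).astype(float)
        planted = np.arange(0, 12)
        for j in planted:
            hi = rng.random(n) < 0.5
            vals[hi, j] += 2.0 * lam[j]
        idx = set(pp.select_hvg(_em(vals)))
        recovered = len(idx & set(planted.tolist())) / len(planted)
        assert recovered >= 0.9


class TestSmooth:
    def test_t0_identity(self, rng):
        e = _em(rng.random((30, 5)))
        out = pp.smooth(e, k=5, t=0)
        np.testing.assert_array_equal(out.values, e.values)

    def test_no_cross_blob_mixing(self, rng):
        a = rng.normal(size=(40, 3)) * 0.1
        b = rng.normal(size=(40, 3)) * 0.1 + 100.0
        vals = np.abs(np.vstack([a, b]))
        marker = np.zeros((80, 1))
        marker[:40] = 1.0
        e = _em(np.hstack([vals, marker]))
        out = pp.smooth(e, k=5, t=3)
        assert np.all(out.values[:40, -1] > 1 - 1e-6)
        assert np.all(out.values[40:, -1] < 1e-6)

    def test_variance_never_increases(self, rng):
        e = _em(rng.random((60, 8)))
        out = pp.smooth(e, k=6, t=2)
        assert np.all(
            out.values.var(axis=0) <= e.values.var(axis=0) + 1e-12
        )

    def test_bad_k(self, rng):
        e = _em(rng.random((10, 3)))
        with pytest.raises(ValueError):
            pp.smooth(e, k=0)


class TestEmbedPCA:
    def test_planar_data_zero_reconstruction(self, rng):
        basis = rng.normal(size=(2, 6))
        coef = rng.normal(size=(40, 2))
        X = np.abs(coef @ basis + 10)
        emb = pp.embed_pca(_em(X), d=2)
        np.testing.assert_allclose(emb.decode(emb.coords), X, atol=1e-8)

    def test_truncation_error_bounded_by_discarded_eigenvalues(self, rng):
        X = np.abs(rng.normal(size=(80, 12)) + 5)
        e = _em(X)
        emb = pp.embed_pca(e, d=4)
        full = pp.embed_pca(e, d=12)
        recon_err = np.sum((emb.decode(emb.coords) - X) ** 2)
        discarded = np.sum(full.explained_variance[4:]) * (X.shape[0] - 1)
        np.testing.assert_allclose(recon_err, discarded, rtol=1e-6)

    def test_excluded_genes_decode_to_mean(self, rng):
        X = np.abs(rng.normal(size=(30, 5)) + 5)
        e = _em(X)
        emb = pp.embed_pca(e, d=2, exclude_genes=["g0"])
        decoded = emb.decode(emb.coords)
        np.testing.assert_allclose(decoded[:, 0], X[:, 0].mean())

    def test_decoder_exactly_linear(self, rng):
        X = np.abs(rng.normal(size=(30, 6)) + 5)
        emb = pp.embed_pca(_em(X), d=3)
        x, y = emb.coords[0], emb.coords[1]
        a, b = 0.3, 1.7
        lhs = emb.decode(a * x + b * y)
        rhs = a * emb.decode(x) + b * emb.decode(y) - (a + b - 1) * emb.mean
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        X = np.abs(rng.normal(size=(40, 7)) + 5)
        e1 = pp.embed_pca(_em(X), d=3)
        e2 = pp.embed_pca(_em(X), d=3)
        np.testing.assert_array_equal(e1.coords, e2.coords)
        for j in range(3):
            i_max = np.argmax(np.abs(e1.loadings[j]))
            assert e1.loadings[j, i_max] > 0


class TestKMeans:
    def test_separated_blobs_perfect_stability(self, rng):
        centers = np.array([[0, 0], [50, 0], [0, 50]])
        X = np.vstack([c + 0.1 * rng.normal(size=(30, 2)) for c in centers])
        emb = pp.embed_pca(_em(np.abs(X + 100)), d=2)
        labels, stability = pp.cluster_kmeans(emb, k=3, runs=5, seed=0)
        assert stability == pytest.approx(1.0)
        assert len(np.unique(labels)) == 3
        assert labels.shape == (90,)

    def test_bad_k(self, rng):
        emb = pp.embed_pca(_em(np.abs(rng.normal(size=(20, 4)) + 5)), d=2)
        with pytest.raises(ValueError):
            pp.cluster_kmeans(emb, k=1)


class TestDEGWilcoxon:
    def test_null_type_one_error_controlled(self, rng):
        vals = rng.poisson(5.0, size=(200, 300)).astype(float)
        group = np.zeros(200, dtype=bool)
        group[rng.choice(200, 100, replace=False)] = True
        table = pp.deg_wilcoxon(_em(vals), group)
        assert table["significant"].mean() <= 0.05

    def test_strong_upregulation_flagged(self, rng):
        vals = rng.poisson(5.0, size=(200, 20)).astype(float)
        group = np.arange(200) < 100
        vals[group, 0] *= 4.0
        table = pp.deg_wilcoxon(_em(vals), group)
        assert bool(table["significant"].iloc[0])

    def test_downregulated_gene_not_flagged(self, rng):
        vals = rng.poisson(5.0, size=(200, 20)).astype(float)
        group = np.arange(200) < 100
        vals[group, 0] *= 0.1  # strongly down in the group
        table = pp.deg_wilcoxon(_em(vals), group)
        assert table["p"].iloc[0] < 1e-6
        assert not bool(table["significant"].iloc[0])

    def test_degenerate_group_error(self, rng):
        vals = rng.poisson(5.0, size=(10, 5)).astype(float)
        with pytest.raises(ValueError):
            pp.deg_wilcoxon(_em(vals), np.ones(10, dtype=bool))
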