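"""Granger scoring vs an independently coded OLS oracle; network rules."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx
from scipy import stats

from isletflow import grn
from isletflow.synth import gen_trend_pair
from isletflow.trajectory import GeneTrend


def oracle_granger_p(x, y, L, statistic="ssr"):
    """Two-regression chi-square Granger test, coded independently.

    Normal-equation solves (vs lstsq in the implementation); ssr statistic
    n * (RSS_r - RSS_u) / RSS_u or corrected-LR
    (n - 2L - 1) * log(RSS_r / RSS_u), both ~ chi2(L).
    """
    G = len(x)
    yt = y[L:]
    n = len(yt)

    def design(series_list):
        cols = [np.ones(n)]
        for s in series_list:
            for j in range(1, L + 1):
                cols.append(s[L - j:G - j])
        return np.column_stack(cols)

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ yt)
        r = yt - X @ beta
        return r @ r

    rss_r = rss(design([y]))
    rss_u = rss(design([y, x]))
    if statistic == "ssr":
        stat = n * (rss_r - rss_u) / rss_u
    else:
        stat = (n - 2 * L - 1) * np.log(rss_r / rss_u)
    return stats.chi2.sf(max(stat, 0.0), df=L)


def _trend_obj(series_dict, G=101):
    genes = np.array(list(series_dict))
    values = np.stack([series_dict[g] for g in genes])
    return GeneTrend(values=values, genes=genes,
                     s_grid=np.linspace(0, 1, values.shape[1]),
                     clipped_fraction=0.0)


class TestGrangerScore:
    def test_p_one_gives_zero_score(self):
        res = grn.GrangerResult("a", "b", 10, 1.0, 1, 0.0)
        assert res.score == 0.0
        # constant series: degenerate, score exactly 0
        out = grn.granger_score(np.ones(101), np.arange(101.0), L=10)
        assert out.degenerate and out.score == 0.0

    def test_exact_lag_copy_hits_floor_with_positive_sign(self):
        tf, target = gen_trend_pair(101, lag=10, effect=1.0, noise_sd=0.0,
                                    seed=4)
        res = grn.granger_score(tf, target, L=10)
        assert res.floored
        assert res.score == pytest.approx(-np.log(1e-300))
        assert res.sign == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("statistic", ["ssr", "lr"])
    def test_matches_independent_oracle(self, seed, statistic):
        tf, target = gen_trend_pair(101, lag=10, effect=0.5, noise_sd=0.3,
                                    seed=seed)
        res = grn.granger_score(tf, target, L=10, statistic=statistic)
        p_oracle = oracle_granger_p(tf, target, 10, statistic=statistic)
        assert res.p == pytest.approx(p_oracle, abs=1e-10)

    def test_matches_statsmodels_ssr_chi2(self):
        from statsmodels.tsa.stattools import grangercausalitytests
        tf, target = gen_trend_pair(101, lag=5, effect=0.4, noise_sd=0.5,
                                    seed=9)
        res = grn.granger_score(tf, target, L=5)
        data = np.column_stack([target, tf])
        sm_out = grangercausalitytests(data, maxlag=[5])
        p_sm = sm_out[5][0]["ssr_chi2test"][1]
        assert res.p == pytest.approx(p_sm, rel=1e-8)

    def test_anticorrelated_driver_flips_sign_same_p(self):
        tf, target = gen_trend_pair(101, lag=10, effect=0.8, noise_sd=0.1,
                                    seed=5)
        pos = grn.granger_score(tf, target, L=10)
        neg = grn.granger_score(-tf, target, L=10)
        assert neg.p == pytest.approx(pos.p, rel=1e-9)
        assert neg.sign == -pos.sign

    def test_short_series_error(self):
        with pytest.raises(ValueError):
            grn.granger_score(np.arange(20.0), np.arange(20.0), L=10)


class TestScoreAll:
    def test_bookkeeping_self_pairs_excluded(self, rng):
        trends = _trend_obj({
            "tf1": rng.normal(size=101), "tf2": rng.normal(size=101),
            "g1": rng.normal(size=101),
        })
        df = grn.score_all(trends, ["tf1", "tf2", "absent"], L=10)
        assert df.shape == (2, 3)
        assert np.isnan(df.loc["tf1", "tf1"])
        assert df.attrs["skipped"] == ["absent"]

    def test_gene_order_equivariance(self, rng):
        series = {f"g{i}": rng.normal(size=101) for i in range(4)}
        a = grn.score_all(_trend_obj(series), ["g0"], L=10)
        rev = {k: series[k] for k in reversed(list(series))}
        b = grn.score_all(_trend_obj(rev), ["g0"], L=10)
        for g in series:
            if g == "g0":
                continue
            assert a.loc["g0", g] == pytest.approx(b.loc["g0", g], rel=1e-12)


class TestBuildNetwork:
    def _prior(self, pairs):
        return pd.DataFrame(
            [{"tf": a, "target": b, "mode": "activation"} for a, b in pairs]
        )

    def test_infinite_threshold_empty_network(self, rng):
        scores = pd.DataFrame([[40.0, 50.0]], index=["tf1"],
                              columns=["a", "b"])
        g = grn.build_network(scores, self._prior([("tf1", "a"), ("tf1", "b")]),
                              min_neglogp=np.inf)
        assert g.number_of_edges() == 0

    def test_high_score_absent_from_prior_excluded(self):
        scores = pd.DataFrame([[500.0, 400.0]], index=["tf1"],
                              columns=["a", "b"])
        g = grn.build_network(scores, self._prior([("tf1", "a")]))
        assert g.has_edge("tf1", "a")
        assert not g.has_edge("tf1", "b")

    def test_output_subset_of_prior_and_top_tfs(self, rng):
        tfs = [f"tf{i}" for i in range(30)]
        genes = [f"g{i}" for i in range(50)]
        scores = pd.DataFrame(rng.normal(scale=20, size=(30, 50)),
                              index=tfs, columns=genes)
        prior_pairs = [(t, g) for t in tfs[:10] for g in genes[:10]]
        prior = self._prior(prior_pairs)
        net = grn.build_network(scores, prior, top_n_tfs=5, min_neglogp=10.0)
        strength = scores.abs().max(axis=1)
        top5 = set(strength.sort_values(ascending=False).head(5).index)
        for u, v in net.edges:
            assert (u, v) in set(prior_pairs)
            assert u in top5
            assert abs(scores.loc[u, v]) > 10.0

    def test_empty_prior_error(self):
        scores = pd.DataFrame([[1.0]], index=["tf1"], columns=["a"])
        with pytest.raises(ValueError):
            grn.build_network(scores, pd.DataFrame())


class TestIncreasingSubnetwork:
    def _net(self, edges):
        g = nx.DiGraph()
        for u, v in edges:
            g.add_edge(u, v, score=30.0, neglogp=30.0, sign=1)
        return g

    def test_all_decreasing_empty(self):
        g = self._net([("a", "b")])
        sub = grn.increasing_subnetwork(g, {"a": "decreasing", "b": "decreasing"})
        assert sub.number_of_edges() == 0

    def test_largest_component_flagged(self):
        # components of size 5 (a-chain) and 3 (x-chain)
        g = self._net([("a1", "a2"), ("a2", "a3"), ("a3", "a4"), ("a4", "a5"),
                       ("x1", "x2"), ("x2", "x3")])
        clusters = {n: "increasing" for n in g.nodes}
        sub = grn.increasing_subnetwork(g, clusters)
        in_largest = {n for n in sub.nodes if sub.nodes[n]["in_largest_component"]}
        assert in_largest == {"a1", "a2", "a3", "a4", "a5"}

    def test_components_match_union_find_oracle(self, rng):
        nodes = [f"n{i}" for i in range(40)]
        edges = [
            (nodes[rng.integers(40)], nodes[rng.integers(40)])
            for _ in range(30)
        ]
        edges = [(u, v) for u, v in edges if u != v]
        g = self._net(edges)
        clusters = {n: "increasing" for n in g.nodes}
        sub = grn.increasing_subnetwork(g, clusters)

        # union-find oracle over the undirected edge set
        parent = {n: n for n in sub.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in sub.edges:
            parent[find(u)] = find(v)
        comps = {}
        for n in sub.nodes:
            comps.setdefault(find(n), set()).add(n)
        expected = max(comps.values(), key=len) if comps else set()
        flagged = {n for n in sub.nodes if sub.nodes[n]["in_largest_component"]}
        assert flagged == expected

    def test_missing_cluster_label_error(self):
        g = self._net([("a", "b")])
        with pytest.raises(ValueError):
            grn.increasing_subnetwork(g, {"a": "increasing"})


class TestCalibration:
    def test_corrected_lr_type_one_error_in_band(self):
        """The calibrated variant controls size on white-noise nulls."""
        rng = np.random.default_rng(77)
        hits = 0
        n_pairs = 400
        for _ in range(n_pairs):
            x = rng.normal(size=101)
            y = rng.normal(size=101)
            if grn.granger_score(x, y, L=10, statistic="lr").p < 0.05:
                hits += 1
        assert 0.02 <= hits / n_pairs <= 0.08

    def test_default_ssr_is_anticonservative_but_score_threshold_screens(self):
        """The classic ssr statistic over-rejects at nominal alpha, yet
        white-noise nulls essentially never clear the -log p > 25 bar."""
        rng = np.random.default_rng(78)
        alpha_hits, thr_hits = 0, 0
        for _ in range(300):
            x = rng.normal(size=101)
            y = rng.normal(size=101)
            res = grn.granger_score(x, y, L=10)
            alpha_hits += res.p < 0.05
            thr_hits += abs(res.score) > 25
        assert alpha_hits / 300 > 0.10  # documented inflation
        assert thr_hits == 0

    def test_power_for_planted_effect(self):
        hits = 0
        for seed in range(50):
            tf, target = gen_trend_pair(101, lag=10, effect=0.8,
                                        noise_sd=0.1, seed=seed)
            if grn.granger_score(tf, target, L=10).p < 0.001:
                hits += 1
        assert hits / 50 >= 0.9
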