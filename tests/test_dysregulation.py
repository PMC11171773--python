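import math

import numpy as np
import pytest
from scipy import stats as sps

from tcsignal.dysregulation import (DriverConfig, EdgeDysregulation,
                                    aggregate_gene, augment_with_mean_group,
                                    build_cloud, edge_kld, empirical_pvalue,
                                    null_kld_distribution, regularize_cloud,
                                    run_driver_analysis, _kld_pair)
from tcsignal.pkn import Edge, KnowledgeNetwork, Mechanism

from conftest import make_series, simple_net


class TestAugmentation:
    def test_two_replicates_appends_mean(self, rng):
        vals = rng.normal(10, 1, (3, 4))
        series = make_series(vals, ["T1", "T2"], 2)
        a1, a2 = augment_with_mean_group(series, ("T1", "T2"))
        assert a1.shape == (3, 3) and a2.shape == (3, 3)
        assert np.allclose(a1[:, 2], vals[:, :2].mean(axis=1))
        assert np.allclose(a2[:, 2], vals[:, 2:].mean(axis=1))

    def test_single_replicate_reaches_three_points(self):
        series = make_series([[4.0, 8.0]], ["T1", "T2"], 1)
        a1, a2 = augment_with_mean_group(series, ("T1", "T2"))
        assert a1.shape == (1, 3) and a2.shape == (1, 3)
        # mean of a singleton is itself; midpoint of the pair completes the three
        assert list(a1[0]) == [4.0, 4.0, 6.0]
        assert list(a2[0]) == [8.0, 8.0, 6.0]

    def test_five_replicates_mean_is_sixth(self, rng):
        vals = rng.normal(0, 1, (2, 10))
        series = make_series(vals, ["T1", "T2"], 5)
        a1, _ = augment_with_mean_group(series, ("T1", "T2"))
        assert a1.shape == (2, 6)
        assert np.allclose(a1[:, :5].mean(axis=1), a1[:, 5])


class TestRegularize:
    def test_collinear_points_get_full_rank(self, rng):
        x = np.linspace(0, 1, 4)
        cloud = build_cloud(("a", "b"), x, 2 * x, x + 0.5, 2 * (x + 0.5))
        out = regularize_cloud(cloud, rng=rng)
        cov = np.cov(np.vstack([out.points1, out.points2]), rowvar=False)
        assert np.linalg.matrix_rank(cov, tol=1e-12) == 2

    def test_well_conditioned_cloud_unchanged(self, rng):
        p = rng.normal(0, 1, (4, 2))
        q = rng.normal(0, 1, (4, 2))
        cloud = build_cloud(("a", "b"), p[:, 0], p[:, 1], q[:, 0], q[:, 1])
        out = regularize_cloud(cloud, rng=rng)
        assert out is cloud

    def test_identical_points_deterministic_under_seed(self):
        x = np.full(4, 3.0)
        cloud = build_cloud(("a", "b"), x, x, x, x)
        a = regularize_cloud(cloud, rng=np.random.default_rng(7))
        b = regularize_cloud(cloud, rng=np.random.default_rng(7))
        assert np.array_equal(a.points1, b.points1)
        cov = np.cov(np.vstack([a.points1, a.points2]), rowvar=False)
        assert np.linalg.matrix_rank(cov, tol=1e-30) == 2


class TestEdgeKLD:
    def test_identical_groups_zero(self, rng):
        p = rng.normal(0, 1, (5, 2))
        cloud = build_cloud(("a", "b"), p[:, 0], p[:, 1], p[:, 0], p[:, 1])
        assert edge_kld(cloud) == 0.0

    def test_symmetric_under_group_swap_bit_exact(self, rng):
        p = rng.normal(0, 1, (4, 2))
        q = rng.normal(1, 1, (4, 2))
        fwd = build_cloud(("a", "b"), p[:, 0], p[:, 1], q[:, 0], q[:, 1])
        rev = build_cloud(("a", "b"), q[:, 0], q[:, 1], p[:, 0], p[:, 1])
        assert edge_kld(fwd) == edge_kld(rev)

    def test_nonnegative_on_random_clouds(self, rng):
        for _ in range(20):
            p = rng.normal(0, 1, (4, 2))
            q = rng.normal(rng.normal(0, 2), 1, (4, 2))
            cloud = build_cloud(("a", "b"), p[:, 0], p[:, 1], q[:, 0], q[:, 1])
            assert edge_kld(cloud) >= 0.0

    def test_matches_fine_grid_numerical_oracle(self):
        # separated Gaussian clouds; oracle recodes the mixture densities and
        # the discretized symmetric KLD independently on a finer grid
        rng = np.random.default_rng(42)
        sig = 0.5
        x1, y1 = rng.normal(0, sig, 8), rng.normal(0, sig, 8)
        x2, y2 = rng.normal(5 * sig, sig, 8), rng.normal(0, sig, 8)
        cfg = DriverConfig(grid="regular", grid_bins=81, grid_pad=3.0)
        impl = _kld_pair(x1, y1, x2, y2, cfg, np.random.default_rng(0))

        p1 = np.column_stack([x1, y1])
        p2 = np.column_stack([x2, y2])
        pooled = np.vstack([p1, p2])
        M = len(pooled)

        def silverman(v):
            a = min(v.std(ddof=1), np.subtract(*np.percentile(v, [75, 25])) / 1.349)
            return 0.9 * a * M ** -0.2

        hx, hy = silverman(pooled[:, 0]), silverman(pooled[:, 1])
        gx = np.linspace(pooled[:, 0].min() - 3 * hx, pooled[:, 0].max() + 3 * hx, 201)
        gy = np.linspace(pooled[:, 1].min() - 3 * hy, pooled[:, 1].max() + 3 * hy, 201)
        gxx, gyy = np.meshgrid(gx, gy, indexing="ij")

        def density(pts):
            d = np.zeros_like(gxx)
            for cx, cy in pts:
                d += np.exp(-0.5 * ((gxx - cx) / hx) ** 2 - 0.5 * ((gyy - cy) / hy) ** 2)
            d /= len(pts) * 2 * np.pi * hx * hy
            d = np.maximum(d, 1e-12)
            return d / d.sum()

        d1, d2 = density(p1), density(p2)
        oracle = 0.5 * ((d1 * np.log(d1 / d2)).sum() + (d2 * np.log(d2 / d1)).sum())
        assert impl == pytest.approx(oracle, rel=0.05)


class TestEmpiricalPvalue:
    def test_observed_above_all(self):
        null = list(range(1000))
        assert empirical_pvalue(1e9, null) == pytest.approx(1 / 1001)

    def test_observed_below_all(self):
        assert empirical_pvalue(-1.0, [1.0, 2.0, 3.0]) == 1.0

    def test_tie_at_median_brute_force(self, rng):
        null = rng.normal(0, 1, 999)
        obs = float(np.median(null))
        expected = (1 + int(sum(1 for v in null if v >= obs))) / (1 + len(null))
        assert empirical_pvalue(obs, null) == pytest.approx(expected)
        assert expected == pytest.approx((1 + 500) / 1000)


class TestAggregateGene:
    def _edges(self, pvals):
        return [EdgeDysregulation(("g", f"p{i}"), 1.0, p) for i, p in enumerate(pvals)]

    def test_all_p_one_gives_p_one(self):
        out = aggregate_gene("g", self._edges([1.0, 1.0, 1.0]))
        assert out.chi2 == 0.0 and out.p == pytest.approx(1.0)

    def test_single_edge_reduces_to_edge_p(self):
        out = aggregate_gene("g", self._edges([0.05]))
        assert out.chi2 == pytest.approx(-2 * math.log(0.05))
        assert out.df == 2
        assert out.p == pytest.approx(0.05, rel=1e-12)

    def test_two_independent_edges_chi2_df4(self):
        out = aggregate_gene("g", self._edges([0.1, 0.2]), np.eye(2))
        expected = sps.chi2.sf(-2 * (math.log(0.1) + math.log(0.2)), 4)
        assert out.df == pytest.approx(4)
        assert out.p == pytest.approx(expected, rel=1e-12)

    def test_positive_correlation_reduces_df(self):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        out = aggregate_gene("g", self._edges([0.1, 0.2]), corr)
        assert out.df < 4

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            aggregate_gene("g", self._edges([0.0]))


class TestNull:
    def _setup(self, rng):
        net = simple_net([("a", "b"), ("c", "d")])
        for extra in "efgh":
            net.ensure_node(extra)
        vals = rng.normal(10, 0.3, (8, 6))
        series = make_series(vals, ["T1", "T2"], 3,
                             genes=list("abcdefgh"))
        return net, series

    def test_deterministic_under_seed(self, rng):
        net, series = self._setup(rng)
        a = null_kld_distribution(series, ("T1", "T2"), net, n_draws=50, seed=3)
        b = null_kld_distribution(series, ("T1", "T2"), net, n_draws=50, seed=3)
        assert np.array_equal(a, b)

    def test_excludes_adjacent_pairs_and_warns_when_scarce(self, caplog):
        net = simple_net([("a", "b")])
        net.ensure_node("c")
        vals = np.random.default_rng(0).normal(10, 0.3, (3, 4))
        series = make_series(vals, ["T1", "T2"], 2, genes=list("abc"))
        with caplog.at_level("WARNING"):
            out = null_kld_distribution(series, ("T1", "T2"), net, n_draws=10, seed=1)
        assert len(out) == 10  # only pairs (a,c),(b,c): replacement sampling
        assert any("replacement" in r.message for r in caplog.records)

    def test_complete_graph_has_no_null_pairs(self, rng):
        net = simple_net([("a", "b"), ("b", "c"), ("a", "c")])
        vals = rng.normal(10, 0.3, (3, 4))
        series = make_series(vals, ["T1", "T2"], 2, genes=list("abc"))
        with pytest.raises(ValueError, match="no null pairs"):
            null_kld_distribution(series, ("T1", "T2"), net, n_draws=5, seed=1)


class TestRunDriverAnalysis:
    def test_empty_network_empty_result(self, rng):
        net = KnowledgeNetwork()
        series = make_series(rng.normal(10, 0.3, (3, 4)), ["T1", "T2"], 2,
                             genes=list("abc"))
        out = run_driver_analysis(series, ("T1", "T2"), net)
        assert out.genes == []

    def test_deterministic_ranking_under_seed(self, rng):
        net = simple_net([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
                          ("e", "f"), ("a", "d"), ("b", "e")])
        vals = rng.normal(10, 0.3, (6, 6))
        vals[0, 3:] += 2.0
        series = make_series(vals, ["T1", "T2"], 3, genes=list("abcdef"))
        cfg = DriverConfig(null_draws=100, seed=9)
        r1 = run_driver_analysis(series, ("T1", "T2"), net, cfg)
        r2 = run_driver_analysis(series, ("T1", "T2"), net, cfg)
        assert [(g.gene, g.p) for g in r1.genes] == [(g.gene, g.p) for g in r2.genes]

    def test_perturbed_gene_ranks_first(self, rng):
        # star around "hub" plus background chain; hub's expression steps
        edges = [("hub", f"t{i}") for i in range(6)]
        edges += [(f"t{i}", f"u{i}") for i in range(6)]
        net = simple_net(edges)
        for i in range(10):
            net.ensure_node(f"bg{i}")
        genes = sorted(net.node_ids())
        vals = rng.normal(10, 0.3, (len(genes), 6))
        vals[genes.index("hub"), 3:] += 2.5
        series = make_series(vals, ["T1", "T2"], 3, genes=genes)
        cfg = DriverConfig(null_draws=300, seed=4)
        out = run_driver_analysis(series, ("T1", "T2"), net, cfg)
        assert out.genes[0].gene == "hub"
        assert out.genes[0].is_driver
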