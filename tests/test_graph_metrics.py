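import networkx as nx
import numpy as np
import pytest

import oracles
from connectoperm import ValidationError, auc_over_densities, binarize_at_density
from connectoperm.graph_metrics import (
    DensityGrid,
    edge_count,
    global_metric_curves,
    global_metrics,
    nested_binarize,
    nodal_metrics,
    random_null_metrics,
    rewired_null,
)


def adjacency(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return a


K4 = adjacency(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
P3 = adjacency(3, [(0, 1), (1, 2)])
TRIANGLE_PENDANT = adjacency(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
STAR4 = adjacency(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
STAR3 = adjacency(4, [(0, 1), (0, 2), (0, 3)])


class TestDensityGrid:
    def test_default_grid_is_10_to_34_percent(self):
        grid = DensityGrid()
        assert len(grid) == 25
        np.testing.assert_allclose(grid.densities, np.arange(10, 35) / 100)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValidationError):
            DensityGrid((10, 10, 12))


class TestBinarize:
    def test_lowest_density_keeps_global_max(self, rng):
        z = rng.standard_normal((5, 5))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        adj = binarize_at_density(z, 0.10)
        assert adj.sum() // 2 == 1
        iu, ju = np.triu_indices(5, 1)
        i, j = np.unravel_index(np.argmax(np.where(np.triu(np.ones_like(z), 1), z, -np.inf)), z.shape)
        assert adj[i, j]

    def test_schaefer_scale_edge_count(self):
        assert edge_count(400, 0.34) == 27_132

    def test_all_equal_ties_take_lexicographic_first(self):
        z = np.ones((5, 5))
        np.fill_diagonal(z, 0)
        adj = binarize_at_density(z, 0.30)  # k = 3 of 10 edges
        iu, ju = np.triu_indices(5, 1)
        kept = [(i, j) for i, j in zip(iu, ju) if adj[i, j]]
        assert kept == [(0, 1), (0, 2), (0, 3)]

    def test_signed_thresholding_prefers_positive(self):
        z = np.zeros((4, 4))
        z[0, 1] = z[1, 0] = 0.3
        z[2, 3] = z[3, 2] = -0.9  # large magnitude but negative
        adj = binarize_at_density(z, 1 / 6)  # keep 1 of 6 edges
        assert adj[0, 1] and not adj[2, 3]

    def test_nested_graphs(self, rng):
        z = rng.standard_normal((12, 12))
        z = (z + z.T) / 2
        graphs = nested_binarize(z, DensityGrid((10, 20, 30)))
        for lo, hi in zip(graphs, graphs[1:]):
            assert np.all(hi[lo])  # every edge of the sparser graph persists

    def test_zero_edges_rejected(self):
        with pytest.raises(ValidationError):
            binarize_at_density(np.zeros((4, 4)), 0.01)


class TestClosedForms:
    def test_complete_k4(self):
        m = global_metrics(K4)
        assert m["C_P"] == 1.0
        assert m["L_P"] == 1.0
        assert m["E_glob"] == 1.0
        assert m["E_loc"] == 1.0

    def test_path_p3(self):
        m = global_metrics(P3)
        assert m["L_P"] == pytest.approx(4 / 3)
        assert m["E_glob"] == pytest.approx(5 / 6)

    def test_triangle_plus_pendant_clustering(self):
        # local clustering by node: 1/3, 1, 1, 0 -> mean 7/12
        assert global_metrics(TRIANGLE_PENDANT)["C_P"] == pytest.approx(7 / 12)

    def test_star_assortativity_minus_one(self):
        assert global_metrics(STAR3)["assortativity"] == pytest.approx(-1.0)

    def test_regular_graph_assortativity_is_nan(self):
        ring = adjacency(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert np.isnan(global_metrics(ring)["assortativity"])

    def test_star_center_nodal(self):
        m = nodal_metrics(STAR4)
        assert m["degree"][0] == 4
        assert m["betweenness"][0] == pytest.approx(6.0)  # all C(4,2) leaf pairs
        assert np.all(m["betweenness"][1:] == 0)

    def test_p3_end_node_efficiency(self):
        m = nodal_metrics(P3)
        assert m["nodal_efficiency"][0] == pytest.approx((1 + 0.5) / 2)

    def test_k4_nodal_efficiency_one(self):
        assert np.all(nodal_metrics(K4)["nodal_efficiency"] == 1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_and_networkx(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        adj = oracles.random_adjacency(rng, n, rng.uniform(0.2, 0.7))
        m = global_metrics(adj)
        nm = nodal_metrics(adj)
        assert m["C_P"] == pytest.approx(oracles.bf_mean_clustering(adj), abs=1e-12)
        assert m["L_P"] == pytest.approx(oracles.bf_char_path(adj), abs=1e-12, nan_ok=True)
        assert m["E_glob"] == pytest.approx(oracles.bf_global_efficiency(adj), abs=1e-12)
        assert m["E_loc"] == pytest.approx(oracles.bf_local_efficiency(adj), abs=1e-12)
        if np.isnan(m["assortativity"]):
            assert np.isnan(oracles.bf_assortativity(adj))
        else:
            assert m["assortativity"] == pytest.approx(
                oracles.bf_assortativity(adj), abs=1e-12
            )
        np.testing.assert_allclose(nm["degree"], oracles.bf_degree(adj), atol=0)
        np.testing.assert_allclose(
            nm["betweenness"], oracles.bf_betweenness(adj), atol=1e-9
        )
        np.testing.assert_allclose(
            nm["nodal_efficiency"], oracles.bf_nodal_efficiency(adj), atol=1e-12
        )
        # independent library cross-check
        g = nx.from_numpy_array(adj)
        assert m["C_P"] == pytest.approx(nx.average_clustering(g), abs=1e-12)
        nx_bc = nx.betweenness_centrality(g, normalized=False)
        np.testing.assert_allclose(
            nm["betweenness"], [nx_bc[i] for i in range(n)], atol=1e-9
        )


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        adj = oracles.random_adjacency(rng, 15, 0.3)
        null = rewired_null(adj, seed=4)
        np.testing.assert_array_equal(adj.sum(axis=1), null.sum(axis=1))
        assert not np.any(np.diag(null))

    def test_complete_graph_is_fixed_point(self):
        k5 = ~np.eye(5, dtype=bool)
        cp_rand, lp_rand = random_null_metrics(k5, n_null=3, seed=0)
        assert cp_rand == 1.0 and lp_rand == 1.0

    def test_seeded_determinism(self, rng):
        adj = oracles.random_adjacency(rng, 15, 0.3)
        assert random_null_metrics(adj, 5, seed=9) == random_null_metrics(adj, 5, seed=9)

    def test_rewiring_actually_changes_edges(self, rng):
        adj = oracles.random_adjacency(rng, 20, 0.3)
        null = rewired_null(adj, seed=1)
        assert np.any(adj != null)

    def test_too_few_edges_rejected(self):
        single = adjacency(4, [(0, 1)])
        with pytest.raises(ValidationError):
            random_null_metrics(single, 2, seed=0)


class TestAUC:
    def test_constant_metric_rectangle(self):
        grid = DensityGrid()
        assert auc_over_densities(np.full(25, 2.0), grid.densities) == pytest.approx(0.48)

    def test_linear_metric_exact_integral(self):
        grid = DensityGrid()
        d = grid.densities
        assert auc_over_densities(d, d) == pytest.approx((0.34**2 - 0.10**2) / 2)

    def test_single_point_rejected(self):
        with pytest.raises(ValidationError):
            auc_over_densities(np.array([1.0]), np.array([0.1]))

    def test_nan_excluded_pairwise(self):
        d = np.array([0.1, 0.2, 0.3])
        vals = np.array([1.0, np.nan, 1.0])
        assert auc_over_densities(vals, d) == pytest.approx(0.2)


class TestCurves:
    def test_sigma_is_gamma_over_lambda(self, small_fcs):
        fcs, _ = small_fcs
        curves = global_metric_curves(fcs[0].z, DensityGrid((15, 25, 34)), n_null=5, seed=3)
        np.testing.assert_allclose(
            curves["sigma"], curves["gamma"] / curves["lambda"], rtol=1e-12
        )

    def test_e_glob_nondecreasing_in_density(self, small_fcs):
        fcs, _ = small_fcs
        curves = global_metric_curves(fcs[0].z, DensityGrid(tuple(range(10, 35, 4))), n_null=1, seed=0)
        eg = curves["E_glob"].to_numpy()
        assert np.all(np.diff(eg) >= -1e-12)

    def test_relabeling_invariance(self, rng):
        adj = oracles.random_adjacency(rng, 10, 0.4)
        perm = rng.permutation(10)
        permuted = adj[np.ix_(perm, perm)]
        m1, m2 = global_metrics(adj), global_metrics(permuted)
        for key in ("C_P", "L_P", "E_glob", "E_loc", "assortativity"):
            if np.isnan(m1[key]):
                assert np.isnan(m2[key])
            else:
                assert m1[key] == pytest.approx(m2[key], abs=1e-12)
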