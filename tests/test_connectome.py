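"""Nodal graph metrics against hand enumerations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from braingut.connectome import (
    FiberConnectivity,
    WeightedNetwork,
    average_path_length,
    betweenness_centrality,
    build_weighted_network,
    compute_node_metrics,
    eigenvector_centrality,
    flatten_metrics,
    node_strength,
)
from conftest import make_network
from _oracles import (
    avg_path_length_exhaustive,
    betweenness_exhaustive,
    random_symmetric_weights,
)


def fibers(counts, volumes):
    counts = np.asarray(counts)
    return FiberConnectivity(
        counts=counts,
        volumes=np.asarray(volumes, dtype=float),
        region_names=[f"r{i}" for i in range(counts.shape[0])],
    )


class TestBuildWeightedNetwork:
    def test_sum_of_volumes_convention(self):
        f = fibers([[0, 10], [10, 0]], [2, 3])
        net = build_weighted_network(f)
        assert net.weights[0, 1] == pytest.approx(2.0)

    def test_zero_count_gives_zero_weight_and_symmetry(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 20, size=(5, 5))
        c = np.triu(c, 1)
        c[0, 1] = 0
        c = c + c.T
        net = build_weighted_network(fibers(c, rng.uniform(1, 5, 5)))
        assert net.weights[0, 1] == 0.0
        assert np.array_equal(net.weights, net.weights.T)

    def test_alternative_conventions(self):
        f = fibers([[0, 12], [12, 0]], [2, 3])
        assert build_weighted_network(f, "mean").weights[0, 1] == pytest.approx(12 / 2.5)
        assert build_weighted_network(f, "product").weights[0, 1] == pytest.approx(2.0)
        with pytest.raises(ValueError, match="convention"):
            build_weighted_network(f, "max")

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            FiberConnectivity(np.array([[0, 1], [2, 0]]), np.ones(2), ["a", "b"])
        with pytest.raises(ValueError, match="positive"):
            fibers([[0, 1], [1, 0]], [1.0, 0.0])
        with pytest.raises(ValueError, match="diagonal"):
            fibers([[2, 1], [1, 0]], [1.0, 1.0])


class TestNodeStrength:
    def test_star_and_isolated(self):
        W = np.zeros((5, 5))
        W[0, 1:4] = W[1:4, 0] = 1.0  # star on 4 nodes, node 4 isolated
        s = node_strength(make_network(W))
        assert s.iloc[0] == pytest.approx(3.0)
        assert list(s.iloc[1:4]) == pytest.approx([1.0, 1.0, 1.0])
        assert s.iloc[4] == 0.0

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(3)
        W = random_symmetric_weights(6, 0.6, rng)
        s = node_strength(make_network(W))
        expected = [W[i].sum() for i in range(6)]  # independent row summation
        assert list(s) == pytest.approx(expected)


class TestBetweenness:
    def test_three_node_path(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        b = betweenness_centrality(make_network(W))
        assert list(b) == pytest.approx([0.0, 1.0, 0.0])

    def test_complete_graph_is_zero(self):
        W = np.ones((5, 5)) - np.eye(5)
        assert list(betweenness_centrality(make_network(W))) == pytest.approx([0.0] * 5)

    def test_requires_three_regions(self):
        with pytest.raises(ValueError, match="3 regions"):
            betweenness_centrality(make_network(np.array([[0, 1], [1, 0]], dtype=float)))


class TestEigenvector:
    def test_complete_graph_uniform(self):
        W = np.ones((6, 6)) - np.eye(6)
        e = eigenvector_centrality(make_network(W))
        assert list(e) == pytest.approx([1 / np.sqrt(6)] * 6)

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            W = random_symmetric_weights(5, 0.9, rng)
            net = make_network(W)
            try:
                e = eigenvector_centrality(net)
            except ValueError:
                continue  # disconnected draw
            vals, vecs = np.linalg.eigh(W)
            v = vecs[:, -1]
            v = v if v.sum() >= 0 else -v
            assert np.abs(e.to_numpy() - v / np.linalg.norm(v)).max() < 1e-8

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        W = random_symmetric_weights(5, 1.0, rng)
        e1 = eigenvector_centrality(make_network(W))
        e2 = eigenvector_centrality(make_network(10 * W))
        assert np.allclose(e1, e2, atol=1e-9)

    def test_disconnected_error_names_components(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(ValueError, match=r"r0.*r1.*r2.*r3"):
            eigenvector_centrality(make_network(W))


class TestAveragePathLength:
    def test_three_node_path_hand_enumeration(self):
        W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        apl = average_path_length(make_network(W))
        assert apl.iloc[0] == pytest.approx(1.5)  # (1 + 2) / 2
        assert apl.iloc[1] == pytest.approx(1.0)

    def test_complete_graph_unit_weights(self):
        W = np.ones((5, 5)) - np.eye(5)
        assert list(average_path_length(make_network(W))) == pytest.approx([1.0] * 5)

    def test_isolated_region_flagged_nan(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 2.0
        apl = average_path_length(make_network(W))
        assert np.isnan(apl.iloc[2])
        assert apl.iloc[0] == pytest.approx(0.5)


class TestOracleEquivalence:
    """Betweenness and average path length vs exhaustive path enumeration."""

    @pytest.mark.parametrize("seed", range(20))
    def test_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        W = random_symmetric_weights(n, rng.uniform(0.3, 0.9), rng)
        net = make_network(W)
        if n >= 3:
            assert np.abs(
                betweenness_centrality(net).to_numpy() - betweenness_exhaustive(W)
            ).max() < 1e-9
        got = average_path_length(net).to_numpy()
        exp = avg_path_length_exhaustive(W)
        both = np.isnan(got) == np.isnan(exp)
        assert both.all()
        mask = ~np.isnan(exp)
        if mask.any():
            assert np.abs(got[mask] - exp[mask]).max() < 1e-9


class TestScalingAndRelabeling:
    def test_weight_scale_behavior(self):
        rng = np.random.default_rng(5)
        W = random_symmetric_weights(6, 0.8, rng)
        c = 3.7
        n1, n2 = make_network(W), make_network(c * W)
        assert np.allclose(betweenness_centrality(n1), betweenness_centrality(n2))
        assert np.allclose(node_strength(n2), c * node_strength(n1))
        a1, a2 = average_path_length(n1), average_path_length(n2)
        mask = ~np.isnan(a1)
        assert np.allclose(a2[mask], a1[mask] / c)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        W = random_symmetric_weights(6, 0.9, rng)
        perm = rng.permutation(6)
        Wp = W[np.ix_(perm, perm)]
        names = [f"r{i}" for i in range(6)]
        net = WeightedNetwork(W, names)
        netp = WeightedNetwork(Wp, [names[i] for i in perm])
        for func in (node_strength, betweenness_centrality, average_path_length):
            orig = func(net)
            permuted = func(netp)
            assert np.allclose(
                permuted.to_numpy(), orig.to_numpy()[perm], equal_nan=True
            )


class TestFlattenMetrics:
    def _tables(self, n_subj, regions, metrics):
        rng = np.random.default_rng(1)
        return {
            f"s{i}": pd.DataFrame(
                rng.normal(size=(len(regions), len(metrics))), index=regions, columns=metrics
            )
            for i in range(n_subj)
        }

    def test_default_selection_two_columns_per_region(self):
        regions = [f"r{i:03d}" for i in range(165)]
        tables = self._tables(3, regions, ["betweenness", "avg_path_length"])
        block = flatten_metrics(tables)
        assert block.shape == (3, 330)
        assert block.columns[0].startswith("AvPathLength__")

    def test_four_metrics_sorted_by_tag_then_region(self):
        regions = [f"r{i}" for i in range(10)]
        metrics = ("betweenness", "avg_path_length", "strength", "eigenvector")
        block = flatten_metrics(self._tables(2, regions, list(metrics)), metrics=metrics)
        assert block.shape == (2, 40)
        tags = [c.split("__")[0] for c in block.columns]
        assert tags == sorted(tags)
        assert set(tags) == {"AvPathLength", "EigCent", "NodeBWCent", "Strength"}

    def test_mismatched_regions_rejected(self):
        t1 = self._tables(1, ["a", "b"], ["betweenness", "avg_path_length"])
        t2 = self._tables(1, ["a", "c"], ["betweenness", "avg_path_length"])
        with pytest.raises(ValueError, match="different region set"):
            flatten_metrics({"s1": t1["s0"], "s2": t2["s0"]})

    def test_compute_node_metrics_columns(self, small_cohort):
        tab = compute_node_metrics(small_cohort.fiber_matrices[0])
        assert list(tab.columns) == ["betweenness", "avg_path_length"]
        assert (tab["betweenness"].dropna() >= 0).all()
        assert (tab["betweenness"].dropna() <= 1).all()
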