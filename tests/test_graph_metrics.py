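"""Nodal graph-metric tests, including brute-force oracles on small graphs."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dotprobe_eeg.graph_metrics import (BinaryNetwork, WeightedNetwork,
                                        compute_nodal_metrics, node_betweenness,
                                        node_degree, node_lateralization,
                                        node_strength, proportional_threshold,
                                        read_hemisphere_map,
                                        write_hemisphere_map)


def wnet(weights, hemis=None):
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    labels = [f"n{i}" for i in range(n)]
    if hemis is None:
        hemis = {lab: ("left" if i % 2 == 0 else "right")
                 for i, lab in enumerate(labels)}
    return WeightedNetwork(weights=w, node_labels=labels, hemisphere_map=hemis)


def brute_force_betweenness(dist: np.ndarray) -> np.ndarray:
    """Exponential-time betweenness oracle: enumerate every simple path.

    ``dist[i, j]``: edge length, np.inf when absent. For each unordered
    pair (j, k) finds all simple paths, the minimum length, the number of
    shortest paths and, per node i, the fraction passing through i.
    """
    n = dist.shape[0]
    bc = np.zeros(n)
    for j, k in itertools.combinations(range(n), 2):
        best = np.inf
        shortest: list[tuple[int, ...]] = []
        others = [x for x in range(n) if x not in (j, k)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (j,) + mid + (k,)
                length = sum(dist[a, b] for a, b in zip(path, path[1:]))
                if not np.isfinite(length):
                    continue
                if length < best - 1e-9:
                    best, shortest = length, [path]
                elif abs(length - best) <= 1e-9:
                    shortest.append(path)
        if not np.isfinite(best):
            continue
        for path in shortest:
            for node in path[1:-1]:
                bc[node] += 1.0 / len(shortest)
    return bc


class TestProportionalThreshold:
    def test_sparsity_one_gives_complete_graph(self, rng):
        w = rng.uniform(0.1, 1.0, (5, 5))
        w = (w + w.T) / 2
        net = wnet(w)
        b = proportional_threshold(net, 1.0)
        assert b.adjacency.sum() == 5 * 4   # both triangles

    def test_single_edge_is_global_max(self, rng):
        w = rng.uniform(0.1, 0.5, (6, 6))
        w = (w + w.T) / 2
        w[2, 4] = w[4, 2] = 0.99
        net = wnet(w)
        b = proportional_threshold(net, 1.0 / 15.0)    # keeps exactly 1 edge
        assert b.adjacency.sum() == 2
        assert b.adjacency[2, 4] == 1

    @pytest.mark.parametrize("n,sparsity", [(6, 0.2), (8, 0.35), (10, 0.5)])
    def test_edge_count_matches_floor_formula(self, rng, n, sparsity):
        w = rng.uniform(0.0, 1.0, (n, n))
        w = (w + w.T) / 2
        b = proportional_threshold(wnet(w), sparsity)
        expected = math.floor(sparsity * n * (n - 1) / 2)
        assert b.adjacency.sum() // 2 == expected

    def test_tie_break_is_stable(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        b = proportional_threshold(wnet(w), 1.0 / 6.0)  # keep 1 of 6 equal
        assert b.adjacency[0, 1] == 1 and b.adjacency.sum() == 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            proportional_threshold(wnet(np.zeros((3, 3))), 0.0)


class TestDegreeStrength:
    def test_star_closed_form(self):
        a = np.zeros((5, 5), dtype=int)
        a[0, 1:] = a[1:, 0] = 1
        b = BinaryNetwork(adjacency=a, node_labels=list("abcde"))
        np.testing.assert_array_equal(node_degree(b), [4, 1, 1, 1, 1])

    def test_complete_graph(self):
        a = 1 - np.eye(6, dtype=int)
        b = BinaryNetwork(adjacency=a, node_labels=list("abcdef"))
        np.testing.assert_array_equal(node_degree(b), [5] * 6)

    def test_strength_single_edge(self):
        w = np.zeros((4, 4))
        w[1, 3] = w[3, 1] = 0.7
        np.testing.assert_allclose(node_strength(wnet(w)), [0, 0.7, 0, 0.7])

    def test_binary_weights_reduce_to_degree(self, rng):
        a = (rng.random((7, 7)) > 0.5).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        net = wnet(a)
        b = BinaryNetwork(adjacency=a.astype(int),
                          node_labels=net.node_labels)
        np.testing.assert_allclose(node_strength(net), node_degree(b))


class TestBetweenness:
    def test_path_graph_single_intermediary(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        b = BinaryNetwork(adjacency=a, node_labels=list("abc"))
        np.testing.assert_allclose(node_betweenness(b, "unit"), [0, 1, 0])

    def test_star_center_closed_form(self):
        a = np.zeros((5, 5), dtype=int)
        a[0, 1:] = a[1:, 0] = 1
        b = BinaryNetwork(adjacency=a, node_labels=list("abcde"))
        np.testing.assert_allclose(node_betweenness(b, "unit"),
                                   [math.comb(4, 2), 0, 0, 0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 8)
        w = rng.uniform(0.2, 1.0, (n, n))
        w = (w + w.T) / 2
        w[rng.random((n, n)) < 0.4] = 0.0
        w = np.triu(w, 1)
        w = w + w.T
        net = wnet(w)
        with np.errstate(divide="ignore"):
            dist = np.where(w > 0, 1.0 / w, np.inf)
        np.testing.assert_allclose(
            node_betweenness(net, "inverse_weight"),
            brute_force_betweenness(dist), atol=1e-8)

    def test_negative_weight_rejected(self):
        w = np.zeros((3, 3))
        net = wnet(w)
        net.weights[0, 1] = net.weights[1, 0] = -1.0   # bypass validation
        with pytest.raises(ValueError):
            node_betweenness(net, "inverse_weight")


class TestLateralization:
    def test_arithmetic(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 3.0     # n1 is right per default tagging? set maps
        w[0, 2] = w[2, 0] = 1.0
        net = wnet(w, hemis={"n0": "midline", "n1": "left", "n2": "right"})
        nlp, defined = node_lateralization(net)
        assert nlp[0] == pytest.approx((3.0 - 1.0) / 4.0)
        assert defined[0]

    def test_mirror_symmetric_weights_zero(self):
        # midline node connected equally left and right
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[0, 2] = w[2, 0] = 0.8
        net = wnet(w, hemis={"n0": "midline", "n1": "left", "n2": "right"})
        nlp, _ = node_lateralization(net)
        assert nlp[0] == pytest.approx(0.0)

    def test_boundary_values(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        net = wnet(w, hemis={"n0": "midline", "n1": "left", "n2": "right"})
        nlp, _ = node_lateralization(net)
        assert nlp[0] == pytest.approx(1.0)
        net2 = wnet(w, hemis={"n0": "midline", "n1": "right", "n2": "left"})
        nlp2, _ = node_lateralization(net2)
        assert nlp2[0] == pytest.approx(-1.0)

    def test_isolated_node_flagged_undefined(self):
        net = wnet(np.zeros((3, 3)),
                   hemis={"n0": "midline", "n1": "left", "n2": "right"})
        nlp, defined = node_lateralization(net)
        assert not defined.any()
        assert np.isnan(nlp).all()

    def test_missing_tag_rejected(self):
        net = wnet(np.zeros((3, 3)), hemis={"n0": "left"})
        with pytest.raises(ValueError, match="hemisphere"):
            node_lateralization(net)


class TestComputeNodalMetrics:
    def test_single_edge_hand_computation(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.6
        net = wnet(w, hemis={"n0": "left", "n1": "right",
                             "n2": "left", "n3": "right"})
        nm = compute_nodal_metrics(net, sparsity=1.0)
        t = nm.table.set_index("node")
        assert t.loc["n0", "dc"] == 1 and t.loc["n2", "dc"] == 0
        assert t.loc["n0", "ne"] == pytest.approx(0.6)
        assert (t["bc"] == 0).all()
        assert t.loc["n0", "nlp"] == pytest.approx(-1.0)  # only right link

    def test_permutation_equivariance(self, rng):
        n = 6
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        hemis = {f"n{i}": h for i, h in enumerate(
            ["left", "right", "left", "right", "midline", "left"])}
        net = wnet(w, hemis=hemis)
        nm = compute_nodal_metrics(net, sparsity=0.4)
        perm = rng.permutation(n)
        labels_p = [f"n{i}" for i in perm]
        net_p = WeightedNetwork(weights=w[np.ix_(perm, perm)],
                                node_labels=labels_p,
                                hemisphere_map=hemis)
        nm_p = compute_nodal_metrics(net_p, sparsity=0.4)
        a = nm.table.set_index("node").loc[labels_p]
        b = nm_p.table.set_index("node")
        for col in ("dc", "ne", "bc"):
            np.testing.assert_allclose(a[col].to_numpy(), b[col].to_numpy(),
                                       atol=1e-9)

    def test_weight_scaling_behaviour(self, rng):
        n = 6
        w = rng.uniform(0.1, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = wnet(w)
        net_c = wnet(3.5 * w)
        a = compute_nodal_metrics(net, sparsity=0.4).table
        b = compute_nodal_metrics(net_c, sparsity=0.4).table
        np.testing.assert_allclose(b["ne"], 3.5 * a["ne"])       # Ne scales
        np.testing.assert_array_equal(b["dc"], a["dc"])          # Dc invariant
        np.testing.assert_allclose(b["nlp"], a["nlp"])           # Nlp invariant
        np.testing.assert_allclose(b["bc"], a["bc"], atol=1e-9)  # paths same


def test_hemisphere_map_roundtrip(tmp_path):
    hemi = {"O1": "left", "O2": "right", "Pz": "midline"}
    write_hemisphere_map(hemi, tmp_path / "hemi.txt")
    assert read_hemisphere_map(tmp_path / "hemi.txt") == hemi
    (tmp_path / "bad.txt").write_text("O1 up\n")
    with pytest.raises(ValueError):
        read_hemisphere_map(tmp_path / "bad.txt")
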