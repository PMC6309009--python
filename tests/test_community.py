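"""Modularity partitioning and weighted network metrics."""

import numpy as np
import pandas as pd
import pytest

from socionet.community import (
    metric_permutation_compare,
    modularity_q,
    network_export,
    newman_eigenvector_partition,
    node_metrics,
    write_graphml,
)
from socionet.matrices import DyadMatrix
from socionet.permutations import PermutationConfig, build_incidence
from socionet.synthetic import simulate

from conftest import null_scenario


def all_partitions(items):
    """Every set partition of `items` (recursive enumeration)."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [head]] + part[k + 1 :]
        yield part + [[head]]


def brute_force_best_q(w):
    """Exhaustive maximum modularity over all partitions (n <= 8)."""
    n = w.shape[0]
    best = -np.inf
    for part in all_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for u, grp in enumerate(part):
            labels[grp] = u
        q = modularity_q(w, labels)
        best = max(best, q)
    return best


def two_cliques(k, bridge=0.1):
    n = 2 * k
    w = np.zeros((n, n))
    w[:k, :k] = 1.0
    w[k:, k:] = 1.0
    np.fill_diagonal(w, 0.0)
    w[0, k] = w[k, 0] = bridge
    return w


class TestPartition:
    def test_two_cliques_split_exactly(self):
        w = two_cliques(5)
        m = DyadMatrix([f"I{k}" for k in range(10)], w)
        part = newman_eigenvector_partition(m)
        assert part.n_units == 2
        units = {frozenset(part.members(u)) for u in range(part.n_units)}
        assert units == {
            frozenset(f"I{k}" for k in range(5)),
            frozenset(f"I{k}" for k in range(5, 10)),
        }

    def test_uniform_complete_graph_single_unit(self):
        n = 8
        w = np.ones((n, n)) - np.eye(n)
        part = newman_eigenvector_partition(DyadMatrix([f"I{k}" for k in range(n)], w))
        assert part.n_units == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        """Leading-eigenvector + refinement vs. brute-force enumeration.

        On 30 random weighted graphs with n in 5..7 the returned Q never
        exceeds the exhaustive optimum and attains it almost always.
        """
        rng = np.random.default_rng(0)
        attained = 0
        trials = 30
        for t in range(trials):
            n = int(rng.integers(5, 8))
            w = (rng.random((n, n)) < 0.45) * rng.random((n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            if w.sum() == 0:
                w[0, 1] = w[1, 0] = 1.0
            part = newman_eigenvector_partition(DyadMatrix([str(i) for i in range(n)], w))
            best = brute_force_best_q(w)
            assert part.q <= best + 1e-12
            if part.q >= best - 1e-9:
                attained += 1
        assert attained / trials >= 0.9

    def test_invariant_to_relabeling_and_rescaling(self):
        rng = np.random.default_rng(1)
        n = 12
        w = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        ids = [f"I{k}" for k in range(n)]
        p1 = newman_eigenvector_partition(DyadMatrix(ids, w))
        p2 = newman_eigenvector_partition(DyadMatrix(ids, w * 7.5))
        assert p1.q == pytest.approx(p2.q, abs=1e-12)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        perm = rng.permutation(n)
        p3 = newman_eigenvector_partition(
            DyadMatrix([ids[i] for i in perm], w[np.ix_(perm, perm)])
        )
        assert p3.q == pytest.approx(p1.q, abs=1e-10)

    def test_q_never_below_trivial_partition(self):
        rng = np.random.default_rng(2)
        for t in range(10):
            n = 10
            w = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            if w.sum() == 0:
                continue
            part = newman_eigenvector_partition(DyadMatrix([str(i) for i in range(n)], w))
            assert part.q >= -1e-12

    def test_negative_weights_clamped_with_warning(self):
        w = two_cliques(4)
        w[0, 5] = w[5, 0] = -0.5
        with pytest.warns(UserWarning, match="clamped"):
            part = newman_eigenvector_partition(DyadMatrix([str(i) for i in range(8)], w))
        assert part.n_units == 2

    def test_disconnected_input_warns(self):
        w = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="disconnected"):
            part = newman_eigenvector_partition(DyadMatrix(list("abcd"), w))
        assert part.q == 0.0


class TestModularityQ:
    def test_single_unit_is_zero(self):
        rng = np.random.default_rng(3)
        w = rng.random((7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        assert modularity_q(w, np.zeros(7, dtype=int)) == pytest.approx(0.0, abs=1e-14)

    def test_two_disconnected_cliques_give_half(self):
        w = two_cliques(4, bridge=0.0)
        labels = np.array([0] * 4 + [1] * 4)
        assert modularity_q(w, labels) == pytest.approx(0.5, abs=1e-12)

    def test_random_assignment_matches_analytic_expectation(self):
        """Labels independent of the graph: E[Q] has a closed form.

        Off-diagonal modularity terms cancel in expectation (they sum to the
        negated diagonal), leaving E[Q] = (1 - 1/k) * sum_i B_ii / 2m for k
        equiprobable labels - slightly negative, approaching 0 for large
        networks.  The Monte-Carlo mean must match it.
        """
        rng = np.random.default_rng(4)
        n = 12
        w = (rng.random((n, n)) < 0.3) * 1.0
        w = np.triu(w, 1)
        w = w + w.T
        s = w.sum(axis=1)
        m2 = s.sum()
        k = 3
        expected = (1 - 1 / k) * (-(s**2).sum() / m2) / m2
        qs = [modularity_q(w, rng.integers(0, k, n)) for _ in range(400)]
        assert np.mean(qs) == pytest.approx(expected, abs=0.01)
        assert abs(np.mean(qs)) < 0.1

    def test_partition_q_equals_recomputation(self, small_study):
        from socionet import association

        counts = association.tally_counts(small_study.records)
        hg = association.hwig(association.hwi(counts))
        part = newman_eigenvector_partition(hg)
        assert part.q == pytest.approx(modularity_q(hg, part.assignment), abs=1e-12)


class TestNodeMetrics:
    def test_binary_triangle_closed_forms(self):
        w = np.ones((3, 3)) - np.eye(3)
        met = node_metrics(DyadMatrix(list("abc"), w))
        np.testing.assert_allclose(met["clustering_coefficient"], 1.0)
        np.testing.assert_allclose(met["strength"], 2.0)
        np.testing.assert_allclose(met["eigenvector_centrality"], 1.0)

    def test_star_graph_center(self):
        n = 6
        w = np.zeros((n, n))
        w[0, 1:] = w[1:, 0] = 1.0
        met = node_metrics(DyadMatrix([str(i) for i in range(n)], w))
        assert met.loc["0", "strength"] == n - 1
        assert met.loc["0", "eigenvector_centrality"] == pytest.approx(1.0)
        # leaves have no connected pairs among neighbours -> clustering NaN
        assert np.isnan(met.loc["1", "clustering_coefficient"])

    def test_regular_graph_affinity_equals_strength(self):
        # ring of 6 with uniform weights: every node's neighbours all have
        # the same strength, so affinity == that common strength
        n = 6
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 0.7
        met = node_metrics(DyadMatrix([str(i) for i in range(n)], w))
        np.testing.assert_allclose(met["affinity"], met["strength"])

    def test_isolated_node_masked(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        met = node_metrics(DyadMatrix(list("abcd"), w))
        assert np.isnan(met.loc["c", "clustering_coefficient"])
        assert np.isnan(met.loc["c", "affinity"])


class TestMetricPermutationCompare:
    def test_deterministic_and_shaped(self):
        sim = simulate(null_scenario(n=12, occasions=25), seed=7)
        inc = build_incidence(sim.records)
        from socionet import association

        counts = association.tally_counts(sim.records)
        hg = association.hwig(association.hwi(counts))
        part = newman_eigenvector_partition(hg.reorder(inc.ids))
        cfg = PermutationConfig(n_permutations=40, flips_per_permutation=30, seed=5)
        t1 = metric_permutation_compare(inc, part, cfg)
        t2 = metric_permutation_compare(inc, part, cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1["metric"]) == {
            "strength", "eigenvector_centrality", "clustering_coefficient", "affinity",
        }
        assert ((t1["p"] > 0) & (t1["p"] <= 1)).all()


class TestExport:
    def _matrix(self):
        rng = np.random.default_rng(8)
        v = rng.random((6, 6)) * 2
        v = (v + v.T) / 2
        return DyadMatrix([f"I{k}" for k in range(6)], v, kind="HWIG")

    def test_threshold_above_max_empty(self):
        m = self._matrix()
        edges = network_export(m, float(np.nanmax(m.values)) + 1.0)
        assert edges.empty

    def test_threshold_one_keeps_above_chance_dyads(self):
        m = self._matrix()
        edges = network_export(m, 1.0)
        expect = {(a, b) for a, b, v in m.dyads() if v > 1.0}
        assert {(r.id1, r.id2) for r in edges.itertuples()} == expect

    def test_round_trip_preserves_weights(self, tmp_path):
        import networkx as nx

        m = self._matrix()
        edges = network_export(m, 0.0)
        p = tmp_path / "net.graphml"
        write_graphml(edges, p)
        g = nx.read_graphml(p)
        for r in edges.itertuples():
            assert g[r.id1][r.id2]["weight"] == r.weight
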