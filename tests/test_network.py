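import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import gutlink as gl


def brute_force_c_score(m):
    """Independent O(T^2 S) oracle in pure integer arithmetic."""
    t = m.shape[0]
    total = 0
    for i, j in itertools.combinations(range(t), 2):
        ri = int(m[i].sum())
        rj = int(m[j].sum())
        s = int((m[i] & m[j]).sum())
        total += (ri - s) * (rj - s)
    return total / (t * (t - 1) // 2)


class TestPrevalenceFilter:
    def _table(self, occupancies, n_samples=18):
        rows = []
        for occ in occupancies:
            row = np.zeros(n_samples, dtype=int)
            row[:occ] = 5
            rows.append(row)
        return gl.CountTable([f"t{i}" for i in range(len(rows))],
                             [f"s{j}" for j in range(n_samples)], np.array(rows))

    def test_strictly_more_than_half(self):
        t = self._table([9, 10, 18])
        out = gl.prevalence_filter(t)
        assert out.taxon_ids == ["t1", "t2"]  # 9/18 is not > 9

    def test_all_present_unchanged(self):
        t = self._table([18, 18, 18])
        out = gl.prevalence_filter(t)
        assert out.taxon_ids == t.taxon_ids
        assert np.array_equal(out.counts, t.counts)

    def test_nothing_retained_is_an_error(self):
        t = self._table([2, 3])
        with pytest.raises(ValueError, match="half"):
            gl.prevalence_filter(t)


class TestCScore:
    def test_perfect_checkerboard(self):
        p = gl.PresenceMatrix(["a", "b"], ["s1", "s2"], np.array([[1, 0], [0, 1]]))
        assert gl.c_score(p) == 1.0

    def test_all_ones_zero(self):
        p = gl.PresenceMatrix(["a", "b", "c"], ["s1", "s2"], np.ones((3, 2), dtype=int))
        assert gl.c_score(p) == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        for seed in range(20):
            p = gl.generate_presence_matrix(5, 6, "random", 0.5, seed=seed)
            assert gl.c_score(p) == brute_force_c_score(p.matrix)


class TestSim9:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(m=arrays(np.int64, (6, 8), elements=st.integers(0, 1)),
           steps=st.integers(0, 400), seed=st.integers(0, 2**31 - 1))
    def test_margins_conserved(self, m, steps, seed):
        p = gl.PresenceMatrix([f"t{i}" for i in range(6)],
                              [f"s{j}" for j in range(8)], m)
        out = gl.sim9_swap_chain(p, steps, seed=seed)
        assert np.array_equal(out.row_totals(), p.row_totals())
        assert np.array_equal(out.matrix.sum(axis=0), p.matrix.sum(axis=0))

    def test_single_swap_of_2x2_checkerboard(self):
        p = gl.PresenceMatrix(["a", "b"], ["s1", "s2"], np.array([[1, 0], [0, 1]]))
        for seed in range(5):
            out = gl.sim9_swap_chain(p, 200, seed=seed)
            assert np.array_equal(out.matrix, [[1, 0], [0, 1]]) or \
                np.array_equal(out.matrix, [[0, 1], [1, 0]])

    def test_matrix_without_checkerboard_is_fixed(self):
        nested = gl.PresenceMatrix(["a", "b"], ["s1", "s2"], np.array([[1, 1], [1, 0]]))
        out = gl.sim9_swap_chain(nested, 1000, seed=0)
        assert np.array_equal(out.matrix, nested.matrix)


class TestCScoreNullTest:
    def test_planted_checkerboard_rejected(self):
        p = gl.generate_presence_matrix(10, 18, "checkerboard", 0.5, seed=0)
        res = gl.cscore_null_test(p, n_null=199, seed=1)
        assert res.p_value <= 0.05
        assert res.ses is not None and res.ses > 0

    def test_vacuous_matrix_reported(self):
        p = gl.generate_presence_matrix(6, 8, "nested", 0.5, seed=0)
        res = gl.cscore_null_test(p, n_null=99, seed=1)
        assert res.vacuous and res.p_value == 1.0 and res.ses is None

    def test_p_never_zero(self):
        p = gl.generate_presence_matrix(8, 10, "checkerboard", 0.5, seed=3)
        res = gl.cscore_null_test(p, n_null=99, seed=4)
        assert res.p_value >= 1 / 100


class TestSpearmanEdges:
    @staticmethod
    def _abund(rows, prefix="t"):
        vals = np.array(rows, dtype=float)
        vals /= vals.sum(axis=0)
        return gl.AbundanceTable([f"{prefix}{i}" for i in range(len(rows))],
                                 [f"s{j}" for j in range(vals.shape[1])], vals)

    def test_monotone_pair_retained_with_exact_p(self):
        t = self._abund([[1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12],
                         [9, 1, 7, 3, 5, 2]])
        edges = gl.spearman_edges(t)
        pair = [(e[0], e[1], e[2], e[3]) for e in edges
                if {e[0], e[1]} == {"t0", "t1"}]
        assert len(pair) == 1
        assert pair[0][2] == 1.0
        assert pair[0][3] == pytest.approx(2 / 720)

    def test_antimonotone_pair_negative_sign(self):
        a = np.array([0.10, 0.15, 0.20, 0.25, 0.30, 0.35])
        vals = np.vstack([a, 0.7 - a, np.full(6, 0.3)])
        t = gl.AbundanceTable(["t0", "t1", "t2"],
                              [f"s{j}" for j in range(6)], vals)
        edges = gl.spearman_edges(t)
        rho = {frozenset((u, v)): r for u, v, r, _ in edges}[frozenset(("t0", "t1"))]
        assert rho == -1.0

    def test_threshold_is_strict(self):
        t = self._abund([[1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12],
                         [9, 1, 7, 3, 5, 2]])
        assert gl.spearman_edges(t, rho_threshold=1.0) == []

    def test_constant_taxon_excluded(self):
        a = np.array([0.10, 0.15, 0.20, 0.25, 0.30, 0.35])
        vals = np.vstack([a, np.full(6, 0.2), 0.8 - a])
        t = gl.AbundanceTable(["a", "const", "b"],
                              [f"s{j}" for j in range(6)], vals)
        edges = gl.spearman_edges(t)
        assert edges  # the non-constant pair still forms an edge
        assert all("const" not in (u, v) for u, v, _, _ in edges)


class TestBuildNetwork:
    def test_triangle(self):
        g = gl.build_network([("a", "b", 0.8, 0.01), ("b", "c", 0.9, 0.01),
                              ("a", "c", 0.75, 0.02)])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_empty(self):
        g = gl.build_network([])
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gl.build_network([("a", "b", 0.8, 0.01), ("b", "a", 0.9, 0.01)])

    def test_isolated_taxa_not_in_node_set(self):
        g = gl.build_network([("a", "b", 0.8, 0.01)], all_taxa=["a", "b", "z"])
        assert set(g.nodes) == {"a", "b"}


class TestNetworkProperties:
    def test_complete_graph(self):
        g = gl.build_network([(a, b, 0.9, 0.01)
                              for a, b in itertools.combinations("abcd", 2)])
        p = gl.network_properties(g)
        assert p.V == 4 and p.E == 6
        assert p.density == 1.0 and p.clustering == 1.0
        assert p.mean_degree == 3.0

    def test_path_graph_clustering_zero(self):
        g = gl.build_network([("a", "b", 0.9, 0.01), ("b", "c", 0.9, 0.01),
                              ("c", "d", 0.9, 0.01)])
        p = gl.network_properties(g)
        assert p.clustering == 0.0
        assert p.mean_path_length == pytest.approx((1 * 3 + 2 * 2 + 3) / 6)

    def test_transitivity_matches_triple_enumeration(self):
        """Global clustering against an O(V^3) triangle/triad count."""
        g = nx.gnm_random_graph(20, 50, seed=42)
        nodes = list(g.nodes)
        triangles = triads = 0
        for a, b, c in itertools.combinations(nodes, 3):
            e = g.has_edge(a, b) + g.has_edge(b, c) + g.has_edge(a, c)
            if e == 3:
                triangles += 1
            if e >= 2:
                triads += 1
        expected = 3 * triangles / (triangles * 3 + (triads - triangles) * 1) \
            if triads else 0.0
        # open triads each contribute one path of length 2; triangles three
        p = gl.network_properties(g)
        assert p.clustering == pytest.approx(expected)

    def test_empty_graph_all_missing(self):
        p = gl.network_properties(nx.Graph())
        assert p.V == 0 and p.E == 0 and p.clustering is None


class TestErEnsemble:
    def test_every_draw_has_exact_edge_count(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            e = gl.sample_gnm(12, 17, rng)
            assert e.shape == (17, 2)
            assert len({tuple(sorted(p)) for p in e.tolist()}) == 17

    def test_impossible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            gl.sample_gnm(4, 7, np.random.default_rng(0))

    def test_er_draw_is_typical_of_its_own_ensemble(self):
        """An ER graph compared against its own ensemble is rarely flagged:
        p > 0.05 in at least 90% of seeded repetitions."""
        rng = np.random.default_rng(3)
        typical = 0
        n_rep = 20
        for rep in range(n_rep):
            edges = gl.sample_gnm(20, 40, rng)
            g = nx.Graph(edges.tolist())
            props = gl.network_properties(g)
            res = gl.er_ensemble_compare(props, n_random=200, seed=rep)
            typical += res["clustering"].p_value > 0.05
        assert typical >= 0.9 * n_rep


class TestAnnotateNodes:
    def _net(self):
        return gl.build_network([("a", "b", 0.8, 0.01), ("b", "c", -0.9, 0.01)])

    def test_categories_applied(self):
        g = annotated = gl.annotate_nodes(
            self._net(),
            [gl.ResponseCategory("a", "restored", 0.01, 1, 0.01, -1)],
        )
        assert annotated.nodes["a"]["category"] == "restored"
        assert annotated.nodes["a"]["color"] == "green"
        assert g.nodes["b"]["category"] == "neutral"
        assert g.edges["b", "c"]["sign"] == -1

    def test_no_categories_all_neutral(self):
        g = gl.annotate_nodes(self._net(), [])
        assert all(d["category"] == "neutral" for _, d in g.nodes(data=True))

    def test_absent_taxon_ignored(self):
        g = gl.annotate_nodes(
            self._net(), [gl.ResponseCategory("zz", "restored", 0.01, 1, 0.01, -1)]
        )
        assert "zz" not in g
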