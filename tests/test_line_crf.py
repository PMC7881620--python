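import itertools

import networkx as nx
import numpy as np
import pytest

from _reference import reference_mad_flags, reference_score
from conftest import random_line_graph
from rigidseg import (CapacityError, compute_gammas, expand_outliers,
                      line_graph, mad_outliers, map_labeling, score_labeling)
from rigidseg.coarse_grain import CoarseGraph
from rigidseg.line_crf import LabeledLineGraph


def _coarse(edges, n=None, xi=None):
    g = nx.Graph()
    nodes = sorted(set(itertools.chain.from_iterable(edges))) if edges else []
    n = n or (max(nodes) + 1 if nodes else 0)
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    if xi is None:
        xi = np.arange(n * n, dtype=float).reshape(n, n)
        xi = (xi + xi.T) / 2
        np.fill_diagonal(xi, 0)
    return CoarseGraph([(i,) for i in range(n)], g, xi)


class TestLineGraph:
    def test_triangle_yields_no_line_edges(self):
        lg = line_graph(_coarse([(0, 1), (1, 2), (0, 2)]))
        assert lg.n_vertices == 3
        assert lg.edges == []

    def test_path_yields_one_edge_with_end_node_xi(self):
        coarse = _coarse([(0, 1), (1, 2)])
        lg = line_graph(coarse)
        assert lg.vertices == [(0, 1), (1, 2)]
        assert lg.edges == [(0, 1)]
        assert lg.xi_edge[0] == coarse.xi[0, 2]
        assert lg.xi_vertex[0] == coarse.xi[0, 1]

    def test_star_yields_complete_line_graph(self):
        lg = line_graph(_coarse([(0, i) for i in range(1, 5)]))
        assert lg.n_vertices == 4
        assert len(lg.edges) == 6  # K4

    def test_random_coarse_graphs_respect_the_modification(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.4]
            coarse = _coarse(edges, n=n)
            lg = line_graph(coarse)
            for i1, i2 in lg.edges:
                shared = set(lg.vertices[i1]) & set(lg.vertices[i2])
                ends = (set(lg.vertices[i1]) | set(lg.vertices[i2])) - shared
                assert len(shared) == 1
                assert not coarse.graph.has_edge(*sorted(ends))

    def test_edgeless_coarse_graph_gives_empty_line_graph(self):
        lg = line_graph(_coarse([], n=3))
        assert lg.n_vertices == 0


class TestMadOutliers:
    def test_constant_array_has_no_outliers(self):
        np.testing.assert_array_equal(mad_outliers([2, 2, 2, 2]),
                                      [1, 1, 1, 1])

    def test_gross_outlier_is_flagged(self):
        flags = mad_outliers([1, 1, 1, 1, 1, 1, 1, 100])
        np.testing.assert_array_equal(flags, [1] * 7 + [-1])

    def test_planted_outliers_match_reference_implementation(self):
        rng = np.random.default_rng(12)
        values = np.sort(np.concatenate([
            rng.gamma(2.0, 1.0, size=50), [40.0, 55.0, 70.0]]))
        flags = mad_outliers(values)
        np.testing.assert_array_equal(flags, reference_mad_flags(values))
        assert (flags[-3:] == -1).all()  # the planted values

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            mad_outliers([3.0, 1.0, 2.0])

    def test_zero_mad_falls_back_to_mean_absolute_deviation(self):
        # majority at 1 makes MAD zero; the large value must still be caught
        values = np.array([1.0] * 9 + [50.0])
        assert mad_outliers(values)[-1] == -1


class TestExpandOutliers:
    def test_zero_fraction_is_identity(self):
        gamma = np.array([1, 1, 1, -1])
        values = np.array([1.0, 2.0, 3.0, 9.0])
        np.testing.assert_array_equal(expand_outliers(gamma, values, 0.0),
                                      gamma)

    def test_fraction_adds_largest_non_flagged_entries(self):
        gamma = np.array([1] * 9 + [-1])
        values = np.arange(10, dtype=float)
        out = expand_outliers(gamma, values, 0.2)
        np.testing.assert_array_equal(out, [1] * 7 + [-1] * 3)

    def test_output_flags_are_superset_of_input_flags(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 15))
            values = np.sort(rng.normal(size=n))
            k = int(rng.integers(0, n))
            gamma = np.array([1] * (n - k) + [-1] * k)
            out = expand_outliers(gamma, values, float(rng.uniform(0, 0.5)))
            assert set(np.flatnonzero(gamma == -1)) <= \
                set(np.flatnonzero(out == -1))

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            expand_outliers(np.array([1, 1]), np.array([0.0, 1.0]), -0.1)


class TestScoreLabeling:
    def test_isolated_vertex_prefers_its_indicator(self):
        lg = LabeledLineGraph([(0, 1)], [], np.array([1.0]), np.empty(0),
                              np.array([1]), np.empty(0, dtype=int))
        assert score_labeling(lg, [1]) == 1
        assert score_labeling(lg, [-1]) == -1

    def test_agreeing_pair_with_no_outliers_scores_three(self):
        # both vertices and the edge are non-outliers, labels all +1:
        # vertex terms 1 + 1, edge term +1
        lg = LabeledLineGraph([(0, 1), (1, 2)], [(0, 1)],
                              np.array([1.0, 2.0]), np.array([1.5]),
                              np.array([1, 1]), np.array([1]))
        assert score_labeling(lg, [1, 1]) == 3

    def test_matches_independent_scorer_on_all_labelings(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            lg = random_line_graph(rng, n=4)
            for y in itertools.product((1, -1), repeat=4):
                assert score_labeling(lg, y) == reference_score(lg, y)

    def test_score_requires_computed_indicators(self):
        lg = LabeledLineGraph([(0, 1)], [], np.array([1.0]), np.empty(0))
        with pytest.raises(RuntimeError, match="indicator"):
            score_labeling(lg, [1])

    def test_flipping_isolated_vertex_changes_score_by_two_gamma_y(self):
        rng = np.random.default_rng(8)
        lg = random_line_graph(rng, n=6, p=0.0)  # no edges: all isolated
        y = np.array([1, -1, 1, 1, -1, 1])
        for v in range(6):
            flipped = y.copy()
            flipped[v] = -flipped[v]
            delta = score_labeling(lg, flipped) - score_labeling(lg, y)
            assert delta == -2 * lg.gamma_vertex[v] * y[v]


class TestMapLabeling:
    def test_all_positive_indicators_without_edges(self):
        lg = LabeledLineGraph([(0, 1), (1, 2), (2, 3)], [],
                              np.array([1.0, 2.0, 3.0]), np.empty(0),
                              np.array([1, 1, 1]), np.empty(0, dtype=int))
        np.testing.assert_array_equal(map_labeling(lg), [1, 1, 1])

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            lg = random_line_graph(rng)
            y_exact = map_labeling(lg, backend="exact")
            y_brute = map_labeling(lg, backend="brute-force")
            assert score_labeling(lg, y_exact) == score_labeling(lg, y_brute)
            np.testing.assert_array_equal(y_exact, y_brute)

    def test_disconnected_graph_solves_componentwise(self):
        rng = np.random.default_rng(5)
        a = random_line_graph(rng, n=5)
        b = random_line_graph(rng, n=4)
        joint = LabeledLineGraph(
            a.vertices + [(v[0] + 50, v[1] + 50) for v in b.vertices],
            a.edges + [(i + 5, j + 5) for i, j in b.edges],
            np.concatenate([a.xi_vertex, b.xi_vertex]),
            np.concatenate([a.xi_edge, b.xi_edge]),
            np.concatenate([a.gamma_vertex, b.gamma_vertex]),
            np.concatenate([a.gamma_edge, b.gamma_edge]),
        )
        np.testing.assert_array_equal(
            map_labeling(joint),
            np.concatenate([map_labeling(a), map_labeling(b)]))

    def test_empty_line_graph_gives_empty_labeling(self):
        lg = LabeledLineGraph([], [], np.empty(0), np.empty(0),
                              np.empty(0, dtype=int), np.empty(0, dtype=int))
        assert map_labeling(lg).size == 0

    def test_too_wide_graph_raises_capacity_error(self):
        n = 27  # a clique: induced width n - 1 > the cap
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        lg = LabeledLineGraph(
            [(i, 100 + i) for i in range(n)], edges,
            np.arange(n, dtype=float), np.zeros(len(edges)),
            np.ones(n, dtype=int), np.ones(len(edges), dtype=int))
        with pytest.raises(CapacityError, match="communities"):
            map_labeling(lg, backend="exact")


def test_compute_gammas_flags_large_xi_suffix(two_domain):
    from rigidseg import (build_coarse_graph, build_protein_graph,
                          distance_tensor, louvain_partition)
    ensemble, _ = two_domain
    tensor = distance_tensor(ensemble)
    graph = build_protein_graph(tensor, delta=7.5)
    coarse = build_coarse_graph(graph, tensor,
                                louvain_partition(graph, seed=0))
    lg = compute_gammas(line_graph(coarse))
    # flags must sit on the largest xi values only
    for arr, gamma in ((lg.xi_vertex, lg.gamma_vertex),
                       (lg.xi_edge, lg.gamma_edge)):
        if (gamma == -1).any():
            assert arr[gamma == -1].min() >= arr[gamma == 1].max()


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1e6,
                          allow_nan=False), min_size=1, max_size=40),
       st.floats(min_value=0.5, max_value=6.0))
def test_mad_flags_form_suffix_and_shrink_with_threshold(values, threshold):
    """Outlier flags always occupy a suffix of the ascending array, and a
    stricter threshold never flags more entries."""
    values = np.sort(np.asarray(values))
    flags = mad_outliers(values, threshold)
    neg = np.flatnonzero(flags == -1)
    if neg.size:
        assert neg[-1] == flags.size - 1
        assert np.all(np.diff(neg) == 1)
    stricter = mad_outliers(values, threshold + 1.0)
    assert (stricter == -1).sum() <= neg.size
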