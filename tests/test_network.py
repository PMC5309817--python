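"""Co-occurrence network construction and tightening statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilweb import (
    ValidationError,
    binarize,
    build_edges,
    connectance,
    count_possible,
    export_edges,
    filter_single_occurrence,
    interaction_strengths,
    shannon_index,
    spearman_matrix,
    stage_network,
)
from soilweb.network import CooccurrenceNetwork, EdgeSet, Edge

from conftest import make_table


# ---------------------------------------------------------------------------
# Independent oracle: average ranks, then the Pearson product-moment formula
# ---------------------------------------------------------------------------

def _average_ranks(v):
    v = np.asarray(v, dtype=float)
    n = len(v)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _pearson(x, y):
    x = np.asarray(x, dtype=float) - np.mean(x)
    y = np.asarray(y, dtype=float) - np.mean(y)
    denom = np.sqrt(np.sum(x * x) * np.sum(y * y))
    if denom == 0:
        return np.nan
    return float(np.sum(x * y) / denom)


def brute_force_spearman(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    ranks = [_average_ranks(row) for row in values]
    out = np.full((n, n), np.nan)
    for i in range(n):
        if np.ptp(ranks[i]) > 0:
            out[i, i] = 1.0
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _pearson(ranks[i], ranks[j])
    return out


class TestSpearman:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 2, 4], [1, 3, 3, 4], 1.0),  # identical average-rank vectors
    ])
    def test_known_pairs(self, x, y, expected):
        table = make_table(np.array([x, y], dtype=float))
        m = spearman_matrix(table)
        assert m.rho.iloc[0, 1] == pytest.approx(expected, abs=1e-14)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_rank_then_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 6, size=(8, 9)).astype(float)
        m = spearman_matrix(make_table(values)).rho.to_numpy()
        oracle = brute_force_spearman(values)
        np.testing.assert_allclose(m, oracle, atol=1e-12, equal_nan=True)

    def test_zero_variance_is_undefined_not_propagated(self):
        values = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        m = spearman_matrix(make_table(values)).rho
        assert np.isnan(m.iloc[0, 1]) and np.isnan(m.iloc[0, 0])
        assert m.iloc[1, 1] == 1.0
        assert np.isfinite(m.iloc[1, 2])

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(7)
        values = rng.random((6, 9))
        m = spearman_matrix(make_table(values)).rho.to_numpy()
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError, match="2 samples"):
            spearman_matrix(np.ones((3, 1)))


class TestEdgesAndCounts:
    def _matrix(self, values):
        return spearman_matrix(make_table(values))

    def test_threshold_separates(self):
        # rho(t0,t1) = 1 > 0.9; the third taxon correlates below threshold
        m = self._matrix(np.array([[1, 2, 3, 4], [2, 3, 4, 5],
                                   [1, 3, 2, 4]], dtype=float))
        edges = build_edges(m, tau=0.9)
        assert [(e.taxon_a, e.taxon_b) for e in edges.edges] == [("t0", "t1")]

    def test_negative_correlations_never_edges(self):
        m = self._matrix(np.array([[1, 2, 3], [3, 2, 1]], dtype=float))
        assert m.rho.iloc[0, 1] == -1.0
        assert len(build_edges(m, tau=0.9)) == 0

    def test_undefined_pairs_are_non_edges(self):
        m = self._matrix(np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]]))
        assert len(build_edges(m, tau=0.9)) == 0

    def test_strictness_at_exact_tie(self):
        m = self._matrix(np.array([[1, 2, 3], [1, 2, 3]], dtype=float))
        m.rho.iloc[0, 1] = m.rho.iloc[1, 0] = 0.9
        assert len(build_edges(m, tau=0.9, strict=True)) == 0
        assert len(build_edges(m, tau=0.9, strict=False)) == 1

    @pytest.mark.parametrize("sizes, policy, expected", [
        ((2, 3), "between_only", 6),
        ((2, 3), "all_pairs", 10),
        ((4,), "between_only", 0),
    ])
    def test_count_possible(self, sizes, policy, expected):
        assert count_possible(sizes, policy) == expected

    def test_count_possible_empty(self):
        with pytest.raises(ValidationError):
            count_possible([], "all_pairs")


class TestConnectance:
    # all six printed count pairs of the successional networks
    @pytest.mark.parametrize("n_strong, n_possible, expected", [
        (10961, 1749816, 0.626),
        (26571, 2239795, 1.186),
        (19308, 1510742, 1.278),
        (4833, 822361, 0.588),
        (12621, 1057646, 1.193),
        (9029, 786379, 1.148),
    ])
    def test_published_count_pairs(self, n_strong, n_possible, expected):
        assert round(connectance(n_strong, n_possible), 3) == expected

    def test_empty_network(self):
        assert connectance(0, 100) == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ValidationError):
            connectance(0, 0)

    @given(st.integers(0, 1000), st.integers(1, 1000))
    @settings(deadline=None, derandomize=True)
    def test_bounded_between_0_and_100(self, n, m):
        if n > m:
            n, m = m, n
        assert 0.0 <= connectance(n, m) <= 100.0


class TestInteractionStrengths:
    def test_between_group_strength(self):
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
        edges = EdgeSet(edges=[Edge("a1", "b1", 0.95), Edge("a1", "b2", 0.92),
                               Edge("a2", "b3", 0.99)], tau=0.9)
        out = {(g.group_a, g.group_b): g for g in
               interaction_strengths(edges, groups)}
        ab = out[("A", "B")]
        assert ab.n_possible_ab == 6 and ab.n_strong_ab == 3
        assert ab.interaction_strength == 0.5
        assert out[("A", "A")].displayed is False

    def test_no_edges_zero_strength(self):
        out = interaction_strengths(EdgeSet(edges=[], tau=0.9),
                                    {"a1": "A", "b1": "B"})
        assert all(g.interaction_strength == 0.0 for g in out)

    def test_saturated_pair_reaches_one(self):
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}
        edges = EdgeSet(edges=[Edge(a, b, 0.95) for a, b in
                               itertools.product(["a1", "a2"],
                                                 ["b1", "b2", "b3"])], tau=0.9)
        out = {(g.group_a, g.group_b): g for g in
               interaction_strengths(edges, groups)}
        assert out[("A", "B")].interaction_strength == 1.0

    def test_unmapped_taxon_named(self):
        edges = EdgeSet(edges=[Edge("a1", "zz", 0.95)], tau=0.9)
        with pytest.raises(ValidationError, match="zz"):
            interaction_strengths(edges, {"a1": "A"})

    def test_group_counts_sum_to_total(self, four_taxon_table):
        res = stage_network(four_taxon_table, "recent", tau=0.5)
        total = sum(g.n_strong_ab for g in res.subgroup_interactions)
        assert total == len(res.edge_set)


class TestFilterAndBinarize:
    def test_single_occurrence_removed_boundary_kept(self):
        values = np.zeros((3, 9))
        values[0, 0] = 5.0          # one sample -> removed
        values[1, [0, 1]] = 3.0     # two samples -> retained
        # taxon 2 absent everywhere -> removed
        table = make_table(values, stages=["recent"] * 9)
        kept = filter_single_occurrence(table, "recent")
        assert list(kept.values.index) == ["t1"]

    def test_absent_stage_errors(self):
        table = make_table(np.ones((2, 2)))
        with pytest.raises(ValidationError, match="mid"):
            filter_single_occurrence(table, "mid")

    def test_binarize_values(self):
        table = make_table(np.array([[0.0, 2.5, 7.0]] * 2))
        b = binarize(table)
        assert list(b.values.iloc[0]) == [0.0, 1.0, 1.0]

    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=8))
    @settings(deadline=None, derandomize=True)
    def test_binarize_idempotent(self, row):
        table = make_table(np.array([row, row]))
        once = binarize(table)
        twice = binarize(once)
        assert once.values.equals(twice.values)


class TestShannon:
    @pytest.mark.parametrize("abund, expected", [
        ([1, 1, 1, 1], np.log(4)),
        ([7], 0.0),
        ([0.5, 0.25, 0.25], 1.0397207708399179),
    ])
    def test_known_values(self, abund, expected):
        assert shannon_index(abund) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            shannon_index([0.0, 0.0])

    def test_scale_invariance(self):
        assert shannon_index([2, 4, 6]) == pytest.approx(
            shannon_index([20, 40, 60]), abs=1e-12)


class TestStagePipeline:
    def test_hand_enumerated_connectance(self, four_taxon_table):
        res = stage_network(four_taxon_table, "recent", tau=0.9,
                            policy="all_pairs")
        assert res.summary.n_strong == 1
        assert res.summary.n_possible == 6
        assert res.summary.connectance_pct == pytest.approx(100.0 / 6.0)

    def test_binarized_variant_stays_in_range(self, four_taxon_table):
        res = stage_network(four_taxon_table, "recent", tau=0.9, binary=True)
        assert 0.0 <= res.summary.connectance_pct <= 100.0

    def test_sample_order_invariance(self, four_taxon_table):
        res = stage_network(four_taxon_table, "recent", tau=0.9)
        shuffled = four_taxon_table.subset(
            samples=["s2", "s0", "s3", "s1"])
        res2 = stage_network(shuffled, "recent", tau=0.9)
        assert res.summary == res2.summary

    def test_monotone_transform_invariance(self, four_taxon_table):
        res = stage_network(four_taxon_table, "recent", tau=0.9)
        transformed = make_table(
            np.sqrt(four_taxon_table.values.to_numpy()) * 3.7,
            subgroups=["A", "A", "B", "B"])
        res2 = stage_network(transformed, "recent", tau=0.9)
        assert res.summary == res2.summary
        assert [(e.taxon_a, e.taxon_b) for e in res.edge_set.edges] == \
            [(e.taxon_a, e.taxon_b) for e in res2.edge_set.edges]

    def test_between_only_policy_counts_between_edges(self, four_taxon_table):
        res = stage_network(four_taxon_table, "recent", tau=0.9,
                            policy="between_only")
        # the single strong pair (t0, t1) is within group A
        assert res.summary.n_strong == 0
        assert res.summary.n_possible == 4  # 2 x 2 between A and B

    def test_model_results_interface(self, four_taxon_table):
        results = CooccurrenceNetwork(four_taxon_table, tau=0.9).fit()
        frame = results.summary_frame()
        assert list(frame["stage"]) == ["recent"]
        assert "connectance_pct" in frame.columns
        assert "recent" in results.summary()


class TestExport:
    def test_sif_one_line_per_edge(self, four_taxon_table, tmp_path):
        res = stage_network(four_taxon_table, "recent", tau=0.9)
        path = tmp_path / "e.sif"
        export_edges(res, path, fmt="SIF")
        lines = path.read_text().strip().splitlines()
        assert lines == ["t0 pp t1"]

    def test_graphml_round_trip(self, four_taxon_table, tmp_path):
        res = stage_network(four_taxon_table, "recent", tau=0.9)
        path = tmp_path / "e.graphml"
        export_edges(res, path, fmt="GraphML")
        g = nx.read_graphml(path)
        assert g.number_of_edges() == len(res.edge_set)
        assert g.nodes["t0"]["group"] == "A"
        assert g.edges["t0", "t1"]["rho"] == pytest.approx(1.0)

    def test_empty_network_header_only_tsv(self, tmp_path):
        table = make_table(np.array([[1, 2, 3], [3, 2, 1]], dtype=float))
        res = stage_network(table, "recent", tau=0.9)
        path = tmp_path / "e.tsv"
        export_edges(res, path, fmt="TSV")
        lines = path.read_text().strip().splitlines()
        assert lines == ["a\tb\trho\tgroup_a\tgroup_b"]

    def test_unknown_format(self, four_taxon_table, tmp_path):
        res = stage_network(four_taxon_table, "recent", tau=0.9)
        with pytest.raises(ValidationError, match="format"):
            export_edges(res, tmp_path / "e.xyz", fmt="XYZ")
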