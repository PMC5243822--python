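import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlfc import (
    between_group_tau,
    feature_index,
    feature_pairs,
    n_features,
    rank_features,
    select_top_fraction,
    significant_rois,
)


def tau_by_enumeration(a, b):
    """Independent O(m*n) cross-pair counting oracle."""
    nc = nd = 0
    for va in a:
        for vb in b:
            if vb > va:
                nc += 1
            elif vb < va:
                nd += 1
    return (nc - nd) / (len(a) * len(b))


class TestBetweenGroupTau:
    def test_complete_separation(self):
        assert between_group_tau([1, 2], [3, 4]) == pytest.approx(1.0)

    def test_sign_flip_under_reversal(self):
        assert between_group_tau([3, 4], [1, 2]) == pytest.approx(-1.0)

    def test_interleaved_fixture(self):
        # cross pairs: (1,2)c (1,4)c (3,2)d (3,4)c -> (3-1)/4
        assert between_group_tau([1, 3], [2, 4]) == pytest.approx(0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            between_group_tau([], [1.0])

    def test_matches_enumeration_on_random_fixtures(self, rng):
        for _ in range(200):
            m, n = rng.integers(1, 12, size=2)
            a = rng.integers(0, 6, size=m).astype(float)  # ties likely
            b = rng.integers(0, 6, size=n).astype(float)
            assert between_group_tau(a, b) == pytest.approx(tau_by_enumeration(a, b))

    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=8),
        st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, a, b):
        assert between_group_tau(a, b) == pytest.approx(-between_group_tau(b, a))

    def test_monotone_invariance(self, rng):
        a = rng.standard_normal(7)
        b = rng.standard_normal(5)
        t0 = between_group_tau(a, b)
        assert between_group_tau(np.exp(a), np.exp(b)) == pytest.approx(t0)
        assert between_group_tau(3 * a + 1, 3 * b + 1) == pytest.approx(t0)


class TestIndexMap:
    def test_bijection(self):
        r = 9
        pairs = feature_pairs(r)
        assert len(pairs) == n_features(r)
        ks = [feature_index(i, j, r) for i, j in pairs]
        assert ks == list(range(n_features(r)))

    def test_invalid_pairs_rejected(self):
        with pytest.raises(ValueError):
            feature_index(3, 3, 5)
        with pytest.raises(ValueError):
            feature_index(4, 2, 5)


class TestRankFeatures:
    def test_planted_separator_ranks_first(self, rng):
        codes = np.array([1] * 5 + [2] * 4)
        x = rng.standard_normal((9, 20))
        x[:, 7] = codes  # feature equal to group code
        table = rank_features(x, codes)
        assert table.ranking[0] == 7
        assert abs(table.tau[7]) == pytest.approx(1.0)

    def test_identical_features_tie_break_by_index(self):
        codes = np.array([1, 1, 2, 2])
        x = np.ones((4, 6))
        table = rank_features(x, codes)
        np.testing.assert_array_equal(table.tau, 0.0)
        np.testing.assert_array_equal(table.ranking, np.arange(6))

    def test_matches_per_feature_oracle(self, rng):
        codes = np.array([1, 1, 2, 2])
        x = rng.integers(0, 4, size=(4, 3)).astype(float)
        table = rank_features(x, codes)
        for k in range(3):
            expected = tau_by_enumeration(x[:2, k], x[2:, k])
            assert table.tau[k] == pytest.approx(expected)

    def test_group_swap_negates_tau_keeps_ranking(self, rng):
        codes = np.array([1] * 4 + [3] * 4)
        x = rng.standard_normal((8, 15))
        t13 = rank_features(x, codes, contrast=(1, 3))
        swapped = np.where(codes == 1, 3, 1)
        t_swapped = rank_features(x, swapped, contrast=(1, 3))
        np.testing.assert_allclose(t_swapped.tau, -t13.tau)
        np.testing.assert_array_equal(t_swapped.ranking, t13.ranking)


class TestSelection:
    @pytest.mark.parametrize(
        "n,fraction,expected", [(6670, 0.01, 67), (100, 0.01, 1), (10, 0.25, 3)]
    )
    def test_ceiling_rule(self, rng, n, fraction, expected):
        codes = np.array([1, 1, 2, 2])
        table = rank_features(rng.standard_normal((4, n)), codes)
        selected = select_top_fraction(table, fraction)
        assert selected.size == expected
        np.testing.assert_array_equal(selected, table.ranking[:expected])

    def test_fraction_bounds(self, rng):
        table = rank_features(rng.standard_normal((4, 5)), np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError):
            select_top_fraction(table, 0.0)


class TestSignificantRois:
    def test_hub_node_wins(self):
        # edges {(0,1), (0,2), (0,3), (1,2)}: node 0 has degree 3
        r = 4
        sel = [feature_index(*p, r) for p in [(0, 1), (0, 2), (0, 3), (1, 2)]]
        top, edges = significant_rois(sel, r, ["A", "B", "C", "D"], top_k=1)
        assert top == ["A"]
        assert len(edges) == 4

    def test_single_edge_both_endpoints(self):
        sel = [feature_index(0, 1, 4)]
        top, _ = significant_rois(sel, 4, ["A", "B", "C", "D"], top_k=2)
        assert top == ["A", "B"]

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            significant_rois([], 4)

    def test_degree_matches_networkx(self, rng):
        """67 random selected edges: degrees agree with an independent
        graph-library tally."""
        import networkx as nx

        r = 30
        sel = rng.choice(n_features(r), size=67, replace=False)
        top, edges = significant_rois(sel, r, top_k=4)
        g = nx.from_pandas_edgelist(edges, "region_i", "region_j")
        deg = dict(g.degree())
        labels = [f"R{k:03d}" for k in range(r)]
        best = sorted(labels, key=lambda l: (-deg.get(l, 0), labels.index(l)))[:4]
        assert top == best
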