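import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import entropy

from nlfc import (
    DegenerateSeriesError,
    RoiTimeSeries,
    brute_force_mic,
    characteristic_matrix,
    emic,
    fc_matrix,
    grid_budget,
    grid_mutual_information,
    mic,
    pearson_corr,
)

SEED = 20170119

series_pairs = st.integers(8, 40).flatmap(
    lambda n: st.tuples(
        hnp.arrays(np.float64, n, elements=st.floats(-50, 50, width=32)),
        hnp.arrays(np.float64, n, elements=st.floats(-50, 50, width=32)),
    )
)


class TestPearson:
    def test_self_correlation(self):
        assert pearson_corr([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert pearson_corr([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_evaluated_ratio(self):
        # covariance/sigma ratio computed by hand: 10 / sqrt(10 * 14.8)
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 6]
        assert pearson_corr(x, y) == pytest.approx(10 / np.sqrt(10 * 14.8))

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateSeriesError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGridMutualInformation:
    def test_perfect_association(self):
        assert grid_mutual_information([[5, 0], [0, 5]]) == pytest.approx(1.0)

    def test_exact_independence(self):
        assert grid_mutual_information([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_entropy_sum_oracle(self):
        counts = np.array([[3.0, 1.0], [1.0, 3.0]])
        p = counts / counts.sum()
        expected = (
            entropy(p.sum(1), base=2) + entropy(p.sum(0), base=2) - entropy(p.ravel(), base=2)
        )
        assert grid_mutual_information(counts) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            grid_mutual_information([[1, -1], [0, 2]])


class TestCharacteristicMatrix:
    def test_monotone_median_split(self):
        x = np.arange(1.0, 17.0)
        cm = characteristic_matrix(x, x)
        assert cm.values[2, 2] == pytest.approx(1.0)
        assert cm.b == grid_budget(16)

    def test_constant_column_gives_zero_everywhere(self):
        x = np.arange(1.0, 17.0)
        cm = characteristic_matrix(x, np.ones(16))
        assert np.nanmax(cm.values) == pytest.approx(0.0)

    def test_entries_within_unit_interval(self, rng):
        cm = characteristic_matrix(rng.standard_normal(60), rng.standard_normal(60))
        vals = cm.values[np.isfinite(cm.values)]
        assert np.all((vals >= 0) & (vals <= 1))


class TestMic:
    def test_noiseless_monotone_relation(self):
        x = np.arange(1.0, 21.0)
        assert mic(x, 3 * x + 2) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        x = np.linspace(0.0, 3.0, 24)
        assert mic(x, x) == pytest.approx(mic(x, np.exp(x)))

    def test_quadratic_matches_exhaustive_search(self):
        x = np.arange(1.0, 9.0)
        y = (x - 4.5) ** 2
        assert mic(x, y) == pytest.approx(brute_force_mic(x, y), abs=1e-12)

    def test_oracle_dominates_heuristic(self, rng):
        """The exhaustive search is an upper bound; on easy 10-point data
        the heuristic lands within 0.05 of it."""
        for _ in range(25):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10)
            bf = brute_force_mic(x, y)
            h = mic(x, y)
            assert h <= bf + 1e-9
            assert bf - h <= 0.05

    def test_brute_force_refuses_large_n(self, rng):
        with pytest.raises(ValueError):
            brute_force_mic(rng.standard_normal(13), rng.standard_normal(13))

    def test_independence_limit(self):
        """Independent Gaussian pairs at T = 230: median MIC below 0.35,
        median |PCC| below 0.15 over 200 seeded replicates."""
        rng = np.random.default_rng(SEED)
        mics, pccs = [], []
        for _ in range(200):
            x = rng.standard_normal(230)
            y = rng.standard_normal(230)
            mics.append(mic(x, y))
            pccs.append(abs(pearson_corr(x, y)))
        assert np.median(mics) < 0.35
        assert np.median(pccs) < 0.15


class TestEmic:
    def test_noiseless_linear_limit(self):
        x = np.arange(1.0, 21.0)
        assert emic(x, 2 * x - 1) == pytest.approx(0.0)

    def test_symmetric_quadratic_has_zero_linear_part(self):
        # x symmetric about its mean: sum x^3 = 0 forces rho = 0, so
        # eMIC reduces to the MIC value (checked against the oracle).
        x = np.arange(-4.0, 5.0)
        y = x**2
        assert pearson_corr(x, y) == pytest.approx(0.0)
        assert emic(x, y) == pytest.approx(mic(x, y))
        assert mic(x, y) <= brute_force_mic(x, y) + 1e-9

    @given(series_pairs)
    @settings(max_examples=30, deadline=None)
    def test_identity_and_bounds(self, pair):
        x, y = pair
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        m = mic(x, y)
        r = pearson_corr(x, y)
        assert 0.0 <= m <= 1.0
        assert abs(r) <= 1.0
        assert emic(x, y) == pytest.approx(m - r**2)
        assert mic(y, x) == pytest.approx(m)


class TestFcMatrix:
    def test_identical_rows_pcc(self, rng):
        row = rng.standard_normal(30)
        ts = RoiTimeSeries("s", np.vstack([row, row]), ["a", "b"])
        conn = fc_matrix(ts, "pcc")
        assert conn.values[0, 1] == pytest.approx(1.0)
        assert conn.values[0, 0] == 1.0

    def test_full_parcellation_feature_count(self, rng):
        """R = 116 regions yield 6,670 non-redundant pair values."""
        ts = RoiTimeSeries("s", rng.standard_normal((116, 16)), [f"r{i}" for i in range(116)])
        conn = fc_matrix(ts, "pcc")
        iu = np.triu_indices(116, k=1)
        assert iu[0].size == 6670
        np.testing.assert_array_equal(conn.values, conn.values.T)

    @pytest.mark.parametrize("method", ["pcc", "mic", "emic"])
    def test_symmetry_all_methods(self, toy_series, method):
        conn = fc_matrix(toy_series, method)
        np.testing.assert_array_equal(conn.values, conn.values.T)
        expected_diag = 0.0 if method == "emic" else 1.0
        np.testing.assert_allclose(np.diag(conn.values), expected_diag)

    @pytest.mark.parametrize("method", ["pcc", "emic"])
    def test_label_equivariance(self, toy_series, method):
        """Permuting regions permutes the matrix identically."""
        perm = np.array([2, 0, 3, 1])
        permuted = RoiTimeSeries(
            "p",
            toy_series.values[perm],
            [toy_series.region_labels[i] for i in perm],
        )
        a = fc_matrix(toy_series, method).values
        b = fc_matrix(permuted, method).values
        np.testing.assert_allclose(b, a[np.ix_(perm, perm)], atol=1e-12)

    def test_degenerate_region_substituted_with_warning(self, rng, caplog):
        vals = rng.standard_normal((3, 30))
        vals[1] = 4.2
        ts = RoiTimeSeries("s", vals, ["a", "flat", "c"])
        with caplog.at_level("WARNING"):
            conn = fc_matrix(ts, "emic")
        assert "flat" in caplog.text
        assert conn.values[0, 1] == pytest.approx(0.0)

    def test_round_trip_csv(self, toy_series, tmp_path):
        conn = fc_matrix(toy_series, "pcc")
        path = tmp_path / "conn.csv"
        conn.to_csv(path, alpha=0.6)
        back = type(conn).from_csv(path)
        np.testing.assert_array_equal(back.values, conn.values)
        assert back.method == "pcc"
        assert back.region_labels == conn.region_labels
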