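"""COD, pairwise matrices, distances, Moran's I, and group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from pmnet import core, spatial
from pmnet.core import InsufficientDataError, ValidationError


def _cod_oracle(x, y):
    """Element-by-element loop transliteration of the COD definition."""
    total, p = 0.0, 0
    for xi, yi in zip(x, y):
        if xi + yi == 0:
            continue
        total += ((xi - yi) / (xi + yi)) ** 2
        p += 1
    return np.sqrt(total / p)


class TestCod:
    def test_identical_series_diverge_not_at_all(self):
        assert spatial.cod_pair([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_example(self):
        assert spatial.cod_pair([1.0, 3.0], [3.0, 1.0]) == pytest.approx(0.5)

    def test_zero_against_positive_is_total_divergence(self):
        assert spatial.cod_pair([0.0, 0.0, 0.0], [5.0, 1.0, 2.0]) == pytest.approx(1.0)

    def test_scale_sensitivity(self):
        x = np.array([1.0, 2.0, 3.0])
        assert spatial.cod_pair(x, 2 * x) > 0.0

    def test_zero_sum_pairs_skipped(self):
        # the (0, 0) pair carries no relative information
        assert spatial.cod_pair([0.0, 1.0], [0.0, 1.0]) == 0.0
        with pytest.raises(InsufficientDataError):
            spatial.cod_pair([0.0], [0.0])

    @given(
        hnp.arrays(float, st.integers(2, 30), elements=st.floats(0, 100)),
        st.integers(0, 10_000),
    )
    def test_matches_loop_oracle_and_bounds(self, x, seed):
        y = np.random.default_rng(seed).uniform(0, 100, x.size)
        if np.all(x + y == 0):
            return
        v = spatial.cod_pair(x, y)
        assert abs(v - _cod_oracle(x, y)) < 1e-12
        assert abs(v - spatial.cod_pair(y, x)) < 1e-15  # symmetry
        assert 0.0 <= v <= 1.0


class TestPairwiseMatrix:
    def _series_map(self, arrays):
        idx = pd.date_range("2016-12-01", periods=len(next(iter(arrays.values()))), freq="h")
        return {k: pd.Series(v, index=idx) for k, v in arrays.items()}

    def test_shared_series_gives_trivial_matrices(self):
        base = np.random.default_rng(0).gamma(4, 3, 50)
        m = self._series_map({"a": base, "b": base, "c": base})
        cod = spatial.pairwise_matrix(m, "cod", min_overlap=10)
        r2 = spatial.pairwise_matrix(m, "r2", min_overlap=10)
        assert np.allclose(cod.values, 0.0)
        assert np.allclose(r2.values, 1.0)

    def test_invariant_to_site_ordering(self):
        rng = np.random.default_rng(1)
        m = self._series_map({k: rng.gamma(4, 3, 60) for k in "abcd"})
        fwd = spatial.pairwise_matrix(m, "cod", min_overlap=10)
        rev = spatial.pairwise_matrix(dict(reversed(list(m.items()))), "cod", min_overlap=10)
        pd.testing.assert_frame_equal(
            fwd.values, rev.values.loc[fwd.values.index, fwd.values.columns]
        )

    def test_below_minimum_overlap_left_missing(self):
        rng = np.random.default_rng(2)
        m = self._series_map({k: rng.gamma(4, 3, 30) for k in "ab"})
        m["b"] = m["b"].iloc[:5]
        out = spatial.pairwise_matrix(m, "cod", min_overlap=10)
        assert np.isnan(out.values.loc["a", "b"])
        assert out.n_overlap.loc["a", "b"] == 5


class TestHomogeneity:
    def _matrix(self, value):
        sites = ["a", "b"]
        vals = pd.DataFrame([[0.0, value], [value, 0.0]], index=sites, columns=sites)
        return spatial.PairwiseStatMatrix("cod", "hourly", vals, vals * 0 + 100)

    def test_threshold_boundary(self):
        table, frac = spatial.classify_homogeneity(self._matrix(0.19))
        assert table["label"].iloc[0] == "homogeneous" and frac == 0.0
        table, frac = spatial.classify_homogeneity(self._matrix(0.20))
        assert table["label"].iloc[0] == "heterogeneous" and frac == 1.0

    def test_rejects_r2_matrix(self):
        m = self._matrix(0.1)
        bad = spatial.PairwiseStatMatrix("r2", "hourly", m.values, m.n_overlap)
        with pytest.raises(ValidationError):
            spatial.classify_homogeneity(bad)

    def test_printed_daily_cod_table_is_almost_all_homogeneous(self):
        fx = core.load_fixture_table("table5")
        matrix = spatial.PairwiseStatMatrix("cod", "daily", fx.daily, fx.daily * 0 + 100)
        table, frac = spatial.classify_homogeneity(matrix)
        assert len(table) == 105
        # 11 printed daily pairs sit at or above the 0.2 threshold (eight
        # at exactly 0.20), so ~90% of pairs are homogeneous
        assert (table["label"] == "homogeneous").sum() == 94
        assert (table["cod"] >= 0.2).sum() == 11
        assert table["cod"].max() == pytest.approx(0.22)


class TestDistances:
    def test_haversine_reference_points(self):
        assert spatial.haversine_km((10.0, 20.0), (10.0, 20.0)) == 0.0
        assert spatial.haversine_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(111.19, abs=0.01)
        assert spatial.haversine_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(20015.1, abs=0.1)

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValidationError):
            spatial.haversine_km((95.0, 0.0), (0.0, 0.0))

    def test_distance_matrix_triangle_inequality(self):
        sites = pd.DataFrame(
            {"site_id": list("abc"), "lat": [38.5, 38.55, 38.6], "lon": [-121.5, -121.45, -121.48]}
        )
        km = spatial.distance_matrix(sites)
        for i, j, k in itertools.permutations("abc", 3):
            assert km.loc[i, j] <= km.loc[i, k] + km.loc[k, j] + 1e-9


class TestDistanceDecay:
    def test_fixture_matrices_decay_with_distance(self):
        dist = core.load_fixture_table("table3").km
        cod = core.load_fixture_table("table5")
        r2 = core.load_fixture_table("table4")
        assert spatial.distance_decay(cod.hourly, dist)["slope"] > 0
        assert spatial.distance_decay(r2.hourly, dist)["slope"] < 0

    def test_constant_statistic_has_zero_slope(self):
        dist = core.load_fixture_table("table3").km
        const = dist * 0 + 0.5
        assert spatial.distance_decay(const, dist)["slope"] == 0.0


def _moran_oracle(values, w):
    """Double-sum transliteration of Moran's I with row-standardized w."""
    x = np.asarray(values, float)
    n = x.size
    w = np.asarray(w, float)
    w = w / w.sum(axis=1, keepdims=True)
    z = x - x.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / w.sum() * num / (z @ z)


class TestMoransI:
    def test_paired_partners_give_plus_one(self):
        w = np.array([[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], float)
        out = spatial.morans_i([1.0, 1.0, -1.0, -1.0], w, n_permutations=0)
        assert out["I"] == pytest.approx(1.0)

    def test_alternating_ring_gives_minus_one(self):
        w = np.array(
            [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], float
        )
        out = spatial.morans_i([1.0, -1.0, 1.0, -1.0], w, n_permutations=0)
        assert out["I"] == pytest.approx(-1.0)

    @given(st.integers(0, 500))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        values = rng.normal(size=n)
        w = rng.uniform(0.1, 1.0, (n, n))
        np.fill_diagonal(w, 0.0)
        out = spatial.morans_i(values, w, n_permutations=0)
        assert abs(out["I"] - _moran_oracle(values, w)) < 1e-12

    def test_constant_values_rejected(self):
        w = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(InsufficientDataError):
            spatial.morans_i([2.0, 2.0, 2.0, 2.0], w)

    def test_permutation_p_uniform_under_null(self):
        """For i.i.d. values the permutation p-value should reject at
        roughly the nominal 5% rate."""
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(15)],
                "lat": 38.5 + np.linspace(0, 0.14, 15),
                "lon": -121.5 + np.tile([0.0, 0.05, 0.1], 5),
            }
        )
        w = spatial.spatial_weights(sites)
        rejections = 0
        n_trials = 200
        for seed in range(n_trials):
            values = np.random.default_rng(10_000 + seed).normal(size=15)
            out = spatial.morans_i(values, w, n_permutations=199, seed=seed)
            rejections += out["p_value"] < 0.05
        assert 0.02 <= rejections / n_trials <= 0.08


def _ranksum_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[:n].sum()
    center = n * (len(pooled) + 1) / 2
    stats = [
        ranks[list(combo)].sum() for combo in itertools.combinations(range(len(pooled)), n)
    ]
    dev = abs(observed - center)
    return np.mean([abs(s - center) >= dev - 1e-12 for s in stats])


class TestGroupTests:
    def _series_map(self, arrays):
        return {
            k: pd.Series(v, index=pd.date_range("2016-12-01", periods=len(v), freq="h"))
            for k, v in arrays.items()
        }

    def test_identical_groups_do_not_differ(self):
        m = self._series_map({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        out = spatial.group_test(m, ["a"], ["b"], "welch_t")
        assert out.statistic == pytest.approx(0.0, abs=1e-12)
        assert out.p_value == pytest.approx(1.0)

    def test_exact_rank_sum_on_separated_triples(self):
        m = self._series_map({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        table = spatial.group_test(m, ["a"], ["b"], "wilcoxon_rank")
        assert table["p_value"].iloc[0] == pytest.approx(0.1)
        assert table["mean_difference"].iloc[0] == pytest.approx(-3.0)

    @pytest.mark.parametrize("sizes", [(3, 3), (4, 5), (6, 6)])
    def test_rank_sum_matches_enumeration(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        for _ in range(5):
            x = rng.permutation(np.arange(1.0, sizes[0] + sizes[1] + 1))[: sizes[0]]
            y = np.setdiff1d(np.arange(1.0, sizes[0] + sizes[1] + 1), x)
            m = self._series_map({"a": x, "b": y})
            table = spatial.group_test(m, ["a"], ["b"], "wilcoxon_rank")
            assert table["p_value"].iloc[0] == pytest.approx(_ranksum_oracle(x, y), abs=1e-12)

    def test_holm_adjustment_is_conservative(self):
        rng = np.random.default_rng(9)
        m = self._series_map({k: rng.normal(size=30) for k in "abcdef"})
        table = spatial.rank_sum_pairwise(m, ["a", "b", "c"], ["d", "e", "f"], holm=True)
        assert len(table) == 9
        assert (table["p_holm"] >= table["p_value"] - 1e-12).all()

    def test_empty_group_rejected(self):
        m = self._series_map({"a": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            spatial.group_test(m, ["a"], [], "welch_t")
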