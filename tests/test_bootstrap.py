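"""Bootstrap machinery: type-6 quantiles, CIs, difference tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netboot as nb


class TestQuantileType6:
    def test_median_of_one_to_ten(self):
        # h = 11 * 0.5 = 5.5 -> halfway between 5 and 6
        assert nb.quantile_type6(np.arange(1, 11), 0.5) == pytest.approx(5.5)

    def test_lower_boundary(self):
        # h = 11/11 = 1 -> first order statistic
        assert nb.quantile_type6(np.arange(1, 11), 1 / 11) == pytest.approx(1.0)

    def test_clamps_outside_bracket(self):
        x = np.arange(1, 11)
        assert nb.quantile_type6(x, 0.0) == 1.0
        assert nb.quantile_type6(x, 1.0) == 10.0

    def test_constant_vector(self):
        assert nb.quantile_type6(np.full(7, 3.3), 0.77) == 3.3

    def test_interpolation_formula(self):
        # h = (n+1) p; hand-check an interior value
        x = np.array([2.0, 4.0, 6.0, 8.0])
        h = 5 * 0.6  # 3.0 -> exactly x_(3)
        assert h == 3.0
        assert nb.quantile_type6(x, 0.6) == pytest.approx(6.0)
        # h = 5 * 0.7 = 3.5 -> halfway between x_(3) and x_(4)
        assert nb.quantile_type6(x, 0.7) == pytest.approx(7.0)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            nb.quantile_type6(np.array([]), 0.5)
        with pytest.raises(ValueError):
            nb.quantile_type6(np.array([1.0, np.nan]), 0.5)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bounded_by_order_statistics(self, values, prob):
        q = nb.quantile_type6(np.array(values), prob)
        assert min(values) <= q <= max(values)


class TestCounts:
    def test_min_alpha(self):
        assert nb.min_alpha(1000) == pytest.approx(0.002)
        assert nb.min_alpha(2) == pytest.approx(1.0)
        assert nb.min_alpha(2500) == pytest.approx(0.0008)
        with pytest.raises(ValueError):
            nb.min_alpha(1)

    def test_pair_and_edge_difference_counts(self):
        assert nb.pair_count(17) == 136
        assert nb.edge_difference_count(20) == 17955
        assert nb.pair_count(20) == 190

    def test_bonferroni_level(self):
        assert round(nb.bonferroni_alpha(nb.edge_difference_count(20)), 6) == 0.000003


class TestNonparametricBoot:
    def test_constant_estimator_gives_zero_width_cis(self, ring_data, ring10):
        def constant(_data):
            return ring10

        result = nb.nonparametric_boot(ring_data, constant, n_boot=30, seed=1)
        table = nb.edge_ci_table(result, alpha=0.1)
        np.testing.assert_allclose(table["ci_lower"], table["sample"])
        np.testing.assert_allclose(table["ci_upper"], table["sample"])

    def test_seed_reproducibility(self, ring_data, fast_estimator):
        r1 = nb.nonparametric_boot(ring_data, fast_estimator, n_boot=15, seed=9)
        r2 = nb.nonparametric_boot(ring_data, fast_estimator, n_boot=15, seed=9)
        np.testing.assert_array_equal(r1.edge_samples, r2.edge_samples)
        np.testing.assert_array_equal(r1.centrality_samples, r2.centrality_samples)

    def test_failed_replicates_redrawn_and_counted(self, ring_data, ring10):
        calls = {"k": 0}

        def flaky(data):
            calls["k"] += 1
            if calls["k"] % 12 == 0:
                raise nb.DegenerateVariableError("synthetic failure")
            return ring10

        result = nb.nonparametric_boot(ring_data, flaky, n_boot=30, seed=2)
        assert result.n_boot == 30
        assert result.edge_samples.shape[0] == 30
        assert result.n_redrawn >= 2

    def test_excessive_failures_abort(self, ring_data, ring10):
        def broken(_data):
            raise nb.DegenerateVariableError("always fails")

        with pytest.raises(RuntimeError, match="10%"):
            nb.nonparametric_boot(
                ring_data, broken, n_boot=20, seed=3, sample_network=ring10
            )


class TestParametricBoot:
    def test_empty_network_bootstraps_near_zero(self):
        net = nb.NetworkModel(np.zeros((6, 6)))
        result = nb.parametric_boot(net, n=300, n_boot=25, seed=4)
        assert result.note == "continuous-data bootstrap"
        assert np.median(np.abs(result.edge_samples)) == pytest.approx(0.0, abs=0.02)

    def test_seed_reproducibility(self, ring10):
        r1 = nb.parametric_boot(ring10, n=200, n_boot=10, seed=5)
        r2 = nb.parametric_boot(ring10, n=200, n_boot=10, seed=5)
        np.testing.assert_array_equal(r1.edge_samples, r2.edge_samples)

    def test_shrinkage_biased_toward_zero_not_away(self, ring10):
        """Replicated edge weights of true ring edges stay within 0.07 of
        |0.25| and the bias points toward zero (lasso shrinkage)."""
        result = nb.parametric_boot(ring10, n=2500, n_boot=25, seed=6)
        true_mask = np.abs(ring10.edge_vector()) > 0
        signs = np.sign(ring10.edge_vector()[true_mask])
        means = result.edge_samples[:, true_mask].mean(axis=0) * signs
        assert np.all(np.abs(means - 0.25) < 0.07)
        assert np.mean(means) <= 0.25 + 1e-6

    def test_unrepresentable_network_rejected(self):
        w = np.full((3, 3), 0.9)
        np.fill_diagonal(w, 0.0)
        with pytest.raises(nb.NotRepresentableError):
            nb.parametric_boot(nb.NetworkModel(w), n=100, n_boot=10, seed=0)


class TestEdgeCiTable:
    def test_alpha_below_floor_rejected(self, small_boot):
        with pytest.raises(ValueError, match="2/N_B"):
            nb.edge_ci_table(small_boot, alpha=0.001)

    def test_alpha_at_floor_spans_replicate_range(self, small_boot):
        table = nb.edge_ci_table(small_boot, alpha=nb.min_alpha(small_boot.n_boot))
        # map rows back to edge slots to compare with min/max
        pairs = [f"{a}--{b}" for a, b in small_boot.edge_pairs]
        for _, row in table.iterrows():
            e = pairs.index(row["edge"])
            assert row["ci_lower"] == pytest.approx(small_boot.edge_samples[:, e].min())
            assert row["ci_upper"] == pytest.approx(small_boot.edge_samples[:, e].max())

    def test_rows_ordered_by_sample_then_boot_mean(self, small_boot):
        table = nb.edge_ci_table(small_boot, alpha=0.05)
        s = table["sample"].to_numpy()
        assert np.all(np.diff(s) <= 0)
        ties = np.flatnonzero(np.diff(s) == 0)
        for t in ties:
            assert table["boot_mean"].iloc[t] >= table["boot_mean"].iloc[t + 1]

    def test_normal_theory_coverage(self):
        """Type-6 CI endpoints on 200 standard-normal replicates land near
        +-1.96 on average over 50 seeded draws."""
        rng = np.random.default_rng(8)
        los, his = [], []
        for _ in range(50):
            x = rng.standard_normal(200)
            los.append(nb.quantile_type6(x, 0.025))
            his.append(nb.quantile_type6(x, 0.975))
        assert abs(np.mean(los) + 1.96) < 0.15
        assert abs(np.mean(his) - 1.96) < 0.15


class TestDifferenceTest:
    def test_identical_replicates_not_significant(self, ring_data, ring10):
        # a constant estimator ties every pair of statistics in every
        # replicate, the way lasso-zeroed edges tie at exactly 0
        result = nb.nonparametric_boot(ring_data, lambda d: ring10, n_boot=60, seed=7)
        zero_cols = np.flatnonzero((result.edge_samples == 0.0).all(axis=0))
        test = nb.difference_test(
            result, "edge", int(zero_cols[0]), int(zero_cols[1]), alpha=0.05
        )
        assert test.ci_lower == test.ci_upper == 0.0
        assert not test.significant

    def test_mirrored_pair_gives_mirrored_ci(self, small_boot):
        t_ab = nb.difference_test(small_boot, "strength", 0, 5, alpha=0.05)
        t_ba = nb.difference_test(small_boot, "strength", 5, 0, alpha=0.05)
        assert t_ab.ci_lower == pytest.approx(-t_ba.ci_upper)
        assert t_ab.ci_upper == pytest.approx(-t_ba.ci_lower)
        assert t_ab.significant == t_ba.significant

    def test_ci_nesting_in_alpha(self, small_boot):
        t_wide = nb.difference_test(small_boot, "strength", 0, 3, alpha=0.05)
        t_narrow = nb.difference_test(small_boot, "strength", 0, 3, alpha=0.5)
        assert t_wide.ci_lower <= t_narrow.ci_lower
        assert t_wide.ci_upper >= t_narrow.ci_upper

    def test_same_id_rejected(self, small_boot):
        with pytest.raises(ValueError):
            nb.difference_test(small_boot, "strength", 2, 2)

    def test_unknown_id_rejected(self, small_boot):
        with pytest.raises(ValueError, match="unknown id"):
            nb.difference_test(small_boot, "strength", "nope", 0)

    def test_significance_matches_ci(self, small_boot):
        test = nb.difference_test(small_boot, "closeness", 1, 4, alpha=0.05)
        assert test.significant == (not test.ci_lower <= 0 <= test.ci_upper)

    def test_all_pairs_matrix_counts(self, small_boot):
        dm = nb.difference_matrix(small_boot, "strength", alpha=0.05)
        assert dm.n_tests == nb.pair_count(10)
        assert dm.significant.shape == (10, 10)
        assert not dm.significant.diagonal().any()
        np.testing.assert_array_equal(dm.significant, dm.significant.T)

    def test_only_nonzero_restricts_edges(self, small_boot):
        dm = nb.difference_matrix(small_boot, "edge", alpha=0.05, only_nonzero=True)
        assert len(dm.ids) == small_boot.sample_network.n_edges()
        payload = dm.to_json_dict()
        assert payload["n_tests"] == nb.pair_count(len(dm.ids))
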