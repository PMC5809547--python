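"""Polychoric/polyserial/Pearson correlation estimation and PD repair."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import netboot as nb
from netboot.correlations import PD_FLOOR, RHO_MAX


def ordinalize(z, thresholds):
    return np.searchsorted(np.asarray(thresholds), z)


class TestThresholds:
    def test_balanced_binary_threshold_is_zero(self):
        col = np.repeat([0, 1], 50)
        np.testing.assert_allclose(nb.estimate_thresholds(col), [0.0], atol=1e-12)

    def test_equiprobable_four_levels_match_normal_quantiles(self):
        col = np.repeat([0, 1, 2, 3], 25)
        expected = stats.norm.ppf([0.25, 0.5, 0.75])
        np.testing.assert_allclose(nb.estimate_thresholds(col), expected, atol=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(nb.DegenerateVariableError, match="degenerate"):
            nb.estimate_thresholds(np.zeros(30))

    def test_thresholds_strictly_increasing_and_finite(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 5, size=200)
        thr = nb.estimate_thresholds(col)
        assert np.all(np.isfinite(thr))
        assert np.all(np.diff(thr) > 0)

    @given(st.permutations(list(range(4))))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_invariant_to_monotone_relabeling(self, perm):
        # any strictly increasing relabeling of the categories
        rng = np.random.default_rng(3)
        col = rng.integers(0, 4, size=300)
        relabel = np.array(sorted(10 * np.array(perm) + 5))  # increasing codes
        np.testing.assert_allclose(
            nb.estimate_thresholds(col), nb.estimate_thresholds(relabel[col])
        )


class TestNearestPd:
    def test_identity_unchanged(self):
        np.testing.assert_array_equal(nb.nearest_pd(np.eye(4)), np.eye(4))

    def test_overcorrelated_2x2_repaired(self):
        m = np.array([[1.0, 1.2], [1.2, 1.0]])
        out = nb.nearest_pd(m)
        np.testing.assert_allclose(np.diag(out), 1.0)
        assert abs(out[0, 1]) < 1.0
        assert np.linalg.eigvalsh(out)[0] >= PD_FLOOR * (1 - 1e-9)

    def test_postcondition_on_random_indefinite_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            m = rng.uniform(-1, 1, size=(6, 6))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 1.0)
            out = nb.nearest_pd(m)
            assert np.linalg.eigvalsh(out)[0] >= PD_FLOOR * (1 - 1e-9)
            np.testing.assert_allclose(np.diag(out), 1.0, atol=1e-12)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            nb.nearest_pd(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestPolychoric:
    def test_identical_columns_clamp_to_rho_max(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 4, size=300).astype(float)
        data = nb.OrdinalDataset(
            np.column_stack([col, col]), ["a", "b"], ["ordinal", "ordinal"]
        )
        # perfect agreement hits the rho_max clamp when the empty
        # off-diagonal cells are left at zero ...
        est = nb.polychoric_matrix(data, continuity=False)
        assert est.matrix[0, 1] >= RHO_MAX - 0.01
        # ... and the continuity constant (default) pulls it only slightly off
        est = nb.polychoric_matrix(data)
        assert est.matrix[0, 1] > 0.9

    def test_recovers_latent_correlation(self):
        # latent bivariate normal, rho = 0.5, symmetric quartile thresholds
        rng = np.random.default_rng(4)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=4000)
        thr = [-0.6745, 0.0, 0.6745]
        x = np.column_stack([ordinalize(z[:, 0], thr), ordinalize(z[:, 1], thr)])
        est = nb.polychoric_matrix(
            nb.OrdinalDataset(x, ["a", "b"], ["ordinal", "ordinal"])
        )
        assert abs(est.matrix[0, 1] - 0.5) < 0.05

    @pytest.mark.parametrize("rho", [-0.6, 0.0, 0.6])
    def test_parameter_recovery_across_sign_and_strength(self, rho):
        """Two-step estimate lands within 0.05 of the latent rho at n=5000
        (20 Monte-Carlo replicates with random 4-level thresholds)."""
        rng = np.random.default_rng(int(10 * (rho + 1)))
        errors = []
        for _ in range(20):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
            cols = []
            for j in range(2):
                while True:
                    thr = np.sort(rng.standard_normal(3))
                    c = ordinalize(z[:, j], thr)
                    if np.unique(c).size == 4:
                        break
                cols.append(c)
            est = nb.polychoric_matrix(
                nb.OrdinalDataset(np.column_stack(cols), ["a", "b"], ["ordinal"] * 2)
            )
            errors.append(est.matrix[0, 1] - rho)
        assert np.max(np.abs(errors)) < 0.05

    def test_continuous_columns_equal_plain_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(200, 4))
        data = nb.OrdinalDataset(x, list("abcd"), ["continuous"] * 4)
        est = nb.polychoric_matrix(data)
        np.testing.assert_allclose(est.matrix, np.corrcoef(x.T), atol=1e-12)
        assert est.method == "pearson"
        assert est.n == 200

    def test_mixed_polyserial_recovers_latent_correlation(self):
        rng = np.random.default_rng(6)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=4000)
        x = np.column_stack([z[:, 0], ordinalize(z[:, 1], [-0.6745, 0, 0.6745])])
        est = nb.polychoric_matrix(
            nb.OrdinalDataset(x, ["a", "b"], ["continuous", "ordinal"])
        )
        assert est.method == "mixed"
        assert abs(est.matrix[0, 1] - 0.5) < 0.05

    def test_output_symmetric_unit_diagonal_pd(self, ring_data):
        est = nb.polychoric_matrix(ring_data)
        np.testing.assert_allclose(est.matrix, est.matrix.T)
        np.testing.assert_allclose(np.diag(est.matrix), 1.0)
        assert np.linalg.eigvalsh(est.matrix)[0] > 0

    def test_matches_scipy_bivariate_cdf_likelihood(self):
        """Golden-section optimum agrees with a brute-force grid search
        using scipy's bivariate normal CDF as an independent likelihood."""
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=800)
        thr = [-0.5, 0.5]
        x = np.column_stack([ordinalize(z[:, 0], thr), ordinalize(z[:, 1], thr)])
        data = nb.OrdinalDataset(x, ["a", "b"], ["ordinal"] * 2)
        est = nb.polychoric_matrix(data, continuity=False)

        tx = nb.estimate_thresholds(x[:, 0])
        ty = nb.estimate_thresholds(x[:, 1])
        table = np.zeros((3, 3))
        for i, j in x.astype(int):
            table[i, j] += 1
        ex = np.concatenate(([-np.inf], tx, [np.inf]))
        ey = np.concatenate(([-np.inf], ty, [np.inf]))

        def loglik(rho):
            mvn = stats.multivariate_normal(cov=[[1, rho], [rho, 1]])

            def cdf(h, k):
                if h == -np.inf or k == -np.inf:
                    return 0.0
                if h == np.inf and k == np.inf:
                    return 1.0
                if h == np.inf:
                    return stats.norm.cdf(k)
                if k == np.inf:
                    return stats.norm.cdf(h)
                return mvn.cdf([h, k])

            ll = 0.0
            for i in range(3):
                for j in range(3):
                    pij = (
                        cdf(ex[i + 1], ey[j + 1])
                        - cdf(ex[i], ey[j + 1])
                        - cdf(ex[i + 1], ey[j])
                        + cdf(ex[i], ey[j])
                    )
                    ll += table[i, j] * np.log(max(pij, 1e-300))
            return ll

        grid = np.linspace(-0.95, 0.95, 381)
        brute = grid[np.argmax([loglik(r) for r in grid])]
        assert abs(est.matrix[0, 1] - brute) < 0.01


class TestDatasetValidation:
    def test_rejects_constant_column(self):
        vals = np.column_stack([np.ones(10), np.arange(10)])
        with pytest.raises(nb.DegenerateVariableError):
            nb.OrdinalDataset(vals, ["a", "b"], ["ordinal", "ordinal"])

    def test_rejects_tiny_shapes(self):
        with pytest.raises(ValueError):
            nb.OrdinalDataset(np.zeros((1, 3)), list("abc"), ["ordinal"] * 3)

    def test_auto_detection_integer_vs_continuous(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        frame = pd.DataFrame(
            {"ord": rng.integers(0, 4, 50), "cont": rng.normal(size=50)}
        )
        data = nb.OrdinalDataset.from_frame(frame)
        assert data.level == ["ordinal", "continuous"]

    def test_round_trip_through_csv(self, tmp_path):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 4, size=(40, 3)).astype(float)
        data = nb.OrdinalDataset(x, ["a", "b", "c"], ["ordinal"] * 3)
        path = tmp_path / "d.csv"
        data.to_frame().to_csv(path, index=False)
        back = nb.read_table(path)
        np.testing.assert_array_equal(back.values, data.values)
        assert back.level == data.level


def test_pairwise_missing_handling():
    rng = np.random.default_rng(10)
    x = rng.integers(0, 4, size=(300, 3)).astype(float)
    x[:30, 0] = np.nan
    data = nb.OrdinalDataset(x, list("abc"), ["ordinal"] * 3)
    est = nb.polychoric_matrix(data)
    assert np.all(np.isfinite(est.matrix))
    assert est.n < 300  # average pairwise-complete count


def test_listwise_missing_handling():
    rng = np.random.default_rng(11)
    x = rng.integers(0, 4, size=(300, 3)).astype(float)
    x[:30, 0] = np.nan
    data = nb.OrdinalDataset(x, list("abc"), ["ordinal"] * 3)
    est = nb.polychoric_matrix(data, missing="listwise")
    assert np.all(np.isfinite(est.matrix))
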