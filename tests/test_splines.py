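"""Spline basis, lag matrix and cross-basis construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from heatrisk.splines import (LagSpec, SplineSpec, cross_basis, lag_matrix,
                              ns_basis, ns_basis_deriv, percentile_knots)


# ---------------------------------------------------------------------------
# independent oracle: natural cubic splines in truncated-power form
# ---------------------------------------------------------------------------

def truncated_power_natural_basis(knots):
    """Span of natural cubic splines with the given knots, textbook form.

    Returns a callable x -> matrix with columns [1, x, N_1..N_{K-2}] where
    N_i(x) = d_i(x) - d_{K-1}(x), d_i(x) = ((x-k_i)_+^3 - (x-k_K)_+^3)/(k_K - k_i).
    """
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(i, x):
        return (np.maximum(x - knots[i], 0) ** 3
                - np.maximum(x - knots[K - 1], 0) ** 3) / (knots[K - 1] - knots[i])

    def evaluate(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        cols = [np.ones_like(x), x]
        for i in range(K - 2):
            cols.append(d(i, x) - d(K - 2, x))
        return np.column_stack(cols)

    return evaluate


def oracle_cardinal_basis(spec, x):
    """Cardinal natural-spline basis values solved in truncated-power form."""
    knots = spec.all_knots
    tp = truncated_power_natural_basis(knots)
    A = tp(knots)  # K x K, full rank
    out = []
    for j in range(1, len(knots)):
        target = np.zeros(len(knots))
        target[j] = 1.0
        coef = np.linalg.solve(A, target)
        out.append(tp(x) @ coef)
    return np.column_stack(out)


# ---------------------------------------------------------------------------
# percentile_knots
# ---------------------------------------------------------------------------

class TestPercentileKnots:
    def test_constant_sample(self):
        assert percentile_knots([5, 5, 5, 5], [50, 90]).tolist() == [5, 5]

    def test_exact_order_statistic(self):
        assert percentile_knots(np.arange(101), [50]).tolist() == [50.0]

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 30, 200)
        got = percentile_knots(values, [50, 90])
        srt = np.sort(values)
        expected = []
        for p in (50, 90):
            h = (len(srt) - 1) * p / 100
            lo = int(np.floor(h))
            expected.append(srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo]))
        np.testing.assert_allclose(got, sorted(expected), atol=1e-12)

    @pytest.mark.parametrize("bad", [[], [np.nan, 1.0]])
    def test_rejects_empty_or_nonfinite(self, bad):
        with pytest.raises(ValueError):
            percentile_knots(bad, [50])

    def test_rejects_probs_outside_open_interval(self):
        with pytest.raises(ValueError):
            percentile_knots([1, 2, 3], [0])


# ---------------------------------------------------------------------------
# ns_basis
# ---------------------------------------------------------------------------

class TestNsBasis:
    spec = SplineSpec(internal_knots=(15.0, 22.0), boundary_knots=(2.0, 30.0))

    def test_dimension_rule(self):
        assert ns_basis(np.linspace(2, 30, 7), self.spec).shape == (7, 3)

    def test_linear_beyond_boundary(self):
        # natural condition: second differences vanish outside the boundary
        for grid in (np.linspace(30.5, 40, 50), np.linspace(-10, 1.5, 50)):
            B = ns_basis(grid, self.spec)
            second = np.diff(B, 2, axis=0)
            assert np.abs(second).max() < 1e-8

    def test_agrees_with_truncated_power_oracle(self):
        spec = SplineSpec(internal_knots=(0.0,), boundary_knots=(-1.0, 1.0))
        x = np.array([0.5])
        np.testing.assert_allclose(ns_basis(x, spec), oracle_cardinal_basis(spec, x),
                                   atol=1e-8)
        x = np.linspace(-1.5, 1.5, 41)
        np.testing.assert_allclose(ns_basis(x, self.spec),
                                   oracle_cardinal_basis(self.spec, x), atol=1e-8)

    def test_rejects_nonfinite_listing_indices(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            ns_basis([1.0, np.nan, 2.0], self.spec)

    def test_pointwise_equals_vectorized(self):
        x = np.linspace(0, 32, 9)
        full = ns_basis(x, self.spec)
        rows = np.vstack([ns_basis([v], self.spec) for v in x])
        np.testing.assert_array_equal(full, rows)

    @given(st.integers(0, 2**32 - 1))
    def test_family_closure(self, seed):
        # any natural spline on the same knots is reproduced with ~0 residual
        rng = np.random.default_rng(seed)
        coef = rng.normal(0, 2, 3)
        const = rng.normal()
        x = rng.uniform(-2, 34, 60)
        y = ns_basis(x, self.spec) @ coef + const
        X = np.column_stack([np.ones_like(x), ns_basis(x, self.spec)])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(resid).max() < 1e-8

    def test_derivative_matches_finite_differences(self):
        x = np.linspace(3, 29, 11)
        h = 1e-6
        fd = (ns_basis(x + h, self.spec) - ns_basis(x - h, self.spec)) / (2 * h)
        np.testing.assert_allclose(ns_basis_deriv(x, self.spec), fd, atol=1e-6)


# ---------------------------------------------------------------------------
# lag_matrix / cross_basis
# ---------------------------------------------------------------------------

class TestLagMatrix:
    def test_hand_shift(self):
        mat, valid = lag_matrix([10, 11, 12, 13, 14], 2)
        assert mat[4].tolist() == [14, 13, 12]
        assert valid.tolist() == [False, False, True, True, True]

    def test_zero_lag_is_identity(self):
        series = np.array([3.0, 1.0, 4.0])
        mat, valid = lag_matrix(series, 0)
        np.testing.assert_array_equal(mat[:, 0], series)
        assert valid.all()

    def test_lag_window_three_gives_four_columns(self):
        mat, _ = lag_matrix(np.arange(10.0), 3)
        assert mat.shape[1] == 4

    def test_blocks_do_not_leak_across_boundaries(self):
        series = np.arange(6.0)
        blocks = [0, 0, 0, 1, 1, 1]
        mat, valid = lag_matrix(series, 2, block_ids=blocks)
        assert valid.tolist() == [False, False, True, False, False, True]
        assert np.isnan(mat[3, 1])  # day 4 must not see day 3 across the gap


class TestCrossBasis:
    spec = SplineSpec(internal_knots=(16.0, 23.0), boundary_knots=(5.0, 30.0))

    def test_collapses_to_spline_basis_at_zero_lag(self):
        series = np.linspace(6, 29, 12)
        cb = cross_basis(series, self.spec, LagSpec(0))
        np.testing.assert_allclose(cb.matrix, ns_basis(series, self.spec), atol=0)

    def test_product_dimension(self):
        cb = cross_basis(np.linspace(6, 29, 12), self.spec, LagSpec(3))
        assert cb.matrix.shape[1] == 12  # 3 exposure df x 4 lag strata

    def test_identity_exposure_reduces_to_lag_matrix(self):
        series = np.array([10.0, 12.0, 9.0, 14.0, 11.0, 13.0])
        cb = cross_basis(series, None, LagSpec(2))
        lagmat, valid = lag_matrix(series, 2)
        np.testing.assert_array_equal(cb.matrix[valid], lagmat[valid])
        np.testing.assert_array_equal(cb.valid_rows, valid)

    def test_column_layout_and_block_sum(self):
        # column (j, l) holds ns_j at lag l; summing lag blocks gives the
        # cumulative quantity sum_l ns(series[t-l])
        rng = np.random.default_rng(5)
        series = rng.uniform(5, 30, 40)
        L = 3
        cb = cross_basis(series, self.spec, LagSpec(L))
        valid = cb.valid_rows
        for l in range(L + 1):
            expect = ns_basis(np.roll(series, l), self.spec)
            got = cb.matrix[:, [j * (L + 1) + l for j in range(3)]]
            np.testing.assert_allclose(got[valid], expect[valid], atol=1e-12)
        summed = sum(
            cb.matrix[:, [j * (L + 1) + l for j in range(3)]] for l in range(L + 1)
        )
        direct = sum(ns_basis(np.roll(series, l), self.spec) for l in range(L + 1))
        np.testing.assert_allclose(summed[valid], direct[valid], atol=1e-10)

    def test_masked_rows_are_nan_not_zero(self):
        cb = cross_basis(np.linspace(6, 29, 8), self.spec, LagSpec(3))
        assert np.isnan(cb.matrix[:3]).all()
        assert np.isfinite(cb.matrix[3:]).all()
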