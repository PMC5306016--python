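import math

import numpy as np
import pytest
from scipy import stats as sps

from mycomediate.stats_core import aic, fit_segmented, fit_spatial_gls, kendall_tau


def sum_ties(v):
    _, counts = np.unique(v, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def oracle_tau_b(x, y):
    """Independent O(n^2) pair-counting oracle for tau-b."""
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    n0 = n * (n - 1) // 2
    return s / math.sqrt((n0 - sum_ties(x)) * (n0 - sum_ties(y)))


class TestKendall:
    def test_perfect_orderings(self):
        x = np.arange(10.0)
        assert kendall_tau(x, 2 * x + 1).estimate == 1.0
        assert kendall_tau(x, -x).estimate == -1.0

    def test_small_example_matches_pair_counting(self):
        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 2, 3, 1, 5], float)
        t = kendall_tau(x, y)
        assert t.estimate == pytest.approx(oracle_tau_b(x, y), abs=1e-12)

    def test_matches_oracle_on_random_tied_vectors(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 31))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if sum_ties(x) == n * (n - 1) // 2 or sum_ties(y) == n * (n - 1) // 2:
                continue
            assert kendall_tau(x, y).estimate == pytest.approx(
                oracle_tau_b(x, y), abs=1e-12
            )

    def test_normal_approximation_agrees_with_reference(self, rng):
        """Tie-adjusted z p-values match the scipy asymptotic implementation."""
        for _ in range(10):
            x = rng.integers(0, 8, 40).astype(float)
            y = rng.integers(0, 8, 40).astype(float)
            ours = kendall_tau(x, y)
            ref = sps.kendalltau(x, y, method="asymptotic")
            assert ours.estimate == pytest.approx(ref.statistic, abs=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_small_n_enumeration_is_valid(self, rng):
        """Exact permutation p at n<=8 upper-bounds alpha under the null."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([3.0, 1.0, 4.0, 2.0, 6.0, 5.0])
        t = kendall_tau(x, y)
        assert 0.0 < t.p_value <= 1.0
        # enumeration over all 6! permutations is symmetric: reversing y gives same p
        assert kendall_tau(x, y[::-1].copy()).p_value == pytest.approx(t.p_value, abs=0.2)

    def test_completely_tied_vector_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            kendall_tau(np.ones(10), np.arange(10.0))


class TestSegmented:
    @staticmethod
    def _piecewise(x, psi=0.043, a=0.02, b1=8.0, b2=-8.0):
        return a + b1 * x + b2 * np.maximum(x - psi, 0.0)

    def test_exact_recovery_on_noise_free_data(self, rng):
        x = rng.uniform(0, 0.15, 200)
        f = fit_segmented(x, self._piecewise(x), n_boot=0)
        assert abs(f.psi - 0.043) < 1e-6
        assert f.sse < 1e-10
        assert f.slope_left == pytest.approx(8.0, abs=1e-4)
        assert f.slope_right == pytest.approx(0.0, abs=1e-4)
        assert f.material

    def test_globally_linear_data_flags_no_material_breakpoint(self, rng):
        x = rng.uniform(0, 1, 300)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.1, 300)
        f = fit_segmented(x, y, n_boot=0)
        assert not f.material
        assert f.sse <= f.sse_line + 1e-9

    def test_two_segment_sse_never_exceeds_single_line(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 1, 80)
            y = rng.standard_normal(80)
            f = fit_segmented(x, y, n_boot=0)
            assert f.sse <= f.sse_line + 1e-9

    def test_sse_non_increasing_under_grid_refinement(self, rng):
        x = rng.uniform(0, 1, 150)
        y = np.sin(3 * x) + rng.normal(0, 0.2, 150)
        coarse = fit_segmented(x, y, n_grid=20, n_boot=0)
        fine = fit_segmented(x, y, n_grid=400, n_boot=0)
        assert fine.sse <= coarse.sse + 1e-9

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_segmented(np.ones(20), np.arange(20.0), n_boot=0)

    def test_bootstrap_ci_brackets_strong_breakpoint(self, rng):
        x = rng.uniform(0, 0.15, 300)
        y = self._piecewise(x) + rng.normal(0, 0.03, 300)
        f = fit_segmented(x, y, n_boot=100, seed=1)
        lo, hi = f.psi_ci
        assert lo <= f.psi <= hi


class TestSpatialGLS:
    def test_nugget_one_collapses_to_ols(self, rng):
        n = 100
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 2.0] + rng.standard_normal(n)
        coords = rng.uniform(0, 1000, (n, 2))
        g = fit_spatial_gls(X, y, coords, fix_nugget=1.0)
        o = fit_spatial_gls(X, y, coords, correlation="none")
        np.testing.assert_allclose(g.beta, o.beta, atol=1e-6)

    def test_duplicated_coordinates_handled_by_nugget(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [0.5, 1.0] + rng.standard_normal(n)
        coords = np.repeat(rng.uniform(0, 100, (n // 2, 2)), 2, axis=0)
        g = fit_spatial_gls(X, y, coords)
        assert np.isfinite(g.loglik)
        assert 0 <= g.nugget <= 1

    def test_singular_design_rejected(self, rng):
        n = 40
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="singular"):
            fit_spatial_gls(X, rng.standard_normal(n), rng.uniform(0, 10, (n, 2)))

    def test_optimum_beats_near_independence_corner(self, rng):
        from scipy.linalg import cholesky
        from scipy.spatial.distance import pdist, squareform

        n = 120
        coords = rng.uniform(0, 2000, (n, 2))
        d = squareform(pdist(coords))
        C = 0.8 * np.exp(-d / 400)
        np.fill_diagonal(C, 1.0)
        L = cholesky(C, lower=True)
        x = rng.standard_normal(n)
        y = x + L @ rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        g = fit_spatial_gls(X, y, coords, n_starts=3, seed=0)
        corner = fit_spatial_gls(X, y, coords, fix_range=1e-3, fix_nugget=0.5)
        assert g.loglik >= corner.loglik - 1e-6

    def test_reml_runs_and_differs_from_ml(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 1.0] + rng.standard_normal(n)
        coords = rng.uniform(0, 500, (n, 2))
        ml = fit_spatial_gls(X, y, coords, method="ML", n_starts=2, seed=0)
        reml = fit_spatial_gls(X, y, coords, method="REML", n_starts=2, seed=0)
        assert np.isfinite(reml.loglik) and reml.loglik != ml.loglik


class TestAIC:
    def test_closed_form(self):
        assert aic(0.0, 1) == 2.0
        assert aic(-10.0, 3) == 26.0

    def test_difference_identity(self):
        assert aic(-5.0, 4) - aic(-2.0, 2) == pytest.approx(2 * 2 - 2 * (-3.0))

    def test_requires_positive_k(self):
        with pytest.raises(ValueError):
            aic(0.0, 0)
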