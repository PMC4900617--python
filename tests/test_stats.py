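"""Descriptive moments, yield classes, raster correlation and regression."""

import math

import numpy as np
import pytest

from pivotyield import (
    classify_yield,
    correlate_grids,
    correlation_matrix,
    describe,
    regress_yield_on_index,
)
from pivotyield.stats import kurtosis_se, skewness_se

from conftest import make_grid


class TestDescribe:
    def test_symmetric_sample(self):
        d = describe(np.array([1.0, 2.0, 3.0]))
        assert d.skewness == pytest.approx(0.0, abs=1e-12)
        assert d.variance == pytest.approx(1.0)
        assert d.std == pytest.approx(1.0)

    def test_se_values_at_study_count(self):
        """n = 1677 gives SE_skew ~ 0.06 and SE_kurt ~ 0.12."""
        assert round(skewness_se(1677), 2) == 0.06
        assert round(kurtosis_se(1677), 2) == 0.12

    def test_moments_match_sum_formula_oracle(self, rng):
        z = rng.gamma(3.0, 1.0, size=500)
        d = describe(z)
        n = len(z)
        mean = z.sum() / n
        m2 = ((z - mean) ** 2).sum() / n
        m3 = ((z - mean) ** 3).sum() / n
        m4 = ((z - mean) ** 4).sum() / n
        var = ((z - mean) ** 2).sum() / (n - 1)
        g1 = m3 / m2**1.5
        G1 = g1 * math.sqrt(n * (n - 1)) / (n - 2)
        g2 = m4 / m2**2 - 3.0
        G2 = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
        assert d.mean == pytest.approx(mean, abs=1e-9)
        assert d.variance == pytest.approx(var, abs=1e-9)
        assert d.std == pytest.approx(math.sqrt(var), abs=1e-9)
        assert d.skewness == pytest.approx(G1, abs=1e-9)
        assert d.kurtosis == pytest.approx(G2, abs=1e-9)

    def test_variance_is_squared_std(self, rng):
        d = describe(rng.normal(size=100))
        assert d.variance == pytest.approx(d.std**2, abs=1e-9)

    def test_small_n_omits_ses(self):
        d = describe(np.array([1.0, 2.0, 4.0]))
        assert d.skewness_se is None and d.kurtosis is None


class TestYieldClasses:
    def test_uniform_raster_single_class(self):
        g = make_grid(np.full((6, 6), 2.5))
        t = classify_yield(g, (2.0, 3.0, 4.0, 5.0))
        shares = dict(zip(t.labels, t.shares_pct))
        assert shares["2-3"] == pytest.approx(100.0)
        assert t.average_yield == pytest.approx(2.5)

    def test_matches_loop_oracle(self, rng):
        vals = rng.uniform(0, 7, (20, 20))
        mask = rng.random((20, 20)) > 0.1
        g = make_grid(np.where(mask, vals, np.nan), mask=mask)
        edges = (2.0, 3.0, 4.0, 5.0)
        t = classify_yield(g, edges)
        cell_ha = g.pixel**2 / 1e4
        bins = [-np.inf, *edges, np.inf]
        for k in range(5):
            n = sum(
                1
                for v in vals[mask]
                if bins[k] <= v < bins[k + 1]
            )
            assert t.areas_ha[k] == pytest.approx(n * cell_ha, abs=1e-12)

    def test_left_closed_right_open_edges(self):
        g = make_grid(np.array([[2.0, 3.0], [4.0, 5.0]]))
        t = classify_yield(g, (2.0, 3.0, 4.0, 5.0))
        # each value lands in the class it opens
        assert t.shares_pct == [0.0, 25.0, 25.0, 25.0, 25.0]

    def test_shares_and_areas_conserve_totals(self, rng):
        vals = rng.uniform(0, 8, (15, 15))
        mask = rng.random((15, 15)) > 0.3
        g = make_grid(np.where(mask, vals, np.nan), mask=mask)
        t = classify_yield(g)
        assert sum(t.shares_pct) == pytest.approx(100.0, abs=0.1)
        assert sum(t.areas_ha) == pytest.approx(t.total_area_ha, abs=g.pixel**2 / 1e4)

    def test_empty_raster_raises(self):
        g = make_grid(np.full((3, 3), np.nan), mask=np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            classify_yield(g)


class TestCorrelation:
    def test_perfect_linearity(self, rng):
        a = make_grid(rng.normal(size=(10, 10)))
        b = a.with_values(2 * a.values + 1)
        r, p, n = correlate_grids(a, b)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-30)
        assert n == 100

    def test_shuffled_grid_uncorrelated(self, rng):
        vals = rng.normal(size=200)
        a = make_grid(vals.reshape(10, 20))
        shuffled = vals.copy()
        rng.shuffle(shuffled)
        b = make_grid(shuffled.reshape(10, 20))
        r, p, n = correlate_grids(a, b)
        assert abs(r) < 0.2

    def test_p_monotone_in_abs_r(self):
        """At fixed n, stronger correlation gives a smaller p-value."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(8, 8))
        a = make_grid(base)
        ps = []
        for lam in (0.3, 0.6, 0.9):
            noisy = lam * base + (1 - lam) * rng.normal(size=(8, 8))
            ps.append(correlate_grids(a, make_grid(noisy))[1])
        assert ps[0] > ps[1] > ps[2]

    def test_zero_variance_raises(self, rng):
        a = make_grid(rng.normal(size=(5, 5)))
        b = make_grid(np.full((5, 5), 1.0))
        with pytest.raises(ValueError, match="zero variance"):
            correlate_grids(a, b)

    def test_mismatched_geometry_raises(self, rng):
        a = make_grid(rng.normal(size=(5, 5)), pixel=10.0)
        b = make_grid(rng.normal(size=(5, 5)), pixel=30.0)
        with pytest.raises(ValueError):
            correlate_grids(a, b)


class TestCorrelationMatrix:
    def test_identical_grids_all_one(self, rng):
        g = make_grid(rng.normal(size=(6, 6)))
        rep = correlation_matrix({"a": g, "b": g.copy(), "c": g.copy()})
        np.testing.assert_allclose(rep.r, 1.0)

    def test_symmetric_unit_diagonal(self, rng):
        grids = {k: make_grid(rng.normal(size=(6, 6))) for k in "abc"}
        rep = correlation_matrix(grids)
        np.testing.assert_allclose(rep.r, rep.r.T)
        np.testing.assert_allclose(np.diag(rep.r), 1.0)
        assert np.all(rep.r >= -1) and np.all(rep.r <= 1)

    def test_total_correlates_highest(self, rng):
        """Each grid correlates at least as well with the sum of all grids
        as with any single other grid, when grids share a common component."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            common = r.normal(size=(10, 10))
            grids = {
                f"h{i}": make_grid(common + 0.8 * r.normal(size=(10, 10)))
                for i in range(4)
            }
            rep = correlation_matrix(grids, include_total=True)
            k = len(grids)
            for i in range(k):
                off = [rep.r[i, j] for j in range(k) if j != i]
                assert rep.r[i, k] >= max(off) - 1e-9

    def test_significance_stars(self, rng):
        base = rng.normal(size=(12, 12))
        grids = {"a": make_grid(base), "b": make_grid(base + 0.1 * rng.normal(size=(12, 12)))}
        rep = correlation_matrix(grids)
        assert rep.stars[0][1] == "**"


class TestRegression:
    def test_exact_linear_relation(self, rng):
        vi = make_grid(rng.uniform(0.1, 0.9, (8, 8)))
        y = vi.with_values(3.0 * vi.values)
        res = regress_yield_on_index(y, vi)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)

    def test_r2_equals_squared_correlation(self, rng):
        vi = make_grid(rng.uniform(0.1, 0.9, (10, 10)))
        y = make_grid(2 * vi.values + rng.normal(0, 0.3, (10, 10)))
        res = regress_yield_on_index(y, vi)
        r, _, _ = correlate_grids(y, vi)
        assert res.r2 == pytest.approx(r**2, abs=1e-12)

    def test_implied_correlation_gives_expected_r2(self):
        """A predictor built with implied r ~ 0.73 yields R^2 near 0.53."""
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.normal(3.0, 1.0, (20, 20))
            target_r = 0.73
            noise_sd = np.sqrt(1 / target_r**2 - 1)  # unit-slope, unit-sigma_y
            vi = y + noise_sd * rng.normal(size=(20, 20))
            res = regress_yield_on_index(make_grid(y), make_grid(vi))
            r2s.append(res.r2)
        assert np.mean(r2s) == pytest.approx(0.73**2, abs=0.1)

    def test_zero_predictor_variance_raises(self, rng):
        y = make_grid(rng.normal(size=(5, 5)))
        vi = make_grid(np.full((5, 5), 0.5))
        with pytest.raises(ValueError):
            regress_yield_on_index(y, vi)
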