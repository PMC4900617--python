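"""Variography and ordinary kriging against hand-worked and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from pivotyield import (
    FieldSpec,
    GRFParams,
    KrigingConfig,
    VariogramModel,
    YieldPointSet,
    cross_validate,
    empirical_variogram,
    fit_variogram,
    krige_points,
    model_semivariance,
    ordinary_kriging,
    simulate_yield_surface,
    structural_proportion,
)
from pivotyield.geostat import EmpiricalVariogram

from conftest import make_grid


def _point_set(coords, z, harvest_id=1):
    df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "dry_yield_t_ha": z})
    return YieldPointSet(df, harvest_id=harvest_id)


def brute_force_variogram(coords, z, edges):
    """Independent all-pairs oracle for the binned semivariance."""
    nb = len(edges) - 1
    num = np.zeros(nb)
    cnt = np.zeros(nb, dtype=int)
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(*(coords[i] - coords[j]))
            if d > edges[-1]:
                continue
            for b in range(nb):
                if edges[b] <= d <= edges[b + 1] and (d < edges[b + 1] or b == nb - 1):
                    num[b] += (z[i] - z[j]) ** 2
                    cnt[b] += 1
                    break
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, num / np.maximum(2 * cnt, 1), np.nan), cnt


class TestEmpiricalVariogram:
    def test_constant_field_zero_everywhere(self, rng):
        coords = rng.uniform(0, 100, (40, 2))
        emp = empirical_variogram((coords, np.full(40, 3.3)), lag_width=10, max_lag=100)
        assert np.all(emp.gamma[emp.counts > 0] == 0.0)

    def test_collinear_hand_example(self):
        """Points x=0,1,2 with z=0,1,2: gamma(1)=0.5 over 2 pairs, gamma(2)=2 over 1."""
        coords = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        emp = empirical_variogram((coords, np.array([0.0, 1.0, 2.0])),
                                  lag_width=1.0, max_lag=2.5)
        # bins [0,1), [1,2), [2,2.5): the unit pairs land in bin of lag 1
        by_count = dict(zip(emp.counts, emp.gamma))
        assert by_count[2] == pytest.approx(0.5)
        assert by_count[1] == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        coords = rng.uniform(0, 200, (200, 2))
        z = rng.normal(size=200)
        lag_w, max_lag = 20.0, 140.0
        emp = empirical_variogram((coords, z), lag_width=lag_w, max_lag=max_lag)
        edges = np.arange(len(emp.lags) + 1) * lag_w
        g_ref, c_ref = brute_force_variogram(coords, z, edges)
        np.testing.assert_array_equal(emp.counts, c_ref)
        np.testing.assert_allclose(
            emp.gamma[emp.counts > 0], g_ref[c_ref > 0], rtol=1e-12
        )

    def test_chunked_path_matches_dense(self, rng, monkeypatch):
        """The memory-bounded pair loop equals the dense pdist path."""
        import pivotyield.geostat as gs

        coords = rng.uniform(0, 300, (500, 2))
        z = rng.normal(size=500)
        dense = empirical_variogram((coords, z), lag_width=25, max_lag=200)
        monkeypatch.setattr(gs, "_DENSE_MAX", 100)
        chunked = empirical_variogram((coords, z), lag_width=25, max_lag=200)
        np.testing.assert_array_equal(dense.counts, chunked.counts)
        np.testing.assert_allclose(
            dense.gamma[dense.counts > 0], chunked.gamma[chunked.counts > 0], rtol=1e-12
        )

    def test_empty_variogram_raises(self):
        coords = np.array([[0.0, 0.0], [500.0, 500.0]])
        with pytest.raises(ValueError, match="no point pairs"):
            empirical_variogram((coords, np.array([1.0, 2.0])), lag_width=10, max_lag=50)


class TestModelSemivariance:
    def test_spherical_reaches_sill_at_range(self):
        m = VariogramModel("spherical", 0.5, 1.0, 100.0)
        assert model_semivariance(m, 100.0) == pytest.approx(1.5)
        assert model_semivariance(m, 1e6) == pytest.approx(1.5)

    def test_exponential_practical_range(self):
        """At h = a the exponential model attains Co + (1 - e^-3) C."""
        m = VariogramModel("exponential", 0.5, 1.0, 100.0)
        assert model_semivariance(m, 100.0) == pytest.approx(0.5 + 0.950213, abs=1e-5)
        assert model_semivariance(m, 1e7) == pytest.approx(1.5)

    def test_zero_at_origin(self):
        m = VariogramModel("exponential", 0.5, 1.0, 100.0)
        assert model_semivariance(m, 0.0) == 0.0

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            model_semivariance(VariogramModel("spherical", 0, 1, 10), -1.0)


class TestStructuralProportion:
    @pytest.mark.parametrize(
        "nugget, sill, expected",
        [(0.54, 1.47, 0.63), (0.67, 2.88, 0.77), (1.43, 4.25, 0.66)],
    )
    def test_matches_printed_arithmetic(self, nugget, sill, expected):
        m = VariogramModel("spherical", nugget, sill - nugget, 100.0)
        assert round(structural_proportion(m), 2) == expected

    def test_limits(self):
        assert structural_proportion(VariogramModel("spherical", 0.0, 1.0, 10)) == 1.0
        assert structural_proportion(VariogramModel("spherical", 1.0, 0.0, 10)) == 0.0

    def test_zero_total_sill_raises(self):
        with pytest.raises(ValueError):
            structural_proportion(VariogramModel("spherical", 0.0, 0.0, 10))


class TestFit:
    def test_noise_free_spherical_recovered_exactly(self):
        truth = VariogramModel("spherical", 0.5, 1.0, 100.0)
        lags = np.linspace(10, 180, 12)
        emp = EmpiricalVariogram(
            lags, model_semivariance(truth, lags), np.full(12, 100), 15.0, 190.0
        )
        m = fit_variogram(emp)
        assert m.form == "spherical"
        assert m.nugget == pytest.approx(0.5, abs=1e-3)
        assert m.partial_sill == pytest.approx(1.0, abs=1e-3)
        assert m.range_ == pytest.approx(100.0, abs=0.5)
        assert m.r2 > 0.999

    def test_pure_nugget_gives_zero_structure(self, rng):
        lags = np.linspace(10, 150, 10)
        gamma = 1.0 + rng.normal(0, 0.01, 10)
        emp = EmpiricalVariogram(lags, gamma, np.full(10, 500), 15.0, 160.0)
        m = fit_variogram(emp)
        assert structural_proportion(m) < 0.1

    def test_too_few_bins_raises(self):
        emp = EmpiricalVariogram(
            np.array([10.0, 20, 30]), np.array([1.0, 1, 1]), np.array([5, 5, 5]), 10, 35
        )
        with pytest.raises(ValueError):
            fit_variogram(emp)


def full_cfg(**kw):
    kw.setdefault("search_radius", 1e9)
    kw.setdefault("max_neighbors", 64)
    kw.setdefault("block_disc", 1)
    return KrigingConfig(**kw)


class TestKriging:
    def test_single_point_constant_estimate(self):
        coords = np.array([[50.0, 50.0]])
        model = VariogramModel("spherical", 0.1, 1.0, 60.0)
        targets = np.array([[10.0, 10.0], [90.0, 90.0]])
        est, var = krige_points(coords, np.array([3.0]), targets, model, full_cfg())
        np.testing.assert_allclose(est, 3.0)
        assert np.all(var >= 0)

    def test_exact_interpolation_iff_zero_nugget(self, rng):
        coords = rng.uniform(0, 100, (8, 2))
        z = rng.uniform(1, 5, 8)
        m0 = VariogramModel("spherical", 0.0, 1.0, 60.0)
        m1 = VariogramModel("spherical", 0.4, 1.0, 60.0)
        e0, _ = krige_points(coords, z, coords, m0, full_cfg())
        e1, _ = krige_points(coords, z, coords, m1, full_cfg())
        np.testing.assert_allclose(e0, z, atol=1e-9)
        assert np.max(np.abs(e1 - z)) > 1e-3

    def test_matches_dense_solve_oracle(self, rng):
        """5 points, full neighborhood: weights/estimates vs direct solve."""
        coords = rng.uniform(0, 100, (5, 2))
        z = rng.uniform(1, 5, 5)
        model = VariogramModel("exponential", 0.2, 1.3, 70.0)
        targets = rng.uniform(0, 100, (3, 2))
        est, _ = krige_points(coords, z, targets, model, full_cfg())

        def gamma(d):
            return model.nugget + model.partial_sill * (1 - np.exp(-3 * d / model.range_))

        for t in range(3):
            d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
            A = np.zeros((6, 6))
            A[:5, :5] = gamma(d)
            np.fill_diagonal(A[:5, :5], 0.0)
            A[5, :5] = 1.0
            A[:5, 5] = 1.0
            b = np.append(gamma(np.sqrt(((coords - targets[t]) ** 2).sum(-1))), 1.0)
            lam = np.linalg.solve(A, b)
            assert lam[:5].sum() == pytest.approx(1.0, abs=1e-9)
            assert est[t] == pytest.approx(lam[:5] @ z, abs=1e-9)

    def test_block_converges_to_point(self, rng):
        coords = rng.uniform(0, 100, (10, 2))
        z = rng.uniform(1, 5, 10)
        model = VariogramModel("spherical", 0.1, 1.0, 60.0)
        targets = rng.uniform(20, 80, (6, 2))
        point, _ = krige_points(coords, z, targets, model, full_cfg(), block=False)
        tiny, _ = krige_points(
            coords, z, targets, model,
            full_cfg(block_size=1e-9, block_disc=4), block=True,
        )
        assert np.max(np.abs(point - tiny)) < 1e-6

    def test_variance_nonnegative_and_grid_masked_outside_radius(self, rng):
        coords = rng.uniform(40, 60, (12, 2))
        z = rng.uniform(1, 5, 12)
        pts = _point_set(coords, z)
        model = VariogramModel("spherical", 0.1, 1.0, 30.0)
        geom = make_grid(np.full((10, 10), np.nan), mask=np.ones((10, 10), bool), pixel=10.0)
        cfg = KrigingConfig(block_size=10, block_disc=2, max_neighbors=8, search_radius=25.0)
        est, var = ordinary_kriging(pts, model, geom, cfg)
        assert np.all(var.values[var.mask] >= 0)
        assert (~est.mask).sum() > 0  # far corners out of search radius

    def test_duplicate_points_resolved(self):
        coords = np.array([[0.0, 0], [0.0, 0], [10.0, 0], [0, 10.0], [10.0, 10.0]])
        z = np.array([2.0, 4.0, 3.0, 3.0, 3.0])
        model = VariogramModel("spherical", 0.0, 1.0, 20.0)
        est, _ = krige_points(coords, z, np.array([[0.0, 0.0]]), model, full_cfg())
        assert est[0] == pytest.approx(3.0)  # duplicates averaged


class TestCrossValidation:
    def test_constant_field_zero_error(self, rng):
        coords = rng.uniform(0, 100, (20, 2))
        pts = _point_set(coords, np.full(20, 2.5))
        model = VariogramModel("spherical", 0.0, 1.0, 60.0)
        cv = cross_validate(pts, model, full_cfg())
        assert cv.rmse == pytest.approx(0.0, abs=1e-9)
        assert cv.mean_error == pytest.approx(0.0, abs=1e-9)

    def test_structured_field_beats_pure_nugget(self):
        """LOOCV r is higher when most variance is spatially structured."""
        spec = FieldSpec(radius=150.0, pixel_size=10.0)
        rs = {}
        for name, (co, c) in {"structured": (0.1, 0.9), "nugget": (1.0, 0.0)}.items():
            surf = simulate_yield_surface(
                spec, GRFParams("spherical", co, c, 80.0, mean=3.0, seed=13)
            )
            X, Y = surf.cell_centers()
            sel = np.where(surf.mask.ravel())[0][::4]
            coords = np.column_stack([X.ravel()[sel], Y.ravel()[sel]])
            pts = _point_set(coords, surf.values.ravel()[sel])
            model = VariogramModel("spherical", co, max(c, 1e-6), 80.0)
            cfg = KrigingConfig(block_disc=1, max_neighbors=16, search_radius=100.0)
            r = cross_validate(pts, model, cfg).r
            rs[name] = r
        assert rs["structured"] > rs["nugget"] + 0.2

    def test_weights_constraint_is_active(self, rng):
        """Dropping the unbiasedness row changes the prediction (guard)."""
        coords = rng.uniform(0, 100, (6, 2))
        z = rng.uniform(1, 5, 6) + 10.0  # large mean: constraint matters
        model = VariogramModel("spherical", 0.2, 1.0, 60.0)
        target = np.array([[50.0, 50.0]])
        est, _ = krige_points(coords, z, target, model, full_cfg())

        def gamma(d):
            r = d / model.range_
            return model.nugget + model.partial_sill * np.where(
                r < 1, 1.5 * r - 0.5 * r**3, 1.0
            )

        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        A = gamma(d)
        np.fill_diagonal(A, 1e-9)
        b = gamma(np.sqrt(((coords - target[0]) ** 2).sum(-1)))
        lam_simple = np.linalg.solve(A, b)  # simple-kriging-style, unconstrained
        assert abs(lam_simple.sum() - 1.0) > 1e-3
        assert abs(est[0] - lam_simple @ z) > 1e-3
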