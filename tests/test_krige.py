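"""Variograms, ordinary kriging, transforms, trend and regression kriging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist, pdist, squareform

from rfsp.geodata import CovariateStack, GridSpec, InputError, PointSet
from rfsp.krige import (
    VariogramModel,
    boxcox,
    boxcox_inverse,
    empirical_variogram,
    fit_mlr,
    fit_variogram,
    lognormal_backtransform,
    ok_predict,
    predict_mlr,
    rk_predict,
)
from rfsp.synthfields import simulate_grf_at


class TestBoxCox:
    def test_log_branch(self):
        assert boxcox(np.e, eta=0) == pytest.approx(1.0)

    def test_linear_branch(self):
        assert boxcox(5.0, eta=1) == pytest.approx(4.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(InputError):
            boxcox([-1.0, 2.0], eta=0)

    @pytest.mark.parametrize("eta", [-0.5, 0.0, 0.5, 1.0])
    def test_round_trip_identity(self, eta, rng):
        y = rng.uniform(0.01, 50.0, size=1000)
        np.testing.assert_allclose(boxcox_inverse(boxcox(y, eta), eta), y,
                                   rtol=0, atol=1e-12 * y.max())


class TestVariogramModel:
    def test_sill_decomposition(self):
        v = VariogramModel("exponential", nugget=0.3, psill=0.7, range_param=2.0)
        assert v.total_sill == pytest.approx(1.0)
        assert v.covariance(0.0) == pytest.approx(1.0)
        h = np.array([0.5, 1.0, 5.0])
        np.testing.assert_allclose(v.semivariance(h) + v.covariance(h),
                                   v.total_sill)

    def test_practical_range_correlation_005(self):
        for fam in ("exponential", "gaussian", "spherical"):
            v = VariogramModel(fam, nugget=0.0, psill=1.0, range_param=3.0)
            pr = v.practical_range
            assert v.covariance(pr) / v.psill == pytest.approx(0.05, abs=1e-6)

    def test_json_round_trip(self):
        v = VariogramModel("spherical", 0.2, 1.5, 7.0, eta=0.0)
        back = VariogramModel.from_json(v.to_json())
        assert back == v


class TestEmpiricalVariogram:
    def test_two_points_hand_value(self):
        ps = PointSet(coords=[[0, 0], [3, 4]], target=[0.0, 2.0])
        emp = empirical_variogram(ps, n_bins=1, max_dist=10)
        lags, gam, counts = emp.populated()
        assert counts.tolist() == [1] and gam[0] == pytest.approx(2.0)

    def test_constant_field_zero_everywhere(self, rng):
        ps = PointSet(coords=rng.uniform(0, 10, (30, 2)), target=np.full(30, 5.0))
        emp = empirical_variogram(ps)
        _, gam, _ = emp.populated()
        assert np.all(gam == 0.0)

    def test_matches_all_pairs_double_loop(self, rng):
        n = 100
        coords = rng.uniform(0, 50, (n, 2))
        y = rng.normal(size=n)
        ps = PointSet(coords=coords, target=y)
        emp = empirical_variogram(ps, n_bins=10)
        # independent double loop
        sums = np.zeros(emp.n_bins)
        counts = np.zeros(emp.n_bins, dtype=int)
        edges = np.linspace(0, emp.max_dist, emp.n_bins + 1)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.hypot(*(coords[i] - coords[j]))
                if d == 0 or d > emp.max_dist:
                    continue
                b = min(np.searchsorted(edges, d, side="left") - 1, emp.n_bins - 1)
                b = max(b, 0)
                sums[b] += (y[i] - y[j]) ** 2
                counts[b] += 1
        np.testing.assert_array_equal(emp.pair_counts, counts)
        nz = counts > 0
        np.testing.assert_allclose(emp.gamma_hat[nz], sums[nz] / (2 * counts[nz]))


class TestFitVariogram:
    def test_noise_free_recovery(self):
        true = VariogramModel("exponential", nugget=0.2, psill=1.0, range_param=4.0)
        lags = np.linspace(0.5, 20, 15)
        from rfsp.krige import EmpiricalVariogram

        emp = EmpiricalVariogram(
            lag_centers=lags, gamma_hat=true.semivariance(lags),
            pair_counts=np.full(15, 50), max_dist=20.0, n_bins=15,
        )
        fit = fit_variogram(emp, family="exponential")
        assert fit.nugget == pytest.approx(0.2, rel=1e-4, abs=1e-6)
        assert fit.psill == pytest.approx(1.0, rel=1e-4)
        assert fit.range_param == pytest.approx(4.0, rel=1e-4)

    def test_white_noise_mostly_nugget(self, rng):
        fractions = []
        for rep in range(20):
            coords = rng.uniform(0, 100, (200, 2))
            ps = PointSet(coords=coords, target=rng.normal(size=200))
            emp = empirical_variogram(ps)
            fit = fit_variogram(emp, family="exponential")
            lags, _, _ = emp.populated()
            fractions.append(
                fit.structured_fraction(float(lags.max()), float(lags.min())))
        assert np.median(fractions) < 0.1

    def test_grf_parameter_recovery(self):
        """Median relative errors on simulated exponential fields stay
        within the tolerances a practitioner would accept from 300 points."""
        true = VariogramModel("exponential", nugget=0.1, psill=1.0, range_param=10.0)
        rng = np.random.default_rng(7)
        range_err, sill_err = [], []
        for rep in range(20):
            coords = rng.uniform(0, 100, (300, 2))
            y = simulate_grf_at(coords, true, seed=1000 + rep)
            ps = PointSet(coords=coords, target=y)
            fit = fit_variogram(empirical_variogram(ps), family="exponential")
            range_err.append(abs(fit.range_param - 10.0) / 10.0)
            sill_err.append(abs(fit.total_sill - 1.1) / 1.1)
        assert np.median(range_err) < 0.5
        assert np.median(sill_err) < 0.3


class TestOrdinaryKriging:
    def _ps(self, rng, n=8):
        return PointSet(coords=rng.uniform(0, 10, (n, 2)), target=rng.normal(size=n))

    def test_exact_interpolation_zero_nugget(self, rng):
        vgm = VariogramModel("exponential", nugget=0.0, psill=1.0, range_param=3.0)
        ps = self._ps(rng)
        res = ok_predict(ps, ps.coords, vgm)
        np.testing.assert_allclose(res.predictions, ps.target, atol=1e-8)
        assert np.all(res.variances < 1e-8)

    def test_weights_sum_to_one(self, rng):
        vgm = VariogramModel("spherical", nugget=0.2, psill=0.8, range_param=5.0)
        ps = self._ps(rng, 15)
        targets = rng.uniform(-2, 12, (20, 2))
        res = ok_predict(ps, targets, vgm, keep_weights=True)
        np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-10)

    def test_matches_dense_augmented_solve(self, rng):
        """3-point configuration vs. an independently coded dense solve of
        the augmented covariance system."""
        vgm = VariogramModel("exponential", nugget=0.1, psill=0.9, range_param=2.0)
        coords = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        y = np.array([1.0, -1.0, 2.0])
        ps = PointSet(coords=coords, target=y)
        s0 = np.array([[1.0, 1.0]])
        res = ok_predict(ps, s0, vgm, keep_weights=True)

        C = vgm.covariance(squareform(pdist(coords)))
        c0 = vgm.covariance(cdist(s0, coords))[0]
        A = np.zeros((4, 4))
        A[:3, :3] = C
        A[3, :3] = A[:3, 3] = 1.0
        sol = np.linalg.solve(A, np.append(c0, 1.0))
        w, phi = sol[:3], sol[3]
        assert res.predictions[0] == pytest.approx(w @ y, abs=1e-10)
        assert res.variances[0] == pytest.approx(
            vgm.total_sill - w @ c0 - phi, abs=1e-10)

    def test_duplicate_points_zero_nugget_rejected(self):
        vgm = VariogramModel("exponential", nugget=0.0, psill=1.0, range_param=2.0)
        ps = PointSet(coords=[[0, 0], [0, 0], [1, 1]], target=[1.0, 2.0, 3.0])
        with pytest.raises(InputError, match="singular"):
            ok_predict(ps, np.array([[0.5, 0.5]]), vgm)

    def test_pure_nugget_predicts_sample_mean(self, rng):
        ps = self._ps(rng, 12)
        vgm = VariogramModel("pure-nugget", nugget=1.0, psill=0.0)
        res = ok_predict(ps, np.array([[3.0, 3.0], [7.0, 2.0]]), vgm)
        np.testing.assert_allclose(res.predictions, ps.target.mean(), atol=1e-10)

    def test_screen_far_point_no_influence(self, rng):
        """A point far beyond the practical range is screened out: exactly
        under a nearest-m neighborhood, and down to the O(1/n) unbiasedness
        weight under a global neighborhood."""
        vgm = VariogramModel("exponential", nugget=0.1, psill=1.0, range_param=2.0)
        ps = self._ps(rng, 10)
        target = np.array([[5.0, 5.0]])
        base = ok_predict(ps, target, vgm, n_neighbors=10).predictions[0]
        far = PointSet(
            coords=np.vstack([ps.coords, [[1e6, 1e6]]]),
            target=np.append(ps.target, 99.0),
        )
        with_far = ok_predict(far, target, vgm, n_neighbors=10).predictions[0]
        assert abs(with_far - base) < 1e-6
        # global neighborhood: the far point keeps only its mean-estimation
        # weight; the prediction shift is bounded by |w_far * y_far|
        res = ok_predict(far, target, vgm, keep_weights=True)
        assert abs(res.weights[0, -1]) < 0.06

    def test_local_neighborhood_matches_global_when_m_large(self, rng):
        vgm = VariogramModel("exponential", nugget=0.2, psill=1.0, range_param=4.0)
        ps = self._ps(rng, 12)
        targets = rng.uniform(0, 10, (5, 2))
        g = ok_predict(ps, targets, vgm).predictions
        l = ok_predict(ps, targets, vgm, n_neighbors=12).predictions
        np.testing.assert_allclose(l, g, atol=1e-10)

    def test_variances_nonnegative(self, rng):
        vgm = VariogramModel("gaussian", nugget=0.05, psill=1.0, range_param=3.0)
        ps = self._ps(rng, 20)
        res = ok_predict(ps, rng.uniform(0, 10, (50, 2)), vgm)
        assert np.all(res.variances >= 0)


class TestLognormalBacktransform:
    def test_degenerate_zero_variance(self):
        mean, var = lognormal_backtransform(2.0, 0.0)
        assert mean == pytest.approx(np.exp(2.0)) and var == 0.0

    def test_closed_form_moments(self):
        mean, var = lognormal_backtransform(0.0, 1.0)
        assert mean == pytest.approx(np.exp(0.5), rel=1e-12)       # 1.64872
        assert var == pytest.approx(np.e * (np.e - 1.0), rel=1e-12)  # 4.67077

    def test_matches_monte_carlo(self):
        # moderate log-scale variance keeps the MC variance estimator's own
        # noise well inside the 1% band at 10^6 draws (heavy-tail kurtosis
        # dominates the standard error for larger sigma^2)
        rng = np.random.default_rng(42)
        mu, s2 = 0.3, 0.25
        draws = np.exp(rng.normal(mu, np.sqrt(s2), 10**6))
        mean, var = lognormal_backtransform(mu, s2)
        assert mean == pytest.approx(draws.mean(), rel=0.01)
        assert var == pytest.approx(draws.var(), rel=0.01)


class TestMLR:
    def test_exact_linear_data(self, rng):
        X = rng.normal(size=(30, 3))
        beta = np.array([2.0, -1.0, 0.5])
        y = 1.5 + X @ beta
        tm = fit_mlr(X, y)
        np.testing.assert_allclose(tm.beta, [1.5, 2.0, -1.0, 0.5], atol=1e-10)
        assert tm.mse == pytest.approx(0.0, abs=1e-18)
        _, var = predict_mlr(tm, rng.normal(size=(5, 3)))
        np.testing.assert_allclose(var, 0.0, atol=1e-15)

    def test_variance_minimized_at_covariate_center(self, rng):
        X = rng.normal(size=(50, 2))
        y = X @ [1.0, 2.0] + rng.normal(size=50)
        tm = fit_mlr(X, y)
        center = X.mean(axis=0, keepdims=True)
        _, v_center = predict_mlr(tm, center)
        _, v_far = predict_mlr(tm, center + 5 * X.std(axis=0))
        assert v_center[0] < v_far[0]

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        tm = fit_mlr(X, y)
        Xd = np.column_stack([np.ones(40), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(tm.beta, beta, atol=1e-10)

    def test_underdetermined_redirects_to_forest(self, rng):
        with pytest.raises(InputError, match="forest"):
            fit_mlr(rng.normal(size=(3, 5)), rng.normal(size=3))

    def test_rank_deficiency_dropped_with_warning(self, rng):
        X = rng.normal(size=(30, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])  # exact collinearity
        with pytest.warns(UserWarning, match="rank"):
            tm = fit_mlr(X, rng.normal(size=30))
        assert tm.p == 3  # intercept + 2 independent columns


class TestRegressionKriging:
    def _setup(self, rng, beta=(2.0, 0.5), noise=0.5, n=40):
        grid = GridSpec(origin=(0.0, 20.0), cell_size=1.0, nrows=20, ncols=20)
        stack = CovariateStack(grid=grid)
        X, Y = grid.cell_centers()
        stack.add_layer("cov", np.sin(X / 3.0) + 0.1 * Y)
        coords = rng.uniform(0.5, 19.5, (n, 2))
        i, j = grid.cell_index(coords[:, 0], coords[:, 1])
        y = beta[0] + beta[1] * stack.layers["cov"][i, j] + noise * rng.normal(size=n)
        ps = PointSet(coords=coords, target=y)
        return grid, stack, ps

    def test_pure_nugget_residuals_reduce_to_mlr(self, rng):
        grid, stack, ps = self._setup(rng)
        targets = rng.uniform(1, 19, (10, 2))
        nug = VariogramModel("pure-nugget", nugget=0.25, psill=0.0)
        res = rk_predict(ps, stack, targets, vgm=nug)
        from rfsp.geodata import overlay

        Xdf = overlay(ps, stack)
        tm = fit_mlr(Xdf.to_numpy(), ps.target.astype(float))
        i, j = grid.cell_index(targets[:, 0], targets[:, 1])
        mlr_pred, _ = predict_mlr(tm, stack.layers["cov"][i, j][:, None])
        np.testing.assert_allclose(res.predictions, mlr_pred, atol=1e-8)

    def test_zero_trend_matches_ok(self, rng):
        grid, stack, _ = self._setup(rng)
        coords = rng.uniform(0.5, 19.5, (40, 2))
        y = rng.normal(size=40)  # no dependence on the covariate
        ps = PointSet(coords=coords, target=y)
        vgm = VariogramModel("exponential", nugget=0.3, psill=0.7, range_param=4.0)
        targets = rng.uniform(1, 19, (15, 2))
        rk = rk_predict(ps, stack, targets, vgm=vgm)
        # OK on the demeaned data with the same variogram
        from rfsp.geodata import overlay

        Xdf = overlay(ps, stack)
        tm = fit_mlr(Xdf.to_numpy(), y)
        resid_ps = PointSet(coords=coords,
                            target=y - predict_mlr(tm, Xdf.to_numpy())[0])
        ok = ok_predict(resid_ps, targets, vgm)
        i, j = grid.cell_index(targets[:, 0], targets[:, 1])
        trend, _ = predict_mlr(tm, stack.layers["cov"][i, j][:, None])
        np.testing.assert_allclose(rk.predictions, trend + ok.predictions,
                                   atol=1e-8)

    def test_composition_equals_hand_pipeline(self, rng):
        """5-point toy case: rk_predict equals the step-by-step pipeline
        (trend fit -> residuals -> OK of residuals -> sum) composed by hand."""
        grid, stack, _ = self._setup(rng)
        coords = np.array([[2.3, 4.1], [8.0, 12.5], [15.2, 3.3],
                           [5.5, 17.8], [11.1, 9.9]])
        i, j = grid.cell_index(coords[:, 0], coords[:, 1])
        cov = stack.layers["cov"][i, j]
        y = 1.0 + 2.0 * cov + np.array([0.3, -0.2, 0.1, 0.4, -0.6])
        ps = PointSet(coords=coords, target=y)
        vgm = VariogramModel("exponential", nugget=0.05, psill=0.2, range_param=5.0)
        targets = np.array([[10.0, 10.0], [3.0, 15.0]])
        res = rk_predict(ps, stack, targets, vgm=vgm)

        tm = fit_mlr(cov[:, None], y)
        resid = y - predict_mlr(tm, cov[:, None])[0]
        it, jt = grid.cell_index(targets[:, 0], targets[:, 1])
        trend0, tvar0 = predict_mlr(tm, stack.layers["cov"][it, jt][:, None])
        okr = ok_predict(PointSet(coords=coords, target=resid), targets, vgm)
        np.testing.assert_allclose(res.predictions, trend0 + okr.predictions,
                                   atol=1e-8)
        np.testing.assert_allclose(res.variances, tvar0 + okr.variances,
                                   atol=1e-8)


class TestFittedSillApproachesFieldVariance:
    def test_large_sample_total_sill(self):
        true = VariogramModel("exponential", nugget=0.2, psill=1.0, range_param=5.0)
        rng = np.random.default_rng(5)
        sills = []
        for rep in range(10):
            coords = rng.uniform(0, 120, (400, 2))
            y = simulate_grf_at(coords, true, seed=300 + rep)
            ps = PointSet(coords=coords, target=y)
            fit = fit_variogram(empirical_variogram(ps), family="exponential")
            sills.append(fit.total_sill)
        assert np.mean(sills) == pytest.approx(1.2, rel=0.25)
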