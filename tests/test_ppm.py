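"""Berman-Turner quadrature, Poisson point-process fits, LRT, model search."""

import numpy as np
import pytest
from scipy.stats import chi2

import lithospat as ls


class TestBuildQuadrature:
    def test_empty_pattern_unit_window_uniform_weights(self, unit_window):
        pat = ls.CellPattern(np.zeros((0, 2)), unit_window)
        quad = ls.build_quadrature(pat, dummy_spacing_um=0.1)
        assert quad.m == 100
        np.testing.assert_allclose(quad.weights, 0.01, rtol=1e-12)
        assert quad.weights.sum() == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("spacing", [0.07, 0.1, 0.23])
    def test_weight_conservation(self, unit_window, rng, spacing):
        pts = np.column_stack([rng.uniform(0, 1, 60), rng.uniform(0, 1, 60)])
        pat = ls.CellPattern(pts, unit_window)
        quad = ls.build_quadrature(pat, dummy_spacing_um=spacing)
        assert quad.weights.sum() == pytest.approx(unit_window.area_um2,
                                                   rel=1e-6)
        assert quad.n_data == 60
        assert (quad.weights > 0).all()

    def test_data_and_dummy_share_tile_area(self, unit_window):
        # one data point in one tile: tile area split between it and the dummy
        pat = ls.CellPattern(np.array([[0.05, 0.05]]), unit_window)
        quad = ls.build_quadrature(pat, dummy_spacing_um=0.1)
        w_data = quad.weights[quad.is_data][0]
        tile_area = 0.1 * 0.1
        assert w_data == pytest.approx(tile_area / 2, rel=1e-9)

    def test_conservation_with_partial_window(self, rng):
        mask = np.ones((50, 80), bool)
        mask[:, :20] = False
        w = ls.ObservationWindow(80, 50, 0.1, valid_mask=mask)
        pat = ls.CellPattern(np.array([[4.0, 2.0], [6.0, 3.0]]), w)
        quad = ls.build_quadrature(pat, dummy_spacing_um=0.37)
        assert quad.weights.sum() == pytest.approx(w.area_um2, rel=1e-6)

    def test_point_on_invalid_pixel_rejected(self):
        mask = np.ones((10, 10), bool)
        w_ok = ls.ObservationWindow(10, 10, 1.0)
        pat = ls.CellPattern(np.array([[0.5, 0.5]]), w_ok)
        mask[0, 0] = False
        w_bad = ls.ObservationWindow(10, 10, 1.0, valid_mask=mask)
        with pytest.raises(ValueError):
            ls.build_quadrature(pat, window=w_bad, dummy_spacing_um=1.0)


class TestFitPpm:
    def test_null_model_homogeneous_mle(self, unit_window, rng):
        pts = np.column_stack([rng.uniform(0, 1, 100), rng.uniform(0, 1, 100)])
        pat = ls.CellPattern(pts, unit_window)
        fit = ls.fit_ppm(pat)
        assert fit.beta[0] == pytest.approx(np.log(100), abs=1e-6)
        # integral of fitted intensity over W equals n
        integral = np.nansum(fit.fitted_intensity) * unit_window.pixel_size_um**2
        assert integral == pytest.approx(100, rel=1e-6)

    def test_constant_covariate_dropped_equals_null(self, unit_window, rng):
        pts = np.column_stack([rng.uniform(0, 1, 80), rng.uniform(0, 1, 80)])
        pat = ls.CellPattern(pts, unit_window)
        em = ls.ElementMap(unit_window, ["Fe"],
                           np.full((1, 100, 100), 3.7))
        quad = ls.build_quadrature(pat)
        null = ls.fit_ppm(pat, quad=quad)
        alt = ls.fit_ppm(pat, em, quad=quad, covariate_names=["Fe"])
        assert alt.dropped == ["Fe"]
        assert alt.covariate_names == []
        assert alt.loglik == pytest.approx(null.loglik, abs=1e-9)

    def test_nesting_monotonicity(self, small_map, selective_pattern):
        pat, _ = selective_pattern
        quad = ls.build_quadrature(pat)
        null = ls.fit_ppm(pat, quad=quad)
        lls = [null.loglik]
        for names in (["S"], ["S", "Fe"], ["S", "Fe", "Si"]):
            lls.append(ls.fit_ppm(pat, small_map, quad=quad,
                                  covariate_names=names).loglik)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_parameter_recovery_within_3se(self, small_map, selective_pattern):
        pat, truth = selective_pattern
        fit = ls.fit_ppm(pat, small_map, covariate_names=["S"])
        assert fit.converged
        assert abs(fit.beta[1] - 1.5) <= 3 * fit.se[1]

    def test_matches_statsmodels_glm_oracle(self, small_map, selective_pattern):
        # independent route: weighted Poisson GLM on the same quadrature
        import statsmodels.api as sm

        pat, _ = selective_pattern
        quad = ls.build_quadrature(pat)
        fit = ls.fit_ppm(pat, small_map, quad=quad, covariate_names=["S", "Fe"])
        std = small_map.standardized()
        row, col = quad.window.pixel_of(quad.x, quad.y)
        X = np.column_stack([
            np.ones(quad.m),
            std.channel("S")[row, col],
            std.channel("Fe")[row, col],
        ])
        y = np.where(quad.is_data, 1.0 / quad.weights, 0.0)
        glm = sm.GLM(y, X, family=sm.families.Poisson(),
                     var_weights=quad.weights).fit()
        np.testing.assert_allclose(fit.beta, glm.params, rtol=1e-6)
        np.testing.assert_allclose(fit.se, glm.bse, rtol=1e-4)

    def test_deviance_invariant_to_covariate_rescaling(self, small_map,
                                                       selective_pattern):
        pat, _ = selective_pattern
        quad = ls.build_quadrature(pat)
        null = ls.fit_ppm(pat, quad=quad)
        alt1 = ls.fit_ppm(pat, small_map, quad=quad, covariate_names=["S"])
        scaled = ls.ElementMap(small_map.window, small_map.channels,
                               small_map.values * 37.5 + 4.0)
        alt2 = ls.fit_ppm(pat, scaled, quad=quad, covariate_names=["S"])
        s1 = ls.likelihood_ratio_test(null, alt1).stat
        s2 = ls.likelihood_ratio_test(null, alt2).stat
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_quadrature_refinement_stability(self, small_map, selective_pattern):
        # halving the dummy spacing moves beta-hat by < 1%
        pat, _ = selective_pattern
        spacing = ls.ppm.default_dummy_spacing(pat, pat.window)
        fits = []
        for sp in (spacing, spacing / 2):
            quad = ls.build_quadrature(pat, dummy_spacing_um=sp)
            fits.append(ls.fit_ppm(pat, small_map, quad=quad,
                                   covariate_names=["S"]))
        b0, b1 = fits[0].beta[1], fits[1].beta[1]
        assert abs(b1 - b0) / abs(b0) < 0.01

    def test_quadrature_integral_matches_fine_grid(self, small_map,
                                                   selective_pattern):
        # sum w_j lambda(u_j) vs per-pixel integration of the same intensity
        pat, _ = selective_pattern
        quad = ls.build_quadrature(pat)
        fit = ls.fit_ppm(pat, small_map, quad=quad, covariate_names=["S"])
        row, col = quad.window.pixel_of(quad.x, quad.y)
        lam_quad = fit.fitted_intensity[row, col]
        quad_integral = float(np.sum(quad.weights * lam_quad))
        pixel_integral = float(np.nansum(fit.fitted_intensity)
                               * quad.window.pixel_size_um**2)
        assert abs(quad_integral - pixel_integral) / pixel_integral < 0.005


class TestLikelihoodRatioTest:
    def test_model_vs_itself_stat_zero(self, unit_window, rng):
        pts = np.column_stack([rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)])
        pat = ls.CellPattern(pts, unit_window)
        em = ls.ElementMap(unit_window, ["Fe"],
                           rng.normal(5, 1, (1, 100, 100)).clip(0))
        quad = ls.build_quadrature(pat)
        null = ls.fit_ppm(pat, quad=quad)
        alt = ls.fit_ppm(pat, em, quad=quad, covariate_names=["Fe"])
        # same model twice -> df error; stat 0 via identical loglik instead
        with pytest.raises(ValueError):
            ls.likelihood_ratio_test(null, null)
        res = ls.likelihood_ratio_test(null, alt)
        assert res.stat >= 0 and 0 <= res.p_value <= 1

    def test_chisq_quantile(self):
        # stat 3.84 on 1 df sits at the 5% upper tail
        assert chi2.sf(3.84, 1) == pytest.approx(0.050, abs=5e-4)
        r = ls.LRTResult(stat=3.84, df=1, p_value=float(chi2.sf(3.84, 1)),
                         log_p=float(chi2.logsf(3.84, 1)))
        assert r.p_value == pytest.approx(0.050, abs=5e-4)

    def test_non_nested_rejected(self, small_map, selective_pattern):
        pat, _ = selective_pattern
        quad = ls.build_quadrature(pat)
        a = ls.fit_ppm(pat, small_map, quad=quad, covariate_names=["S"])
        b = ls.fit_ppm(pat, small_map, quad=quad, covariate_names=["Fe", "Ti"])
        with pytest.raises(ValueError, match="nested"):
            ls.likelihood_ratio_test(a, b)


class TestModelSearch:
    def test_planted_covariate_recovered(self, small_map, selective_pattern):
        pat, _ = selective_pattern
        report = ls.model_search(pat, small_map, max_covariates=2)
        assert report.best is not None
        assert "S" in report.best

    def test_all_subsets_listed(self, small_map, selective_pattern):
        pat, _ = selective_pattern
        report = ls.model_search(pat, small_map, max_covariates=2)
        from math import comb

        k = len(small_map.channels)
        assert report.n_models == comb(k, 1) + comb(k, 2)
        assert len(report.rows) == report.n_models

    def test_min_cells_flag(self, small_map):
        truth = ls.calibrate_beta0(small_map, {"S": 1.5}, 40)
        pat = ls.simulate_selective_cells(small_map, truth, seed=77)
        report = ls.model_search(pat, small_map.subset(["S", "Fe"]),
                                 max_covariates=1, min_cells=70)
        assert not report.min_cells_ok

    def test_model_cap(self, small_map, selective_pattern):
        pat, _ = selective_pattern
        with pytest.raises(ValueError, match="cap"):
            ls.model_search(pat, small_map, max_covariates=5, max_models=3)

    def test_table2_schema(self, small_map, selective_pattern):
        pat, _ = selective_pattern
        report = ls.model_search(pat, small_map.subset(["S", "Fe"]),
                                 max_covariates=1)
        df = report.table2_rows(coupon="D1T6", substrate="homestake")
        assert list(df.columns) == ["coupon", "substrate", "model",
                                    "p_value", "deviance"]
        assert (df["deviance"] >= 0).all()
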