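"""Distance-effect inference: fits, derivative bands, radius and magnitude."""

import numpy as np
import pandas as pd
import pytest

from seamount_oasis import distance_effects as de
from seamount_oasis import synthetic as syn


class TestFit:
    def test_minimum_observations_enforced(self):
        df = pd.DataFrame({"distance_km": np.arange(5.0),
                           "response": np.arange(5.0)})
        with pytest.raises(ValueError):
            de.fit_distance_gam(df, family="gaussian")

    def test_negative_counts_rejected_under_log_link(self):
        df = pd.DataFrame({"distance_km": np.linspace(0, 40, 50),
                           "response": np.r_[-1.0, np.ones(49)]})
        with pytest.raises(ValueError):
            de.fit_distance_gam(df, family="nb")

    def test_flat_null_small_edf_and_no_significant_slope(self, flat_survey):
        m = de.fit_distance_gam(flat_survey, family="gaussian")
        assert m.results.block_edf("s(global)") < 2.5
        band = de.derivative_band(m)
        assert not band.significant.any()

    def test_fitted_curve_tracks_planted_kernel(self, enriched_survey):
        samples, kernel = enriched_survey
        m = de.fit_distance_gam(samples, family="nb", k=20)
        g = np.array([0.0, 2.0, 10.0, 18.0])
        pred = m.predict(g)
        truth = kernel(g)
        assert np.all(np.abs(np.log(pred) - np.log(truth)) < 1.0)

    def test_transect_random_intercept_reduces_to_levels(self):
        kern = syn.EnrichmentKernel(baseline_mean=3.0, summit_multiplier=1.0)
        cfg = syn.SurveyConfig(seed=10, n_samples=200, n_transects=8,
                               transect_sd=0.7)
        df = syn.gen_radial_survey(cfg, kern, family="nb")
        m = de.fit_distance_gam(df, family="nb")
        sl = m.results.col_slices["transect_re"]
        assert sl.stop - sl.start == 8
        # shrunken intercepts should correlate with the per-transect means
        b = m.results.beta[sl]
        obs = np.log(df.groupby("transect_id").response.mean() + 0.1)
        assert np.corrcoef(b, obs)[0, 1] > 0.5

    def test_ar1_whitening_estimates_rho(self):
        kern = syn.EnrichmentKernel(baseline_mean=5.0, summit_multiplier=1.0)
        cfg = syn.SurveyConfig(seed=11, n_samples=400, n_transects=8,
                               ar1_rho=0.6, ar1_sigma=1.0,
                               gaussian_sigma=0.3)
        df = syn.gen_radial_survey(cfg, kern, family="gaussian")
        m = de.fit_distance_gam(df, family="gaussian", ar1=True)
        assert m.rho == pytest.approx(0.6, abs=0.25)


class TestSmoothDifference:
    def test_model_differenced_with_itself_is_zero(self, flat_survey):
        df = flat_survey.copy()
        df["seamount_id"] = np.where(np.arange(len(df)) % 2 == 0, "A", "B")
        m = de.fit_distance_gam(df, family="gaussian",
                                structure="per-seamount")
        band = de.smooth_difference(m, level_a="A", level_b="A")
        assert np.allclose(band.difference, 0.0)
        assert not band.distinct

    def test_planted_offset_recovered(self):
        rng = np.random.default_rng(6)
        n, delta = 300, 1.5
        d = rng.uniform(0, 40, n)
        sm = np.where(np.arange(n) % 2 == 0, "A", "B")
        y = 5.0 + delta * (sm == "B") + rng.normal(0, 1, n)
        df = pd.DataFrame({"distance_km": d, "response": y,
                           "seamount_id": sm})
        m = de.fit_distance_gam(df, family="gaussian",
                                structure="per-seamount")
        band = de.smooth_difference(m, level_a="B", level_b="A")
        assert np.mean(band.difference) == pytest.approx(delta, abs=0.4)
        assert band.distinct

    def test_same_kernel_fits_rarely_flagged_distinct(self):
        """Type-I check: independent same-kernel halves flagged ~alpha."""
        flags = 0
        for s in range(12):
            rng = np.random.default_rng(200 + s)
            n = 240
            d = rng.uniform(0, 40, n)
            y = 5.0 + rng.normal(0, 1, n)
            df = pd.DataFrame({
                "distance_km": d, "response": y,
                "seamount_id": np.where(np.arange(n) % 2 == 0, "A", "B"),
            })
            m = de.fit_distance_gam(df, family="gaussian",
                                    structure="per-seamount")
            flags += de.smooth_difference(m, level_a="A",
                                          level_b="B").distinct
        assert flags <= 3


class TestPosteriorSimulate:
    def test_draw_mean_converges_to_estimates(self, flat_survey):
        m = de.fit_distance_gam(flat_survey, family="gaussian")
        draws = de.posterior_simulate(m, n_draws=10000, seed=1)
        se = np.sqrt(np.diag(m.results.cov) / 10000)
        assert np.all(np.abs(draws.mean(axis=0) - m.results.beta)
                      < 4 * np.maximum(se, 1e-12))

    def test_draws_reproduce_covariance(self, flat_survey):
        m = de.fit_distance_gam(flat_survey, family="gaussian")
        draws = de.posterior_simulate(m, n_draws=20000, seed=2)
        emp = np.cov(draws.T)
        V = m.results.cov
        err = np.linalg.norm(emp - V) / np.linalg.norm(V)
        assert err < 0.1

    def test_zero_covariance_returns_estimates(self, flat_survey):
        m = de.fit_distance_gam(flat_survey, family="gaussian")
        m.results.cov = np.zeros_like(m.results.cov)
        draws = de.posterior_simulate(m, n_draws=10, seed=3)
        assert np.allclose(draws, m.results.beta)

    def test_seeded_reproducibility(self, flat_survey):
        m = de.fit_distance_gam(flat_survey, family="gaussian")
        a = de.posterior_simulate(m, n_draws=50, seed=9)
        b = de.posterior_simulate(m, n_draws=50, seed=9)
        assert np.array_equal(a, b)


class TestDerivativeBand:
    def test_linear_trend_slope_recovered(self):
        rng = np.random.default_rng(8)
        n, slope = 300, 0.25
        d = rng.uniform(0, 40, n)
        y = 1.0 + slope * d + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"distance_km": d, "response": y})
        m = de.fit_distance_gam(df, family="gaussian")
        band = de.derivative_band(m)
        assert np.allclose(band.derivative, slope, atol=0.08)

    def test_null_coverage_near_nominal(self):
        """Pointwise 95% CI covers zero at ~95% of grid points under null."""
        cover = []
        for s in range(10):
            rng = np.random.default_rng(300 + s)
            df = pd.DataFrame({"distance_km": rng.uniform(0, 40, 200),
                               "response": rng.normal(0, 1, 200)})
            m = de.fit_distance_gam(df, family="gaussian")
            band = de.derivative_band(m)
            cover.append(1.0 - band.significant.mean())
        assert np.mean(cover) > 0.85

    def test_symmetric_bump_derivative_changes_sign_at_peak(self):
        rng = np.random.default_rng(9)
        n = 400
        d = rng.uniform(0, 40, n)
        y = np.exp(-((d - 20.0) ** 2) / 18.0) * 5 + rng.normal(0, 0.3, n)
        m = de.fit_distance_gam(pd.DataFrame(
            {"distance_km": d, "response": y}), family="gaussian", k=20)
        band = de.derivative_band(m)
        peak = band.grid[np.argmin(np.abs(band.grid - 20.0))]
        before = band.derivative[band.grid < peak - 2]
        after = band.derivative[band.grid > peak + 2]
        assert before[np.abs(before).argmax()] > 0
        assert after[np.abs(after).argmax()] < 0


class TestRadiusAndMagnitude:
    def test_null_data_yield_no_effect_and_unit_magnitude(self, flat_survey):
        m = de.fit_distance_gam(flat_survey, family="gaussian")
        est = de.radius_of_influence(m)
        assert est.method == "none" and est.R_km is None
        mag, ci = de.enrichment_magnitude(m, R=20.0, n_draws=200, seed=0)
        assert mag == pytest.approx(1.0, abs=0.1)

    def test_planted_kernel_radius_and_magnitude(self, enriched_survey):
        samples, kernel = enriched_survey
        m = de.fit_distance_gam(samples, family="nb", k=20)
        est = de.radius_of_influence(m)
        assert est.method == "derivative-scan"
        assert 3.0 < est.R_km < 9.0
        mag, ci = de.enrichment_magnitude(m, est.R_km, n_draws=500, seed=1)
        assert 10.0 < mag < 35.0
        assert ci[0] < mag < ci[1]

    def test_near_zero_baseline_triggers_crossing_rule(self):
        kern = syn.EnrichmentKernel(baseline_mean=0.01,
                                    summit_multiplier=400.0, radius_true=5.0)
        cfg = syn.SurveyConfig(seed=21, n_samples=400, max_distance_km=20.0)
        df = syn.gen_radial_survey(cfg, kern, family="nb")
        m = de.fit_distance_gam(df, family="nb", k=20)
        est = de.radius_of_influence(m, oceanic_baseline=0.02)
        assert est.method == "baseline-crossing"
        assert est.R_km is not None

    def test_ci_width_shrinks_with_sample_size(self):
        kern = syn.EnrichmentKernel(baseline_mean=2.0, summit_multiplier=20.0,
                                    radius_true=5.0)
        widths = {}
        for n in (100, 1000):
            cfg = syn.SurveyConfig(seed=22, n_samples=n,
                                   max_distance_km=20.0)
            df = syn.gen_radial_survey(cfg, kern, family="nb")
            m = de.fit_distance_gam(df, family="nb", k=20)
            mag, ci = de.enrichment_magnitude(m, 6.0, n_draws=400, seed=2)
            widths[n] = ci[1] - ci[0]
        assert widths[1000] < widths[100]


class TestStructureSelection:
    def test_single_seamount_returns_global(self, flat_survey):
        assert de.select_structure(flat_survey, family="gaussian") == "global"

    def test_shared_kernel_prefers_global(self):
        picks = []
        for s in range(10):
            kern = syn.EnrichmentKernel(baseline_mean=2.0,
                                        summit_multiplier=8.0,
                                        radius_true=5.0)
            parts = []
            for i, sm in enumerate(("Grattan", "Young")):
                cfg = syn.SurveyConfig(seed=500 + 2 * s + i, n_samples=150,
                                       max_distance_km=20.0, seamount_id=sm)
                parts.append(syn.gen_radial_survey(cfg, kern, family="nb"))
            df = pd.concat(parts, ignore_index=True)
            picks.append(de.select_structure(df, family="nb"))
        assert picks.count("global") >= 7

    def test_contrasting_kernels_prefer_per_seamount(self):
        picks = []
        for s in range(5):
            parts = []
            for i, (sm, mult) in enumerate([("Grattan", 20.0), ("Young", 1.0)]):
                kern = syn.EnrichmentKernel(baseline_mean=2.0,
                                            summit_multiplier=mult,
                                            radius_true=5.0)
                cfg = syn.SurveyConfig(seed=600 + 2 * s + i, n_samples=200,
                                       max_distance_km=20.0, seamount_id=sm)
                parts.append(syn.gen_radial_survey(cfg, kern, family="nb"))
            df = pd.concat(parts, ignore_index=True)
            picks.append(de.select_structure(df, family="nb"))
        assert picks.count("per-seamount") >= 4


class TestTwoProportion:
    def test_seamount_vs_oceanic_sailfish_occurrence(self):
        # presence 8 of 41 seamount deployments vs 1 of 56 oceanic ones
        res = de.two_proportion_test(8, 41, 1, 56)
        assert round(res["chi_square"], 1) == 6.9
        assert round(res["p"], 3) == 0.009

    def test_equal_proportions_give_zero(self):
        res = de.two_proportion_test(5, 10, 5, 10)
        assert res["chi_square"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_evaluated_corrected_formula(self):
        x1, n1, x2, n2 = 10, 20, 0, 20
        res = de.two_proportion_test(x1, n1, x2, n2)
        a, b, c, d = x1, n1 - x1, x2, n2 - x2
        n = n1 + n2
        expect = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            n1 * n2 * (a + c) * (b + d))
        assert res["chi_square"] == pytest.approx(expect, rel=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            de.two_proportion_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            de.two_proportion_test(11, 10, 1, 10)


class TestTensorSmooth:
    def test_distance_depth_field_recovered(self):
        """Tensor-product smooth of distance x depth reproduces the
        scattering-layer structure of the acoustic generator."""
        from seamount_oasis import acoustics as ac

        cfg = syn.NascConfig(seed=30, fish_multiplier=10.0,
                             zoo_sv120_peak=-95.0, noise_db=1.0,
                             layer_depth_m=120.0, summit_layer_depth_m=220.0,
                             max_distance_km=30.0)
        cells = ac.classify_cells(syn.gen_nasc_field(cfg))
        prof = ac.depth_profile(cells, "fish")
        samples = ac.nasc_to_radial_samples(prof)
        samples["response"] = np.log1p(samples["response"])
        m = de.fit_distance_gam(samples, family="gaussian", depth=True,
                                k=8, k_depth=5)
        # far from the summit the fitted field peaks near the planted layer
        far_layer = m.predict(np.array([25.0]), depth=125.0)[0]
        far_off = m.predict(np.array([25.0]), depth=275.0)[0]
        assert far_layer > far_off
        # near the summit mass shifts to the deeper accumulation
        near_deep = m.predict(np.array([0.5]), depth=225.0)[0]
        near_shallow = m.predict(np.array([0.5]), depth=25.0)[0]
        assert near_deep > near_shallow
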