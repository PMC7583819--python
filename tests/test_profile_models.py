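"""Profile-equation evaluation, NLS fitting and cross-validation tests."""

import numpy as np
import pandas as pd
import pytest

import crownlidar as cl
from crownlidar.profile_models import (FAMILIES, cross_validate,
                                       evaluate_profile, fit_by_group,
                                       fit_profile, reference_profile)

TRUE_PARAMS = {
    "parabola": {"a1": 1.0, "a2": 0.5, "b": -1.2},
    "mitscherlich": {"a": 2.7, "b1": -0.28, "b2": 1.1},
    "power": {"a1": 0.14, "a2": 1.19, "b1": 0.38, "b2": 0.12},
    "beta": {"a": 1.0928, "b1": 1.4175, "b2": 0.1787,
             "c1": 0.2125, "c2": 0.6590},
}


class TestEvaluateProfile:
    @pytest.mark.parametrize("family", sorted(FAMILIES))
    def test_zero_radius_at_crown_tip(self, family):
        out = evaluate_profile(family, TRUE_PARAMS[family], 0.0, 1.3)
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_parabola_fitted_coefficients_arithmetic(self):
        # plantation-scale coefficients, evaluated at the crown base
        params = {"a1": 1.3512, "a2": 1.8672, "b": -2.2775}
        out = evaluate_profile("parabola", params, 1.0, 1.3)
        assert out == pytest.approx(1.50106, abs=1e-10)

    def test_mitscherlich_scalar_arithmetic(self):
        p = {"a": 2.0, "b1": 0.5, "b2": 1.0}
        lcr = 1.4
        expected = 2.0 * (1 - np.exp(-(0.5 + 1.0 * lcr) * 1.0))
        assert evaluate_profile("mitscherlich", p, 1.0, lcr) \
            == pytest.approx(expected, rel=1e-14)

    def test_beta_requires_positive_shape_parameters(self):
        bad = {"a": -0.5, "b1": 1.4, "b2": 0.2, "c1": 0.2, "c2": 0.6}
        with pytest.raises(ValueError, match="beta family requires"):
            evaluate_profile("beta", bad, 0.5, 1.0)

    def test_rdinc_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="RDINC"):
            evaluate_profile("parabola", TRUE_PARAMS["parabola"], 1.2, 1.0)

    @pytest.mark.parametrize("family", sorted(FAMILIES))
    def test_finite_on_unit_interval(self, family):
        x = np.linspace(0, 1, 101)
        out = evaluate_profile(family, TRUE_PARAMS[family], x, 1.5)
        assert np.all(np.isfinite(out))


class TestFitProfile:
    @pytest.mark.parametrize("family", sorted(FAMILIES))
    def test_noiseless_exact_recovery(self, family):
        pts = cl.generate_profile_points(family, TRUE_PARAMS[family],
                                         n_trees=50, bins_per_tree=10,
                                         noise_sd=0.0, seed=3)
        fit = fit_profile(pts, family)
        for name, truth in TRUE_PARAMS[family].items():
            assert fit.params[name] == pytest.approx(truth, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("family", sorted(FAMILIES))
    def test_noisy_recovery_within_three_standard_errors(self, family):
        pts = cl.generate_profile_points(family, TRUE_PARAMS[family],
                                         n_trees=200, bins_per_tree=10,
                                         noise_sd=0.2, seed=42)
        fit = fit_profile(pts, family)
        for name, truth in TRUE_PARAMS[family].items():
            assert abs(fit.params[name] - truth) <= 3 * fit.std_errors[name]

    def test_r2_and_rmse_match_residual_sums(self):
        pts = cl.generate_profile_points("parabola", TRUE_PARAMS["parabola"],
                                         n_trees=40, bins_per_tree=8,
                                         noise_sd=0.15, seed=9)
        fit = fit_profile(pts, "parabola")
        pred = fit.predict(pts["RDINC"].to_numpy(), pts["LCR"].to_numpy())
        resid = pts["OR"].to_numpy() - pred
        sse = float((resid**2).sum())
        sst = float(((pts["OR"] - pts["OR"].mean()) ** 2).sum())
        assert fit.rmse == pytest.approx(np.sqrt(sse / len(pts)), rel=1e-9)
        assert fit.r2 == pytest.approx(1 - sse / sst, rel=1e-9)

    def test_error_shrinks_with_sample_size(self):
        errs = []
        for n_trees in (50, 200, 800):
            pts = cl.generate_profile_points(
                "parabola", TRUE_PARAMS["parabola"], n_trees=n_trees,
                bins_per_tree=10, noise_sd=0.2, seed=7)
            fit = fit_profile(pts, "parabola")
            errs.append(abs(fit.params["a1"] - TRUE_PARAMS["parabola"]["a1"]))
        assert errs[2] < errs[0]

    def test_rmse_monotone_in_noise_level(self):
        rmses = []
        for sd in (0.05, 0.2):
            vals = [fit_profile(
                cl.generate_profile_points("parabola",
                                           TRUE_PARAMS["parabola"], 60, 10,
                                           noise_sd=sd, seed=seed),
                "parabola").rmse for seed in range(4)]
            rmses.append(np.mean(vals))
        assert rmses[0] < rmses[1]

    def test_upper_scope_matches_entire_on_monotone_data(self):
        # a monotonically widening profile has no lower crown: both
        # scopes see identical points and must give identical estimates
        pts = cl.generate_profile_points("mitscherlich",
                                         TRUE_PARAMS["mitscherlich"],
                                         n_trees=30, bins_per_tree=8,
                                         noise_sd=0.0, seed=5)
        entire = fit_profile(pts, "mitscherlich", "entire")
        upper = fit_profile(pts, "mitscherlich", "upper")
        for name in entire.params:
            assert entire.params[name] == pytest.approx(upper.params[name],
                                                        abs=1e-9)

    def test_too_few_points_rejected(self):
        pts = cl.generate_profile_points("beta", TRUE_PARAMS["beta"],
                                         n_trees=1, bins_per_tree=6, seed=0)
        with pytest.raises(ValueError, match="at least"):
            fit_profile(pts, "beta")

    def test_grouped_refits_recover_group_parameters(self):
        a = cl.generate_profile_points("parabola",
                                       {"a1": 1.0, "a2": 0.5, "b": -1.2},
                                       30, 8, seed=1)
        b = cl.generate_profile_points("parabola",
                                       {"a1": 0.6, "a2": 0.9, "b": -0.8},
                                       30, 8, seed=2)
        a["plot"], b["plot"] = "one", "two"
        b["tree_id"] += 100
        fits = fit_by_group(pd.concat([a, b], ignore_index=True),
                            "parabola", "plot")
        assert fits["one"].params["a1"] == pytest.approx(1.0, abs=1e-6)
        assert fits["two"].params["a1"] == pytest.approx(0.6, abs=1e-6)


class TestCrossValidate:
    def test_noiseless_correctly_specified_has_zero_error(self):
        pts = cl.generate_profile_points("parabola", TRUE_PARAMS["parabola"],
                                         n_trees=10, bins_per_tree=8, seed=1)
        cv = cross_validate(pts, "parabola", mode="by_tree")
        assert cv.MPE == pytest.approx(0.0, abs=1e-9)
        assert cv.MAE == pytest.approx(0.0, abs=1e-9)
        assert cv.MAE_pct == pytest.approx(0.0, abs=1e-7)

    def test_matches_manual_fold_loop(self):
        pts = cl.generate_profile_points("parabola", TRUE_PARAMS["parabola"],
                                         n_trees=5, bins_per_tree=6,
                                         noise_sd=0.1, seed=8)
        cv = cross_validate(pts, "parabola", mode="by_tree")
        errors = []
        observed = []
        for tree in sorted(pts["tree_id"].unique()):
            train = pts[pts["tree_id"] != tree]
            hold = pts[pts["tree_id"] == tree]
            fit = fit_profile(train, "parabola")
            pred = fit.predict(hold["RDINC"].to_numpy(),
                               hold["LCR"].to_numpy())
            errors.append(hold["OR"].to_numpy() - pred)
            observed.append(hold["OR"].to_numpy())
        e = np.concatenate(errors)
        obs = np.concatenate(observed)
        assert cv.MPE == pytest.approx(e.mean(), rel=1e-9)
        assert cv.MAE == pytest.approx(np.abs(e).mean(), rel=1e-9)
        assert cv.MAE_pct == pytest.approx(
            (np.abs(e[obs > 0]) / obs[obs > 0]).mean() * 100, rel=1e-9)

    def test_by_point_mode_runs(self):
        pts = cl.generate_profile_points("parabola", TRUE_PARAMS["parabola"],
                                         n_trees=3, bins_per_tree=4,
                                         noise_sd=0.05, seed=2)
        cv = cross_validate(pts, "parabola", mode="by_point")
        assert cv.n == len(pts)
        assert cv.MAE >= abs(cv.MPE)

    def test_too_few_groups_rejected(self):
        pts = cl.generate_profile_points("parabola", TRUE_PARAMS["parabola"],
                                         n_trees=2, bins_per_tree=6, seed=0)
        with pytest.raises(ValueError, match="at least 3"):
            cross_validate(pts, "parabola", mode="by_tree")


class TestReferenceProfile:
    PARAMS = {"a1": 0.5, "a2": 0.9, "a3": 0.6, "a4": 0.5, "a5": 0.4,
              "a6": 0.1}

    def test_zero_at_crown_tip(self):
        assert reference_profile(self.PARAMS, 0.0, 10.0, 0.55, 0.95) == 0.0

    def test_matches_scalar_rederivation(self):
        x, dbh, ch, hd = 0.6, 12.0, 0.5, 0.9
        p = self.PARAMS
        X = (1 - np.sqrt(1 - x)) / (1 - np.sqrt(p["a3"] * ch ** p["a4"]))
        E = p["a5"] * (1 - x) + p["a6"] * np.exp(1 / hd) * (1 - x)
        expected = p["a1"] * dbh ** p["a2"] * X ** E
        assert reference_profile(self.PARAMS, x, dbh, ch, hd) \
            == pytest.approx(expected, rel=1e-14)

    def test_invalid_covariates_rejected(self):
        with pytest.raises(ValueError, match="DBH"):
            reference_profile(self.PARAMS, 0.5, -1.0, 0.5, 1.0)

    def test_injected_linear_reference_reproduces_itself(self):
        # any callable can stand in for the field-based reference
        lcr = 1.4
        linear = lambda x: lcr * np.asarray(x)  # noqa: E731
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(linear(x), lcr * x)
        v = cl.volume_of_revolution(linear, CL=6.0)
        assert v == pytest.approx(np.pi * lcr**2 * 6.0 / 3.0, rel=1e-8)
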