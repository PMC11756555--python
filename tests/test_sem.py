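import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from driftsem import (GeneratorConfig, SemModelSpec, count_df,
                      detect_suppression, extended_ddm_model, fit_ml,
                      generate_participant_params, generate_scores,
                      indirect_effects, overt_two_factor_model)
from driftsem.sem import _Ram, product_delta_se


def _population_fit_inputs():
    """A population covariance generated exactly from the overt model."""
    spec = overt_two_factor_model()
    ram = _Ram(spec)
    vals = {}
    for name in ram.names:
        if "=~" in name:
            vals[name] = 0.8
        elif "~~" in name:
            a, b = name.split("~~")
            if a == b:
                vals[name] = 0.5
            else:
                vals[name] = -0.3 if a == "SCC" else 0.15
        else:
            vals[name] = {"PSI~SCC": 0.0, "PSI~SCB": 0.6,
                          "OSI~SCC": -0.3, "OSI~SCB": 0.3}[name]
    theta_star = np.array([vals[n] for n in ram.names])
    return spec, ram, theta_star, ram.implied_sigma(theta_star)


class TestDegreesOfFreedom:
    def test_overt_two_factor_model_has_16(self):
        assert count_df(overt_two_factor_model()) == 16
        assert len(overt_two_factor_model().observed) == 8

    def test_extended_model_has_24(self):
        assert count_df(extended_ddm_model()) == 24
        assert len(extended_ddm_model().observed) == 10

    def test_saturated_model_has_zero(self):
        spec = SemModelSpec(
            observed_exogenous=["a", "b", "c"],
            covariances=[("a", "b"), ("a", "c"), ("b", "c")])
        assert count_df(spec) == 0

    def test_df_matches_optimizer_free_parameter_count(self):
        for spec in (overt_two_factor_model(), extended_ddm_model()):
            p = len(spec.observed)
            assert count_df(spec) == p * (p + 1) // 2 - len(
                spec.free_parameters())

    def test_underidentified_model_rejected(self):
        spec = SemModelSpec(observed_exogenous=["a", "b"],
                            covariances=[("a", "b"), ("a", "b"), ("a", "b")])
        with pytest.raises(ValueError, match="not identified"):
            count_df(spec)

    def test_latent_needs_two_indicators(self):
        with pytest.raises(ValueError):
            SemModelSpec(latents={"F": ["only_one"]})


class TestFitMl:
    def test_perfect_fit_limit_recovers_parameters(self):
        spec, ram, theta_star, sigma_pop = _population_fit_inputs()
        fit = fit_ml(spec, sample_cov=sigma_pop, n=271)
        assert fit.chi_square == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == pytest.approx(1.0, abs=1e-8)
        assert fit.rmsea == pytest.approx(0.0, abs=1e-6)
        assert np.abs(fit.theta - theta_star).max() < 1e-4

    def test_second_optimizer_oracle_agrees_on_discrepancy(self):
        # independent route: Nelder-Mead on the raw discrepancy from a
        # perturbed start must land on the same minimum
        cfg = GeneratorConfig(n_participants=400, seed=17)
        scores = generate_scores(cfg, generate_participant_params(cfg))
        spec = overt_two_factor_model()
        fit = fit_ml(spec, scores)

        ram = _Ram(spec)
        obs = scores[spec.observed].dropna().to_numpy(dtype=float)
        S = np.cov(obs, rowvar=False, ddof=1)
        sign, logdet_S = np.linalg.slogdet(S)
        p = S.shape[0]

        def discrepancy(theta):
            sigma = ram.implied_sigma(theta)
            s2, ld = np.linalg.slogdet(sigma)
            if s2 <= 0:
                return 1e10
            return ld + np.trace(np.linalg.solve(sigma, S)) - logdet_S - p

        rng = np.random.default_rng(1)
        start = fit.theta * (1 + 0.05 * rng.standard_normal(fit.theta.size))
        res = minimize(discrepancy, start, method="Nelder-Mead",
                       options={"maxiter": 40_000, "maxfev": 40_000,
                                "fatol": 1e-12, "xatol": 1e-8})
        assert fit.fmin == pytest.approx(res.fun, abs=1e-4)
        assert fit.fmin <= res.fun + 1e-6   # quasi-Newton at least as good

    def test_scale_invariance_of_chi_square(self):
        # standardized and raw data imply the same test statistic
        cfg = GeneratorConfig(n_participants=300, seed=23)
        scores = generate_scores(cfg, generate_participant_params(cfg))
        spec = overt_two_factor_model()
        fit_raw = fit_ml(spec, scores)
        z = (scores[spec.observed] - scores[spec.observed].mean()) \
            / scores[spec.observed].std()
        fit_std = fit_ml(spec, z)
        assert fit_raw.chi_square == pytest.approx(fit_std.chi_square,
                                                   abs=1e-5)

    def test_implied_covariance_positive_definite_at_optimum(self):
        cfg = GeneratorConfig(n_participants=300, seed=29)
        scores = generate_scores(cfg, generate_participant_params(cfg))
        fit = fit_ml(overt_two_factor_model(), scores)
        sigma = fit._ram.implied_sigma(fit.theta)
        assert np.linalg.eigvalsh(sigma).min() > 0
        assert np.allclose(sigma, sigma.T)

    def test_singular_sample_covariance_rejected(self):
        cfg = GeneratorConfig(n_participants=100, seed=2)
        scores = generate_scores(cfg, generate_participant_params(cfg))
        scores["OSI"] = scores["PSI"]   # exact collinearity
        with pytest.raises(ValueError, match="positive definite"):
            fit_ml(overt_two_factor_model(), scores)

    def test_needs_more_cases_than_variables(self):
        cfg = GeneratorConfig(n_participants=6, seed=2)
        scores = generate_scores(cfg, generate_participant_params(cfg))
        with pytest.raises(ValueError, match="complete cases"):
            fit_ml(overt_two_factor_model(), scores)


class TestIndirectEffects:
    def test_delta_method_arithmetic(self):
        # stated-formula check: a=0.5, b=0.4, Var=0.01 each, zero covariance
        assert product_delta_se(0.5, 0.4, 0.01, 0.01) == pytest.approx(
            np.sqrt(0.16 * 0.01 + 0.25 * 0.01))

    def test_estimate_is_product_of_path_coefficients(self):
        cfg = GeneratorConfig(n_participants=500, seed=3,
                              ddm_latent_coupling={("v", "SCC"): 0.4})
        scores = generate_scores(cfg, generate_participant_params(cfg))
        fit = fit_ml(extended_ddm_model(t0="t0_baseline", v="v_baseline"),
                     scores)
        ie = indirect_effects(fit, [("v_baseline", "SCC", "OSI")]).iloc[0]
        a = fit.estimate("SCC~v_baseline")
        b = fit.estimate("OSI~SCC")
        assert ie["estimate"] == pytest.approx(a * b, rel=1e-12)
        a_s = fit.estimate("SCC~v_baseline", standardized=True)
        b_s = fit.estimate("OSI~SCC", standardized=True)
        assert ie["std"] == pytest.approx(a_s * b_s, rel=1e-12)

    def test_absent_path_raises(self):
        cfg = GeneratorConfig(n_participants=300, seed=5)
        scores = generate_scores(cfg, generate_participant_params(cfg))
        fit = fit_ml(overt_two_factor_model(), scores)
        with pytest.raises(KeyError):
            indirect_effects(fit, [("SCC", "SCB", "PSI")])

    def test_delta_se_matches_bootstrap(self):
        # bootstrap oracle at n = 500 (200 resamples, warm-started refits)
        cfg = GeneratorConfig(n_participants=500, seed=37,
                              ddm_latent_coupling={("v", "SCC"): 0.4})
        scores = generate_scores(cfg, generate_participant_params(cfg))
        spec = extended_ddm_model(t0="t0_baseline", v="v_baseline")
        fit = fit_ml(spec, scores)
        ie = indirect_effects(fit, [("v_baseline", "SCC", "OSI")]).iloc[0]

        rng = np.random.default_rng(11)
        boots = []
        for _ in range(200):
            resampled = scores.sample(n=len(scores), replace=True,
                                      random_state=rng.integers(2**31))
            bfit = fit_ml(spec, resampled, theta0=fit.theta)
            bie = indirect_effects(bfit, [("v_baseline", "SCC", "OSI")])
            boots.append(float(bie["estimate"].iloc[0]))
        boot_se = np.std(boots, ddof=1)
        assert abs(ie["se"] - boot_se) / boot_se < 0.15


class TestSuppression:
    @pytest.fixture(scope="class")
    def suppression_fit(self):
        # nondecision time raises social-cognitive bias (positive indirect
        # route to loneliness) while its direct effect on loneliness is
        # negative: the textbook suppression pattern
        cfg = GeneratorConfig(
            n_participants=2000, seed=31,
            ddm_latent_coupling={("t0", "SCB"): 0.45},
            structural_paths={("SCB", "PSI"): 0.56, ("SCB", "OSI"): 0.31,
                              ("SCC", "OSI"): -0.26, ("SCC", "PSI"): 0.0,
                              ("t0", "PSI"): -0.25})
        scores = generate_scores(cfg, generate_participant_params(cfg))
        return fit_ml(extended_ddm_model(t0="t0_baseline", v="v_baseline"),
                      scores)

    def test_opposite_significant_effects_flagged(self, suppression_fit):
        rep = detect_suppression(suppression_fit, "t0_baseline", "PSI", "SCB")
        assert rep["suppression"] is True
        assert rep["direct"] < 0 < rep["indirect"]
        assert rep["total"] == pytest.approx(rep["direct"] + rep["indirect"])

    def test_same_sign_is_not_suppression(self, suppression_fit):
        # SCB -> OSI direct and the v -> SCC -> OSI chain do not oppose
        rep = detect_suppression(suppression_fit, "v_baseline", "OSI", "SCC")
        assert rep["suppression"] is False

    def test_nonsignificant_effects_reported_with_reason(self):
        cfg = GeneratorConfig(n_participants=300, seed=41)
        scores = generate_scores(cfg, generate_participant_params(cfg))
        fit = fit_ml(extended_ddm_model(t0="t0_baseline", v="v_baseline"),
                     scores)
        rep = detect_suppression(fit, "v_baseline", "PSI", "SCB")
        assert rep["suppression"] is False
        assert rep["reason"] is not None
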