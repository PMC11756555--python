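import numpy as np
import pytest

from driftsem import (DDMParams, SamplerConfig, compute_mpsf, point_estimates,
                      run_demc, simulate_trials)
from driftsem.demcmc import ChainSet, PARAM_NAMES


def _toy_gaussian(seed=1, n_iter=1500, burn_in=500):
    """Sample a 5-D spherical Gaussian well inside the prior support."""
    mu = np.array([2.0, 1.0, 0.4, 0.25, 1.5])
    sig = 0.05

    def lp(x):
        return float(-0.5 * np.sum((x - mu) ** 2) / sig ** 2)

    cfg = SamplerConfig(seed=seed, n_iter=n_iter, burn_in=burn_in)
    return mu, sig, run_demc(None, cfg, log_density=lp)


class TestSampler:
    def test_gaussian_target_posterior_mean_and_variance(self):
        # analytic-target oracle: marginal means and variances must match
        # within 3 Monte-Carlo SEs (estimated from between-chain spread)
        mu, sig, chains = _toy_gaussian()
        flat = chains.retained().reshape(-1, 5)
        chain_means = chains.retained().mean(axis=1)
        se_mean = chain_means.std(axis=0, ddof=1) / np.sqrt(len(chain_means))
        assert np.all(np.abs(flat.mean(axis=0) - mu) < 3 * se_mean)

        chain_vars = chains.retained().var(axis=1, ddof=1)
        se_var = chain_vars.std(axis=0, ddof=1) / np.sqrt(len(chain_vars))
        assert np.all(np.abs(flat.var(axis=0, ddof=1) - sig ** 2)
                      < 3 * se_var)

    def test_deterministic_under_seed(self):
        _, _, a = _toy_gaussian(seed=3, n_iter=300, burn_in=100)
        _, _, b = _toy_gaussian(seed=3, n_iter=300, burn_in=100)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.log_posterior, b.log_posterior)

    def test_samples_respect_prior_support(self):
        _, _, chains = _toy_gaussian(seed=5, n_iter=400, burn_in=100)
        cfg = SamplerConfig()
        flat = chains.samples.reshape(-1, 5)
        for j, name in enumerate(PARAM_NAMES):
            lo, hi = cfg.priors[name]
            assert flat[:, j].min() >= lo and flat[:, j].max() <= hi
        assert np.all(flat[:, 2] - flat[:, 3] / 2 > 0.05)

    def test_too_few_trials_rejected(self):
        p = DDMParams(v=3, a=1.2, t0=0.3)
        rt, c = simulate_trials(p, 20, seed=1)
        with pytest.raises(ValueError, match="at least 40"):
            run_demc((rt, c), SamplerConfig(seed=1, n_iter=50, burn_in=10))

    def test_single_boundary_data_flagged(self):
        p = DDMParams(v=3, a=1.2, t0=0.3)
        rt, c = simulate_trials(p, 60, seed=1)
        chains = run_demc((rt, np.ones_like(c)),
                          SamplerConfig(seed=1, n_iter=60, burn_in=20))
        assert chains.degenerate_responses
        _, warnings = point_estimates(chains, check_convergence=False)
        assert any("boundary" in w for w in warnings)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_chains=5)          # fewer than 2 x 5 params
        with pytest.raises(ValueError):
            SamplerConfig(n_iter=100, burn_in=100)


class TestMpsf:
    def _chains(self, m=4, n=200, d=3, seed=0):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((m, n, d))

    def test_identical_chains_give_exactly_one(self):
        one = self._chains(m=1)[0]
        stacked = np.stack([one] * 5)
        rep = compute_mpsf(stacked)
        assert rep.mpsf == pytest.approx(1.0, abs=1e-6)
        assert rep.converged

    def test_offset_chain_flags_divergence(self):
        x = self._chains()
        x[0] += 10.0
        rep = compute_mpsf(x)
        assert rep.mpsf > 1.15
        assert not rep.converged

    def test_one_parameter_case_reduces_to_univariate_psrf(self):
        x = self._chains(d=1, seed=3)
        x[1] += 0.4
        rep = compute_mpsf(x)
        assert rep.mpsf == pytest.approx(rep.psrf["p0"], abs=1e-10)

    def test_affine_invariance(self):
        x = self._chains(m=5, n=300, d=4, seed=4)
        x[2] += 0.3
        rng = np.random.default_rng(9)
        M = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        b = rng.standard_normal(4)
        y = x @ M.T + b
        assert compute_mpsf(y).mpsf == pytest.approx(compute_mpsf(x).mpsf,
                                                     abs=1e-8)

    def test_stuck_chains_raise_singular_error(self):
        x = np.zeros((3, 50, 2))
        with pytest.raises(np.linalg.LinAlgError):
            compute_mpsf(x)

    def test_needs_enough_chains_and_iterations(self):
        with pytest.raises(ValueError):
            compute_mpsf(np.zeros((1, 100, 2)))
        with pytest.raises(ValueError):
            compute_mpsf(np.zeros((3, 5, 2)))


class TestPointEstimates:
    def _constant_chainset(self, value):
        samples = np.tile(np.asarray(value, dtype=float), (4, 50, 1))
        return ChainSet(samples=samples, log_posterior=np.zeros((4, 50)),
                        accepted=np.zeros(4, dtype=int), burn_in=10)

    def test_constant_chains_return_the_constant(self):
        value = [2.0, 1.1, 0.33, 0.1, 0.7]
        est, _ = point_estimates(self._constant_chainset(value),
                                 check_convergence=False)
        assert [est.v, est.a, est.t0, est.st0, est.sv] == pytest.approx(value)

    def test_pooled_mean_equals_mean_of_chain_means(self):
        _, _, chains = _toy_gaussian(seed=6, n_iter=300, burn_in=100)
        pooled = chains.retained().reshape(-1, 5).mean(axis=0)
        per_chain = chains.retained().mean(axis=1).mean(axis=0)
        assert pooled == pytest.approx(per_chain, rel=1e-12)

    def test_nonconverged_estimate_carries_warning(self):
        x = np.abs(np.random.default_rng(0).standard_normal((15, 100, 5)))
        x = 0.2 + 0.1 * x
        x[:, :, 2] += 0.2   # keep t0 - st0/2 positive
        x[0] += 5.0
        chains = ChainSet(samples=x, log_posterior=np.zeros((15, 100)),
                          accepted=np.zeros(15, dtype=int), burn_in=20)
        est, warnings = point_estimates(chains)
        assert est is not None
        assert any("not converged" in w for w in warnings)


class TestCredibleIntervalCalibration:
    def test_drift_credible_intervals_cover_truth(self):
        # 10 participants from the population model, 400 trials each so the
        # likelihood dominates the bounded flat prior; 90% intervals must
        # cover the generating drift in >= 80% of cases
        from driftsem import GeneratorConfig, generate_participant_params
        gc = GeneratorConfig(n_participants=10, seed=0)
        truth = generate_participant_params(gc)
        cover = 0
        for i, row in truth.iterrows():
            p = DDMParams(v=row.v_baseline, a=row.a_baseline,
                          t0=row.t0_baseline, st0=row.st0_baseline,
                          sv=row.sv_baseline)
            rt, c = simulate_trials(p, 400, seed=3000 + i)
            chains = run_demc((rt, c), SamplerConfig(seed=4000 + i,
                                                     n_iter=1000,
                                                     burn_in=500))
            lo, hi = np.quantile(chains.retained().reshape(-1, 5)[:, 0],
                                 [0.05, 0.95])
            cover += int(lo <= p.v <= hi)
        assert cover >= 8
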