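"""Sampler validation: reproducibility, conjugate-block oracles,
convergence diagnostics, and parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cptrend as ct
from cptrend.model_core import ModelSpec

from conftest import make_draws


def _panel_from_values(values, times=None, country="BE"):
    times = times if times is not None else range(1, len(values) + 1)
    return ct.PanelDataset(
        pd.DataFrame({"country": country, "time": list(times), "value": values}),
        allow_negative=True,
    )


class TestReproducibility:
    def test_same_seed_bit_identical(self, small_panel):
        panel, _ = small_panel
        scfg = ct.SamplerConfig(n_chains=2, n_iterations=300, n_burnin=100, thin=2, seed=17)
        a = ct.run_mcmc(panel, ModelSpec(1), ct.PriorConfig(), scfg)
        b = ct.run_mcmc(panel, ModelSpec(1), ct.PriorConfig(), scfg)
        for key in ("beta0", "cps", "sigma2_eps", "deviance", "b0"):
            np.testing.assert_array_equal(a.pooled(key), b.pooled(key))

    def test_retained_count(self, small_panel):
        panel, _ = small_panel
        scfg = ct.SamplerConfig(n_chains=2, n_iterations=315, n_burnin=100, thin=4, seed=17)
        draws = ct.run_mcmc(panel, ModelSpec(0), ct.PriorConfig(), scfg)
        assert draws.n_retained_per_chain == (315 - 100) // 4

    def test_save_load_roundtrip(self, small_panel, tmp_path):
        panel, _ = small_panel
        scfg = ct.SamplerConfig(n_chains=2, n_iterations=200, n_burnin=50, thin=2, seed=4)
        draws = ct.run_mcmc(panel, ModelSpec(1), ct.PriorConfig(), scfg)
        draws.save(tmp_path / "d")
        again = ct.PosteriorDraws.load(tmp_path / "d")
        for key in ("beta0", "cps", "b_cp", "deviance"):
            np.testing.assert_allclose(again.pooled(key), draws.pooled(key), rtol=1e-12)


class TestConjugateOracles:
    """Each conjugate block, conditioned on a clamped remainder, must
    reproduce its analytic full conditional."""

    def test_beta0_normal_mean_posterior(self):
        # K=0, seasonal and random effects clamped to zero, known noise
        # variance: beta0 | y is exactly N(m, v)
        rng = np.random.default_rng(0)
        y = rng.normal(17.0, math.sqrt(2.0), size=8)
        panel = _panel_from_values(y)
        s2, v0 = 2.0, 1000.0
        clamp = dict(beta1=0.0, beta0s=0.0, beta1s=0.0, delta=0.0,
                     random_effects=0.0, sigma2_eps=s2)
        scfg = ct.SamplerConfig(
            n_chains=2, n_iterations=10500, n_burnin=500, thin=1, seed=3,
            fixed_params=clamp,
        )
        draws = ct.run_mcmc(panel, ModelSpec(0), ct.PriorConfig(), scfg)
        b0 = draws.pooled("beta0")
        v = 1.0 / (len(y) / s2 + 1.0 / v0)
        m = v * y.sum() / s2
        n = len(b0)  # draws are i.i.d. here
        assert abs(b0.mean() - m) < 3 * math.sqrt(v / n)
        assert abs(b0.var(ddof=1) - v) < 3 * v * math.sqrt(2.0 / (n - 1))

    def test_beta0_collapsed_marginal_posterior(self):
        # random intercepts sampled but integrated out of the beta draw:
        # beta0 | y marginally N(m, v) with per-country variance
        # sigma2_eps + J * sigma2_b0 on the country mean
        rng = np.random.default_rng(1)
        n_c, J = 4, 6
        s2e, s2b = 1.5, 3.0
        frames = []
        for i in range(n_c):
            yi = 17.0 + rng.normal(0, math.sqrt(s2b)) + rng.normal(0, math.sqrt(s2e), J)
            frames.append(
                pd.DataFrame({"country": f"C{i}", "time": range(1, J + 1), "value": yi})
            )
        panel = ct.PanelDataset(pd.concat(frames, ignore_index=True))
        clamp = dict(beta1=0.0, beta0s=0.0, beta1s=0.0, delta=0.0,
                     sigma2_eps=s2e, sigma2_b0=s2b, sigma2_b1=1e-10, sigma2_b0s=1e-10)
        scfg = ct.SamplerConfig(
            n_chains=2, n_iterations=10500, n_burnin=500, thin=1, seed=5,
            fixed_params=clamp,
        )
        draws = ct.run_mcmc(panel, ModelSpec(0), ct.PriorConfig(), scfg)
        b0 = draws.pooled("beta0")
        prec = n_c * J / (s2e + J * s2b) + 1.0 / 1000.0
        v = 1.0 / prec
        m = v * sum(
            panel.frame[panel.frame["country"] == f"C{i}"]["value"].sum() / (s2e + J * s2b)
            for i in range(n_c)
        )
        n = len(b0)
        assert abs(b0.mean() - m) < 4 * math.sqrt(v / n)
        assert abs(b0.var(ddof=1) - v) < 4 * v * math.sqrt(2.0 / (n - 1))

    def test_sigma2_eps_inverse_gamma_posterior(self):
        # all location parameters clamped: sigma2_eps | y is exactly
        # IGamma(a + n/2, b + SSR/2)
        rng = np.random.default_rng(2)
        mu0 = 17.0
        y = rng.normal(mu0, 1.2, size=12)
        panel = _panel_from_values(y)
        clamp = dict(beta0=mu0, beta1=0.0, beta0s=0.0, beta1s=0.0, delta=0.0,
                     random_effects=0.0)
        scfg = ct.SamplerConfig(
            n_chains=2, n_iterations=10500, n_burnin=500, thin=1, seed=6,
            fixed_params=clamp,
        )
        draws = ct.run_mcmc(panel, ModelSpec(0), ct.PriorConfig(), scfg)
        s2 = draws.pooled("sigma2_eps")
        shape = 0.001 + len(y) / 2.0
        rate = 0.001 + float(((y - mu0) ** 2).sum()) / 2.0
        dist = stats.invgamma(shape, scale=rate)
        n = len(s2)
        se_mean = math.sqrt(dist.var() / n)
        assert abs(s2.mean() - dist.mean()) < 4 * se_mean
        # delta-method SE for the sample variance via the empirical 4th moment
        m4 = float(((s2 - s2.mean()) ** 4).mean())
        se_var = math.sqrt(max(m4 - s2.var() ** 2, 0.0) / n)
        assert abs(s2.var(ddof=1) - dist.var()) < 4 * se_var


class TestDrawValidity:
    def test_ordered_changepoints_all_draws(self, recovery_fits):
        draws, _, _ = recovery_fits[2]
        cps = draws.pooled("cps")
        assert np.all(np.diff(cps, axis=1) > 0)

    def test_finite_deviance_all_draws(self, recovery_fits):
        for k in recovery_fits:
            dev = recovery_fits[k][0].pooled("deviance")
            assert np.all(np.isfinite(dev))

    def test_positive_variances_all_draws(self, recovery_fits):
        draws, _, _ = recovery_fits[2]
        for key in ("sigma2_b0", "sigma2_b1", "sigma2_b0s", "sigma2_eps"):
            assert np.all(draws.pooled(key) > 0)
        assert np.all(draws.pooled("sigma2_bcp") > 0)

    def test_infeasible_k_rejected(self):
        panel = _panel_from_values([10.0, 11.0, 12.0, 11.5, 10.5])
        with pytest.raises(ValueError, match="fewer change-points"):
            ct.run_mcmc(
                panel,
                ModelSpec(2),
                ct.PriorConfig(),
                ct.SamplerConfig(n_iterations=100, n_burnin=10, seed=0),
            )


class TestConvergenceDiagnostics:
    def test_iid_gaussian_chains_rhat_near_one(self):
        rng = np.random.default_rng(8)
        chains = [{"beta0": rng.normal(size=1000)} for _ in range(2)]
        draws = make_draws(ModelSpec(0), [], chains)
        report = ct.assess_convergence(draws)
        assert report.rhat["beta0"] == pytest.approx(1.0, abs=0.05)
        assert report.converged

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(9)
        chains = [
            {"beta0": rng.normal(loc=0.0, size=1000)},
            {"beta0": rng.normal(loc=5.0, size=1000)},
        ]
        report = ct.assess_convergence(make_draws(ModelSpec(0), [], chains))
        assert report.rhat["beta0"] > 1.1
        assert not report.converged

    def test_single_chain_rejected(self):
        draws = make_draws(ModelSpec(0), [], [{"beta0": np.zeros(10)}])
        with pytest.raises(ValueError, match="2 chains"):
            ct.assess_convergence(draws)

    def test_overfitted_model_fails_convergence(self):
        # one true change-point, three fitted: surplus change-points
        # wander and the chains disagree — the overfitting symptom
        cfg = ct.SimulationConfig(
            n_countries=10, t_max=60, seed=21,
            beta_cp=(0.08,), cps=(30.0,), sigma2_bcp=(0.03,),
        )
        panel, _ = ct.simulate_panel(cfg)
        scfg = ct.SamplerConfig(n_chains=2, n_iterations=3000, n_burnin=1000, thin=2, seed=33)
        draws = ct.run_mcmc(panel, ModelSpec(3), ct.PriorConfig(), scfg)
        assert not ct.assess_convergence(draws).converged


class TestParameterRecovery:
    def test_credible_interval_coverage(self):
        """95% intervals for intercept, amplitude trend, phase and both
        change-points cover the generating values in >= 90% of
        (parameter, replicate) checks over 20 seeded replicates."""
        truth = {"beta0": 18.046, "beta1s": -0.012, "delta": 0.399}
        cps_truth = [29.0, 49.0]
        covered = total = 0
        for r in range(20):
            cfg = ct.SimulationConfig(n_countries=10, t_max=84, seed=1000 + r)
            panel, _ = ct.simulate_panel(cfg)
            scfg = ct.SamplerConfig(
                n_chains=2, n_iterations=2000, n_burnin=500, thin=2, seed=2000 + r
            )
            draws = ct.run_mcmc(panel, ModelSpec(2), ct.PriorConfig(), scfg)
            for key, val in truth.items():
                lo, hi = np.percentile(draws.pooled(key), [2.5, 97.5])
                covered += lo <= val <= hi
                total += 1
            cps = draws.pooled("cps")
            for j, val in enumerate(cps_truth):
                lo, hi = np.percentile(cps[:, j], [2.5, 97.5])
                covered += lo <= val <= hi
                total += 1
        assert total == 100
        assert covered >= 90
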