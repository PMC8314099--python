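"""Shared fixtures: synthetic panels and fitted models reused across tests.

The expensive MCMC fits (15 countries x 84 quarters, K = 0, 1, 2) are
session-scoped so that parameter-recovery and DIC-ordering checks share
one set of chains.
"""

from __future__ import annotations

import numpy as np
import pytest

import cptrend as ct
from cptrend.mcmc import PosteriorDraws


# protocol for the shared recovery fits: 2 chains x 8000 iterations,
# burn-in 2000, thinning 2 (scaled-down version of the recommended
# 2 x 110000 / 10000 / 5 production protocol)
RECOVERY_SIM_SEED = 11
RECOVERY_FIT_SEED = 5


@pytest.fixture(scope="session")
def recovery_panel():
    """15-country, 84-quarter panel at the default generating values
    (two change-points at quarters 29 and 49)."""
    cfg = ct.SimulationConfig(n_countries=15, t_max=84, seed=RECOVERY_SIM_SEED)
    return ct.simulate_panel(cfg)


@pytest.fixture(scope="session")
def recovery_fits(recovery_panel):
    """Fits of K = 0, 1, 2 on the recovery panel: {K: (draws, convergence, dic)}."""
    panel, _ = recovery_panel
    scfg = ct.SamplerConfig(
        n_chains=2, n_iterations=8000, n_burnin=2000, thin=2, seed=RECOVERY_FIT_SEED
    )
    out = {}
    for k in range(3):
        spec = ct.ModelSpec(n_changepoints=k)
        draws = ct.run_mcmc(panel, spec, ct.PriorConfig(), scfg)
        conv = ct.assess_convergence(draws)
        out[k] = (draws, conv, ct.compute_dic(draws, panel, spec, conv))
    return out


@pytest.fixture()
def small_panel():
    """Quick 3-country unbalanced panel for cheap structural tests."""
    cfg = ct.SimulationConfig(
        n_countries=3,
        t_max=16,
        seed=2,
        late_entry_fraction=0.3,
        late_entry_max_delay=4,
        intermittent_missing_rate=0.05,
        right_truncation_fraction=0.2,
        right_truncation_max=3,
    )
    return ct.simulate_panel(cfg)


def make_draws(spec, countries, chain_values, n=None):
    """Hand-build a PosteriorDraws object from per-chain scalar values.

    ``chain_values`` is a list (one entry per chain) of dicts mapping
    chain-dict keys (beta0, cps, b0, ...) to arrays; anything missing is
    filled with zeros of the right shape.  Scalars are broadcast to
    length ``n``.
    """
    k = spec.n_changepoints
    n_c = len(countries)
    chains = []
    for values in chain_values:
        sizes = [np.shape(np.atleast_1d(v))[0] for v in values.values() if np.ndim(v) >= 1]
        length = n or (sizes[0] if sizes else 10)
        c = {
            "beta0": np.zeros(length),
            "beta1": np.zeros(length),
            "beta_cp": np.zeros((length, k)),
            "cps": np.zeros((length, k)),
            "beta0s": np.zeros(length),
            "beta1s": np.zeros(length),
            "delta": np.zeros(length),
            "sigma2_b0": np.ones(length),
            "sigma2_b1": np.ones(length),
            "sigma2_bcp": np.ones((length, k)),
            "sigma2_b0s": np.ones(length),
            "sigma2_eps": np.ones(length),
            "b0": np.zeros((length, n_c)),
            "b1": np.zeros((length, n_c)),
            "b_cp": np.zeros((length, n_c, k)),
            "b0s": np.zeros((length, n_c)),
            "deviance": np.zeros(length),
        }
        for key, v in values.items():
            v = np.asarray(v, dtype=float)
            target = c[key].shape
            if v.ndim == 0 or v.shape == target[1:]:
                c[key] = np.broadcast_to(v, target).copy()
            else:
                c[key] = v.reshape(target) if v.shape != target else v
        chains.append(c)
    cfg = ct.SamplerConfig(n_chains=len(chains), n_iterations=10, n_burnin=0, thin=1)
    return PosteriorDraws(
        chains, spec, list(countries), cfg, ct.PriorConfig(cp_upper=84.0), acceptance=[]
    )
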