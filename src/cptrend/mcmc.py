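"""Metropolis-within-Gibbs sampler for the change-point panel model.

The posterior is proportional to (Gaussian likelihood, conditional on
random effects) × (prior stack).  Given the change-points and the phase
shift, the mean is *linear* in every coefficient, so most of the sweep is
exact conjugate Gibbs:

* fixed-effect block (intercept, slope, slope differences, amplitude
  terms) — joint Gaussian full conditional;
* per-country random-effect vector — Gaussian full conditional;
* every variance component — inverse-gamma full conditional;

leaving only the phase shift ``delta`` and each change-point ``C_k`` to
random-walk Metropolis steps.  Change-point proposals outside the ordered
support (or leaving fewer than two observed time points on either side —
a guard against boundary sticking where the likelihood is flat) are
rejected outright.  Proposal scales are adapted toward ~30% acceptance
during burn-in only, then frozen, so detailed balance holds for every
retained draw.

The recommended protocol for production runs is two chains of 110 000
iterations with a 10 000-iteration burn-in, thinned to every 5th draw;
all counts are configurable and validation tests use much shorter chains.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import PanelDataset
from .model_core import (
    ChangePoints,
    FixedEffects,
    ModelSpec,
    ParameterState,
    RandomEffects,
    VarianceComponents,
)
from .priors import PriorConfig, log_prior_changepoints, _sample_igamma

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "ConvergenceReport",
    "run_mcmc",
    "assess_convergence",
]

_LOG_2PI = math.log(2.0 * math.pi)

# names accepted in SamplerConfig.fixed_params (clamped, not sampled)
_CLAMPABLE = {
    "beta0",
    "beta1",
    "beta_cp",
    "beta0s",
    "beta1s",
    "delta",
    "cps",
    "random_effects",
    "sigma2_b0",
    "sigma2_b1",
    "sigma2_bcp",
    "sigma2_b0s",
    "sigma2_eps",
}


@dataclass
class SamplerConfig:
    """Chain protocol and kernel tuning.

    ``fixed_params`` clamps named parameters to given values and skips
    their updates — used by validation tests (e.g. reducing the model to
    a conjugate normal-mean problem) and by single-country analyses where
    random effects are redundant.
    """

    n_chains: int = 2
    n_iterations: int = 110_000
    n_burnin: int = 10_000
    thin: int = 5
    seed: int = 0
    proposal_scale_delta: float = 0.05
    proposal_scale_cp: float = 2.0
    adapt_during_burnin: bool = True
    rhat_threshold: float = 1.1
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        unknown = set(self.fixed_params) - _CLAMPABLE
        if unknown:
            raise ValueError(f"unknown fixed_params keys: {sorted(unknown)}")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class ConvergenceReport:
    """Split r-hat and effective sample size for the monitored scalars."""

    rhat: dict
    ess: dict
    converged: bool
    threshold: float


class PosteriorDraws:
    """Thinned post-burn-in posterior draws, one block of arrays per chain.

    Each chain dict maps parameter names to arrays with the retained-draw
    axis first (scalars -> (n,), change-points -> (n, K), random effects
    -> (n, N) or (n, N, K)); ``deviance`` holds −2·log-likelihood at each
    retained draw.
    """

    def __init__(
        self,
        chains: list[dict],
        spec: ModelSpec,
        countries: list[str],
        config: SamplerConfig,
        priors: PriorConfig,
        acceptance: list[dict],
    ) -> None:
        self.chains = chains
        self.spec = spec
        self.countries = list(countries)
        self.config = config
        self.priors = priors
        self.acceptance = acceptance

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_retained_per_chain(self) -> int:
        return len(self.chains[0]["deviance"]) if self.chains else 0

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled over chains."""
        return np.concatenate([c[name] for c in self.chains], axis=0)

    # -- plug-in state -----------------------------------------------------

    def posterior_mean_state(self) -> ParameterState:
        """Componentwise posterior mean of every sampled quantity,
        random effects included — the plug-in state for D(θ̄) and for
        prediction curves."""
        k = self.spec.n_changepoints
        mean = lambda name: self.pooled(name).mean(axis=0)  # noqa: E731
        fixed = FixedEffects(
            beta0=float(mean("beta0")),
            beta1=float(mean("beta1")),
            beta_cp=np.atleast_1d(mean("beta_cp")) if k else np.zeros(0),
            beta0s=float(mean("beta0s")),
            beta1s=float(mean("beta1s")),
            delta=float(mean("delta")),
        )
        cps = ChangePoints(np.atleast_1d(mean("cps")) if k else np.zeros(0))
        n = len(self.countries)
        random = RandomEffects(
            countries=self.countries,
            b0=mean("b0") if n else np.zeros(0),
            b1=mean("b1") if n else np.zeros(0),
            b_cp=mean("b_cp") if n else np.zeros((0, k)),
            b0s=mean("b0s") if n else np.zeros(0),
        )
        variances = VarianceComponents(
            sigma2_b0=float(mean("sigma2_b0")),
            sigma2_b1=float(mean("sigma2_b1")),
            sigma2_bcp=np.atleast_1d(mean("sigma2_bcp")) if k else np.zeros(0),
            sigma2_b0s=float(mean("sigma2_b0s")),
            sigma2_eps=float(mean("sigma2_eps")),
        )
        return ParameterState(fixed=fixed, cps=cps, random=random, variances=variances)

    # -- monitored scalars -------------------------------------------------

    def scalar_names(self) -> list[str]:
        """Display names of the monitored scalars (fixed effects,
        change-points, variance components), Table-style: the slope
        difference after change-point k is beta{k+1}."""
        k = self.spec.n_changepoints
        names = ["beta0", "beta1"]
        names += [f"beta{j + 2}" for j in range(k)]
        names += [f"C{j + 1}" for j in range(k)]
        names += ["beta0S", "beta1S", "delta"]
        names += ["sigma2_b0", "sigma2_b1"]
        names += [f"sigma2_b{j + 2}" for j in range(k)]
        names += ["sigma2_b0S", "sigma2_eps"]
        return names

    def scalar_series(self, name: str) -> np.ndarray:
        """(n_chains, n_draws) array for one monitored scalar name."""
        key, col = _scalar_key(name)
        if col is None:
            return np.stack([c[key] for c in self.chains])
        return np.stack([c[key][:, col] for c in self.chains])

    # -- persistence -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per retained draw, one column per scalar
        (chain and draw index first)."""
        rows = []
        for ch, c in enumerate(self.chains):
            n = len(c["deviance"])
            block = {"chain": np.full(n, ch), "draw": np.arange(n)}
            for name in self.scalar_names():
                key, col = _scalar_key(name)
                block[name] = c[key] if col is None else c[key][:, col]
            for i, cc in enumerate(self.countries):
                block[f"b0[{cc}]"] = c["b0"][:, i]
                block[f"b1[{cc}]"] = c["b1"][:, i]
                for j in range(self.spec.n_changepoints):
                    block[f"b{j + 2}[{cc}]"] = c["b_cp"][:, i, j]
                block[f"b0S[{cc}]"] = c["b0s"][:, i]
            block["deviance"] = c["deviance"]
            rows.append(pd.DataFrame(block))
        return pd.concat(rows, ignore_index=True)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "draws.csv", index=False)
        meta = {
            "n_changepoints": self.spec.n_changepoints,
            "period": self.spec.period,
            "countries": self.countries,
            "acceptance": self.acceptance,
            "config": {
                k: v for k, v in asdict(self.config).items() if k != "fixed_params"
            },
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        df = pd.read_csv(directory / "draws.csv")
        spec = ModelSpec(meta["n_changepoints"], meta["period"])
        countries = meta["countries"]
        k, n_c = spec.n_changepoints, len(countries)
        chains = []
        for ch in sorted(df["chain"].unique()):
            sub = df[df["chain"] == ch]
            get = lambda col: sub[col].to_numpy()  # noqa: E731
            c = {
                "beta0": get("beta0"),
                "beta1": get("beta1"),
                "beta_cp": np.column_stack([get(f"beta{j + 2}") for j in range(k)])
                if k
                else np.zeros((len(sub), 0)),
                "cps": np.column_stack([get(f"C{j + 1}") for j in range(k)])
                if k
                else np.zeros((len(sub), 0)),
                "beta0s": get("beta0S"),
                "beta1s": get("beta1S"),
                "delta": get("delta"),
                "sigma2_b0": get("sigma2_b0"),
                "sigma2_b1": get("sigma2_b1"),
                "sigma2_bcp": np.column_stack([get(f"sigma2_b{j + 2}") for j in range(k)])
                if k
                else np.zeros((len(sub), 0)),
                "sigma2_b0s": get("sigma2_b0S"),
                "sigma2_eps": get("sigma2_eps"),
                "b0": np.column_stack([get(f"b0[{cc}]") for cc in countries])
                if n_c
                else np.zeros((len(sub), 0)),
                "b1": np.column_stack([get(f"b1[{cc}]") for cc in countries])
                if n_c
                else np.zeros((len(sub), 0)),
                "b_cp": np.stack(
                    [
                        np.column_stack([get(f"b{j + 2}[{cc}]") for j in range(k)])
                        for cc in countries
                    ],
                    axis=1,
                )
                if (n_c and k)
                else np.zeros((len(sub), n_c, k)),
                "b0s": np.column_stack([get(f"b0S[{cc}]") for cc in countries])
                if n_c
                else np.zeros((len(sub), 0)),
                "deviance": get("deviance"),
            }
            chains.append(c)
        cfg = SamplerConfig(**meta["config"])
        return cls(chains, spec, countries, cfg, PriorConfig().resolved(None), meta["acceptance"])


def _scalar_key(name: str) -> tuple[str, int | None]:
    """Map a display name (beta2, C1, sigma2_b3, ...) to (chain-dict key,
    column index or None)."""
    plain = {
        "beta0": "beta0",
        "beta1": "beta1",
        "beta0S": "beta0s",
        "beta1S": "beta1s",
        "delta": "delta",
        "sigma2_b0": "sigma2_b0",
        "sigma2_b1": "sigma2_b1",
        "sigma2_b0S": "sigma2_b0s",
        "sigma2_eps": "sigma2_eps",
    }
    if name in plain:
        return plain[name], None
    if name.startswith("C"):
        return "cps", int(name[1:]) - 1
    if name.startswith("sigma2_b"):
        return "sigma2_bcp", int(name[len("sigma2_b") :]) - 2
    if name.startswith("beta"):
        return "beta_cp", int(name[4:]) - 2
    raise KeyError(name)


# ---------------------------------------------------------------------------
# sampler internals


class _ChainState:
    """Mutable single-chain state with cached mean decomposition
    mu = trend + amp * sin(omega t + delta)."""

    def __init__(self, y, t, ci, n_countries, spec, pcfg, cfg, rng):
        self.y, self.t, self.ci = y, t, ci
        self.n = len(y)
        self.N = n_countries
        self.k = spec.n_changepoints
        self.omega = spec.omega
        self.pcfg = pcfg
        self.clamp = cfg.fixed_params
        self.rng = rng

        k, N = self.k, self.N
        self.p = k + 4  # [beta0, beta1, beta_cp.., beta0s, beta1s]
        self.q = k + 3  # [b0, b1, b_cp.., b0s]
        self.beta = np.zeros(self.p)
        self.B = np.zeros((N, self.q))
        self.delta = 0.0
        self.s2b = np.ones(self.q)
        self.s2e = 1.0

        lo, up = pcfg.cp_lower, pcfg.cp_upper
        self.cps = lo + (np.arange(1, k + 1) / (k + 1)) * (up - lo)

        self.unique_t = np.unique(t)
        # per-country row indices
        self.rows = [np.flatnonzero(ci == i) for i in range(N)]

        self._apply_clamps()
        self._jitter(rng)
        self._rebuild_design()

    # -- clamping ----------------------------------------------------------

    def _apply_clamps(self):
        c = self.clamp
        k = self.k
        idx = {"beta0": 0, "beta1": 1, "beta0s": k + 2, "beta1s": k + 3}
        self.free_beta = np.ones(self.p, dtype=bool)
        for name, j in idx.items():
            if name in c:
                self.beta[j] = float(c[name])
                self.free_beta[j] = False
        if "beta_cp" in c:
            self.beta[2 : 2 + k] = np.broadcast_to(np.asarray(c["beta_cp"], float), (k,))
            self.free_beta[2 : 2 + k] = False
        if "cps" in c:
            self.cps = np.sort(np.atleast_1d(np.asarray(c["cps"], float)))
        if "random_effects" in c:
            self.B[:] = float(c["random_effects"])
        self.s2_free = {
            "sigma2_b0": "sigma2_b0" not in c,
            "sigma2_b1": "sigma2_b1" not in c,
            "sigma2_bcp": "sigma2_bcp" not in c,
            "sigma2_b0s": "sigma2_b0s" not in c,
            "sigma2_eps": "sigma2_eps" not in c,
        }
        for name, j in (("sigma2_b0", 0), ("sigma2_b1", 1), ("sigma2_b0s", self.q - 1)):
            if name in c:
                self.s2b[j] = float(c[name])
        if "sigma2_bcp" in c:
            self.s2b[2 : 2 + k] = np.broadcast_to(np.asarray(c["sigma2_bcp"], float), (k,))
        if "sigma2_eps" in c:
            self.s2e = float(c["sigma2_eps"])
        if "delta" in c:
            self.delta = float(c["delta"])

    def _jitter(self, rng):
        """Seed-controlled starting-value jitter so chains differ."""
        self.beta[self.free_beta] += rng.normal(0.0, 0.01, int(self.free_beta.sum()))
        if "delta" not in self.clamp:
            self.delta += rng.normal(0.0, 0.01)
        if self.k and "cps" not in self.clamp:
            lo, up = self.pcfg.cp_lower, self.pcfg.cp_upper
            prop = np.sort(self.cps + rng.uniform(-0.5, 0.5, self.k))
            if lo < prop[0] and prop[-1] < up and np.all(np.diff(prop) > 0):
                self.cps = prop

    # -- cached design -----------------------------------------------------

    def _rebuild_design(self):
        t = self.t
        self.H = np.maximum(t[:, None] - self.cps[None, :], 0.0) if self.k else np.zeros((self.n, 0))
        self.s = np.sin(self.omega * t + self.delta)
        self._refresh_mean()

    def _refresh_mean(self):
        t, ci, B = self.t, self.ci, self.B
        k = self.k
        if self.n == 0:
            self.trend = np.zeros(0)
            self.amp = np.zeros(0)
            return
        b0 = B[ci, 0]
        b1 = B[ci, 1]
        b0s = B[ci, self.q - 1]
        self.trend = (self.beta[0] + b0) + (self.beta[1] + b1) * t
        if k:
            coef = self.beta[2 : 2 + k][None, :] + B[ci, 2 : 2 + k]
            self.trend = self.trend + (self.H * coef).sum(axis=1)
        self.amp = self.beta[k + 2] + b0s + self.beta[k + 3] * t

    @property
    def mu(self):
        return self.trend + self.amp * self.s

    def loglik(self, mu=None):
        if self.n == 0:
            return 0.0
        r = self.y - (self.mu if mu is None else mu)
        return -0.5 * (self.n * (_LOG_2PI + math.log(self.s2e)) + float(r @ r) / self.s2e)

    def design_X(self):
        t, s = self.t, self.s
        return np.column_stack([np.ones(self.n), t, self.H, s, t * s])

    def design_Z(self):
        return np.column_stack([np.ones(self.n), self.t, self.H, self.s])

    # -- Gibbs updates -----------------------------------------------------

    def update_beta(self):
        """Fixed-effect block draw.

        When random effects are sampled, they are integrated out of this
        draw (partially collapsed Gibbs via Woodbury on the per-country
        marginal covariance); the subsequent random-effect update then
        conditions on the new betas, so the pair is one exact blocked
        draw from p(beta, b | rest).  Collapsing removes the near-flat
        direction beta0 + mean(b0) that cripples the plain alternating
        scheme.  With clamped (or absent) random effects the plain
        conditional draw is used.
        """
        free = self.free_beta
        if not free.any():
            return
        pc = self.pcfg
        nf = int(free.sum())
        A = np.eye(nf) / pc.coef_variance
        bvec = np.full(nf, pc.coef_mean / pc.coef_variance)
        collapse = self.N > 0 and "random_effects" not in self.clamp and self.n > 0
        if self.n:
            X = self.design_X()
            Z = self.design_Z()
            Xf = X[:, free]
            r = self.y - X[:, ~free] @ self.beta[~free]
            if collapse:
                d_inv = np.diag(1.0 / self.s2b)
                for i in range(self.N):
                    idx = self.rows[i]
                    Zi, Xi, ri = Z[idx], Xf[idx], r[idx]
                    ZtZ = Zi.T @ Zi
                    M = np.linalg.inv(d_inv + ZtZ / self.s2e)
                    XtZ = Xi.T @ Zi / self.s2e
                    A += Xi.T @ Xi / self.s2e - XtZ @ M @ XtZ.T
                    bvec += Xi.T @ ri / self.s2e - XtZ @ M @ (Zi.T @ ri / self.s2e)
            else:
                zb = (Z * self.B[self.ci]).sum(axis=1)
                A += Xf.T @ Xf / self.s2e
                bvec += Xf.T @ (r - zb) / self.s2e
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, bvec))
        draw = mean + np.linalg.solve(L.T, self.rng.standard_normal(nf))
        self.beta[free] = draw
        self._refresh_mean()

    def update_random_effects(self):
        if self.N == 0 or "random_effects" in self.clamp:
            return
        Z = self.design_Z()
        X = self.design_X()
        fixed_mu = X @ self.beta
        prior_prec = 1.0 / self.s2b
        for i in range(self.N):
            idx = self.rows[i]
            Zi = Z[idx]
            ri = self.y[idx] - fixed_mu[idx]
            A = np.diag(prior_prec) + Zi.T @ Zi / self.s2e
            bvec = Zi.T @ ri / self.s2e
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, bvec))
            self.B[i] = mean + np.linalg.solve(L.T, self.rng.standard_normal(self.q))
        self._refresh_mean()

    def update_variances(self):
        a, b = self.pcfg.igamma_shape, self.pcfg.igamma_rate
        N = self.N
        names = ["sigma2_b0", "sigma2_b1"] + ["sigma2_bcp"] * self.k + ["sigma2_b0s"]
        cols = [0, 1] + list(range(2, 2 + self.k)) + [self.q - 1]
        for name, j in zip(names, cols):
            if not self.s2_free[name]:
                continue
            ss = float(self.B[:, j] @ self.B[:, j]) if N else 0.0
            self.s2b[j] = _sample_igamma(self.rng, a + N / 2.0, b + ss / 2.0)
        if self.s2_free["sigma2_eps"]:
            if self.n:
                r = self.y - self.mu
                ss = float(r @ r)
            else:
                ss = 0.0
            self.s2e = _sample_igamma(self.rng, a + self.n / 2.0, b + ss / 2.0)

    # -- Metropolis updates ------------------------------------------------

    def update_delta(self, scale) -> bool:
        if "delta" in self.clamp:
            return False
        pc = self.pcfg
        prop = self.delta + scale * self.rng.standard_normal()
        s_prop = np.sin(self.omega * self.t + prop)
        ll_cur = self.loglik()
        ll_prop = self.loglik(self.trend + self.amp * s_prop)
        dprior = ((self.delta - pc.coef_mean) ** 2 - (prop - pc.coef_mean) ** 2) / (
            2.0 * pc.coef_variance
        )
        if math.log(self.rng.uniform()) < ll_prop - ll_cur + dprior:
            self.delta = prop
            self.s = s_prop
            return True
        return False

    def _cp_guard_ok(self, c: float) -> bool:
        """Require >= 2 distinct observed time points strictly on each
        side of a proposed change-point (no data -> no guard)."""
        u = self.unique_t
        if len(u) == 0:
            return True
        below = np.searchsorted(u, c, side="left")
        above = len(u) - np.searchsorted(u, c, side="right")
        return below >= 2 and above >= 2

    def update_cp(self, j: int, scale) -> bool:
        if "cps" in self.clamp:
            return False
        prop = self.cps.copy()
        prop[j] = self.cps[j] + scale * self.rng.standard_normal()
        lp_prop = log_prior_changepoints(prop, self.pcfg)
        if lp_prop == -math.inf or not self._cp_guard_ok(prop[j]):
            return False
        lp_cur = log_prior_changepoints(self.cps, self.pcfg)
        if self.n:
            h_prop = np.maximum(self.t - prop[j], 0.0)
            coef = self.beta[2 + j] + self.B[self.ci, 2 + j]
            trend_prop = self.trend + coef * (h_prop - self.H[:, j])
            ll_cur = self.loglik()
            ll_prop = self.loglik(trend_prop + self.amp * self.s)
        else:
            ll_cur = ll_prop = 0.0
        if math.log(self.rng.uniform()) < ll_prop - ll_cur + lp_prop - lp_cur:
            self.cps = prop
            if self.n:
                self.H[:, j] = h_prop
                self.trend = trend_prop
            return True
        return False


def _check_feasible(spec: ModelSpec, data: PanelDataset, pcfg: PriorConfig) -> None:
    k = spec.n_changepoints
    if k == 0:
        return
    if pcfg.cp_upper - pcfg.cp_lower <= 0:
        raise ValueError("change-point support is empty")
    if len(data):
        u = np.unique(data.frame["time"].to_numpy())
        if len(u) < 2 * (k + 1):
            raise ValueError(
                f"{k} change-points need at least {2 * (k + 1)} distinct observed "
                f"time points ({len(u)} available); try fewer change-points"
            )


def run_mcmc(
    data: PanelDataset,
    spec: ModelSpec,
    priors: PriorConfig | None = None,
    cfg: SamplerConfig | None = None,
) -> PosteriorDraws:
    """Draw from the posterior of the K-change-point model.

    Chains run sequentially; chain c uses an independent stream spawned
    from ``cfg.seed``, so results are bit-reproducible for a fixed seed
    and configuration.  An empty panel is allowed and yields draws from
    the prior (the likelihood is identically one), which is how the
    sampler's prior-recovery validation operates.
    """
    priors = (priors or PriorConfig()).resolved(data.t_max)
    cfg = cfg or SamplerConfig()
    _check_feasible(spec, data, priors)

    countries = data.countries
    n_countries = len(countries)
    idx = data.country_index
    ci = data.frame["country"].map(idx).to_numpy(dtype=int) if len(data) else np.zeros(0, int)
    t = data.frame["time"].to_numpy(dtype=float) if len(data) else np.zeros(0)
    y = data.frame["value"].to_numpy(dtype=float) if len(data) else np.zeros(0)

    k = spec.n_changepoints
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains, acceptance = [], []
    for ch in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[ch])
        st = _ChainState(y, t, ci, n_countries, spec, priors, cfg, rng)
        if not math.isfinite(st.loglik()):
            raise RuntimeError("non-finite likelihood at initialization")

        n_ret = cfg.n_retained
        rec = {
            "beta0": np.empty(n_ret),
            "beta1": np.empty(n_ret),
            "beta_cp": np.empty((n_ret, k)),
            "cps": np.empty((n_ret, k)),
            "beta0s": np.empty(n_ret),
            "beta1s": np.empty(n_ret),
            "delta": np.empty(n_ret),
            "sigma2_b0": np.empty(n_ret),
            "sigma2_b1": np.empty(n_ret),
            "sigma2_bcp": np.empty((n_ret, k)),
            "sigma2_b0s": np.empty(n_ret),
            "sigma2_eps": np.empty(n_ret),
            "b0": np.empty((n_ret, n_countries)),
            "b1": np.empty((n_ret, n_countries)),
            "b_cp": np.empty((n_ret, n_countries, k)),
            "b0s": np.empty((n_ret, n_countries)),
            "deviance": np.empty(n_ret),
        }

        scale_delta = cfg.proposal_scale_delta
        scale_cp = np.full(k, cfg.proposal_scale_cp, dtype=float)
        acc = {"delta": 0, "cps": np.zeros(k)}
        tries = 0
        batch = {"delta": 0, "cps": np.zeros(k), "n": 0, "id": 0}
        r_i = 0
        for it in range(1, cfg.n_iterations + 1):
            st.update_beta()
            st.update_random_effects()
            st.update_variances()
            if st.update_delta(scale_delta):
                batch["delta"] += 1
            for j in range(k):
                if st.update_cp(j, scale_cp[j]):
                    batch["cps"][j] += 1
            batch["n"] += 1

            in_burnin = it <= cfg.n_burnin
            if in_burnin and cfg.adapt_during_burnin and batch["n"] == 50:
                batch["id"] += 1
                step = min(0.5, 5.0 / math.sqrt(batch["id"]))
                scale_delta *= math.exp(step * (batch["delta"] / 50.0 - 0.3))
                for j in range(k):
                    scale_cp[j] *= math.exp(step * (batch["cps"][j] / 50.0 - 0.3))
                batch["delta"], batch["cps"][:], batch["n"] = 0, 0.0, 0
            if not in_burnin:
                acc["delta"] += batch["delta"]
                acc["cps"] += batch["cps"]
                tries += batch["n"]
                batch["delta"], batch["cps"][:], batch["n"] = 0, 0.0, 0
                post = it - cfg.n_burnin
                if post % cfg.thin == 0 and r_i < n_ret:
                    rec["beta0"][r_i] = st.beta[0]
                    rec["beta1"][r_i] = st.beta[1]
                    rec["beta_cp"][r_i] = st.beta[2 : 2 + k]
                    rec["cps"][r_i] = st.cps
                    rec["beta0s"][r_i] = st.beta[k + 2]
                    rec["beta1s"][r_i] = st.beta[k + 3]
                    rec["delta"][r_i] = st.delta
                    rec["sigma2_b0"][r_i] = st.s2b[0]
                    rec["sigma2_b1"][r_i] = st.s2b[1]
                    rec["sigma2_bcp"][r_i] = st.s2b[2 : 2 + k]
                    rec["sigma2_b0s"][r_i] = st.s2b[st.q - 1]
                    rec["sigma2_eps"][r_i] = st.s2e
                    rec["b0"][r_i] = st.B[:, 0]
                    rec["b1"][r_i] = st.B[:, 1]
                    rec["b_cp"][r_i] = st.B[:, 2 : 2 + k]
                    rec["b0s"][r_i] = st.B[:, st.q - 1]
                    rec["deviance"][r_i] = -2.0 * st.loglik()
                    r_i += 1
        chains.append(rec)
        acceptance.append(
            {
                "delta": acc["delta"] / tries if tries else float("nan"),
                "cps": (acc["cps"] / tries).tolist() if tries else [],
                "scale_delta": scale_delta,
                "scale_cp": scale_cp.tolist(),
            }
        )
    return PosteriorDraws(chains, spec, countries, cfg, priors, acceptance)


def assess_convergence(
    draws: PosteriorDraws, threshold: float | None = None
) -> ConvergenceReport:
    """Split r-hat and bulk effective sample size for all fixed effects,
    change-points and variance components (via arviz).

    Parameters clamped to a constant (zero variance in every chain) are
    excluded.  ``converged`` requires every remaining r-hat to be finite
    and at most the threshold.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("convergence assessment needs at least 2 chains")
    threshold = threshold if threshold is not None else draws.config.rhat_threshold
    series = {}
    for name in draws.scalar_names():
        arr = draws.scalar_series(name)
        if np.ptp(arr) == 0.0:  # clamped / degenerate
            continue
        series[name] = arr
    idata = az.from_dict(posterior={k: v for k, v in series.items()})
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in series}
    ess = {k: float(ess_ds[k].values) for k in series}
    vals = np.array(list(rhat.values()), dtype=float)
    converged = bool(len(vals) == 0 or (np.all(np.isfinite(vals)) and np.all(vals <= threshold)))
    return ConvergenceReport(rhat=rhat, ess=ess, converged=converged, threshold=threshold)
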