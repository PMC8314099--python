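"""Prior stack: vague normals on coefficients, ordered uniforms on
change-points, inverse-gamma on variance components.

Coefficients (intercept, slopes, slope differences, amplitude terms and
phase shift) get independent Normal(0, 1000) priors — mean 0, *variance*
1000.  The first change-point is Uniform(1, T_max) over the whole time
range; each subsequent one is Uniform over the range following its
predecessor, which pins down the ordering C_1 < C_2 < ... and prevents
label switching.  Variance components get IGamma(0.001, 0.001) in the
shape–rate convention: x ~ IGamma(a, b) iff 1/x ~ Gamma(a, rate=b).

The phase shift delta shares the vague normal prior; no angular wrapping
is applied, so delta and delta + 2*pi are aliases (accepted, as the
posterior concentrates far inside one period in practice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model_core import ModelSpec, ParameterState, ChangePoints, FixedEffects, RandomEffects, VarianceComponents

__all__ = ["PriorConfig", "log_prior", "sample_prior"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the prior stack.

    ``cp_upper=None`` means "resolve to the largest observed time index"
    (84 for a 1997–2017 quarterly panel); use :meth:`resolved` once the
    data are known.
    """

    coef_mean: float = 0.0
    coef_variance: float = 1000.0
    cp_lower: float = 1.0
    cp_upper: float | None = None
    igamma_shape: float = 0.001
    igamma_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.coef_variance <= 0:
            raise ValueError("coef_variance must be > 0")
        if self.igamma_shape <= 0 or self.igamma_rate <= 0:
            raise ValueError("inverse-gamma hyperparameters must be > 0")
        if self.cp_upper is not None and self.cp_lower >= self.cp_upper:
            raise ValueError("cp_lower must be < cp_upper")

    def resolved(self, t_max: float | None) -> "PriorConfig":
        """Fill in cp_upper from the data's largest time index (fallback 84)."""
        if self.cp_upper is not None:
            return self
        return replace(self, cp_upper=float(t_max) if t_max is not None else 84.0)


def _norm_logpdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (_LOG_2PI + math.log(var) + (x - mean) ** 2 / var)


def _igamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -math.inf
    return shape * math.log(rate) - math.lgamma(shape) - (shape + 1) * math.log(x) - rate / x


def log_prior_changepoints(cps: np.ndarray, cfg: PriorConfig) -> float:
    """Joint log-density of the ordered-uniform change-point prior;
    −inf outside the support."""
    lo, up = cfg.cp_lower, cfg.cp_upper
    out = 0.0
    prev = lo
    for c in np.atleast_1d(cps):
        if not (prev < c < up):
            return -math.inf
        out -= math.log(up - prev)
        prev = c
    return out


def log_prior(state: ParameterState, spec: ModelSpec, cfg: PriorConfig) -> float:
    """Joint log prior density of a full parameter state.

    Returns −inf (never raises) when any change-point violates its
    ordered support or any variance component is non-positive.
    """
    if cfg.cp_upper is None:
        raise ValueError("cp_upper unresolved; call cfg.resolved(t_max) first")
    v = state.variances
    if not v.all_positive():
        return -math.inf
    lp = log_prior_changepoints(state.cps.values, cfg)
    if lp == -math.inf:
        return lp
    f = state.fixed
    for coef in (f.beta0, f.beta1, *f.beta_cp, f.beta0s, f.beta1s, f.delta):
        lp += _norm_logpdf(coef, cfg.coef_mean, cfg.coef_variance)
    r = state.random
    n = len(r.countries)
    if n:
        # z-scored form: arr@arr can overflow when an extreme tail draw of
        # the vague inverse-gamma makes the variances astronomically large
        for arr, s2 in (
            (r.b0, v.sigma2_b0),
            (r.b1, v.sigma2_b1),
            (r.b0s, v.sigma2_b0s),
        ):
            z = arr / math.sqrt(s2)
            lp += -0.5 * (n * (_LOG_2PI + math.log(s2)) + float(z @ z))
        for k in range(spec.n_changepoints):
            z = r.b_cp[:, k] / math.sqrt(v.sigma2_bcp[k])
            lp += -0.5 * (n * (_LOG_2PI + math.log(v.sigma2_bcp[k])) + float(z @ z))
    for s2 in (v.sigma2_b0, v.sigma2_b1, *v.sigma2_bcp, v.sigma2_b0s, v.sigma2_eps):
        lp += _igamma_logpdf(s2, cfg.igamma_shape, cfg.igamma_rate)
    return lp


def _sample_igamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    """Inverse-gamma draw; re-draws on (vanishingly rare) gamma underflow
    to zero so the reciprocal stays finite."""
    g = rng.gamma(shape)
    while g == 0.0 or not math.isfinite(rate / g):
        g = rng.gamma(shape)
    return rate / g


def sample_prior(
    spec: ModelSpec,
    n_countries: int,
    cfg: PriorConfig,
    rng: np.random.Generator,
    countries: list[str] | None = None,
) -> ParameterState:
    """Draw a full parameter state from the prior.

    Variances are drawn first, then random effects given their variances,
    then coefficients and the ordered change-points.  The returned state
    always satisfies every state invariant and has finite log prior.
    """
    if n_countries < 0:
        raise ValueError("n_countries must be >= 0")
    if cfg.cp_upper is None:
        raise ValueError("cp_upper unresolved; call cfg.resolved(t_max) first")
    k = spec.n_changepoints
    a, b = cfg.igamma_shape, cfg.igamma_rate
    variances = VarianceComponents(
        sigma2_b0=_sample_igamma(rng, a, b),
        sigma2_b1=_sample_igamma(rng, a, b),
        sigma2_bcp=np.array([_sample_igamma(rng, a, b) for _ in range(k)]),
        sigma2_b0s=_sample_igamma(rng, a, b),
        sigma2_eps=_sample_igamma(rng, a, b),
    )
    if countries is None:
        countries = [f"C{i + 1:02d}" for i in range(n_countries)]
    n = len(countries)
    random = RandomEffects(
        countries=list(countries),
        b0=rng.normal(0.0, math.sqrt(variances.sigma2_b0), size=n),
        b1=rng.normal(0.0, math.sqrt(variances.sigma2_b1), size=n),
        b_cp=rng.normal(size=(n, k)) * np.sqrt(variances.sigma2_bcp)[None, :]
        if k
        else np.zeros((n, 0)),
        b0s=rng.normal(0.0, math.sqrt(variances.sigma2_b0s), size=n),
    )
    sd = math.sqrt(cfg.coef_variance)
    fixed = FixedEffects(
        beta0=rng.normal(cfg.coef_mean, sd),
        beta1=rng.normal(cfg.coef_mean, sd),
        beta_cp=rng.normal(cfg.coef_mean, sd, size=k),
        beta0s=rng.normal(cfg.coef_mean, sd),
        beta1s=rng.normal(cfg.coef_mean, sd),
        delta=rng.normal(cfg.coef_mean, sd),
    )
    cps = []
    prev = cfg.cp_lower
    for _ in range(k):
        prev = rng.uniform(prev, cfg.cp_upper)
        cps.append(prev)
    return ParameterState(
        fixed=fixed,
        cps=ChangePoints(np.array(cps)),
        random=random,
        variances=variances,
    )
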