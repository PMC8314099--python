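"""Mean function, Gaussian log-likelihood and deviance of the change-point model.

The model for consumption :math:`Y_{ij}` of country *i* at quarter
:math:`t_{ij}` combines a piecewise-linear trend with K common
change-points and a sine wave with linearly time-varying amplitude:

.. math::

   Y_{ij} = (\\beta_0 + b_{0i}) + (\\beta_1 + b_{1i}) t_{ij}
          + \\sum_{k=1}^{K} (\\beta_{k+1} + b_{(k+1)i}) (t_{ij} - C_k)_+
          + (\\beta_0^S + b_{0i}^S + \\beta_1^S t_{ij})
            \\sin(\\omega t_{ij} + \\delta) + \\varepsilon_{ij}

with :math:`x_+ = \\max(x, 0)`, fixed frequency :math:`\\omega = 2\\pi/T`
(T = 4 quarters per year), independent mean-zero Gaussian random effects
per country, and i.i.d. Gaussian errors with variance
:math:`\\sigma^2_\\varepsilon`.  With K = 0 the trend is a single line;
the hinge basis keeps the mean continuous at every change-point.

Everything here is pure computation, conditional on the random effects;
the likelihood skips absent (country, quarter) cells, so unbalanced
panels need no special handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import PanelDataset

__all__ = [
    "ModelSpec",
    "FixedEffects",
    "ChangePoints",
    "RandomEffects",
    "VarianceComponents",
    "ParameterState",
    "hinge",
    "mean_value",
    "log_likelihood",
    "deviance",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Number of common change-points K and the fixed seasonal frequency."""

    n_changepoints: int = 0
    period: int = 4

    def __post_init__(self) -> None:
        if self.n_changepoints < 0:
            raise ValueError("n_changepoints must be >= 0")
        if self.period < 2:
            raise ValueError("period must be >= 2 quarters")

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi/period of the seasonal sine wave."""
        return 2.0 * math.pi / self.period


@dataclass
class FixedEffects:
    """Population-level coefficients.

    ``beta0``/``beta1``: intercept and linear slope per quarter;
    ``beta_cp[k]``: slope difference after versus before change-point k;
    ``beta0s``/``beta1s``: seasonal amplitude at t=0 and its change per
    quarter; ``delta``: phase shift of the sine wave (radians).
    """

    beta0: float = 0.0
    beta1: float = 0.0
    beta_cp: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta0s: float = 0.0
    beta1s: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        self.beta_cp = np.atleast_1d(np.asarray(self.beta_cp, dtype=float))


@dataclass
class ChangePoints:
    """Ordered common change-point locations on the time-index scale."""

    values: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.size and np.any(np.diff(self.values) <= 0):
            raise ValueError(f"change-points must be strictly increasing, got {self.values}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class RandomEffects:
    """Per-country deviations; row order follows ``countries``.

    ``b0``: intercept deviations (N,); ``b1``: slope deviations (N,);
    ``b_cp``: slope-difference deviations (N, K); ``b0s``: amplitude
    deviations (N,).
    """

    countries: list[str]
    b0: np.ndarray
    b1: np.ndarray
    b_cp: np.ndarray
    b0s: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.countries)
        self.b0 = np.asarray(self.b0, dtype=float).reshape(n)
        self.b1 = np.asarray(self.b1, dtype=float).reshape(n)
        self.b0s = np.asarray(self.b0s, dtype=float).reshape(n)
        self.b_cp = np.asarray(self.b_cp, dtype=float).reshape(n, -1) if n else np.zeros((0, 0))

    @classmethod
    def zeros(cls, countries: list[str], n_changepoints: int) -> "RandomEffects":
        n = len(countries)
        return cls(
            countries=list(countries),
            b0=np.zeros(n),
            b1=np.zeros(n),
            b_cp=np.zeros((n, n_changepoints)),
            b0s=np.zeros(n),
        )

    def index_of(self, country: str) -> int:
        try:
            return self.countries.index(country)
        except ValueError:
            raise KeyError(f"unknown country {country!r}") from None


@dataclass
class VarianceComponents:
    """Independent variance components (diagonal random-effect covariance)."""

    sigma2_b0: float = 1.0
    sigma2_b1: float = 1.0
    sigma2_bcp: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma2_b0s: float = 1.0
    sigma2_eps: float = 1.0

    def __post_init__(self) -> None:
        self.sigma2_bcp = np.atleast_1d(np.asarray(self.sigma2_bcp, dtype=float))

    def all_positive(self) -> bool:
        scalars = (self.sigma2_b0, self.sigma2_b1, self.sigma2_b0s, self.sigma2_eps)
        return all(v > 0 for v in scalars) and bool(np.all(self.sigma2_bcp > 0))


@dataclass
class ParameterState:
    """One full point in parameter space (fixed + random effects,
    change-points, variances)."""

    fixed: FixedEffects
    cps: ChangePoints
    random: RandomEffects
    variances: VarianceComponents

    def __post_init__(self) -> None:
        k = len(self.cps)
        if self.fixed.beta_cp.size != k:
            raise ValueError(
                f"beta_cp has length {self.fixed.beta_cp.size}, expected {k}"
            )
        if self.random.b_cp.shape[0] and self.random.b_cp.shape[1] != k:
            raise ValueError(
                f"b_cp has {self.random.b_cp.shape[1]} columns, expected {k}"
            )
        if self.variances.sigma2_bcp.size != k:
            raise ValueError(
                f"sigma2_bcp has length {self.variances.sigma2_bcp.size}, expected {k}"
            )

    @property
    def n_changepoints(self) -> int:
        return len(self.cps)


def hinge(x):
    """Positive part max(x, 0); accepts scalars or arrays."""
    return np.maximum(x, 0.0)


def _mean_array(
    spec: ModelSpec,
    state: ParameterState,
    t: np.ndarray,
    country_codes: np.ndarray,
) -> np.ndarray:
    """Vectorised mean over records; ``country_codes`` are 0-based rows
    into the random-effect arrays."""
    f, r = state.fixed, state.random
    t = np.asarray(t, dtype=float)
    ci = np.asarray(country_codes, dtype=int)
    mu = (f.beta0 + r.b0[ci]) + (f.beta1 + r.b1[ci]) * t
    if len(state.cps):
        h = hinge(t[:, None] - state.cps.values[None, :])  # (n, K)
        mu = mu + (h * (f.beta_cp[None, :] + r.b_cp[ci, :])).sum(axis=1)
    amp = f.beta0s + r.b0s[ci] + f.beta1s * t
    mu = mu + amp * np.sin(spec.omega * t + f.delta)
    return mu


def mean_value(spec: ModelSpec, state: ParameterState, country: str, t: float) -> float:
    """Model mean for one country at (possibly fractional) time index t."""
    i = state.random.index_of(country)
    return float(_mean_array(spec, state, np.array([t]), np.array([i]))[0])


def log_likelihood(data: PanelDataset, spec: ModelSpec, state: ParameterState) -> float:
    """Gaussian log-likelihood of the panel, conditional on the random
    effects.  Missing cells contribute nothing; an empty panel gives 0."""
    s2 = state.variances.sigma2_eps
    if not s2 > 0:
        raise ValueError(f"sigma2_eps must be > 0, got {s2}")
    if not len(data):
        return 0.0
    # index random effects by the state's own country order, which need
    # not coincide with the dataset's sorted order
    idx = {c: i for i, c in enumerate(state.random.countries)}
    codes = data.frame["country"].map(idx)
    if codes.isna().any():
        missing = data.frame.loc[codes.isna(), "country"].iloc[0]
        raise KeyError(f"country {missing!r} has no random effects in the state")
    ci = codes.to_numpy(dtype=int)
    t = data.frame["time"].to_numpy(dtype=float)
    y = data.frame["value"].to_numpy(dtype=float)
    mu = _mean_array(spec, state, t, ci)
    resid = y - mu
    n = len(y)
    return float(-0.5 * (n * (_LOG_2PI + math.log(s2)) + resid @ resid / s2))


def deviance(data: PanelDataset, spec: ModelSpec, state: ParameterState) -> float:
    """Deviance −2·log-likelihood (conditional on random effects)."""
    return -2.0 * log_likelihood(data, spec, state)
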