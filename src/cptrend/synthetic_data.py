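"""Synthetic unbalanced quarterly consumption panels.

Generates panels with the exact generative structure of the fitted model:
per-country Gaussian random effects around population-level intercept,
slope, slope differences at common change-points and seasonal amplitude;
a winter-peak/summer-trough sine wave whose amplitude drifts linearly;
and i.i.d. Gaussian noise.  Default parameter values sit in the magnitude
regime of community antibiotic consumption in EU/EEA countries over
1997–2017 (levels near 18 DDD per 1000 inhabitants per day, amplitude
near 4, residual variance near 1.6, two change-points at quarters 29 and
49 with slope changes of ±0.05 per quarter).

Realistic missingness motifs are layered on top, mirroring how
surveillance networks accumulate data: *late entry* (a country joins the
network some years after the study start), *intermittent gaps* (missed
quarterly calls for data) and *right truncation* (most recent years not
yet submitted).  Missingness is completely at random given the country's
pattern class, which the model's likelihood tolerates by simply skipping
absent cells.

The Gaussian model can produce negative values when the mean is small;
they are kept by default so that parameter-recovery experiments stay
unbiased (the fitted model is Gaussian too).  ``clip_negative`` exists
for display purposes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import PanelDataset, DEFAULT_ORIGIN, CalendarQuarter
from .model_core import (
    ChangePoints,
    FixedEffects,
    ModelSpec,
    ParameterState,
    RandomEffects,
    VarianceComponents,
    _mean_array,
)

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_panel"]


@dataclass
class SimulationConfig:
    """Generating values and missingness pattern for a synthetic panel.

    Defaults emulate a 25-country, 84-quarter (21-year) surveillance
    panel with two common change-points (quarters 29 and 49) and the
    fixed-effect/variance magnitudes typical of community antibiotic
    consumption data.
    """

    n_countries: int = 25
    t_max: int = 84
    # population-level truth
    beta0: float = 18.046
    beta1: float = -0.017
    beta_cp: tuple = (0.054, -0.051)
    cps: tuple = (29.0, 49.0)
    beta0s: float = 3.808
    beta1s: float = -0.012
    delta: float = 0.399
    # variance components
    sigma2_b0: float = 40.711
    sigma2_b1: float = 0.007
    sigma2_bcp: tuple = (0.029, 0.042)
    sigma2_b0s: float = 2.572
    sigma2_eps: float = 1.646
    period: int = 4
    # missingness motifs
    late_entry_fraction: float = 0.4
    late_entry_max_delay: int = 40
    intermittent_missing_rate: float = 0.05
    right_truncation_fraction: float = 0.2
    right_truncation_max: int = 12
    seed: int = 0
    clip_negative: bool = False
    origin: CalendarQuarter = field(default=DEFAULT_ORIGIN)

    def __post_init__(self) -> None:
        if self.t_max < 8:
            raise ValueError("t_max must be >= 8")
        for name in ("late_entry_fraction", "intermittent_missing_rate", "right_truncation_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if len(self.beta_cp) != len(self.cps) or len(self.sigma2_bcp) != len(self.cps):
            raise ValueError("beta_cp, cps and sigma2_bcp must have equal length")

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(n_changepoints=len(self.cps), period=self.period)


@dataclass
class SimulationTruth:
    """Complete ground truth behind a simulated panel: the generating
    state (random effects included) and the model spec."""

    state: ParameterState
    spec: ModelSpec


def _truth_state(cfg: SimulationConfig, rng: np.random.Generator) -> ParameterState:
    k = len(cfg.cps)
    n = cfg.n_countries
    countries = [f"C{i + 1:02d}" for i in range(n)]
    s2bcp = np.asarray(cfg.sigma2_bcp, dtype=float)
    random = RandomEffects(
        countries=countries,
        b0=rng.normal(0.0, np.sqrt(cfg.sigma2_b0), size=n),
        b1=rng.normal(0.0, np.sqrt(cfg.sigma2_b1), size=n),
        b_cp=rng.normal(size=(n, k)) * np.sqrt(s2bcp)[None, :] if k else np.zeros((n, 0)),
        b0s=rng.normal(0.0, np.sqrt(cfg.sigma2_b0s), size=n),
    )
    return ParameterState(
        fixed=FixedEffects(
            beta0=cfg.beta0,
            beta1=cfg.beta1,
            beta_cp=np.asarray(cfg.beta_cp, dtype=float),
            beta0s=cfg.beta0s,
            beta1s=cfg.beta1s,
            delta=cfg.delta,
        ),
        cps=ChangePoints(np.asarray(cfg.cps, dtype=float)),
        random=random,
        variances=VarianceComponents(
            sigma2_b0=cfg.sigma2_b0,
            sigma2_b1=cfg.sigma2_b1,
            sigma2_bcp=s2bcp,
            sigma2_b0s=cfg.sigma2_b0s,
            sigma2_eps=cfg.sigma2_eps,
        ),
    )


def simulate_panel(cfg: SimulationConfig) -> tuple[PanelDataset, SimulationTruth]:
    """Simulate an unbalanced panel and return it with its ground truth.

    Per country: the full 1..t_max series is built as model mean +
    Gaussian noise; then a late-entry country loses an initial block of
    uniform random length (1..late_entry_max_delay), each remaining cell
    is dropped independently with ``intermittent_missing_rate``, and a
    right-truncated country loses a terminal block (1..right_truncation_max
    quarters).  Same seed, same panel.
    """
    rng = np.random.default_rng(cfg.seed)
    spec = cfg.spec
    state = _truth_state(cfg, rng)
    n, T = cfg.n_countries, cfg.t_max
    t_grid = np.arange(1, T + 1, dtype=float)

    frames = []
    for i, country in enumerate(state.random.countries):
        mu = _mean_array(spec, state, t_grid, np.full(T, i))
        noise = (
            rng.normal(0.0, np.sqrt(cfg.sigma2_eps), size=T)
            if cfg.sigma2_eps > 0
            else np.zeros(T)
        )
        y = mu + noise
        keep = np.ones(T, dtype=bool)
        if rng.uniform() < cfg.late_entry_fraction and cfg.late_entry_max_delay >= 1:
            delay = rng.integers(1, cfg.late_entry_max_delay + 1)
            keep[:delay] = False
        if cfg.intermittent_missing_rate > 0:
            keep &= rng.uniform(size=T) >= cfg.intermittent_missing_rate
        if rng.uniform() < cfg.right_truncation_fraction and cfg.right_truncation_max >= 1:
            cut = rng.integers(1, cfg.right_truncation_max + 1)
            keep[T - cut :] = False
        if cfg.clip_negative:
            y = np.maximum(y, 0.0)
        frames.append(
            pd.DataFrame(
                {"country": country, "time": t_grid[keep].astype(int), "value": y[keep]}
            )
        )
    frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["country", "time", "value"])
    )
    data = PanelDataset(frame, origin=cfg.origin, allow_negative=not cfg.clip_negative)
    return data, SimulationTruth(state=state, spec=spec)
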