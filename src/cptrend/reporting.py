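"""Posterior summary tables and prediction curves.

``summarize_posterior`` produces the familiar results-table layout:
posterior mean and posterior standard deviation (reported as the
"standard error") for every fixed effect, change-point and variance
component of the fitted model, with each change-point mean additionally
translated to its calendar quarter.  Prediction curves evaluate the mean
function at the posterior-mean state: the population curve zeroes the
random effects; a country curve adds that country's posterior-mean
random effects.  ``seasonal=False`` drops the sine term entirely,
giving the de-seasonalised trend (which by default keeps the hinge
terms, so it tracks the trend through the change-points).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .data_model import CalendarQuarter, DEFAULT_ORIGIN, time_index_to_quarter
from .mcmc import PosteriorDraws
from .model_core import ParameterState, RandomEffects, _mean_array
from .model_selection import DICReport

__all__ = [
    "summarize_posterior",
    "predict_population",
    "predict_country",
]


def summarize_posterior(
    draws: PosteriorDraws,
    dic: DICReport | None = None,
    origin: CalendarQuarter = DEFAULT_ORIGIN,
) -> pd.DataFrame:
    """Posterior means and standard deviations, chains pooled.

    Returns a frame with columns ``parameter``, ``mean``, ``sd`` and
    ``calendar`` (blank except for change-points).  Only the parameters
    of the fitted spec appear — a K=1 fit has no beta3 row.  When a DIC
    report is given, DIC(pD) and DIC(pV) rows are prepended.
    """
    rows = []
    if dic is not None:
        rows.append({"parameter": "DIC(pD)", "mean": dic.dic_pd, "sd": np.nan, "calendar": ""})
        rows.append({"parameter": "DIC(pV)", "mean": dic.dic_pv, "sd": np.nan, "calendar": ""})
    for name in draws.scalar_names():
        pooled = draws.scalar_series(name).ravel()
        mean = float(pooled.mean())
        sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
        cal = ""
        if name.startswith("C") and name[1:].isdigit():
            cal = str(time_index_to_quarter(mean, origin))
        rows.append({"parameter": name, "mean": mean, "sd": sd, "calendar": cal})
    return pd.DataFrame(rows)


def _population_state(draws: PosteriorDraws) -> ParameterState:
    state = draws.posterior_mean_state()
    zero_re = RandomEffects.zeros(state.random.countries, draws.spec.n_changepoints)
    return replace(state, random=zero_re)


def _curve(state: ParameterState, draws: PosteriorDraws, country_row: int, times, seasonal: bool):
    spec = draws.spec
    times = np.asarray(times, dtype=float)
    if not seasonal:
        state = replace(
            state,
            fixed=replace(state.fixed, beta0s=0.0, beta1s=0.0),
        )
        # country amplitude deviation must go too, or the sine survives
        zero_amp = replace(state.random, b0s=np.zeros_like(state.random.b0s))
        state = replace(state, random=zero_amp)
    ci = np.full(len(times), country_row)
    values = _mean_array(spec, state, times, ci)
    return pd.DataFrame({"time": times, "value": values})


def predict_population(
    draws: PosteriorDraws, times, seasonal: bool = True
) -> pd.DataFrame:
    """Population-level prediction curve at the posterior-mean fixed
    effects and change-points, random effects zero.  ``seasonal=False``
    yields the de-seasonalised ("predicted linear") trend, hinge terms
    included."""
    state = _population_state(draws)
    if not state.random.countries:
        state = replace(
            state, random=RandomEffects.zeros(["_pop"], draws.spec.n_changepoints)
        )
    return _curve(state, draws, 0, times, seasonal)


def predict_country(
    draws: PosteriorDraws, country: str, times, seasonal: bool = True
) -> pd.DataFrame:
    """Country-specific prediction: population curve plus the country's
    posterior-mean random effects."""
    state = draws.posterior_mean_state()
    row = state.random.index_of(country)
    return _curve(state, draws, row, times, seasonal)
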