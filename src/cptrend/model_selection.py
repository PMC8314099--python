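"""DIC computation (pD and pV variants) and K = 0..K_max model comparison.

DIC = D̄ + penalty, where D̄ is the posterior mean of the (conditional)
deviance.  The pD penalty is D̄ − D(θ̄) with D(θ̄) the deviance at the
componentwise posterior mean of *all* sampled quantities, random effects
included (the plug-in convention of hierarchical Gibbs software).  Since
pD is not invariant to reparameterisation and can go negative, the
pV = Var(deviance)/2 variant is reported alongside; selection defaults
to DIC(pD).  Smaller DIC means a better fitting model; fits that fail
the r-hat convergence check are reported but excluded from selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import PanelDataset
from .mcmc import PosteriorDraws, SamplerConfig, assess_convergence, run_mcmc, ConvergenceReport
from .model_core import ModelSpec, deviance
from .priors import PriorConfig

__all__ = ["DICReport", "compute_dic", "ModelComparison", "compare_models"]


@dataclass
class DICReport:
    """Deviance summaries for one fitted model.

    dbar: posterior mean deviance D̄; dhat: deviance at the posterior
    mean D(θ̄); pd = dbar − dhat; pv = Var(deviance)/2;
    dic_pd = dbar + pd; dic_pv = dbar + pv.
    """

    dbar: float
    dhat: float
    pd: float
    pv: float
    dic_pd: float
    dic_pv: float
    converged: bool = True


def dic_from_deviances(deviances: np.ndarray, dhat: float, converged: bool = True) -> DICReport:
    """Assemble a DIC report from per-draw deviances and a plug-in deviance."""
    deviances = np.asarray(deviances, dtype=float)
    if deviances.size < 2:
        raise ValueError("DIC needs at least 2 posterior draws")
    dbar = float(deviances.mean())
    pv = float(deviances.var(ddof=1) / 2.0)
    pd_ = dbar - dhat
    return DICReport(
        dbar=dbar,
        dhat=float(dhat),
        pd=pd_,
        pv=pv,
        dic_pd=dbar + pd_,
        dic_pv=dbar + pv,
        converged=converged,
    )


def compute_dic(
    draws: PosteriorDraws,
    data: PanelDataset,
    spec: ModelSpec,
    convergence: ConvergenceReport | None = None,
) -> DICReport:
    """DIC from posterior draws: D̄ from the recorded per-draw deviances,
    D(θ̄) by plugging the posterior-mean state into the deviance."""
    dhat = deviance(data, spec, draws.posterior_mean_state())
    converged = convergence.converged if convergence is not None else True
    return dic_from_deviances(draws.pooled("deviance"), dhat, converged)


@dataclass
class ModelComparison:
    """Comparison of candidate models K = 0..k_max."""

    table: pd.DataFrame
    reports: dict
    selected_k: int | None
    draws: dict

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ModelComparison(selected_k={self.selected_k})\n{self.table}"


def compare_models(
    data: PanelDataset,
    k_max: int,
    priors: PriorConfig | None = None,
    cfg: SamplerConfig | None = None,
    select_by: str = "pd",
    keep_draws: bool = False,
) -> ModelComparison:
    """Fit K = 0..k_max sequentially and rank by DIC.

    Selection takes the smallest DIC (pD variant by default,
    ``select_by="pv"`` switches) among *converged* fits; non-converged
    fits stay in the table but are never selected.  A fit that errors out
    (e.g. more change-points than the data can support) is recorded with
    NaN entries.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if select_by not in ("pd", "pv"):
        raise ValueError("select_by must be 'pd' or 'pv'")
    rows, reports, draws_by_k = [], {}, {}
    for k in range(k_max + 1):
        spec = ModelSpec(n_changepoints=k)
        try:
            draws = run_mcmc(data, spec, priors, cfg)
        except ValueError as exc:
            rows.append(
                dict(K=k, dbar=np.nan, dhat=np.nan, pd=np.nan, pv=np.nan,
                     dic_pd=np.nan, dic_pv=np.nan, converged=False, error=str(exc))
            )
            continue
        conv = (
            assess_convergence(draws)
            if draws.n_chains >= 2
            else ConvergenceReport({}, {}, True, draws.config.rhat_threshold)
        )
        rep = compute_dic(draws, data, spec, conv)
        reports[k] = rep
        if keep_draws:
            draws_by_k[k] = draws
        rows.append(
            dict(K=k, dbar=rep.dbar, dhat=rep.dhat, pd=rep.pd, pv=rep.pv,
                 dic_pd=rep.dic_pd, dic_pv=rep.dic_pv, converged=rep.converged, error="")
        )
    table = pd.DataFrame(rows)
    crit = "dic_pd" if select_by == "pd" else "dic_pv"
    eligible = table[table["converged"] & table[crit].notna()]
    selected_k = int(eligible.loc[eligible[crit].idxmin(), "K"]) if len(eligible) else None
    return ModelComparison(table=table, reports=reports, selected_k=selected_k, draws=draws_by_k)
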