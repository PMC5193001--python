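"""Model-building workflows: sequential fitting, BIC covariate selection,
and posterior-sample correlation screening.

Sequential fitting estimates the disposition fixed effects (CL, V1, Q,
V2) from the intravenous data alone, then freezes those typical values
while the absorption parameters, covariate coefficients, all random
effects and the residual error are estimated from the full (IV + SC)
dataset.  Covariate selection is backward elimination under
``BIC = -2 LL + ln(n) P`` with n the number of *subjects* and P the
total number of estimated quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataset import PKDataset
from .popmodel import PopulationModel
from .saem.engine import FitResult, SaemSettings, saem_fit
from .structural import PARAM_NAMES

__all__ = [
    "DISPOSITION_PARAMS",
    "ABSORPTION_PARAMS",
    "DEFAULT_SEARCH_SPACE",
    "SequentialFit",
    "EliminationTrace",
    "bic",
    "sequential_fit",
    "backward_eliminate",
    "correlation_screen",
]

DISPOSITION_PARAMS = ("CL", "V1", "Q", "V2")
ABSORPTION_PARAMS = ("Ftot", "F0", "ka", "Tk0")

#: canonical covariate search space: every covariate on CL, V1 and Ftot;
#: the list order is also the tie-break order during elimination
DEFAULT_SEARCH_SPACE: Tuple[Tuple[str, str], ...] = tuple(
    (param, cov)
    for param in ("CL", "V1", "Ftot")
    for cov in ("ANEST", "t_AGE", "t_WEIGHT0", "GENDER"))


def bic(loglik: float, n: int, P: int) -> float:
    """Bayesian information criterion, -2 LL + ln(n) P (n = subjects)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if P < 0:
        raise ValueError("P must be >= 0")
    return -2.0 * loglik + math.log(n) * P


@dataclass
class SequentialFit:
    iv_fit: FitResult
    combined_fit: FitResult


@dataclass
class EliminationStep:
    description: str
    active: Tuple[Tuple[str, str], ...]
    loglik: float
    P: int
    n: int
    bic: float
    action: str


@dataclass
class EliminationTrace:
    steps: List[EliminationStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "description": s.description,
            "active": ";".join(f"{p}~{c}" for p, c in s.active),
            "loglik": s.loglik, "P": s.P, "n": s.n, "bic": s.bic,
            "action": s.action,
        } for s in self.steps])


# ----------------------------------------------------------------------

def _stage1_model(model: PopulationModel) -> PopulationModel:
    """Disposition-only variant: absorption omegas zeroed, no covariates."""
    m = model.copy()
    for p in ABSORPTION_PARAMS:
        m.random.omega[p] = 0.0
    m.random.corr = {k: v for k, v in m.random.corr.items()
                     if k[0] in DISPOSITION_PARAMS and k[1] in DISPOSITION_PARAMS}
    m.fixed.beta_cov = {}
    return m


def _stage2_model(model: PopulationModel, iv_fit: FitResult) -> PopulationModel:
    """Full model initialized with (and later frozen at) the IV disposition."""
    m = model.copy()
    for p in DISPOSITION_PARAMS:
        m.fixed.mu[p] = iv_fit.model.fixed.mu[p]
        if m.random.omega.get(p, 0.0) > 0:
            # carry the stage-1 omega as a starting point
            w1 = iv_fit.model.random.omega.get(p, 0.0)
            if w1 > 0:
                m.random.omega[p] = w1
    m.error = iv_fit.model.error
    return m


def sequential_fit(dataset: PKDataset, initial_model: PopulationModel,
                   settings: Optional[SaemSettings] = None) -> SequentialFit:
    """Two-stage fit: IV disposition first, then the combined dataset.

    Stage 1 fits the IV occasions only, estimating CL, V1, Q, V2 (and
    their omegas).  Stage 2 fits everything with those four typical
    values frozen bit-exactly, estimating the absorption parameters,
    covariate coefficients, all omegas, correlations and the error
    model.
    """
    settings = settings or SaemSettings()
    ds_iv = dataset.iv_subset()
    if not ds_iv.subjects:
        raise ValueError("no IV administrations: sequential fitting needs an "
                         "IV stage; fit the model jointly instead")
    s1 = SaemSettings(**{**settings.__dict__, "seed": settings.seed,
                         "compute_rse": settings.compute_rse})
    iv_fit = saem_fit(ds_iv, _stage1_model(initial_model),
                      fixed_flags=ABSORPTION_PARAMS, settings=s1)
    m2 = _stage2_model(initial_model, iv_fit)
    s2 = SaemSettings(**{**settings.__dict__, "seed": settings.seed + 1})
    combined = saem_fit(dataset, m2, fixed_flags=DISPOSITION_PARAMS,
                        settings=s2)
    for p in DISPOSITION_PARAMS:
        assert combined.model.fixed.mu[p] == iv_fit.model.fixed.mu[p]
    return SequentialFit(iv_fit=iv_fit, combined_fit=combined)


# ----------------------------------------------------------------------

def backward_eliminate(dataset: PKDataset,
                       settings: Optional[SaemSettings] = None,
                       search_space: Sequence[Tuple[str, str]] = DEFAULT_SEARCH_SPACE,
                       initial_model: Optional[PopulationModel] = None,
                       fit_fn: Optional[Callable] = None,
                       ) -> Tuple[Tuple[Tuple[str, str], ...], EliminationTrace]:
    """Backward elimination of covariate coefficients by BIC.

    Starts from the model with every coefficient in ``search_space``
    active; at each step the removal yielding the largest BIC decrease
    is accepted (ties broken by the search-space order), stopping when
    no removal decreases BIC.  A candidate whose fit fails is skipped
    with a trace annotation.  ``fit_fn(active, seed) -> (loglik, P, n)``
    may be injected (mainly for testing the selection logic); by default
    each candidate is a stage-2 sequential refit sharing one IV fit.
    """
    settings = settings or SaemSettings()
    search_space = tuple(search_space)
    trace = EliminationTrace()

    if fit_fn is None:
        if initial_model is None:
            raise ValueError("initial_model required unless fit_fn is given")
        iv_fit = saem_fit(dataset.iv_subset(),
                          _stage1_model(initial_model),
                          fixed_flags=ABSORPTION_PARAMS, settings=settings)

        def fit_fn(active, seed):
            m = _stage2_model(initial_model, iv_fit)
            m.fixed.beta_cov = {k: initial_model.fixed.beta_cov.get(k, 0.0)
                                for k in active}
            s = SaemSettings(**{**settings.__dict__, "seed": seed})
            fit = saem_fit(dataset, m, fixed_flags=("CL", "V1", "Q", "V2"),
                           settings=s)
            return fit.loglik, fit.n_params, fit.n_subjects

    fit_counter = [0]

    def run(active):
        fit_counter[0] += 1
        seed = settings.seed + 1000 + fit_counter[0]
        ll, P, n = fit_fn(tuple(active), seed)
        return ll, P, n, bic(ll, n, P)

    active = list(search_space)
    ll, P, n, cur_bic = run(active)
    trace.steps.append(EliminationStep(
        "full model", tuple(active), ll, P, n, cur_bic, "start"))

    while active:
        best = None
        for idx, coef in enumerate(active):
            candidate = [c for c in active if c != coef]
            try:
                ll_c, P_c, n_c, bic_c = run(candidate)
            except Exception as exc:  # failed candidate: discard, annotate
                trace.steps.append(EliminationStep(
                    f"remove {coef[0]}~{coef[1]}", tuple(candidate),
                    math.nan, math.nan, n, math.nan,
                    f"skipped ({type(exc).__name__})"))
                continue
            trace.steps.append(EliminationStep(
                f"remove {coef[0]}~{coef[1]}", tuple(candidate),
                ll_c, P_c, n_c, bic_c, "candidate"))
            if bic_c <= cur_bic and (best is None or bic_c < best[0]):
                best = (bic_c, idx, coef, candidate, ll_c, P_c)
        if best is None:
            break
        cur_bic, _, coef, active, ll, P = best
        trace.steps.append(EliminationStep(
            f"removed {coef[0]}~{coef[1]}", tuple(active), ll, P, n,
            cur_bic, "accepted"))

    trace.steps.append(EliminationStep(
        "selected model", tuple(active), ll, P, n, cur_bic, "final"))
    return tuple(active), trace


# ----------------------------------------------------------------------

def correlation_screen(samples: Dict[int, np.ndarray]) -> pd.DataFrame:
    """Pearson correlations of eta across subjects.

    ``samples`` maps subject id to either a single eta vector (EBEs) or
    an (n_chains, 8) array of posterior draws; draws are pooled so each
    subject contributes one point per chain.  Parameters with zero
    variance across the pooled points yield NaN rows/columns.
    """
    if len(samples) < 2:
        raise ValueError("correlation screen needs at least 2 subjects")
    rows = []
    for sid, arr in samples.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        rows.append(arr)
    pooled = np.vstack(rows)
    sd = pooled.std(axis=0)
    out = np.full((pooled.shape[1], pooled.shape[1]), np.nan)
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(pooled[:, ok], rowvar=False)
        out[np.ix_(ok, ok)] = np.atleast_2d(sub)
    return pd.DataFrame(out, index=list(PARAM_NAMES), columns=list(PARAM_NAMES))
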