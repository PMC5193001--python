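"""Goodness-of-fit and validation diagnostics.

All diagnostics are pure functions of (fit, dataset, seed): population
and individual predictions with individual weighted residuals (IWRES),
simulation-based normalized prediction distribution errors (NPDE),
eta-shrinkage, and the visual predictive check (VPC).  Censored (BLQ)
and predose samples are excluded from residual-type diagnostics; in the
VPC they enter percentile computation as LLOQ/2, applied identically to
observed and simulated values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .dataset import PKDataset
from .popmodel import PopulationModel, residual_sd, transformed_mean
from .saem.encode import EncodedData
from .saem.engine import FitResult, _Structure, _back_transform, _omega_matrix
from .popmodel import transform_value
from .structural import PARAM_NAMES

__all__ = ["DiagnosticsBundle", "VPCResult", "residuals", "npde",
           "shrinkage", "vpc"]

_NPDE_MIN_SIM = 10


@dataclass
class DiagnosticsBundle:
    """Per-observation predictions/residuals plus summary statistics."""

    table: pd.DataFrame
    shrinkage: Dict[str, float]
    residual_summary: Dict[str, float]


@dataclass
class VPCResult:
    table: pd.DataFrame
    n_sims: int
    warnings: list = field(default_factory=list)


def _mean_matrix(model: PopulationModel, dataset: PKDataset) -> np.ndarray:
    return np.vstack([transformed_mean(model, s) for s in dataset.subjects])


def _predict_all(enc: EncodedData, model: PopulationModel,
                 etas: np.ndarray) -> np.ndarray:
    """(n_obs,) predictions for per-subject etas (n_subj, 8)."""
    M = _mean_matrix(model, enc.dataset)
    psi = (M + etas)[:, None, :]
    return enc.predict(_back_transform(psi))[:, 0]


def residuals(fit: FitResult, dataset: PKDataset,
              impute_censored: bool = False,
              seed: int = 0) -> DiagnosticsBundle:
    """Population/individual predictions and IWRES.

    The population prediction sets eta = 0 (keeping each subject's
    covariates); the individual prediction uses the EBE;
    IWRES = (obs - ipred) / sd(ipred) for uncensored, non-predose
    samples.  With ``impute_censored`` BLQ samples receive a value drawn
    from the model's conditional distribution on [0, LLOQ] so residual
    summaries are free of the selection bias that excluding the left
    tail would otherwise introduce.
    """
    from scipy.special import ndtr, ndtri
    enc = EncodedData(dataset, include_predose=True)
    n = enc.n_subj
    zeros = np.zeros((n, len(PARAM_NAMES)))
    ebes = np.vstack([fit.ebes[sid] for sid in enc.subject_ids])
    pred_pop = _predict_all(enc, fit.model, zeros)
    pred_ind = _predict_all(enc, fit.model, ebes)
    sd_ind = residual_sd(pred_ind, fit.model.error)
    usable = ~enc.obs_cens & ~enc.obs_predose
    value = enc.obs_value.copy()
    if impute_censored:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        sel = enc.obs_cens & ~enc.obs_predose
        if sel.any():
            lo = ndtr((0.0 - pred_ind[sel]) / sd_ind[sel])
            hi = ndtr((enc.obs_lloq[sel] - pred_ind[sel]) / sd_ind[sel])
            u = rng.uniform(lo, np.maximum(hi, lo + 1e-12))
            value[sel] = pred_ind[sel] + sd_ind[sel] * ndtri(
                np.clip(u, 1e-15, 1 - 1e-15))
            usable = usable | sel
    iwres = np.where(usable, (value - pred_ind) / sd_ind, np.nan)
    table = pd.DataFrame({
        "subject_id": [enc.subject_ids[i] for i in enc.obs_subj],
        "occasion": enc.obs_occ,
        "time": enc.obs_time,
        "dv": np.where(enc.obs_cens, np.nan, enc.obs_value),
        "censored": enc.obs_cens,
        "predose": enc.obs_predose,
        "pred_pop": pred_pop,
        "pred_ind": pred_ind,
        "iwres": iwres,
    })
    vals = iwres[usable]
    summary = {
        "iwres_mean": float(np.mean(vals)) if vals.size else math.nan,
        "iwres_var": float(np.var(vals)) if vals.size else math.nan,
        "n": int(vals.size),
    }
    return DiagnosticsBundle(table=table, shrinkage=shrinkage(fit),
                             residual_summary=summary)


def npde(fit: FitResult, dataset: PKDataset, n_sim: int = 1000,
         seed: int = 0, impute_censored: bool = False) -> pd.DataFrame:
    """Normalized prediction distribution errors.

    ``n_sim`` replicate datasets are simulated under the fitted model;
    per subject, observed and simulated vectors are decorrelated with
    the empirical simulated mean and covariance (Cholesky square root),
    the per-observation rank among simulations gives the prediction
    discrepancy pd, and NPDE = Phi^{-1}(pd).  Under a correct model the
    NPDE are standard normal.

    Censored (BLQ) observations are excluded by default; with
    ``impute_censored`` each receives a value resampled from its own
    simulated distribution restricted to below the LLOQ, so the full
    residual distribution is assessed without left-tail selection bias.
    """
    if n_sim < _NPDE_MIN_SIM:
        raise ValueError(f"n_sim must be >= {_NPDE_MIN_SIM} "
                         "(>= 500 recommended)")
    enc = EncodedData(dataset)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    model = fit.model
    st = _Structure(model, dataset, fixed_flags=PARAM_NAMES)
    M = _mean_matrix(model, dataset)
    omega = model.random.covariance()
    adim = np.where(model.random.omega_vector() > 0)[0]
    psi = np.tile(M[:, None, :], (1, n_sim, 1))
    if adim.size:
        L = np.linalg.cholesky(
            omega[np.ix_(adim, adim)] + 1e-12 * np.eye(adim.size))
        z = rng.standard_normal((enc.n_subj, n_sim, adim.size))
        psi[:, :, adim] += z @ L.T
    pred = enc.predict(_back_transform(psi))
    ysim = enc.simulate(pred, model.error.a, model.error.b, rng)

    value = enc.obs_value.copy()
    usable = ~enc.obs_cens
    if impute_censored:
        sel = np.where(enc.obs_cens)[0]
        for j in sel:
            below = ysim[j][ysim[j] < enc.obs_lloq[j]]
            value[j] = rng.choice(below) if below.size \
                else enc.obs_lloq[j] / 2.0
        usable = np.ones(enc.n_obs, dtype=bool)
    out_npde = np.full(enc.n_obs, np.nan)
    for i in range(enc.n_subj):
        idx = enc.subj_obs_idx[i]
        idx = idx[usable[idx]]
        if not idx.size:
            continue
        sims = ysim[idx]                  # (ni, n_sim)
        mu = sims.mean(axis=1)
        cov = np.cov(sims)
        cov = np.atleast_2d(cov)
        ridge = 1e-8 * np.trace(cov) / max(len(idx), 1)
        try:
            L = np.linalg.cholesky(cov + ridge * np.eye(len(idx)))
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(cov + (1e-3 * np.trace(cov) + 1e-8)
                                   * np.eye(len(idx)))
        yd = np.linalg.solve(L, value[idx] - mu)
        sd = np.linalg.solve(L, sims - mu[:, None])
        pd_ = (sd < yd[:, None]).mean(axis=1)
        pd_ = np.clip(pd_, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        out_npde[idx] = ndtri(pd_)
    return pd.DataFrame({
        "subject_id": [enc.subject_ids[i] for i in enc.obs_subj],
        "time": enc.obs_time,
        "censored": enc.obs_cens,
        "npde": out_npde,
    })


def shrinkage(fit: FitResult) -> Dict[str, float]:
    """Eta-shrinkage per parameter: 100 (1 - sd(EBE eta)/omega).

    Near-100% values mean the EBEs collapse to the population value
    (sparse data); undefined (NaN) when omega = 0.
    """
    ebes = np.vstack(list(fit.ebes.values()))
    out = {}
    for j, p in enumerate(PARAM_NAMES):
        w = fit.model.random.omega.get(p, 0.0)
        if w <= 0:
            out[p] = math.nan
        else:
            out[p] = 100.0 * (1.0 - ebes[:, j].std(ddof=1) / w)
    return out


def _make_bins(times: np.ndarray, binning) -> np.ndarray:
    """Bin edges: explicit, or nominal times when few, else quantile bins."""
    if binning is not None and not isinstance(binning, str):
        return np.asarray(binning, dtype=float)
    uniq = np.unique(np.round(times, 3))
    if (binning == "nominal") or (binning is None and uniq.size <= 15):
        mids = 0.5 * (uniq[1:] + uniq[:-1])
        return np.concatenate([[times.min() - 1e-9], mids,
                               [times.max() + 1e-9]])
    q = np.linspace(0, 1, 5)  # default 4 quantile bins for irregular times
    edges = np.quantile(times, q)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return np.unique(edges)


def vpc(fit: FitResult, dataset: PKDataset, n_sim: int = 500,
        percentiles: Tuple[float, ...] = (10, 50, 90), ci: float = 95,
        binning=None, seed: int = 0) -> VPCResult:
    """Visual predictive check statistics.

    Observed percentiles per time bin are overlaid with the ``ci``%
    band of the same percentiles across ``n_sim`` Monte-Carlo replicate
    datasets.  Values below the LLOQ (observed or simulated) enter the
    percentile computation as LLOQ/2 so the treatment is symmetric.
    """
    enc = EncodedData(dataset)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    model = fit.model
    M = _mean_matrix(model, dataset)
    omega = model.random.covariance()
    adim = np.where(model.random.omega_vector() > 0)[0]
    psi = np.tile(M[:, None, :], (1, n_sim, 1))
    if adim.size:
        L = np.linalg.cholesky(
            omega[np.ix_(adim, adim)] + 1e-12 * np.eye(adim.size))
        z = rng.standard_normal((enc.n_subj, n_sim, adim.size))
        psi[:, :, adim] += z @ L.T
    pred = enc.predict(_back_transform(psi))
    ysim = enc.simulate(pred, model.error.a, model.error.b, rng)
    half = enc.obs_lloq / 2.0
    ysim = np.where(ysim < enc.obs_lloq[:, None], half[:, None], ysim)
    yobs = np.where(enc.obs_cens, half, enc.obs_value)

    edges = _make_bins(enc.obs_time, binning)
    warnings = []
    rows = []
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    for k in range(len(edges) - 1):
        sel = (enc.obs_time > edges[k]) & (enc.obs_time <= edges[k + 1])
        if k == 0:
            sel |= enc.obs_time == edges[0]
        if not sel.any():
            warnings.append(f"empty bin ({edges[k]:.3g}, {edges[k+1]:.3g}]")
            continue
        row = {"bin_lo": edges[k], "bin_hi": edges[k + 1],
               "t_mid": float(np.median(enc.obs_time[sel])),
               "n_obs": int(sel.sum())}
        for p in percentiles:
            row[f"obs_p{int(p)}"] = float(np.percentile(yobs[sel], p))
            simp = np.percentile(ysim[sel], p, axis=0)
            row[f"sim_p{int(p)}_lo"] = float(np.percentile(simp, lo_q))
            row[f"sim_p{int(p)}_med"] = float(np.percentile(simp, 50))
            row[f"sim_p{int(p)}_hi"] = float(np.percentile(simp, hi_q))
        rows.append(row)
    return VPCResult(table=pd.DataFrame(rows), n_sims=n_sim,
                     warnings=warnings)


def lag1_autocorrelation(fit: FitResult, dataset: PKDataset) -> pd.DataFrame:
    """Lag-1 autocorrelation of IWRES per subject with >= 4 usable samples."""
    bundle = residuals(fit, dataset)
    t = bundle.table
    rows = []
    for sid, grp in t[~t.iwres.isna()].groupby("subject_id"):
        r = grp.sort_values(["occasion", "time"]).iwres.to_numpy()
        if r.size >= 4:
            x, y = r[:-1], r[1:]
            denom = x.std() * y.std()
            rows.append({"subject_id": sid, "n": r.size,
                         "lag1": float(np.corrcoef(x, y)[0, 1])
                         if denom > 0 else math.nan})
    return pd.DataFrame(rows)
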