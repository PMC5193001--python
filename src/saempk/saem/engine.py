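"""SAEM estimation of the nonlinear mixed-effects population PK model.

The E-step samples each subject's transformed parameter vector
``psi_i = m_i + eta_i`` from its conditional distribution given the data
by Metropolis-Hastings (three kernels per sweep: an independent proposal
from the population prior, a componentwise random walk, and a
full-vector random walk, with scales adapted toward ~0.3 acceptance).
Sufficient statistics are updated by stochastic approximation with step
size 1 during the exploratory phase and ``k**-step_exponent`` during
smoothing; the M-step is closed form for the means/covariates (least
squares on the transformed scale) and for Omega, and a small numerical
minimization for the combined residual-error parameters.

Censored (BLQ) observations enter every likelihood through the exact
interval probability between zero and the LLOQ — no latent values are
imputed.  During exploration the random-effect variances and error
parameters are kept above a geometrically decaying floor (simulated
annealing) to prevent premature collapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from ..dataset import PKDataset
from ..popmodel import (ErrorModel, FixedEffects, PopulationModel,
                        RandomEffectsSpec, back_transform_value,
                        covariate_values, transform_value, transformed_mean)
from ..structural import PARAM_NAMES
from .encode import EncodedData

__all__ = [
    "SaemSettings",
    "FitResult",
    "saem_fit",
    "conditional_samples",
    "estimate_loglik_is",
    "compute_rse",
    "extract_posteriors",
    "extract_ebes",
]

_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}
_NP = len(PARAM_NAMES)
_PSI_CLIP = 30.0  # transformed-scale guard against overflow


@dataclass
class SaemSettings:
    """Tuning of the SAEM run.

    ``n_chains`` Markov chains are run in parallel per subject; the
    final-iteration states are the per-subject posterior samples.
    Defaults (10 chains, 1000 exploratory + 500 smoothing iterations)
    match the study-scale configuration; reduce for quick fits.
    """

    n_chains: int = 10
    n_explore: int = 1000
    n_smooth: int = 500
    step_exponent: float = 0.7
    mh_steps_per_iter: int = 1
    seed: int = 0
    annealing: bool = True
    anneal_decay: float = 0.95
    n_is_samples: int = 10000
    compute_loglik: bool = True
    compute_rse: bool = True
    trace_stride: int = 1

    def __post_init__(self):
        if min(self.n_chains, self.n_explore, self.n_smooth,
               self.mh_steps_per_iter) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.5 < self.step_exponent <= 1.0):
            raise ValueError("step_exponent must lie in (0.5, 1]")


@dataclass
class FitResult:
    """Estimates, uncertainty, likelihood and per-subject quantities."""

    model: PopulationModel
    fixed_flags: tuple
    loglik: float
    loglik_se: float
    bic: float
    rse: Dict[str, float]
    ebes: Dict[int, np.ndarray]
    posterior_samples: Dict[int, np.ndarray]
    convergence_trace: pd.DataFrame
    n_subjects: int
    n_params: int
    settings: SaemSettings
    warnings: List[str] = field(default_factory=list)
    # conditional moments (per-subject, transformed scale) for reuse
    cond_mean: Optional[np.ndarray] = None
    cond_cov: Optional[np.ndarray] = None
    score_matrix: Optional[np.ndarray] = None
    score_labels: Optional[List[str]] = None


# ----------------------------------------------------------------------
# structure bookkeeping
# ----------------------------------------------------------------------

class _Structure:
    """Which quantities are estimated, and the covariate designs."""

    def __init__(self, model: PopulationModel, dataset: PKDataset,
                 fixed_flags: Iterable[str]):
        self.fixed_flags = tuple(fixed_flags)
        unknown = set(self.fixed_flags) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed_flags {sorted(unknown)}")
        omega = model.random.omega_vector()
        self.active = omega > 0                       # eta sampled
        self.est_mu = np.array([n not in self.fixed_flags
                                for n in PARAM_NAMES])
        self.noiiv_est = self.est_mu & ~self.active   # mu by direct optimization
        self.coeffs = list(model.fixed.beta_cov.keys())
        self.corr_pairs = list(model.random.corr.keys())
        for (p, q) in self.corr_pairs:
            if not (self.active[_IDX[p]] and self.active[_IDX[q]]):
                raise ValueError(
                    f"correlation ({p},{q}) requires both omegas > 0")
        # covariate value matrix per subject
        cov_rows = [covariate_values(s, model.covariate_medians)
                    for s in dataset.subjects]
        self.covmat = {c: np.array([r[c] for r in cov_rows])
                       for c in ("ANEST", "t_AGE", "t_WEIGHT0", "GENDER")}

    @property
    def n_params(self) -> int:
        """Count of estimated quantities (BIC's P)."""
        return (int(self.est_mu.sum()) + len(self.coeffs)
                + int(self.active.sum()) + len(self.corr_pairs) + 2)

    def mean_matrix(self, tmu: np.ndarray,
                    beta: Dict[Tuple[str, str], float],
                    n_subj: int) -> np.ndarray:
        m = np.tile(tmu, (n_subj, 1))
        for (p, c), val in beta.items():
            m[:, _IDX[p]] += val * self.covmat[c]
        return m


def _omega_matrix(omega_var: np.ndarray,
                  corr: Dict[Tuple[str, str], float]) -> np.ndarray:
    om = np.diag(omega_var)
    sd = np.sqrt(omega_var)
    for (p, q), r in corr.items():
        i, j = _IDX[p], _IDX[q]
        om[i, j] = om[j, i] = r * sd[i] * sd[j]
    return om


def _nearest_psd(mat: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    if mat.size == 0:
        return mat
    w, v = np.linalg.eigh(mat)
    if w.min() >= floor:
        return mat
    w = np.maximum(w, floor)
    return (v * w) @ v.T


def _back_transform(psi: np.ndarray) -> np.ndarray:
    """Transformed-scale (..., 8) -> natural scale."""
    phi = np.empty_like(psi)
    phi[..., :2] = 1.0 / (1.0 + np.exp(-psi[..., :2]))
    phi[..., 2:] = np.exp(psi[..., 2:])
    return phi


# ----------------------------------------------------------------------
# MCMC sampler (shared between SAEM and standalone conditional sampling)
# ----------------------------------------------------------------------

class _Sampler:
    def __init__(self, enc: EncodedData, structure: _Structure,
                 n_chains: int, rng: np.random.Generator):
        self.enc = enc
        self.st = structure
        self.C = n_chains
        self.rng = rng
        self.adim = np.where(structure.active)[0]
        na = self.adim.size
        self.steps_cw = np.full((enc.n_subj, na), 0.4)
        self.steps_full = np.full(enc.n_subj, 0.25)
        self.psi = None
        self.pred = None
        self.ll = None
        # running per-subject conditional moments for the adaptive kernel
        self.run_mean = None
        self.run_cov = None
        self.steps_adapt = np.full(enc.n_subj, 0.8)
        self.n_seen = 0

    # -- state ----------------------------------------------------------
    def initialize(self, M: np.ndarray, omega: np.ndarray,
                   corr: Dict[Tuple[str, str], float]):
        self._set_prior(omega, corr)
        self.M = M
        psi = np.tile(M[:, None, :], (1, self.C, 1))
        if self.adim.size:
            z = self.rng.standard_normal((self.enc.n_subj, self.C, self.adim.size))
            psi[:, :, self.adim] += z @ self.L.T
        self.psi = np.clip(psi, -_PSI_CLIP, _PSI_CLIP)
        self.pred = self.enc.predict(_back_transform(self.psi))

    def _set_prior(self, omega_var: np.ndarray,
                   corr: Dict[Tuple[str, str], float]):
        self.omega_var = omega_var
        om = _omega_matrix(omega_var, corr)
        sub = om[np.ix_(self.adim, self.adim)]
        sub = _nearest_psd(sub, 1e-12)
        self.L = np.linalg.cholesky(sub) if self.adim.size else np.zeros((0, 0))
        self.Om_inv = np.linalg.inv(sub) if self.adim.size else np.zeros((0, 0))

    def refresh(self, M: np.ndarray, omega_var: np.ndarray,
                corr: Dict[Tuple[str, str], float], a: float, b: float):
        """Re-pin inactive dimensions and recompute predictions/likelihood."""
        self._set_prior(omega_var, corr)
        inactive = ~self.st.active
        self.psi[:, :, inactive] = M[:, None, inactive]
        self.M = M
        self.pred = self.enc.predict(_back_transform(self.psi))
        self.ll = self.enc.loglik_subjects(self.pred, a, b)

    # -- pieces ---------------------------------------------------------
    def _logprior(self, psi: np.ndarray) -> np.ndarray:
        if not self.adim.size:
            return np.zeros(psi.shape[:2])
        eta = psi[:, :, self.adim] - self.M[:, None, self.adim]
        return -0.5 * np.einsum("ncj,jk,nck->nc", eta, self.Om_inv, eta)

    def _accept(self, psi_new, a, b, extra_delta=None):
        pred_new = self.enc.predict(_back_transform(psi_new))
        ll_new = self.enc.loglik_subjects(pred_new, a, b)
        delta = ll_new - self.ll
        if extra_delta is not None:
            delta = delta + extra_delta
        acc = np.log(self.rng.uniform(size=delta.shape)) < delta
        if acc.any():
            self.psi = np.where(acc[:, :, None], psi_new, self.psi)
            obs_mask = acc[self.enc.obs_subj]
            self.pred = np.where(obs_mask, pred_new, self.pred)
            self.ll = np.where(acc, ll_new, self.ll)
        return acc

    # -- one full sweep --------------------------------------------------
    def sweep(self, a: float, b: float, adapt_rate: float):
        n, C = self.enc.n_subj, self.C
        if not self.adim.size:
            return
        # kernel 1: independent proposal from the population prior
        z = self.rng.standard_normal((n, C, self.adim.size))
        psi_new = self.psi.copy()
        psi_new[:, :, self.adim] = np.clip(
            self.M[:, None, self.adim] + z @ self.L.T, -_PSI_CLIP, _PSI_CLIP)
        self._accept(psi_new, a, b)

        # kernel 2: componentwise random walk
        lp = self._logprior(self.psi)
        for j, dim in enumerate(self.adim):
            step = self.steps_cw[:, j] * np.sqrt(self.omega_var[dim])
            psi_new = self.psi.copy()
            psi_new[:, :, dim] = np.clip(
                psi_new[:, :, dim]
                + step[:, None] * self.rng.standard_normal((n, C)),
                -_PSI_CLIP, _PSI_CLIP)
            lp_new = self._logprior(psi_new)
            acc = self._accept(psi_new, a, b, extra_delta=lp_new - lp)
            lp = np.where(acc, lp_new, lp)
            rate = acc.mean(axis=1)
            self.steps_cw[:, j] *= np.exp(adapt_rate * (rate - 0.3))

        # kernel 3: full-vector random walk along the prior Cholesky
        z = self.rng.standard_normal((n, C, self.adim.size))
        psi_new = self.psi.copy()
        psi_new[:, :, self.adim] = np.clip(
            psi_new[:, :, self.adim]
            + self.steps_full[:, None, None] * (z @ self.L.T),
            -_PSI_CLIP, _PSI_CLIP)
        lp_new = self._logprior(psi_new)
        acc = self._accept(psi_new, a, b, extra_delta=lp_new - lp)
        lp = np.where(acc, lp_new, lp)
        rate = acc.mean(axis=1)
        self.steps_full *= np.exp(adapt_rate * (rate - 0.3))

        # kernel 4: random walk shaped by the running per-subject
        # conditional covariance — mixes along likelihood ridges that the
        # prior-shaped kernels cannot traverse
        self._update_running_moments()
        if self.n_seen >= 20:
            na = self.adim.size
            cov = self.run_cov + 1e-10 * np.eye(na)
            try:
                Ls = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                Ls = None
            if Ls is not None:
                z = self.rng.standard_normal((n, C, na))
                step = np.einsum("njk,nck->ncj", Ls, z)
                psi_new = self.psi.copy()
                psi_new[:, :, self.adim] = np.clip(
                    psi_new[:, :, self.adim]
                    + self.steps_adapt[:, None, None] * step,
                    -_PSI_CLIP, _PSI_CLIP)
                lp_new = self._logprior(psi_new)
                acc = self._accept(psi_new, a, b, extra_delta=lp_new - lp)
                rate = acc.mean(axis=1)
                self.steps_adapt *= np.exp(adapt_rate * (rate - 0.3))

    def _update_running_moments(self, rate: float = 0.05):
        x = self.psi[:, :, self.adim]
        m = x.mean(axis=1)
        dev = x - m[:, None, :]
        c = np.einsum("ncj,nck->njk", dev, dev) / max(self.C - 1, 1)
        # between-chain spread plus drift of the mean keeps the proposal wide
        if self.run_mean is None:
            self.run_mean = m
            self.run_cov = c + 1e-6 * np.eye(self.adim.size)
        else:
            dm = m - self.run_mean
            self.run_mean += rate * dm
            self.run_cov += rate * (
                c + np.einsum("nj,nk->njk", dm, dm) - self.run_cov)
        self.n_seen += 1


# ----------------------------------------------------------------------
# the SAEM loop
# ----------------------------------------------------------------------

def saem_fit(dataset: PKDataset, initial_model: PopulationModel,
             fixed_flags: Iterable[str] = (),
             settings: Optional[SaemSettings] = None) -> FitResult:
    """Fit ``initial_model`` to ``dataset`` by SAEM.

    ``fixed_flags`` lists typical values held constant (bit-identical in
    the result) — the mechanism behind sequential IV-then-combined
    fitting.  Parameters with ``omega == 0`` carry no random effect; if
    their typical value is estimated it is updated by direct likelihood
    optimization inside the M-step.  Reproducible under
    ``settings.seed``.
    """
    settings = settings or SaemSettings()
    st = _Structure(initial_model, dataset, fixed_flags)
    enc = EncodedData(dataset)
    n = enc.n_subj
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    warnings: List[str] = []

    tmu = np.array([transform_value(p, initial_model.fixed.mu[p])
                    for p in PARAM_NAMES])
    beta = dict(initial_model.fixed.beta_cov)
    omega_var = initial_model.random.omega_vector() ** 2
    corr = dict(initial_model.random.corr)
    a, b = max(initial_model.error.a, 1e-8), max(initial_model.error.b, 1e-8)

    frozen_tmu = tmu.copy()

    sampler = _Sampler(enc, st, settings.n_chains, rng)
    M = st.mean_matrix(tmu, beta, n)
    sampler.initialize(M, omega_var, corr)

    if not np.isfinite(enc.loglik_subjects(sampler.pred, a, b)).all():
        bad = np.where(~np.isfinite(
            enc.loglik_obs(sampler.pred, a, b)).all(axis=1))[0]
        raise RuntimeError(
            "non-finite likelihood at initialization; first offending "
            f"observation index {bad[0] if bad.size else '?'}")

    n_iter = settings.n_explore + settings.n_smooth
    S1 = np.zeros((n, _NP))
    S2 = np.zeros((n, _NP, _NP))
    Sf2 = np.zeros(enc.n_obs)
    Sr2 = np.zeros(enc.n_obs)
    uncens = ~enc.obs_cens

    # accumulators over the smoothing phase
    cond_n = 0
    cond_mean = np.zeros((n, _NP))
    cond_sq = np.zeros((n, _NP, _NP))
    score_sum = None
    score_n = 0
    score_labels = None

    trace_rows = []
    err_x0 = np.log([a, b])

    for k in range(n_iter):
        exploring = k < settings.n_explore
        gamma = 1.0 if exploring else \
            (k - settings.n_explore + 1) ** (-settings.step_exponent)
        adapt_rate = 0.2 if exploring else \
            0.2 * (k - settings.n_explore + 1) ** (-0.5)

        M = st.mean_matrix(tmu, beta, n)
        sampler.refresh(M, omega_var, corr, a, b)
        for _ in range(settings.mh_steps_per_iter):
            sampler.sweep(a, b, adapt_rate)

        psi = sampler.psi
        psi_bar = psi.mean(axis=1)
        psi2_bar = np.einsum("ncj,nck->njk", psi, psi) / settings.n_chains
        S1 += gamma * (psi_bar - S1)
        S2 += gamma * (psi2_bar - S2)

        pred = sampler.pred
        f2 = (pred ** 2).mean(axis=1)
        r2 = ((enc.obs_value[:, None] - pred) ** 2).mean(axis=1)
        Sf2 += gamma * (f2 - Sf2)
        Sr2 += gamma * (r2 - Sr2)

        # ---- M-step -----------------------------------------------------
        tmu, beta = _update_means(st, S1, tmu, beta)
        if st.noiiv_est.any():
            tmu = _update_noiiv(enc, st, sampler, tmu, beta, a, b,
                                1.0 if exploring else gamma)
        M = st.mean_matrix(tmu, beta, n)
        prev_var, prev_a2, prev_b2 = omega_var.copy(), a * a, b * b
        omega_var, corr = _update_omega(st, S1, S2, M, omega_var, corr)
        a, b, err_x0 = _update_error(Sf2, Sr2, uncens, err_x0)
        if settings.annealing and exploring:
            # simulated annealing: variances may shrink at most 5% per
            # exploratory iteration, preventing the multiplicative
            # collapse of weakly identified components under the
            # memoryless (step size 1) update
            omega_var = np.where(
                st.active,
                np.maximum(omega_var, settings.anneal_decay * prev_var), 0.0)
            a = math.sqrt(max(a * a, settings.anneal_decay * prev_a2))
            b = math.sqrt(max(b * b, settings.anneal_decay * prev_b2))

        # ---- smoothing-phase accumulators -------------------------------
        if not exploring:
            # conditional moments over the stabilized second half only
            if k - settings.n_explore >= settings.n_smooth // 2:
                cond_n += 1
                cond_mean += (psi_bar - cond_mean) / cond_n
                cond_sq += (psi2_bar - cond_sq) / cond_n
            if settings.compute_rse:
                sc, score_labels = _score_contributions(
                    enc, st, sampler, M, omega_var, corr, a, b,
                    psi_bar, psi2_bar)
                score_n += 1
                if score_sum is None:
                    score_sum = sc
                else:
                    score_sum += sc

        if k % settings.trace_stride == 0 or k == n_iter - 1:
            row = {"iteration": k, "phase": "explore" if exploring else "smooth"}
            for p in PARAM_NAMES:
                row[f"mu_{p}"] = back_transform_value(p, tmu[_IDX[p]])
                row[f"omega_{p}"] = math.sqrt(omega_var[_IDX[p]])
            for (p, c), v in beta.items():
                row[f"beta_{p}_{c}"] = v
            for (p, q), r in corr.items():
                row[f"corr_{p}_{q}"] = r
            row["a"], row["b"] = a, b
            trace_rows.append(row)

    # ------------------------------------------------------------------
    # finalize
    for p in np.where(~st.est_mu)[0]:
        assert tmu[p] == frozen_tmu[p]

    final_model = PopulationModel(
        fixed=FixedEffects(
            mu={p: float(back_transform_value(p, tmu[_IDX[p]]))
                for p in PARAM_NAMES},
            beta_cov={k2: float(v) for k2, v in beta.items()},
        ),
        random=RandomEffectsSpec(
            omega={p: float(math.sqrt(omega_var[_IDX[p]]))
                   for p in PARAM_NAMES},
            corr={k2: float(np.clip(v, -0.95, 0.95))
                  for k2, v in corr.items()},
        ),
        error=ErrorModel(a=float(a), b=float(b)),
        covariate_medians=dict(initial_model.covariate_medians),
    )

    posterior = {sid: (sampler.psi[i] - M[i]).copy()
                 for i, sid in enumerate(enc.subject_ids)}
    cond_cov = cond_sq - np.einsum("nj,nk->njk", cond_mean, cond_mean)

    ebes = _compute_ebes(enc, st, M, omega_var, corr, a, b, cond_mean)

    n_params = st.n_params
    fit = FitResult(
        model=final_model, fixed_flags=tuple(fixed_flags),
        loglik=math.nan, loglik_se=math.nan, bic=math.nan,
        rse={}, ebes=ebes, posterior_samples=posterior,
        convergence_trace=pd.DataFrame(trace_rows),
        n_subjects=n, n_params=n_params, settings=settings,
        warnings=warnings, cond_mean=cond_mean, cond_cov=cond_cov,
    )
    if score_sum is not None:
        fit.score_matrix = score_sum / score_n
        fit.score_labels = score_labels
        fit.rse = _rse_from_scores(fit, final_model)
    if settings.compute_loglik:
        ll, se = estimate_loglik_is(fit, dataset,
                                    settings.n_is_samples,
                                    seed=rng.integers(2 ** 31))
        fit.loglik, fit.loglik_se = ll, se
        fit.bic = -2.0 * ll + math.log(n) * n_params
    return fit


# ----------------------------------------------------------------------
# M-step pieces
# ----------------------------------------------------------------------

def _update_means(st: _Structure, S1, tmu, beta):
    tmu = tmu.copy()
    beta = dict(beta)
    for p in range(_NP):
        name = PARAM_NAMES[p]
        coefs = [(pp, c) for (pp, c) in st.coeffs if pp == name]
        est_mu = st.est_mu[p] and st.active[p]
        if not est_mu and not coefs:
            continue
        cols = []
        if est_mu:
            cols.append(np.ones(S1.shape[0]))
        target = S1[:, p].copy()
        if not est_mu:
            target -= tmu[p]
        for (_, c) in coefs:
            cols.append(st.covmat[c])
        if not cols:
            continue
        D = np.column_stack(cols)
        sol, *_ = np.linalg.lstsq(D, target, rcond=None)
        j = 0
        if est_mu:
            tmu[p] = sol[0]
            j = 1
        for (pp, c) in coefs:
            beta[(pp, c)] = float(sol[j])
            j += 1
    return tmu, beta


def _update_noiiv(enc, st, sampler, tmu, beta, a, b, gamma):
    """Direct likelihood update of typical values without random effects."""
    dims = np.where(st.noiiv_est)[0]
    tmu = tmu.copy()

    def neg_ll(x):
        t2 = tmu.copy()
        t2[dims] = x
        M2 = st.mean_matrix(t2, beta, enc.n_subj)
        psi = sampler.psi.copy()
        psi[:, :, dims] = M2[:, None, dims]
        pred = enc.predict(_back_transform(psi))
        return -enc.loglik_subjects(pred, a, b).mean(axis=1).sum()

    res = minimize(neg_ll, tmu[dims], method="Nelder-Mead",
                   options={"maxiter": 25 * len(dims), "xatol": 1e-5,
                            "fatol": 1e-7})
    tmu[dims] += gamma * (res.x - tmu[dims])
    return tmu


def _update_omega(st: _Structure, S1, S2, M, omega_var, corr):
    E = (S2 - np.einsum("nj,nk->njk", S1, M)
         - np.einsum("nj,nk->njk", M, S1)
         + np.einsum("nj,nk->njk", M, M)).mean(axis=0)
    new_var = omega_var.copy()
    new_var[st.active] = np.maximum(np.diag(E)[st.active], 1e-12)
    new_corr = {}
    for (p, q) in st.corr_pairs:
        i, j = _IDX[p], _IDX[q]
        r = E[i, j] / math.sqrt(new_var[i] * new_var[j])
        new_corr[(p, q)] = float(np.clip(r, -0.95, 0.95))
    return new_var, new_corr


def _update_error(Sf2, Sr2, uncens, x0):
    f2 = Sf2[uncens]
    r2 = Sr2[uncens]
    if not f2.size:
        return math.exp(x0[0]), math.exp(x0[1]), x0

    def obj(x):
        a2 = math.exp(2 * x[0])
        b2 = math.exp(2 * x[1])
        v = a2 + b2 * f2
        val = 0.5 * np.sum(np.log(v) + r2 / v)
        dv = (1.0 / v - r2 / v ** 2)
        return val, np.array([a2 * np.sum(dv), b2 * np.sum(dv * f2)])

    res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                   bounds=[(-18, 12), (-18, 5)],
                   options={"maxiter": 30})
    x = res.x
    return math.exp(x[0]), math.exp(x[1]), x


# ----------------------------------------------------------------------
# Fisher-score accumulation (for standard errors)
# ----------------------------------------------------------------------

def _score_layout(st: _Structure):
    labels = []
    for p in np.where(st.est_mu & st.active)[0]:
        labels.append(("mu", PARAM_NAMES[p]))
    for (p, c) in st.coeffs:
        labels.append(("beta", f"{p}:{c}"))
    for p in np.where(st.active)[0]:
        labels.append(("var", PARAM_NAMES[p]))
    for (p, q) in st.corr_pairs:
        labels.append(("cov", f"{p}:{q}"))
    labels.append(("err", "a"))
    labels.append(("err", "b"))
    return labels


def _score_contributions(enc, st, sampler, M, omega_var, corr, a, b,
                         psi_bar, psi2_bar):
    """Per-subject marginal scores via Fisher's identity (chain averages)."""
    labels = _score_layout(st)
    n = enc.n_subj
    adim = np.where(st.active)[0]
    om = _omega_matrix(omega_var, corr)[np.ix_(adim, adim)]
    om_inv = np.linalg.inv(_nearest_psd(om, 1e-12))

    eta_bar = (psi_bar - M)[:, adim]
    Eee = (psi2_bar - np.einsum("nj,nk->njk", psi_bar, M)
           - np.einsum("nj,nk->njk", M, psi_bar)
           + np.einsum("nj,nk->njk", M, M))[:, adim[:, None], adim[None, :]]
    g_mean_full = np.zeros((n, _NP))
    g_mean_full[:, adim] = eta_bar @ om_inv
    W = 0.5 * (np.einsum("jk,nkl,lm->njm", om_inv, Eee, om_inv) - om_inv)

    # error-model scores per subject (uncensored observations only)
    pred = sampler.pred
    y = enc.obs_value[:, None]
    v = a * a + (b * pred) ** 2
    core = ((y - pred) ** 2 / v ** 2 - 1.0 / v)
    core[enc.obs_cens] = 0.0
    ga_obs = (a * core).mean(axis=1)
    gb_obs = (b * pred ** 2 * core).mean(axis=1)
    ga = np.zeros(n)
    gb = np.zeros(n)
    np.add.at(ga, enc.obs_subj, ga_obs)
    np.add.at(gb, enc.obs_subj, gb_obs)

    cols = []
    pos = {d: j for j, d in enumerate(adim)}
    for kind, name in labels:
        if kind == "mu":
            cols.append(g_mean_full[:, _IDX[name]])
        elif kind == "beta":
            p, c = name.split(":")
            cols.append(g_mean_full[:, _IDX[p]] * st.covmat[c])
        elif kind == "var":
            j = pos[_IDX[name]]
            cols.append(W[:, j, j])
        elif kind == "cov":
            p, q = name.split(":")
            cols.append(2.0 * W[:, pos[_IDX[p]], pos[_IDX[q]]])
        elif name == "a":
            cols.append(ga)
        else:
            cols.append(gb)
    return np.column_stack(cols), labels


def _rse_from_scores(fit: FitResult, model: PopulationModel) -> Dict[str, float]:
    S = fit.score_matrix
    info = S.T @ S
    try:
        cov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:
        return {}
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    out: Dict[str, float] = {}
    for (kind, name), s in zip(fit.score_labels, se):
        if kind == "mu":
            mu = model.fixed.mu[name]
            if name in ("Ftot", "F0"):
                out[name] = 100.0 * s * (1.0 - mu)
            else:
                out[name] = 100.0 * s
        elif kind == "beta":
            p, c = name.split(":")
            val = model.fixed.beta_cov.get((p, c), math.nan)
            out[f"beta({p},{c})"] = 100.0 * s / abs(val) if val else math.nan
        elif kind == "var":
            w = model.random.omega[name]
            out[f"omega_{name}"] = 100.0 * s / (2.0 * w * w) if w else math.nan
        elif kind == "cov":
            p, q = name.split(":")
            wp, wq = model.random.omega[p], model.random.omega[q]
            r = model.random.corr.get((p, q), math.nan)
            out[f"corr({p},{q})"] = (100.0 * s / (wp * wq) / abs(r)
                                     if r else math.nan)
        else:
            val = getattr(model.error, name)
            out[name] = 100.0 * s / abs(val) if val else math.nan
    return out


def compute_rse(fit: FitResult, dataset: PKDataset) -> Dict[str, float]:
    """Relative standard errors (%) from the observed Fisher information.

    Uses the cross-product of per-subject marginal scores accumulated
    during the smoothing phase (Fisher's identity).  Frozen parameters
    carry no entry; singular directions are reported as NaN.
    """
    if fit.score_matrix is None:
        raise ValueError("fit was run without score accumulation "
                         "(settings.compute_rse=False)")
    if fit.score_matrix.shape[0] != dataset.n_subjects:
        raise ValueError("dataset does not match the fitted subjects")
    return _rse_from_scores(fit, fit.model)


# ----------------------------------------------------------------------
# EBEs, posterior samples, conditional sampling
# ----------------------------------------------------------------------

def _compute_ebes(enc, st, M, omega_var, corr, a, b, cond_mean):
    adim = np.where(st.active)[0]
    ebes: Dict[int, np.ndarray] = {}
    if not adim.size:
        for i, sid in enumerate(enc.subject_ids):
            ebes[sid] = np.zeros(_NP)
        return ebes
    om = _omega_matrix(omega_var, corr)[np.ix_(adim, adim)]
    om_inv = np.linalg.inv(_nearest_psd(om, 1e-12))

    for i, sid in enumerate(enc.subject_ids):
        def neg_post(x, i=i):
            psi = M[i].copy()
            psi[adim] = x
            pred = enc.predict_subject(i, _back_transform(psi[None, :]))[:, 0]
            sd = np.sqrt(a * a + (b * pred) ** 2)
            yv = enc.obs_value[enc.subj_obs_idx[i]]
            cens = enc.obs_cens[enc.subj_obs_idx[i]]
            lloq = enc.obs_lloq[enc.subj_obs_idx[i]]
            from .encode import interval_logprob
            with np.errstate(invalid="ignore", over="ignore"):
                r = (yv - pred) / sd
                ll = np.where(cens,
                              interval_logprob((lloq - pred) / sd, -pred / sd),
                              -0.5 * r * r - np.log(sd))
            ll = np.nan_to_num(ll, nan=-1e8, neginf=-1e8)
            e = x - M[i][adim]
            return -(ll.sum() - 0.5 * e @ om_inv @ e)

        res = minimize(neg_post, cond_mean[i][adim], method="L-BFGS-B",
                       options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9})
        eta = np.zeros(_NP)
        eta[adim] = res.x - M[i][adim]
        ebes[sid] = eta
    return ebes


def extract_posteriors(fit: FitResult) -> Dict[int, np.ndarray]:
    """Per-subject (n_chains, 8) eta draws from the final SAEM iteration."""
    return fit.posterior_samples


def extract_ebes(fit: FitResult) -> Dict[int, np.ndarray]:
    """Per-subject conditional-mode etas (empirical Bayes estimates)."""
    return fit.ebes


def evaluate_at(model: PopulationModel, dataset: PKDataset,
                n_chains: int = 10, n_iter: int = 300,
                seed: int = 0) -> FitResult:
    """Wrap a *given* population model as a :class:`FitResult`.

    No population parameters are estimated: the conditional
    distributions are sampled at the supplied model, yielding EBEs and
    posterior samples for diagnostics (residuals, NPDE, VPC) of a model
    obtained elsewhere.  Log-likelihood fields are left NaN; call
    :func:`estimate_loglik_is` if needed.
    """
    posterior, ebes = conditional_samples(model, dataset, n_chains,
                                          n_iter, seed)
    enc = EncodedData(dataset)
    st = _Structure(model, dataset, fixed_flags=PARAM_NAMES)
    tmu = np.array([transform_value(p, model.fixed.mu[p])
                    for p in PARAM_NAMES])
    M = st.mean_matrix(tmu, model.fixed.beta_cov, enc.n_subj)
    draws = np.stack([posterior[sid] for sid in enc.subject_ids])
    cond_mean = M + draws.mean(axis=1)
    psi = M[:, None, :] + draws
    cond_cov = (np.einsum("ncj,nck->njk", psi, psi) / draws.shape[1]
                - np.einsum("nj,nk->njk", cond_mean, cond_mean))
    return FitResult(
        model=model.copy(), fixed_flags=tuple(PARAM_NAMES),
        loglik=math.nan, loglik_se=math.nan, bic=math.nan, rse={},
        ebes=ebes, posterior_samples=posterior,
        convergence_trace=pd.DataFrame(), n_subjects=enc.n_subj,
        n_params=0, settings=SaemSettings(n_chains=n_chains, seed=seed),
        cond_mean=cond_mean, cond_cov=cond_cov,
    )


def conditional_samples(model: PopulationModel, dataset: PKDataset,
                        n_chains: int = 10, n_iter: int = 300,
                        seed: int = 0) -> Tuple[Dict[int, np.ndarray],
                                                Dict[int, np.ndarray]]:
    """Sample p(eta | data) at fixed population parameters.

    Runs the MH kernels for ``n_iter`` sweeps and returns the final
    chain states (one eta vector per chain per subject) together with
    the conditional modes (EBEs).  Useful for shrinkage and correlation
    diagnostics without re-estimating the model.
    """
    st = _Structure(model, dataset, fixed_flags=PARAM_NAMES)
    enc = EncodedData(dataset)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sampler = _Sampler(enc, st, n_chains, rng)
    tmu = np.array([transform_value(p, model.fixed.mu[p])
                    for p in PARAM_NAMES])
    M = st.mean_matrix(tmu, model.fixed.beta_cov, enc.n_subj)
    omega_var = model.random.omega_vector() ** 2
    corr = dict(model.random.corr)
    a, b = max(model.error.a, 1e-8), max(model.error.b, 1e-8)
    sampler.initialize(M, omega_var, corr)
    sampler.refresh(M, omega_var, corr, a, b)
    mean_psi = np.zeros((enc.n_subj, _NP))
    for k in range(n_iter):
        sampler.sweep(a, b, adapt_rate=0.2 if k < n_iter // 2 else 0.0)
        if k >= n_iter // 2:
            mean_psi += sampler.psi.mean(axis=1)
    mean_psi /= max(n_iter - n_iter // 2, 1)
    posterior = {sid: (sampler.psi[i] - M[i]).copy()
                 for i, sid in enumerate(enc.subject_ids)}
    ebes = _compute_ebes(enc, st, M, omega_var, corr, a, b, mean_psi)
    return posterior, ebes


# ----------------------------------------------------------------------
# marginal log-likelihood by importance sampling
# ----------------------------------------------------------------------

def estimate_loglik_is(fit: FitResult, dataset: PKDataset,
                       n_is_samples: int = 10000,
                       seed: int = 0, df: float = 5.0
                       ) -> Tuple[float, float]:
    """Importance-sampling estimate of the marginal log-likelihood.

    Per subject, etas are proposed from a heavy-tailed (Student-t,
    ``df`` degrees of freedom) location-scale fit to the conditional
    distribution recorded during the smoothing phase.  Returns the
    estimate and its Monte-Carlo standard error; a low effective sample
    size (< 5%) appends a warning to the fit.
    """
    model = fit.model
    enc = EncodedData(dataset)
    st = _Structure(model, dataset, fixed_flags=PARAM_NAMES)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tmu = np.array([transform_value(p, model.fixed.mu[p])
                    for p in PARAM_NAMES])
    M = st.mean_matrix(tmu, model.fixed.beta_cov, enc.n_subj)
    omega_var = model.random.omega_vector() ** 2
    adim = np.where(omega_var > 0)[0]
    a, b = max(model.error.a, 1e-12), max(model.error.b, 1e-12)

    def subject_ll_y(i, psi_mat):
        pred = enc.predict_subject(i, _back_transform(psi_mat))
        idx = enc.subj_obs_idx[i]
        sd = np.sqrt(a * a + (b * pred) ** 2)
        yv = enc.obs_value[idx][:, None]
        cens = enc.obs_cens[idx][:, None]
        lloq = enc.obs_lloq[idx][:, None]
        from .encode import interval_logprob
        with np.errstate(invalid="ignore", over="ignore"):
            r = (yv - pred) / sd
            ll = np.where(cens,
                          interval_logprob((lloq - pred) / sd, -pred / sd),
                          -0.5 * r * r - np.log(sd)
                          - 0.5 * math.log(2 * math.pi))
        ll = np.nan_to_num(ll, nan=-1e8, neginf=-1e8)
        return ll.sum(axis=0)

    if not adim.size:
        total = sum(float(subject_ll_y(i, M[i][None, :])[0])
                    for i in range(enc.n_subj))
        return total, 0.0

    om = _omega_matrix(omega_var, model.random.corr)[np.ix_(adim, adim)]
    om = _nearest_psd(om, 1e-12)
    om_inv = np.linalg.inv(om)
    _, logdet_om = np.linalg.slogdet(om)
    da = adim.size
    const_prior = -0.5 * (da * math.log(2 * math.pi) + logdet_om)

    total, var_total = 0.0, 0.0
    min_ess = math.inf
    for i in range(enc.n_subj):
        mean_i = (fit.cond_mean[i][adim] if fit.cond_mean is not None
                  else M[i][adim])
        cov_i = (fit.cond_cov[i][np.ix_(adim, adim)]
                 if fit.cond_cov is not None else om)
        cov_i = _nearest_psd(cov_i + 1e-10 * np.eye(da), 1e-12)
        L = np.linalg.cholesky(cov_i)
        _, logdet_c = np.linalg.slogdet(cov_i)

        z = rng.standard_normal((n_is_samples, da))
        g = rng.chisquare(df, n_is_samples) / df
        x = mean_i + (z / np.sqrt(g)[:, None]) @ L.T
        # multivariate-t log-density of the proposal
        dev = x - mean_i
        sol = np.linalg.solve(L, dev.T)
        q = np.sum(sol ** 2, axis=0)
        logq = (gammaln((df + da) / 2) - gammaln(df / 2)
                - 0.5 * da * math.log(df * math.pi) - 0.5 * logdet_c
                - 0.5 * (df + da) * np.log1p(q / df))
        psi = np.tile(M[i], (n_is_samples, 1))
        psi[:, adim] = x
        e = x - M[i][adim]
        logprior = const_prior - 0.5 * np.einsum("nj,jk,nk->n", e, om_inv, e)
        lw = subject_ll_y(i, psi) + logprior - logq
        m = lw.max()
        w = np.exp(lw - m)
        sw = w.sum()
        ll_i = m + math.log(sw / n_is_samples)
        wn = w / sw
        ess = 1.0 / np.sum(wn ** 2)
        min_ess = min(min_ess, ess)
        var_total += float(np.var(w) / (n_is_samples * (sw / n_is_samples) ** 2))
        total += float(ll_i)
    if min_ess < 0.05 * n_is_samples:
        fit.warnings.append(
            f"importance sampling ESS low (min {min_ess:.0f} of "
            f"{n_is_samples})")
    return total, math.sqrt(var_total)
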