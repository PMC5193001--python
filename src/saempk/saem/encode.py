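"""Flattened array representation of a dataset for fast batched likelihoods.

The estimation engine evaluates the structural model for every subject
and every MCMC chain at once.  To do so the dataset is flattened into
per-observation arrays plus (dose event, observation) pairs restricted
to the same subject and occasion with the observation at or after the
dose; predictions are accumulated over pairs by scatter-add.  Predose
(time-0) samples are excluded from the likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

from ..dataset import PKDataset
from ..structural import (MGL_TO_NGML, bolus_unit_conc, impulse_terms,
                          sc_unit_conc)

_LOG_2PI = float(np.log(2.0 * np.pi))
#: floor for a censored-interval log-probability (finite, never -inf)
CENSOR_LL_FLOOR = -1e8


def interval_logprob(zu, zl):
    """log[Phi(zu) - Phi(zl)] for zl <= zu, computed stably in log space."""
    lu = log_ndtr(zu)
    ll = log_ndtr(zl)
    d = ll - lu
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        out = np.where(d < -36.0, lu, lu + np.log1p(-np.exp(np.minimum(d, -1e-300))))
    return np.maximum(out, CENSOR_LL_FLOOR)


class EncodedData:
    """Array view of a :class:`PKDataset` used by the SAEM engine."""

    def __init__(self, dataset: PKDataset, include_predose: bool = False):
        self.dataset = dataset
        self.subject_ids = [s.subject_id for s in dataset.subjects]
        sidx = {sid: i for i, sid in enumerate(self.subject_ids)}
        self.n_subj = len(self.subject_ids)

        obs = [o for o in dataset.observations
               if include_predose or not o.predose]
        self.observations = obs
        self.n_obs = len(obs)
        self.obs_subj = np.array([sidx[o.subject_id] for o in obs], dtype=int)
        self.obs_time = np.array([o.time for o in obs])
        self.obs_occ = np.array([o.occasion for o in obs], dtype=int)
        self.obs_cens = np.array([o.censored for o in obs], dtype=bool)
        self.obs_lloq = np.array([o.lloq for o in obs])
        self.obs_value = np.array(
            [0.0 if o.value is None else o.value for o in obs])
        self.obs_predose = np.array([o.predose for o in obs], dtype=bool)

        iv_pairs, sc_pairs = [], []
        for d in dataset.doses:
            i = sidx.get(d.subject_id)
            if i is None:
                continue
            match = np.where((self.obs_subj == i)
                             & (self.obs_occ == d.occasion)
                             & (self.obs_time >= d.time))[0]
            bucket = iv_pairs if d.route == "IV" else sc_pairs
            for j in match:
                bucket.append((j, i, self.obs_time[j] - d.time, d.amount))

        def _pack(pairs):
            if not pairs:
                return (np.zeros(0, dtype=int), np.zeros(0, dtype=int),
                        np.zeros(0), np.zeros(0))
            a = np.array(pairs, dtype=float)
            return (a[:, 0].astype(int), a[:, 1].astype(int), a[:, 2], a[:, 3])

        (self.iv_obs, self.iv_subj, self.iv_dt, self.iv_amt) = _pack(iv_pairs)
        (self.sc_obs, self.sc_subj, self.sc_dt, self.sc_amt) = _pack(sc_pairs)

        # per-subject views for subject-local evaluation (EBE, importance sampling)
        self.subj_obs_idx = [np.where(self.obs_subj == i)[0]
                             for i in range(self.n_subj)]

    # ------------------------------------------------------------------
    def predict(self, phi: np.ndarray) -> np.ndarray:
        """Predicted concentrations (n_obs, C) for phi of shape (n_subj, C, 8)."""
        C = phi.shape[1]
        alpha, beta, a_c, b_c = impulse_terms(
            phi[..., 4], phi[..., 5], phi[..., 6], phi[..., 7])
        pred = np.zeros((self.n_obs, C))
        if self.iv_obs.size:
            ia = self.iv_subj
            c = bolus_unit_conc(alpha[ia], beta[ia], a_c[ia], b_c[ia],
                                self.iv_dt[:, None])
            np.add.at(pred, self.iv_obs,
                      MGL_TO_NGML * self.iv_amt[:, None] * c)
        if self.sc_obs.size:
            ia = self.sc_subj
            c = sc_unit_conc(alpha[ia], beta[ia], a_c[ia], b_c[ia],
                             phi[ia, :, 0], phi[ia, :, 1],
                             phi[ia, :, 2], phi[ia, :, 3],
                             self.sc_dt[:, None])
            np.add.at(pred, self.sc_obs,
                      MGL_TO_NGML * self.sc_amt[:, None] * c)
        return pred

    def predict_subject(self, i: int, phi: np.ndarray) -> np.ndarray:
        """Predictions (n_obs_i, k) for subject ``i``.

        ``phi`` holds natural-scale parameter vectors, shape (k, 8).
        """
        phi = np.atleast_2d(phi)
        idx = self.subj_obs_idx[i]
        alpha, beta, a_c, b_c = impulse_terms(
            phi[:, 4], phi[:, 5], phi[:, 6], phi[:, 7])
        pred = np.zeros((self.n_obs, phi.shape[0]))
        sel_iv = self.iv_subj == i
        if sel_iv.any():
            c = bolus_unit_conc(alpha[None, :], beta[None, :],
                                a_c[None, :], b_c[None, :],
                                self.iv_dt[sel_iv, None])
            np.add.at(pred, self.iv_obs[sel_iv],
                      MGL_TO_NGML * self.iv_amt[sel_iv, None] * c)
        sel_sc = self.sc_subj == i
        if sel_sc.any():
            c = sc_unit_conc(alpha[None, :], beta[None, :],
                             a_c[None, :], b_c[None, :],
                             phi[None, :, 0], phi[None, :, 1],
                             phi[None, :, 2], phi[None, :, 3],
                             self.sc_dt[sel_sc, None])
            np.add.at(pred, self.sc_obs[sel_sc],
                      MGL_TO_NGML * self.sc_amt[sel_sc, None] * c)
        return pred[idx]

    # ------------------------------------------------------------------
    def loglik_obs(self, pred: np.ndarray, a: float, b: float) -> np.ndarray:
        """Per-observation log-likelihood (n_obs, C).

        Uncensored samples contribute a normal log-density; censored
        (BLQ) samples contribute the log-probability of the interval
        [0, LLOQ] under the prediction (M3 convention).
        """
        sd = np.sqrt(a * a + (b * pred) ** 2)
        r = (self.obs_value[:, None] - pred) / sd
        ll_unc = -0.5 * r * r - np.log(sd) - 0.5 * _LOG_2PI
        if self.obs_cens.any():
            zu = (self.obs_lloq[:, None] - pred) / sd
            zl = (0.0 - pred) / sd
            ll_cens = interval_logprob(zu, zl)
            out = np.where(self.obs_cens[:, None], ll_cens, ll_unc)
        else:
            out = ll_unc
        return np.nan_to_num(out, nan=CENSOR_LL_FLOOR,
                             neginf=CENSOR_LL_FLOOR)

    def loglik_subjects(self, pred: np.ndarray, a: float, b: float) -> np.ndarray:
        """Per-subject log-likelihood (n_subj, C)."""
        ll = self.loglik_obs(pred, a, b)
        out = np.zeros((self.n_subj, ll.shape[1]))
        np.add.at(out, self.obs_subj, ll)
        return out

    # ------------------------------------------------------------------
    def simulate(self, pred: np.ndarray, a: float, b: float, rng) -> np.ndarray:
        """Replicate observations with combined noise truncated at zero.

        Matches the generative convention of the simulation module: the
        assay reports no negative concentrations, so a value below the
        LLOQ genuinely lies in [0, LLOQ].
        """
        from scipy.special import ndtr, ndtri
        sd = np.sqrt(a * a + (b * pred) ** 2)
        lo = ndtr(-pred / sd)
        u = rng.uniform(lo, 1.0)
        return pred + sd * ndtri(np.clip(u, 1e-16, 1.0 - 1e-16))
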