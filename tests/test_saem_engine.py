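"""SAEM estimation engine: conditional sampling against quadrature
oracles, parameter recovery, frozen effects, importance-sampling
likelihood and standard errors."""

import copy
import math

import numpy as np
import pytest
from scipy.special import logsumexp

import saempk as sp
from saempk.popmodel import transform_value, transformed_mean
from saempk.saem import (SaemSettings, compute_rse, conditional_samples,
                         estimate_loglik_is, evaluate_at, saem_fit)
from saempk.saem.encode import EncodedData
from saempk.saem.engine import _back_transform, _Sampler, _Structure
from saempk.structural import PARAM_NAMES

from conftest import make_one_compartment_dataset


# ----------------------------------------------------------------------
# a single-subject toy with one random effect (V1): the conditional
# p(eta | y) is one-dimensional and can be integrated on a grid
# ----------------------------------------------------------------------

def _single_subject_problem(omega=0.3, a=50.0, seed=0):
    truth = sp.PopulationModel(
        fixed=sp.FixedEffects(
            mu={"Ftot": 0.5, "F0": 0.5, "ka": 1.0, "Tk0": 1.0,
                "CL": 0.5, "V1": 0.16, "Q": 1e-12, "V2": 1.0}),
        random=sp.RandomEffectsSpec(omega={"V1": omega}),
        error=sp.ErrorModel(a=a, b=0.0))
    rng = np.random.default_rng(seed)
    s = sp.SubjectRecord(1, 3.5, 1.0, "F", 0, "toy")
    d = sp.DoseEvent(1, 0.0, 2.0, "IV")
    t = np.array([0.25, 1.0, 3.0])
    p = sp.individual_params(truth, {"V1": 0.2}, s)
    y = sp.predict_profile(p, [d], t) + a * rng.standard_normal(3)
    obs = [sp.Observation(1, float(tj), float(yj), False, 1e-6)
           for tj, yj in zip(t, y)]
    return truth, sp.PKDataset([s], [d], obs)


def _grid_posterior(model, ds):
    """Quadrature oracle for the 1-D conditional of eta_V1."""
    enc = EncodedData(ds)
    m = transformed_mean(model, ds.subjects[0])
    j = PARAM_NAMES.index("V1")
    omega = model.random.omega["V1"]
    grid = np.linspace(-5 * omega, 5 * omega, 4001)
    psi = np.tile(m, (grid.size, 1))
    psi[:, j] = m[j] + grid
    pred = enc.predict_subject(0, _back_transform(psi))
    yv = enc.obs_value[:, None]
    ll = (-0.5 * ((yv - pred) / model.error.a) ** 2).sum(axis=0)
    logpost = ll - 0.5 * (grid / omega) ** 2
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    mean = float(np.sum(w * grid))
    var = float(np.sum(w * grid ** 2) - mean ** 2)
    mode = float(grid[np.argmax(logpost)])
    return mean, var, mode


def test_mcmc_conditional_matches_quadrature_oracle():
    model, ds = _single_subject_problem()
    mean, var, _ = _grid_posterior(model, ds)
    st = _Structure(model, ds, fixed_flags=PARAM_NAMES)
    enc = EncodedData(ds)
    rng = np.random.default_rng(5)
    sampler = _Sampler(enc, st, n_chains=10, rng=rng)
    tmu = np.array([transform_value(p, model.fixed.mu[p])
                    for p in PARAM_NAMES])
    M = st.mean_matrix(tmu, {}, 1)
    omega_var = model.random.omega_vector() ** 2
    sampler.initialize(M, omega_var, {})
    sampler.refresh(M, omega_var, {}, model.error.a, 1e-12)
    j = PARAM_NAMES.index("V1")
    draws = []
    for k in range(5500):
        sampler.sweep(model.error.a, 1e-12, adapt_rate=0.2 if k < 500 else 0.0)
        if k >= 500:
            draws.append(sampler.psi[0, :, j] - M[0, j])
    draws = np.concatenate(draws)   # 50,000 conditional samples
    assert draws.mean() == pytest.approx(mean, abs=0.02 * math.sqrt(var))
    assert draws.var() == pytest.approx(var, rel=0.05)


def test_degenerate_kernel_keeps_chain_constant():
    model, ds = _single_subject_problem()
    st = _Structure(model, ds, fixed_flags=PARAM_NAMES)
    enc = EncodedData(ds)
    sampler = _Sampler(enc, st, n_chains=4, rng=np.random.default_rng(0))
    tmu = np.array([transform_value(p, model.fixed.mu[p])
                    for p in PARAM_NAMES])
    M = st.mean_matrix(tmu, {}, 1)
    omega_var = model.random.omega_vector() ** 2
    sampler.initialize(M, omega_var, {})
    # start every chain exactly at the population mean so that zero-width
    # kernels propose the current state
    sampler.psi[:] = M[:, None, :]
    sampler.refresh(M, omega_var, {}, model.error.a, 1e-12)
    psi0 = sampler.psi.copy()
    sampler.steps_cw[:] = 0.0
    sampler.steps_full[:] = 0.0
    sampler.steps_adapt[:] = 0.0
    sampler.L[:] = 0.0
    sampler.sweep(model.error.a, 1e-12, adapt_rate=0.0)
    np.testing.assert_array_equal(sampler.psi, psi0)


def test_acceptance_rates_adapt_into_target_band(reference_model,
                                                 study_dataset):
    st = _Structure(reference_model, study_dataset, fixed_flags=PARAM_NAMES)
    enc = EncodedData(study_dataset)
    sampler = _Sampler(enc, st, n_chains=3, rng=np.random.default_rng(1))
    tmu = np.array([transform_value(p, reference_model.fixed.mu[p])
                    for p in PARAM_NAMES])
    M = st.mean_matrix(tmu, reference_model.fixed.beta_cov, enc.n_subj)
    omega_var = reference_model.random.omega_vector() ** 2
    corr = dict(reference_model.random.corr)
    a, b = reference_model.error.a, reference_model.error.b
    sampler.initialize(M, omega_var, corr)
    sampler.refresh(M, omega_var, corr, a, b)
    accs = []
    for k in range(200):
        lp = sampler._logprior(sampler.psi)
        psi_new = sampler.psi.copy()
        adim = sampler.adim
        z = np.random.default_rng(k).standard_normal(
            (enc.n_subj, 3, adim.size))
        psi_new[:, :, adim] = psi_new[:, :, adim] \
            + sampler.steps_full[:, None, None] * (z @ sampler.L.T)
        lp_new = sampler._logprior(psi_new)
        acc = sampler._accept(psi_new, a, b, extra_delta=lp_new - lp)
        accs.append(acc.mean())
        sampler.steps_full *= np.exp(0.2 * (acc.mean(axis=1) - 0.3))
    assert 0.2 <= np.mean(accs[-50:]) <= 0.5


def test_ebe_matches_posterior_mode_oracle():
    model, ds = _single_subject_problem()
    _, _, mode = _grid_posterior(model, ds)
    fit = evaluate_at(model, ds, n_chains=5, n_iter=200, seed=2)
    j = PARAM_NAMES.index("V1")
    assert fit.ebes[1][j] == pytest.approx(mode, abs=1e-3)


def test_ebes_vanish_when_omega_tiny():
    model, ds = _single_subject_problem(omega=1e-4)
    fit = evaluate_at(model, ds, n_chains=4, n_iter=100, seed=3)
    assert abs(fit.ebes[1][PARAM_NAMES.index("V1")]) < 1e-3


# ----------------------------------------------------------------------
# saem_fit
# ----------------------------------------------------------------------

def test_noise_free_no_iiv_recovers_mu_deterministically():
    """omega = 0, near-zero noise: the direct-optimization update drives
    the typical values to the data-generating ones."""
    ds, truth, _ = make_one_compartment_dataset(
        n_subjects=12, seed=3, a=1e-3, b=1e-6, omega=0.0)
    init = truth.copy()
    init.fixed.mu.update({"CL": 0.4, "V1": 0.12})
    init.error = sp.ErrorModel(a=1e-2, b=1e-4)
    fit = saem_fit(ds, init,
                   fixed_flags=("Ftot", "F0", "ka", "Tk0", "Q", "V2"),
                   settings=SaemSettings(n_chains=1, n_explore=60,
                                         n_smooth=40, seed=0,
                                         compute_loglik=False,
                                         compute_rse=False))
    assert fit.model.fixed.mu["CL"] == pytest.approx(0.5, rel=1e-3)
    assert fit.model.fixed.mu["V1"] == pytest.approx(0.16, rel=1e-3)


def test_frozen_fixed_effects_bit_identical(one_compartment, quick_settings):
    ds, truth, _ = one_compartment
    init = truth.copy()
    init.fixed.mu["CL"] = 0.3717
    fit = saem_fit(ds, init, fixed_flags=("Ftot", "F0", "ka", "Tk0", "Q",
                                          "V2", "CL"),
                   settings=quick_settings)
    assert fit.model.fixed.mu["CL"] == 0.3717
    assert fit.model.fixed.mu["ka"] == init.fixed.mu["ka"]
    assert "CL" not in fit.rse  # frozen parameters carry no RSE entry


def test_one_compartment_recovery_over_seeds():
    """Known-truth self-consistency: estimates center on the truth and
    the reported RSEs are calibrated against the seed-to-seed scatter."""
    cl_est, v1_est, cl_rse, v1_rse = [], [], [], []
    for seed in range(20):
        ds, truth, _ = make_one_compartment_dataset(n_subjects=60, seed=seed)
        init = truth.copy()
        init.fixed.mu.update({"CL": 0.35, "V1": 0.25})
        init.random.omega.update({"CL": 0.35, "V1": 0.35})
        init.error = sp.ErrorModel(a=1.0, b=0.2)
        fit = saem_fit(ds, init,
                       fixed_flags=("Ftot", "F0", "ka", "Tk0", "Q", "V2"),
                       settings=SaemSettings(n_chains=3, n_explore=100,
                                             n_smooth=80, seed=1000 + seed,
                                             compute_loglik=False))
        cl_est.append(fit.model.fixed.mu["CL"])
        v1_est.append(fit.model.fixed.mu["V1"])
        cl_rse.append(fit.rse.get("CL", np.nan))
        v1_rse.append(fit.rse.get("V1", np.nan))
    cl_est, v1_est = np.array(cl_est), np.array(v1_est)
    for est, true in ((cl_est, 0.5), (v1_est, 0.16)):
        sd = est.std(ddof=1)
        n_ok = int(np.sum(np.abs(est - true) <= 2 * sd))
        assert n_ok >= 18
        assert abs(est.mean() - true) <= 3 * sd / math.sqrt(20)
    # RSE calibration: reported SE tracks the empirical scatter
    for est, rse, true in ((cl_est, cl_rse, 0.5), (v1_est, v1_rse, 0.16)):
        implied = np.nanmean(rse) / 100 * true
        assert 0.6 <= implied / est.std(ddof=1) <= 1.6


def test_rse_shrinks_with_replication():
    ds1, truth, _ = make_one_compartment_dataset(n_subjects=40, seed=2)
    ds4, _, _ = make_one_compartment_dataset(n_subjects=160, seed=2)
    init = truth.copy()
    init.error = sp.ErrorModel(a=1.0, b=0.2)
    settings = SaemSettings(n_chains=3, n_explore=100, n_smooth=80, seed=9,
                            compute_loglik=False)
    f1 = saem_fit(ds1, init, ("Ftot", "F0", "ka", "Tk0", "Q", "V2"), settings)
    f4 = saem_fit(ds4, init, ("Ftot", "F0", "ka", "Tk0", "Q", "V2"), settings)
    ratio = f1.rse["CL"] / f4.rse["CL"]
    assert ratio == pytest.approx(2.0, rel=0.35)  # ~ 1/sqrt(4)


def test_reproducible_under_seed(one_compartment):
    ds, truth, _ = one_compartment
    settings = SaemSettings(n_chains=2, n_explore=40, n_smooth=30, seed=5,
                            compute_loglik=False, compute_rse=False)
    f1 = saem_fit(ds, truth, ("Ftot", "F0", "ka", "Tk0", "Q", "V2"), settings)
    f2 = saem_fit(ds, truth, ("Ftot", "F0", "ka", "Tk0", "Q", "V2"), settings)
    assert f1.model.fixed.mu == f2.model.fixed.mu
    assert f1.model.random.omega == f2.model.random.omega


# ----------------------------------------------------------------------
# importance-sampling likelihood
# ----------------------------------------------------------------------

def test_is_loglik_equals_complete_loglik_when_no_iiv():
    ds, truth, _ = make_one_compartment_dataset(n_subjects=5, seed=4,
                                                omega=0.0)
    fit = evaluate_at(truth, ds, n_chains=2, n_iter=20, seed=0)
    ll, se = estimate_loglik_is(fit, ds, 100, seed=1)
    from saempk.saem import complete_loglik
    expected = complete_loglik(truth, ds,
                               {s.subject_id: np.zeros(8)
                                for s in ds.subjects})
    assert ll == pytest.approx(expected, abs=1e-9)
    assert se == 0.0


def test_is_loglik_matches_prior_monte_carlo_oracle():
    ds, truth, _ = make_one_compartment_dataset(n_subjects=8, seed=6)
    fit = evaluate_at(truth, ds, n_chains=10, n_iter=300, seed=0)
    ll, se = estimate_loglik_is(fit, ds, 8000, seed=1)

    # oracle: naive Monte-Carlo from the prior, subject by subject
    enc = EncodedData(ds)
    rng = np.random.default_rng(99)
    active = truth.random.omega_vector() > 0
    cov = truth.random.covariance()[np.ix_(active, active)]
    L = np.linalg.cholesky(cov)
    M = np.vstack([transformed_mean(truth, s) for s in ds.subjects])
    total, mc_var = 0.0, 0.0
    n_mc = 200_000
    for i in range(enc.n_subj):
        z = rng.standard_normal((n_mc, int(active.sum())))
        psi = np.tile(M[i], (n_mc, 1))
        psi[:, active] += z @ L.T
        pred = enc.predict_subject(i, _back_transform(psi))
        sd = np.sqrt(truth.error.a ** 2 + (truth.error.b * pred) ** 2)
        yv = enc.obs_value[enc.subj_obs_idx[i]][:, None]
        llv = (-0.5 * ((yv - pred) / sd) ** 2 - np.log(sd)
               - 0.5 * math.log(2 * math.pi)).sum(axis=0)
        w = np.exp(llv - llv.max())
        total += llv.max() + math.log(w.mean())
        mc_var += float(w.var() / (n_mc * w.mean() ** 2))
    assert ll == pytest.approx(total,
                               abs=3 * math.sqrt(se ** 2 + mc_var))


def test_is_loglik_se_scales_with_samples():
    ds, truth, _ = make_one_compartment_dataset(n_subjects=10, seed=7)
    fit = evaluate_at(truth, ds, n_chains=8, n_iter=200, seed=0)
    ses_small = [estimate_loglik_is(fit, ds, 1000, seed=s)[1]
                 for s in range(5)]
    ses_big = [estimate_loglik_is(fit, ds, 4000, seed=s)[1]
               for s in range(5)]
    ratio = np.mean(ses_small) / np.mean(ses_big)
    assert ratio == pytest.approx(2.0, rel=0.3)  # sqrt(4)


# ----------------------------------------------------------------------
# posterior samples and pooled dispersion
# ----------------------------------------------------------------------

def test_posterior_sample_counts(one_compartment, quick_settings):
    ds, truth, _ = one_compartment
    fit = saem_fit(ds, truth, ("Ftot", "F0", "ka", "Tk0", "Q", "V2"),
                   SaemSettings(n_chains=4, n_explore=50, n_smooth=40,
                                seed=3, compute_loglik=False,
                                compute_rse=False))
    assert all(v.shape == (4, 8) for v in fit.posterior_samples.values())
    assert len(fit.posterior_samples) == ds.n_subjects


def test_pooled_posterior_dispersion_matches_omega(one_compartment):
    """Draws from the conditional pooled over subjects recover the
    population dispersion even though EBEs shrink."""
    ds, truth, etas = one_compartment
    post, ebes = conditional_samples(truth, ds, n_chains=10, n_iter=400,
                                     seed=4)
    pooled = np.vstack([post[sid] for sid in post])
    eb = np.vstack([ebes[sid] for sid in ebes])
    for name in ("CL", "V1"):
        j = PARAM_NAMES.index(name)
        w = truth.random.omega[name]
        assert pooled[:, j].var() == pytest.approx(w * w, rel=0.10)
        assert eb[:, j].var() <= pooled[:, j].var() + 1e-12
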