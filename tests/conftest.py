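"""Shared fixtures: small synthetic datasets and reduced fit settings."""

import numpy as np
import pytest

import saempk as sp
from saempk.popmodel import truncated_noise
from saempk.structural import PARAM_NAMES


@pytest.fixture(scope="session")
def reference_model():
    return sp.robenacoxib_reference_model()


@pytest.fixture(scope="session")
def study_dataset(reference_model):
    """One realization of the full synthetic study."""
    return sp.generate_study(sp.build_design(), reference_model, seed=1)


def make_neutral_init(reference_model):
    """Neutral starting values for estimation (not the simulation truth)."""
    return sp.PopulationModel(
        fixed=sp.FixedEffects(
            mu={"Ftot": 0.5, "F0": 0.5, "ka": 1.0, "Tk0": 1.0,
                "CL": 0.3, "V1": 0.1, "Q": 0.1, "V2": 0.1},
            beta_cov={("V1", "ANEST"): 0.0}),
        random=sp.RandomEffectsSpec(
            omega={p: 0.3 for p in PARAM_NAMES},
            corr={("ka", "Tk0"): 0.0}),
        error=sp.ErrorModel(a=1.0, b=0.3),
        covariate_medians=reference_model.covariate_medians)


@pytest.fixture
def neutral_init(reference_model):
    return make_neutral_init(reference_model)


def make_one_compartment_dataset(n_subjects=100, seed=1, a=0.5, b=0.1,
                                 omega=0.2, cl=0.5, v1=0.16,
                                 times=(0.25, 0.5, 1, 2, 4, 8)):
    """IV one-compartment toy (Q ~ 0) with known truth, no censoring."""
    truth = sp.PopulationModel(
        fixed=sp.FixedEffects(
            mu={"Ftot": 0.5, "F0": 0.5, "ka": 1.0, "Tk0": 1.0,
                "CL": cl, "V1": v1, "Q": 1e-12, "V2": 1.0}),
        random=sp.RandomEffectsSpec(omega={"CL": omega, "V1": omega}),
        error=sp.ErrorModel(a=a, b=b))
    rng = np.random.default_rng(seed)
    etas = sp.sample_etas(truth.random, n_subjects, seed + 1)
    subs, doses, obs = [], [], []
    t = np.asarray(times, dtype=float)
    for i in range(n_subjects):
        s = sp.SubjectRecord(i + 1, 3.5, 1.0, "F", 0, "toy")
        subs.append(s)
        d = sp.DoseEvent(i + 1, 0.0, 2.0, "IV")
        doses.append(d)
        p = sp.individual_params(truth, dict(zip(PARAM_NAMES, etas[i])), s)
        f = sp.predict_profile(p, [d], t)
        y = truncated_noise(f, truth.error, rng)
        for tj, yj in zip(t, y):
            obs.append(sp.Observation(i + 1, float(tj), float(yj),
                                      False, 1e-6))
    return sp.PKDataset(subs, doses, obs), truth, etas


@pytest.fixture
def one_compartment():
    return make_one_compartment_dataset()


@pytest.fixture
def quick_settings():
    return sp.SaemSettings(n_chains=3, n_explore=120, n_smooth=80, seed=7,
                           n_is_samples=2000)


@pytest.fixture(scope="session")
def typical_params():
    """Reported typical values for robenacoxib in cats (rounded table)."""
    return sp.IndividualParams(Ftot=0.78, F0=0.50, ka=0.68, Tk0=1.78,
                               CL=0.50, V1=0.16, Q=0.065, V2=0.047)
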