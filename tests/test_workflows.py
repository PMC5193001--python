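"""BIC, sequential fitting, backward covariate elimination and the
posterior-sample correlation screen."""

import math

import numpy as np
import pytest

import saempk as sp
from saempk.saem import SaemSettings, conditional_samples, saem_fit
from saempk.structural import PARAM_NAMES
from saempk.workflows import (DEFAULT_SEARCH_SPACE, backward_eliminate, bic,
                              correlation_screen, sequential_fit)

from conftest import make_neutral_init


# ----------------------------------------------------------------------
# BIC
# ----------------------------------------------------------------------

def test_bic_worked_example():
    assert bic(-100.0, 83, 10) == pytest.approx(200 + 10 * math.log(83))
    assert bic(-100.0, 83, 10) == pytest.approx(244.188, abs=2e-3)


def test_bic_edge_cases():
    assert bic(-50.0, 10, 0) == 100.0
    lls = [bic(-100.0, 10, p) for p in range(5)]
    assert np.all(np.diff(lls) > 0)  # increasing in P for n >= 2
    with pytest.raises(ValueError):
        bic(-1.0, 0, 1)


# ----------------------------------------------------------------------
# sequential fitting
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_crossover_dataset():
    """A reduced study: the two cross-over arms plus one IV arm."""
    model = sp.robenacoxib_reference_model()
    design = sp.build_design()
    design.arms = [a for a in design.arms
                   if a.label in ("CRA 04/034", "CRA 04/094", "CRA 08/189")]
    return sp.generate_study(design, model, seed=11), model


def test_sequential_freezes_disposition_bit_exactly(small_crossover_dataset):
    ds, model = small_crossover_dataset
    init = make_neutral_init(model)
    seq = sequential_fit(ds, init, settings=SaemSettings(
        n_chains=2, n_explore=80, n_smooth=50, seed=21,
        n_is_samples=1000, compute_rse=False))
    for p in ("CL", "V1", "Q", "V2"):
        assert seq.combined_fit.model.fixed.mu[p] \
            == seq.iv_fit.model.fixed.mu[p]
    # absorption typical values were re-estimated, not left at the start
    assert seq.combined_fit.model.fixed.mu["ka"] != init.fixed.mu["ka"]


def test_sequential_requires_iv_data(reference_model, neutral_init):
    design = sp.build_design()
    design.arms = [a for a in design.arms if a.label == "CRA 03/182"]
    ds = sp.generate_study(design, reference_model, seed=2)
    with pytest.raises(ValueError, match="IV"):
        sequential_fit(ds, neutral_init)


def test_stage2_on_iv_only_data_degenerates_cleanly(reference_model,
                                                    neutral_init):
    """With zero SC records stage 2 just re-estimates random effects."""
    design = sp.build_design()
    design.arms = [a for a in design.arms if a.label == "CRA 07/137"]
    ds = sp.generate_study(design, reference_model, seed=3)
    init = neutral_init
    init.fixed.beta_cov = {}
    seq = sequential_fit(ds, init, settings=SaemSettings(
        n_chains=2, n_explore=60, n_smooth=40, seed=5,
        n_is_samples=500, compute_rse=False))
    assert seq.combined_fit.model.fixed.mu["CL"] \
        == seq.iv_fit.model.fixed.mu["CL"]


# ----------------------------------------------------------------------
# backward elimination (selection logic via an injected fit function)
# ----------------------------------------------------------------------

def _fake_fit(important, noise_by_coef=None):
    """Deterministic surrogate: each active unimportant coefficient costs
    one parameter (BIC penalty) and buys nothing; important ones carry
    real likelihood."""
    def fit_fn(active, seed):
        ll = -100.0
        for coef in active:
            if coef in important:
                ll += 20.0
            elif noise_by_coef:
                ll += noise_by_coef.get(coef, 0.0)
        P = 5 + len(active)
        return ll, P, 50
    return fit_fn


def test_elimination_drops_all_null_coefficients():
    space = DEFAULT_SEARCH_SPACE[:4]
    selected, trace = backward_eliminate(None, SaemSettings(seed=0),
                                         search_space=space,
                                         fit_fn=_fake_fit(set()))
    assert selected == ()
    accepted = [s.bic for s in trace.steps if s.action in ("start", "accepted")]
    assert all(b2 <= b1 + 1e-9 for b1, b2 in zip(accepted, accepted[1:]))


def test_elimination_keeps_exactly_the_important_coefficient():
    space = DEFAULT_SEARCH_SPACE[:5]
    important = {("V1", "ANEST")}
    selected, trace = backward_eliminate(None, SaemSettings(seed=0),
                                         search_space=space,
                                         fit_fn=_fake_fit(important))
    assert set(selected) == important
    assert trace.steps[-1].action == "final"


def test_elimination_tie_break_uses_canonical_order():
    # two equally useless coefficients: the earlier one is removed first
    space = (("CL", "ANEST"), ("CL", "GENDER"))
    removals = []

    def fit_fn(active, seed):
        return -100.0, 5 + len(active), 50

    _, trace = backward_eliminate(None, SaemSettings(seed=0),
                                  search_space=space, fit_fn=fit_fn)
    removed = [s.description for s in trace.steps if s.action == "accepted"]
    assert removed[0] == "removed CL~ANEST"


def test_elimination_refit_budget():
    space = DEFAULT_SEARCH_SPACE  # K = 12
    calls = []

    def fit_fn(active, seed):
        calls.append(active)
        return -100.0, 5 + len(active), 50

    backward_eliminate(None, SaemSettings(seed=0), search_space=space,
                       fit_fn=fit_fn)
    K = len(space)
    assert len(calls) <= K * (K + 1) // 2 + 1


def test_elimination_skips_failing_candidates():
    space = (("CL", "ANEST"), ("V1", "ANEST"))

    def fit_fn(active, seed):
        if ("CL", "ANEST") not in active and active != space:
            # any candidate dropping CL~ANEST cannot be assessed
            raise RuntimeError("no convergence")
        return -100.0, 5 + len(active), 50

    selected, trace = backward_eliminate(None, SaemSettings(seed=0),
                                         search_space=space, fit_fn=fit_fn)
    notes = [s.action for s in trace.steps]
    assert any(a.startswith("skipped") for a in notes)
    assert ("CL", "ANEST") in selected  # its removal could not be assessed


def test_elimination_end_to_end_retains_anesthesia_effect(reference_model):
    """On data carrying the anesthesia effect on V1 (0.16 -> 0.33 L/kg),
    elimination over a two-coefficient space keeps exactly that effect.
    Replicates are scaled down to keep the suite fast."""
    design = sp.build_design()
    keep = ("CRA 04/094", "CRA 07/137", "Perioperative")
    design.arms = [a for a in design.arms if a.label in keep]
    space = (("V1", "ANEST"), ("CL", "GENDER"))
    hits = 0
    for rep in range(3):
        ds = sp.generate_study(design, reference_model, seed=40 + rep)
        init = make_neutral_init(reference_model)
        init.fixed.beta_cov = {c: 0.0 for c in space}
        selected, trace = backward_eliminate(
            ds, SaemSettings(n_chains=2, n_explore=100, n_smooth=60,
                             seed=60 + rep, n_is_samples=1000,
                             compute_rse=False),
            search_space=space, initial_model=init)
        if set(selected) == {("V1", "ANEST")}:
            hits += 1
    assert hits >= 2


def test_elimination_null_data_selects_no_covariates(reference_model):
    """Simulated without covariate effects, the covariate-free model wins."""
    model = reference_model.copy()
    model.fixed.beta_cov = {}
    design = sp.build_design()
    keep = ("CRA 04/094", "CRA 07/137", "Perioperative")
    design.arms = [a for a in design.arms if a.label in keep]
    space = (("V1", "ANEST"), ("CL", "GENDER"))
    hits = 0
    for rep in range(3):
        ds = sp.generate_study(design, model, seed=80 + rep)
        init = make_neutral_init(model)
        init.fixed.beta_cov = {c: 0.0 for c in space}
        selected, _ = backward_eliminate(
            ds, SaemSettings(n_chains=2, n_explore=100, n_smooth=60,
                             seed=90 + rep, n_is_samples=1000,
                             compute_rse=False),
            search_space=space, initial_model=init)
        if selected == ():
            hits += 1
    assert hits >= 2


# ----------------------------------------------------------------------
# correlation screen
# ----------------------------------------------------------------------

def test_correlation_screen_identical_samples_yield_nan():
    samples = {1: np.zeros((3, 8)), 2: np.zeros((3, 8))}
    out = correlation_screen(samples)
    assert out.isna().all().all()


def test_correlation_screen_needs_two_subjects():
    with pytest.raises(ValueError):
        correlation_screen({1: np.zeros((3, 8))})


def test_correlation_screen_null_rich_data(reference_model):
    """Diagonal Omega, richly sampled subjects: pooled posterior
    correlations stay near zero.  A single realization of the sample
    correlation carries ~0.1 noise, so the screen is averaged over two
    independent replicates."""
    model = reference_model.copy()
    model.random.corr = {}
    model.fixed.beta_cov = {}
    design = sp.build_design()
    design.arms = [a for a in design.arms if a.label == "CRA 03/182"]
    design.arms[0] = sp.ArmSpec(
        "rich", 150, (75, 75), (3.1, 4.1), (1.2, 2.2), ("SC",), 2.0,
        design.arms[0].schedule)
    informative = [PARAM_NAMES.index(p)
                   for p in ("Ftot", "F0", "ka", "Tk0", "CL")]
    mats = []
    for rep in (0, 1):
        ds = sp.generate_study(design, model, seed=13 + rep)
        post, _ = conditional_samples(model, ds, n_chains=5, n_iter=400,
                                      seed=1 + rep)
        mats.append(correlation_screen(post).to_numpy())
    vals = np.mean(mats, axis=0)
    off = [abs(vals[i, j]) for i in informative for j in informative if i < j]
    assert max(off) < 0.15
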