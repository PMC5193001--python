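"""Sequential SAEM fit of a synthetic study (reduced settings).

Stage 1 estimates the disposition fixed effects (CL, V1, Q, V2) from
the IV occasions; stage 2 freezes them and estimates the absorption
parameters, the anesthesia effect on V1, all random effects and the
residual error from the full dataset.  Takes a couple of minutes.
"""

import math

import saempk as sp
from saempk.structural import PARAM_NAMES
from saempk.workflows import sequential_fit

truth = sp.robenacoxib_reference_model()
ds = sp.generate_study(sp.build_design(), truth, seed=1)

init = sp.PopulationModel(
    fixed=sp.FixedEffects(
        mu={"Ftot": 0.5, "F0": 0.5, "ka": 1.0, "Tk0": 1.0,
            "CL": 0.3, "V1": 0.1, "Q": 0.1, "V2": 0.1},
        beta_cov={("V1", "ANEST"): 0.0}),
    random=sp.RandomEffectsSpec(omega={p: 0.3 for p in PARAM_NAMES},
                                corr={("ka", "Tk0"): 0.0}),
    error=sp.ErrorModel(a=1.0, b=0.3),
    covariate_medians=truth.covariate_medians)

seq = sequential_fit(ds, init, settings=sp.SaemSettings(
    n_chains=5, n_explore=300, n_smooth=200, seed=11, n_is_samples=3000))

iv, cb = seq.iv_fit.model, seq.combined_fit.model
print("stage 1 (IV):   CL = %.3f L/kg/h, V1 = %.3f L/kg, "
      "Q = %.3f, V2 = %.3f" % (iv.fixed.mu["CL"], iv.fixed.mu["V1"],
                               iv.fixed.mu["Q"], iv.fixed.mu["V2"]))
print("stage 2 (all):  Ftot = %.2f, F0 = %.2f, ka = %.2f 1/h, "
      "Tk0 = %.2f h" % (cb.fixed.mu["Ftot"], cb.fixed.mu["F0"],
                        cb.fixed.mu["ka"], cb.fixed.mu["Tk0"]))
v1_1 = cb.fixed.mu["V1"] * math.exp(cb.fixed.beta_cov[("V1", "ANEST")])
print("V1 anesthetized: %.3f L/kg (conscious %.3f)"
      % (v1_1, cb.fixed.mu["V1"]))
print("corr(ka, Tk0) =", round(cb.random.corr[("ka", "Tk0")], 3))
print("error: a = %.2f ng/mL, b = %.3f" % (cb.error.a, cb.error.b))
print("log-likelihood = %.1f (MC se %.2f), BIC = %.1f"
      % (seq.combined_fit.loglik, seq.combined_fit.loglik_se,
         seq.combined_fit.bic))
print("RSE (%):", {k: round(float(v), 1)
                   for k, v in seq.combined_fit.rse.items()
                   if not k.startswith(("omega", "corr"))})
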