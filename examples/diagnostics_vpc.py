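"""Model diagnostics: residuals, NPDE, shrinkage and a VPC table.

Evaluates the reference model on a dataset simulated from itself, so
all diagnostics should look calibrated: NPDE approximately standard
normal, the observed VPC percentiles inside their simulation bands.
"""

import saempk as sp
from saempk.diagnostics import npde, residuals, shrinkage, vpc
from saempk.saem import evaluate_at

model = sp.robenacoxib_reference_model()
ds = sp.generate_study(sp.build_design(), model, seed=1)
fit = evaluate_at(model, ds, n_chains=8, n_iter=250, seed=2)

bundle = residuals(fit, ds, impute_censored=True)
s = bundle.residual_summary
print(f"IWRES: n={s['n']}, mean={s['iwres_mean']:+.3f}, "
      f"var={s['iwres_var']:.3f} (variance < 1 reflects epsilon-"
      "shrinkage of the individual fits)")

tab = npde(fit, ds, n_sim=500, seed=3, impute_censored=True)
v = tab.npde.dropna()
print(f"NPDE:  n={v.size}, mean={v.mean():+.3f}, var={v.var():.3f} "
      "(standard normal under a correct model)")

sh = shrinkage(fit)
print("eta-shrinkage (%):",
      {k: round(x, 1) for k, x in sh.items() if x == x})

res = vpc(fit, ds, n_sim=500, seed=4)
t = res.table
inside = ((t.obs_p50 >= t.sim_p50_lo) & (t.obs_p50 <= t.sim_p50_hi)).mean()
print(f"VPC:   {len(t)} bins, observed median inside its 95% band in "
      f"{100 * inside:.0f}% of bins")
print(t[["t_mid", "n_obs", "obs_p50", "sim_p50_lo", "sim_p50_hi"]]
      .round(1).to_string(index=False))
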