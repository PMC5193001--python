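# Methods

This note documents the models, algorithms and numerical choices in
`saempk`, and what the synthetic study can and cannot show.

## Structural model

Disposition is a two-compartment mammillary system with first-order
elimination from the central compartment, parameterized by clearance
`CL` (L/kg/h), central and peripheral volumes `V1`, `V2` (L/kg) and
intercompartmental clearance `Q` (L/kg/h).  Micro constants are
`k10 = CL/V1`, `k12 = Q/V1`, `k21 = Q/V2`; the disposition exponents
`alpha >= beta` are the roots of `s^2 − (k10+k12+k21)s + k10·k21`,
computed with the product form `beta = k10·k21/alpha` for stability.

Subcutaneous input is the superposition of (i) a zero-order infusion of
amount `F0·Ftot·D` at constant rate over `[0, Tk0]` and (ii) a
first-order depot of amount `(1−F0)·Ftot·D` with rate constant `ka`,
both starting at the time of administration ("simultaneous" mixed
absorption, the convention of the software family this analysis style
comes from).  All predictions are closed-form sums of exponentials;
coinciding rates (`ka ≈ alpha` or `beta`, repeated disposition roots)
are resolved at a relative threshold of 1e-10 by the analytic
`t·exp(−λt)` limits or a relative 1e-9 root perturbation, so no input
produces NaN.  Doses are mg/kg, volumes L/kg; predictions in mg/L are
converted to ng/mL (×1000).  Cross-over occasions are independent
(complete washout; compartments reset), and predose (time-0) samples
are stored but excluded from likelihoods: after a ≥1-week washout their
true concentration is zero.

An independent ODE path (`ode_profile`, DOP853 at rtol 1e-10,
atol 1e-16, four states including the cumulative eliminated amount)
exists purely for verification.  Closed form and ODE agree to 1e-8
relative wherever the concentration is within four decades of the peak
(integrator at rtol 1e-12 for the randomized-grid check); deeper tails
are dominated by the reference integrator's own accumulated error, so
the comparison floor is part of the test definition, not a model
tolerance.

## Population model

Random effects act on the transformed scale — log for the six positive
parameters, logit for the two fractions (`Ftot`, and also `F0`, which
is given the logit transform because its between-subject variability is
large and an unbounded transform would breach [0, 1]).  Covariates
enter linearly on the transformed scale; continuous covariates (age,
bodyweight at first administration) are median-normalized and
log-transformed, factors are `GENDER` (F=0, M=1) and `ANEST` (1 =
perioperative).  Reported inter-individual variability percentages are
interpreted as `omega × 100` on the transformed scale.  `Omega` is
diagonal plus a sparse list of correlations (default: `ka`–`Tk0`).

The residual model combines additive (`a`, ng/mL) and proportional
(`b`) noise: `sd(f) = sqrt(a² + b²f²)`.  Simulated measurements draw
from this normal **truncated at zero** (inverse-CDF sampling): a
concentration assay reports no negative values, and truncation makes
the generative model coherent with the interval-censored likelihood —
a value flagged below the LLOQ then genuinely lies in `[0, LLOQ]`.
(The alternative of flooring negative draws into the censored class
contradicts the interval likelihood by ~0.9 nats per deep-censored
point and measurably biases the absorption parameters.)  Values below
the LLOQ (3 ng/mL by default) are interval-censored: they contribute
`log[Φ((LLOQ−f)/sd) − Φ((0−f)/sd)]`, evaluated via `log_ndtr` with a
stable log-difference, floored at a large negative finite value.

## SAEM estimation

Each iteration samples every subject's transformed parameter vector
`psi_i = m_i + eta_i` from its conditional distribution by
Metropolis–Hastings, batched over subjects and chains (default 10
chains).  Four kernels per sweep:

1. independent proposal from the population prior `N(m_i, Omega)`;
2. componentwise random walk (per-subject, per-dimension scales);
3. full-vector random walk along the prior Cholesky factor;
4. full-vector random walk shaped by a running per-subject estimate of
   the conditional covariance (exponentially weighted over chains and
   iterations).

Kernel 4 exists because the conditional distributions ride narrow
correlated ridges — bioavailability against clearance in subjects with
only one route, `ka` against `Tk0` in the absorption peak — that
prior-shaped proposals cross too slowly, which deflates the sampled
second moments and, through the M-step, the variance estimates.
Random-walk scales adapt toward ~0.3 acceptance with a diminishing rate
during smoothing.  Censored observations keep their exact interval
likelihood inside the MH target; no latent values are imputed.

Sufficient statistics (`psi`, `psi psi'`, per-observation `E[f²]` and
`E[(y−f)²]`) are updated with step size 1 for the exploratory phase
(default 1000 iterations) and `k^(−0.7)` during smoothing (default 500;
the exponent satisfies the Robbins–Monro conditions).  M-step:

- typical values and covariate coefficients by per-parameter least
  squares on the transformed scale (frozen values enter as offsets and
  are never touched — sequential fitting relies on this being
  bit-exact);
- `Omega` from the empirical second moments, projected onto its
  structure (diagonal plus declared correlations, correlations clipped
  to ±0.95, PSD enforced by eigenvalue flooring);
- the error pair `(a, b)` by a small L-BFGS minimization of the
  complete-data objective built from the smoothed per-observation
  statistics (the combined error model has no closed-form
  exponential-family update; this surrogate is standard practice and
  validated by recovery tests);
- typical values of parameters *without* a random effect (when not
  frozen) by direct likelihood optimization given the current
  conditional draws.

During exploration, simulated annealing floors each variance component
at 0.95× its previous value.  This is load-bearing: with step size 1
the variance update is a multiplicative noisy map whose Jensen drift is
negative, so weakly identified components (here `omega_Ftot`,
`omega_ka`) otherwise decay geometrically regardless of the data.  The
smoothing phase, which averages rather than overwrites, then settles on
the maximum-likelihood value.

The marginal log-likelihood uses per-subject importance sampling
(default 10,000 draws) with a multivariate Student-t (df 5) proposal
located and scaled by conditional moments accumulated over the second
half of the smoothing phase (the first half still drifts and would
inflate the proposal).  The estimator was checked against brute-force
prior Monte-Carlo at small n.  Standard errors come from the observed
Fisher information approximated by the cross-product of per-subject
marginal scores (Fisher's identity: the smoothing-phase average of
analytic complete-data scores); BLQ observations are omitted from the
error-model score terms.  RSEs are reported on the natural scale by the
delta method.  `BIC = −2·LL + ln(n)·P` with `n` the number of subjects
and `P` counting every estimated quantity (active typical values,
covariate coefficients, variances, correlations, `a`, `b`); frozen
parameters are excluded.

Empirical Bayes estimates maximize each subject's conditional density
(L-BFGS started at the conditional mean); the per-chain states of the
final iteration are the posterior samples (exactly `n_chains` per
subject).

## Workflows

Sequential fitting: stage 1 estimates `CL, V1, Q, V2` (and their
omegas) on the IV occasions only; stage 2 freezes those four typical
values and estimates absorption, covariate coefficients, all random
effects and the error model on the complete dataset — disposition
omegas are re-estimated in stage 2, since the combined data carry the
random-effect information.  Backward elimination starts from the full
covariate model and removes, at each step, the coefficient whose
removal lowers BIC the most (ties broken by the canonical search-space
order), stopping when no removal helps; candidates that fail to fit are
skipped with a trace annotation.  The correlation screen computes
Pearson correlations of etas across subjects, pooling all chains'
posterior draws (or, for contrast, the EBEs); graphical covariate
pre-screening is supported only as data export — selection authority
rests with the BIC step.

## Diagnostics

Population predictions set `eta = 0` with each subject's covariates;
individual predictions use the EBE; `IWRES = (y − ipred)/sd(ipred)`.
NPDE simulates replicate datasets under the model, decorrelates
observed and simulated vectors per subject with the empirical simulated
mean and Cholesky covariance (ridge-regularized if needed), and maps
rank-based discrepancies through the normal quantile.  By default BLQ
samples are excluded; with `impute_censored` they are drawn from the
model's conditional distribution on `[0, LLOQ]` (for NPDE: resampled
from each observation's own below-LLOQ simulations), which removes the
left-tail selection bias and is the configuration under which
calibration is assessed.  VPC bins use nominal times when there are few
distinct times and quantile bins (default 4) otherwise — the sparse
perioperative times are irregular by design; BLQ values enter
percentile computation as LLOQ/2 on both the observed and simulated
sides.  All diagnostics are pure functions of (fit, dataset, seed).

Two calibration facts, established on the packaged design and worth
knowing before reading diagnostics on real data: NPDE with BLQ
imputation is well calibrated (mean ≈ 0, variance ≈ 1 at ~1,400
observations), but raw EBE-based IWRES is not — with 9–12 samples
informing ~6 etas per rich subject, epsilon-shrinkage deflates
var(IWRES) to ~0.6, and the assay's zero-truncation lifts the mean of
near-LLOQ residuals.  That is a property of the design and of the IWRES
definition, not of the estimator; NPDE is the diagnostic to trust here.

## Synthetic study

The generator reproduces the pooled design: eight arms (83 cats, 97
administrations; 23 IV, 74 SC; two IV/SC cross-over arms totalling 14
cats; a perioperative arm of 36 anesthetized female cats).  Weights and
ages draw from log-normals centered at the geometric midpoint of each
arm's reported range (range ≈ ±2 SD), truncated to the range; doses are
fixed or uniform within the reported per-arm range; rich schedules
follow the tabulated nominal times.  Perioperative sampling: 24 cats
dosed preoperatively are sampled at extubation — uniform in
[0.8, 6.2] h after the dose, reflecting variable surgery duration — and
exactly 2 h later; 12 cats dosed at extubation give one sample at 2 h;
all times fall in the reported [0.8, 8.2] h span.

The packaged "reference" scenario uses the published typical values
(CL 0.502 L/kg/h, V1 0.16 L/kg with an anesthesia coefficient
ln(0.33/0.16), Q 0.065, V2 0.047, Ftot 0.78, F0 0.50, ka 0.68 1/h,
Tk0 1.78 h), the reported variability percentages as omegas, and
corr(ka, Tk0) = −0.24.  The residual error was never published; the
defaults `a = 3 ng/mL` (≈ the LLOQ) and `b = 0.15` are plausible assay
noise and yield a BLQ fraction (~10%) of the same order as the study's
(55 of 652).  The nominal schedule count (~743 rows including predose,
682 quantifiable slots) slightly exceeds the 652 measured
concentrations reported — the study does not explain its missing
samples, and the generator makes no assumption about them.

What passing tests on this material do and do not show: they establish
that the estimation machinery recovers the generating process under
the study's design and noise model, including its weak spots.  Two of
those weak spots are quantified by profile likelihood on generated
datasets: the information in this design supports the `ka`–`Tk0`
correlation only to about ±0.2, and the anesthesia coefficient on V1 to
about ±0.15–0.2 on the log scale, so single-dataset estimates of these
two quantities scatter accordingly even though the estimator tracks
each dataset's own likelihood maximum.  Nothing here validates the
structural model against real cats — model choice, assay behavior,
protein binding and anesthesia physiology are outside what synthetic
data can test.

## Problem sizes and defaults

Default estimation settings (10 chains, 1000 exploratory + 500
smoothing iterations) reflect the study-scale configuration; a
sequential fit of the 83-cat study takes a couple of minutes on one
CPU.  The test suite runs its replicate batteries at 5 chains,
300 + 200 iterations and with reduced replicate counts or restricted
covariate search spaces — scaled-down conditions chosen so the whole
suite stays in the tens of minutes while exercising the same code
paths; the acceptance script uses the full defaults.
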