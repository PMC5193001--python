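"""Population layer: fixed effects, covariates, random effects, residual error.

Individual parameters arise from typical values ``mu`` perturbed by
covariate effects and log-normal (or logit-normal, for the two
fractions) random effects:

* fractions (``Ftot``, ``F0``):  ``invlogit(logit(mu) + sum(beta*cov) + eta)``
* positive parameters:           ``mu * exp(sum(beta*cov) + eta)``

``eta`` vectors are multivariate normal with covariance ``Omega``
(diagonal standard deviations ``omega`` plus an optional sparse set of
correlations, by default only between ``ka`` and ``Tk0``).  The residual
error combines an additive SD ``a`` (ng/mL) and a proportional SD ``b``:
``y = f*(1 + b*eps_b) + a*eps_a``, so ``sd(f) = sqrt(a^2 + b^2 f^2)``.

Continuous covariates are median-normalized and log-transformed
(``t_AGE``, ``t_WEIGHT0``); the factors are ``GENDER`` (F=0, M=1) and
``ANEST`` (1 = perioperative/anesthetized).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .dataset import DoseEvent, Observation, PKDataset, SubjectRecord
from .structural import PARAM_NAMES, IndividualParams, predict_profile

__all__ = [
    "COVARIATE_NAMES",
    "FRACTION_PARAMS",
    "FixedEffects",
    "RandomEffectsSpec",
    "ErrorModel",
    "PopulationModel",
    "covariate_transform",
    "covariate_values",
    "individual_params",
    "transformed_mean",
    "sample_etas",
    "residual_sd",
    "simulate_observations",
]

COVARIATE_NAMES = ("ANEST", "t_AGE", "t_WEIGHT0", "GENDER")
#: parameters mapped through the logit (bounded fractions)
FRACTION_PARAMS = ("Ftot", "F0")
_IDX = {n: i for i, n in enumerate(PARAM_NAMES)}


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _invlogit(x):
    # clipped away from {0, 1} so extreme etas keep fractions in the
    # open interval in floating point
    out = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def transform_value(name: str, value):
    """Natural -> estimation scale (logit for fractions, log otherwise)."""
    return _logit(value) if name in FRACTION_PARAMS else np.log(value)


def back_transform_value(name: str, value):
    """Estimation -> natural scale."""
    return _invlogit(value) if name in FRACTION_PARAMS else np.exp(value)


@dataclass
class FixedEffects:
    """Typical values and covariate coefficients (on the transformed scale)."""

    mu: Dict[str, float]
    beta_cov: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(PARAM_NAMES) - set(self.mu)
        if missing:
            raise ValueError(f"mu incomplete, missing {sorted(missing)}")
        for (param, cov) in self.beta_cov:
            if param not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {param!r} in beta_cov")
            if cov not in COVARIATE_NAMES:
                raise ValueError(f"unknown covariate {cov!r} in beta_cov")


@dataclass
class RandomEffectsSpec:
    """Per-parameter eta SDs plus sparse correlation entries."""

    omega: Dict[str, float]
    corr: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for name, w in self.omega.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {name!r} in omega")
            if w < 0:
                raise ValueError(f"omega[{name}] must be >= 0")
        for (p1, p2), r in self.corr.items():
            if abs(r) >= 1:
                raise ValueError(f"correlation ({p1},{p2})={r} out of (-1,1)")

    def omega_vector(self) -> np.ndarray:
        return np.array([self.omega.get(n, 0.0) for n in PARAM_NAMES])

    def covariance(self) -> np.ndarray:
        """The implied 8x8 covariance of eta (zero rows for fixed parameters)."""
        w = self.omega_vector()
        omega = np.diag(w ** 2)
        for (p1, p2), r in self.corr.items():
            i, j = _IDX[p1], _IDX[p2]
            omega[i, j] = omega[j, i] = r * w[i] * w[j]
        active = w > 0
        sub = omega[np.ix_(active, active)]
        if sub.size:
            ev = np.linalg.eigvalsh(sub)
            if ev.min() < -1e-10 * max(ev.max(), 1.0):
                raise ValueError(
                    f"Omega not positive semi-definite (eigenvalue {ev.min():.3g})")
        return omega


@dataclass
class ErrorModel:
    """Combined additive (a, ng/mL) + proportional (b) residual error."""

    a: float = 0.0
    b: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("error SDs must be non-negative")
        if self.a + self.b <= 0:
            raise ValueError("at least one of a, b must be positive")


@dataclass
class PopulationModel:
    fixed: FixedEffects
    random: RandomEffectsSpec
    error: ErrorModel
    covariate_medians: Dict[str, float] = field(
        default_factory=lambda: {"age": 1.0, "weight": 1.0})

    def __post_init__(self):
        for k in ("age", "weight"):
            if self.covariate_medians.get(k, 0) <= 0:
                raise ValueError(f"covariate median {k!r} must be positive")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mu": dict(self.fixed.mu),
            "beta_cov": [
                {"param": p, "cov": c, "value": float(v)}
                for (p, c), v in self.fixed.beta_cov.items()],
            "omega": dict(self.random.omega),
            "corr": [
                {"params": list(k), "value": float(v)}
                for k, v in self.random.corr.items()],
            "error": {"a": float(self.error.a), "b": float(self.error.b)},
            "covariate_medians": dict(self.covariate_medians),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            fixed=FixedEffects(
                mu={k: float(v) for k, v in d["mu"].items()},
                beta_cov={(e["param"], e["cov"]): float(e["value"])
                          for e in d.get("beta_cov", [])},
            ),
            random=RandomEffectsSpec(
                omega={k: float(v) for k, v in d.get("omega", {}).items()},
                corr={tuple(e["params"]): float(e["value"])
                      for e in d.get("corr", [])},
            ),
            error=ErrorModel(**{k: float(v) for k, v in d["error"].items()}),
            covariate_medians={k: float(v)
                               for k, v in d.get("covariate_medians", {})
                               .items()} or {"age": 1.0, "weight": 1.0},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "PopulationModel":
        return PopulationModel.from_dict(self.to_dict())


# ----------------------------------------------------------------------
# covariates and the individual map
# ----------------------------------------------------------------------

def covariate_transform(age: float, weight0: float,
                        medians: Dict[str, float]) -> Tuple[float, float]:
    """Median-normalized log transforms t_AGE = ln(age/median_age), etc."""
    if age <= 0 or weight0 <= 0 or min(medians.values()) <= 0:
        raise ValueError("covariate_transform requires positive inputs")
    return (math.log(age / medians["age"]),
            math.log(weight0 / medians["weight"]))


def covariate_values(subject: SubjectRecord,
                     medians: Dict[str, float]) -> Dict[str, float]:
    t_age, t_wt = covariate_transform(subject.age, subject.weight0, medians)
    return {
        "ANEST": float(subject.anest),
        "t_AGE": t_age,
        "t_WEIGHT0": t_wt,
        "GENDER": 1.0 if subject.gender == "M" else 0.0,
    }


def transformed_mean(model: PopulationModel,
                     subject: SubjectRecord) -> np.ndarray:
    """Transformed-scale individual mean: t(mu) plus covariate terms."""
    cov = covariate_values(subject, model.covariate_medians)
    m = np.array([transform_value(n, model.fixed.mu[n]) for n in PARAM_NAMES])
    for (param, cname), coef in model.fixed.beta_cov.items():
        m[_IDX[param]] += coef * cov[cname]
    return m


def individual_params(model: PopulationModel, eta: Dict[str, float],
                      subject: SubjectRecord) -> IndividualParams:
    """Map (mu, covariates, eta) to the natural-scale individual vector."""
    unknown = set(eta) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameters in eta: {sorted(unknown)}")
    m = transformed_mean(model, subject)
    psi = m + np.array([eta.get(n, 0.0) for n in PARAM_NAMES])
    values = [back_transform_value(n, psi[_IDX[n]]) for n in PARAM_NAMES]
    return IndividualParams(**dict(zip(PARAM_NAMES, map(float, values))))


def sample_etas(random: RandomEffectsSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` eta vectors (n, 8) from N(0, Omega); reproducible under seed."""
    omega = random.covariance()
    rng = np.random.default_rng(seed)
    w = random.omega_vector()
    out = np.zeros((n, len(PARAM_NAMES)))
    active = w > 0
    if active.any():
        sub = omega[np.ix_(active, active)]
        out[:, active] = rng.multivariate_normal(
            np.zeros(active.sum()), sub, size=n, method="cholesky")
    return out


def residual_sd(pred, error: ErrorModel):
    """SD of the combined error model at prediction ``pred`` (ng/mL)."""
    pred = np.asarray(pred, dtype=float)
    out = np.sqrt(error.a ** 2 + (error.b * pred) ** 2)
    return out if out.ndim else float(out)


def truncated_noise(pred, error: ErrorModel, rng) -> np.ndarray:
    """Draw y ~ N(pred, sd(pred)) truncated to y >= 0 (inverse-CDF sampling)."""
    from scipy.special import ndtr, ndtri
    pred = np.asarray(pred, dtype=float)
    sd = residual_sd(pred, error)
    lo = ndtr(-pred / sd)
    u = rng.uniform(lo, 1.0)
    return pred + sd * ndtri(np.clip(u, 1e-16, 1.0 - 1e-16))


# ----------------------------------------------------------------------
# forward simulation
# ----------------------------------------------------------------------

def simulate_observations(model: PopulationModel,
                          params_by_subject: Dict[int, IndividualParams],
                          schedule: PKDataset,
                          lloq: Optional[float] = None,
                          seed=0) -> PKDataset:
    """Simulate observations on the dose/sampling skeleton of ``schedule``.

    ``y = f*(1 + b*eps_b) + a*eps_a`` with the combined normal noise
    truncated at zero (a concentration assay reports no negative
    values); simulated values below the LLOQ are flagged censored with
    the value removed, so a censored datum genuinely lies in
    ``[0, lloq]`` — coherent with the interval likelihood used in
    estimation.  Predose samples are re-emitted as predose-flagged
    censored rows.
    """
    rng = np.random.default_rng(seed)
    new_obs = []
    for sid in [s.subject_id for s in schedule.subjects]:
        p = params_by_subject[sid]
        doses = schedule.doses_for(sid)
        obs = schedule.observations_for(sid)
        if not obs:
            continue
        times = np.array([o.time for o in obs])
        occs = np.array([o.occasion for o in obs])
        f = predict_profile(p, doses, times, occs)
        y = truncated_noise(f, model.error, rng)
        for o, yi in zip(obs, y):
            q = lloq if lloq is not None else o.lloq
            if o.predose:
                new_obs.append(replace(o, value=None, censored=True))
            elif yi < q:
                new_obs.append(replace(o, value=None, censored=True, lloq=q))
            else:
                new_obs.append(replace(o, value=float(yi), censored=False, lloq=q))
    return PKDataset(list(schedule.subjects), list(schedule.doses), new_obs)
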