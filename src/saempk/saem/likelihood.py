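"""Observation-level and complete-data log-likelihoods.

Uncensored samples contribute a normal log-density around the model
prediction; BLQ samples contribute the log-probability that the true
concentration lies between zero and the LLOQ (the censored-data M3
convention), computed stably in log space.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np
from scipy.stats import multivariate_normal

from ..dataset import Observation, PKDataset
from ..popmodel import PopulationModel, transformed_mean
from ..structural import PARAM_NAMES
from .encode import EncodedData, interval_logprob
from .engine import _back_transform

__all__ = ["observation_loglik", "complete_loglik"]


def observation_loglik(obs: Observation, pred: float, sd: float) -> float:
    """Log-likelihood contribution of one observation.

    Censored: log[Phi((LLOQ - pred)/sd) - Phi((0 - pred)/sd)], finite
    even deep in the tail.  Uncensored: normal log-density of the value.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if obs.censored:
        return float(interval_logprob(np.array((obs.lloq - pred) / sd),
                                      np.array((0.0 - pred) / sd)))
    r = (obs.value - pred) / sd
    return float(-0.5 * r * r - math.log(sd) - 0.5 * math.log(2 * math.pi))


def complete_loglik(model: PopulationModel, dataset: PKDataset,
                    etas: Dict[int, np.ndarray]) -> float:
    """Complete-data log-likelihood: observation terms plus the eta prior.

    ``etas`` maps every subject id to an 8-vector on the transformed
    scale.  Predose samples are excluded, matching the estimation
    engine.
    """
    enc = EncodedData(dataset)
    M = np.vstack([transformed_mean(model, s) for s in dataset.subjects])
    E = np.vstack([etas[sid] for sid in enc.subject_ids])
    psi = (M + E)[:, None, :]
    pred = enc.predict(_back_transform(psi))
    total = float(enc.loglik_subjects(pred, model.error.a,
                                      model.error.b).sum())
    omega = model.random.covariance()
    active = model.random.omega_vector() > 0
    if active.any():
        sub = omega[np.ix_(active, active)]
        mvn = multivariate_normal(mean=np.zeros(active.sum()), cov=sub,
                                  allow_singular=True)
        total += float(np.sum(mvn.logpdf(E[:, active])))
    return total
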