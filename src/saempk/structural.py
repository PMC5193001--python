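"""Two-compartment disposition with IV bolus and mixed SC absorption.

The structural model is a mammillary two-compartment system with
first-order elimination from the central compartment.  Subcutaneous
input is the superposition of a first-order depot (rate constant ``ka``,
amount ``(1-F0)*Ftot*D``) and a zero-order infusion (amount
``F0*Ftot*D`` delivered at a constant rate over ``Tk0`` hours), both
starting at the time of administration.

All parameters are bodyweight-normalized: volumes in L/kg, clearances in
L/kg/h, doses in mg/kg.  Predicted concentrations (mg/L) are converted
to ng/mL by a factor of 1000.

The closed forms below are exact for this linear system; an independent
ODE integrator (:func:`ode_profile`) is provided as a reference path for
verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PARAM_NAMES",
    "IndividualParams",
    "MicroConstants",
    "DispositionExponents",
    "DerivedPK",
    "micro_constants",
    "disposition_exponents",
    "conc_iv_bolus",
    "conc_sc",
    "predict_profile",
    "cardiac_output",
    "derived_quantities",
    "ode_profile",
]

#: canonical ordering of the individual parameter vector
PARAM_NAMES = ("Ftot", "F0", "ka", "Tk0", "CL", "V1", "Q", "V2")

MGL_TO_NGML = 1000.0

# relative-difference threshold below which coinciding exponential rates
# are resolved by their analytic limit (t * exp(-l t) terms)
_DEGENERATE_EPS = 1e-10


@dataclass(frozen=True)
class IndividualParams:
    """The individual parameter vector (Ftot, F0, ka, Tk0, CL, V1, Q, V2)."""

    Ftot: float   # absolute SC bioavailability, in (0, 1)
    F0: float     # fraction of the absorbed dose via the zero-order path
    ka: float     # first-order absorption rate constant, 1/h
    Tk0: float    # zero-order input duration, h
    CL: float     # clearance, L/kg/h
    V1: float     # central volume, L/kg
    Q: float      # intercompartmental clearance, L/kg/h
    V2: float     # peripheral volume, L/kg

    def __post_init__(self):
        if not (0.0 < self.Ftot < 1.0):
            raise ValueError("Ftot must lie in (0, 1)")
        if not (0.0 <= self.F0 <= 1.0):
            raise ValueError("F0 must lie in [0, 1]")
        for name in ("ka", "Tk0", "CL", "V1", "V2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Q < 0:
            raise ValueError("Q must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "IndividualParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))


@dataclass(frozen=True)
class MicroConstants:
    k10: float
    k12: float
    k21: float


@dataclass(frozen=True)
class DispositionExponents:
    alpha: float
    beta: float


@dataclass(frozen=True)
class DerivedPK:
    vss: float                 # steady-state volume of distribution, L/kg
    extraction_ratio: float    # CL over whole-body (cardiac-output) blood flow
    cardiac_output: float      # mL/kg/min
    t_half_terminal_sc: float  # terminal half-life after SC dosing, h
    t_half_beta: float         # disposition (beta) half-life, h
    flip_flop: bool            # ka < beta: absorption rate-limits the terminal phase


def micro_constants(p: IndividualParams) -> MicroConstants:
    """Micro rate constants of the mammillary model: k10=CL/V1, k12=Q/V1, k21=Q/V2."""
    return MicroConstants(p.CL / p.V1, p.Q / p.V1, p.Q / p.V2)


def disposition_exponents(m: MicroConstants) -> DispositionExponents:
    """Roots of s^2 - (k10+k12+k21) s + k10 k21 = 0, with alpha >= beta.

    Computed with the numerically stable product form beta = k10*k21/alpha.
    """
    if m.k10 <= 0:
        raise ValueError("k10 must be positive")
    s = m.k10 + m.k12 + m.k21
    prod = m.k10 * m.k21
    disc = s * s - 4.0 * prod
    if disc < 0:
        # impossible for non-negative rate constants up to round-off
        if disc < -1e-12 * s * s:
            raise ArithmeticError("negative discriminant in disposition exponents")
        disc = 0.0
    alpha = 0.5 * (s + math.sqrt(disc))
    beta = prod / alpha if alpha > 0 else 0.0
    return DispositionExponents(alpha, beta)


# ----------------------------------------------------------------------
# vectorized closed-form core (shared with the estimation engine)
# ----------------------------------------------------------------------

def impulse_terms(cl, v1, q, v2):
    """Exponents and coefficients of the unit-impulse central response.

    For a unit amount (mg/kg) placed in the central compartment,
    ``C(t) = A exp(-alpha t) + B exp(-beta t)`` in mg/L.  All inputs may
    be arrays (broadcast elementwise).  Exactly repeated roots are
    perturbed by a relative 1e-9 so the two-exponential form stays valid.
    """
    cl, v1, q, v2 = np.broadcast_arrays(*map(np.asarray, (cl, v1, q, v2)))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        k10 = cl / v1
        k21 = np.divide(q, v2, out=np.zeros_like(k10), where=v2 > 0)
        s = k10 + q / v1 + k21
        prod = k10 * k21
        disc = np.maximum(s * s - 4.0 * prod, 0.0)
        alpha = 0.5 * (s + np.sqrt(disc))
        beta = np.divide(prod, alpha, out=np.zeros_like(alpha), where=alpha > 0)
        near = np.abs(alpha - beta) <= _DEGENERATE_EPS * alpha
        beta = np.where(near, alpha * (1.0 - 1e-9), beta)
        denom = v1 * (alpha - beta)
        a_coef = (alpha - k21) / denom
        b_coef = (k21 - beta) / denom
    return alpha, beta, a_coef, b_coef


def _safe_rate_diff(ka, lam):
    """ka - lam, floored away from zero (analytic-limit switch)."""
    diff = ka - lam
    tiny = _DEGENERATE_EPS * np.maximum(np.abs(ka), np.abs(lam))
    near = np.abs(diff) <= tiny
    return np.where(near, np.where(diff >= 0, 1.0, -1.0) * np.maximum(tiny, 1e-300), diff), near


def bolus_unit_conc(alpha, beta, a_coef, b_coef, dt):
    """Central concentration per unit IV bolus amount at elapsed time dt (mg/L)."""
    dt = np.asarray(dt)
    pos = dt >= 0
    out = a_coef * np.exp(-alpha * np.where(pos, dt, 0.0)) + \
        b_coef * np.exp(-beta * np.where(pos, dt, 0.0))
    return np.where(pos, out, 0.0)


def first_order_unit_conc(alpha, beta, a_coef, b_coef, ka, dt):
    """Central concentration per unit depot amount, first-order input rate ka."""
    dt = np.asarray(dt)
    pos = dt >= 0
    t = np.where(pos, dt, 0.0)
    out = np.zeros(np.broadcast_shapes(np.shape(t), np.shape(alpha)))
    e_ka = np.exp(-ka * t)
    for lam, coef in ((alpha, a_coef), (beta, b_coef)):
        diff, near = _safe_rate_diff(ka, lam)
        term = ka * coef * (np.exp(-lam * t) - e_ka) / diff
        limit = ka * coef * t * np.exp(-lam * t)
        out = out + np.where(near, limit, term)
    return np.where(pos, out, 0.0)


def zero_order_unit_conc(alpha, beta, a_coef, b_coef, tk0, dt):
    """Central concentration per unit amount infused at constant rate over [0, tk0]."""
    dt = np.asarray(dt)
    pos = dt >= 0
    t = np.where(pos, dt, 0.0)
    rate = 1.0 / tk0
    out = np.zeros(np.broadcast_shapes(np.shape(t), np.shape(alpha), np.shape(tk0)))
    for lam, coef in ((alpha, a_coef), (beta, b_coef)):
        with np.errstate(divide="ignore", invalid="ignore"):
            on = coef / lam * (1.0 - np.exp(-lam * t))
            off = coef / lam * (np.exp(-lam * np.maximum(t - tk0, 0.0)) - np.exp(-lam * t))
        contrib = np.where(t <= tk0, on, off)
        # lam == 0 only occurs with zero coefficient (one-compartment limit)
        out = out + rate * np.where(lam > 0, contrib, 0.0)
    return np.where(pos, out, 0.0)


def sc_unit_conc(alpha, beta, a_coef, b_coef, ftot, f0, ka, tk0, dt):
    """Central concentration per unit SC dose (mg/kg), mixed absorption (mg/L)."""
    first = (1.0 - f0) * first_order_unit_conc(alpha, beta, a_coef, b_coef, ka, dt)
    zero = f0 * zero_order_unit_conc(alpha, beta, a_coef, b_coef, tk0, dt)
    return ftot * (first + zero)


# ----------------------------------------------------------------------
# scalar/public operations
# ----------------------------------------------------------------------

def conc_iv_bolus(p: IndividualParams, dose: float, t) -> np.ndarray:
    """Blood concentration (ng/mL) after an IV bolus of ``dose`` mg/kg at t=0."""
    alpha, beta, a_coef, b_coef = impulse_terms(p.CL, p.V1, p.Q, p.V2)
    out = MGL_TO_NGML * dose * bolus_unit_conc(alpha, beta, a_coef, b_coef, t)
    return out if np.ndim(t) else float(out)


def conc_sc(p: IndividualParams, dose: float, t) -> np.ndarray:
    """Blood concentration (ng/mL) after an SC dose of ``dose`` mg/kg at t=0."""
    alpha, beta, a_coef, b_coef = impulse_terms(p.CL, p.V1, p.Q, p.V2)
    out = MGL_TO_NGML * dose * sc_unit_conc(
        alpha, beta, a_coef, b_coef, p.Ftot, p.F0, p.ka, p.Tk0, t)
    return out if np.ndim(t) else float(out)


def predict_profile(p: IndividualParams, doses: Sequence, times,
                    occasions: Optional[Sequence[int]] = None) -> np.ndarray:
    """Superpose all dose events onto the requested sampling times (ng/mL).

    ``times`` are hours since the start of each occasion; ``occasions``
    gives the occasion of each requested time (default: all 1).  Dose
    events only contribute to times of their own occasion — occasions
    are treated as fully independent (complete washout between them).
    """
    times = np.asarray(times, dtype=float)
    occ = np.ones(times.shape, dtype=int) if occasions is None \
        else np.asarray(occasions, dtype=int)
    out = np.zeros(times.shape)
    for d in doses:
        mask = occ == d.occasion
        if not mask.any():
            continue
        dt = times[mask] - d.time
        if d.route == "IV":
            out[mask] += conc_iv_bolus(p, d.amount, dt)
        else:
            out[mask] += conc_sc(p, d.amount, dt)
    return out


def cardiac_output(bw: float) -> float:
    """Allometric whole-body blood flow of a cat, 180 * BW^-0.195 (mL/kg/min)."""
    if bw <= 0:
        raise ValueError("bodyweight must be positive")
    return 180.0 * bw ** (-0.195)


def derived_quantities(p: IndividualParams, bw: float) -> DerivedPK:
    """Steady-state volume, extraction ratio, half-lives and the flip-flop flag.

    The extraction ratio is clearance over cardiac output (converted
    from mL/kg/min to L/kg/h).  With flip-flop kinetics (ka < beta) the
    terminal slope after SC dosing is the absorption rate, so the
    terminal half-life is ln 2 over min(ka, beta).
    """
    ex = disposition_exponents(micro_constants(p))
    co = cardiac_output(bw)
    co_l_kg_h = co * 60.0 / 1000.0
    return DerivedPK(
        vss=p.V1 + p.V2,
        extraction_ratio=p.CL / co_l_kg_h,
        cardiac_output=co,
        t_half_terminal_sc=math.log(2.0) / min(p.ka, ex.beta),
        t_half_beta=math.log(2.0) / ex.beta,
        flip_flop=p.ka < ex.beta,
    )


# ----------------------------------------------------------------------
# ODE reference path
# ----------------------------------------------------------------------

def ode_profile(p: IndividualParams, doses: Sequence, times,
                occasions: Optional[Sequence[int]] = None,
                rtol: float = 1e-10, atol: float = 1e-16,
                return_states: bool = False):
    """Numerically integrate the full system as an independent reference.

    States: first-order depot, central amount, peripheral amount,
    cumulative eliminated amount (all mg/kg).  The zero-order input is a
    time-dependent rate into the central compartment.  This is a
    verification path, not the production predictor.
    """
    times = np.asarray(times, dtype=float)
    occ_req = np.ones(times.shape, dtype=int) if occasions is None \
        else np.asarray(occasions, dtype=int)
    m = micro_constants(p)
    out = np.zeros(times.shape)
    states = np.zeros(times.shape + (4,))

    for occasion in sorted({d.occasion for d in doses}):
        dlist = sorted([d for d in doses if d.occasion == occasion],
                       key=lambda d: d.time)
        mask = occ_req == occasion
        if not mask.any():
            continue
        t_req = times[mask]
        # breakpoints: dose starts and zero-order input switch-offs
        infusions = []  # (t_on, t_off, rate)
        bolus = []      # (t, amount into central)
        depot = []      # (t, amount into first-order depot)
        for d in dlist:
            if d.route == "IV":
                bolus.append((d.time, d.amount))
            else:
                a0 = p.F0 * p.Ftot * d.amount
                a1 = (1.0 - p.F0) * p.Ftot * d.amount
                if a0 > 0:
                    infusions.append((d.time, d.time + p.Tk0, a0 / p.Tk0))
                if a1 > 0:
                    depot.append((d.time, a1))

        def rate_in(t):
            return sum(r for (on, off, r) in infusions if on <= t < off)

        def rhs(t, y):
            dep, a1, a2, _ = y
            return [
                -p.ka * dep,
                p.ka * dep + rate_in(t) - (m.k10 + m.k12) * a1 + m.k21 * a2,
                m.k12 * a1 - m.k21 * a2,
                m.k10 * a1,
            ]

        events = sorted({0.0}
                        | {t for t, _ in bolus} | {t for t, _ in depot}
                        | {t for t, _, _ in infusions}
                        | {t for _, t, _ in infusions})
        # every requested time becomes an integration endpoint so no
        # dense-output interpolation enters the reference values
        stops = np.unique(np.concatenate(
            [np.asarray(events, dtype=float), t_req]))
        y = np.zeros(4)
        state_at: dict = {}
        for seg_start, seg_end in zip(stops[:-1], stops[1:]):
            for t, amt in bolus:
                if t == seg_start:
                    y[1] += amt
            for t, amt in depot:
                if t == seg_start:
                    y[0] += amt
            state_at[seg_start] = y.copy()
            sol = solve_ivp(rhs, (seg_start, seg_end), y, method="DOP853",
                            rtol=rtol, atol=atol)
            y = sol.y[:, -1].copy()
        for t, amt in bolus:
            if t == stops[-1]:
                y[1] += amt
        for t, amt in depot:
            if t == stops[-1]:
                y[0] += amt
        state_at[stops[-1]] = y.copy()
        sel = np.vstack([state_at[t] for t in t_req])
        out[mask] = MGL_TO_NGML * sel[:, 1] / p.V1
        states[mask] = sel
    if return_states:
        return out, states
    return out
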