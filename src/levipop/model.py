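"""Two-compartment intravenous-infusion structural model.

Closed-form central-compartment concentrations for zero-order infusions,
single-dose and multiple-dose (steady-state) regimens, plus the renal-function
covariate model on clearance.

The disposition model is the standard two-compartment system parameterised by
total clearance CL, central volume V1, intercompartmental clearance Q and
peripheral volume V2.  Concentrations are expressed as a sum of two
exponentials with macro rate constants alpha >= beta > 0 and coefficients
A + B = 1.  Population clearance follows an additive power law in urinary
creatinine clearance centred at 120 mL/min:

    CL (L/h) = theta_nr + (CrCl / 120) ** theta_r

so that theta_nr is the clearance of a subject with CrCl 120 mL/min minus one
unit contributed by the (normalised) renal term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

CRCL_CENTER = 120.0  # mL/min, covariate centring value (study median rounded)

__all__ = [
    "PKParams",
    "CovariateEffect",
    "CovariateModel",
    "MicroConstants",
    "DosingRegimen",
    "typical_clearance",
    "micro_constants",
    "conc_profile",
    "conc_steady_state",
    "apply_covariates",
    "published_params",
    "published_covariate_model",
]


@dataclass(frozen=True)
class PKParams:
    """Fixed-effect structural parameters.

    theta_nr : L/h
        Non-renal (base) clearance intercept.
    theta_r : dimensionless
        Exponent of the creatinine-clearance power term on CL.
    v1, v2 : L
        Central and peripheral volumes of distribution.
    q : L/h
        Intercompartmental clearance.
    """

    theta_nr: float = 3.5
    theta_r: float = 2.5
    v1: float = 20.7
    q: float = 31.9
    v2: float = 33.5

    def __post_init__(self) -> None:
        for name in ("theta_nr", "v1", "q", "v2"):
            val = getattr(self, name)
            if not (val > 0 and math.isfinite(val)):
                raise ValueError(f"{name} must be strictly positive, got {val!r}")
        if not math.isfinite(self.theta_r):
            raise ValueError(f"theta_r must be finite, got {self.theta_r!r}")


#: Functional forms for covariate effects.  ``value`` below is the covariate
#: value, ``c`` the centring constant and ``coef`` the effect coefficient.
#:
#: - ``linear``:          multiply by (1 + coef * (value - c))
#: - ``exponential``:     multiply by exp(coef * (value - c))
#: - ``power``:           multiply by (value / c) ** coef
#: - ``shift``:           multiply by (1 + coef) when the category flag is set
#: - ``additive_power``:  add (value / c) ** coef  (the published CL--CrCl form)
COVARIATE_FORMS = ("linear", "exponential", "power", "shift", "additive_power")


@dataclass(frozen=True)
class CovariateEffect:
    parameter: str  # "cl", "v1", "q" or "v2"
    covariate: str  # SubjectCovariates field name
    form: str
    center: float = 1.0
    coef: float = 0.0
    category: object = None  # for "shift": covariate value that triggers the shift

    def __post_init__(self) -> None:
        if self.form not in COVARIATE_FORMS:
            raise ValueError(
                f"unknown covariate function {self.form!r}; expected one of {COVARIATE_FORMS}"
            )
        if self.form in ("power", "exponential", "additive_power") and not self.center > 0:
            raise ValueError("centring value must be > 0 for power/exponential forms")


@dataclass(frozen=True)
class CovariateModel:
    effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        pairs = [(e.parameter, e.covariate) for e in self.effects]
        if len(pairs) != len(set(pairs)):
            raise ValueError("at most one effect per (parameter, covariate) pair")

    def __iter__(self):
        return iter(self.effects)


@dataclass(frozen=True)
class MicroConstants:
    """Micro/macro constants of the two-compartment model."""

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float
    coef_a: float
    coef_b: float


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated intravenous-infusion regimen.

    dose : mg, tau : h (dosing interval), infusion_duration : h.
    ``n_doses`` is the number of administered doses, or ``None`` for steady
    state (the closed-form accumulation limit).
    """

    dose: float
    tau: float = 12.0
    infusion_duration: float = 0.5
    n_doses: int | None = None  # None => steady state

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if not (0 < self.infusion_duration <= self.tau):
            raise ValueError("need 0 < infusion_duration <= tau")
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def steady_state(self) -> bool:
        return self.n_doses is None

    @property
    def daily_dose(self) -> float:
        return self.dose * 24.0 / self.tau


def published_params() -> PKParams:
    """Final published fixed effects."""
    return PKParams()


def published_covariate_model(params: PKParams | None = None) -> CovariateModel:
    """The final covariate model: additive CrCl power term on CL."""
    p = params or published_params()
    return CovariateModel(
        effects=(
            CovariateEffect(
                parameter="cl",
                covariate="crcl",
                form="additive_power",
                center=CRCL_CENTER,
                coef=p.theta_r,
            ),
        )
    )


def typical_clearance(crcl, params: PKParams | None = None):
    """Typical (population) clearance at a given urinary creatinine clearance.

    CL = theta_nr + (crcl / 120) ** theta_r, in L/h.  Accepts scalars or arrays.
    """
    p = params or published_params()
    crcl = np.asarray(crcl, dtype=float)
    if np.any(crcl <= 0):
        raise ValueError("crcl must be strictly positive (mL/min)")
    out = p.theta_nr + (crcl / CRCL_CENTER) ** p.theta_r
    return float(out) if out.ndim == 0 else out


# relative tolerance below which alpha ~ beta is treated as a repeated root
_DEGENERATE_RTOL = 1e-12


def micro_constants(cl: float, v1: float, q: float, v2: float) -> MicroConstants:
    """Micro rate constants and macro exponents from (CL, V1, Q, V2).

    alpha and beta are the roots of s^2 - (k10+k12+k21) s + k10*k21; the
    central-compartment bolus coefficients are A = (alpha-k21)/(alpha-beta)
    and B = (k21-beta)/(alpha-beta), normalised so A + B = 1.

    Raises ``ValueError`` on a repeated root (alpha == beta), which occurs on
    a measure-zero parameter set only; callers needing that limit should
    perturb explicitly.
    """
    if min(cl, v1, q, v2) <= 0:
        raise ValueError("cl, v1, q, v2 must all be strictly positive")
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    if disc <= _DEGENERATE_RTOL * alpha:
        raise ValueError(
            "degenerate two-compartment model: repeated macro root alpha == beta"
        )
    coef_a = (alpha - k21) / (alpha - beta)
    coef_b = (k21 - beta) / (alpha - beta)
    return MicroConstants(k10, k12, k21, alpha, beta, coef_a, coef_b)


def _macro_arrays(cl, v1, q, v2):
    """Vectorised macro constants; no degeneracy guard (measure-zero event)."""
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    coef_a = (alpha - k21) / (alpha - beta)
    coef_b = (k21 - beta) / (alpha - beta)
    return alpha, beta, coef_a, coef_b


def _infusion_term(lam, coef, tinf, t):
    """One exponential term of the single-infusion solution (dose at t=0)."""
    t = np.asarray(t, dtype=float)
    during = 1.0 - np.exp(-lam * np.clip(t, 0.0, None))
    post = (1.0 - np.exp(-lam * tinf)) * np.exp(-lam * np.clip(t - tinf, 0.0, None))
    x = np.where(t <= tinf, during, post)
    return coef / lam * np.where(t < 0.0, 0.0, x)


def conc_infusion_single(cl, v1, q, v2, dose, tinf, t):
    """Central concentration after one zero-order infusion starting at t=0.

    All arguments broadcast; concentrations in mg/L.
    """
    alpha, beta, ca, cb = _macro_arrays(
        np.asarray(cl, float), np.asarray(v1, float),
        np.asarray(q, float), np.asarray(v2, float),
    )
    rate = np.asarray(dose, float) / tinf
    out = rate / np.asarray(v1, float) * (
        _infusion_term(alpha, ca, tinf, t) + _infusion_term(beta, cb, tinf, t)
    )
    return out


def _ss_term(lam, coef, tinf, tau, t):
    """One exponential term of the steady-state multiple-infusion solution.

    ``t`` is time within the dosing interval, 0 <= t <= tau.  Each
    exponential carries the accumulation factor 1/(1 - exp(-lam*tau)).
    """
    acc = 1.0 / (1.0 - np.exp(-lam * tau))
    e_tinf = 1.0 - np.exp(-lam * tinf)
    # residual of all previous doses, evaluated during the current infusion
    during = (1.0 - np.exp(-lam * t)) + e_tinf * np.exp(-lam * (t + tau - tinf)) * acc
    post = e_tinf * np.exp(-lam * (t - tinf)) * acc
    return coef / lam * np.where(t < tinf, during, post)


def conc_ss(cl, v1, q, v2, dose, tinf, tau, t):
    """Steady-state central concentration at time ``t`` within the interval.

    Broadcasts over all arguments; ``t`` must satisfy 0 <= t <= tau
    (``conc_steady_state`` validates, this kernel assumes it).
    """
    cl = np.asarray(cl, float)
    v1 = np.asarray(v1, float)
    alpha, beta, ca, cb = _macro_arrays(cl, v1, np.asarray(q, float), np.asarray(v2, float))
    t = np.asarray(t, dtype=float)
    rate = np.asarray(dose, float) / tinf
    return rate / v1 * (_ss_term(alpha, ca, tinf, tau, t) + _ss_term(beta, cb, tinf, tau, t))


def conc_profile(
    cl: float,
    v1: float,
    q: float,
    v2: float,
    regimen: DosingRegimen,
    times: Sequence[float],
) -> np.ndarray:
    """Concentration-time profile for an individual under a dosing regimen.

    For a finite number of doses the profile is the superposition of
    single-infusion solutions; for ``n_doses=None`` (steady state) the
    closed-form accumulation solution is evaluated at ``t mod tau``.
    """
    times = np.asarray(times, dtype=float)
    if regimen.dose == 0:
        return np.zeros_like(times)
    if regimen.steady_state:
        t_in = np.mod(times, regimen.tau)
        return conc_ss(
            cl, v1, q, v2, regimen.dose, regimen.infusion_duration, regimen.tau, t_in
        )
    out = np.zeros_like(times)
    for k in range(regimen.n_doses):
        out += conc_infusion_single(
            cl, v1, q, v2, regimen.dose, regimen.infusion_duration,
            times - k * regimen.tau,
        )
    return out


def conc_steady_state(
    cl: float,
    v1: float,
    q: float,
    v2: float,
    regimen: DosingRegimen,
    t_in_interval,
) -> np.ndarray | float:
    """Steady-state concentration at a time within the dosing interval.

    The solution is tau-periodic: the value at t=0 (pre-dose) equals the
    value at t=tau (the trough).
    """
    t = np.asarray(t_in_interval, dtype=float)
    if np.any(t < 0) or np.any(t > regimen.tau):
        raise ValueError("t_in_interval must lie in [0, tau]")
    if regimen.dose == 0:
        out = np.zeros_like(t)
    else:
        out = conc_ss(cl, v1, q, v2, regimen.dose, regimen.infusion_duration, regimen.tau, t)
    return float(out) if out.ndim == 0 else out


def apply_covariates(params: PKParams, model: CovariateModel, covs) -> dict[str, float]:
    """Individual typical parameters after applying covariate effects.

    Returns a dict with keys ``cl``, ``v1``, ``q``, ``v2`` (L/h or L).  With an
    empty model, CL equals ``theta_nr`` and the volumes/Q are unchanged.  The
    published additive CrCl power effect on CL reproduces
    :func:`typical_clearance`.
    """
    values = {"cl": params.theta_nr, "v1": params.v1, "q": params.q, "v2": params.v2}
    for eff in model:
        cov_val = getattr(covs, eff.covariate, None) if not isinstance(covs, dict) else covs.get(eff.covariate)
        if cov_val is None:
            subj = getattr(covs, "subject_id", None) or ""
            raise ValueError(
                f"covariate {eff.covariate!r} required by the model is missing"
                + (f" for subject {subj}" if subj else "")
            )
        base = values[eff.parameter]
        if eff.form == "linear":
            values[eff.parameter] = base * (1.0 + eff.coef * (cov_val - eff.center))
        elif eff.form == "exponential":
            values[eff.parameter] = base * math.exp(eff.coef * (cov_val - eff.center))
        elif eff.form == "power":
            values[eff.parameter] = base * (cov_val / eff.center) ** eff.coef
        elif eff.form == "additive_power":
            values[eff.parameter] = base + (cov_val / eff.center) ** eff.coef
        elif eff.form == "shift":
            if cov_val == eff.category:
                values[eff.parameter] = base * (1.0 + eff.coef)
    return values
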