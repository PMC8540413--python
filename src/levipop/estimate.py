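"""Nonlinear mixed-effects estimation by FOCE with interaction.

The marginal likelihood of each subject's data is approximated by
linearising the model around the subject's conditional mode eta_hat (the
empirical Bayes estimate).  With f(eta) the structural prediction, G the
Jacobian df/deta at eta_hat, and v(eta_hat) the residual variance evaluated
at the conditional prediction (the "interaction"), the subject contribution
to the objective function is

    OFV_i = log det V_i + r_i' V_i^{-1} r_i,
    V_i   = G Omega G' + diag(v),   r_i = y - f(eta_hat) + G eta_hat,

and the total OFV (NONMEM convention: -2 log-likelihood without the
n log 2pi constant) is the sum over subjects.  The conditional mode
minimises

    l(eta) = sum_j [ (y_j - f_j(eta))^2 / v_j(eta) + log v_j(eta) ]
             + eta' Omega^{-1} eta

by a damped Newton iteration, batched across subjects.  Fixed effects and
variance parameters are optimised on log scale; standard errors come from
the central-difference Hessian of the OFV.

Also provided: stepwise covariate model building with forward-inclusion /
backward-elimination OFV gates, and the nonparametric (subject-resampling)
bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model import CovariateEffect, CovariateModel, PKParams
from .popsim import ModelBundle, OmegaSpec, ResidualSpec

logger = logging.getLogger("levipop")

__all__ = [
    "FitResult",
    "SCMConfig",
    "BootstrapResult",
    "foce_objective",
    "ofv_foce",
    "fit",
    "scm",
    "bootstrap",
]

_VAR_FLOOR = 1e-10  # residual-variance floor guarding f -> 0 predictions


# ---------------------------------------------------------------------------
# generic FOCE-I engine


def _subject_objective(y, f, v, obs_subj, n_subj, eta, omega_var):
    """l(eta) per subject: conditional -2LL kernel + eta' Omega^-1 eta."""
    dev = (y - f) ** 2 / v + np.log(v)
    l = np.bincount(obs_subj, weights=dev, minlength=n_subj)
    if eta.shape[1]:
        l = l + np.sum(eta**2 / omega_var[None, :], axis=1)
    return l


_ETA_CAP = 8.0  # |eta| beyond this is physically absurd; bounds the search


def _var_deriv(var_fn, f, h=1e-6):
    """Elementwise dv/df of the residual-variance function."""
    step = h * np.maximum(np.abs(f), 1.0)
    return (var_fn(f + step) - var_fn(f - step)) / (2.0 * step)


def _dldf(y, f, var_fn):
    """Elementwise d l / d f for l_j = (y-f)^2/v(f) + log v(f)."""
    resid = y - f
    v = np.maximum(var_fn(f), _VAR_FLOOR)
    dv = _var_deriv(var_fn, f)
    return -2.0 * resid / v + dv * (1.0 / v - resid**2 / v**2)


def _conditional_modes(predict, y, obs_subj, n_subj, omega_var, var_fn, eta0,
                       max_iter=60, gtol=1e-8, hG=1e-6):
    """Batched Levenberg-damped Newton search for the conditional modes.

    ``predict(eta)`` maps an (n_subj, k) eta matrix to per-observation
    predictions.  Because the residual variance is an explicit function of
    the prediction, the gradient of l(eta) is exact given the Jacobian
    G = df/deta (forward differences, one predict call per eta dimension),
    and the Hessian G' diag(d2l/df2) G + 2 Omega^-1 is exact up to the
    d2f/deta2 term; per-subject adaptive damping handles indefiniteness and
    overshoot.  Warm starts are sanity-checked against a zero start so a
    poisoned history (from an extreme parameter trial elsewhere) cannot
    stall the search.
    """
    k = eta0.shape[1]

    def evaluate(e):
        # extreme trial etas legitimately overflow; non-finite l is rejected
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            f = predict(e)
            v = np.maximum(var_fn(f), _VAR_FLOOR)
            l = _subject_objective(y, f, v, obs_subj, n_subj, e, omega_var)
        return f, v, np.where(np.isfinite(l), l, np.inf)

    eta = np.clip(np.nan_to_num(eta0, nan=0.0), -_ETA_CAP, _ETA_CAP)
    f_cur, v_cur, l_cur = evaluate(eta)
    if np.any(eta != 0.0):
        f0, v0, l0 = evaluate(np.zeros_like(eta))
        worse = l0 < l_cur
        eta[worse] = 0.0
        m = worse[obs_subj]
        f_cur[m], v_cur[m] = f0[m], v0[m]
        l_cur[worse] = l0[worse]
    lam = np.full(n_subj, 1e-3)
    eye = np.eye(k)
    inv_omega2 = 2.0 / omega_var
    stalled_rounds = 0
    for _ in range(max_iter):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            G = np.empty((y.size, k))
            for a in range(k):
                e = eta.copy()
                e[:, a] += hG
                G[:, a] = (predict(e) - f_cur) / hG
            dldf = _dldf(y, f_cur, var_fn)
            grad = np.stack([np.bincount(obs_subj, weights=G[:, a] * dldf,
                                         minlength=n_subj) for a in range(k)],
                            axis=1)
            grad += eta * inv_omega2[None, :]
            grad = np.nan_to_num(grad, nan=0.0, posinf=1e12, neginf=-1e12)
            # curvature d2l/df2 by elementwise differencing of dldf
            hf = 1e-5 * np.maximum(np.abs(f_cur), 1.0)
            d2 = (_dldf(y, f_cur + hf, var_fn)
                  - _dldf(y, f_cur - hf, var_fn)) / (2 * hf)
            hess = np.empty((n_subj, k, k))
            for a in range(k):
                for b_ in range(a, k):
                    acc = np.bincount(obs_subj,
                                      weights=G[:, a] * G[:, b_] * d2,
                                      minlength=n_subj)
                    hess[:, a, b_] = hess[:, b_, a] = acc
            hess += np.diag(inv_omega2)[None, :, :]
            hess = np.nan_to_num(hess, nan=0.0, posinf=1e12, neginf=-1e12)
        gnorm = np.max(np.abs(grad), axis=1)
        # scale-aware tolerance: huge l values cannot meet an absolute gtol
        tol = gtol * np.maximum(1.0, np.abs(l_cur))
        pending = gnorm > tol
        if not pending.any():
            break
        if k == 1:
            eigmin = hess[:, 0, 0]
        elif k == 2:
            tr = hess[:, 0, 0] + hess[:, 1, 1]
            det_part = np.sqrt((hess[:, 0, 0] - hess[:, 1, 1]) ** 2
                               + 4.0 * hess[:, 0, 1] ** 2)
            eigmin = 0.5 * (tr - det_part)
        else:
            eigmin = np.linalg.eigvalsh(hess).min(axis=1)
        lam_floor = np.maximum(0.0, 1e-6 - eigmin)
        any_progress = False
        max_gain = 0.0
        for _attempt in range(6):
            if not pending.any():
                break
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                H = hess + (lam + lam_floor)[:, None, None] * eye[None, :, :]
                if k == 2:
                    det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] * H[:, 1, 0]
                    det = np.where(np.abs(det) < 1e-300, 1e-300, det)
                    step = np.empty_like(grad)
                    step[:, 0] = -(H[:, 1, 1] * grad[:, 0]
                                   - H[:, 0, 1] * grad[:, 1]) / det
                    step[:, 1] = -(H[:, 0, 0] * grad[:, 1]
                                   - H[:, 1, 0] * grad[:, 0]) / det
                elif k == 1:
                    step = -grad / np.maximum(H[:, :, 0], 1e-300)
                else:
                    step = -np.linalg.solve(H, grad[:, :, None])[:, :, 0]
                # cap the step so a flat Hessian cannot fling eta to overflow
                step = np.nan_to_num(step, nan=0.0, posinf=1e12, neginf=-1e12)
                norms = np.linalg.norm(step, axis=1)
                step *= np.minimum(1.0, 3.0 / np.maximum(norms, 1e-300))[:, None]
            trial = np.clip(eta + step * pending[:, None], -_ETA_CAP, _ETA_CAP)
            f_t, v_t, l_t = evaluate(trial)
            better = (l_t < l_cur) & pending
            if better.any():
                max_gain = max(max_gain, float(np.max((l_cur - l_t)[better])))
            eta[better] = trial[better]
            m = better[obs_subj]
            f_cur[m], v_cur[m] = f_t[m], v_t[m]
            l_cur[better] = l_t[better]
            lam[better] = np.maximum(lam[better] / 3.0, 1e-8)
            lam[pending & ~better] *= 10.0
            any_progress |= bool(better.any())
            pending = pending & ~better
        if not any_progress:
            break
        stalled_rounds = stalled_rounds + 1 if max_gain < 1e-11 else 0
        if stalled_rounds >= 2:
            break
    return eta, l_cur


def foce_objective(predict, y, obs_subj, n_subj, omega_sd, var_fn,
                   eta0=None, interaction=True, return_detail=False):
    """FOCE(-I) objective for a generic nonlinear mixed model.

    Parameters
    ----------
    predict : callable
        ``predict(eta)`` with eta of shape (n_subj, k) returning
        per-observation structural predictions.
    y, obs_subj : arrays
        Observations and their subject indices (0..n_subj-1).
    omega_sd : array (k,)
        SDs of the (independent) random effects.
    var_fn : callable
        Residual variance as a function of the prediction vector.
    interaction : bool
        If True (FOCE-I) the residual variance is evaluated at the
        conditional prediction f(eta_hat); if False at f(0).

    Returns the scalar OFV, or (ofv, eta_hat, detail) with
    ``return_detail=True``.
    """
    y = np.asarray(y, dtype=float)
    obs_subj = np.asarray(obs_subj)
    k = len(omega_sd)
    if k == 0:
        f = predict(np.zeros((n_subj, 0)))
        v = np.maximum(var_fn(f), _VAR_FLOOR)
        ofv = float(np.sum((y - f) ** 2 / v + np.log(v)))
        if return_detail:
            return ofv, np.zeros((n_subj, 0)), {"f": f, "v": v}
        return ofv
    omega_sd = np.asarray(omega_sd, dtype=float)
    if np.any(omega_sd <= 0):
        raise ValueError("omega SDs must be strictly positive (drop zero terms)")
    omega_var = omega_sd**2
    eta0 = np.zeros((n_subj, k)) if eta0 is None else np.asarray(eta0, dtype=float).copy()
    eta_hat, _ = _conditional_modes(predict, y, obs_subj, n_subj, omega_var, var_fn, eta0)

    f_hat = predict(eta_hat)
    v = np.maximum(var_fn(f_hat if interaction else predict(np.zeros_like(eta_hat))),
                   _VAR_FLOOR)
    # Jacobian G = df/deta at eta_hat, forward differences
    hG = 1e-6
    G = np.empty((y.size, k))
    for a in range(k):
        e = eta_hat.copy()
        e[:, a] += hG
        G[:, a] = (predict(e) - f_hat) / hG

    w = 1.0 / v
    r = y - f_hat + np.sum(G * eta_hat[obs_subj], axis=1)
    # Woodbury assembly with diagonal Omega
    M = np.empty((n_subj, k, k))
    for a in range(k):
        for b_ in range(a, k):
            acc = np.bincount(obs_subj, weights=G[:, a] * G[:, b_] * w,
                              minlength=n_subj)
            M[:, a, b_] = M[:, b_, a] = acc
    M += np.diag(1.0 / omega_var)[None, :, :]
    b = np.stack([np.bincount(obs_subj, weights=G[:, a] * w * r,
                              minlength=n_subj) for a in range(k)], axis=1)
    Minv_b = np.linalg.solve(M, b[:, :, None])[:, :, 0]
    quad = (np.bincount(obs_subj, weights=r**2 * w, minlength=n_subj)
            - np.sum(b * Minv_b, axis=1))
    _, logdet_M = np.linalg.slogdet(M)
    logdet_V = (np.bincount(obs_subj, weights=np.log(v), minlength=n_subj)
                + np.sum(np.log(omega_var)) + logdet_M)
    per_subject = quad + logdet_V
    ofv = float(np.sum(per_subject))
    if return_detail:
        return ofv, eta_hat, {"f": f_hat, "v": v, "G": G, "per_subject": per_subject}
    return ofv


# ---------------------------------------------------------------------------
# compiled dataset + vectorised PK prediction


@dataclass
class _Compiled:
    subject_ids: list[str]
    y: np.ndarray
    obs_subj: np.ndarray
    obs_time: np.ndarray
    c_obs: np.ndarray  # contribution row -> observation row
    c_subj: np.ndarray
    c_amt: np.ndarray
    c_t0: np.ndarray
    c_dur: np.ndarray
    c_tau: np.ndarray
    c_ss: np.ndarray  # bool
    covariates: dict  # subject_id -> SubjectCovariates

    @property
    def n_subj(self) -> int:
        return len(self.subject_ids)


def _compile(dataset) -> _Compiled:
    sids = dataset.subject_ids
    index = {s: i for i, s in enumerate(sids)}
    y, obs_subj, obs_time = [], [], []
    c_obs, c_subj, c_amt, c_t0, c_dur, c_tau, c_ss = [], [], [], [], [], [], []
    doses_by_subj: dict[str, list] = {s: [] for s in sids}
    for rec in dataset.records:
        if rec.kind == "dose":
            doses_by_subj[rec.subject_id].append(rec)
    for rec in dataset.records:
        if rec.kind != "observation":
            continue
        j = len(y)
        y.append(rec.concentration)
        obs_subj.append(index[rec.subject_id])
        obs_time.append(rec.time)
        for d in doses_by_subj[rec.subject_id]:
            c_obs.append(j)
            c_subj.append(index[rec.subject_id])
            c_amt.append(d.amount)
            c_t0.append(d.time)
            c_dur.append(d.infusion_duration)
            c_tau.append(d.tau if d.tau is not None else np.inf)
            c_ss.append(d.ss)
    if not y:
        raise ValueError("dataset has no observations to fit")
    return _Compiled(
        subject_ids=sids,
        y=np.array(y), obs_subj=np.array(obs_subj), obs_time=np.array(obs_time),
        c_obs=np.array(c_obs, dtype=int), c_subj=np.array(c_subj, dtype=int),
        c_amt=np.array(c_amt), c_t0=np.array(c_t0), c_dur=np.array(c_dur),
        c_tau=np.array(c_tau), c_ss=np.array(c_ss, dtype=bool),
        covariates=dict(dataset.subjects),
    )


def _covariate_arrays(compiled: _Compiled, covmodel: CovariateModel) -> dict[str, np.ndarray]:
    arrays = {}
    for eff in covmodel:
        if eff.covariate in arrays:
            continue
        vals = []
        for sid in compiled.subject_ids:
            v = getattr(compiled.covariates[sid], eff.covariate)
            if v is None:
                raise ValueError(
                    f"covariate {eff.covariate!r} missing for subject {sid}"
                )
            vals.append(v)
        arrays[eff.covariate] = np.asarray(
            vals, dtype=object if eff.form == "shift" else float
        )
    return arrays


def _typical_params(struct: Mapping[str, float], covmodel: CovariateModel,
                    coefs: Mapping[int, float], cov_arrays, n_subj):
    """Per-subject typical cl/v1/q/v2 after covariate effects (vectorised)."""
    values = {name: np.full(n_subj, struct[name]) for name in ("cl", "v1", "q", "v2")}
    for idx, eff in enumerate(covmodel):
        coef = coefs[idx]
        cov = cov_arrays[eff.covariate]
        base = values[eff.parameter]
        if eff.form == "linear":
            values[eff.parameter] = base * (1.0 + coef * (cov.astype(float) - eff.center))
        elif eff.form == "exponential":
            values[eff.parameter] = base * np.exp(coef * (cov.astype(float) - eff.center))
        elif eff.form == "power":
            values[eff.parameter] = base * (cov.astype(float) / eff.center) ** coef
        elif eff.form == "additive_power":
            values[eff.parameter] = base + (cov.astype(float) / eff.center) ** coef
        elif eff.form == "shift":
            hit = np.array([c == eff.category for c in cov])
            values[eff.parameter] = base * np.where(hit, 1.0 + coef, 1.0)
    return values


try:  # compiled kernel: the predictor is the hot path of every fit
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=False)
def _conc_kernel(cl, v1, q, v2, c_subj, c_obs, amt, t0, dur, tau, ss,
                 obs_time, n_obs):  # pragma: no cover - exercised via predict
    out = np.zeros(n_obs)
    for i in range(c_obs.size):
        s = c_subj[i]
        k10 = cl[s] / v1[s]
        k12 = q[s] / v1[s]
        k21 = q[s] / v2[s]
        tot = k10 + k12 + k21
        disc = math.sqrt(max(tot * tot - 4.0 * k10 * k21, 0.0))
        al = 0.5 * (tot + disc)
        be = 0.5 * (tot - disc)
        if be < 1e-300:
            be = 1e-300
        if al - be < 1e-300:
            return out * np.nan  # repeated root: let the caller reject
        ca = (al - k21) / (al - be)
        cb = (k21 - be) / (al - be)
        tinf = dur[i]
        t = obs_time[c_obs[i]] - t0[i]
        conc = 0.0
        if ss[i]:
            ti = t % tau[i]
            # alpha term  (-expm1(-x) = 1 - exp(-x), stable for small x)
            acc = 1.0 / -math.expm1(-al * tau[i])
            e_t = -math.expm1(-al * tinf)
            if ti < tinf:
                x = -math.expm1(-al * ti) \
                    + e_t * math.exp(-al * (ti + tau[i] - tinf)) * acc
            else:
                x = e_t * math.exp(-al * (ti - tinf)) * acc
            conc += ca / al * x
            # beta term
            acc = 1.0 / -math.expm1(-be * tau[i])
            e_t = -math.expm1(-be * tinf)
            if ti < tinf:
                x = -math.expm1(-be * ti) \
                    + e_t * math.exp(-be * (ti + tau[i] - tinf)) * acc
            else:
                x = e_t * math.exp(-be * (ti - tinf)) * acc
            conc += cb / be * x
        elif t > 0.0:
            if t <= tinf:
                conc += ca / al * -math.expm1(-al * t)
                conc += cb / be * -math.expm1(-be * t)
            else:
                conc += ca / al * -math.expm1(-al * tinf) \
                    * math.exp(-al * (t - tinf))
                conc += cb / be * -math.expm1(-be * tinf) \
                    * math.exp(-be * (t - tinf))
        out[c_obs[i]] += conc * amt[i] / tinf / v1[s]
    return out


@_njit(cache=False)
def _pred_sub(o0, o1, c_ptr, c_amt, c_t0, c_dur, c_tau, c_ss, obs_time,
              cl, v1, q, v2, out):  # pragma: no cover - numba kernel
    """Predictions for one subject's observations into out[0:o1-o0]."""
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    tot = k10 + k12 + k21
    disc = math.sqrt(max(tot * tot - 4.0 * k10 * k21, 0.0))
    al = 0.5 * (tot + disc)
    be = 0.5 * (tot - disc)
    if be < 1e-300:
        be = 1e-300
    if al - be < 1e-300:
        for j in range(o1 - o0):
            out[j] = np.nan
        return
    ca = (al - k21) / (al - be)
    cb = (k21 - be) / (al - be)
    for j in range(o0, o1):
        conc = 0.0
        for i in range(c_ptr[j], c_ptr[j + 1]):
            tinf = c_dur[i]
            t = obs_time[j] - c_t0[i]
            if c_ss[i]:
                ti = t % c_tau[i]
                acc = 1.0 / -math.expm1(-al * c_tau[i])
                e_t = -math.expm1(-al * tinf)
                if ti < tinf:
                    x = -math.expm1(-al * ti) \
                        + e_t * math.exp(-al * (ti + c_tau[i] - tinf)) * acc
                else:
                    x = e_t * math.exp(-al * (ti - tinf)) * acc
                cc = ca / al * x
                acc = 1.0 / -math.expm1(-be * c_tau[i])
                e_t = -math.expm1(-be * tinf)
                if ti < tinf:
                    x = -math.expm1(-be * ti) \
                        + e_t * math.exp(-be * (ti + c_tau[i] - tinf)) * acc
                else:
                    x = e_t * math.exp(-be * (ti - tinf)) * acc
                cc += cb / be * x
            elif t > 0.0:
                if t <= tinf:
                    cc = ca / al * -math.expm1(-al * t) \
                        + cb / be * -math.expm1(-be * t)
                else:
                    cc = ca / al * -math.expm1(-al * tinf) * math.exp(-al * (t - tinf)) \
                        + cb / be * -math.expm1(-be * tinf) * math.exp(-be * (t - tinf))
            else:
                cc = 0.0
            conc += cc * c_amt[i] / tinf / v1
        out[j - o0] = conc


@_njit(cache=False)
def _foce_fast(y, obs_time, obs_ptr, c_ptr, c_amt, c_t0, c_dur, c_tau, c_ss,
               typ, kmap, omega_var, s2, a2, eta0,
               gtol, max_iter):  # pragma: no cover - numba kernel
    """Per-subject FOCE-I: damped-Newton conditional modes plus the
    Woodbury-assembled objective, all in one compiled pass.

    Returns (ofv, eta_hat); mirrors the generic engine with the
    proportional(+additive) residual model v = s2*f^2 + a2.
    """
    n_subj = obs_ptr.size - 1
    k = kmap.size
    eta_out = eta0.copy()
    log_om = 0.0
    for a in range(k):
        log_om += math.log(omega_var[a])
    ofv_total = 0.0
    hG = 1e-6
    for s in range(n_subj):
        o0 = obs_ptr[s]
        o1 = obs_ptr[s + 1]
        n_o = o1 - o0
        p = np.empty(4)
        f_cur = np.empty(n_o)
        f_tmp = np.empty(n_o)
        G = np.empty((n_o, k))
        eta = eta_out[s].copy()
        for a in range(k):
            if eta[a] > _ETA_CAP:
                eta[a] = _ETA_CAP
            elif eta[a] < -_ETA_CAP:
                eta[a] = -_ETA_CAP

        # --- local helpers inlined: evaluate l(eta) ---
        def _params(e):
            for c in range(4):
                p[c] = typ[s, c]
            for a in range(k):
                p[kmap[a]] *= math.exp(e[a])

        def _l_of(e, f_buf):
            _params(e)
            _pred_sub(o0, o1, c_ptr, c_amt, c_t0, c_dur, c_tau, c_ss, obs_time,
                      p[0], p[1], p[2], p[3], f_buf)
            l = 0.0
            for j in range(n_o):
                fj = f_buf[j]
                v = s2 * fj * fj + a2
                if v < _VAR_FLOOR:
                    v = _VAR_FLOOR
                d = y[o0 + j] - fj
                l += d * d / v + math.log(v)
            for a in range(k):
                l += e[a] * e[a] / omega_var[a]
            if not math.isfinite(l):
                l = np.inf
            return l

        l_cur = _l_of(eta, f_cur)
        nonzero = False
        for a in range(k):
            if eta[a] != 0.0:
                nonzero = True
        if nonzero:
            zero = np.zeros(k)
            l_zero = _l_of(zero, f_tmp)
            if l_zero < l_cur:
                eta = zero
                l_cur = l_zero
                for j in range(n_o):
                    f_cur[j] = f_tmp[j]
            else:
                l_cur = _l_of(eta, f_cur)  # restore f_cur for eta
        lam = 1e-3
        grad = np.empty(k)
        hess = np.empty((k, k))
        etry = np.empty(k)
        stalled = 0
        for _it in range(max_iter):
            if k == 0:
                break
            # Jacobian by forward differences
            for a in range(k):
                for b in range(k):
                    etry[b] = eta[b]
                etry[a] += hG
                _params(etry)
                _pred_sub(o0, o1, c_ptr, c_amt, c_t0, c_dur, c_tau, c_ss,
                          obs_time, p[0], p[1], p[2], p[3], f_tmp)
                for j in range(n_o):
                    G[j, a] = (f_tmp[j] - f_cur[j]) / hG
            # gradient and curvature through f (dv/df = 2*s2*f analytic)
            for a in range(k):
                grad[a] = 2.0 * eta[a] / omega_var[a]
                for b in range(a, k):
                    hess[a, b] = 0.0
            for j in range(n_o):
                fj = f_cur[j]
                v = s2 * fj * fj + a2
                if v < _VAR_FLOOR:
                    v = _VAR_FLOOR
                d = y[o0 + j] - fj
                dv = 2.0 * s2 * fj
                dldf = -2.0 * d / v + dv * (1.0 / v - d * d / (v * v))
                # second derivative of the per-observation kernel wrt f
                d2 = (2.0 / v + 2.0 * d * dv / (v * v)
                      + 2.0 * s2 * (1.0 / v - d * d / (v * v))
                      + dv * (-dv / (v * v) + 2.0 * d / (v * v)
                              + 2.0 * d * d * dv / (v * v * v)))
                for a in range(k):
                    grad[a] += G[j, a] * dldf
                    for b in range(a, k):
                        hess[a, b] += G[j, a] * G[j, b] * d2
            for a in range(k):
                hess[a, a] += 2.0 / omega_var[a]
                for b in range(a + 1, k):
                    hess[b, a] = hess[a, b]
            gmax = 0.0
            for a in range(k):
                g = abs(grad[a])
                if g > gmax:
                    gmax = g
            tol = gtol * max(1.0, abs(l_cur))
            if gmax <= tol:
                break
            # smallest eigenvalue floor for damping
            if k == 1:
                eigmin = hess[0, 0]
            else:
                tr = hess[0, 0] + hess[1, 1]
                dpart = math.sqrt((hess[0, 0] - hess[1, 1]) ** 2
                                  + 4.0 * hess[0, 1] ** 2)
                eigmin = 0.5 * (tr - dpart)
            lam_floor = max(0.0, 1e-6 - eigmin)
            progressed = False
            max_gain = 0.0
            for _att in range(16):
                d00 = hess[0, 0] + lam + lam_floor
                if k == 2:
                    d11 = hess[1, 1] + lam + lam_floor
                    det = d00 * d11 - hess[0, 1] * hess[1, 0]
                    if abs(det) < 1e-300:
                        det = 1e-300
                    s0 = -(d11 * grad[0] - hess[0, 1] * grad[1]) / det
                    s1 = -(d00 * grad[1] - hess[1, 0] * grad[0]) / det
                    nrm = math.sqrt(s0 * s0 + s1 * s1)
                    if nrm > 3.0:
                        s0 *= 3.0 / nrm
                        s1 *= 3.0 / nrm
                    etry[0] = min(max(eta[0] + s0, -_ETA_CAP), _ETA_CAP)
                    etry[1] = min(max(eta[1] + s1, -_ETA_CAP), _ETA_CAP)
                else:
                    s0 = -grad[0] / max(d00, 1e-300)
                    if abs(s0) > 3.0:
                        s0 = 3.0 if s0 > 0 else -3.0
                    etry[0] = min(max(eta[0] + s0, -_ETA_CAP), _ETA_CAP)
                l_try = _l_of(etry, f_tmp)
                if l_try < l_cur:
                    gain = l_cur - l_try
                    if gain > max_gain:
                        max_gain = gain
                    for a in range(k):
                        eta[a] = etry[a]
                    for j in range(n_o):
                        f_cur[j] = f_tmp[j]
                    l_cur = l_try
                    lam = max(lam / 3.0, 1e-8)
                    progressed = True
                    break
                lam *= 10.0
            if not progressed:
                break
            if max_gain < 1e-11:
                stalled += 1
                if stalled >= 2:
                    break
            else:
                stalled = 0
        for a in range(k):
            eta_out[s, a] = eta[a]
        # --- FOCE-I objective assembly (Woodbury, diagonal Omega) ---
        if k == 0:
            _params(eta)
            _pred_sub(o0, o1, c_ptr, c_amt, c_t0, c_dur, c_tau, c_ss, obs_time,
                      p[0], p[1], p[2], p[3], f_cur)
            for j in range(n_o):
                fj = f_cur[j]
                v = s2 * fj * fj + a2
                if v < _VAR_FLOOR:
                    v = _VAR_FLOOR
                d = y[o0 + j] - fj
                ofv_total += d * d / v + math.log(v)
            continue
        for a in range(k):
            for b in range(k):
                etry[b] = eta[b]
            etry[a] += hG
            _params(etry)
            _pred_sub(o0, o1, c_ptr, c_amt, c_t0, c_dur, c_tau, c_ss, obs_time,
                      p[0], p[1], p[2], p[3], f_tmp)
            for j in range(n_o):
                G[j, a] = (f_tmp[j] - f_cur[j]) / hG
        M = np.zeros((k, k))
        bvec = np.zeros(k)
        quad_diag = 0.0
        logdet_v = 0.0
        for j in range(n_o):
            fj = f_cur[j]
            v = s2 * fj * fj + a2
            if v < _VAR_FLOOR:
                v = _VAR_FLOOR
            w = 1.0 / v
            logdet_v += math.log(v)
            ge = 0.0
            for a in range(k):
                ge += G[j, a] * eta[a]
            r = y[o0 + j] - fj + ge
            quad_diag += r * r * w
            for a in range(k):
                bvec[a] += G[j, a] * w * r
                for b in range(a, k):
                    M[a, b] += G[j, a] * G[j, b] * w
        for a in range(k):
            M[a, a] += 1.0 / omega_var[a]
            for b in range(a + 1, k):
                M[b, a] = M[a, b]
        if k == 1:
            logdet_m = math.log(M[0, 0])
            quad = quad_diag - bvec[0] * bvec[0] / M[0, 0]
        else:
            det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
            logdet_m = math.log(det)
            i00 = M[1, 1] / det
            i11 = M[0, 0] / det
            i01 = -M[0, 1] / det
            quad = quad_diag - (bvec[0] * bvec[0] * i00
                                + 2.0 * bvec[0] * bvec[1] * i01
                                + bvec[1] * bvec[1] * i11)
        ofv_total += quad + logdet_v + log_om + logdet_m
    return ofv_total, eta_out


def _make_predictor(compiled: _Compiled, covmodel: CovariateModel,
                    omega_names: Sequence[str], cov_arrays):
    """Closure factory: (struct, coefs) -> predict(eta) -> per-obs f."""
    from .model import _macro_arrays

    c = compiled
    in_mask = ~c.c_ss
    ss_mask = c.c_ss
    tau_safe = np.where(np.isfinite(c.c_tau), c.c_tau, 1.0)

    def make(struct, coefs):
        typ = _typical_params(struct, covmodel, coefs, cov_arrays, c.n_subj)

        def predict_numba(eta):
            vals = dict(typ)
            for a, name in enumerate(omega_names):
                vals[name] = vals[name] * np.exp(eta[:, a])
            return _conc_kernel(
                np.ascontiguousarray(vals["cl"], dtype=np.float64),
                np.ascontiguousarray(vals["v1"], dtype=np.float64),
                np.ascontiguousarray(vals["q"], dtype=np.float64),
                np.ascontiguousarray(vals["v2"], dtype=np.float64),
                c.c_subj, c.c_obs, c.c_amt, c.c_t0, c.c_dur, tau_safe,
                c.c_ss, c.obs_time, c.y.size,
            )

        def predict_numpy(eta):
            vals = dict(typ)
            for a, name in enumerate(omega_names):
                vals[name] = vals[name] * np.exp(eta[:, a])
            cl = vals["cl"][c.c_subj]
            v1 = vals["v1"][c.c_subj]
            q = vals["q"][c.c_subj]
            v2 = vals["v2"][c.c_subj]
            alpha, beta, ca, cb = _macro_arrays(cl, v1, q, v2)
            t_rel = c.obs_time[c.c_obs] - c.c_t0
            conc = np.zeros(c.c_obs.size)
            if ss_mask.any():
                t_in = np.mod(t_rel[ss_mask], c.c_tau[ss_mask])
                for lam, coefx in ((alpha[ss_mask], ca[ss_mask]),
                                   (beta[ss_mask], cb[ss_mask])):
                    tau = c.c_tau[ss_mask]
                    tinf = c.c_dur[ss_mask]
                    acc = 1.0 / (1.0 - np.exp(-lam * tau))
                    e_t = 1.0 - np.exp(-lam * tinf)
                    during = (1.0 - np.exp(-lam * t_in)) \
                        + e_t * np.exp(-lam * (t_in + tau - tinf)) * acc
                    post = e_t * np.exp(-lam * np.maximum(t_in - tinf, 0.0)) * acc
                    conc[ss_mask] += coefx / lam * np.where(t_in < tinf, during, post)
            if in_mask.any():
                t = t_rel[in_mask]
                tinf = c.c_dur[in_mask]
                for lam, coefx in ((alpha[in_mask], ca[in_mask]),
                                   (beta[in_mask], cb[in_mask])):
                    during = 1.0 - np.exp(-lam * np.clip(t, 0.0, None))
                    post = (1.0 - np.exp(-lam * tinf)) \
                        * np.exp(-lam * np.clip(t - tinf, 0.0, None))
                    conc[in_mask] += coefx / lam * np.where(
                        t < 0.0, 0.0, np.where(t <= tinf, during, post)
                    )
            conc *= (c.c_amt / c.c_dur) / v1
            return np.bincount(c.c_obs, weights=conc, minlength=c.y.size)

        return predict_numba if _HAVE_NUMBA else predict_numpy

    return make


# ---------------------------------------------------------------------------
# parameter layout (natural <-> optimiser scale)


@dataclass
class _Layout:
    names: list[str]
    transforms: list[str]  # "log" | "id"
    bounds: list[tuple[float, float]] | None = None  # natural-scale bounds

    def packed_bounds(self) -> list[tuple[float, float]]:
        out = []
        for (lo, hi), tr in zip(self.bounds, self.transforms):
            if tr == "log":
                out.append((math.log(lo), math.log(hi)))
            else:
                out.append((lo, hi))
        return out

    def pack(self, natural: Sequence[float]) -> np.ndarray:
        out = []
        for v, tr in zip(natural, self.transforms):
            out.append(math.log(v) if tr == "log" else v)
        return np.array(out)

    def unpack(self, x: np.ndarray) -> np.ndarray:
        out = []
        for v, tr in zip(x, self.transforms):
            out.append(math.exp(v) if tr == "log" else v)
        return np.array(out)


def _build_layout(bundle: ModelBundle) -> tuple[_Layout, list[float]]:
    # natural-scale boxes keep every optimiser trial point physically sane
    # (finite OFV), which keeps line searches informative
    names, transforms, init, bounds = [], [], [], []
    p = bundle.params
    for name, val in (("theta_nr", p.theta_nr), ("v1", p.v1), ("q", p.q), ("v2", p.v2)):
        names.append(name); transforms.append("log"); init.append(val)
        bounds.append((0.05, 500.0))
    for idx, eff in enumerate(bundle.covariates):
        if eff.parameter == "cl" and eff.covariate == "crcl" and eff.form == "additive_power":
            name = "theta_r"
        else:
            name = f"beta_{eff.parameter}_{eff.covariate}"
        names.append(name)
        if eff.form == "additive_power":
            transforms.append("log")
            bounds.append((0.02, 8.0))
        else:
            transforms.append("id")
            bounds.append((-10.0, 10.0))
        init.append(eff.coef)
    for om_name in bundle.omega.names:
        names.append(f"omega_{om_name}"); transforms.append("log")
        init.append(max(bundle.omega.terms[om_name], 1e-3))
        bounds.append((1e-3, 4.0))
    if bundle.residual.kind in ("proportional", "combined"):
        names.append("sigma_prop"); transforms.append("log")
        init.append(max(bundle.residual.sigma_prop, 1e-3))
        bounds.append((1e-3, 2.0))
    if bundle.residual.kind in ("additive", "combined"):
        names.append("sigma_add"); transforms.append("log")
        init.append(max(bundle.residual.sigma_add, 1e-3))
        bounds.append((1e-3, 50.0))
    return _Layout(names, transforms, bounds), init


def _bundle_from_values(bundle: ModelBundle, layout: _Layout,
                        values: np.ndarray) -> ModelBundle:
    d = dict(zip(layout.names, values))
    n_eff = len(bundle.covariates.effects)
    effects = []
    theta_r = bundle.params.theta_r
    for idx, eff in enumerate(bundle.covariates):
        if eff.parameter == "cl" and eff.covariate == "crcl" and eff.form == "additive_power":
            coef = d["theta_r"]
            theta_r = coef
        else:
            coef = d[f"beta_{eff.parameter}_{eff.covariate}"]
        effects.append(CovariateEffect(eff.parameter, eff.covariate, eff.form,
                                       eff.center, coef, eff.category))
    params = PKParams(theta_nr=d["theta_nr"], theta_r=theta_r,
                      v1=d["v1"], q=d["q"], v2=d["v2"])
    omega = OmegaSpec(terms={n: d[f"omega_{n}"] for n in bundle.omega.names})
    residual = ResidualSpec(
        kind=bundle.residual.kind,
        sigma_prop=d.get("sigma_prop", 0.0),
        sigma_add=d.get("sigma_add", 0.0),
    )
    return ModelBundle(params=params, covariates=CovariateModel(tuple(effects)),
                       omega=omega, residual=residual)


_PARAM_INDEX = {"cl": 0, "v1": 1, "q": 2, "v2": 3}


def _objective_factory(compiled: _Compiled, bundle: ModelBundle, layout: _Layout):
    if not bundle.omega.diagonal:
        raise NotImplementedError(
            "estimation assumes a diagonal Omega (no eta correlations)"
        )
    cov_arrays = _covariate_arrays(compiled, bundle.covariates)
    omega_names = bundle.omega.names
    k = len(omega_names)
    make_pred = _make_predictor(compiled, bundle.covariates, omega_names, cov_arrays)
    eta_cell = {"eta": np.zeros((compiled.n_subj, k))}
    res_kind = bundle.residual.kind

    c = compiled
    fast = (
        _HAVE_NUMBA and k <= 2
        and all(n in _PARAM_INDEX for n in omega_names)
        and np.all(np.diff(c.obs_subj) >= 0)
        and np.all(np.diff(c.c_obs) >= 0)
    )
    if fast:
        obs_ptr = np.searchsorted(c.obs_subj, np.arange(c.n_subj + 1)).astype(np.int64)
        c_ptr = np.searchsorted(c.c_obs, np.arange(c.y.size + 1)).astype(np.int64)
        kmap = np.array([_PARAM_INDEX[n] for n in omega_names], dtype=np.int64)
        tau_safe = np.where(np.isfinite(c.c_tau), c.c_tau, 1.0)

    def _values_to_parts(values):
        d = dict(zip(layout.names, values))
        struct = {"cl": d["theta_nr"], "v1": d["v1"], "q": d["q"], "v2": d["v2"]}
        coefs = {}
        for idx, eff in enumerate(bundle.covariates):
            if (eff.parameter == "cl" and eff.covariate == "crcl"
                    and eff.form == "additive_power"):
                coefs[idx] = d["theta_r"]
            else:
                coefs[idx] = d[f"beta_{eff.parameter}_{eff.covariate}"]
        sp = d.get("sigma_prop", 0.0)
        sa = d.get("sigma_add", 0.0)
        omega_sd = np.array([d[f"omega_{n}"] for n in omega_names])
        return d, struct, coefs, sp, sa, omega_sd

    def ofv_at(values: np.ndarray, return_detail: bool = False):
        d, struct, coefs, sp, sa, omega_sd = _values_to_parts(values)

        if fast and not return_detail:
            typ = _typical_params(struct, bundle.covariates, coefs, cov_arrays,
                                  c.n_subj)
            typ_mat = np.column_stack([typ["cl"], typ["v1"], typ["q"], typ["v2"]])
            ofv, eta_hat = _foce_fast(
                c.y, c.obs_time, obs_ptr, c_ptr, c.c_amt, c.c_t0, c.c_dur,
                tau_safe, c.c_ss, np.ascontiguousarray(typ_mat), kmap,
                omega_sd**2, sp * sp, sa * sa,
                np.ascontiguousarray(eta_cell["eta"]), 1e-8, 60,
            )
            if np.all(np.isfinite(eta_hat)):
                eta_cell["eta"] = eta_hat
            return ofv

        predict = make_pred(struct, coefs)

        def var_fn(f):
            v = np.zeros_like(f)
            if res_kind in ("proportional", "combined"):
                v = v + (sp * f) ** 2
            if res_kind in ("additive", "combined"):
                v = v + sa**2
            return v

        out = foce_objective(predict, c.y, c.obs_subj, c.n_subj,
                             omega_sd, var_fn, eta0=eta_cell["eta"],
                             return_detail=True)
        ofv, eta_hat, detail = out
        if np.all(np.isfinite(eta_hat)):
            eta_cell["eta"] = eta_hat
        if return_detail:
            return ofv, eta_hat, detail
        return ofv

    return ofv_at


# ---------------------------------------------------------------------------
# public API


@dataclass
class FitResult:
    bundle: ModelBundle  # fitted parameter values
    estimates: dict  # name -> value (natural scale)
    se: dict | None  # name -> SE, None if Hessian not positive definite
    rse_pct: dict | None
    ofv: float
    ebe: pd.DataFrame  # per-subject empirical Bayes eta
    eta_shrinkage_pct: dict
    eps_shrinkage_pct: float
    converged: bool
    n_subjects: int
    n_observations: int
    message: str = ""

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, est in self.estimates.items():
            se = self.se.get(name) if self.se else None
            rows.append({
                "parameter": name, "estimate": est,
                "se": se, "rse_pct": (100.0 * se / abs(est)) if se and est else None,
            })
        return pd.DataFrame(rows)


def ofv_foce(dataset, bundle: ModelBundle, interaction: bool = True) -> float:
    """FOCE(-I) objective function value at the bundle's parameter values."""
    compiled = _compile(dataset)
    layout, init = _build_layout(bundle)
    ofv_at = _objective_factory(compiled, bundle, layout)
    return ofv_at(np.array(init))


def fit(dataset, bundle: ModelBundle, maxiter: int = 300,
        compute_se: bool = True, ftol: float = 1e-9) -> FitResult:
    """Estimate fixed effects, IIV and residual variability by FOCE-I.

    ``bundle`` supplies the model structure and the initial values.  Standard
    errors come from the central-difference Hessian of the OFV (covariance
    2*H^-1); empirical Bayes etas and shrinkage are reported at the optimum.
    """
    compiled = _compile(dataset)
    layout, init = _build_layout(bundle)
    ofv_at = _objective_factory(compiled, bundle, layout)

    first_val: list[float] = []

    def obj(x):
        try:
            val = ofv_at(layout.unpack(x))
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            val = float("nan")
        if not first_val:
            first_val.append(val)
        return val if np.isfinite(val) else 1e12

    x0 = layout.pack(init)
    bounds = layout.packed_bounds()
    x0 = np.clip(x0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "ftol": ftol,
                                     "gtol": 1e-5, "eps": 1e-4})
    if first_val and not np.isfinite(first_val[0]):
        raise ValueError("OFV not finite at the initial values")
    if res.fun >= first_val[0] - 1e-4:
        # quasi-Newton made no headway (noise-limited line search);
        # fall back to a simplex search, which tolerates small noise
        nm = optimize.minimize(obj, res.x, method="Nelder-Mead",
                               options={"maxfev": 250 * x0.size,
                                        "xatol": 1e-5, "fatol": 1e-7,
                                        "adaptive": True})
        if nm.fun < res.fun:
            res = nm
        res.x = np.clip(res.x, [lo for lo, _ in bounds], [hi for _, hi in bounds])
    values = layout.unpack(res.x)
    ofv, eta_hat, detail = ofv_at(values, return_detail=True)
    fitted = _bundle_from_values(bundle, layout, values)
    estimates = dict(zip(layout.names, values))

    se = rse = None
    converged = bool(res.success)
    message = res.message if isinstance(res.message, str) else str(res.message)
    if compute_se:
        try:
            H = _numeric_hessian(lambda v: ofv_at(v), np.asarray(values))
            cov = 2.0 * np.linalg.inv(H)
            diag = np.diag(cov)
            if np.all(diag > 0):
                se_vals = np.sqrt(diag)
                se = dict(zip(layout.names, se_vals))
                rse = {n: 100.0 * s / abs(e) for (n, e), s in
                       zip(estimates.items(), se_vals)}
            else:
                converged = False
                message += "; Hessian not positive definite, SEs unavailable"
        except np.linalg.LinAlgError:
            converged = False
            message += "; Hessian inversion failed, SEs unavailable"

    omega_names = bundle.omega.names
    ebe = pd.DataFrame(eta_hat, index=compiled.subject_ids,
                       columns=[f"eta_{n}" for n in omega_names])
    eta_shr = {}
    for a, n in enumerate(omega_names):
        om = estimates[f"omega_{n}"]
        sd_ebe = float(np.std(eta_hat[:, a], ddof=1)) if eta_hat.shape[0] > 1 else 0.0
        eta_shr[n] = 100.0 * (1.0 - sd_ebe / om) if om > 0 else float("nan")
    iwres = (compiled.y - detail["f"]) / np.sqrt(detail["v"])
    eps_shr = 100.0 * (1.0 - float(np.std(iwres, ddof=1)))

    return FitResult(
        bundle=fitted, estimates=estimates, se=se, rse_pct=rse, ofv=ofv,
        ebe=ebe, eta_shrinkage_pct=eta_shr, eps_shrinkage_pct=eps_shr,
        converged=converged, n_subjects=compiled.n_subj,
        n_observations=compiled.y.size, message=message,
    )


def _numeric_hessian(fun, x, rel_step=1e-4):
    """Central-difference Hessian with per-coordinate relative steps."""
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (
                    4 * h[i] * h[j]
                )
    return H


# ---------------------------------------------------------------------------
# stepwise covariate modelling


@dataclass(frozen=True)
class SCMConfig:
    """Candidates and OFV gates for stepwise covariate model building.

    Each candidate is a :class:`CovariateEffect` template (its ``coef`` is
    the initial value for estimation).  ``forward_delta`` (default 3.84, the
    5% chi-square point for 1 df) gates inclusion; ``backward_delta``
    (default 6.63, the 1% point) gates retention.
    """

    candidates: tuple[CovariateEffect, ...]
    forward_delta: float = 3.84
    backward_delta: float = 6.63

    def __post_init__(self) -> None:
        if not self.forward_delta < self.backward_delta:
            raise ValueError("forward_delta must be < backward_delta")


def _with_effect(bundle: ModelBundle, eff: CovariateEffect) -> ModelBundle:
    return ModelBundle(params=bundle.params,
                       covariates=CovariateModel(bundle.covariates.effects + (eff,)),
                       omega=bundle.omega, residual=bundle.residual)


def _without_effect(bundle: ModelBundle, eff: CovariateEffect) -> ModelBundle:
    rest = tuple(e for e in bundle.covariates.effects
                 if not (e.parameter == eff.parameter and e.covariate == eff.covariate))
    return ModelBundle(params=bundle.params, covariates=CovariateModel(rest),
                       omega=bundle.omega, residual=bundle.residual)


def scm(dataset, base_bundle: ModelBundle, config: SCMConfig,
        maxiter: int = 100, ftol: float = 1e-8) -> tuple[ModelBundle, pd.DataFrame]:
    """Stepwise covariate model building: forward inclusion then backward
    elimination, with a full audit log of every tested step.

    Returns the selected model bundle (with fitted values) and the step log
    (phase, candidate, OFV of both models, delta, decision).
    """
    log_rows = []
    current = fit(dataset, base_bundle, maxiter=maxiter, compute_se=False, ftol=ftol)
    current_bundle = current.bundle
    remaining = list(config.candidates)
    # forward inclusion
    while remaining:
        trials = []
        for eff in remaining:
            pair = (eff.parameter, eff.covariate)
            if any((e.parameter, e.covariate) == pair for e in current_bundle.covariates):
                continue
            try:
                cand_fit = fit(dataset, _with_effect(current_bundle, eff),
                               maxiter=maxiter, compute_se=False, ftol=ftol)
                delta = current.ofv - cand_fit.ofv
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("candidate %s failed: %s", eff, exc)
                delta, cand_fit = -np.inf, None
            log_rows.append({
                "phase": "forward", "parameter": eff.parameter,
                "covariate": eff.covariate, "form": eff.form,
                "ofv_without": current.ofv,
                "ofv_with": cand_fit.ofv if cand_fit else np.nan,
                "delta_ofv": delta,
                "included": False,
            })
            trials.append((delta, eff, cand_fit))
        accepted = [t for t in trials if t[0] >= config.forward_delta and t[2] is not None]
        if not accepted:
            break
        # largest OFV drop wins; ties by lexical order of (parameter, covariate)
        accepted.sort(key=lambda t: (-t[0], t[1].parameter, t[1].covariate))
        delta, eff, cand_fit = accepted[0]
        for row in log_rows:
            if (row["phase"] == "forward" and row["parameter"] == eff.parameter
                    and row["covariate"] == eff.covariate and not row["included"]
                    and row["ofv_without"] == current.ofv):
                row["included"] = True
        current = cand_fit
        current_bundle = cand_fit.bundle
        remaining = [e for e in remaining
                     if (e.parameter, e.covariate) != (eff.parameter, eff.covariate)]
    # backward elimination over covariates added by the search
    candidate_pairs = {(e.parameter, e.covariate) for e in config.candidates}
    changed = True
    while changed:
        changed = False
        removable = [e for e in current_bundle.covariates
                     if (e.parameter, e.covariate) in candidate_pairs]
        trials = []
        for eff in removable:
            reduced = _without_effect(current_bundle, eff)
            try:
                red_fit = fit(dataset, reduced, maxiter=maxiter, compute_se=False, ftol=ftol)
                delta = red_fit.ofv - current.ofv  # increase on removal
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("removal of %s failed: %s", eff, exc)
                continue
            log_rows.append({
                "phase": "backward", "parameter": eff.parameter,
                "covariate": eff.covariate, "form": eff.form,
                "ofv_without": red_fit.ofv, "ofv_with": current.ofv,
                "delta_ofv": delta, "included": delta > config.backward_delta,
            })
            trials.append((delta, eff, red_fit))
        drops = [t for t in trials if t[0] <= config.backward_delta]
        if drops:
            drops.sort(key=lambda t: (t[0], t[1].parameter, t[1].covariate))
            _, eff, red_fit = drops[0]
            current = red_fit
            current_bundle = red_fit.bundle
            changed = True
    return current_bundle, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# nonparametric bootstrap


@dataclass
class BootstrapResult:
    n_replicates: int
    n_failed: int
    replicates: pd.DataFrame  # one row per successful replicate
    summary: pd.DataFrame  # median and 2.5/97.5 percentiles per parameter


def bootstrap(dataset, bundle: ModelBundle, n_replicates: int, seed,
              maxiter: int = 60, ftol: float = 1e-8) -> BootstrapResult:
    """Subject-resampling bootstrap of the model fit.

    Each replicate resamples subjects with replacement to the original
    subject count, re-fits, and records the estimates; the summary reports
    the per-parameter median and 2.5/97.5 percentiles over successful
    replicates.  Raises if more than half the replicates fail.
    """
    from .io import EventRecord, PKDataset

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    sids = dataset.subject_ids
    recs_by_subj = {s: dataset.records_for(s) for s in sids}
    rows = []
    n_failed = 0
    for rep in range(n_replicates):
        chosen = rng.choice(sids, size=len(sids), replace=True)
        records, subjects = [], {}
        for j, sid in enumerate(chosen):
            new_id = f"R{j:03d}_{sid}"
            subjects[new_id] = dataset.subjects[sid]
            for r in recs_by_subj[sid]:
                records.append(EventRecord(
                    subject_id=new_id, time=r.time, kind=r.kind, amount=r.amount,
                    infusion_duration=r.infusion_duration, ss=r.ss, tau=r.tau,
                    concentration=r.concentration, bloq_flag=r.bloq_flag,
                ))
        replicate = PKDataset(records=records, subjects=subjects)
        try:
            f = fit(replicate, bundle, maxiter=maxiter, compute_se=False, ftol=ftol)
            if not np.isfinite(f.ofv):
                raise ValueError("non-finite OFV")
            rows.append({"replicate": rep, "ofv": f.ofv, **f.estimates})
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
    if n_failed > n_replicates / 2:
        raise RuntimeError(
            f"bootstrap unstable: {n_failed}/{n_replicates} replicates failed"
        )
    reps = pd.DataFrame(rows)
    params = [c for c in reps.columns if c not in ("replicate", "ofv")]
    summary = pd.DataFrame({
        "median": reps[params].median(),
        "ci_lo": reps[params].quantile(0.025),
        "ci_hi": reps[params].quantile(0.975),
    })
    return BootstrapResult(n_replicates=n_replicates, n_failed=n_failed,
                           replicates=reps, summary=summary)
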