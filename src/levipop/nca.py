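"""Noncompartmental analysis of steady-state concentration profiles.

Exposure metrics over one dosing interval: Cmax/tmax (observed), AUC_tau by
the linear-log trapezoidal rule, terminal slope lambda_z by best-adjusted-R^2
log-linear regression, half-life ln2/lambda_z, clearance dose/AUC_tau and
Vz = CL/lambda_z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NCAResult", "auc_linlog", "fit_lambda_z", "nca_steady_state", "nca_dataset"]


class TerminalPhaseError(ValueError):
    """Terminal slope not estimable from the data."""


@dataclass(frozen=True)
class NCAResult:
    cmax: float  # mg/L
    tmax: float  # h
    auc_tau: float  # mg*h/L
    lambda_z: float  # 1/h
    t_half: float  # h
    cl: float  # L/h
    vz: float  # L
    n_lambda_points: int
    lambda_fit_r2adj: float


def auc_linlog(times, concs) -> float:
    """AUC by the linear-log trapezoidal rule.

    Per segment: the logarithmic trapezoid (C1-C2)*dt/ln(C1/C2) when the
    concentration declines with both endpoints positive; the linear trapezoid
    otherwise (rising, constant, or zero endpoint).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points for an AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    c1, c2 = c[:-1], c[1:]
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c1 - c2) * dt / np.log(c1 / c2)
    lin_seg = 0.5 * (c1 + c2) * dt
    use_log = (c2 < c1) & (c2 > 0)
    return float(np.sum(np.where(use_log, log_seg, lin_seg)))


def _loglin_fit(t, logc):
    n = t.size
    slope, intercept = np.polyfit(t, logc, 1)
    resid = logc - (slope * t + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, r2adj


def fit_lambda_z(times, concs) -> tuple[float, int, float]:
    """Terminal elimination rate by log-linear regression.

    Candidate windows are the last 3, 4, ... points, excluding the time of
    the maximum concentration; the window with the highest adjusted R^2 wins
    (ties go to more points).  Returns (lambda_z, n_points, r2adj).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    order = np.argsort(t)
    t, c = t[order], c[order]
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < 3:
        raise TerminalPhaseError("need >= 3 positive terminal concentrations")
    i_tmax = int(np.argmax(c))
    best = None
    for n_pts in range(3, t.size + 1):
        idx = np.arange(t.size - n_pts, t.size)
        idx = idx[idx != i_tmax]
        if idx.size < 3:
            continue
        slope, r2adj = _loglin_fit(t[idx], np.log(c[idx]))
        lam = -slope
        if lam <= 0:
            continue
        if best is None or r2adj > best[2] + 1e-12:
            best = (lam, idx.size, r2adj)
    if best is None:
        raise TerminalPhaseError("no terminal window with a positive slope")
    return best


def nca_steady_state(times, concs, dose: float, tau: float) -> NCAResult:
    """Noncompartmental metrics for one steady-state dosing interval.

    CL = dose / AUC_tau (steady-state identity, no extrapolation to
    infinity); Vz = CL / lambda_z; t1/2 = ln2 / lambda_z.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    order = np.argsort(t)
    t, c = t[order], c[order]
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc = auc_linlog(t, c)
    lam, n_pts, r2adj = fit_lambda_z(t, c)
    cl = dose / auc
    return NCAResult(
        cmax=cmax, tmax=tmax, auc_tau=auc, lambda_z=lam,
        t_half=math.log(2.0) / lam, cl=cl, vz=cl / lam,
        n_lambda_points=n_pts, lambda_fit_r2adj=r2adj,
    )


def nca_dataset(dataset) -> pd.DataFrame:
    """Per-subject NCA table for an event-record dataset.

    Uses each subject's observations within one interval and the amount/
    interval of their (steady-state) dose row.  Subjects whose terminal phase
    is not estimable get NaN slope-derived metrics.
    """
    rows = []
    for sid in dataset.subject_ids:
        recs = dataset.records_for(sid)
        doses = [r for r in recs if r.kind == "dose"]
        obs = [(r.time, r.concentration) for r in recs if r.kind == "observation"]
        if not obs or not doses:
            continue
        d = doses[0]
        tau = d.tau if d.tau is not None else 12.0
        t, c = zip(*obs)
        row = {"subject_id": sid, "dose_mg": d.amount, "tau_h": tau,
               "crcl_ml_min": dataset.subjects[sid].crcl}
        try:
            res = nca_steady_state(t, c, d.amount, tau)
            row.update(cmax_mg_L=res.cmax, tmax_h=res.tmax, auc_tau_mg_h_L=res.auc_tau,
                       lambda_z_1_h=res.lambda_z, t_half_h=res.t_half, cl_L_h=res.cl,
                       vz_L=res.vz, n_lambda_points=res.n_lambda_points,
                       lambda_fit_r2adj=res.lambda_fit_r2adj)
        except (TerminalPhaseError, ValueError):
            try:
                auc = auc_linlog(t, c)
                row.update(cmax_mg_L=max(c), tmax_h=t[int(np.argmax(c))],
                           auc_tau_mg_h_L=auc, cl_L_h=d.amount / auc,
                           lambda_z_1_h=np.nan, t_half_h=np.nan, vz_L=np.nan,
                           n_lambda_points=0, lambda_fit_r2adj=np.nan)
            except ValueError:
                continue
        rows.append(row)
    return pd.DataFrame(rows)
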