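"""Model diagnostics: conditional weighted residuals, goodness-of-fit
tables, and the prediction-corrected visual predictive check.

CWRES are the FOCE-linearised residuals r = y - f(eta_hat) + G eta_hat
decorrelated by the inverse square root of the linearised covariance
V = G Omega G' + diag(v); under a correct model they are approximately
standard normal.  The pcVPC normalises observed and simulated values by
bin-typical population predictions before comparing percentiles, removing
the variability explained by dose and covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import _compile, _covariate_arrays, _make_predictor, foce_objective
from .popsim import ModelBundle

logger = logging.getLogger("levipop")

__all__ = ["VPCResult", "cwres", "gof_table", "pcvpc", "plot_pcvpc"]

#: nominal-design bin edges (h after dose): pre-dose, end of infusion,
#: 1-2 h, 3-5 h, 6-8 h, trough
DEFAULT_BIN_EDGES = (-0.001, 0.25, 0.75, 2.5, 5.5, 9.0, 12.001)


def _predictor_for(dataset, bundle: ModelBundle):
    compiled = _compile(dataset)
    cov_arrays = _covariate_arrays(compiled, bundle.covariates)
    make = _make_predictor(compiled, bundle.covariates, bundle.omega.names, cov_arrays)
    struct = {"cl": bundle.params.theta_nr, "v1": bundle.params.v1,
              "q": bundle.params.q, "v2": bundle.params.v2}
    coefs = {}
    for idx, eff in enumerate(bundle.covariates):
        if eff.parameter == "cl" and eff.covariate == "crcl" and eff.form == "additive_power":
            coefs[idx] = bundle.params.theta_r
        else:
            coefs[idx] = eff.coef
    return compiled, make(struct, coefs)


def _bundle_of(fit_or_bundle) -> ModelBundle:
    return fit_or_bundle.bundle if hasattr(fit_or_bundle, "bundle") else fit_or_bundle


def cwres(dataset, fit_or_bundle) -> pd.DataFrame:
    """Conditional weighted residuals for every observation.

    Accepts a :class:`~levipop.estimate.FitResult` or a bare model bundle
    (in which case the conditional modes are recomputed at those values).
    Returns a frame with subject, time, DV, PRED, IPRED and CWRES.
    """
    bundle = _bundle_of(fit_or_bundle)
    compiled, predict = _predictor_for(dataset, bundle)
    omega_sd = np.array([bundle.omega.terms[n] for n in bundle.omega.names])
    var_fn = bundle.residual.variance
    _, eta_hat, detail = foce_objective(
        predict, compiled.y, compiled.obs_subj, compiled.n_subj,
        omega_sd, lambda f: var_fn(f), return_detail=True,
    )
    f_hat, v = detail["f"], detail["v"]
    pred_pop = predict(np.zeros_like(eta_hat)) if omega_sd.size else f_hat
    out = np.empty(compiled.y.size)
    if omega_sd.size == 0:
        out = (compiled.y - f_hat) / np.sqrt(v)
    else:
        G = detail["G"]
        omega = np.diag(omega_sd**2)
        for i in range(compiled.n_subj):
            m = compiled.obs_subj == i
            Gi = G[m]
            Vi = Gi @ omega @ Gi.T + np.diag(v[m])
            ri = compiled.y[m] - f_hat[m] + Gi @ eta_hat[i]
            w, U = np.linalg.eigh(Vi)
            if np.any(w <= 0):
                logger.warning("singular linearised covariance for subject %s",
                               compiled.subject_ids[i])
                w = np.maximum(w, 1e-12)
            out[m] = U @ np.diag(1.0 / np.sqrt(w)) @ U.T @ ri
    return pd.DataFrame({
        "subject_id": [compiled.subject_ids[i] for i in compiled.obs_subj],
        "time_h": compiled.obs_time,
        "dv_mg_L": compiled.y,
        "pred": pred_pop,
        "ipred": f_hat,
        "cwres": out,
    })


def gof_table(dataset, fit_or_bundle) -> pd.DataFrame:
    """Observed vs population/individual predictions plus CWRES (GOF data)."""
    return cwres(dataset, fit_or_bundle)


@dataclass
class VPCResult:
    bin_edges: np.ndarray
    table: pd.DataFrame  # per bin: observed and simulated-band percentiles
    n_replicates: int
    percentiles: tuple = (10.0, 50.0, 90.0)


def _assign_bins(times, edges, min_per_bin=5):
    edges = list(edges)
    idx = np.digitize(times, edges) - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    # merge under-filled bins into their left neighbour
    while True:
        counts = np.bincount(idx, minlength=len(edges) - 1)
        small = [b for b in range(len(edges) - 1) if 0 < counts[b] < min_per_bin]
        if not small or len(edges) <= 2:
            break
        b = small[0]
        drop = b if b > 0 else b + 1
        logger.info("merging VPC bin at edge %.3g (<%d observations)",
                    edges[drop], min_per_bin)
        edges.pop(drop)
        idx = np.clip(np.digitize(times, edges) - 1, 0, len(edges) - 2)
    return idx, np.asarray(edges)


def pcvpc(dataset, bundle: ModelBundle, n_replicates: int = 1000,
          bin_edges=DEFAULT_BIN_EDGES, seed=0,
          percentiles=(10.0, 50.0, 90.0)) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observed and simulated concentrations are multiplied by
    (bin median population prediction) / (own population prediction), then
    the observed 10th/50th/90th percentiles per bin are compared with the
    95% confidence band of the same percentiles across ``n_replicates``
    simulated studies with the original design.
    """
    bundle = _bundle_of(bundle)
    compiled, predict = _predictor_for(dataset, bundle)
    k = len(bundle.omega.names)
    pred = predict(np.zeros((compiled.n_subj, k)))
    bin_idx, edges = _assign_bins(compiled.obs_time, bin_edges)
    n_bins = len(edges) - 1
    bin_median_pred = np.array([
        np.median(pred[bin_idx == b]) if np.any(bin_idx == b) else np.nan
        for b in range(n_bins)
    ])
    with np.errstate(divide="ignore", invalid="ignore"):
        pc_factor = np.where(pred > 0, bin_median_pred[bin_idx] / pred, 1.0)
    pc_obs = compiled.y * pc_factor

    qs = np.asarray(percentiles)
    obs_pcts = np.full((n_bins, qs.size), np.nan)
    for b in range(n_bins):
        m = bin_idx == b
        if m.any():
            obs_pcts[b] = np.percentile(pc_obs[m], qs)

    from .popsim import sample_etas, split_streams

    streams = split_streams(seed, ["eta", "eps"])
    sim_pcts = np.full((n_replicates, n_bins, qs.size), np.nan)
    res = bundle.residual
    for rep in range(n_replicates):
        eta = sample_etas(bundle.omega, compiled.n_subj, streams["eta"])
        f = predict(eta)
        dv = f.copy()
        if res.kind in ("proportional", "combined") and res.sigma_prop > 0:
            dv = dv * (1.0 + streams["eps"].normal(0.0, res.sigma_prop, size=f.shape))
        if res.kind in ("additive", "combined") and res.sigma_add > 0:
            dv = dv + streams["eps"].normal(0.0, res.sigma_add, size=f.shape)
        dv = np.clip(dv, 0.0, None)
        pc_sim = dv * pc_factor
        for b in range(n_bins):
            m = bin_idx == b
            if m.any():
                sim_pcts[rep, b] = np.percentile(pc_sim[m], qs)

    rows = []
    for b in range(n_bins):
        if not np.any(bin_idx == b):
            continue
        row = {
            "bin_lo_h": edges[b], "bin_hi_h": edges[b + 1],
            "t_mid_h": 0.5 * (max(edges[b], 0) + edges[b + 1]),
            "n_obs": int(np.sum(bin_idx == b)),
        }
        for qi, q in enumerate(qs):
            row[f"obs_p{q:g}"] = obs_pcts[b, qi]
            row[f"sim_p{q:g}_lo"] = np.nanpercentile(sim_pcts[:, b, qi], 2.5)
            row[f"sim_p{q:g}_med"] = np.nanpercentile(sim_pcts[:, b, qi], 50.0)
            row[f"sim_p{q:g}_hi"] = np.nanpercentile(sim_pcts[:, b, qi], 97.5)
        rows.append(row)
    return VPCResult(bin_edges=edges, table=pd.DataFrame(rows),
                     n_replicates=n_replicates, percentiles=tuple(qs))


def plot_pcvpc(result: VPCResult, path=None):
    """Render the pcVPC: observed percentile lines over simulated bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table["t_mid_h"]
    fig, ax = plt.subplots(figsize=(7, 5))
    shades = {10.0: "0.85", 50.0: "0.7", 90.0: "0.85"}
    for q in result.percentiles:
        ax.fill_between(t, result.table[f"sim_p{q:g}_lo"],
                        result.table[f"sim_p{q:g}_hi"],
                        color=shades.get(q, "0.8"), zorder=1)
        ax.plot(t, result.table[f"obs_p{q:g}"], "o-",
                color="k" if q == 50.0 else "0.3",
                lw=2 if q == 50.0 else 1, zorder=2,
                label=f"observed p{q:g}")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
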