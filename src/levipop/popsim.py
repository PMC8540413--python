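"""Population simulation: interindividual variability and residual error.

Individual parameters are generated from the fixed effects and covariates by
exponential (log-normal) random effects,

    CL_i = CL_typ(CrCl_i) * exp(eta_1),   V1_i = V1_typ * exp(eta_2),

with eta ~ N(0, Omega); Q and V2 carry no interindividual variability in the
final model.  Observations carry proportional residual error y = f * (1 + eps)
with eps ~ N(0, sigma_prop^2), plus an additive term when configured.

Randomness is organised as purpose-split child streams of one master seed so
that e.g. toggling residual noise never changes the eta sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    CovariateModel,
    DosingRegimen,
    PKParams,
    apply_covariates,
    conc_profile,
)

logger = logging.getLogger("levipop")

__all__ = [
    "OmegaSpec",
    "ResidualSpec",
    "IndividualParams",
    "ModelBundle",
    "SimulatedProfile",
    "split_streams",
    "sample_individual",
    "sample_etas",
    "simulate_observations",
    "simulate_study",
    "simulate_from_dataset",
]


@dataclass(frozen=True)
class OmegaSpec:
    """Between-subject variability: SD of log-scale random effects per
    parameter (reported in tables as 100*omega %), optionally with
    correlations between named pairs."""

    terms: Mapping[str, float] = field(
        default_factory=lambda: {"cl": 0.327, "v1": 0.561}
    )
    correlations: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, om in self.terms.items():
            if om < 0:
                raise ValueError(f"omega for {name} must be >= 0, got {om}")
        # materialise the covariance matrix once; raises if not PSD
        np.linalg.cholesky(self.matrix() + 1e-12 * np.eye(len(self.terms)))

    @property
    def names(self) -> list[str]:
        return list(self.terms)

    def matrix(self) -> np.ndarray:
        names = self.names
        k = len(names)
        om = np.array([self.terms[n] for n in names])
        cov = np.diag(om**2)
        for (a, b), rho in self.correlations.items():
            ia, ib = names.index(a), names.index(b)
            cov[ia, ib] = cov[ib, ia] = rho * om[ia] * om[ib]
        return cov

    @property
    def diagonal(self) -> bool:
        return not any(v != 0 for v in self.correlations.values())


@dataclass(frozen=True)
class ResidualSpec:
    """Residual (within-subject) error model."""

    kind: str = "proportional"  # proportional | additive | combined
    sigma_prop: float = 0.223  # fraction (22.3% in the final model)
    sigma_add: float = 0.0  # mg/L

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown residual model {self.kind!r}")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual sigmas must be >= 0")
        if self.kind == "proportional" and self.sigma_add != 0:
            raise ValueError("proportional model cannot carry sigma_add")
        if self.kind == "additive" and self.sigma_prop != 0:
            raise ValueError("additive model cannot carry sigma_prop")

    def variance(self, f):
        """Residual variance at prediction ``f`` (elementwise)."""
        f = np.asarray(f, dtype=float)
        v = np.zeros_like(f)
        if self.kind in ("proportional", "combined"):
            v = v + (self.sigma_prop * f) ** 2
        if self.kind in ("additive", "combined"):
            v = v + self.sigma_add**2
        return v


@dataclass(frozen=True)
class ModelBundle:
    """Fixed effects + covariate model + IIV + residual model: everything a
    simulation or fit needs besides the data."""

    params: PKParams = field(default_factory=PKParams)
    covariates: CovariateModel = None  # type: ignore[assignment]
    omega: OmegaSpec = field(default_factory=OmegaSpec)
    residual: ResidualSpec = field(default_factory=ResidualSpec)

    def __post_init__(self) -> None:
        if self.covariates is None:
            from .model import published_covariate_model

            object.__setattr__(
                self, "covariates", published_covariate_model(self.params)
            )


@dataclass(frozen=True)
class IndividualParams:
    subject_id: str
    eta: tuple[float, ...]
    cl: float
    v1: float
    q: float
    v2: float
    crcl: float

    def __post_init__(self) -> None:
        if min(self.cl, self.v1, self.q, self.v2) <= 0:
            raise ValueError("individual parameters must be positive")


@dataclass(frozen=True)
class SimulatedProfile:
    """Per-subject concentration-time curve with and without residual error."""

    subject_id: str
    times: np.ndarray
    pred: np.ndarray  # structural (noise-free) predictions
    dv: np.ndarray  # with residual error if requested, else == pred


def split_streams(seed, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Purpose-named independent generators spawned from one master seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def sample_etas(omega: OmegaSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n multivariate-normal eta vectors, shape (n, k)."""
    cov = omega.matrix()
    if not np.any(cov):
        return np.zeros((n, cov.shape[0]))
    return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n)


def _assemble(params, covmodel, omega, covs, eta, subject_id):
    typ = apply_covariates(params, covmodel, covs)
    values = dict(typ)
    for j, name in enumerate(omega.names):
        values[name] = typ[name] * math.exp(eta[j])
    return IndividualParams(
        subject_id=subject_id, eta=tuple(float(e) for e in eta),
        cl=values["cl"], v1=values["v1"], q=values["q"], v2=values["v2"],
        crcl=covs.crcl if not isinstance(covs, dict) else covs["crcl"],
    )


def sample_individual(
    params: PKParams,
    covmodel: CovariateModel,
    omega: OmegaSpec,
    covs,
    rng: np.random.Generator,
    subject_id: str = "1",
) -> IndividualParams:
    """Draw one individual's parameter set under the population model."""
    eta = sample_etas(omega, 1, rng)[0]
    return _assemble(params, covmodel, omega, covs, eta, subject_id)


def simulate_observations(
    ind: IndividualParams,
    regimen: DosingRegimen,
    times: Sequence[float],
    residual: ResidualSpec,
    rng: np.random.Generator | None = None,
    include_residual: bool = True,
) -> SimulatedProfile:
    """Simulate observed concentrations for one individual.

    Structural predictions come from the closed-form profile; residual error
    is applied multiplicatively (and/or additively) when requested.  Negative
    simulated values are floored at zero with a logged count.
    """
    times = np.asarray(times, dtype=float)
    pred = conc_profile(ind.cl, ind.v1, ind.q, ind.v2, regimen, times)
    if not include_residual:
        return SimulatedProfile(ind.subject_id, times, pred, pred.copy())
    if rng is None:
        raise ValueError("rng required when include_residual=True")
    dv = pred.copy()
    if residual.kind in ("proportional", "combined"):
        dv = dv * (1.0 + rng.normal(0.0, residual.sigma_prop, size=times.shape))
    if residual.kind in ("additive", "combined"):
        dv = dv + rng.normal(0.0, residual.sigma_add, size=times.shape)
    n_neg = int(np.sum(dv < 0))
    if n_neg:
        logger.info("floored %d negative simulated concentrations at 0", n_neg)
        dv = np.clip(dv, 0.0, None)
    return SimulatedProfile(ind.subject_id, times, pred, dv)


def simulate_study(design, bundle: ModelBundle, seed):
    """Simulate a full virtual study under a design; see
    :func:`levipop.study.generate_study` (this is the same operation exposed
    from the simulation side)."""
    from .study import generate_study

    return generate_study(design, bundle, seed)


def simulate_from_dataset(dataset, bundle: ModelBundle, rng_eta, rng_eps=None,
                          include_residual: bool = True):
    """Replicate a study: keep every subject's doses, sampling times and
    covariates, redraw eta and residual error.  Returns a new PKDataset.

    Used by the pcVPC (study replication with the original design).
    """
    from .io import EventRecord, PKDataset

    if rng_eps is None:
        rng_eps = rng_eta
    records = []
    for sid in dataset.subject_ids:
        covs = dataset.subjects[sid]
        recs = dataset.records_for(sid)
        ind = sample_individual(bundle.params, bundle.covariates, bundle.omega,
                                covs, rng_eta, subject_id=sid)
        obs_times = np.array([r.time for r in recs if r.kind == "observation"])
        doses = [r for r in recs if r.kind == "dose"]
        pred = _predict_events(ind, doses, obs_times)
        profile = SimulatedProfile(sid, obs_times, pred, pred.copy())
        if include_residual:
            dv = pred * (1.0 + rng_eps.normal(0.0, bundle.residual.sigma_prop, size=pred.shape)) \
                if bundle.residual.kind in ("proportional", "combined") else pred.copy()
            if bundle.residual.kind in ("additive", "combined"):
                dv = dv + rng_eps.normal(0.0, bundle.residual.sigma_add, size=pred.shape)
            dv = np.clip(dv, 0.0, None)
        else:
            dv = pred
        it = iter(range(len(obs_times)))
        for r in recs:
            if r.kind == "dose":
                records.append(r)
            else:
                j = next(it)
                records.append(EventRecord(
                    subject_id=sid, time=r.time, kind="observation",
                    concentration=float(dv[j]), bloq_flag=False,
                ))
    return PKDataset(records=records, subjects=dict(dataset.subjects))


def _predict_events(ind, dose_records, times):
    """Structural prediction at ``times`` given a subject's dose rows."""
    from .model import conc_infusion_single, conc_ss

    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    for d in dose_records:
        if d.ss:
            t_in = np.mod(times - d.time, d.tau)
            out += conc_ss(ind.cl, ind.v1, ind.q, ind.v2, d.amount,
                           d.infusion_duration, d.tau, t_in)
        else:
            out += conc_infusion_single(ind.cl, ind.v1, ind.q, ind.v2, d.amount,
                                        d.infusion_duration, times - d.time)
    return out
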