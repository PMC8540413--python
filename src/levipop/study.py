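"""Virtual-study generator emulating the clinical cohort design.

The emulated study: 27 critically ill ICU subjects on intravenous
levetiracetam at steady state, 500/1000/1500 mg every 12 h as 30-min
infusions (18/6/3 subjects respectively), sampled at 0 h (pre-dose), 0.5 h
(end of infusion), one sample in each of the 1-2 h, 3-5 h and 6-8 h windows,
and 12 h (trough); urinary creatinine clearance spans 54-239 mL/min with
median 117 and ~37% of subjects above the 130 mL/min augmented-renal-
clearance cut-off.  Assay LLOQ is 2 mg/L.

Covariates are drawn independently of each other (the cohort's joint
structure is unreported); each marginal is a truncated log-normal or normal
matched to the cohort's median and observed range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .model import DosingRegimen
from .popsim import (
    ModelBundle,
    sample_individual,
    simulate_observations,
    split_streams,
)

__all__ = ["StudyDesign", "generate_covariates", "generate_study"]


def _default_allocation() -> dict[float, int]:
    return {500.0: 18, 1000.0: 6, 1500.0: 3}


@dataclass(frozen=True)
class StudyDesign:
    """Design of a virtual steady-state PK study.

    ``sampling_windows`` lists the six nominal samples: fixed times as floats
    and random windows as (lo, hi) tuples sampled uniformly per subject.
    ``n_five_sample_subjects`` subjects lose one random mid-interval sample,
    reproducing the cohort's 5-to-6 samples per subject (27*6 - 4 = 158).
    """

    n_subjects: int = 27
    dose_allocation: Mapping[float, int] = field(default_factory=_default_allocation)
    tau: float = 12.0
    infusion_duration: float = 0.5
    sampling_windows: tuple = (0.0, 0.5, (1.0, 2.0), (3.0, 5.0), (6.0, 8.0), 12.0)
    n_five_sample_subjects: int = 4
    lloq: float = 2.0
    bloq_policy: str = "drop"
    steady_state: bool = True

    def __post_init__(self) -> None:
        if sum(self.dose_allocation.values()) != self.n_subjects:
            raise ValueError("dose allocation counts must sum to n_subjects")
        if self.n_five_sample_subjects > self.n_subjects:
            raise ValueError("n_five_sample_subjects cannot exceed n_subjects")

    @classmethod
    def scaled(cls, n_subjects: int, **kwargs) -> "StudyDesign":
        """Design with the study's dose-allocation proportions at another n."""
        base = _default_allocation()
        total = sum(base.values())
        alloc = {d: int(round(c * n_subjects / total)) for d, c in base.items()}
        drift = n_subjects - sum(alloc.values())
        alloc[500.0] += drift  # absorb rounding in the largest group
        n_five = kwargs.pop(
            "n_five_sample_subjects", max(0, int(round(4 * n_subjects / total)))
        )
        return cls(n_subjects=n_subjects, dose_allocation=alloc,
                   n_five_sample_subjects=n_five, **kwargs)


# cohort anchors: median (min-max) per covariate
_CRCL_MEDIAN, _CRCL_LO, _CRCL_HI = 117.0, 54.0, 239.0
# log-scale SD chosen so that P(CrCl > 130) matches the cohort's 37% ARC
# fraction: Phi^-1(0.63) = ln(130/117)/sigma  =>  sigma = 0.3176
_CRCL_SIGMA = math.log(130.0 / 117.0) / stats.norm.ppf(0.63)

_CONTINUOUS = {
    # name: (median, lo, hi, log-scale?)
    "age": (60.0, 23.0, 81.0, False),
    "weight": (80.0, 58.0, 115.0, True),
    "height": (168.0, 148.0, 189.0, False),
    "apache2": (18.0, 5.0, 35.0, False),
    "albumin": (3.4, 2.1, 3.9, False),
    "glucose": (142.0, 91.0, 337.0, True),
    "bilirubin": (0.6, 0.2, 2.1, True),
    "hemoglobin": (11.6, 6.7, 14.5, False),
    "leukocytes": (10.4, 3.0, 24.6, True),
}

_DIAGNOSES = ("haemorrhagic_stroke", "trauma", "other")
_DIAGNOSIS_P = (10 / 27, 8 / 27, 9 / 27)
_P_MALE = 18 / 27


def _trunc_lognormal(median, lo, hi, sigma, n, rng):
    mu = math.log(median)
    a = (math.log(lo) - mu) / sigma
    b = (math.log(hi) - mu) / sigma
    z = stats.truncnorm.ppf(rng.uniform(size=n), a, b)
    return np.exp(mu + sigma * z)


def _trunc_normal(median, lo, hi, sd, n, rng):
    a = (lo - median) / sd
    b = (hi - median) / sd
    return median + sd * stats.truncnorm.ppf(rng.uniform(size=n), a, b)


def generate_covariates(n: int, rng: np.random.Generator):
    """Draw n subjects' baseline covariates matched to the cohort anchors.

    CrCl is truncated log-normal (median 117, truncated to [54, 239]) with
    log-SD calibrated so ~37% of draws exceed the 130 mL/min ARC cut-off.
    Other continuous covariates use truncated normals (or log-normals for
    right-skewed labs) spanning the observed range; diagnosis is multinomial
    10/8/9 over stroke/trauma/other and sex Bernoulli 18/27 male.
    """
    from .io import SubjectCovariates

    if n < 1:
        raise ValueError("n must be >= 1")
    crcl = _trunc_lognormal(_CRCL_MEDIAN, _CRCL_LO, _CRCL_HI, _CRCL_SIGMA, n, rng)
    cont = {}
    for name, (median, lo, hi, logscale) in _CONTINUOUS.items():
        if logscale:
            sigma = min(math.log(hi / median), math.log(median / lo)) / 2.0
            cont[name] = _trunc_lognormal(median, lo, hi, sigma, n, rng)
        else:
            sd = (hi - lo) / 4.0
            cont[name] = _trunc_normal(median, lo, hi, sd, n, rng)
    diagnosis = rng.choice(_DIAGNOSES, size=n, p=_DIAGNOSIS_P)
    sex = np.where(rng.uniform(size=n) < _P_MALE, "male", "female")
    return [
        SubjectCovariates(
            crcl=float(crcl[i]), age=float(cont["age"][i]),
            weight=float(cont["weight"][i]), height=float(cont["height"][i]),
            sex=str(sex[i]), apache2=float(cont["apache2"][i]),
            diagnosis=str(diagnosis[i]), albumin=float(cont["albumin"][i]),
            glucose=float(cont["glucose"][i]), bilirubin=float(cont["bilirubin"][i]),
            hemoglobin=float(cont["hemoglobin"][i]),
            leukocytes=float(cont["leukocytes"][i]),
        )
        for i in range(n)
    ]


def _draw_sampling_times(design: StudyDesign, rng: np.random.Generator) -> np.ndarray:
    times = []
    for w in design.sampling_windows:
        if isinstance(w, tuple):
            times.append(rng.uniform(w[0], w[1]))
        else:
            times.append(float(w))
    return np.sort(np.asarray(times))


def generate_study(design: StudyDesign, bundle: ModelBundle, seed) -> PKDataset:
    """Generate one virtual study dataset under the population model.

    Builds steady-state dose events and per-subject sampling times, simulates
    concentrations with IIV and residual error, censors below-LLOQ samples
    per the design's policy, and returns a validated event-record dataset.
    """
    from .io import AssayConfig, EventRecord, PKDataset

    streams = split_streams(seed, ["covariates", "design", "eta", "eps"])
    covs = generate_covariates(design.n_subjects, streams["covariates"])

    doses = [d for d, c in design.dose_allocation.items() for _ in range(c)]
    # dose allocation is covariate-independent: shuffle assignment
    order = streams["design"].permutation(design.n_subjects)
    five_sample = set(
        streams["design"].choice(
            design.n_subjects, size=design.n_five_sample_subjects, replace=False
        )
    )
    # indices of droppable (mid-interval window) samples
    droppable = [i for i, w in enumerate(design.sampling_windows) if isinstance(w, tuple)]

    assay = AssayConfig(lloq=design.lloq, bloq_policy=design.bloq_policy)
    records: list[EventRecord] = []
    subjects: dict[str, SubjectCovariates] = {}
    n_doses_if_not_ss = max(10, int(math.ceil(120.0 / design.tau)))
    for i in range(design.n_subjects):
        sid = f"S{i + 1:03d}"
        subjects[sid] = covs[i]
        dose = doses[order[i]]
        regimen = DosingRegimen(
            dose=dose, tau=design.tau, infusion_duration=design.infusion_duration,
            n_doses=None if design.steady_state else n_doses_if_not_ss,
        )
        times = _draw_sampling_times(design, streams["design"])
        if i in five_sample and droppable:
            drop = int(streams["design"].choice(droppable))
            times = _drop_window_sample(design, times, drop)
        ind = sample_individual(
            bundle.params, bundle.covariates, bundle.omega, covs[i],
            streams["eta"], subject_id=sid,
        )
        profile = simulate_observations(
            ind, regimen, times, bundle.residual, streams["eps"], include_residual=True
        )
        records.append(EventRecord(
            subject_id=sid, time=0.0, kind="dose", amount=dose,
            infusion_duration=design.infusion_duration,
            ss=design.steady_state, tau=design.tau if design.steady_state else None,
        ))
        for t, dv in zip(profile.times, profile.dv):
            bloq = dv < assay.lloq
            if bloq and assay.bloq_policy == "drop":
                continue
            conc = dv if not bloq else (assay.lloq / 2.0 if assay.bloq_policy == "lloq_half" else 0.0)
            records.append(EventRecord(
                subject_id=sid, time=float(t), kind="observation",
                concentration=float(conc), bloq_flag=bool(bloq),
            ))
    return PKDataset(records=records, subjects=subjects)


def _drop_window_sample(design: StudyDesign, times: np.ndarray, window_idx: int) -> np.ndarray:
    """Remove the sample belonging to the window_idx-th sampling window."""
    lo, hi = design.sampling_windows[window_idx]
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        return times
    drop_at = np.argmax(mask)
    return np.delete(times, drop_at)
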