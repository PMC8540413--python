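"""Event-record dataset format, model configuration, and readers/writers.

The interchange format is a NONMEM-style event-record table: one row per dose
or observation.  Columns (header required; comma- or tab-separated, separator
auto-detected from the header line):

    subject_id, time_h, evid, amt_mg, dur_h, ss, tau_h, dv_mg_L, bloq,
    crcl_ml_min, age_y, weight_kg, height_cm, sex, apache2, diagnosis,
    albumin_g_dl, glucose_mg_dl, bilirubin_mg_dl, hemoglobin_g_dl,
    leukocytes_1e9_L

``evid`` is 1 for dose rows and 0 for observations.  Dose rows carry
``amt_mg``/``dur_h`` and may be flagged ``ss=1`` with a dosing interval
``tau_h``, meaning the subject is at steady state on that regimen (historical
doses are not enumerated).  Observation rows carry ``dv_mg_L`` (mg/L) and a
``bloq`` flag for samples below the assay's lower limit of quantification.
Covariates repeat on every row of a subject.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    CRCL_CENTER,
    CovariateEffect,
    CovariateModel,
    DosingRegimen,
    PKParams,
)
from .popsim import ModelBundle, OmegaSpec, ResidualSpec

logger = logging.getLogger("levipop")

__all__ = [
    "PKDataset",
    "EventRecord",
    "SubjectCovariates",
    "AssayConfig",
    "read_dataset",
    "write_dataset",
    "load_model_config",
    "DatasetError",
]

DATASET_COLUMNS = [
    "subject_id", "time_h", "evid", "amt_mg", "dur_h", "ss", "tau_h",
    "dv_mg_L", "bloq",
    "crcl_ml_min", "age_y", "weight_kg", "height_cm", "sex", "apache2",
    "diagnosis", "albumin_g_dl", "glucose_mg_dl", "bilirubin_mg_dl",
    "hemoglobin_g_dl", "leukocytes_1e9_L",
]

MANDATORY_COLUMNS = ["subject_id", "time_h", "evid", "amt_mg", "dur_h", "dv_mg_L"]

_COV_COLUMN_MAP = {
    "crcl": "crcl_ml_min", "age": "age_y", "weight": "weight_kg",
    "height": "height_cm", "sex": "sex", "apache2": "apache2",
    "diagnosis": "diagnosis", "albumin": "albumin_g_dl",
    "glucose": "glucose_mg_dl", "bilirubin": "bilirubin_mg_dl",
    "hemoglobin": "hemoglobin_g_dl", "leukocytes": "leukocytes_1e9_L",
}


class DatasetError(ValueError):
    """Schema or validation failure in an event-record dataset."""


@dataclass(frozen=True)
class AssayConfig:
    """Assay quantification limits and below-LLOQ handling.

    The assay is linear over 2--100 mg/L; ``bloq_policy`` selects what happens
    to observations below the lower limit: drop the row, impute LLOQ/2, or
    impute zero.
    """

    lloq: float = 2.0
    bloq_policy: str = "drop"

    def __post_init__(self) -> None:
        if not self.lloq > 0:
            raise ValueError("lloq must be > 0")
        if self.bloq_policy not in ("drop", "lloq_half", "zero"):
            raise ValueError(f"unknown bloq_policy {self.bloq_policy!r}")


@dataclass(frozen=True)
class SubjectCovariates:
    """Baseline covariates; missing values are ``None`` and are excluded
    from covariate screening."""

    crcl: float
    age: float | None = None
    weight: float | None = None
    height: float | None = None
    sex: str | None = None
    apache2: float | None = None
    diagnosis: str | None = None
    albumin: float | None = None
    glucose: float | None = None
    bilirubin: float | None = None
    hemoglobin: float | None = None
    leukocytes: float | None = None

    def __post_init__(self) -> None:
        if not (self.crcl > 0 and math.isfinite(self.crcl)):
            raise ValueError(f"crcl must be positive and finite, got {self.crcl!r}")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"covariate {f.name} must be finite, got {v!r}")


@dataclass(frozen=True)
class EventRecord:
    """One dose or observation event.

    Dose rows (kind="dose") carry amount/infusion_duration and optionally a
    steady-state flag with the dosing interval; observation rows carry the
    measured concentration and BLOQ flag.  Kind-specific fields are mutually
    exclusive.
    """

    subject_id: str
    time: float
    kind: str  # "dose" | "observation"
    amount: float | None = None
    infusion_duration: float | None = None
    ss: bool = False
    tau: float | None = None
    concentration: float | None = None
    bloq_flag: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("dose", "observation"):
            raise ValueError(f"kind must be 'dose' or 'observation', got {self.kind!r}")
        if self.time < 0:
            raise ValueError(f"negative time {self.time} for subject {self.subject_id}")
        if self.kind == "dose":
            if self.amount is None or not self.amount > 0:
                raise ValueError(f"dose row needs amount > 0 (subject {self.subject_id})")
            if self.infusion_duration is None or not self.infusion_duration > 0:
                raise ValueError(
                    f"dose row needs infusion duration > 0 (subject {self.subject_id})"
                )
            if self.concentration is not None or self.bloq_flag:
                raise ValueError("dose rows cannot carry observation fields")
            if self.ss and (self.tau is None or not self.tau > 0):
                raise ValueError("steady-state dose rows need tau > 0")
        else:
            if self.amount is not None or self.infusion_duration is not None:
                raise ValueError("observation rows cannot carry dose fields")
            if self.concentration is None or self.concentration < 0:
                raise ValueError(
                    f"observation needs concentration >= 0 (subject {self.subject_id})"
                )


@dataclass
class PKDataset:
    """Ordered event records plus per-subject covariates.

    The single interchange container of the pipeline: the simulator writes it,
    the estimator, NCA, and diagnostics read it.
    """

    records: list[EventRecord] = field(default_factory=list)
    subjects: dict[str, SubjectCovariates] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ---------------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def records_for(self, subject_id: str) -> list[EventRecord]:
        return [r for r in self.records if r.subject_id == subject_id]

    def observations(self) -> list[EventRecord]:
        return [r for r in self.records if r.kind == "observation"]

    def doses(self) -> list[EventRecord]:
        return [r for r in self.records if r.kind == "dose"]

    @property
    def n_observations(self) -> int:
        return sum(1 for r in self.records if r.kind == "observation")

    def validate(self) -> None:
        seen: dict[str, float] = {}
        has_dose: set[str] = set()
        for i, rec in enumerate(self.records):
            if rec.subject_id not in self.subjects:
                raise DatasetError(
                    f"record {i}: subject {rec.subject_id!r} has no covariate entry"
                )
            prev = seen.get(rec.subject_id)
            if prev is not None and rec.time < prev:
                raise DatasetError(
                    f"record {i}: times must be non-decreasing within subject "
                    f"{rec.subject_id} ({rec.time} after {prev})"
                )
            seen[rec.subject_id] = rec.time
            if rec.kind == "dose":
                has_dose.add(rec.subject_id)
        for sid in seen:
            if sid not in has_dose:
                raise DatasetError(f"subject {sid!r} has observations but no dose row")

    def subset(self, subject_ids: Sequence[str]) -> "PKDataset":
        keep = set(subject_ids)
        return PKDataset(
            records=[r for r in self.records if r.subject_id in keep],
            subjects={s: c for s, c in self.subjects.items() if s in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            cov = self.subjects[rec.subject_id]
            rows.append({
                "subject_id": rec.subject_id,
                "time_h": rec.time,
                "evid": 1 if rec.kind == "dose" else 0,
                "amt_mg": rec.amount if rec.kind == "dose" else "",
                "dur_h": rec.infusion_duration if rec.kind == "dose" else "",
                "ss": int(rec.ss) if rec.kind == "dose" else "",
                "tau_h": rec.tau if (rec.kind == "dose" and rec.tau is not None) else "",
                "dv_mg_L": rec.concentration if rec.kind == "observation" else "",
                "bloq": int(rec.bloq_flag) if rec.kind == "observation" else "",
                **{col: ("" if getattr(cov, name) is None else getattr(cov, name))
                   for name, col in _COV_COLUMN_MAP.items()},
            })
        return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def _opt_float(val):
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        return None
    return float(val)


def _opt_str(val):
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        return None
    return str(val)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_dataset(path, assay: AssayConfig | None = None) -> PKDataset:
    """Read and validate an event-record dataset file.

    BLOQ observations (flagged, or with concentration below the assay LLOQ)
    are handled per ``assay.bloq_policy``.  Rows are sorted by subject then
    time.  A parse report (doses / observations / BLOQ counts) is logged.
    """
    assay = assay or AssayConfig()
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing mandatory column(s): {', '.join(missing)}")
    if df.empty:
        logger.info("read %s: 0 subjects, 0 records", path)
        return PKDataset()

    df["subject_id"] = df["subject_id"].astype(str)
    df = df.sort_values(["subject_id", "time_h"], kind="stable").reset_index(drop=True)

    records: list[EventRecord] = []
    subjects: dict[str, SubjectCovariates] = {}
    n_bloq = 0
    for i, row in df.iterrows():
        sid = row["subject_id"]
        t = float(row["time_h"])
        if t < 0:
            raise DatasetError(f"row {i}: negative time {t}")
        if sid not in subjects:
            try:
                subjects[sid] = SubjectCovariates(
                    crcl=float(row.get("crcl_ml_min", float("nan"))),
                    age=_opt_float(row.get("age_y")),
                    weight=_opt_float(row.get("weight_kg")),
                    height=_opt_float(row.get("height_cm")),
                    sex=_opt_str(row.get("sex")),
                    apache2=_opt_float(row.get("apache2")),
                    diagnosis=_opt_str(row.get("diagnosis")),
                    albumin=_opt_float(row.get("albumin_g_dl")),
                    glucose=_opt_float(row.get("glucose_mg_dl")),
                    bilirubin=_opt_float(row.get("bilirubin_mg_dl")),
                    hemoglobin=_opt_float(row.get("hemoglobin_g_dl")),
                    leukocytes=_opt_float(row.get("leukocytes_1e9_L")),
                )
            except ValueError as exc:
                raise DatasetError(f"row {i}: {exc}") from exc
        if int(row["evid"]) == 1:
            amt = _opt_float(row["amt_mg"])
            if amt is None or amt <= 0:
                raise DatasetError(f"row {i}: dose amount must be > 0, got {amt}")
            ss = bool(int(row["ss"])) if _opt_float(row.get("ss")) is not None else False
            try:
                records.append(EventRecord(
                    subject_id=sid, time=t, kind="dose", amount=amt,
                    infusion_duration=_opt_float(row["dur_h"]),
                    ss=ss, tau=_opt_float(row.get("tau_h")),
                ))
            except ValueError as exc:
                raise DatasetError(f"row {i}: {exc}") from exc
        else:
            dv = _opt_float(row["dv_mg_L"])
            if dv is None or dv < 0:
                raise DatasetError(f"row {i}: observation concentration must be >= 0, got {dv}")
            flagged = bool(int(row["bloq"])) if _opt_float(row.get("bloq")) is not None else False
            bloq = flagged or dv < assay.lloq
            if bloq:
                n_bloq += 1
                if assay.bloq_policy == "drop":
                    continue
                dv = assay.lloq / 2.0 if assay.bloq_policy == "lloq_half" else 0.0
            records.append(EventRecord(
                subject_id=sid, time=t, kind="observation",
                concentration=dv, bloq_flag=bloq,
            ))
    ds = PKDataset(records=records, subjects=subjects)
    logger.info(
        "read %s: %d subjects, %d doses, %d observations (%d BLOQ, policy=%s)",
        path, ds.n_subjects, len(ds.doses()), ds.n_observations, n_bloq,
        assay.bloq_policy,
    )
    return ds


def write_dataset(dataset: PKDataset, path) -> Path:
    """Write a dataset as CSV; ``read_dataset`` of the output reproduces it.

    Note BLOQ rows already transformed in memory are written as-is with their
    flag; re-reading with ``bloq_policy='drop'`` would remove them, so
    round-trips of flagged data should use a non-dropping policy.
    """
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# model configuration

_FORM_ALIASES = {
    "linear": "linear", "exponential": "exponential", "power": "power",
    "shift": "shift", "dichotomous-shift": "shift",
    "additive_power": "additive_power", "additive-power": "additive_power",
}


def load_model_config(path=None, text: str | None = None) -> ModelBundle:
    """Load a model bundle from a YAML/JSON config; omitted fields default to
    the final published model.

    Recognised keys (all optional): ``theta_nr``, ``theta_r``, ``v1``, ``q``,
    ``v2`` (fixed effects), ``iiv_cl_pct``, ``iiv_v1_pct`` (100*omega),
    ``residual`` mapping with ``kind``/``sigma_prop_pct``/``sigma_add``, and
    ``covariate_effects`` (list of parameter/covariate/form/center/coef).
    An empty config yields the published final model.
    """
    if text is not None:
        doc = yaml.safe_load(text) or {}
    elif path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    else:
        doc = {}
    if not isinstance(doc, Mapping):
        raise DatasetError("model config must be a mapping")

    defaults = PKParams()
    kwargs = {}
    for key in ("theta_nr", "theta_r", "v1", "q", "v2"):
        val = doc.get(key, getattr(defaults, key))
        if key != "theta_r" and val is not None and val <= 0:
            raise DatasetError(f"parameter {key} must be positive, got {val}")
        kwargs[key] = float(val)
    params = PKParams(**kwargs)

    omega = OmegaSpec(terms={
        "cl": float(doc.get("iiv_cl_pct", 32.7)) / 100.0,
        "v1": float(doc.get("iiv_v1_pct", 56.1)) / 100.0,
    })

    rdoc = doc.get("residual", {}) or {}
    residual = ResidualSpec(
        kind=rdoc.get("kind", "proportional"),
        sigma_prop=float(rdoc.get("sigma_prop_pct", 22.3)) / 100.0,
        sigma_add=float(rdoc.get("sigma_add", 0.0)),
    )

    if "covariate_effects" in doc:
        effects = []
        for e in doc["covariate_effects"] or []:
            form = _FORM_ALIASES.get(str(e.get("form", "")).lower())
            if form is None:
                raise DatasetError(f"unknown covariate function name {e.get('form')!r}")
            effects.append(CovariateEffect(
                parameter=e["parameter"], covariate=e["covariate"], form=form,
                center=float(e.get("center", 1.0)), coef=float(e.get("coef", 0.0)),
                category=e.get("category"),
            ))
        covmodel = CovariateModel(effects=tuple(effects))
    else:
        covmodel = CovariateModel(effects=(
            CovariateEffect("cl", "crcl", "additive_power",
                            center=CRCL_CENTER, coef=params.theta_r),
        ))
    return ModelBundle(params=params, covariates=covmodel, omega=omega, residual=residual)
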