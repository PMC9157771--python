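"""Patient-level data: dosing histories, observations, and tabular I/O.

Datasets are exchanged in the NONMEM-style rectangular layout: one row per
event with columns ``ID, TIME, AMT, RATE, DUR, DV, EVID, MDV`` plus covariate
columns. ``EVID=1`` rows are doses; ``EVID=0`` rows are observations, where
``DV=0`` with ``MDV=1`` means a missing measurement.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateRecord
from .pk import DoseEvent

__all__ = [
    "Observation",
    "Patient",
    "apply_lloq_filter",
    "read_nonmem",
    "write_nonmem",
    "write_truth",
]

log = logging.getLogger(__name__)

LLOQ_DEFAULT = 0.5  # mg/L, assay lower limit of quantification

_COV_COLUMNS = {
    "AGE": "age",
    "SEX": "sex",  # 1 = male, 0 = female
    "WT": "weight",
    "HT": "height",
    "ALB": "albumin",
    "SCR": "serum_creatinine",
    "CRRT": "crrt",
    "DIUR": "residual_diuresis",
    "SEPSIS": "sepsis",
    "CRRTFL": "crrt_flow",
}


@dataclass(frozen=True)
class Observation:
    """One measured concentration."""

    time: float  # h since first dose
    concentration: float  # mg/L
    bql: bool = False  # below the limit of quantification
    occasion: int | None = None


@dataclass
class Patient:
    """Covariates + dosing history + concentration observations.

    ``truth`` is populated for synthetic patients: the generator's η draw and
    the noise-free concentrations at each observation time.
    """

    pid: str
    covariates: CovariateRecord
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    truth: dict | None = None

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def obs_times(self) -> np.ndarray:
        return np.asarray([o.time for o in self.observations], dtype=float)

    @property
    def obs_values(self) -> np.ndarray:
        return np.asarray([o.concentration for o in self.observations], dtype=float)

    def sorted_observations(self) -> list[Observation]:
        return sorted(self.observations, key=lambda o: o.time)


def apply_lloq_filter(patients, lloq: float = LLOQ_DEFAULT):
    """Remove observations below the quantification limit.

    Returns ``(filtered_patients, n_removed)``. Patients left with no
    observation are dropped from the evaluation set (logged).
    """
    if not lloq > 0:
        raise ValueError(f"lloq must be positive, got {lloq}")
    kept: list[Patient] = []
    n_removed = 0
    for p in patients:
        retained = [o for o in p.observations if not o.bql and o.concentration >= lloq]
        n_removed += len(p.observations) - len(retained)
        if retained:
            q = copy.copy(p)
            q.observations = retained
            kept.append(q)
        else:
            log.info("patient %s dropped: no observation above LLOQ %.3g", p.pid, lloq)
    return kept, n_removed


# ---------------------------------------------------------------------------
# NONMEM-style CSV


def write_nonmem(patients, path) -> pd.DataFrame:
    """Write patients to a NONMEM-style CSV; returns the DataFrame written."""
    rows = []
    for p in patients:
        cov = p.covariates
        covs = {
            "AGE": cov.age,
            "SEX": 1 if cov.sex == "male" else 0,
            "WT": cov.weight,
            "HT": cov.height,
            "ALB": cov.albumin,
            "SCR": cov.serum_creatinine,
            "CRRT": int(cov.crrt),
            "DIUR": cov.residual_diuresis,
            "SEPSIS": int(cov.sepsis),
            "CRRTFL": cov.crrt_flow,
        }
        for d in p.doses:
            rows.append({
                "ID": p.pid, "TIME": d.start_time, "AMT": d.amount,
                "RATE": d.rate, "DUR": d.duration, "DV": 0.0,
                "EVID": 1, "MDV": 1, **covs,
            })
        for o in p.observations:
            rows.append({
                "ID": p.pid, "TIME": o.time, "AMT": 0.0, "RATE": 0.0,
                "DUR": 0.0, "DV": 0.0 if o.bql else o.concentration,
                "EVID": 0, "MDV": 1 if o.bql else 0, **covs,
            })
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable")
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def read_nonmem(path) -> list[Patient]:
    """Read a NONMEM-style CSV into a list of patients."""
    df = pd.read_csv(path)
    patients: list[Patient] = []
    for pid, grp in df.groupby("ID", sort=False):
        first = grp.iloc[0]
        kw = {}
        for col, fieldname in _COV_COLUMNS.items():
            if col not in grp.columns:
                continue
            v = first[col]
            if fieldname == "sex":
                kw[fieldname] = "male" if int(v) == 1 else "female"
            elif fieldname in ("crrt", "sepsis"):
                kw[fieldname] = bool(int(v))
            else:
                kw[fieldname] = float(v)
        cov = CovariateRecord(**kw)
        doses = [
            DoseEvent(amount=float(r.AMT), duration=float(r.DUR),
                      start_time=float(r.TIME))
            for r in grp.itertuples()
            if int(r.EVID) == 1
        ]
        obs = [
            Observation(
                time=float(r.TIME),
                concentration=float(r.DV),
                bql=bool(int(r.MDV)) and float(r.DV) == 0.0,
            )
            for r in grp.itertuples()
            if int(r.EVID) == 0
        ]
        patients.append(Patient(pid=str(pid), covariates=cov, doses=doses,
                                observations=obs))
    return patients


def write_truth(patients, path) -> pd.DataFrame:
    """Sidecar CSV with generator ground truth for synthetic cohorts."""
    rows = []
    for p in patients:
        if not p.truth:
            continue
        eta = p.truth.get("eta", {})
        c_true = p.truth.get("c_true", [])
        for o, ct in zip(p.observations, c_true):
            rows.append({
                "ID": p.pid, "TIME": o.time, "C_TRUE": ct,
                "DV": o.concentration, "BQL": int(o.bql),
                **{f"ETA_{k.upper()}": v for k, v in eta.items()},
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6g")
    return df
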