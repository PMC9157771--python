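"""Patient covariates and the clinical derivations the registered models need.

Units follow routine ICU laboratory reporting: serum creatinine in µmol/L
(converted to mg/dL where a model's covariate scale requires it, 88.4 µmol/L
per mg/dL), albumin in g/L, body weight in kg, creatinine clearance in
ml/min, residual diuresis in ml/day, CRRT effluent flow in L/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "UMOL_PER_MGDL",
    "CovariateRecord",
    "cockcroft_gault",
    "mdrd_gfr",
    "modified_scr",
    "ideal_body_weight",
    "adjusted_body_weight",
]

UMOL_PER_MGDL = 88.4  # serum creatinine unit conversion


def cockcroft_gault(age: float, weight: float, scr_umol: float, sex: str) -> float:
    """Creatinine clearance (ml/min) from the Cockcroft–Gault equation.

    Parameters
    ----------
    age : years
    weight : kg
    scr_umol : serum creatinine, µmol/L
    sex : ``"male"`` or ``"female"`` (females scaled by 0.85)
    """
    if scr_umol <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr_umol}")
    if age <= 0 or weight <= 0:
        raise ValueError("age and weight must be positive")
    sex = _norm_sex(sex)
    scr_mgdl = scr_umol / UMOL_PER_MGDL
    clcr = (140.0 - age) * weight / (72.0 * scr_mgdl)
    if sex == "female":
        clcr *= 0.85
    return clcr


def mdrd_gfr(scr_umol: float, age: float, sex: str) -> float:
    """Estimated GFR (ml/min/1.73 m²) from the 4-variable MDRD study equation."""
    if scr_umol <= 0 or age <= 0:
        raise ValueError("serum creatinine and age must be positive")
    sex = _norm_sex(sex)
    scr_mgdl = scr_umol / UMOL_PER_MGDL
    gfr = 175.0 * scr_mgdl ** -1.154 * age ** -0.203
    if sex == "female":
        gfr *= 0.742
    return gfr


def modified_scr(scr_mgdl: float, floor: float = 0.4) -> float:
    """Serum creatinine (mg/dL) with a lower floor.

    Very low creatinine in ICU patients (muscle wasting, dilution) overstates
    renal function; values below ``floor`` are raised to it before entering a
    clearance covariate formula. Default floor 0.4 mg/dL.
    """
    if scr_mgdl <= 0:
        raise ValueError("serum creatinine must be positive")
    return max(scr_mgdl, floor)


def ideal_body_weight(height_cm: float, sex: str) -> float:
    """Devine ideal body weight (kg)."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    sex = _norm_sex(sex)
    base = 50.0 if sex == "male" else 45.5
    return max(base + 0.9055 * (height_cm - 152.4), 1.0)


def adjusted_body_weight(
    weight: float, height_cm: float, sex: str, factor: float = 0.4
) -> float:
    """Adjusted body weight: IBW + factor·(TBW − IBW) when TBW exceeds IBW."""
    ibw = ideal_body_weight(height_cm, sex)
    if weight <= ibw:
        return weight
    return ibw + factor * (weight - ibw)


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("m", "male", "1"):
        return "male"
    if s in ("f", "female", "0"):
        return "female"
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


@dataclass
class CovariateRecord:
    """One patient's covariates at the evaluation time point.

    ``clcr`` may be supplied directly (ml/min); if left ``None`` it is derived
    from serum creatinine with Cockcroft–Gault on access.
    """

    age: float  # years
    sex: str  # "male" / "female"
    weight: float  # kg
    height: float = 166.0  # cm
    albumin: float = 29.1  # g/L
    serum_creatinine: float = 143.0  # µmol/L
    clcr: float | None = None  # ml/min; derived when None
    crrt: bool = False
    residual_diuresis: float = 2000.0  # ml/day
    sepsis: bool = False
    crrt_flow: float = 2.0  # L/h, filtrate + dialysate

    def __post_init__(self) -> None:
        self.sex = _norm_sex(self.sex)
        if self.age < 18:
            raise ValueError(f"adult cohort: age must be ≥ 18, got {self.age}")
        for name in ("weight", "height", "albumin", "serum_creatinine"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        for name in ("residual_diuresis", "crrt_flow"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.clcr is not None and self.clcr < 0:
            raise ValueError(f"clcr must be non-negative, got {self.clcr}")

    @property
    def clcr_cg(self) -> float:
        """Creatinine clearance (ml/min): supplied value or Cockcroft–Gault."""
        if self.clcr is not None:
            return self.clcr
        return cockcroft_gault(self.age, self.weight, self.serum_creatinine, self.sex)

    def namespace(self, mscr_floor: float = 0.4) -> dict[str, float]:
        """Flat symbol table used when evaluating model covariate formulas."""
        scr_mgdl = self.serum_creatinine / UMOL_PER_MGDL
        return {
            "age": float(self.age),
            "wt": float(self.weight),
            "ht": float(self.height),
            "alb": float(self.albumin),
            "alb_gdl": float(self.albumin) / 10.0,  # g/dL scale
            "scr": float(self.serum_creatinine),
            "scr_mgdl": scr_mgdl,
            "mscr": modified_scr(scr_mgdl, floor=mscr_floor),
            "clcr": float(self.clcr_cg),
            "mdrd_clcr": mdrd_gfr(self.serum_creatinine, self.age, self.sex),
            "adjbw": adjusted_body_weight(self.weight, self.height, self.sex),
            "crrt": 1.0 if self.crrt else 0.0,
            "crrt_flow": float(self.crrt_flow),
            "residual_diuresis": float(self.residual_diuresis),
            "sepsis": 1.0 if self.sepsis else 0.0,
            "male": 1.0 if self.sex == "male" else 0.0,
            "female": 1.0 if self.sex == "female" else 0.0,
        }

    def to_dict(self) -> dict:
        return asdict(self)
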