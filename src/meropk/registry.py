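"""Registry of the 14 published meropenem population-PK models.

Each model ships as a human-editable YAML document (``meropk/models/*.yaml``)
holding its structure, fixed effects (θ), covariate formulas, interindividual
variability (IIV, reported as CV%), and residual-error specification.
Covariate formulas are stored as arithmetic expressions over a fixed symbol
table (see :meth:`meropk.covariates.CovariateRecord.namespace`) plus the
model's θ values, so the registry round-trips losslessly through its
serialized form.

Interindividual variability is log-normal: an individual parameter is
P_i = TVP·exp(η), η ~ N(0, ω²). Printed CV% are converted to variances as
ω² = ln(1 + CV²) by default (``iiv_dialect="lognormal_cv"``); the alternative
ω = CV reading is available as ``iiv_dialect="omega_eq_cv"``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .covariates import CovariateRecord, UMOL_PER_MGDL
from .pk import PKParameters

__all__ = [
    "ModelSpec",
    "EtaVector",
    "ModelError",
    "MissingCovariateError",
    "list_models",
    "get_model",
    "model_ids",
    "compute_individual_parameters",
    "reference_record",
]

POPULATION_CLASSES = ("mixed", "non_crrt", "crrt")
PROVENANCE = ("printed", "original_publication", "placeholder")

_EVAL_FUNCS = {
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "min": min,
    "max": max,
    "abs": abs,
    "where": lambda cond, a, b: a if cond else b,
}


class ModelError(ValueError):
    """A model definition is invalid or was used with unsuitable inputs."""


class MissingCovariateError(ModelError):
    """A covariate required by a model's formula is unavailable."""


@dataclass
class EtaVector:
    """Random-effect vector η (log scale) with the Ω it is distributed under."""

    values: np.ndarray
    names: tuple[str, ...]
    omega: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("eta dimension does not match its parameter names")
        if self.omega.shape != (len(self.names), len(self.names)):
            raise ValueError("eta dimension does not match omega")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("eta must be finite")

    @classmethod
    def zeros(cls, model: "ModelSpec", dialect: str = "lognormal_cv") -> "EtaVector":
        return cls(
            np.zeros(len(model.eta_names)), model.eta_names, model.omega(dialect)
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class ModelSpec:
    """One published population-PK model of meropenem.

    ``thetas`` map a name to ``{value, unit, provenance}``; provenance is
    ``printed`` for values transcribed from the evaluated summary table,
    ``original_publication`` for values taken from the cited source, and
    ``placeholder`` for documented defaults standing in for unavailable
    values.
    """

    model_id: str
    label: str
    population_class: str
    n_compartments: int
    parametrization: str  # "clv" or "micro"
    thetas: dict[str, dict]
    formulas: dict[str, str]
    iiv: dict[str, dict]
    sigma: dict
    reference: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.population_class not in POPULATION_CLASSES:
            raise ModelError(
                f"{self.model_id}: unknown population class {self.population_class!r}"
            )
        if self.n_compartments not in (1, 2):
            raise ModelError(f"{self.model_id}: n_compartments must be 1 or 2")
        if self.parametrization not in ("clv", "micro"):
            raise ModelError(f"{self.model_id}: unknown parametrization")
        for name, t in self.thetas.items():
            if t.get("provenance", "printed") not in PROVENANCE:
                raise ModelError(f"{self.model_id}: bad provenance for theta {name}")
        if self.sigma.get("kind") not in ("proportional", "additive", "combined"):
            raise ModelError(f"{self.model_id}: bad residual-error kind")

    # -- random effects -------------------------------------------------
    @property
    def eta_names(self) -> tuple[str, ...]:
        """Parameters carrying IIV, in declaration order."""
        return tuple(self.iiv.keys())

    def omega(self, dialect: str = "lognormal_cv") -> np.ndarray:
        """IIV variance–covariance Ω (diagonal; no covariances are printed)."""
        var = []
        for name, spec in self.iiv.items():
            cv = spec["cv_percent"] / 100.0
            if dialect == "lognormal_cv":
                var.append(math.log1p(cv * cv))
            elif dialect == "omega_eq_cv":
                var.append(cv * cv)
            else:
                raise ValueError(f"unknown IIV dialect {dialect!r}")
        return np.diag(var)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "label": self.label,
            "population_class": self.population_class,
            "n_compartments": self.n_compartments,
            "parametrization": self.parametrization,
            "thetas": copy.deepcopy(self.thetas),
            "formulas": dict(self.formulas),
            "iiv": copy.deepcopy(self.iiv),
            "sigma": dict(self.sigma),
            "reference": dict(self.reference),
            "options": dict(self.options),
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelSpec":
        doc = copy.deepcopy(doc)
        return cls(**doc)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def load(cls, path: str | Path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# registry loading

_REGISTRY: dict[str, ModelSpec] | None = None


def _load_registry() -> dict[str, ModelSpec]:
    global _REGISTRY
    if _REGISTRY is None:
        reg = {}
        root = resources.files("meropk") / "models"
        for entry in sorted(root.iterdir(), key=lambda p: p.name):
            if entry.name.endswith(".yaml"):
                spec = ModelSpec.from_dict(yaml.safe_load(entry.read_text()))
                reg[spec.model_id] = spec
        _REGISTRY = reg
    return _REGISTRY


def model_ids() -> list[str]:
    return sorted(_load_registry())


def list_models(population_class: str | None = None) -> list[ModelSpec]:
    """All registered models, optionally filtered by development population.

    ``population_class`` ∈ {"mixed", "non_crrt", "crrt"} or None for all;
    ordering is stable (by model_id).
    """
    if population_class is not None and population_class not in POPULATION_CLASSES:
        raise ValueError(
            f"unknown population class {population_class!r}; "
            f"expected one of {POPULATION_CLASSES}"
        )
    reg = _load_registry()
    return [
        reg[mid]
        for mid in sorted(reg)
        if population_class is None or reg[mid].population_class == population_class
    ]


def get_model(model_id: str) -> ModelSpec:
    reg = _load_registry()
    try:
        return reg[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; registered: {', '.join(sorted(reg))}"
        ) from None


# ---------------------------------------------------------------------------
# individual parameters

def _evaluate_formulas(model: ModelSpec, cov: CovariateRecord) -> dict[str, float]:
    ns = dict(_EVAL_FUNCS)
    ns.update(cov.namespace(mscr_floor=model.options.get("mscr_floor", 0.4)))
    for name, t in model.thetas.items():
        ns[f"theta_{name}"] = float(t["value"])
    out = {}
    for param, expr in model.formulas.items():
        if param == "v1" and model.model_id == "burger" and (
            model.options.get("v_reading") == "power"
        ):
            expr = "theta_vc * (wt / theta_median_bw) ** 1.7"
        try:
            out[param] = float(eval(expr, {"__builtins__": {}}, ns))  # noqa: S307
        except NameError as exc:
            raise MissingCovariateError(
                f"model {model.model_id!r}: formula for {param} needs an "
                f"unavailable symbol ({exc})"
            ) from exc
    return out


def compute_individual_parameters(
    model: ModelSpec,
    cov: CovariateRecord,
    eta: EtaVector | np.ndarray | dict | None = None,
    iiv_dialect: str = "lognormal_cv",
) -> PKParameters:
    """Individual PK parameters from a model's covariate formulas and η.

    Random effects apply exponentially (P_i = TVP·exp(η)); ``eta=None`` gives
    the typical-value (population) parameters. Micro-constant models are
    converted to the clearance parametrization.
    """
    values = _evaluate_formulas(model, cov)
    eta_map = _eta_as_dict(model, eta)
    for name, e in eta_map.items():
        key = name if name in values else {"v": "v1", "cl": "k10"}.get(name)
        if key is None or key not in values:
            raise ModelError(
                f"model {model.model_id!r} has no parameter {name!r} for eta"
            )
        values[key] *= math.exp(e)
    if model.parametrization == "micro":
        params = PKParameters.from_micro(
            k10=values["k10"], v1=values["v1"],
            k12=values.get("k12"), k21=values.get("k21"),
        )
    else:
        params = PKParameters(
            cl=values["cl"], v1=values["v1"],
            q=values.get("q"), v2=values.get("v2"),
        )
    if params.cl <= 0 or params.v1 <= 0:
        raise ModelError(f"model {model.model_id!r}: non-positive CL or V")
    return params


def _eta_as_dict(model: ModelSpec, eta) -> dict[str, float]:
    names = model.eta_names
    if eta is None:
        return {}
    if isinstance(eta, EtaVector):
        if eta.names != names:
            raise ModelError(
                f"eta names {eta.names} do not match model {model.model_id!r} "
                f"random effects {names}"
            )
        return eta.as_dict()
    if isinstance(eta, dict):
        unknown = set(eta) - set(names)
        if unknown:
            raise ModelError(f"unknown eta names {sorted(unknown)} for {model.model_id}")
        return {k: float(v) for k, v in eta.items()}
    arr = np.asarray(eta, dtype=float)
    if arr.shape != (len(names),):
        raise ModelError(
            f"eta dimension {arr.shape} does not match model {model.model_id!r} "
            f"omega dimension {len(names)}"
        )
    return dict(zip(names, arr.tolist()))


# mapping from reference-dict keys (formula symbols) to CovariateRecord fields
_REF_DEFAULTS = dict(
    age=55.0, sex="male", weight=70.0, height=170.0, albumin=30.0,
    serum_creatinine=88.4, crrt=False, residual_diuresis=2000.0,
    sepsis=False, crrt_flow=2.0,
)


def reference_record(model: ModelSpec) -> CovariateRecord:
    """A covariate record at the model's printed reference values.

    Used for typical-value checks: evaluating the model at this record with
    η = 0 should return the printed typical parameters (where the evaluated
    table prints both formula and value).
    """
    kw = dict(_REF_DEFAULTS)
    for key, val in model.reference.items():
        if key == "mscr":
            kw["serum_creatinine"] = float(val) * UMOL_PER_MGDL
        elif key == "wt":
            kw["weight"] = float(val)
        elif key == "alb":
            kw["albumin"] = float(val)
        elif key == "female":
            kw["sex"] = "female" if val else "male"
        elif key in ("clcr", "age", "crrt", "crrt_flow", "residual_diuresis", "sepsis"):
            kw[key] = val
        else:
            raise ModelError(f"unknown reference key {key!r} in {model.model_id}")
    return CovariateRecord(**kw)
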