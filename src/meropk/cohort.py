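"""Seeded generator of virtual ICU patients on meropenem TDM.

The generator emulates the covariate structure, regimen mix, sampling
sparsity and assay censoring of a routine-TDM ICU cohort: 33.58% of patients
on CRRT; age 22–89 y (median 58), weight 40–84 kg (median 58.5), serum
creatinine 24–1,145 µmol/L (median 143); 1 g q8h for 57.3% of patients with
the remaining regimen mass spread over 1 g q6h, 0.5 g q8h, 2 g q8h, 2 g q12h
and an "others" pool; infusions of 0.5–4 h; roughly two thirds of patients
contribute a single (trough-biased) sample; LLOQ 0.5 mg/L.

Continuous covariates are drawn from truncated log-normals parameterized so
the printed median is the distribution median and the printed range endpoints
sit near the 1st/99th percentiles. Concentrations are simulated at steady
state (five run-in dosing cycles) from a registered generator model with
per-patient log-normal η and the model's residual error; the η draw and the
noise-free concentrations are retained as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .covariates import CovariateRecord
from .data import LLOQ_DEFAULT, Observation, Patient
from .pk import DoseEvent, concentration
from .registry import compute_individual_parameters, get_model
from .forecasting import residual_sd

__all__ = ["CohortConfig", "generate_cohort"]

_Z99 = 2.3263478740408408  # standard-normal 99th percentile

# (amount mg, interval h, continuous?) : probability — routine regimen mix
DEFAULT_REGIMENS = {
    (1000.0, 8.0, False): 0.573,
    (1000.0, 6.0, False): 0.129,
    (500.0, 8.0, False): 0.086,
    (2000.0, 8.0, False): 0.065,
    (2000.0, 12.0, False): 0.043,
    # "others" pool, split uniformly
    (1000.0, 12.0, False): 0.026,
    (500.0, 6.0, False): 0.026,
    (2000.0, 6.0, False): 0.026,
    (1000.0, 8.0, True): 0.026,  # continuous infusion
}

DEFAULT_COVARIATES = {
    # name: (median, low, high)
    "age": (58.0, 22.0, 89.0),
    "height": (166.0, 148.0, 175.0),
    "weight": (58.5, 40.0, 84.0),
    "albumin": (29.1, 16.7, 54.0),
    "serum_creatinine": (143.0, 24.0, 1145.0),
}


@dataclass
class CohortConfig:
    """Study-cohort conditions for the synthetic generator."""

    n_patients: int = 134
    crrt_fraction: float = 0.3358
    male_fraction: float = 83.0 / 134.0
    sepsis_fraction: float = 0.6
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    regimens: dict = field(default_factory=lambda: dict(DEFAULT_REGIMENS))
    infusion_durations: tuple = (0.5, 1.0, 2.0, 3.0, 4.0)
    infusion_probs: tuple = (0.30, 0.35, 0.15, 0.12, 0.08)
    single_sample_fraction: float = 88.0 / 134.0
    multi_sample_probs: dict = field(
        default_factory=lambda: {2: 0.55, 3: 0.35, 4: 0.10}
    )
    n_runin_cycles: int = 5  # dosing cycles before the first sample
    model_id: str = "muro"  # generator model
    residual_proportional: float | None = None  # None → model sigma
    omega_scale: float = 1.0  # 0 disables IIV
    lloq: float = LLOQ_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        for probs, what in (
            (self.regimens.values(), "regimen"),
            (self.infusion_probs, "infusion duration"),
            (self.multi_sample_probs.values(), "multi-sample"),
        ):
            total = float(sum(probs))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{what} probabilities sum to {total}, expected 1")
        if not 0 <= self.crrt_fraction <= 1:
            raise ValueError("crrt_fraction must be in [0, 1]")
        for name, (med, lo, hi) in self.covariates.items():
            if not lo < med < hi:
                raise ValueError(f"covariate {name}: range ({lo}, {hi}) must "
                                 f"bracket the median {med}")


def _trunc_lognormal(rng, median, lo, hi, size=None):
    """Log-normal with the given median, truncated to [lo, hi].

    σ is set so the wider of the two range half-widths sits at the 99th
    percentile; rejection sampling enforces the bounds.
    """
    mu = math.log(median)
    sigma = max(math.log(hi / median), math.log(median / lo)) / _Z99
    n = 1 if size is None else size
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = np.exp(rng.normal(mu, sigma, todo.size))
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return float(out[0]) if size is None else out


def generate_cohort(config: CohortConfig) -> list[Patient]:
    """Generate a reproducible synthetic cohort (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    model = get_model(config.model_id)
    omega = model.omega() * config.omega_scale
    eta_names = model.eta_names
    sigma = dict(model.sigma)
    if config.residual_proportional is not None:
        sigma = {"kind": "proportional",
                 "proportional": config.residual_proportional, "additive": 0.0}

    reg_keys = list(config.regimens)
    reg_probs = np.asarray([config.regimens[k] for k in reg_keys])
    reg_probs = reg_probs / reg_probs.sum()
    multi_ks = list(config.multi_sample_probs)
    multi_ps = np.asarray([config.multi_sample_probs[k] for k in multi_ks])
    multi_ps = multi_ps / multi_ps.sum()

    patients: list[Patient] = []
    for i in range(config.n_patients):
        crrt = bool(rng.random() < config.crrt_fraction)
        sex = "male" if rng.random() < config.male_fraction else "female"
        draw = {
            name: _trunc_lognormal(rng, *config.covariates[name])
            for name in config.covariates
        }
        # CRRT patients are typically oliguric; others keep routine diuresis
        if crrt:
            diuresis = float(np.clip(rng.normal(500.0, 600.0), 0.0, 3000.0))
        else:
            diuresis = float(np.clip(rng.normal(2077.7, 1633.7), 0.0, 6000.0))
        cov = CovariateRecord(
            age=draw["age"], sex=sex, weight=draw["weight"],
            height=draw["height"], albumin=draw["albumin"],
            serum_creatinine=draw["serum_creatinine"],
            crrt=crrt, residual_diuresis=diuresis,
            sepsis=bool(rng.random() < config.sepsis_fraction),
            crrt_flow=float(_trunc_lognormal(rng, 2.0, 1.0, 4.0)),
        )

        amount, tau, continuous = reg_keys[rng.choice(len(reg_keys), p=reg_probs)]
        if continuous:
            dur = tau
        else:
            dur = float(
                np.asarray(config.infusion_durations)[
                    rng.choice(len(config.infusion_durations),
                               p=np.asarray(config.infusion_probs))
                ]
            )
            dur = min(dur, tau)

        if rng.random() < config.single_sample_fraction:
            n_samples = 1
        else:
            n_samples = int(multi_ks[rng.choice(len(multi_ks), p=multi_ps)])
        # one observation per occasion, occasions one dosing interval apart,
        # trough-biased (within 1 h before the next dose)
        n_cycles = config.n_runin_cycles + n_samples
        doses = [
            DoseEvent(amount=amount, duration=dur, start_time=k * tau)
            for k in range(n_cycles)
        ]
        obs_times = np.asarray([
            (config.n_runin_cycles + j + 1) * tau - rng.uniform(0.0, 1.0)
            for j in range(n_samples)
        ])

        eta = (
            rng.multivariate_normal(np.zeros(len(eta_names)), omega)
            if len(eta_names) else np.zeros(0)
        )
        params = compute_individual_parameters(model, cov, eta)
        c_true = concentration(params, doses, obs_times)
        g = residual_sd(sigma, c_true)
        c_obs = np.maximum(c_true + g * rng.standard_normal(c_true.shape), 0.0)

        observations = [
            Observation(time=float(t), concentration=float(c),
                        bql=bool(c < config.lloq), occasion=j)
            for j, (t, c) in enumerate(zip(obs_times, c_obs))
        ]
        patients.append(Patient(
            pid=f"S{i + 1:05d}", covariates=cov, doses=doses,
            observations=observations,
            truth={
                "eta": dict(zip(eta_names, np.asarray(eta).tolist())),
                "c_true": c_true.tolist(),
                "model_id": config.model_id,
                "seed": config.seed,
                "regimen": {"amount": amount, "interval": tau,
                            "duration": dur, "continuous": continuous},
            },
        ))
    return patients
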