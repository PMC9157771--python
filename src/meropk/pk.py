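"""Closed-form concentration prediction for 1- and 2-compartment infusion models.

Plasma concentration under linear disposition is a sum of exponentials; each
zero-order infusion contributes, per disposition term (λᵢ, cᵢ),

    C(t) = R·cᵢ/λᵢ · (1 − e^{−λᵢ·min(t, T_inf)}) · e^{−λᵢ·max(t − T_inf, 0)}

with infusion rate R = amount / T_inf. Multiple doses superpose; steady state
under a periodic regimen follows from the geometric accumulation factor
1/(1 − e^{−λτ}) applied per term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DoseEvent",
    "PKParameters",
    "concentration",
    "concentration_batch",
    "steady_state_profile",
    "predict",
    "expand_regimen",
]

# α≈β in a 2-CMT model only when Q≈0 and k10≈k21; below this relative
# discriminant the profile is treated as mono-exponential.
_EQUAL_ROOT_RTOL = 1e-10


@dataclass(frozen=True)
class DoseEvent:
    """One administration: zero-order infusion of ``amount`` mg over ``duration`` h.

    A continuous infusion is represented by a duration equal to the regimen
    horizon. ``interval`` (h) marks the event as a template for a periodic
    regimen (q-τ dosing) and is used by :func:`expand_regimen` and
    :func:`steady_state_profile`.
    """

    amount: float  # mg
    duration: float  # h
    start_time: float = 0.0  # h
    interval: float | None = None  # h, for regimen templates

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if not self.duration > 0:
            raise ValueError(f"infusion duration must be positive, got {self.duration}")
        if self.interval is not None and not self.interval > 0:
            raise ValueError(f"interval must be positive, got {self.interval}")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.duration


def expand_regimen(template: DoseEvent, n_doses: int) -> list[DoseEvent]:
    """Expand a periodic dose template into ``n_doses`` explicit events."""
    if template.interval is None:
        raise ValueError("template must carry an interval to be expanded")
    return [
        replace(template, start_time=template.start_time + k * template.interval,
                interval=None)
        for k in range(n_doses)
    ]


@dataclass(frozen=True)
class PKParameters:
    """Individual disposition parameters (clearance parametrization).

    ``q``/``v2`` are ``None`` for one-compartment models. Micro-constant
    models (K10, K12, K21, V1) are converted on construction via
    :meth:`from_micro`.
    """

    cl: float  # L/h
    v1: float  # L
    q: float | None = None  # L/h
    v2: float | None = None  # L

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v1 > 0):
            raise ValueError(f"CL and V1 must be positive (CL={self.cl}, V1={self.v1})")
        if (self.q is None) != (self.v2 is None):
            raise ValueError("q and v2 must be supplied together")
        if self.q is not None and (self.q < 0 or self.v2 <= 0):
            raise ValueError(f"invalid peripheral parameters q={self.q}, v2={self.v2}")

    @classmethod
    def from_micro(cls, k10: float, v1: float,
                   k12: float | None = None, k21: float | None = None) -> "PKParameters":
        """Build from micro constants: CL = k10·V1, Q = k12·V1, V2 = Q/k21."""
        if k12 is None or k12 == 0:
            return cls(cl=k10 * v1, v1=v1)
        if k21 is None or k21 <= 0:
            raise ValueError("k21 must be positive when k12 > 0")
        q = k12 * v1
        return cls(cl=k10 * v1, v1=v1, q=q, v2=q / k21)

    @property
    def n_compartments(self) -> int:
        return 1 if (self.q is None or self.q == 0) else 2

    @property
    def k10(self) -> float:
        return self.cl / self.v1

    def disposition_terms(self) -> tuple[np.ndarray, np.ndarray]:
        """Exponential rates λᵢ (1/h) and unit-bolus coefficients cᵢ (1/L).

        A unit bolus gives C(t) = Σ cᵢ e^{−λᵢ t}; Σ cᵢ = 1/V1.
        """
        lam, coef = _terms_arrays(
            np.asarray([self.cl]), np.asarray([self.v1]),
            None if self.q is None else np.asarray([self.q]),
            None if self.v2 is None else np.asarray([self.v2]),
        )
        return lam[0], coef[0]


def _terms_arrays(cl, v1, q, v2):
    """Vectorized disposition terms for a batch of parameter sets.

    Returns (lam, coef), each of shape (B, n_terms); n_terms is 1 or 2.
    """
    cl = np.asarray(cl, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    if q is None:
        lam = (cl / v1)[:, None]
        coef = (1.0 / v1)[:, None]
        return lam, coef
    q = np.asarray(q, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    # discriminant in a cancellation-safe form: s² − 4·k10·k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    near_equal = disc <= _EQUAL_ROOT_RTOL * s
    # generic biexponential coefficients for the central compartment
    denom = np.where(near_equal, 1.0, alpha - beta)
    a = np.where(near_equal, 1.0 / v1, (alpha - k21) / (v1 * denom))
    b = np.where(near_equal, 0.0, (k21 - beta) / (v1 * denom))
    # equal-root limit (only reachable as Q→0 with k10→k21): mono-exponential
    beta = np.where(near_equal, alpha, beta)
    lam = np.stack([alpha, beta], axis=1)
    coef = np.stack([a, b], axis=1)
    # a zero-coefficient term may carry lambda 0 (e.g. Q=0 exactly); give it a
    # harmless positive rate so the infusion solution stays finite
    lam = np.where((coef == 0.0) & (lam <= 0.0), 1.0, lam)
    return lam, coef


def _infusion_sum(lam, coef, doses, t):
    """Superposed infusion solution.

    lam, coef: (B, T); t: (M,) → concentrations (B, M).
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros((lam.shape[0], t.size))
    lam_e = lam[:, :, None]  # (B, T, 1)
    coef_e = coef[:, :, None]
    for d in doses:
        trel = t - d.start_time  # (M,)
        active = trel > 0
        if not np.any(active):
            continue
        te = np.clip(trel, 0.0, d.duration)  # exposure time within infusion
        decay = np.maximum(trel - d.duration, 0.0)
        term = (d.rate * coef_e / lam_e) * (
            -np.expm1(-lam_e * te)
        ) * np.exp(-lam_e * decay)
        out += np.where(active[None, None, :], term, 0.0).sum(axis=1)
    return out


def concentration(params: PKParameters, doses, t):
    """Concentration (mg/L) at time(s) ``t`` under a list of dose events.

    Times before the first dose return 0. Accepts a scalar or array ``t``.
    """
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("times must be non-negative")
    lam, coef = _terms_arrays(
        np.asarray([params.cl]), np.asarray([params.v1]),
        None if params.q is None else np.asarray([params.q]),
        None if params.v2 is None else np.asarray([params.v2]),
    )
    c = _infusion_sum(lam, coef, list(doses), t_arr)[0]
    return float(c[0]) if scalar else c


def concentration_batch(cl, v1, q, v2, doses, t) -> np.ndarray:
    """Concentrations for a batch of parameter sets at shared times.

    ``cl``/``v1`` (and optionally ``q``/``v2``) are arrays of shape (B,);
    returns an array of shape (B, len(t)). Used to vectorize Monte-Carlo
    replicates over random-effect draws.
    """
    lam, coef = _terms_arrays(cl, v1, q, v2)
    return _infusion_sum(lam, coef, list(doses), np.asarray(t, dtype=float))


def steady_state_profile(params: PKParameters, regimen: DoseEvent, times):
    """Steady-state concentrations under a periodic regimen.

    ``regimen`` must carry a finite ``interval`` τ with duration ≤ τ; ``times``
    are hours after the start of a steady-state dose (values beyond τ wrap
    around the dosing cycle). Uses the per-term accumulation factor
    1/(1 − e^{−λτ}).
    """
    if regimen.interval is None:
        raise ValueError(
            "steady_state_profile needs a periodic regimen (interval set); "
            "use concentration() for non-periodic histories"
        )
    tau = regimen.interval
    if regimen.duration > tau:
        raise ValueError("infusion duration must not exceed the dosing interval")
    t = np.mod(np.atleast_1d(np.asarray(times, dtype=float)), tau)
    lam, coef = _terms_arrays(
        np.asarray([params.cl]), np.asarray([params.v1]),
        None if params.q is None else np.asarray([params.q]),
        None if params.v2 is None else np.asarray([params.v2]),
    )
    lam = lam[0][:, None]  # (T, 1)
    coef = coef[0][:, None]
    r = regimen.rate
    tinf = regimen.duration
    te = np.minimum(t, tinf)
    decay = np.maximum(t - tinf, 0.0)
    current = (r * coef / lam) * (-np.expm1(-lam * te)) * np.exp(-lam * decay)
    # all completed previous doses, summed geometrically
    acc = np.exp(-lam * tau) / (-np.expm1(-lam * tau))
    past = (r * coef / lam) * (-np.expm1(-lam * tinf)) * np.exp(-lam * (t - tinf)) * acc
    c = (current + past).sum(axis=0)
    return c if np.ndim(times) else float(c[0])


def predict(model, patient, eta=None) -> np.ndarray:
    """Model predictions (mg/L) at a patient's observation times.

    ``eta=None`` (or zeros) gives the population prediction PRED; a supplied
    random-effect vector gives the individual prediction IPRED.
    """
    from .registry import compute_individual_parameters  # local: avoid cycle

    times = np.asarray([o.time for o in patient.observations], dtype=float)
    params = compute_individual_parameters(model, patient.covariates, eta)
    if times.size == 0:
        return np.zeros(0)
    if len(patient.doses) == 0 or times.min() < min(d.start_time for d in patient.doses):
        import warnings

        warnings.warn(
            f"patient {patient.pid}: observation before first dose predicts 0",
            stacklevel=2,
        )
    return concentration(params, patient.doses, times)
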