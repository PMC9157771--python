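"""Scalar predictive-performance statistics with their pass/fail thresholds.

Population level, on prediction errors PE% = (PRED − OBS)/OBS·100:

* MDPE — median PE% (bias); acceptable within ±20%.
* MAPE — median |PE|% (precision); acceptable ≤ 30%.
* F20 / F30 — percentage of |PE| ≤ 20% / ≤ 30%; acceptable ≥ 35% / ≥ 50%.

Individual level, comparing predicted with observed concentrations pairwise:

* rBias = mean of (p − o)/((p + o)/2)·100, each term bounded in (−200, 200);
  a method is called unbiased when |rBias| ≤ 20%.
* rRMSE = sqrt(mean of [(p − o)/((p + o)/2)]²)·100.

The same summaries applied to individual predictions (IPRED) are reported as
MDIPE/MAIPE/IF20/IF30.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricsReport",
    "pe_percent",
    "ipe_percent",
    "summarize_population",
    "summarize_individual",
    "rbias_rrmse",
    "RBIAS_UNBIASED_LIMIT",
]

# population pass/fail criteria
MDPE_LIMIT = 20.0
MAPE_LIMIT = 30.0
F20_MIN = 35.0
F30_MIN = 50.0
RBIAS_UNBIASED_LIMIT = 20.0


@dataclass(frozen=True)
class MetricsReport:
    """Summary statistics for one model × stratum × method."""

    mdpe: float
    mape: float
    f20: float
    f30: float
    n: int
    stratum: str = "all"
    rbias: float = float("nan")
    rrmse: float = float("nan")

    @property
    def passes_population_criteria(self) -> bool:
        return (
            abs(self.mdpe) <= MDPE_LIMIT
            and self.mape <= MAPE_LIMIT
            and self.f20 >= F20_MIN
            and self.f30 >= F30_MIN
        )

    @property
    def rbias_unbiased(self) -> bool:
        return abs(self.rbias) <= RBIAS_UNBIASED_LIMIT

    def as_dict(self) -> dict:
        return {
            "mdpe": self.mdpe, "mape": self.mape, "f20": self.f20,
            "f30": self.f30, "rbias": self.rbias, "rrmse": self.rrmse,
            "n": self.n, "stratum": self.stratum,
            "passes_population_criteria": self.passes_population_criteria,
            "rbias_unbiased": self.rbias_unbiased,
        }


def pe_percent(pred: float, obs: float) -> float:
    """Relative prediction error, percent: (PRED − OBS)/OBS·100."""
    if np.ndim(obs) == 0:
        if obs <= 0:
            raise ValueError(f"observed concentration must be positive, got {obs}")
        return (pred - obs) / obs * 100.0
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observed concentrations must be positive")
    return (pred - obs) / obs * 100.0


#: identical arithmetic applied to individual predictions (IPRED)
ipe_percent = pe_percent


def summarize_population(pe_values, stratum: str = "all") -> MetricsReport:
    """MDPE/MAPE/F20/F30 from a list of prediction errors (percent).

    Even-length medians are the midpoint of the central pair; the F20/F30
    thresholds are inclusive (|PE| = 20 counts toward F20).
    """
    pe = np.asarray(list(pe_values), dtype=float)
    if pe.size == 0:
        raise ValueError("cannot summarize an empty prediction-error list")
    abs_pe = np.abs(pe)
    return MetricsReport(
        mdpe=float(np.median(pe)),
        mape=float(np.median(abs_pe)),
        f20=float(np.mean(abs_pe <= 20.0) * 100.0),
        f30=float(np.mean(abs_pe <= 30.0) * 100.0),
        n=int(pe.size),
        stratum=stratum,
    )


def summarize_individual(ipe_values, stratum: str = "all") -> MetricsReport:
    """MDIPE/MAIPE/IF20/IF30 — the population summaries applied to IPE%."""
    return summarize_population(ipe_values, stratum=stratum)


def rbias_rrmse(preds, obs) -> tuple[float, float]:
    """Relative bias and relative RMSE (percent), mean-of-pair denominator."""
    p = np.asarray(list(preds), dtype=float)
    o = np.asarray(list(obs), dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("preds and obs must be equal-length, non-empty")
    if np.any(p <= 0) or np.any(o <= 0):
        raise ValueError("concentrations must be positive")
    rel = (p - o) / ((p + o) / 2.0)
    rbias = float(np.mean(rel) * 100.0)
    rrmse = float(np.sqrt(np.mean(rel * rel)) * 100.0)
    return rbias, rrmse
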