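"""Simulation-based diagnostics: replicate simulation, pcVPC and NPDE.

Monte-Carlo replicates re-simulate the observed design (same patients, doses
and sampling times) from the evaluated model: per replicate a fresh η per
patient from N(0, Ω) and a residual per observation from the model's error
spec.

The prediction-corrected VPC normalizes observed and simulated values by
(bin-median PRED / individual PRED) before computing quantiles, so that
covariate- and dose-driven heterogeneity within a time bin does not inflate
the spread. NPDE decorrelates each patient's observation vector with the
simulated mean and covariance (Cholesky), ranks the observation among its
decorrelated simulations, and maps the rank to a standard-normal quantile;
under the evaluated model the NPDE sample is N(0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pk import concentration, concentration_batch
from .registry import ModelSpec, compute_individual_parameters
from .forecasting import residual_sd

__all__ = [
    "SimulatedEnsemble",
    "VPCResult",
    "NPDEResult",
    "simulate_replicates",
    "pcvpc",
    "npde",
]

log = logging.getLogger(__name__)


@dataclass
class SimulatedEnsemble:
    """Replicated concentrations aligned to the observed design.

    ``matrix`` has shape (n_rep, n_obs) over the flattened observations of
    ``patients`` (patient order, then observation order within patient);
    ``pred`` holds the population predictions for the same flattening.
    """

    matrix: np.ndarray
    patients: list
    pred: np.ndarray
    seed: int
    patient_slices: list[slice] = field(default_factory=list)

    @property
    def n_rep(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[1]


def simulate_replicates(model: ModelSpec, patients, n_rep: int = 1000,
                        seed: int = 0) -> SimulatedEnsemble:
    """Simulate ``n_rep`` Monte-Carlo datasets on the observed design."""
    if n_rep < 1:
        raise ValueError("n_rep must be ≥ 1")
    rng = np.random.default_rng(seed)
    omega = model.omega()
    names = model.eta_names
    cols, preds, slices = [], [], []
    start = 0
    for p in patients:
        t = p.obs_times
        typ = compute_individual_parameters(model, p.covariates, None)
        preds.append(concentration(typ, p.doses, t))
        # vectorize over replicates: individual parameters = typical × exp(η)
        eta = rng.multivariate_normal(np.zeros(len(names)), omega, size=n_rep) \
            if len(names) else np.zeros((n_rep, 0))
        fac = {n: np.exp(eta[:, j]) for j, n in enumerate(names)}
        cl = np.full(n_rep, typ.cl) * fac.get("cl", 1.0)
        v1 = np.full(n_rep, typ.v1) * fac.get("v1", 1.0)
        if typ.q is None:
            c = concentration_batch(cl, v1, None, None, p.doses, t)
        else:
            c = concentration_batch(cl, v1, np.full(n_rep, typ.q),
                                    np.full(n_rep, typ.v2), p.doses, t)
        g = residual_sd(model.sigma, c)
        c = np.maximum(c + g * rng.standard_normal(c.shape), 0.0)
        cols.append(c)
        slices.append(slice(start, start + t.size))
        start += t.size
    return SimulatedEnsemble(
        matrix=np.concatenate(cols, axis=1) if cols else np.zeros((n_rep, 0)),
        patients=list(patients),
        pred=np.concatenate(preds) if preds else np.zeros(0),
        seed=seed,
        patient_slices=slices,
    )


# ---------------------------------------------------------------------------
# pcVPC

@dataclass
class VPCResult:
    """Prediction-corrected VPC summaries.

    ``table`` has one row per (bin, percentile) with the observed percentile
    and the simulated 90% confidence band for it.
    """

    table: pd.DataFrame
    bin_edges: np.ndarray
    correction: np.ndarray  # per-observation pc factor

    def coverage(self) -> float:
        """Fraction of observed-percentile points inside their bands."""
        t = self.table
        return float(np.mean((t.observed >= t.band_lo) & (t.observed <= t.band_hi)))


def _time_after_dose(patients) -> np.ndarray:
    tad = []
    for p in patients:
        starts = np.asarray(sorted(d.start_time for d in p.doses))
        for o in p.observations:
            prior = starts[starts <= o.time]
            tad.append(o.time - (prior[-1] if prior.size else 0.0))
    return np.asarray(tad)


def _make_bins(x: np.ndarray, n_bins: int, min_per_bin: int = 2) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # all observations share one time after dose
        edges = np.asarray([edges[0], edges[0]])
    edges = edges.astype(float)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    # merge bins holding fewer than min_per_bin observations into a neighbor
    while len(edges) > 2:
        counts, _ = np.histogram(x, edges)
        small = np.flatnonzero(counts < min_per_bin)
        if small.size == 0:
            break
        i = small[0]
        drop = i + 1 if i + 1 < len(edges) - 1 else i
        log.info("pcVPC: merging sparse bin %d into neighbor", i)
        edges = np.delete(edges, drop)
    return edges


def pcvpc(ensemble: SimulatedEnsemble, n_bins: int = 8,
          percentiles=(5, 50, 95), ci: float = 90.0) -> VPCResult:
    """Prediction-corrected visual predictive check."""
    obs = np.concatenate([p.obs_values for p in ensemble.patients])
    pred = ensemble.pred
    if np.any(pred <= 0):
        raise ValueError("population predictions must be positive for pcVPC")
    tad = _time_after_dose(ensemble.patients)
    edges = _make_bins(tad, n_bins)
    idx = np.clip(np.digitize(tad, edges) - 1, 0, len(edges) - 2)
    pc = np.empty_like(pred)
    for b in range(len(edges) - 1):
        sel = idx == b
        pc[sel] = np.median(pred[sel]) / pred[sel]
    obs_pc = obs * pc
    sim_pc = ensemble.matrix * pc[None, :]
    lo_q, hi_q = (100 - ci) / 2.0, 100 - (100 - ci) / 2.0
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        t_mid = float(np.median(tad[sel]))
        sim_b = sim_pc[:, sel]
        for q in percentiles:
            sim_q = np.percentile(sim_b, q, axis=1)  # per replicate
            rows.append({
                "bin": b, "t_mid": t_mid, "n_obs": int(sel.sum()),
                "percentile": q,
                "observed": float(np.percentile(obs_pc[sel], q)),
                "band_lo": float(np.percentile(sim_q, lo_q)),
                "band_hi": float(np.percentile(sim_q, hi_q)),
                "band_mid": float(np.median(sim_q)),
            })
    return VPCResult(pd.DataFrame(rows), edges, pc)


# ---------------------------------------------------------------------------
# NPDE

@dataclass
class NPDEResult:
    """Normalized prediction distribution errors and their test battery."""

    npde: np.ndarray
    p_mean: float
    p_variance: float
    p_normality: float
    ridge_epsilon: float = 0.0

    @property
    def p_global(self) -> float:
        """Bonferroni-corrected global p-value over the three tests."""
        return min(1.0, 3.0 * min(self.p_mean, self.p_variance, self.p_normality))

    @property
    def rejects(self) -> bool:
        return self.p_global < 0.05

    def as_dict(self) -> dict:
        return {
            "n": int(self.npde.size),
            "mean": float(np.mean(self.npde)),
            "variance": float(np.var(self.npde, ddof=1)),
            "p_mean": self.p_mean, "p_variance": self.p_variance,
            "p_normality": self.p_normality, "p_global": self.p_global,
            "rejects": self.rejects,
        }


def _decorrelate(y: np.ndarray, sims: np.ndarray, ridge_scale: float = 1e-8):
    """Cholesky-decorrelate observed and simulated vectors of one patient."""
    mu = sims.mean(axis=0)
    eps_used = 0.0
    if y.size == 1:
        sd = sims.std(axis=0, ddof=1)
        sd = np.where(sd <= 0, ridge_scale + np.abs(mu), sd)
        return (y - mu) / sd, (sims - mu) / sd, eps_used
    cov = np.cov(sims.T)
    scale = float(np.mean(np.diag(cov))) or 1.0
    eps = 0.0
    for _ in range(12):
        try:
            chol = np.linalg.cholesky(cov + eps * np.eye(y.size))
            break
        except np.linalg.LinAlgError:
            eps_used = eps = max(eps * 10, ridge_scale * scale)
    else:
        raise np.linalg.LinAlgError("simulated covariance not factorizable")
    if eps_used:
        log.info("npde: ridge epsilon %.3g applied", eps_used)
    y_star = np.linalg.solve(chol, y - mu)
    s_star = np.linalg.solve(chol, (sims - mu).T).T
    return y_star, s_star, eps_used


def npde(ensemble: SimulatedEnsemble) -> NPDEResult:
    """Normalized prediction distribution errors with the three-test battery.

    Per observation, pd is the fraction of decorrelated simulations below the
    decorrelated observation (ties add 0.5/K), clamped to
    [1/(2K), 1 − 1/(2K)]; npde = Φ⁻¹(pd). Tests: t-test for mean 0, χ² test
    for variance 1, Shapiro–Wilk for normality; the global decision is
    Bonferroni-corrected over the three.
    """
    k = ensemble.n_rep
    if k < 2:
        raise ValueError("npde needs at least 2 replicates (≥ 100 recommended)")
    obs_all = [p.obs_values for p in ensemble.patients]
    values = []
    eps_max = 0.0
    for sl, y in zip(ensemble.patient_slices, obs_all):
        if y.size == 0:
            continue
        y_star, s_star, eps = _decorrelate(y, ensemble.matrix[:, sl])
        eps_max = max(eps_max, eps)
        below = (s_star < y_star[None, :]).sum(axis=0)
        ties = (s_star == y_star[None, :]).sum(axis=0)
        pd_ = (below + 0.5 * ties) / k
        pd_ = np.clip(pd_, 1.0 / (2 * k), 1.0 - 1.0 / (2 * k))
        values.append(stats.norm.ppf(pd_))
    x = np.concatenate(values)
    n = x.size
    if n > 1:
        p_mean = float(stats.ttest_1samp(x, 0.0).pvalue)
        chi = (n - 1) * float(np.var(x, ddof=1))
        p_var = float(
            2 * min(stats.chi2.cdf(chi, n - 1), stats.chi2.sf(chi, n - 1))
        )
    else:
        p_mean = p_var = 1.0  # a single residual carries no test information
    p_norm = float(stats.shapiro(x).pvalue) if 3 <= n <= 5000 else (
        float(stats.normaltest(x).pvalue) if n > 5000 else 1.0
    )
    return NPDEResult(x, p_mean, min(p_var, 1.0), p_norm, eps_max)
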