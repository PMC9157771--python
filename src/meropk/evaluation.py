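"""End-to-end external evaluation: prediction metrics, simulation diagnostics,
Bayesian forecasting comparison and dose-adaptation scoring, per model and
CRRT stratum.

``ExternalEvaluation(dataset).fit()`` runs, for each requested model and each
stratum (all / CRRT / non-CRRT):

* population prediction errors (MDPE, MAPE, F20, F30 and the pass flag);
* pcVPC and NPDE from Monte-Carlo replicates of the observed design;
* EBE adequacy (estimated vs theoretical η distribution);
* a priori vs Bayesian forecast of each multi-sample patient's last
  observation (rBias/rRMSE and dose-adaptation accuracy), conditioning the
  Bayesian forecast on the most recent earlier observation;
* the prior-combination study on patients with ≥ 3 observations.

A model that raises is recorded under ``failures`` and skipped; the run is
reproducible from its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LLOQ_DEFAULT, apply_lloq_filter
from .dosing import adaptation_accuracy
from .forecasting import MAPForecast, PRIOR_MODES, ebe_adequacy, forecast_third_interval
from .metrics import pe_percent, rbias_rrmse, summarize_individual, summarize_population
from .pk import predict
from .registry import get_model, model_ids
from .simdiag import npde, pcvpc, simulate_replicates

__all__ = ["EvaluationRun", "ExternalEvaluation", "EvaluationResults", "run_evaluation"]

log = logging.getLogger(__name__)

STRATA = ("all", "crrt", "non_crrt")


@dataclass
class EvaluationRun:
    """Configuration of one evaluation run."""

    models: list[str] = field(default_factory=model_ids)
    strata: tuple = STRATA
    n_rep: int = 1000
    seed: int = 0
    lloq: float = LLOQ_DEFAULT
    run_simulation_diagnostics: bool = True
    run_forecasting: bool = True
    min_ebe_patients: int = 20


class ExternalEvaluation:
    """Evaluate registered population-PK models on a patient dataset."""

    def __init__(self, patients, run: EvaluationRun | None = None):
        self.run = run or EvaluationRun()
        self.patients, self.n_bql_removed = apply_lloq_filter(
            patients, self.run.lloq
        )
        if not self.patients:
            raise ValueError("no patients with quantifiable observations")

    def _stratum(self, name):
        if name == "all":
            return self.patients
        want = name == "crrt"
        return [p for p in self.patients if p.covariates.crrt == want]

    def fit(self) -> "EvaluationResults":
        run = self.run
        metric_rows, forecast_rows, prior_rows, adaptation = [], [], [], {}
        vpc_results, npde_rows, ebe_frames, failures = {}, [], [], {}
        seeds = np.random.SeedSequence(run.seed).spawn(len(run.models))
        for model_id, sseq in zip(run.models, seeds):
            try:
                model = get_model(model_id)
                self._evaluate_model(
                    model, int(sseq.generate_state(1)[0] % (2**31)),
                    metric_rows, forecast_rows, prior_rows, adaptation,
                    vpc_results, npde_rows, ebe_frames,
                )
            except Exception as exc:  # a failing model must not kill the run
                log.exception("model %s failed; skipped", model_id)
                failures[model_id] = f"{type(exc).__name__}: {exc}"
        return EvaluationResults(
            run=run,
            metrics=pd.DataFrame(metric_rows),
            forecasts=pd.DataFrame(forecast_rows),
            prior_study=pd.DataFrame(prior_rows),
            adaptation=adaptation,
            vpc=vpc_results,
            npde=pd.DataFrame(npde_rows),
            ebe=pd.concat(ebe_frames, ignore_index=True) if ebe_frames
            else pd.DataFrame(),
            failures=failures,
            n_bql_removed=self.n_bql_removed,
        )

    # -- per-model work --------------------------------------------------
    def _evaluate_model(self, model, seed, metric_rows, forecast_rows,
                        prior_rows, adaptation, vpc_results, npde_rows,
                        ebe_frames):
        run = self.run
        mid = model.model_id
        pred_cache = {p.pid: predict(model, p, None) for p in self.patients}

        for stratum in run.strata:
            pts = self._stratum(stratum)
            if not pts:
                continue
            pe = np.concatenate([
                pe_percent(pred_cache[p.pid], p.obs_values) for p in pts
            ])
            rep = summarize_population(pe, stratum=stratum)
            metric_rows.append({"model": mid, "stratum": stratum,
                                "method": "a_priori", **rep.as_dict()})

        if run.run_simulation_diagnostics:
            for stratum in run.strata:
                pts = self._stratum(stratum)
                if sum(p.n_obs for p in pts) < 4:
                    continue
                ens = simulate_replicates(model, pts, run.n_rep, seed)
                vpc_results[(mid, stratum)] = pcvpc(ens)
                npde_rows.append({"model": mid, "stratum": stratum,
                                  **npde(ens).as_dict()})

        if run.run_forecasting:
            self._forecasting_block(model, forecast_rows, prior_rows, adaptation)
            if len(self.patients) >= run.min_ebe_patients:
                ebe_frames.append(ebe_adequacy(
                    model, self.patients, run.min_ebe_patients
                ).as_frame())

    def _forecasting_block(self, model, forecast_rows, prior_rows, adaptation):
        mid = model.model_id
        multi = [p for p in self.patients if p.n_obs >= 2]
        if multi:
            rows = {"a_priori": ([], []), "bayesian": ([], [])}
            for p in multi:
                obs = p.sorted_observations()
                target = obs[-1]
                apriori = MAPForecast(model, p, []).fit().predict([target.time])[0]
                bayes = MAPForecast(model, p, [obs[-2]]).fit().predict(
                    [target.time]
                )[0]
                for method, value in (("a_priori", apriori), ("bayesian", bayes)):
                    rows[method][0].append(max(value, 1e-9))
                    rows[method][1].append(target.concentration)
            for method, (preds, obs_v) in rows.items():
                rbias, rrmse = rbias_rrmse(preds, obs_v)
                ipe = pe_percent(np.asarray(preds), np.asarray(obs_v))
                rep = summarize_individual(ipe)
                forecast_rows.append({
                    "model": mid, "method": method, "n": len(preds),
                    "rbias": rbias, "rrmse": rrmse, "mdipe": rep.mdpe,
                    "maipe": rep.mape, "if20": rep.f20, "if30": rep.f30,
                })
                adaptation[(mid, method)] = adaptation_accuracy(preds, obs_v)
        rich = [p for p in self.patients if p.n_obs >= 3]
        for p in rich:
            target = p.sorted_observations()[2]
            for mode in PRIOR_MODES:
                res = forecast_third_interval(model, p, mode)
                ipred = float(res.predict([target.time])[0])
                prior_rows.append({
                    "model": mid, "patient": p.pid, "mode": mode,
                    "time": target.time, "obs": target.concentration,
                    "ipred": ipred,
                    "ipe": pe_percent(max(ipred, 1e-9), target.concentration),
                })


@dataclass
class EvaluationResults:
    """Tables and diagnostics produced by one evaluation run."""

    run: EvaluationRun
    metrics: pd.DataFrame
    forecasts: pd.DataFrame
    prior_study: pd.DataFrame
    adaptation: dict
    vpc: dict
    npde: pd.DataFrame
    ebe: pd.DataFrame
    failures: dict
    n_bql_removed: int

    def adaptation_frame(self) -> pd.DataFrame:
        rows = []
        for (mid, method), table in self.adaptation.items():
            rows.append({
                "model": mid, "method": method, "n": table.n,
                "accuracy": table.accuracy,
                **{f"correct_{c}": k for c, k in table.correct.items()},
                **{f"incorrect_{c}": k for c, k in table.incorrect.items()},
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"External evaluation — {len(self.run.models)} models, "
            f"seed {self.run.seed}, {self.n_bql_removed} observation(s) below "
            f"LLOQ removed",
        ]
        if not self.metrics.empty:
            sub = self.metrics[self.metrics.stratum == "all"]
            lines.append(
                sub[["model", "mdpe", "mape", "f20", "f30",
                     "passes_population_criteria"]]
                .round(2).to_string(index=False)
            )
        if self.failures:
            lines.append(f"failed models: {self.failures}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "prediction_metrics.csv", index=False,
                            float_format="%.6g")
        self.forecasts.to_csv(out / "forecast_metrics.csv", index=False,
                              float_format="%.6g")
        self.prior_study.to_csv(out / "prior_combination.csv", index=False,
                                float_format="%.6g")
        self.adaptation_frame().to_csv(out / "dose_adaptation.csv", index=False,
                                       float_format="%.6g")
        self.npde.to_csv(out / "npde_tests.csv", index=False, float_format="%.6g")
        self.ebe.to_csv(out / "ebe_adequacy.csv", index=False, float_format="%.6g")
        for (mid, stratum), res in self.vpc.items():
            res.table.to_csv(out / f"vpc_{mid}_{stratum}.csv", index=False,
                             float_format="%.6g")
        meta = {
            "seed": self.run.seed, "n_rep": self.run.n_rep,
            "models": list(self.run.models), "lloq": self.run.lloq,
            "n_bql_removed": self.n_bql_removed, "failures": self.failures,
        }
        (out / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def run_evaluation(patients, run: EvaluationRun | None = None,
                   outdir=None) -> EvaluationResults:
    """Fit an :class:`ExternalEvaluation` and optionally save the bundle."""
    results = ExternalEvaluation(patients, run).fit()
    if outdir is not None:
        results.save(outdir)
    return results
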