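# Methods notes

This note records the models, assumptions, parameter choices and numerical
decisions behind `meropk`, in the spirit of a package vignette. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The model registry

Each of the 14 published meropenem popPK models is a document under
`src/meropk/models/` with fields mirroring `ModelSpec`: structure, fixed
effects θ (value, unit, provenance), covariate formulas as arithmetic
expressions, interindividual variability (IIV) as CV%, and a residual-error
spec. Population classes: 4 models developed on mixed CRRT/non-CRRT cohorts
(burger, jaruratanasirikul, li, muro), 6 on non-CRRT cohorts (crandon,
dhaese, ehmann, mattioli, roberts, sjovall), 4 on CRRT cohorts (grensemann,
onichimowski, padulles, ulldemolins).

**Covariate conventions.** Time in h, concentration in mg/L, CL in L/h,
volumes in L. Serum creatinine is stored in µmol/L (routine laboratory
scale) and converted to mg/dL (÷ 88.4) where a model's formula needs it.
Creatinine clearance defaults to Cockcroft–Gault from the stored covariates
and can be supplied directly; one model uses the 4-variable MDRD eGFR.
Albumin is stored in g/L and converted to g/dL for the one formula
referenced to 2.79 g/dL. The Muro model's floored ("modified") serum
creatinine uses a 0.4 **mg/dL** floor: the alternative reading of the floor
as 0.4 mg/L is physiologically implausible (two orders of magnitude below
any adult creatinine) and would make the floor inert; the floor is
configurable per model (`options.mscr_floor`).

**IIV convention.** Reported CV% are converted to log-normal variances as
ω² = ln(1 + CV²), the exact relation for a log-normal coefficient of
variation. Because source papers rarely state their convention, the
alternative dialect ω = CV is selectable (`omega("omega_eq_cv")`).
Off-diagonal Ω entries are zero — no covariances are reported. Random
effects act multiplicatively: Pᵢ = TVP·exp(η).

**Provenance and placeholders.** Every θ carries a provenance flag. Values
the evaluated summary table prints are `printed`; parameters it omits are
`placeholder` with documented defaults chosen to be clinically plausible and,
where a printed typical value pins them down, anchored to it:

| model | placeholder | default | anchoring |
|---|---|---|---|
| roberts | CL slope | 0.136 L/h per ml/min | typical CL 13.6 L/h at CLcr 100 |
| roberts | Q, V2 | 15 L/h, 12 L | plausible 2-CMT values |
| burger | sieving coefficient | 0.8 | CL_CRRT 4.8 = 3.2 + 0.8 × 2 L/h flow |
| burger | median CLcr, median BW | 65 ml/min, 70 kg | typical ICU medians |
| ehmann | CLcr inflection | 143 ml/min | upper renal-function range |
| ehmann | θ_V2 | 12 L | plausible peripheral volume |
| jaruratanasirikul | θ1, θ2 | 1.01, 0.02 | typical CL 3.01 at MDRD 100 |
| mattioli | sepsis, sex effects | −0.20, −0.15 | plausible signs/magnitudes |
| mattioli | albumin, age exponents | −0.5, +0.5 | plausible signs |
| crandon | k12, k21 | 0.45, 0.35 /h | plausible distribution rates |
| sjovall | TVCL scale | 1.0 | see notes in the YAML |
| onichimowski, grensemann | Q, V2 | 10/20, 8/15 | plausible 2-CMT values |
| all models | residual error | proportional 20% | none are printed |

Typical-value checks and the acceptance quantities use only fully printed
formulas (muro, li, ulldemolins, ehmann, dhaese, crandon). Known source
inconsistencies are kept visible rather than silently corrected: the Burger
central-volume formula is stored in its literal printed reading
(16 × BW/medianBW × 1.7 = 27.2 L at median BW, vs a printed typical V of
17 L) with a `power` reading selectable; the Sjövall clearance formula
cannot reproduce its printed typical CL under any obvious reference and is
excluded from typical-value checks; the Padullés flow coefficient implies a
reference effluent flow (~11 L/h) above usual CRRT rates. Each is flagged in
the model's `notes`.

## 2. Compartmental kinetics

Linear disposition makes the concentration a sum of exponentials. For each
disposition term (λᵢ, cᵢ) — one term for 1-CMT (λ = CL/V, c = 1/V), two for
2-CMT via the macro-constants α, β of (CL, V1, Q, V2) — a zero-order
infusion of rate R and duration T contributes

C(t) = R·cᵢ/λᵢ · (1 − e^{−λᵢ·min(t,T)}) · e^{−λᵢ·max(t−T,0)}.

Doses superpose; steady state under a q-τ regimen multiplies each completed
dose's tail by the geometric factor 1/(1 − e^{−λτ}). Numerical choices:

* the 2-CMT discriminant √(s² − 4·k10·k21) is clamped at 0; a relative
  discriminant below 1e−10 (reachable only as Q→0 with k10→k21) switches to
  the mono-exponential limiting form;
* Q = 0 degenerates exactly to the 1-CMT profile (tested);
* zero-coefficient terms get a dummy positive rate so 0/0 never occurs;
* micro-parametrized models (K10, K12, K21, V1) are converted to the
  clearance parametrization on construction, one code path for everything.

The engine is validated against `scipy.integrate.solve_ivp` at rtol 1e−11 on
randomized 1-/2-CMT multi-dose problems (≤ 1e−6 relative error), and steady
state against brute-force superposition of 50–80 doses. Mass balance
(AUC over an interval at steady state = Dose/CL) is checked by quadrature.

## 3. MAP estimation

The individual posterior mode minimizes

OFV(η) = Σⱼ [(yⱼ − fⱼ(η))²/gⱼ²(η) + ln gⱼ²(η)] + ηᵀΩ⁻¹η,

with the residual SD g evaluated at the individual prediction (not the
observation) and the objective evaluated exactly — no linearization.
Optimizer: L-BFGS-B from η = 0 plus four perturbed starts drawn from
N(0, Ω) with a fixed internal seed (estimates are deterministic by
contract), η bounded to ±5 prior SDs, ftol 1e−12. A final guard keeps the
reported optimum no worse than the prior mode, so OFV(η̂) ≤ OFV(0) always.
Observations below the LLOQ are excluded from the likelihood, mirroring
their exclusion from the dataset. No between-occasion variability is
modelled (none of the registered models reports any). The MAP optimum is
verified against a dense 1-D grid scan of the posterior (step 1e−4) for
one-random-effect models, including the micro-parametrized case where η on
V1 also scales CL, Q and V2.

## 4. Simulation diagnostics

Replicates re-simulate the observed design: η per patient per replicate from
N(0, Ω), residual per observation from the model's error spec, values
clipped at 0. The default is 1,000 replicates; tests use 60–400 to stay
fast. The **pcVPC** bins observations on time after the last dose (8
quantile bins, sparse bins merged into a neighbor at < 2 observations),
corrects observed and simulated values by bin-median PRED / individual
PRED, and overlays observed 5/50/95th percentiles on the simulated 90%
confidence band of each percentile. **NPDE** decorrelates each patient's
vector with the simulated mean and Cholesky factor of the simulated
covariance (ridge-regularized on failure, with the epsilon logged), ranks
the observation among its decorrelated simulations (ties add 0.5/K), clamps
pd to [1/(2K), 1 − 1/(2K)] and maps through Φ⁻¹. The test battery is the
standard three: t-test for mean 0, two-sided χ² for variance 1,
Shapiro–Wilk for normality (D'Agostino above n = 5000), combined by
Bonferroni. Calibration is verified by repetition: under the generating
model the mean and variance tests reject at ≤ nominal + 3 Monte-Carlo SEs
and ~90% of observed-percentile points fall inside their bands (200
repetitions of 300-replicate ensembles on a 30-patient design — sizes chosen
to make the Monte-Carlo error of the rejection-rate estimate a few percent).

## 5. Prediction metrics and dose adaptation

PE% = (PRED − OBS)/OBS·100; MDPE and MAPE are medians (even-length medians
are midpoints), F20/F30 are inclusive (|PE| = 20 counts toward F20);
the population pass requires MDPE within ±20%, MAPE ≤ 30%, F20 ≥ 35%,
F30 ≥ 50% simultaneously. rBias and rRMSE use the mean-of-pair denominator,
which bounds every rBias summand inside (−200, 200) for positive pairs —
an algebraic consequence worth noting because external reports occasionally
quote values outside that range; this implementation follows the formula
and cannot produce them. |rBias| ≤ 20% is reported as the "unbiased" flag.
Dose directions use the 8–45 mg/L window with both bounds inclusive to
"maintain"; the window is configurable (4×MIC lower bound, fixed toxicity
ceiling).

## 6. The synthetic cohort

The generator emulates a routine-TDM ICU cohort and is the package's stand-in
for restricted patient data; its defaults are the study conditions, not
tuning knobs. Structure: 33.58% CRRT; sex 83M/51F; continuous covariates
from truncated log-normals parameterized so the printed median is the
distribution median and the wider range endpoint sits at the ~99th
percentile (age 58 [22–89] y, height 166 [148–175] cm, weight 58.5 [40–84]
kg, albumin 29.1 [16.7–54] g/L, creatinine 143 [24–1,145] µmol/L); regimen
mix 1 g q8h 57.3%, 1 g q6h 12.9%, 0.5 g q8h 8.6%, 2 g q8h 6.5%, 2 g q12h
4.3%, with the remaining 10.4% split uniformly over 1 g q12h, 0.5 g q6h,
2 g q6h and a continuous infusion (duration = interval); intermittent
infusion durations drawn from {0.5, 1, 2, 3, 4} h with probabilities
{0.30, 0.35, 0.15, 0.12, 0.08} reflecting routine practice. Where the
emulated cohort publishes no value, one realistic choice was made and kept:
sepsis prevalence 0.6; CRRT effluent flow log-normal with median 2 L/h on
[1, 4]; residual diuresis truncated-normal 2078 ± 1634 ml/day for non-CRRT
patients and 500 ± 600 ml/day (oliguric) for CRRT patients; 88/134 of
patients contribute a single sample, the rest 2–4 samples with weights
{0.55, 0.35, 0.10} (matching the cohort's 205-sample total on average).
Sampling is trough-biased — uniformly within 1 h before a scheduled dose —
after five run-in cycles (≥ 97% of steady state for a typical 1 h half-life
times 8 h interval… conservatively more for slow eliminators), one occasion
per dosing interval. The generating model defaults to Muro (its covariate
formula is fully printed and its mixed population matches the cohort); η and
noise-free concentrations are retained as ground truth; observations below
0.5 mg/L are flagged and excluded by the LLOQ filter.

**What the generator does not emulate:** longitudinal covariate drift,
within-day renal-function swings, CRRT machine settings beyond a single
effluent-flow covariate, assay error structure beyond the proportional
model, informative sampling (levels drawn *because* the patient looked
toxic), and real model misspecification — the synthetic data are generated
by one of the candidate models. Passing tests therefore demonstrate internal
consistency of engine + estimator + diagnostics and calibrated error rates
under the stated design; they do not certify any model's accuracy in real
ICU patients.

**A structural note on the population criteria.** With trough-only sampling,
PE compares *population* predictions against *individual* observations, so
MAPE/F20/F30 are bounded by the total interindividual + residual variability
regardless of model quality. At the published Muro IIV (52.1% CV on CL) even
the generating model fails the combined criteria on its own cohort
(measured F20 ≈ 22%) — consistent with none of the published models passing
on real data. The discrimination property (true model passes, halved-CL
model fails) is therefore demonstrated at a moderate-variability setting
(Ω scaled to 0.25, CL CV ≈ 25%), where the criteria are attainable.

## 7. Evaluation pipeline

`ExternalEvaluation.fit()` stratifies everything by CRRT status (all /
CRRT / non-CRRT), caches population predictions per model, and runs: the
PE% summaries; pcVPC and NPDE per stratum; EBE adequacy over all patients
(patients without observations contribute η = 0, i.e. full shrinkage); the
a priori vs Bayesian comparison on patients with ≥ 2 observations, where the
Bayesian forecast of the last observation conditions on the most recent
earlier one (the prior-combination study on ≥ 3-observation patients backs
this choice: one recent prior captures most of the gain); and the
dose-adaptation contingency tables for both methods. Per-model seeds derive
from the run seed via `SeedSequence.spawn`, so runs are byte-identical at a
fixed seed and models can be added without disturbing others' streams. A
failing model is recorded and skipped, never fatal.

## 8. Known limitations

* Placeholder θ values make the affected models structurally faithful but
  quantitatively approximate; conclusions about those specific models should
  rest on the printed-formula subset.
* Saturable elimination, absorption lag, and oral dosing are out of scope.
* Steady state is exact only for periodic regimens; irregular histories are
  handled by explicit superposition of the recorded doses.
* The NPDE decorrelation assumes enough replicates for a stable covariance
  (≥ 100 recommended); below that the ridge guard may engage.
* BQL observations are excluded, not modelled (no M3-style likelihood).
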