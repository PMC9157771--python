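model_id: ulldemolins
label: Ulldemolins et al.
population_class: crrt
n_compartments: 1
parametrization: clv
thetas:
  cl:
    value: 3.68
    unit: L/h
    provenance: printed
  diur:
    value: 0.22
    unit: L/h per 100 ml/day
    provenance: printed
  v:
    value: 33.0
    unit: L
    provenance: printed
formulas:
  cl: theta_cl + theta_diur * (residual_diuresis / 100.0)
  v1: theta_v * (wt / 73.0) ** 2.07
iiv:
  cl:
    cv_percent: 37.0
    provenance: printed
  v1:
    cv_percent: 45.0
    provenance: printed
reference:
  residual_diuresis: 0.0
  wt: 73.0
notes: CRRT population. theta_cl is assumed to equal the published typical CL 3.68 L/h, i.e.
  the zero-diuresis clearance. The diuresis unit in the source is ambiguous; ml/day is used
  here.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
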