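model_id: li
label: Li et al.
population_class: mixed
n_compartments: 2
parametrization: clv
thetas:
  cl:
    value: 14.6
    unit: L/h
    provenance: printed
  vc:
    value: 10.8
    unit: L
    provenance: printed
  q:
    value: 18.6
    unit: L/h
    provenance: printed
  vp:
    value: 12.6
    unit: L
    provenance: printed
formulas:
  cl: theta_cl * (clcr / 83.0) ** 0.62 * (age / 35.0) ** -0.34
  v1: theta_vc * (wt / 70.0) ** 0.99
  q: theta_q
  v2: theta_vp
iiv:
  cl:
    cv_percent: 34.3
    provenance: printed
  v1:
    cv_percent: 31.94
    provenance: printed
reference:
  clcr: 83.0
  age: 35.0
  wt: 70.0
notes: Clearance power-law in CLcr and age; central volume scales with weight.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
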