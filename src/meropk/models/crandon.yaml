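model_id: crandon
label: Crandon et al.
population_class: non_crrt
n_compartments: 2
parametrization: micro
thetas:
  k10_int:
    value: 0.3922
    unit: 1/h
    provenance: printed
  k10_slope:
    value: 0.0025
    unit: 1/h per ml/min
    provenance: printed
  v1_coef:
    value: 0.239
    unit: L/kg
    provenance: printed
  k12:
    value: 0.45
    unit: 1/h
    provenance: placeholder
  k21:
    value: 0.35
    unit: 1/h
    provenance: placeholder
formulas:
  k10: theta_k10_int + theta_k10_slope * clcr
  v1: adjbw * theta_v1_coef
  k12: theta_k12
  k21: theta_k21
iiv:
  v1:
    cv_percent: 53.76
    provenance: printed
reference:
  clcr: 0.0
notes: 'Micro-constant parametrization: elimination rate linear in CLcr, central volume 0.239
  L/kg adjusted body weight (Devine IBW + 0.4x excess). Peripheral k12/k21 are placeholders.
  IIV printed for V only.'
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
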