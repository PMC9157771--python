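model_id: mattioli
label: Mattioli et al.
population_class: non_crrt
n_compartments: 1
parametrization: clv
thetas:
  cl:
    value: 2.181
    unit: L/h
    provenance: printed
  sepsis:
    value: -0.2
    unit: '-'
    provenance: placeholder
  sex:
    value: -0.15
    unit: '-'
    provenance: placeholder
  v:
    value: 8.305
    unit: L
    provenance: printed
  alb_pow:
    value: -0.5
    unit: '-'
    provenance: placeholder
  age_pow:
    value: 0.5
    unit: '-'
    provenance: placeholder
formulas:
  cl: theta_cl * (1 + theta_sepsis * sepsis) * (1 + theta_sex * female)
  v1: theta_v * (alb / 22.0) ** theta_alb_pow * (age / 61.0) ** theta_age_pow
iiv:
  cl:
    cv_percent: 44.38
    provenance: printed
  v1:
    cv_percent: 66.48
    provenance: printed
reference:
  sepsis: false
  female: false
notes: Sepsis and sex shift clearance; albumin and age enter the volume as power terms. Effect
  magnitudes and exponents are not printed; placeholders carry plausible signs and moderate
  sizes.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
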