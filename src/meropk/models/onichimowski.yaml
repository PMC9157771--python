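model_id: onichimowski
label: Onichimowski et al.
population_class: crrt
n_compartments: 2
parametrization: clv
thetas:
  cl:
    value: 15.1
    unit: L/h
    provenance: printed
  v1:
    value: 27.9
    unit: L
    provenance: printed
  q:
    value: 10.0
    unit: L/h
    provenance: placeholder
  v2:
    value: 20.0
    unit: L
    provenance: placeholder
formulas:
  cl: theta_cl
  v1: theta_v1 * (alb / 24.6) ** -2.87
  q: theta_q
  v2: theta_v2
iiv:
  cl:
    cv_percent: 43.7
    provenance: printed
  v1:
    cv_percent: 53.1
    provenance: printed
reference:
  alb: 24.6
notes: CRRT population; central volume a steep inverse power of serum albumin (g/L, reference
  24.6). Q/V2 placeholders.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
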