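model_id: ehmann
label: Ehmann et al.
population_class: non_crrt
n_compartments: 2
parametrization: clv
thetas:
  cl:
    value: 9.25
    unit: L/h
    provenance: printed
  clcr_inf:
    value: 143.0
    unit: ml/min
    provenance: placeholder
  v1:
    value: 7.89
    unit: L
    provenance: printed
  q:
    value: 28.4
    unit: L/h
    provenance: printed
  v2:
    value: 12.0
    unit: L
    provenance: placeholder
formulas:
  cl: theta_cl * (1 + 0.00977 * (min(clcr, theta_clcr_inf) - 80.8))
  v1: theta_v1 * (wt / 70.0) ** 0.945
  q: theta_q
  v2: theta_v2 * (1 - 0.202 * (alb_gdl - 2.79))
iiv:
  cl:
    cv_percent: 27.1
    provenance: printed
  v1:
    cv_percent: 31.5
    provenance: printed
reference:
  clcr: 80.8
  wt: 70.0
  alb: 27.9
notes: Clearance increases linearly with Cockcroft-Gault CLcr up to an inflection point (not
  printed; 143 ml/min placeholder) and is constant above it. Albumin enters the peripheral
  volume on the g/dL scale (reference 2.79 g/dL); theta_v2 is a placeholder.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
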