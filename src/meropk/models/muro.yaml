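model_id: muro
label: Muro et al.
population_class: mixed
n_compartments: 1
parametrization: clv
thetas:
  cl:
    value: 11.1
    unit: L/h
    provenance: printed
  v:
    value: 33.6
    unit: L
    provenance: printed
formulas:
  cl: theta_cl * (mscr / 0.7) ** -1.0
  v1: theta_v
iiv:
  cl:
    cv_percent: 52.1
    provenance: printed
reference:
  mscr: 0.7
notes: Clearance inversely proportional to a floored serum creatinine (mSCR, mg/dL, floor
  0.4). No interindividual variability on V.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
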