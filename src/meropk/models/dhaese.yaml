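model_id: dhaese
label: Dhaese et al.
population_class: non_crrt
n_compartments: 1
parametrization: clv
thetas:
  cl:
    value: 9.46
    unit: L/h
    provenance: printed
  v:
    value: 48.1
    unit: L
    provenance: printed
formulas:
  cl: theta_cl * (clcr / 135.0)
  v1: theta_v
iiv:
  cl:
    cv_percent: 37.5
    provenance: printed
reference:
  clcr: 135.0
notes: Developed on continuous-infusion data. Clearance proportional to Cockcroft-Gault CLcr
  (reference 135 ml/min). No IIV on V.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
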