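model_id: grensemann
label: Grensemann et al.
population_class: crrt
n_compartments: 2
parametrization: clv
thetas:
  cl:
    value: 5.06
    unit: L/h
    provenance: printed
  v1:
    value: 8.31
    unit: L
    provenance: printed
  q:
    value: 8.0
    unit: L/h
    provenance: placeholder
  v2:
    value: 15.0
    unit: L
    provenance: placeholder
formulas:
  cl: theta_cl
  v1: theta_v1
  q: theta_q
  v2: theta_v2
iiv:
  cl:
    cv_percent: 29.8
    provenance: printed
reference: {}
notes: CRRT population; no covariates retained. Q/V2 placeholders; IIV printed for CL only.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
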