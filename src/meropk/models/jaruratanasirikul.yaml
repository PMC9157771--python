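model_id: jaruratanasirikul
label: Jaruratanasirikul et al.
population_class: mixed
n_compartments: 1
parametrization: clv
thetas:
  cl_int:
    value: 1.01
    unit: L/h
    provenance: placeholder
  cl_slope:
    value: 0.02
    unit: L/h per ml/min
    provenance: placeholder
  v:
    value: 23.7
    unit: L
    provenance: printed
formulas:
  cl: theta_cl_int + theta_cl_slope * mdrd_clcr
  v1: theta_v
iiv:
  cl:
    cv_percent: 48.0
    provenance: printed
  v1:
    cv_percent: 35.0
    provenance: printed
reference: {}
notes: Clearance linear in MDRD creatinine clearance; intercept and slope are not printed.
  Placeholders anchor the typical CL 3.01 L/h at MDRD CLcr 100 ml/min/1.73m2.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
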