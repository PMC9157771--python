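model_id: sjovall
label: Sjovall et al.
population_class: non_crrt
n_compartments: 2
parametrization: clv
thetas:
  cl_scale:
    value: 1.0
    unit: '-'
    provenance: placeholder
  v:
    value: 16.916
    unit: L
    provenance: printed
  q:
    value: 7.0
    unit: L/h
    provenance: placeholder
  v2:
    value: 10.0
    unit: L
    provenance: placeholder
formulas:
  cl: theta_cl_scale * (2.0 + 0.083 * clcr)
  v1: theta_v
  q: theta_q
  v2: theta_v2
iiv:
  cl:
    cv_percent: 40.578
    provenance: printed
  v1:
    cv_percent: 38.872
    provenance: printed
reference: {}
notes: The published clearance formula TVCL x [2 + 0.083 x CLcr] does not reproduce the published
  typical CL 6.83 L/h under any obvious reference with a separate TVCL; implemented with a
  unit scale (the bracket alone gives 6.83 at CLcr 58.2 ml/min). Excluded from typical-value
  checks. Q/V2 placeholders.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
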