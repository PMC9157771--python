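model_id: roberts
label: Roberts et al.
population_class: non_crrt
n_compartments: 2
parametrization: clv
thetas:
  cl_slope:
    value: 0.136
    unit: L/h per ml/min
    provenance: placeholder
  v1:
    value: 7.9
    unit: L
    provenance: printed
  q:
    value: 15.0
    unit: L/h
    provenance: placeholder
  v2:
    value: 12.0
    unit: L
    provenance: placeholder
formulas:
  cl: theta_cl_slope * clcr
  v1: theta_v1
  q: theta_q
  v2: theta_v2
iiv:
  cl:
    cv_percent: 15.3
    provenance: printed
  v1:
    cv_percent: 44.7
    provenance: printed
reference:
  clcr: 100.0
notes: Clearance proportional to Cockcroft-Gault CLcr. The slope is not printed; 0.136 anchors
  the typical CL 13.6 L/h at CLcr 100 ml/min. Peripheral Q/V2 are placeholders.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
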