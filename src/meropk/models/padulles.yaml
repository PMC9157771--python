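model_id: padulles
label: Padulles et al.
population_class: crrt
n_compartments: 2
parametrization: clv
thetas:
  cl_fr:
    value: 0.702
    unit: per L/h of effluent
    provenance: printed
  vc:
    value: 24.9
    unit: L
    provenance: printed
  cld:
    value: 6.49
    unit: L/h
    provenance: printed
  vp:
    value: 283.0
    unit: L
    provenance: printed
formulas:
  cl: theta_cl_fr * crrt_flow
  v1: theta_vc
  q: theta_cld
  v2: theta_vp
iiv:
  cl:
    cv_percent: 50.79
    provenance: printed
  v1:
    cv_percent: 45.7
    provenance: printed
reference:
  crrt_flow: 11.083
notes: CRRT population; clearance proportional to the summed dialysate + ultrafiltrate flow.
  The published typical CL 7.78 L/h implies a reference flow of about 11.1 L/h, well above
  usual effluent rates - the flow unit in the source may differ; recorded as printed.
options: {}
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
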