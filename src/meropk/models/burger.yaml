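model_id: burger
label: Burger et al.
population_class: mixed
n_compartments: 2
parametrization: clv
thetas:
  cl_res:
    value: 3.2
    unit: L/h
    provenance: printed
  sc:
    value: 0.8
    unit: '-'
    provenance: placeholder
  cl_pop:
    value: 5.9
    unit: L/h
    provenance: printed
  median_clcr:
    value: 65.0
    unit: ml/min
    provenance: placeholder
  vc:
    value: 16.0
    unit: L
    provenance: printed
  median_bw:
    value: 70.0
    unit: kg
    provenance: placeholder
  q:
    value: 14.0
    unit: L/h
    provenance: printed
  v2:
    value: 15.0
    unit: L
    provenance: printed
formulas:
  cl: where(crrt, theta_cl_res + theta_sc * crrt_flow, theta_cl_pop * (1 + 0.0071 * (clcr
    - theta_median_clcr)))
  v1: theta_vc * (wt / theta_median_bw) * 1.7
  q: theta_q
  v2: theta_v2
options:
  v_reading: literal
iiv:
  cl:
    cv_percent: 40.0
    provenance: printed
  v1:
    cv_percent: 51.0
    provenance: printed
reference:
  crrt: true
  crrt_flow: 2.0
notes: CRRT clearance = residual 3.2 L/h + sieving x effluent flow; a sieving coefficient
  of 0.8 with a 2 L/h flow reproduces the published typical CL_CRRT 4.8 L/h. The central-volume
  formula is recorded literally (16 x BW/medianBW x 1.7 = 27.2 L at median BW) although the
  published typical V is 17.00 L; set option v_reading='power' for the alternative 16 x (BW/medianBW)^1.7
  reading. The published non-CRRT typical CL 8.0 L/h is likewise not reproduced by the printed
  formula at the median CLcr.
sigma:
  kind: proportional
  proportional: 0.2
  additive: 0.0
  provenance: placeholder
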