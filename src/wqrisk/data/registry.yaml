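# Parameter registry: units, index weights and rating-curve references.
# NSF weights cover 9 parameters and sum to 1.00; IRWQI weights cover 11
# parameters and sum to 1.00.
parameters:
  fecal_coliform: {unit: "CFU/100mL", nsf_weight: 0.16, irwqi_weight: 0.140, curve: fecal_coliform}
  bod5: {unit: "mg/L", nsf_weight: 0.11, irwqi_weight: 0.117, curve: bod5}
  no3: {unit: "mg/L", nsf_weight: 0.10, irwqi_weight: 0.108, curve: no3}
  do_sat: {unit: "% saturation", nsf_weight: 0.17, irwqi_weight: 0.097, curve: do_sat}
  ec: {unit: "uS/cm", irwqi_weight: 0.096, curve: ec}
  cod: {unit: "mg/L", irwqi_weight: 0.093, curve: cod}
  nh4: {unit: "mg/L", irwqi_weight: 0.090, curve: nh4}
  po4: {unit: "mg/L", nsf_weight: 0.10, irwqi_weight: 0.087, curve: po4}
  turbidity: {unit: "NTU", nsf_weight: 0.08, irwqi_weight: 0.062, curve: turbidity}
  th: {unit: "mg CaCO3/L", irwqi_weight: 0.059, curve: th}
  ph: {unit: "", nsf_weight: 0.11, irwqi_weight: 0.051, curve: ph}
  temperature: {unit: "degC", nsf_weight: 0.10, curve: temperature}
  ts: {unit: "mg/L", nsf_weight: 0.07, curve: ts}
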