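# Default exposure constants per age group.
# ir: ingestion rate (L/day); ed: exposure duration (years);
# ef: exposure frequency (days/year); bw: body weight (kg);
# rfd: oral reference dose for nitrate (mg/kg/day).
groups:
  children: {ir: 1.25, ed: 8, ef: 345, bw: 16.41, rfd: 1.6}
  teenagers: {ir: 1.58, ed: 8, ef: 345, bw: 39.83, rfd: 1.6}
  adults: {ir: 1.95, ed: 52, ef: 345, bw: 77.45, rfd: 1.6}
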