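# Example input distributions for the probabilistic HQ model.
# ILLUSTRATION ONLY: the underlying study does not publish its input
# distributions, so these are plausible stand-ins, not calibrated values.
#
# Top-level entries are shared across age groups; the groups: section
# overrides per-group inputs (ingestion rate and body weight scale with age).
C: {family: lognormal, median: 16.66, sigma: 0.39, lower: 7.8, upper: 35.6}
EF: {family: triangular, left: 200, mode: 345, right: 365}
IR: {family: uniform, low: 0.25, high: 2.5}
BW: {family: normal, mean: 16.41, sd: 3.3, lower: 5.0}
groups:
  children:
    IR: {family: uniform, low: 0.25, high: 2.5}
    BW: {family: normal, mean: 16.41, sd: 3.3, lower: 5.0}
  teenagers:
    IR: {family: uniform, low: 0.3, high: 3.2}
    BW: {family: normal, mean: 39.83, sd: 8.0, lower: 15.0}
  adults:
    IR: {family: uniform, low: 0.4, high: 3.9}
    BW: {family: normal, mean: 77.45, sd: 15.5, lower: 30.0}
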