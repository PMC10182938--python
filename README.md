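# wqrisk

Reusable analysis chain for reservoir drinking-water monitoring data:

1. **Water-quality indices** (`wqrisk.wqi`) — piecewise-linear rating curves
   map each physicochemical/microbial parameter to a 0–100 sub-index;
   NSFWQI aggregates sub-indices as a weighted arithmetic mean
   (`sum(Q_i*W_i)/sum(W_i)`), IRWQISC as a weighted geometric mean
   (`prod(I_i**W_i)**(1/gamma)`, `gamma = sum(W_i)`); scores are classified
   into quality bands and aggregated over stations/seasons with
   half-away-from-zero rounding at 1 decimal.
2. **Exposure risk** (`wqrisk.risk`) — chronic daily intake
   `CDI = C*IR*ED*EF/(BW*AT)` with `AT = ED*365` (so ED cancels) and hazard
   quotient `HQ = CDI/RfD` for children/teenagers/adults; `HQ >= 1` flags
   unacceptable non-carcinogenic risk.
3. **Monte Carlo** (`wqrisk.montecarlo`) — independent marginal sampling of
   C/IR/EF/BW (point, uniform, triangular, normal, lognormal,
   truncated-normal, empirical families; optional truncation bounds),
   rowwise HQ, type-7 empirical percentiles and P(HQ >= 1).
4. **Sobol sensitivity** (`wqrisk.sobol`) — paired-matrix (A/B plus
   column-swapped) design with `N*(2k+2)` model evaluations; Jansen
   estimators for first- and total-order indices, closed second-order
   effects from the B_A/A_B matrix pairs, bootstrap percentile intervals.
5. **Synthetic data & fixtures** (`wqrisk.synthetic`) — seed-reproducible
   5-station × 4-season × 13-parameter measurement tables drawn within the
   observed parameter ranges, plus the published seasonal index grids and
   CDI/HQ summary packaged as CSV fixtures (`load_fixture`).
6. **CLI** (`wqrisk.cli`) — subcommands tying the stages together.

The packaged rating curves (`src/wqrisk/data/curves.csv`) are best-effort
stand-ins for the standard index curves and are fully replaceable via
`--curves`/`--registry`; unit tests use synthetic curves so correctness does
not depend on them. The packaged distribution config
(`data/distributions.yaml`) is illustrative only — the source study does not
publish its input distributions.

## CLI

```sh
wqrisk synth --seed 1 --out meas.csv
wqrisk wqi --scheme nsf --measurements meas.csv --out wqi_nsf.csv
wqrisk wqi --scheme irwqi --measurements meas.csv --out wqi_ir.csv
wqrisk risk --concentrations conc.csv --out risk.csv
wqrisk mc --group children --n 50000 --seed 1 --out mc.json
wqrisk sobol --group children --n-base 4096 --n-boot 100 --seed 1 --out sobol.json
wqrisk all --seed 1 --out-dir results/
```

Exit codes: 0 ok, 1 input/config error, 2 internal error. Outputs embed the
seed and a config hash; fixed-seed runs are byte-identical.

## Layout

```
src/wqrisk/
  wqi.py          rating curves, registry, NSFWQI/IRWQISC, classification
  risk.py         CDI/HQ and per-group summary statistics
  montecarlo.py   distribution specs, sampling, probabilistic HQ
  sobol.py        sampling design, S/S_ij/T estimators, bootstrap CIs
  synthetic.py    measurement generator + packaged table fixtures
  cli.py          click entry points
  data/           curves.csv, registry.yaml, exposure.yaml,
                  distributions.yaml, table3/4/5.csv
tests/            unit + property tests, test_acceptance.py
scripts/acceptance.py
```
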