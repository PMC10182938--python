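"""Synthetic measurement tables and packaged reference-table fixtures.

The generator emulates the monitoring campaign's structure — 5 stations x
4 seasons x 13 physicochemical/microbial parameters — drawing each value
within the observed range of that parameter, so every pipeline stage can be
exercised without any external data.

``load_fixture`` exposes the published seasonal index grids and the
per-age-group CDI/HQ summary as plain DataFrames for regression tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .wqi import MeasurementTable

__all__ = [
    "ParamGen",
    "GeneratorConfig",
    "generate_measurements",
    "load_fixture",
    "FIXTURE_NAMES",
    "KNOWN_MEAN_DISCREPANCIES",
]

SEASONS = ("spring", "summer", "fall", "winter")

FIXTURE_NAMES = ("table3", "table4", "table5")

# (fixture, station) row-mean cells whose printed value cannot be recovered
# from the printed member cells under half-away-from-zero rounding (the
# source table presumably averaged unrounded monthly scores).
KNOWN_MEAN_DISCREPANCIES = {("table3", "2"), ("table3", "3"), ("table4", "1")}


@dataclass(frozen=True)
class ParamGen:
    """Sampling recipe for one parameter: uniform over [lo, hi] or lognormal
    around an arithmetic mean."""

    family: str = "uniform"
    lo: float = 0.0
    hi: float = 0.0
    mean: float = 0.0
    sigma: float = 0.3
    unit: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "lognormal"):
            raise ConfigError(f"unknown generator family {self.family!r}")
        if self.family == "uniform" and self.lo > self.hi:
            raise ConfigError(f"invalid range [{self.lo}, {self.hi}]")
        if self.family == "lognormal" and (self.mean <= 0 or self.sigma <= 0):
            raise ConfigError("lognormal generator needs positive mean and sigma")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(self.lo, self.hi, size=n)
        mu = np.log(self.mean) - self.sigma**2 / 2.0
        return rng.lognormal(mu, self.sigma, size=n)


def _default_params() -> dict[str, ParamGen]:
    # Ranges follow the observed spans of the monitoring campaign; EC has no
    # published span, and DO/COD bracket the published station statistics.
    return {
        "no3": ParamGen("uniform", 7.8, 35.6, unit="mg/L"),
        "ph": ParamGen("uniform", 6.48, 7.9, unit=""),
        "temperature": ParamGen("uniform", 12.0, 26.0, unit="degC"),
        "turbidity": ParamGen("uniform", 8.0, 24.0, unit="NTU"),
        "ts": ParamGen("uniform", 10.0, 40.0, unit="mg/L"),
        "th": ParamGen("uniform", 154.0, 530.0, unit="mg CaCO3/L"),
        "fecal_coliform": ParamGen("uniform", 0.0, 125.0, unit="CFU/100mL"),
        "po4": ParamGen("uniform", 0.4, 2.3, unit="mg/L"),
        "bod5": ParamGen("uniform", 2.0, 8.3, unit="mg/L"),
        "nh4": ParamGen("lognormal", mean=0.012, sigma=0.3, unit="mg/L"),
        "do_sat": ParamGen("uniform", 35.0, 38.0, unit="% saturation"),
        "cod": ParamGen("uniform", 20.0, 54.0, unit="mg/L"),
        "ec": ParamGen("uniform", 500.0, 1500.0, unit="uS/cm"),
    }


@dataclass
class GeneratorConfig:
    stations: int = 5
    periods: tuple[str, ...] = SEASONS
    parameters: dict[str, ParamGen] = field(default_factory=_default_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stations < 1:
            raise ConfigError(f"need at least 1 station, got {self.stations}")
        if not self.periods:
            raise ConfigError("need at least 1 period")
        if not self.parameters:
            raise ConfigError("need at least 1 parameter")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"generator config not found: {path}")
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"generator config {path}: expected a mapping")
        params = _default_params()
        for name, cfg in (data.get("parameters") or {}).items():
            params[name] = ParamGen(
                family=cfg.get("family", "uniform"),
                lo=float(cfg.get("lo", 0.0)),
                hi=float(cfg.get("hi", 0.0)),
                mean=float(cfg.get("mean", 0.0)),
                sigma=float(cfg.get("sigma", 0.3)),
                unit=str(cfg.get("unit", "")),
            )
        return cls(
            stations=int(data.get("stations", 5)),
            periods=tuple(data.get("periods", SEASONS)),
            parameters=params,
            seed=int(data.get("seed", 0)),
        )


def generate_measurements(config: GeneratorConfig | None = None) -> MeasurementTable:
    """One record per station x period x parameter, seed-reproducible."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for param in config.parameters:  # draw parameter-major for stable streams
        gen = config.parameters[param]
        draws = gen.sample(config.stations * len(config.periods), rng)
        m = 0
        for s in range(1, config.stations + 1):
            for period in config.periods:
                rows.append(
                    {
                        "station": str(s),
                        "period": period,
                        "parameter": param,
                        "value": float(draws[m]),
                        "unit": gen.unit,
                    }
                )
                m += 1
    df = pd.DataFrame(rows).sort_values(["station", "period", "parameter"], kind="stable")
    return MeasurementTable(df.reset_index(drop=True))


def load_fixture(name: str) -> pd.DataFrame:
    """Published reference tables.

    * ``table3`` / ``table4`` — seasonal index grids: columns station, season
      (spring/summer/fall/winter/mean; station 'mean' rows are the seasonal
      column means), score, label.
    * ``table5`` — columns group, metric (cdi/hq), stat (min/mean/max/sd),
      value.
    """
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    with resources.as_file(resources.files("wqrisk.data") / f"{name}.csv") as p:
        df = pd.read_csv(p, dtype={"station": str} if name != "table5" else None)
    return df
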