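"""Monte Carlo propagation of the hazard-quotient model.

Inputs (C, IR, EF, BW) are sampled independently from configured marginal
distributions and pushed through the CDI/HQ formulas; the result reports
empirical percentiles (linear interpolation of order statistics, the
numpy default, i.e. Hyndman-Fan type 7) and the exceedance probability
P(HQ >= 1).

Distribution families: point, uniform, triangular, normal, lognormal,
truncated-normal, empirical.  Optional ``lower``/``upper`` bounds truncate
any continuous family via inverse-CDF restriction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigError
from .risk import DAYS_PER_YEAR, AgeGroupParams

__all__ = [
    "DistributionSpec",
    "MCResult",
    "sample_inputs",
    "mc_hq",
    "load_distributions",
]

INPUT_NAMES = ("C", "IR", "EF", "BW", "ED")
FAMILIES = ("point", "uniform", "triangular", "normal", "lognormal",
            "truncated-normal", "empirical")


@dataclass(frozen=True)
class DistributionSpec:
    """One stochastic model input: a named marginal distribution."""

    name: str
    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(
                f"input {self.name!r}: unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.lower is not None and self.upper is not None and self.lower >= self.upper:
            raise ConfigError(f"input {self.name!r}: truncation bounds out of order")
        self._frozen()  # validate parameters eagerly

    def _frozen(self):
        """Scipy frozen distribution for continuous families; None otherwise."""
        p = self.params
        try:
            if self.family == "uniform":
                lo, hi = float(p["low"]), float(p["high"])
                if not hi > lo:
                    raise ConfigError(f"input {self.name!r}: uniform needs low < high")
                return stats.uniform(loc=lo, scale=hi - lo)
            if self.family == "triangular":
                a, c, b = float(p["left"]), float(p["mode"]), float(p["right"])
                if not (a <= c <= b and a < b):
                    raise ConfigError(f"input {self.name!r}: triangular needs left <= mode <= right")
                return stats.triang(c=(c - a) / (b - a), loc=a, scale=b - a)
            if self.family in ("normal", "truncated-normal"):
                mean, sd = float(p["mean"]), float(p["sd"])
                if sd <= 0:
                    raise ConfigError(f"input {self.name!r}: sd must be positive")
                if self.family == "truncated-normal" and self.lower is None and self.upper is None:
                    raise ConfigError(f"input {self.name!r}: truncated-normal needs bounds")
                return stats.norm(loc=mean, scale=sd)
            if self.family == "lognormal":
                sigma = float(p["sigma"])
                if sigma <= 0:
                    raise ConfigError(f"input {self.name!r}: sigma must be positive")
                if "mu" in p:
                    mu = float(p["mu"])
                elif "median" in p:
                    mu = math.log(float(p["median"]))
                elif "mean" in p:
                    # arithmetic mean of the lognormal
                    mu = math.log(float(p["mean"])) - sigma**2 / 2.0
                else:
                    raise ConfigError(f"input {self.name!r}: lognormal needs mu, median or mean")
                return stats.lognorm(s=sigma, scale=math.exp(mu))
            if self.family == "point":
                if "value" not in p:
                    raise ConfigError(f"input {self.name!r}: point mass needs 'value'")
                return None
            if self.family == "empirical":
                vals = p.get("values")
                if not isinstance(vals, (list, tuple, np.ndarray)) or len(vals) == 0:
                    raise ConfigError(f"input {self.name!r}: empirical needs a non-empty 'values' list")
                return None
        except KeyError as exc:
            raise ConfigError(f"input {self.name!r} ({self.family}): missing parameter {exc}")
        return None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point":
            return np.full(n, float(self.params["value"]))
        if self.family == "empirical":
            vals = np.asarray(self.params["values"], dtype=float)
            draws = rng.choice(vals, size=n, replace=True)
        else:
            frozen = self._frozen()
            if self.lower is not None or self.upper is not None:
                u_lo = frozen.cdf(self.lower) if self.lower is not None else 0.0
                u_hi = frozen.cdf(self.upper) if self.upper is not None else 1.0
                if u_hi <= u_lo:
                    raise ConfigError(
                        f"input {self.name!r}: truncation interval has zero probability mass"
                    )
                draws = frozen.ppf(rng.uniform(u_lo, u_hi, size=n))
            else:
                draws = frozen.ppf(rng.uniform(0.0, 1.0, size=n))
        return np.asarray(draws, dtype=float)

    @classmethod
    def from_dict(cls, name: str, cfg: Mapping) -> "DistributionSpec":
        if not isinstance(cfg, Mapping) or "family" not in cfg:
            raise ConfigError(f"input {name!r}: expected a mapping with a 'family' key")
        params = {k: v for k, v in cfg.items() if k not in ("family", "lower", "upper")}
        return cls(
            name=name,
            family=str(cfg["family"]),
            params=params,
            lower=cfg.get("lower"),
            upper=cfg.get("upper"),
        )


def point(name: str, value: float) -> DistributionSpec:
    """Convenience point-mass spec."""
    return DistributionSpec(name=name, family="point", params={"value": float(value)})


def sample_inputs(
    specs: Mapping[str, DistributionSpec],
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> pd.DataFrame:
    """n independent joint draws (one column per input), seed-reproducible."""
    if n < 1:
        raise ConfigError(f"need n >= 1 draws, got {n}")
    if not specs:
        raise ConfigError("no input distributions specified")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return pd.DataFrame({name: spec.sample(n, rng) for name, spec in specs.items()})


@dataclass(frozen=True)
class MCResult:
    """Monte Carlo HQ summary for one age group."""

    group: str
    n: int
    seed: int
    mean: float
    sd: float
    percentiles: Mapping[float, float]  # level (%) -> HQ value
    p_exceed: float  # P(HQ >= 1)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "seed": self.seed,
            "mean": self.mean,
            "sd": self.sd,
            "percentiles": {str(k): v for k, v in self.percentiles.items()},
            "p_exceed": self.p_exceed,
        }


def hq_model(draws: pd.DataFrame, params: AgeGroupParams) -> np.ndarray:
    """Vectorised HQ = C*IR*EF / (BW*365*RfD); missing columns fall back to
    the group's point values (ED cancels with AT and never enters)."""
    c = draws["C"].to_numpy() if "C" in draws else np.full(len(draws), np.nan)
    ir = draws["IR"].to_numpy() if "IR" in draws else params.ir
    ef = draws["EF"].to_numpy() if "EF" in draws else params.ef
    bw = draws["BW"].to_numpy() if "BW" in draws else params.bw
    return c * ir * ef / (bw * DAYS_PER_YEAR * params.rfd)


def mc_hq(
    specs: Mapping[str, DistributionSpec],
    params: AgeGroupParams,
    n: int = 50_000,
    seed: int = 0,
    levels: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> MCResult:
    """Sample the inputs, evaluate HQ rowwise and summarise.

    ``specs`` must cover C; IR/EF/BW default to point masses at the group's
    constants when absent.
    """
    if "C" not in specs:
        raise ConfigError("Monte Carlo HQ needs a distribution for C (concentration)")
    full = dict(specs)
    for name, value in (("IR", params.ir), ("EF", params.ef), ("BW", params.bw)):
        full.setdefault(name, point(name, value))
    draws = sample_inputs(full, n, seed)
    samples = hq_model(draws, params)
    pct = np.percentile(samples, levels)  # linear (type-7) interpolation
    return MCResult(
        group=params.label,
        n=n,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)) if n > 1 else 0.0,
        percentiles={float(l): float(v) for l, v in zip(levels, pct)},
        p_exceed=float((samples >= 1.0).mean()),
    )


def load_distributions(path: str | Path, group: str | None = None) -> dict[str, DistributionSpec]:
    """Read a distributions YAML.

    Top-level entries are shared defaults; an optional ``groups:`` section
    holds per-age-group overrides merged on top when ``group`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"distributions file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"distributions file {path}: expected a mapping")
    base = {k: v for k, v in data.items() if k != "groups"}
    overrides = data.get("groups", {})
    if group is not None and group in overrides:
        base.update(overrides[group])
    specs = {}
    for name, cfg in base.items():
        if name not in INPUT_NAMES:
            raise ConfigError(f"unknown model input {name!r}; expected one of {INPUT_NAMES}")
        specs[name] = DistributionSpec.from_dict(name, cfg)
    return specs
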