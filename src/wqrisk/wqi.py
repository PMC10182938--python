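"""Water-quality index engine.

Rates raw parameter values into sub-indices via piecewise-linear rating
curves, aggregates sub-indices into two index schemes —

* ``NSFWQI``: weighted arithmetic mean ``sum(Q_i * W_i) / sum(W_i)``;
* ``IRWQISC``: weighted geometric mean ``(prod(I_i ** W_i)) ** (1 / gamma)``
  with ``gamma = sum(W_i)``, evaluated in the log domain;

classifies scores into quality bands, and aggregates scores over stations
and periods.  Both schemes renormalise by the sum of the weights actually
present, so tables with missing parameters remain scoreable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError, RegistryError
from .rounding import round_half_away

__all__ = [
    "NSFWQI",
    "IRWQISC",
    "RatingCurve",
    "ParameterSpec",
    "ParameterRegistry",
    "MeasurementTable",
    "WQIResult",
    "rate_parameter",
    "nsfwqi",
    "irwqi",
    "classify",
    "score_measurements",
    "summarize_scores",
    "aggregate_scores",
    "load_curves",
    "default_curves",
    "default_registry",
]

NSFWQI = "NSFWQI"
IRWQISC = "IRWQISC"

_SCHEME_ALIASES = {
    "nsfwqi": NSFWQI,
    "nsf": NSFWQI,
    "irwqisc": IRWQISC,
    "irwqi": IRWQISC,
}

# Quality bands as (upper bound, inclusive?, label), scanned in order.
# Bands are contiguous: printed gaps between e.g. 25 and 26 are treated as
# bin edges of a continuous score.
_NSF_BANDS = [
    (25.0, True, "Very bad"),
    (50.0, True, "Bad"),
    (70.0, True, "Medium"),
    (90.0, True, "Good"),
    (100.0, True, "Excellent"),
]
_IRWQI_BANDS = [
    (15.0, False, "Very bad"),
    (30.0, False, "Bad"),
    (45.0, False, "Relatively bad"),
    (55.1, False, "Medium"),
    (70.0, True, "Relatively good"),
    (85.0, True, "Good"),
    (100.0, True, "Very good"),
]


def resolve_scheme(scheme: str) -> str:
    try:
        return _SCHEME_ALIASES[scheme.strip().lower()]
    except KeyError:
        raise ConfigError(f"unknown index scheme {scheme!r}; expected NSFWQI or IRWQISC")


# ---------------------------------------------------------------------------
# Rating curves


@dataclass(frozen=True)
class RatingCurve:
    """Piecewise-linear map from a parameter value to a sub-index."""

    parameter: str
    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) < 2:
            raise ConfigError(f"curve {self.parameter!r}: need at least 2 breakpoints")
        xs = [x for x, _ in self.breakpoints]
        qs = [q for _, q in self.breakpoints]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigError(f"curve {self.parameter!r}: x values must be strictly increasing")
        if any(not (0.0 <= q <= 100.0) for q in qs):
            raise ConfigError(f"curve {self.parameter!r}: sub-index values must lie in [0, 100]")

    @property
    def x(self) -> np.ndarray:
        return np.asarray([x for x, _ in self.breakpoints], dtype=float)

    @property
    def q(self) -> np.ndarray:
        return np.asarray([q for _, q in self.breakpoints], dtype=float)

    def rate(self, value: float) -> float:
        """Interpolate the sub-index; clamp outside the curve domain."""
        if not math.isfinite(value):
            raise InputError(f"curve {self.parameter!r}: non-finite value {value!r}")
        return float(np.interp(value, self.x, self.q))


def rate_parameter(value: float, curve: RatingCurve) -> float:
    """Sub-index of ``value`` on ``curve`` (linear interpolation, clamped)."""
    return curve.rate(value)


def load_curves(path: str | Path) -> dict[str, RatingCurve]:
    """Read a curves CSV (columns parameter, x, q) into RatingCurve objects."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"curves file not found: {path}")
    df = pd.read_csv(path)
    missing = {"parameter", "x", "q"} - set(df.columns)
    if missing:
        raise ConfigError(f"curves file {path}: missing columns {sorted(missing)}")
    curves = {}
    for name, grp in df.groupby("parameter", sort=False):
        pts = tuple(zip(grp["x"].astype(float), grp["q"].astype(float)))
        curves[str(name)] = RatingCurve(str(name), pts)
    return curves


def default_curves() -> dict[str, RatingCurve]:
    """Packaged rating-curve tables (replaceable stand-ins; see data/curves.csv)."""
    with resources.as_file(resources.files("wqrisk.data") / "curves.csv") as p:
        return load_curves(p)


# ---------------------------------------------------------------------------
# Parameter registry


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    unit: str = ""
    nsf_weight: float | None = None
    irwqi_weight: float | None = None
    curve_id: str | None = None

    def __post_init__(self) -> None:
        for w in (self.nsf_weight, self.irwqi_weight):
            if w is not None and not (0.0 <= w <= 1.0):
                raise ConfigError(f"parameter {self.name!r}: weight {w} outside [0, 1]")


@dataclass(frozen=True)
class ParameterRegistry:
    """Per-parameter units, index weights and rating-curve references."""

    parameters: Mapping[str, ParameterSpec]

    def __contains__(self, name: str) -> bool:
        return name in self.parameters

    def spec(self, name: str) -> ParameterSpec:
        try:
            return self.parameters[name]
        except KeyError:
            raise RegistryError(f"parameter {name!r} not in registry")

    def weights(self, scheme: str) -> dict[str, float]:
        scheme = resolve_scheme(scheme)
        attr = "nsf_weight" if scheme == NSFWQI else "irwqi_weight"
        return {
            name: w
            for name, spec in self.parameters.items()
            if (w := getattr(spec, attr)) is not None
        }

    def validate_weight_sums(self, tol: float = 1e-9) -> None:
        """Check that each scheme's full weight set sums to 1."""
        for scheme in (NSFWQI, IRWQISC):
            total = sum(self.weights(scheme).values())
            if abs(total - 1.0) > tol:
                raise ConfigError(f"{scheme} weights sum to {total!r}, expected 1.0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "ParameterRegistry":
        params = {}
        entries = data.get("parameters", data)
        for name, cfg in entries.items():
            cfg = cfg or {}
            params[name] = ParameterSpec(
                name=name,
                unit=str(cfg.get("unit", "")),
                nsf_weight=cfg.get("nsf_weight"),
                irwqi_weight=cfg.get("irwqi_weight"),
                curve_id=cfg.get("curve", cfg.get("curve_id", name)),
            )
        return cls(parameters=params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterRegistry":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"registry file not found: {path}")
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"registry file {path}: expected a mapping")
        return cls.from_dict(data)


def default_registry() -> ParameterRegistry:
    """Packaged registry with the standard NSFWQI / IRWQISC weight tables."""
    with resources.as_file(resources.files("wqrisk.data") / "registry.yaml") as p:
        reg = ParameterRegistry.from_yaml(p)
    reg.validate_weight_sums()
    return reg


# ---------------------------------------------------------------------------
# Measurements


@dataclass
class MeasurementTable:
    """Long-format station x period x parameter observations."""

    df: pd.DataFrame = field(repr=False)

    COLUMNS = ("station", "period", "parameter", "value", "unit")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise InputError(f"measurement table missing columns {sorted(missing)}")
        df = self.df.loc[:, list(self.COLUMNS)].copy()
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if not np.isfinite(df["value"]).all():
            raise InputError("measurement table contains non-finite values")
        neg = df[(df["value"] < 0) & (df["parameter"] != "temperature")]
        if not neg.empty:
            row = neg.iloc[0]
            raise InputError(
                f"negative value {row['value']} for {row['parameter']!r} "
                f"(station {row['station']}, period {row['period']})"
            )
        dup = df.duplicated(subset=["station", "period", "parameter"])
        if dup.any():
            row = df[dup].iloc[0]
            raise InputError(
                f"duplicate record for ({row['station']}, {row['period']}, {row['parameter']})"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate_against(self, registry: ParameterRegistry) -> None:
        unknown = set(self.df["parameter"]) - set(registry.parameters)
        if unknown:
            raise RegistryError(f"unknown parameters in measurement table: {sorted(unknown)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementTable":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"measurements file not found: {path}")
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Index aggregation


def _check_subindices(subindices: Mapping[str, float], lo: float) -> None:
    if not subindices:
        raise InputError("empty sub-index set")
    for name, q in subindices.items():
        if not math.isfinite(q):
            raise InputError(f"sub-index for {name!r} is non-finite")
        if q < lo or q > 100.0:
            raise InputError(f"sub-index {q} for {name!r} outside [{lo:g}, 100]")


def nsfwqi(subindices: Mapping[str, float], registry: ParameterRegistry) -> float:
    """Weighted arithmetic index over the parameters present.

    Missing parameters drop out; the score is renormalised by the sum of the
    weights actually used.
    """
    _check_subindices(subindices, lo=0.0)
    weights = registry.weights(NSFWQI)
    used = {p: q for p, q in subindices.items() if p in weights}
    if not used:
        raise InputError("no NSF-weighted parameter present in sub-index set")
    wsum = sum(weights[p] for p in used)
    return sum(q * weights[p] for p, q in used.items()) / wsum


def irwqi(subindices: Mapping[str, float], registry: ParameterRegistry) -> float:
    """Weighted geometric index, exponent 1/gamma with gamma = sum of weights."""
    if not subindices:
        raise InputError("empty sub-index set")
    for name, q in subindices.items():
        if not math.isfinite(q) or q <= 0.0:
            raise InputError(f"sub-index {q} for {name!r}: geometric mean needs values > 0")
        if q > 100.0:
            raise InputError(f"sub-index {q} for {name!r} outside (0, 100]")
    weights = registry.weights(IRWQISC)
    used = {p: q for p, q in subindices.items() if p in weights}
    if not used:
        raise InputError("no IRWQI-weighted parameter present in sub-index set")
    gamma = sum(weights[p] for p in used)
    log_score = sum(weights[p] * math.log(q) for p, q in used.items()) / gamma
    return math.exp(log_score)


def classify(score: float, scheme: str) -> str:
    """Quality-class label for a score under the given scheme."""
    scheme = resolve_scheme(scheme)
    if not math.isfinite(score) or score < 0.0 or score > 100.0:
        raise InputError(f"score {score!r} outside [0, 100]")
    bands = _NSF_BANDS if scheme == NSFWQI else _IRWQI_BANDS
    for upper, inclusive, label in bands:
        if score < upper or (inclusive and score == upper):
            return label
    return bands[-1][2]


# ---------------------------------------------------------------------------
# Scoring measurement tables


@dataclass(frozen=True)
class WQIResult:
    scheme: str
    station_id: str
    period: str
    score: float
    label: str
    subindices: Mapping[str, float]
    used_weight_sum: float


def score_measurements(
    table: MeasurementTable,
    registry: ParameterRegistry,
    curves: Mapping[str, RatingCurve],
    scheme: str,
) -> list[WQIResult]:
    """Rate and aggregate every (station, period) cell of a measurement table."""
    scheme = resolve_scheme(scheme)
    table.validate_against(registry)
    weights = registry.weights(scheme)
    q_floor = 0.0 if scheme == NSFWQI else 1.0
    results = []
    for (station, period), grp in table.df.groupby(["station", "period"], sort=True):
        subs = {}
        for _, row in grp.iterrows():
            param = row["parameter"]
            if param not in weights:
                continue
            spec = registry.spec(param)
            curve_id = spec.curve_id or param
            if curve_id not in curves:
                raise ConfigError(f"no rating curve {curve_id!r} for parameter {param!r}")
            q = rate_parameter(float(row["value"]), curves[curve_id])
            subs[param] = min(max(q, q_floor), 100.0)
        score = nsfwqi(subs, registry) if scheme == NSFWQI else irwqi(subs, registry)
        results.append(
            WQIResult(
                scheme=scheme,
                station_id=str(station),
                period=str(period),
                score=score,
                label=classify(score, scheme),
                subindices=subs,
                used_weight_sum=sum(weights[p] for p in subs),
            )
        )
    return results


def summarize_scores(scores: Sequence[float], scheme: str) -> tuple[float, str]:
    """Mean of member scores rounded to 1 decimal, label from the unrounded mean."""
    if len(scores) == 0:
        raise InputError("cannot aggregate an empty score group")
    mean = float(np.mean(np.asarray(scores, dtype=float)))
    return round_half_away(mean, 1), classify(mean, scheme)


def aggregate_scores(results: Iterable[WQIResult], by: str) -> pd.DataFrame:
    """Group WQI results by station or period and average their scores."""
    results = list(results)
    if not results:
        raise InputError("no results to aggregate")
    schemes = {r.scheme for r in results}
    if len(schemes) != 1:
        raise InputError(f"results mix schemes {sorted(schemes)}")
    scheme = schemes.pop()
    if by not in ("station", "period"):
        raise ConfigError(f"aggregate by {by!r}; expected 'station' or 'period'")
    key = (lambda r: r.station_id) if by == "station" else (lambda r: r.period)
    groups: dict[str, list[float]] = {}
    for r in results:
        groups.setdefault(key(r), []).append(r.score)
    rows = []
    for group in sorted(groups):
        mean, label = summarize_scores(groups[group], scheme)
        rows.append({by: group, "mean_score": mean, "label": label})
    return pd.DataFrame(rows, columns=[by, "mean_score", "label"])
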