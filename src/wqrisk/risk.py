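"""Deterministic non-carcinogenic risk of nitrate in drinking water.

Chronic daily intake (mg/kg/day)::

    CDI = C * IR * ED * EF / (BW * AT),   AT = ED * 365

so CDI is independent of ED.  The hazard quotient HQ = CDI / RfD flags an
unacceptable risk when HQ >= 1.
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

from .errors import ConfigError, InputError
from .rounding import round_half_away

__all__ = [
    "AgeGroupParams",
    "RiskSummary",
    "cdi",
    "hq",
    "summarize_risk",
    "load_exposure",
    "default_exposure",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class AgeGroupParams:
    """Exposure constants for one age group.

    IR: ingestion rate (L/day); ED: exposure duration (years);
    EF: exposure frequency (days/year); BW: body weight (kg);
    AT: averaging time (days, ED*365); RfD: oral reference dose (mg/kg/day).
    """

    label: str
    ir: float
    ed: float
    ef: float
    bw: float
    rfd: float
    at: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.at == 0.0:
            object.__setattr__(self, "at", self.ed * DAYS_PER_YEAR)
        for name in ("ir", "ed", "ef", "bw", "rfd", "at"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ConfigError(f"group {self.label!r}: {name} must be strictly positive, got {v!r}")
        if self.ef > DAYS_PER_YEAR:
            raise ConfigError(f"group {self.label!r}: EF {self.ef} exceeds 365 days/year")
        if abs(self.at - self.ed * DAYS_PER_YEAR) > 1e-6:
            raise ConfigError(f"group {self.label!r}: AT must equal ED*365")


def cdi(c: float, params: AgeGroupParams) -> float:
    """Chronic daily intake (mg/kg/day) at concentration ``c`` (mg/L)."""
    if not math.isfinite(c) or c < 0:
        raise InputError(f"concentration must be a non-negative number, got {c!r}")
    return c * params.ir * params.ed * params.ef / (params.bw * params.at)


def hq(c: float, params: AgeGroupParams) -> float:
    """Hazard quotient CDI/RfD (dimensionless)."""
    if params.rfd <= 0:
        raise ConfigError(f"group {params.label!r}: RfD must be positive")
    return cdi(c, params) / params.rfd


@dataclass(frozen=True)
class RiskSummary:
    """Per-group summary statistics over a set of concentrations."""

    group: str
    cdi_min: float
    cdi_mean: float
    cdi_max: float
    cdi_sd: float
    hq_min: float
    hq_mean: float
    hq_max: float
    hq_sd: float
    exceedance: bool  # any HQ >= 1


def summarize_risk(
    concentrations: Sequence[float],
    groups: Iterable[AgeGroupParams],
) -> dict[str, RiskSummary]:
    """Elementwise CDI/HQ over concentrations, then min/mean/max/sample-sd.

    Sample standard deviation uses the n-1 convention and needs >= 2 values.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise InputError("empty concentration list")
    if conc.size < 2:
        raise InputError("need at least 2 concentrations for a standard deviation")
    out = {}
    for p in groups:
        cdis = np.array([cdi(c, p) for c in conc])
        hqs = cdis / p.rfd
        out[p.label] = RiskSummary(
            group=p.label,
            cdi_min=float(cdis.min()),
            cdi_mean=float(cdis.mean()),
            cdi_max=float(cdis.max()),
            cdi_sd=float(cdis.std(ddof=1)),
            hq_min=float(hqs.min()),
            hq_mean=float(hqs.mean()),
            hq_max=float(hqs.max()),
            hq_sd=float(hqs.std(ddof=1)),
            exceedance=bool((hqs >= 1.0).any()),
        )
    return out


def risk_frame(summaries: Mapping[str, RiskSummary], decimals: int | None = 2) -> pd.DataFrame:
    """Tabular view of risk summaries, rounded for reporting by default."""
    rows = []
    for s in summaries.values():
        row = {
            "group": s.group,
            "cdi_min": s.cdi_min, "cdi_mean": s.cdi_mean,
            "cdi_max": s.cdi_max, "cdi_sd": s.cdi_sd,
            "hq_min": s.hq_min, "hq_mean": s.hq_mean,
            "hq_max": s.hq_max, "hq_sd": s.hq_sd,
            "exceedance": s.exceedance,
        }
        if decimals is not None:
            for k, v in row.items():
                if isinstance(v, float):
                    row[k] = round_half_away(v, decimals)
        rows.append(row)
    return pd.DataFrame(rows)


def _parse_groups(data: Mapping) -> dict[str, AgeGroupParams]:
    entries = data.get("groups", data)
    if not isinstance(entries, Mapping) or not entries:
        raise ConfigError("exposure config: expected a non-empty 'groups' mapping")
    groups = {}
    for label, cfg in entries.items():
        try:
            groups[label] = AgeGroupParams(
                label=label,
                ir=float(cfg["ir"]),
                ed=float(cfg["ed"]),
                ef=float(cfg["ef"]),
                bw=float(cfg["bw"]),
                rfd=float(cfg["rfd"]),
            )
        except KeyError as exc:
            raise ConfigError(f"exposure group {label!r}: missing field {exc}")
    return groups


def load_exposure(path: str | Path) -> dict[str, AgeGroupParams]:
    """Read an exposure YAML (groups with ir/ed/ef/bw/rfd)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"exposure file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"exposure file {path}: expected a mapping")
    return _parse_groups(data)


def default_exposure() -> dict[str, AgeGroupParams]:
    """Packaged children/teenagers/adults exposure constants."""
    with resources.as_file(resources.files("wqrisk.data") / "exposure.yaml") as p:
        return load_exposure(p)
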