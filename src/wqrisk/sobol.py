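"""Variance-based (Sobol) global sensitivity analysis.

Sampling follows the paired-matrix radial design: two independent base
matrices A and B of shape (N, k) plus the column-swapped matrices A_B^(i)
(A with column i taken from B) and B_A^(i), for N*(2k+2) model evaluations
in total.

Estimators:

* first order   S_i = (V - mean((f(B) - f(A_B^i))^2) / 2) / V        (Jansen)
* total order   T_i = (mean((f(A) - f(A_B^i))^2) / 2) / V            (Jansen)
* closed second-order variance  V_ij = mean(f(B_A^i) * f(A_B^j)) - f0^2,
  with the interaction effect S_ij = V_ij / V - S_i - S_j

Small-sample estimates may be slightly negative; they are reported as-is,
with bootstrap percentile intervals (resampling design rows) conveying the
uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, InputError
from .montecarlo import DistributionSpec, point, sample_inputs
from .risk import DAYS_PER_YEAR, AgeGroupParams

__all__ = [
    "SobolDesign",
    "SobolResult",
    "saltelli_design",
    "sobol_indices",
    "hq_sensitivity",
]

DEGENERATE_REL_VAR = 1e-12


@dataclass(frozen=True)
class SobolDesign:
    """Radial sampling design for Sobol index estimation."""

    names: tuple[str, ...]
    n_base: int
    a: np.ndarray          # (N, k)
    b: np.ndarray          # (N, k)
    ab: np.ndarray         # (k, N, k); ab[i] = A with column i from B
    ba: np.ndarray         # (k, N, k); ba[i] = B with column i from A
    seed: int

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def n_evaluations(self) -> int:
        return self.n_base * (2 * self.k + 2)


def saltelli_design(
    specs: Mapping[str, DistributionSpec],
    n_base: int,
    seed: int,
) -> SobolDesign:
    """Draw A and B from the input marginals and build the swapped matrices."""
    names = tuple(specs)
    k = len(names)
    if n_base < 2:
        raise ConfigError(f"need base sample size N >= 2, got {n_base}")
    if k < 2:
        raise ConfigError(f"need at least 2 inputs, got {k}")
    ss = np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    a = sample_inputs(specs, n_base, np.random.default_rng(child_a)).to_numpy()
    b = sample_inputs(specs, n_base, np.random.default_rng(child_b)).to_numpy()
    ab = np.repeat(a[None, :, :], k, axis=0)
    ba = np.repeat(b[None, :, :], k, axis=0)
    for i in range(k):
        ab[i, :, i] = b[:, i]
        ba[i, :, i] = a[:, i]
    return SobolDesign(names=names, n_base=n_base, a=a, b=b, ab=ab, ba=ba, seed=int(seed))


@dataclass(frozen=True)
class SobolResult:
    """Estimated first/second/total-order indices with bootstrap intervals."""

    names: tuple[str, ...]
    first: dict[str, float]
    total: dict[str, float]
    second: dict[tuple[str, str], float]
    variance: float
    first_ci: dict[str, tuple[float, float]]
    total_ci: dict[str, tuple[float, float]]
    second_ci: dict[tuple[str, str], tuple[float, float]]
    first_se: dict[str, float]
    total_se: dict[str, float]
    second_se: dict[tuple[str, str], float]
    n_base: int
    n_boot: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        pair_key = lambda p: f"{p[0]}*{p[1]}"
        return {
            "inputs": list(self.names),
            "variance": self.variance,
            "n_base": self.n_base,
            "n_boot": self.n_boot,
            "degenerate": self.degenerate,
            "first_order": {
                n: {"estimate": self.first[n], "se": self.first_se[n], "ci": list(self.first_ci[n])}
                for n in self.names
            },
            "total_order": {
                n: {"estimate": self.total[n], "se": self.total_se[n], "ci": list(self.total_ci[n])}
                for n in self.names
            },
            "second_order": {
                pair_key(p): {
                    "estimate": self.second[p],
                    "se": self.second_se[p],
                    "ci": list(self.second_ci[p]),
                }
                for p in self.second
            },
        }


def _estimate(
    fa: np.ndarray, fb: np.ndarray, fab: np.ndarray, fba: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Point estimates (S, T, closed-pair S_ij matrix upper-tri, V)."""
    k = fab.shape[0]
    f_all = np.concatenate([fa, fb])
    v = float(f_all.var(ddof=1))
    if v <= 0:
        return np.zeros(k), np.zeros(k), np.zeros((k, k)), 0.0
    s = np.empty(k)
    t = np.empty(k)
    for i in range(k):
        s[i] = (v - 0.5 * np.mean((fb - fab[i]) ** 2)) / v
        t[i] = 0.5 * np.mean((fa - fab[i]) ** 2) / v
    f0_sq = float(np.mean(fa * fb))
    s2 = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v_ij_closed = float(np.mean(fba[i] * fab[j])) - f0_sq
            s2[i, j] = v_ij_closed / v - s[i] - s[j]
    return s, t, s2, v


def sobol_indices(
    design: SobolDesign,
    model: Callable[[np.ndarray], np.ndarray],
    n_boot: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> SobolResult:
    """Evaluate ``model`` on the design and estimate S_i, S_ij and T_i."""
    k, n = design.k, design.n_base

    def run(mat: np.ndarray, label: str) -> np.ndarray:
        out = np.asarray(model(mat), dtype=float)
        if out.shape != (len(mat),):
            raise InputError(f"model returned shape {out.shape} for {len(mat)} rows")
        bad = ~np.isfinite(out)
        if bad.any():
            row = int(np.argmax(bad))
            raise InputError(f"non-finite model output at {label} row {row}: inputs {mat[row]}")
        return out

    fa = run(design.a, "A")
    fb = run(design.b, "B")
    fab = np.stack([run(design.ab[i], f"A_B^{design.names[i]}") for i in range(k)])
    fba = np.stack([run(design.ba[i], f"B_A^{design.names[i]}") for i in range(k)])

    mean_sq = float(np.mean(np.concatenate([fa, fb]))) ** 2
    s, t, s2, v = _estimate(fa, fb, fab, fba)
    pairs = [(design.names[i], design.names[j]) for i in range(k) for j in range(i + 1, k)]

    degenerate = v < DEGENERATE_REL_VAR * max(mean_sq, 1.0)
    if degenerate:
        warnings.warn("model output variance is (near) zero; all Sobol indices set to 0")
        zeros_n = {n_: 0.0 for n_ in design.names}
        zeros_p = {p: 0.0 for p in pairs}
        ci_n = {n_: (0.0, 0.0) for n_ in design.names}
        ci_p = {p: (0.0, 0.0) for p in pairs}
        return SobolResult(
            names=design.names, first=dict(zeros_n), total=dict(zeros_n),
            second=dict(zeros_p), variance=v,
            first_ci=ci_n, total_ci=dict(ci_n), second_ci=ci_p,
            first_se=dict(zeros_n), total_se=dict(zeros_n), second_se=dict(zeros_p),
            n_base=n, n_boot=n_boot, degenerate=True,
        )

    rng = np.random.default_rng(seed)
    boot_s = np.empty((n_boot, k))
    boot_t = np.empty((n_boot, k))
    boot_s2 = np.empty((n_boot, len(pairs)))
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        bs, bt, bs2, _ = _estimate(fa[idx], fb[idx], fab[:, idx], fba[:, idx])
        boot_s[r] = bs
        boot_t[r] = bt
        boot_s2[r] = [bs2[i, j] for i in range(k) for j in range(i + 1, k)]

    alpha = (1.0 - ci_level) / 2.0
    lo, hi = 100.0 * alpha, 100.0 * (1.0 - alpha)

    def ci(col: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(col, lo)), float(np.percentile(col, hi)))

    s2_flat = [s2[i, j] for i in range(k) for j in range(i + 1, k)]
    return SobolResult(
        names=design.names,
        first={n_: float(s[i]) for i, n_ in enumerate(design.names)},
        total={n_: float(t[i]) for i, n_ in enumerate(design.names)},
        second={p: float(s2_flat[m]) for m, p in enumerate(pairs)},
        variance=v,
        first_ci={n_: ci(boot_s[:, i]) for i, n_ in enumerate(design.names)},
        total_ci={n_: ci(boot_t[:, i]) for i, n_ in enumerate(design.names)},
        second_ci={p: ci(boot_s2[:, m]) for m, p in enumerate(pairs)},
        first_se={n_: float(boot_s[:, i].std(ddof=1)) for i, n_ in enumerate(design.names)},
        total_se={n_: float(boot_t[:, i].std(ddof=1)) for i, n_ in enumerate(design.names)},
        second_se={p: float(boot_s2[:, m].std(ddof=1)) for m, p in enumerate(pairs)},
        n_base=n,
        n_boot=n_boot,
    )


def hq_model_factory(names: Sequence[str], params: AgeGroupParams) -> Callable[[np.ndarray], np.ndarray]:
    """Rowwise HQ model over a design matrix with the given column order."""
    idx = {name: i for i, name in enumerate(names)}

    def model(x: np.ndarray) -> np.ndarray:
        col = lambda name, default: x[:, idx[name]] if name in idx else default
        c = col("C", 0.0)
        ir = col("IR", params.ir)
        ef = col("EF", params.ef)
        bw = col("BW", params.bw)
        return c * ir * ef / (bw * DAYS_PER_YEAR * params.rfd)

    return model


def hq_sensitivity(
    specs: Mapping[str, DistributionSpec],
    params: AgeGroupParams,
    n_base: int,
    seed: int,
    n_boot: int = 100,
) -> SobolResult:
    """Sobol analysis of HQ over the stochastic inputs C, IR, EF, BW."""
    required = ("C", "IR", "EF", "BW")
    full: dict[str, DistributionSpec] = {}
    defaults = {"IR": params.ir, "EF": params.ef, "BW": params.bw}
    for name in required:
        if name in specs:
            full[name] = specs[name]
        elif name in defaults:
            full[name] = point(name, defaults[name])
        else:
            raise ConfigError("HQ sensitivity needs a distribution for C")
    design = saltelli_design(full, n_base, seed)
    model = hq_model_factory(design.names, params)
    return sobol_indices(design, model, n_boot=n_boot, seed=seed + 1)
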