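"""Generalizability-theory reliability analysis.

The measurement design is fully crossed Subject x Evaluator x Visit x Image
(S x E x V x I), all facets random, one observation per cell.  The G-study
estimates the 15 variance components (4 main effects, 11 interactions, the
four-way SEVI doubling as the residual) by the method of moments: balanced
ANOVA mean squares equated to their expected values and the triangular
system solved from the highest-order effect downward.

The D-study projects those components onto hypothetical protocols that
average over n_e' evaluators, n_v' visits and n_i' images: the absolute
error variance divides each non-subject component by the product of the
D-study sizes of the averaged facets appearing in it, giving the
dependability coefficient Phi = sigma2_S / (sigma2_S + sigma2_abs), the
standard error of measurement SEM = sqrt(sigma2_abs), and minimal
detectable change MDC_abs = z * sqrt(2) * SEM (z = 1.65 for 90% confidence),
normalized to a percentage of the group mean.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FACETS",
    "EFFECTS",
    "VarianceComponents",
    "DStudyResult",
    "estimate_variance_components",
    "variance_proportions",
    "dstudy",
    "mdc",
    "protocol_grid",
    "interpret_phi",
    "DEFAULT_PROTOCOLS",
    "Z_90",
]

FACETS = ("S", "E", "V", "I")

#: the 15 effects of the crossed random model, in reporting order
EFFECTS = (
    "S", "E", "V", "I",
    "SE", "SV", "SI", "EV", "EI", "VI",
    "SEV", "SEI", "SVI", "EVI",
    "SEVI",
)

Z_90 = 1.65

#: D-study protocols reported by default: one evaluator, 1-2 visits, 1-3 images
DEFAULT_PROTOCOLS = tuple((1, v, i) for v in (1, 2) for i in (1, 2, 3))

_COLMAP = {"S": "tendon_id", "E": "evaluator", "V": "visit", "I": "image"}


@dataclass(frozen=True)
class VarianceComponents:
    """Estimated variance components of the crossed S x E x V x I model."""

    raw: dict[str, float]
    sizes: dict[str, int]
    clamped: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        missing = set(EFFECTS) - set(self.raw)
        if missing:
            raise ValueError(f"missing effects: {sorted(missing)}")
        object.__setattr__(self, "clamped", {k: max(0.0, v) for k, v in self.raw.items()})

    @property
    def subject(self) -> float:
        return self.clamped["S"]

    def error_components(self) -> dict[str, float]:
        return {k: v for k, v in self.clamped.items() if k != "S"}


@dataclass(frozen=True)
class DStudyResult:
    """Reliability projection for one protocol (n_e', n_v', n_i')."""

    n_e: int
    n_v: int
    n_i: int
    phi: float
    g_coefficient: float
    sem: float
    mdc_abs: float
    mdc_norm: float
    group_mean: float
    z: float = Z_90

    @property
    def interpretation(self) -> str:
        return interpret_phi(self.phi)


def _effect_axes(effect: str) -> tuple[int, ...]:
    return tuple(FACETS.index(f) for f in effect)


def _to_array(table: pd.DataFrame, value_col: str = "value") -> tuple[np.ndarray, dict[str, int]]:
    """Arrange a long-format record table into a dense (S, E, V, I) array."""
    df = table
    for facet, col in _COLMAP.items():
        if col not in df.columns:
            raise ValueError(f"measurement table lacks column {col!r}")
    if value_col not in df.columns:
        raise ValueError(f"measurement table lacks column {value_col!r}")
    if df[value_col].isna().any():
        raise ValueError("measurement table contains missing/undefined values")
    levels = {f: sorted(df[_COLMAP[f]].unique()) for f in FACETS}
    sizes = {f: len(levels[f]) for f in FACETS}
    n_cells = int(np.prod(list(sizes.values())))
    if len(df) != n_cells:
        raise ValueError(
            f"design is not balanced/complete: {len(df)} records for {n_cells} cells"
        )
    idx = [df[_COLMAP[f]].map({lv: k for k, lv in enumerate(levels[f])}).to_numpy() for f in FACETS]
    arr = np.full(tuple(sizes[f] for f in FACETS), np.nan)
    arr[tuple(idx)] = df[value_col].to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("design is not balanced/complete: duplicate or missing cells")
    return arr, sizes


def estimate_variance_components(
    table: pd.DataFrame, value_col: str = "value"
) -> VarianceComponents:
    """Method-of-moments (EMS) variance-component estimates.

    Expects a long-format table with columns tendon_id, evaluator, visit,
    image and ``value_col``, forming a complete balanced crossed design with
    one observation per cell.  Facets observed at a single level yield
    structurally-zero components for every effect containing them.
    """
    y, sizes = _to_array(table, value_col)
    if sizes["S"] < 2:
        raise ValueError("at least 2 subjects are required")
    n = {f: sizes[f] for f in FACETS}
    n_total = int(np.prod(list(n.values())))
    grand = float(y.mean())

    # T(alpha) = sum over all cells of the squared alpha-level mean
    T: dict[frozenset, float] = {frozenset(): n_total * grand**2}
    for r in range(1, 5):
        for combo in itertools.combinations(FACETS, r):
            keep = frozenset(combo)
            other_axes = tuple(i for i, f in enumerate(FACETS) if f not in keep)
            means = y.mean(axis=other_axes) if other_axes else y
            mult = int(np.prod([n[f] for f in FACETS if f not in keep])) if other_axes else 1
            T[keep] = float((means**2).sum()) * mult

    ss: dict[str, float] = {}
    df_: dict[str, int] = {}
    for eff in EFFECTS:
        keep = frozenset(eff)
        total = 0.0
        for r in range(0, len(keep) + 1):
            for sub in itertools.combinations(sorted(keep), r):
                total += (-1) ** (len(keep) - r) * T[frozenset(sub)]
        ss[eff] = total
        df_[eff] = int(np.prod([n[f] - 1 for f in eff]))

    ms = {eff: (ss[eff] / df_[eff] if df_[eff] > 0 else 0.0) for eff in EFFECTS}

    # coefficient of sigma2_beta in EMS(alpha) for beta >= alpha:
    # product of sizes of facets absent from beta
    coef = {eff: int(np.prod([n[f] for f in FACETS if f not in eff])) for eff in EFFECTS}
    raw: dict[str, float] = {}
    for eff in sorted(EFFECTS, key=len, reverse=True):
        if df_[eff] == 0:
            raw[eff] = 0.0
            continue
        ems_rest = sum(
            coef[sup] * raw[sup]
            for sup in EFFECTS
            if len(sup) > len(eff) and set(eff) <= set(sup)
        )
        raw[eff] = (ms[eff] - ems_rest) / coef[eff]
    return VarianceComponents(raw={eff: raw[eff] for eff in EFFECTS}, sizes=sizes)


def variance_proportions(vc: VarianceComponents) -> dict[str, float]:
    """Clamped components as percentages of their total (sums to 100)."""
    total = sum(vc.clamped.values())
    if total <= 0:
        raise ValueError("all variance components are zero")
    return {eff: 100.0 * vc.clamped[eff] / total for eff in EFFECTS}


def _error_variance(vc: VarianceComponents, n_e: int, n_v: int, n_i: int, relative: bool) -> float:
    sizes = {"E": n_e, "V": n_v, "I": n_i}
    total = 0.0
    for eff, sigma2 in vc.clamped.items():
        if eff == "S":
            continue
        if relative and "S" not in eff:
            continue
        denom = 1
        for f, nf in sizes.items():
            if f in eff:
                denom *= nf
        total += sigma2 / denom
    return total


def dstudy(
    vc: VarianceComponents,
    n_e: int = 1,
    n_v: int = 1,
    n_i: int = 1,
    group_mean: float = math.nan,
    z: float = Z_90,
) -> DStudyResult:
    """Project components onto a protocol averaging n_e x n_v x n_i scores."""
    if min(n_e, n_v, n_i) < 1:
        raise ValueError("protocol sizes must be >= 1")
    abs_err = _error_variance(vc, n_e, n_v, n_i, relative=False)
    rel_err = _error_variance(vc, n_e, n_v, n_i, relative=True)
    s2 = vc.subject
    if s2 + abs_err == 0:
        raise ValueError("dependability undefined: subject and error variance both zero")
    phi = s2 / (s2 + abs_err)
    g = s2 / (s2 + rel_err) if s2 + rel_err > 0 else math.nan
    sem = math.sqrt(abs_err)
    mdc_abs, mdc_norm = mdc(sem, group_mean, z) if not math.isnan(group_mean) else (
        z * math.sqrt(2.0) * sem,
        math.nan,
    )
    return DStudyResult(
        n_e=n_e, n_v=n_v, n_i=n_i, phi=phi, g_coefficient=g,
        sem=sem, mdc_abs=mdc_abs, mdc_norm=mdc_norm, group_mean=group_mean, z=z,
    )


def mdc(sem: float, group_mean: float, z: float = Z_90) -> tuple[float, float]:
    """(MDC_abs, MDC_norm %): z * sqrt(2) * SEM, then percent of the mean."""
    if sem < 0:
        raise ValueError("sem must be >= 0")
    if group_mean == 0:
        raise ValueError("group mean is zero; normalized MDC undefined")
    mdc_abs = z * math.sqrt(2.0) * sem
    return mdc_abs, 100.0 * mdc_abs / group_mean


def protocol_grid(
    vc: VarianceComponents,
    group_mean: float = math.nan,
    protocols: tuple[tuple[int, int, int], ...] = DEFAULT_PROTOCOLS,
    z: float = Z_90,
) -> list[DStudyResult]:
    """One D-study result per protocol, in the given (reporting) order."""
    return [dstudy(vc, n_e, n_v, n_i, group_mean=group_mean, z=z) for n_e, n_v, n_i in protocols]


def interpret_phi(phi: float) -> str:
    """Reliability band label for a dependability coefficient."""
    if not 0.0 <= phi <= 1.0 + 1e-12:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    if phi < 0.50:
        return "poor"
    if phi < 0.75:
        return "moderate"
    if phi < 0.90:
        return "good"
    return "excellent"
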