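"""Single-site hybridization equilibrium: Kₐ from titration data.

For a conjugate BC binding a target RNA with association constant Kₐ, the
fraction of RNA bound α at total concentrations [BC]₀ and [RNA]₀ obeys

    Kₐ = α / ( [BC]₀ · (1 − α) · (1 − α·[RNA]₀/[BC]₀) )

This module evaluates that expression per titration point, inverts it in
closed form (the physical root of a quadratic in α), and estimates Kₐ ± sd
from a titration series, either as a per-point mean (the study's
"value ± error" reporting style) or by least squares with bootstrap errors.

All concentrations are molar internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TitrationPoint",
    "KaEstimate",
    "BindingDomainError",
    "InsufficientDataError",
    "ka_point",
    "fraction_bound",
    "fit_ka",
    "read_titration_csv",
]


class BindingDomainError(ValueError):
    """Inputs outside the physical domain of the binding model."""


class InsufficientDataError(ValueError):
    """Too few usable titration points to estimate Kₐ."""


@dataclass(frozen=True)
class TitrationPoint:
    """One titration observation: totals (M) and fraction of RNA bound."""

    bc_total: float
    rna_total: float
    alpha: float

    def __post_init__(self):
        if self.bc_total <= 0 or self.rna_total <= 0:
            raise BindingDomainError("total concentrations must be positive")
        if not 0 <= self.alpha < 1:
            raise BindingDomainError(f"alpha={self.alpha} outside [0, 1)")
        if self.alpha * self.rna_total >= self.bc_total:
            raise BindingDomainError(
                "bound conjugate (alpha*[RNA]0) cannot reach total conjugate [BC]0"
            )


@dataclass(frozen=True)
class KaEstimate:
    ka: float           # M^-1
    sd: float           # M^-1
    n_points: int
    method: str

    def __post_init__(self):
        if self.ka < 0 or self.sd < 0 or self.n_points < 1:
            raise ValueError("invalid KaEstimate")


def ka_point(point: TitrationPoint) -> float:
    """Kₐ (M⁻¹) evaluated from a single titration point.

    α = 0 yields Kₐ = 0 with a warning (no binding detected).
    """
    a = point.alpha
    if a == 0:
        warnings.warn("alpha = 0: no binding detected, returning Ka = 0", stacklevel=2)
        return 0.0
    denom = point.bc_total * (1.0 - a) * (1.0 - a * point.rna_total / point.bc_total)
    if denom <= 0:
        raise BindingDomainError("denominator non-positive; point outside model domain")
    return a / denom


def fraction_bound(ka: float, bc_total: float, rna_total: float) -> float:
    """Closed-form inverse of the binding relation: α given Kₐ and totals.

    α solves  K·B·R·α² − (K·B·(1+R) + 1)·α + K·B = 0  with B = [BC]₀ and
    R = [RNA]₀/[BC]₀; the smaller root is the physical one, lying in
    [0, min(1, B/[RNA]₀)).  Solved in the cancellation-free form
    (roots q/a and c/q with q = (−b + √disc)/2), stable for K·B ≫ 1.
    """
    if ka < 0:
        raise BindingDomainError("Ka must be non-negative")
    if bc_total <= 0 or rna_total <= 0:
        raise BindingDomainError("total concentrations must be positive")
    if ka == 0:
        return 0.0
    kb = ka * bc_total
    r = rna_total / bc_total
    a = kb * r
    b = -(kb * (1.0 + r) + 1.0)
    c = kb
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise BindingDomainError("no real root: inputs outside model domain")
    q = (-b + math.sqrt(disc)) / 2.0  # -b > 0, no cancellation
    alpha = c / q                      # smaller root
    upper = min(1.0, bc_total / rna_total)
    if not 0.0 <= alpha < upper + 1e-12:
        raise BindingDomainError(f"no physical root (alpha={alpha})")
    return min(alpha, math.nextafter(upper, 0.0))


def fit_ka(
    series: Sequence[TitrationPoint],
    alpha_window: tuple[float, float] = (0.05, 0.95),
    method: Literal["point", "ls"] = "point",
    n_bootstrap: int = 200,
    seed: int | None = None,
) -> KaEstimate:
    """Estimate Kₐ ± sd from a titration series.

    ``point`` (default): evaluate Kₐ at every point with
    lo < α < hi, report mean ± sd.  Points near α = 0 or 1 are
    ill-conditioned in the model and are windowed out.

    ``ls``: least-squares fit of Kₐ minimizing Σ(α_obs − α_model)², with a
    bootstrap (resampled points) standard deviation.
    """
    lo, hi = alpha_window
    usable = [p for p in series if lo < p.alpha < hi]
    dropped = len(series) - len(usable)
    if dropped:
        warnings.warn(
            f"{dropped} titration point(s) outside alpha window ({lo}, {hi}) excluded",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise InsufficientDataError(
            f"need >= 2 usable points in alpha window ({lo}, {hi}), got {len(usable)}"
        )

    if method == "point":
        kas = np.array([ka_point(p) for p in usable])
        sd = float(np.std(kas, ddof=1)) if len(kas) > 1 else 0.0
        return KaEstimate(float(np.mean(kas)), sd, len(usable), "point")

    if method != "ls":
        raise ValueError(f"unknown method {method!r}")

    from scipy.optimize import least_squares

    bc = np.array([p.bc_total for p in usable])
    rna = np.array([p.rna_total for p in usable])
    obs = np.array([p.alpha for p in usable])

    def resid(log_ka: np.ndarray, idx: np.ndarray) -> np.ndarray:
        k = math.exp(log_ka[0])
        pred = np.array([fraction_bound(k, b, r) for b, r in zip(bc[idx], rna[idx])])
        return pred - obs[idx]

    x0 = math.log(max(np.mean([ka_point(p) for p in usable]), 1.0))
    all_idx = np.arange(len(usable))
    sol = least_squares(resid, [x0], args=(all_idx,))
    ka_hat = math.exp(sol.x[0])

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(usable), size=len(usable))
        try:
            b = least_squares(resid, [math.log(ka_hat)], args=(idx,))
            boots.append(math.exp(b.x[0]))
        except Exception:  # degenerate resample
            continue
    sd = float(np.std(boots, ddof=1)) if len(boots) > 1 else 0.0
    return KaEstimate(float(ka_hat), sd, len(usable), "ls")


def read_titration_csv(path: str | Path) -> dict[str, list[TitrationPoint]]:
    """Read titration series grouped by conjugate.

    Columns: conjugate, bc_total_uM, rna_total_uM, fraction_bound.
    Concentrations are given in μM and converted to molar.
    """
    df = pd.read_csv(path)
    required = {"conjugate", "bc_total_uM", "rna_total_uM", "fraction_bound"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing columns: {sorted(missing)}")
    out: dict[str, list[TitrationPoint]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.conjugate), []).append(
            TitrationPoint(
                bc_total=row.bc_total_uM * 1e-6,
                rna_total=row.rna_total_uM * 1e-6,
                alpha=row.fraction_bound,
            )
        )
    return out
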