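"""Intrinsic DNA-binding constants from UV-Vis titration series.

A chromophore titrated with CT-DNA at fixed compound concentration shows a
drifting apparent extinction coefficient eps_a = A / [compound]. Under 1:1
binding the Wolfe-Shimer double-reciprocal relation

    [DNA] / (eps_a - eps_f) = [DNA] / (eps_b - eps_f) + 1 / (K_b (eps_b - eps_f))

is exactly linear in [DNA], so ordinary least squares of
y = [DNA]/(eps_a - eps_f) on x = [DNA] gives the intrinsic binding constant
K_b = slope / intercept (M^-1) and the bound-form extinction coefficient
eps_b = eps_f + 1/slope. [DNA] is expressed in base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "apparent_epsilon",
    "wolfe_shimer_fit",
    "hypochromism_percent",
]


@dataclass(frozen=True)
class TitrationSeries:
    """One UV-Vis titration: [DNA] grid with apparent extinction coefficients.

    ``dna_conc`` in mol/L base pairs, strictly increasing; ``eps_app`` and
    ``eps_free`` in M^-1 cm^-1. ``ligand_conc`` and ``wavelength`` are
    informational.
    """

    dna_conc: np.ndarray
    eps_app: np.ndarray
    eps_free: float
    ligand_conc: float | None = None
    wavelength: float | None = None

    def __post_init__(self) -> None:
        dna = np.asarray(self.dna_conc, dtype=float)
        eps = np.asarray(self.eps_app, dtype=float)
        if dna.ndim != 1 or dna.shape != eps.shape or dna.size < 2:
            raise ValueError("dna_conc and eps_app must be matching 1-d arrays (n >= 2)")
        if np.any(dna < 0) or np.any(np.diff(dna) <= 0):
            raise ValueError("dna_conc must be non-negative and strictly increasing")
        object.__setattr__(self, "dna_conc", dna)
        object.__setattr__(self, "eps_app", eps)


@dataclass(frozen=True)
class BindingFit:
    slope: float
    intercept: float
    K_b: float
    eps_bound: float
    r_squared: float


def apparent_epsilon(absorbance: float, ligand_conc: float) -> float:
    """Apparent extinction coefficient eps_a = A / [compound] (M^-1 cm^-1)."""
    if ligand_conc <= 0:
        raise ValueError("ligand concentration must be positive")
    return absorbance / ligand_conc


def wolfe_shimer_fit(s: TitrationSeries, drop_zero: bool = True) -> BindingFit:
    """Fit K_b by the Wolfe-Shimer double-reciprocal regression.

    The [DNA] = 0 point is excluded by default (y is undefined there).
    Raises on retained points with eps_a == eps_f (no binding signal) and on
    a zero intercept (K_b unbounded).
    """
    dna = s.dna_conc
    eps = s.eps_app
    if drop_zero:
        keep = dna > 0
        dna, eps = dna[keep], eps[keep]
    if dna.size < 3:
        raise ValueError("need at least 3 retained titration points")
    de = eps - s.eps_free
    if np.any(de == 0):
        raise ValueError("eps_a equals eps_f at a retained point: degenerate")
    y = dna / de
    res = stats.linregress(dna, y)
    if res.intercept == 0:
        raise ZeroDivisionError("zero intercept: K_b is unbounded")
    return BindingFit(
        slope=res.slope,
        intercept=res.intercept,
        K_b=res.slope / res.intercept,
        eps_bound=s.eps_free + 1.0 / res.slope,
        r_squared=res.rvalue**2,
    )


def hypochromism_percent(s: TitrationSeries) -> float:
    """Percent drop of eps_a from the first to the last titration point.

    Summarizes the gradual hypochromic quenching of the monitored band; for
    a saturating 1:1 series it approaches 100 (eps_f - eps_b) / eps_f.
    """
    first = s.eps_app[0]
    if first == 0:
        raise ZeroDivisionError("eps_a at the first point is zero")
    return 100.0 * (first - s.eps_app[-1]) / first
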