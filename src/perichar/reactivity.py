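"""Conceptual-DFT global reactivity descriptors and Hammett regressions.

From frontier-orbital energies (E_HOMO, E_LUMO) the standard global indices
follow in closed form:

    gap   = E_L - E_H
    chi   = -(E_H + E_L) / 2        electronegativity
    mu    = -chi                    chemical potential
    eta   = (E_L - E_H) / 2         global hardness
    S     = eta / 2                 global softness (table convention here;
                                    the common alternative is S = 1/(2 eta))
    omega = mu^2 / (2 eta)          electrophilicity index
    sigma = 1 / eta                 absolute softness

The module is unit-agnostic: descriptors are returned in whatever energy
units the inputs carry.

Hammett linear free-energy regressions (response, or log10 response, against
substituent constants sigma) are ordinary least squares; the slope is the
reaction constant rho.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from types import MappingProxyType
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FrontierEnergies",
    "ReactivityDescriptors",
    "HammettPoint",
    "HammettFit",
    "HAMMETT_SIGMA",
    "descriptors",
    "hammett_fit",
]


#: Hansch-Leo substituent constants for the substituents handled here
#: (sigma_para for para substituents, sigma_meta for 3-Cl). Editable config:
#: pass your own mapping where a different compilation is preferred.
HAMMETT_SIGMA: Mapping[str, float] = MappingProxyType(
    {
        "H": 0.00,
        "4-OMe": -0.27,
        "4-NO2": 0.78,
        "4-Cl": 0.23,
        "3-Cl": 0.37,
    }
)


@dataclass(frozen=True)
class FrontierEnergies:
    """HOMO and LUMO energies in a consistent (arbitrary) energy unit."""

    E_H: float
    E_L: float

    def __post_init__(self) -> None:
        if self.E_L <= self.E_H:
            warnings.warn(
                f"E_LUMO ({self.E_L}) <= E_HOMO ({self.E_H}): negative gap, "
                "derived hardness will be <= 0",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ReactivityDescriptors:
    gap: float
    chi: float
    mu: float
    eta: float
    S_soft: float
    omega: float
    sigma_abs: float


def descriptors(
    f: FrontierEnergies,
    softness_convention: Literal["half-hardness", "inverse"] = "half-hardness",
) -> ReactivityDescriptors:
    """Global reactivity descriptors from one (E_HOMO, E_LUMO) pair.

    ``softness_convention`` selects S = eta/2 (``"half-hardness"``, the
    convention of the tables reproduced here) or the common S = 1/(2 eta)
    (``"inverse"``).
    """
    gap = f.E_L - f.E_H
    chi = -(f.E_H + f.E_L) / 2.0
    mu = -chi
    eta = gap / 2.0
    if eta == 0:
        raise ZeroDivisionError("zero gap: omega and absolute softness undefined")
    if softness_convention == "half-hardness":
        S = eta / 2.0
    elif softness_convention == "inverse":
        S = 1.0 / (2.0 * eta)
    else:
        raise ValueError(f"unknown softness convention {softness_convention!r}")
    return ReactivityDescriptors(
        gap=gap,
        chi=chi,
        mu=mu,
        eta=eta,
        S_soft=S,
        omega=mu * mu / (2.0 * eta),
        sigma_abs=1.0 / eta,
    )


@dataclass(frozen=True)
class HammettPoint:
    """One substituent: its sigma constant and the measured response."""

    substituent_label: str
    sigma_const: float
    response: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma_const) and math.isfinite(self.response)):
            raise ValueError("sigma and response must be finite")


@dataclass(frozen=True)
class HammettFit:
    slope: float
    intercept: float
    pearson_r: float


def hammett_fit(points: Sequence[HammettPoint], log_response: bool = False) -> HammettFit:
    """OLS of the response (or its log10) on Hammett sigma constants.

    Returns the reaction constant rho (slope), the intercept, and Pearson r.
    Requires at least 3 points with non-zero sigma variance.
    """
    if len(points) < 3:
        raise ValueError(f"need at least 3 points, got {len(points)}")
    sigma = np.array([p.sigma_const for p in points], dtype=float)
    y = np.array([p.response for p in points], dtype=float)
    if np.ptp(sigma) == 0:
        raise ValueError("zero variance in sigma constants")
    if log_response:
        if np.any(y <= 0):
            raise ValueError("log fit requires strictly positive responses")
        y = np.log10(y)
    res = stats.linregress(sigma, y)
    return HammettFit(slope=res.slope, intercept=res.intercept, pearson_r=res.rvalue)
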