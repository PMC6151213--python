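"""Single-peak powder-XRD crystallite metrics.

Bragg d-spacing, Debye-Scherrer crystallite size, dislocation density and
strain from one diffraction peak (2-theta position and FWHM), plus FWHM
extraction from a sampled profile.

Unit modes
----------
The Scherrer equation S = K lambda / (beta cos theta) requires beta in
radians; with Cu K-alpha that gives sizes in Angstrom (hundreds of A for a
~0.25 deg peak). A second mode, ``"paper_degrees"``, feeds the raw FWHM
degree number into the formula without conversion. That convention appears in
parts of the characterization literature and is needed to reproduce such
published size/dislocation values; the two modes differ exactly by 180/pi.
The physically meaningful ``"radians"`` mode is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "CU_K_ALPHA",
    "SCHERRER_K",
    "DiffractionPeak",
    "CrystalliteMetrics",
    "bragg_d",
    "scherrer_size",
    "dislocation_density",
    "strain",
    "crystallite_metrics",
    "peak_metrics",
]

#: Cu K-alpha wavelength, Angstrom.
CU_K_ALPHA = 1.5406
#: Scherrer shape factor for roughly spherical crystallites.
SCHERRER_K = 0.94

Mode = Literal["radians", "paper_degrees"]


@dataclass(frozen=True)
class DiffractionPeak:
    """One powder-diffraction peak: position and width in degrees 2-theta."""

    two_theta: float
    fwhm: float
    intensity: float | None = None
    wavelength: float = CU_K_ALPHA

    def __post_init__(self) -> None:
        if not (0.0 < self.two_theta < 180.0):
            raise ValueError(f"two_theta={self.two_theta} outside (0, 180) degrees")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


@dataclass(frozen=True)
class CrystalliteMetrics:
    """Derived metrics; ``size`` units depend on the chosen unit mode."""

    d_spacing: float
    size: float
    dislocation_density: float
    strain: float
    mode: Mode


def bragg_d(two_theta: float, wavelength: float = CU_K_ALPHA) -> float:
    """Bragg d-spacing lambda / (2 sin theta) in Angstrom, first order."""
    if not (0.0 < two_theta < 180.0):
        raise ValueError(f"two_theta={two_theta} outside (0, 180) degrees")
    theta = math.radians(two_theta / 2.0)
    return wavelength / (2.0 * math.sin(theta))


def _beta(p: DiffractionPeak, mode: Mode) -> float:
    if mode == "radians":
        return math.radians(p.fwhm)
    if mode == "paper_degrees":
        return p.fwhm
    raise ValueError(f"unknown mode {mode!r}")


def scherrer_size(p: DiffractionPeak, K: float = SCHERRER_K, mode: Mode = "radians") -> float:
    """Debye-Scherrer crystallite size S = K lambda / (beta cos theta).

    Angstrom in ``"radians"`` mode; in ``"paper_degrees"`` mode the FWHM
    degree value is used unconverted (size comes out 180/pi times smaller).
    """
    theta = math.radians(p.two_theta / 2.0)
    return K * p.wavelength / (_beta(p, mode) * math.cos(theta))


def dislocation_density(size: float) -> float:
    """Dislocation density delta = 1 / S^2 (units: 1/size^2)."""
    if size <= 0:
        raise ValueError("size must be positive")
    return 1.0 / (size * size)


def strain(p: DiffractionPeak, size: float, mode: Mode = "radians") -> float:
    """Lattice strain from the single-peak rearrangement.

    epsilon = (lambda / (S cos theta) - beta) / tan theta

    Single-peak strain is poorly constrained (a Williamson-Hall fit over many
    peaks is the robust estimator); treat the value as indicative only.
    """
    theta = math.radians(p.two_theta / 2.0)
    if math.tan(theta) == 0:
        raise ValueError("theta must be non-zero")
    beta = _beta(p, mode)
    return (p.wavelength / (size * math.cos(theta)) - beta) / math.tan(theta)


def crystallite_metrics(p: DiffractionPeak, K: float = SCHERRER_K, mode: Mode = "radians") -> CrystalliteMetrics:
    """All single-peak metrics in one call."""
    size = scherrer_size(p, K=K, mode=mode)
    return CrystalliteMetrics(
        d_spacing=bragg_d(p.two_theta, p.wavelength),
        size=size,
        dislocation_density=dislocation_density(size),
        strain=strain(p, size, mode=mode),
        mode=mode,
    )


def peak_metrics(
    two_theta: np.ndarray,
    intensity: np.ndarray,
    wavelength: float = CU_K_ALPHA,
) -> DiffractionPeak:
    """Extract (center, FWHM) from a sampled single-peak profile.

    The baseline is the minimum of the first and last 5 % of samples; the
    center is the argmax refined by a 3-point parabola; the FWHM comes from
    linear interpolation of the two half-maximum crossings.
    """
    x = np.asarray(two_theta, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or x.size < 5:
        raise ValueError("need matching 1-d arrays with at least 5 samples")
    edge = max(1, int(0.05 * x.size))
    baseline = min(y[:edge].min(), y[-edge:].min())
    z = y - baseline
    imax = int(np.argmax(z))
    peak = z[imax]
    if peak <= 0:
        raise ValueError("flat profile: no peak above baseline")

    # parabolic refinement of the apex
    center = x[imax]
    if 0 < imax < x.size - 1:
        y0, y1, y2 = z[imax - 1], z[imax], z[imax + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            center = x[imax] + 0.5 * (y0 - y2) / denom * (x[imax + 1] - x[imax])

    half = peak / 2.0

    def cross(idx_range) -> float:
        prev = None
        for i in idx_range:
            if prev is not None:
                lo, hi = (z[prev], z[i])
                if (lo - half) * (hi - half) <= 0 and lo != hi:
                    frac = (half - lo) / (hi - lo)
                    return x[prev] + frac * (x[i] - x[prev])
            prev = i
        raise ValueError("no half-maximum crossing found")

    left = cross(range(imax, -1, -1))
    right = cross(range(imax, x.size))
    fwhm = abs(right - left)
    if fwhm <= 0:
        raise ValueError("degenerate half-maximum crossings")
    return DiffractionPeak(
        two_theta=center, fwhm=fwhm, intensity=float(y[imax]), wavelength=wavelength
    )
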