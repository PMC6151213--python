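"""Spin-Hamiltonian and bonding parameters of axial d1 vanadyl (VO2+) centers.

From the four axial tensor components (g_par, g_perp, A_par, A_perp) measured
on an 8-line VO(II) powder EPR spectrum, together with the two d-d band
energies E1 (2B1g -> 2Eg) and E2 (2B2g -> 2B1g), this module derives the full
bonding-parameter set: isotropic g_o and A_o, the exchange parameter G, the
tetragonal-distortion index f, the spin-orbit coupling constant lambda, the
dipolar hyperfine term p, the Fermi contact term k, the orbital reduction
factors 2K_par / 2K_perp, and the in-plane pi-covalency coefficient beta2.

Conventions
-----------
* Hyperfine magnitudes are stored positive in units of 1e-4 cm^-1; where the
  analysis takes A_par and A_perp as negative (k, beta2) the sign flip is
  applied inside the operation, so the returned values are the positive ones
  a spectroscopist tabulates.
* Two electron-g reference constants coexist in this analysis tradition:
  the free-electron value 2.0023 (used for G, lambda, k, beta2) and 2.00277
  (used only in the 2K expressions). Both are kept as named constants.
* ``f`` is reported on the effective scale 1e4 * g_par / A_par, i.e. g_par
  divided by A_par expressed in cm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "G_E",
    "G_REF_K",
    "MCGARVEY_P_GAUSS",
    "EsrTensors",
    "DdBands",
    "EsrDerived",
    "isotropic_g",
    "isotropic_A",
    "exchange_G",
    "distortion_f",
    "spin_orbit_lambda",
    "dipolar_p",
    "fermi_contact_k",
    "orbital_reduction",
    "beta_squared",
    "alpha_squared_literal",
    "derive_all",
]

#: Free-electron g value, used in G, lambda, k and beta2.
G_E = 2.0023
#: Electron-g reference entering only the orbital-reduction (2K) expressions.
G_REF_K = 2.00277
#: McGarvey's theoretical dipolar term for vanadyl complexes (documentation).
MCGARVEY_P_GAUSS = 136.0


@dataclass(frozen=True)
class EsrTensors:
    """Axial g- and A-tensor components; A in 1e-4 cm^-1, stored positive."""

    g_par: float
    g_perp: float
    A_par: float
    A_perp: float

    def __post_init__(self) -> None:
        for name, g in (("g_par", self.g_par), ("g_perp", self.g_perp)):
            if not (1.5 < g < 2.1):
                raise ValueError(f"{name}={g} outside the plausible range (1.5, 2.1)")
        if self.A_par < 0 or self.A_perp < 0:
            raise ValueError("hyperfine components are stored as positive magnitudes")


@dataclass(frozen=True)
class DdBands:
    """d-d band energies in cm^-1: E1 (2B1g->2Eg) < E2 (2B2g->2B1g)."""

    E1: float
    E2: float

    def __post_init__(self) -> None:
        if not (self.E2 > self.E1 > 0):
            raise ValueError(f"require E2 > E1 > 0, got E1={self.E1}, E2={self.E2}")


@dataclass(frozen=True)
class EsrDerived:
    """One derived bonding-parameter row (units as in the field's tables)."""

    g_o: float
    A_o: float
    G_exchange: float
    f_distortion: float
    lambda_so: float
    p_dipolar: float
    k_fermi: float
    K2_par: float
    K2_perp: float
    beta2: float
    #: literal evaluation of the published alpha^2 expression; numerically
    #: incoherent as printed and kept only for provenance (see docs/methods.md)
    alpha2_literal: float


def isotropic_g(t: EsrTensors) -> float:
    """g_o = (g_par + 2 g_perp) / 3."""
    return (t.g_par + 2.0 * t.g_perp) / 3.0


def isotropic_A(t: EsrTensors) -> float:
    """A_o = (A_par + 2 A_perp) / 3, in 1e-4 cm^-1."""
    return (t.A_par + 2.0 * t.A_perp) / 3.0


def exchange_G(t: EsrTensors) -> float:
    """Exchange parameter G = (g_par - g_e) / (g_perp - g_e).

    G < 4 flags non-negligible exchange coupling between metal centers.
    Axially symmetric g (g_par == g_perp) gives G = 1 identically.
    """
    if t.g_par == t.g_perp:
        return 1.0
    denom = t.g_perp - G_E
    if denom == 0.0:
        raise ZeroDivisionError("g_perp equals the free-electron value")
    return (t.g_par - G_E) / denom


def distortion_f(t: EsrTensors) -> float:
    """Tetragonal distortion index f = g_par / A_par with A_par in cm^-1.

    On tabulated hyperfine units (1e-4 cm^-1) this is 1e4 * g_par / A_par.
    """
    if t.A_par == 0:
        raise ZeroDivisionError("A_par must be non-zero")
    return 1.0e4 * t.g_par / t.A_par


def spin_orbit_lambda(g_par: float, E2: float) -> float:
    """Spin-orbit coupling constant lambda = (g_e - g_par) * E2 / 8, cm^-1.

    Derived from the parallel g-shift of the d_xy ground state,
    g_par = g_e - 8 lambda / E2. The free-ion value for V4+ is 250 cm^-1;
    the strong reduction in vanadyl complexes reflects V=O pi-bonding.
    """
    if E2 <= 0:
        raise ValueError("E2 must be positive")
    return (G_E - g_par) * E2 / 8.0


def dipolar_p(t: EsrTensors, lambda_so: float, E1: float) -> float:
    """Dipolar term p = 7 (A_par - A_perp) / (6 + 1.5 lambda / E1).

    Units follow the hyperfine inputs (1e-4 cm^-1). Both hyperfine
    components carry the same (negative) sign, so only their difference
    of magnitudes enters.
    """
    if E1 <= 0:
        raise ValueError("E1 must be positive")
    return 7.0 * (t.A_par - t.A_perp) / (6.0 + 1.5 * lambda_so / E1)


def fermi_contact_k(A_o: float, p: float, g_o: float) -> float:
    """Fermi contact term k = |A_o| / p - (g_e - g_o).

    With A_o taken negative (vanadyl sign convention) the published
    expression k = -(A_o/p) - (g_e - g_o) reduces to this positive form.
    """
    if p == 0:
        raise ZeroDivisionError("dipolar term p must be non-zero")
    return abs(A_o) / p - (G_E - g_o)


def orbital_reduction(
    g: float,
    E1: float,
    lambda_so: float,
    component: Literal["parallel", "perpendicular"],
) -> float:
    """Orbital reduction factor 2K for one tensor component.

    2K_par  = (g_par  - 2.00277) E1 / (8 lambda)
    2K_perp = (g_perp - 2.00277) E1 / (2 lambda)
    """
    if lambda_so == 0:
        raise ZeroDivisionError("lambda must be non-zero")
    if E1 <= 0:
        raise ValueError("E1 must be positive")
    if component == "parallel":
        return (g - G_REF_K) * E1 / (8.0 * lambda_so)
    if component == "perpendicular":
        return (g - G_REF_K) * E1 / (2.0 * lambda_so)
    raise ValueError(f"component must be 'parallel' or 'perpendicular', got {component!r}")


def beta_squared(t: EsrTensors, p: float) -> float:
    """In-plane pi-bonding coefficient beta^2 (1 = purely ionic).

    beta^2 = (7/6) [ (A_par - A_perp)/P + g_par - (5/14) g_perp - (9/14) g_e ]

    with P the computed dipolar term and both hyperfine components taken
    negative, which turns the published -A_par/P + A_perp/P into the
    magnitude difference used here.
    """
    if p == 0:
        raise ZeroDivisionError("dipolar term p must be non-zero")
    return (7.0 / 6.0) * (
        (t.A_par - t.A_perp) / p
        + t.g_par
        - (5.0 / 14.0) * t.g_perp
        - (9.0 / 14.0) * G_E
    )


def alpha_squared_literal(delta_g: float, beta2: float, lambda_so: float) -> float:
    """Literal evaluation of the published alpha^2 = (g_e - dg) / (8 beta^2 lambda).

    The expression is dimensionally incoherent as printed (it does not
    reproduce the tabulated alpha^2 values) and is provided only so the full
    published parameter chain can be audited. ``delta_g`` is
    (g_perp - g_par) * 1e-3 per the printed definition.
    """
    denom = 8.0 * beta2 * lambda_so
    if denom == 0:
        raise ZeroDivisionError("beta2 and lambda must be non-zero")
    return (G_E - delta_g) / denom


def derive_all(t: EsrTensors, bands: DdBands, lambda_so: float | None = None) -> EsrDerived:
    """Derive the complete bonding-parameter row for one complex.

    If ``lambda_so`` is None it is evaluated from this complex's own parallel
    g-shift and E2; pass a shared value to analyse a series of related
    complexes under a common spin-orbit constant.
    """
    lam = spin_orbit_lambda(t.g_par, bands.E2) if lambda_so is None else lambda_so
    g_o = isotropic_g(t)
    A_o = isotropic_A(t)
    if t.A_par != t.A_perp and not (
        min(t.A_par, t.A_perp) < A_o < max(t.A_par, t.A_perp)
    ):  # pragma: no cover - arithmetic guarantee
        raise AssertionError("A_o must lie between the tensor components")
    p = dipolar_p(t, lam, bands.E1)
    b2 = beta_squared(t, p) if p != 0 else math.nan
    return EsrDerived(
        g_o=g_o,
        A_o=A_o,
        G_exchange=exchange_G(t),
        f_distortion=distortion_f(t),
        lambda_so=lam,
        p_dipolar=p,
        k_fermi=fermi_contact_k(A_o, p, g_o) if p != 0 else math.nan,
        K2_par=orbital_reduction(t.g_par, bands.E1, lam, "parallel"),
        K2_perp=orbital_reduction(t.g_perp, bands.E1, lam, "perpendicular"),
        beta2=b2,
        alpha2_literal=(
            alpha_squared_literal((t.g_perp - t.g_par) * 1e-3, b2, lam)
            if p != 0 and b2 != 0
            else math.nan
        ),
    )
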