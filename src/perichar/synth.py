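"""Synthetic inputs with known ground truth for every analysis stage.

No raw instrument data accompany the tabulated results this package
re-derives, so each analyzer is exercised against generated data whose true
parameters are known exactly:

* 1:1 groove-binding UV-Vis titrations (fractional saturation
  f = K_b [DNA] / (1 + K_b [DNA]), eps_a = eps_f + (eps_b - eps_f) f — the
  unique 1:1 model under which the Wolfe-Shimer linearization is exact),
* single powder-diffraction peaks with known center/FWHM (Gaussian by
  default; Lorentzian behind a flag for robustness checks),
* random but valid compound sheets (formulas, vanadyl-range ESR tensors,
  bound frontier-energy pairs) for property-based testing.

Every generator takes an explicit :class:`GeneratorConfig`; identical seeds
reproduce identical outputs bit-for-bit. No global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .dna import TitrationSeries

__all__ = [
    "GeneratorConfig",
    "make_titration",
    "make_powder_peak",
    "make_compound_sheet",
]

NoiseModel = Literal["none", "additive_gaussian", "multiplicative_gaussian"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed and noise model shared by all generators.

    ``noise_scale`` is a fraction: the additive model uses a standard
    deviation of ``noise_scale`` times the clean signal's maximum magnitude;
    the multiplicative model perturbs each sample by ``1 + N(0, noise_scale)``.
    """

    seed: int = 0
    noise_model: NoiseModel = "none"
    noise_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.noise_model not in ("none", "additive_gaussian", "multiplicative_gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(clean: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    if cfg.noise_model == "none" or cfg.noise_scale == 0.0:
        return clean.copy()
    rng = cfg.rng()
    if cfg.noise_model == "additive_gaussian":
        sd = cfg.noise_scale * np.abs(clean).max()
        return clean + rng.normal(0.0, sd, size=clean.shape)
    return clean * (1.0 + rng.normal(0.0, cfg.noise_scale, size=clean.shape))


def make_titration(
    K_b: float,
    eps_f: float,
    eps_b: float,
    dna_grid: np.ndarray,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> TitrationSeries:
    """Generate a 1:1-isotherm titration series on the given [DNA] grid."""
    if K_b <= 0:
        raise ValueError("K_b must be positive")
    if eps_b == eps_f:
        raise ValueError("eps_b must differ from eps_f (degenerate generator)")
    dna = np.asarray(dna_grid, dtype=float)
    if dna.size == 0:
        raise ValueError("empty [DNA] grid")
    if np.any(dna < 0) or np.any(np.diff(dna) <= 0):
        raise ValueError("dna_grid must be non-negative and strictly increasing")
    frac = K_b * dna / (1.0 + K_b * dna)
    eps = eps_f + (eps_b - eps_f) * frac
    return TitrationSeries(dna_conc=dna, eps_app=_apply_noise(eps, cfg), eps_free=eps_f)


def make_powder_peak(
    center: float,
    fwhm: float,
    amplitude: float,
    grid_step: float,
    cfg: GeneratorConfig = GeneratorConfig(),
    span: float = 5.0,
    shape: Literal["gaussian", "lorentzian"] = "gaussian",
) -> pd.DataFrame:
    """Sample a single peak profile with exact center/FWHM.

    Returns a DataFrame with columns ``two_theta`` and ``intensity`` covering
    center +/- span*fwhm. ``span`` below 2 cannot contain the half-maximum
    crossings and raises.
    """
    if fwhm <= 0 or grid_step <= 0:
        raise ValueError("fwhm and grid_step must be positive")
    if span < 2.0:
        raise ValueError("grid too narrow: span must cover at least 2 x FWHM")
    half_width = span * fwhm
    x = np.arange(center - half_width, center + half_width + grid_step / 2, grid_step)
    if shape == "gaussian":
        sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        clean = amplitude * np.exp(-0.5 * ((x - center) / sd) ** 2)
    elif shape == "lorentzian":
        hwhm = fwhm / 2.0
        clean = amplitude * hwhm**2 / ((x - center) ** 2 + hwhm**2)
    else:
        raise ValueError(f"unknown peak shape {shape!r}")
    return pd.DataFrame({"two_theta": x, "intensity": _apply_noise(clean, cfg)})


#: element pools for random-but-plausible organic/coordination formulas
_HETERO = ("N", "O", "S", "Cl")


def make_compound_sheet(n: int, cfg: GeneratorConfig = GeneratorConfig()) -> pd.DataFrame:
    """Random valid inputs for every analysis stage (property-test fodder).

    Each row carries a parseable formula, axial vanadyl-range ESR tensors
    (1.9 < g < 2.0, A_par > A_perp), d-d band energies with E2 > E1, and a
    bound frontier pair (E_HOMO < E_LUMO).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = cfg.rng()
    rows = []
    for i in range(n):
        c = int(rng.integers(5, 40))
        h = int(rng.integers(4, 2 * c + 2))
        parts = [f"C{c}", f"H{h}"]
        for el in rng.choice(_HETERO, size=int(rng.integers(1, 4)), replace=False):
            parts.append(f"{el}{int(rng.integers(1, 6))}")
        g_perp = float(rng.uniform(1.95, 1.99))
        g_par = float(rng.uniform(1.90, g_perp))  # g_par < g_perp < g_e for d_xy
        A_perp = float(rng.uniform(55.0, 80.0))
        A_par = float(rng.uniform(A_perp + 60.0, A_perp + 110.0))
        E1 = float(rng.uniform(12000.0, 13500.0))
        E2 = float(rng.uniform(E1 + 1500.0, E1 + 3500.0))
        e_h = float(rng.uniform(-0.30, -0.15))
        e_l = float(rng.uniform(e_h + 0.005, -0.02))
        rows.append(
            {
                "compound_id": f"cmpd{i + 1}",
                "formula": "".join(parts),
                "g_par": g_par,
                "g_perp": g_perp,
                "A_par": A_par,
                "A_perp": A_perp,
                "E1_cm": E1,
                "E2_cm": E2,
                "E_HOMO": e_h,
                "E_LUMO": e_l,
            }
        )
    return pd.DataFrame(rows)
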