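"""Intrinsic DNA-binding constant from a synthetic UV-Vis titration.

Generates a 1:1-isotherm titration with 1 % multiplicative noise at a known
K_b and recovers it with the Wolfe-Shimer double-reciprocal fit.
"""

import numpy as np

from perichar import (
    GeneratorConfig,
    hypochromism_percent,
    make_titration,
    wolfe_shimer_fit,
)

K_TRUE = 6.10e4  # M^-1
cfg = GeneratorConfig(seed=7, noise_model="multiplicative_gaussian", noise_scale=0.01)
series = make_titration(
    K_b=K_TRUE,
    eps_f=20000.0,  # free-compound extinction coefficient, M^-1 cm^-1
    eps_b=12000.0,  # fully-bound extinction coefficient
    dna_grid=np.linspace(1e-5, 2.18e-4, 10),
    cfg=cfg,
)

fit = wolfe_shimer_fit(series)
print(f"true K_b      = {K_TRUE:.3g} M^-1")
print(f"fitted K_b    = {fit.K_b:.3g} M^-1  ({100 * (fit.K_b / K_TRUE - 1):+.1f} %)")
print(f"eps_bound     = {fit.eps_bound:.0f} M^-1 cm^-1 (true 12000)")
print(f"r^2           = {fit.r_squared:.5f}")
print(f"hypochromism  = {hypochromism_percent(series):.1f} %")

# K_b around 1e4-1e5 M^-1 with a hypochromic band shift is the classic
# signature of groove binding; the double-reciprocal fit recovers the
# generator's constant to within a few percent at this noise level.
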