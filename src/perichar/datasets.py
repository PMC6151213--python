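"""Bundled reference dataset: the published VO(II)-perimidine study tables.

This module ships, as plain Python data, the measured inputs of the
characterization study this package re-derives — molecular formulas, TGA
decomposition schemes, axial ESR tensors with d-d band energies, frontier
orbital energies, the five reported DNA-binding constants, and the one
crystalline ligand's diffraction-peak parameters — together with the values
the study reports for the derived quantities (``reported_*`` accessors, used
by the golden-comparison tests and by :func:`perichar.pipeline.compare_to_golden`).

Ligand labels follow the analytical table's canonical mapping
(L1 = H, L2 = 4-OMe, L3 = 4-NO2, L4 = 4-Cl, L5 = 3-Cl); the synthesis
section's L3/L4 swap is documented in docs/methods.md.
"""

from __future__ import annotations

import pandas as pd

from .xrd import DiffractionPeak

__all__ = [
    "compounds",
    "tga_schemes",
    "esr_tensor_table",
    "frontier_energy_table",
    "binding_constants",
    "substituent_of_ligand",
    "xrd_peak",
    "reported_elemental_analysis",
    "reported_tga",
    "reported_spin_hamiltonian",
    "reported_reactivity",
    "reported_xrd",
]

# --- inputs -------------------------------------------------------------------

_COMPOUNDS = [
    # id, label, formula, substituent key (ligand series)
    ("1", "L1", "C25H18N4O", "H"),
    ("2", "L1+VO", "[(VO)2(SO4)2(C25H18N4O)]H2O", "H"),
    ("3", "L2", "C26H20N4O2", "4-OMe"),
    ("4", "L2+VO", "[(VO)2(SO4)2(C26H20N4O2)]2H2O", "4-OMe"),
    ("5", "L3", "C25H17N5O3", "4-NO2"),
    ("6", "L3+VO", "[(VO)2(SO4)2(C25H17N5O3)]H2O", "4-NO2"),
    ("7", "L4", "C25H17N4OCl", "4-Cl"),
    ("8", "L4+VO", "[(VO)2(SO4)2(C25H17N4OCl)]H2O", "4-Cl"),
    ("9", "L5", "C25H17N4OCl", "3-Cl"),
    ("10", "L5+VO", "[(VO)2(SO4)2(C25H17N4OCl)]3H2O", "3-Cl"),
]


def compounds() -> pd.DataFrame:
    """The ten study compounds: five ligands and their binuclear VO(II) complexes."""
    return pd.DataFrame(_COMPOUNDS, columns=["id", "label", "formula", "substituent"])


#: TGA decomposition schemes: per compound label, the fragment formulas lost in
#: each stage and the residue formula (None when the stages consume everything).
_TGA: dict[str, dict] = {
    "L1": {
        "stages": [["C6H6", "N2"], ["C6H5", "CO"], ["C8H7N2"]],
        "residue": "C4",
    },
    "L1+VO": {
        "stages": [["H2O", "SO4"], ["SO4", "C6H6", "N2"], ["C19H12N2"]],
        "residue": "V2O3",
    },
    "L2": {
        "stages": [["C6H5OCH3"], ["C6H5", "CO", "N2"], ["C9H7N2"]],
        "residue": "C3",
    },
    "L2+VO": {
        "stages": [["2H2O", "2SO4"], ["C6H5OCH3", "N2"], ["C6H5"], ["C13H7N2"]],
        "residue": "V2O3",
    },
    "L3": {
        "stages": [["C6H6", "NO2"], ["C7H5", "CO", "N2"], ["C11H6N2"]],
        "residue": None,
    },
    "L3+VO": {
        "stages": [["H2O", "SO4"], ["SO4", "C6H5", "CO"], ["NO2", "C6H6", "N2"], ["C12H6N2"]],
        "residue": "V2O2",
    },
    "L4": {
        "stages": [["C6H5Cl", "CO", "N2"], ["C6H5", "N2"], ["C12H7"]],
        "residue": None,
    },
    "L4+VO": {
        "stages": [["H2O", "C6H5Cl", "SO4"], ["SO4", "CON2", "C6H5"], ["C10H7N2"]],
        "residue": "V2O2C2",
    },
    "L5": {
        "stages": [["C6H5", "N2"], ["C6H5Cl", "CO", "N2"], ["C9H7"]],
        "residue": "C3",
    },
    "L5+VO": {
        "stages": [["3H2O", "C6H5Cl"], ["2SO4", "CON2", "C6H5"], ["C8H7N2"]],
        "residue": "V2O2C4",
    },
}


def tga_schemes() -> dict[str, dict]:
    """Stage fragment formulas and residue formula per compound label."""
    return {k: {"stages": [list(s) for s in v["stages"]], "residue": v["residue"]} for k, v in _TGA.items()}


def esr_tensor_table() -> pd.DataFrame:
    """Axial tensors and d-d band energies of the five VO(II) complexes.

    E1/E2 (cm^-1) are each complex's own d-d bands, paired with the
    spin-Hamiltonian rows in ligand order.
    """
    rows = [
        ("L1+VO", 1.93, 1.96, 167.0, 66.0, 12800.0, 15290.0),
        ("L2+VO", 1.94, 1.97, 170.0, 71.0, 12750.0, 15393.0),
        ("L3+VO", 1.92, 1.96, 168.0, 69.0, 12830.0, 15873.0),
        ("L4+VO", 1.94, 1.98, 171.0, 73.0, 12800.0, 15385.0),
        ("L5+VO", 1.93, 1.97, 171.0, 72.0, 12780.0, 15873.0),
    ]
    return pd.DataFrame(
        rows, columns=["complex_id", "g_par", "g_perp", "A_par", "A_perp", "E1_cm", "E2_cm"]
    )


def frontier_energy_table() -> pd.DataFrame:
    """Frontier-orbital energies (as tabulated) for all ten compounds.

    The two VO(II) rows with identical energies (L1+VO and L4+VO) are
    reproduced exactly as published.
    """
    rows = [
        ("L1", -0.17417, -0.07574),
        ("L1+VO", -0.20433, -0.19545),
        ("L2", -0.17142, -0.07426),
        ("L2+VO", -0.20163, -0.19237),
        ("L3", -0.21252, -0.05654),
        ("L3+VO", -0.21881, -0.21008),
        ("L4", -0.25291, -0.05654),
        ("L4+VO", -0.20433, -0.19545),
        ("L5", -0.17808, -0.08420),
        ("L5+VO", -0.19719, -0.16607),
    ]
    return pd.DataFrame(rows, columns=["compound_id", "E_HOMO", "E_LUMO"])


def binding_constants() -> dict[str, float]:
    """Reported intrinsic DNA-binding constants K_b (M^-1) per ligand."""
    return {"L1": 6.10e4, "L2": 6.07e4, "L3": 6.75e4, "L4": 7.99e4, "L5": 8.80e4}


def substituent_of_ligand() -> dict[str, str]:
    """Ligand label -> substituent key into the Hammett sigma table."""
    return {"L1": "H", "L2": "4-OMe", "L3": "4-NO2", "L4": "4-Cl", "L5": "3-Cl"}


def xrd_peak() -> DiffractionPeak:
    """High-intensity diffraction peak of the one crystalline ligand (L1)."""
    return DiffractionPeak(two_theta=21.18, fwhm=0.2454, intensity=857.0)


# --- reported derived values (golden references for tests/diff reports) -------


def reported_elemental_analysis() -> pd.DataFrame:
    """Published formula weights and calcd percentages (elemental analysis).

    ``so4_or_cl`` is the SO4 percentage for complexes and the Cl percentage
    for the chloro ligands; chloro complexes additionally report ``cl``.
    """
    rows = [
        # label, FW, C, H, N, so4_or_cl, cl, V
        ("L1", 390.44, 76.91, 4.65, 14.35, None, None, None),
        ("L1+VO", 734.46, 40.88, 2.74, 7.63, 26.16, None, 13.87),
        ("L2", 420.47, 74.27, 4.79, 13.32, None, None, None),
        ("L2+VO", 782.51, 39.91, 3.09, 7.16, 24.55, None, 13.02),
        ("L3", 435.44, 68.96, 3.93, 16.08, None, None, None),
        ("L3+VO", 779.46, 38.52, 2.46, 8.99, 24.65, None, 13.07),
        ("L4", 424.88, 70.67, 4.03, 13.19, 8.34, None, None),
        ("L4+VO", 768.90, 39.05, 2.49, 7.29, 24.99, 4.61, 13.25),
        ("L5", 424.88, 70.67, 4.03, 13.19, 8.34, None, None),
        ("L5+VO", 804.93, 37.30, 2.88, 6.96, 23.87, 4.40, 12.66),
    ]
    return pd.DataFrame(
        rows, columns=["label", "fw", "C", "H", "N", "so4_or_cl", "cl", "V"]
    )


def reported_tga() -> dict[str, dict]:
    """Published calcd (and found) stage losses and residues, percent."""
    return {
        "L1": {"stages": [27.18, 26.92, 33.59], "residue": 12.31},
        "L1+VO": {"stages": [15.53, 27.53, 36.53], "residue": 20.41},
        "L2": {"stages": [25.72, 31.66, 34.05], "residue": 8.57},
        "L2+VO": {"stages": [29.16, 17.40, 9.85, 24.43], "residue": 19.15},
        "L3": {"stages": [28.50, 33.33, 38.16], "residue": None},
        "L3+VO": {"stages": [14.63, 25.81, 19.52, 22.86], "residue": 17.18},
        "L4": {"stages": [39.68, 24.74, 35.58], "residue": None},
        "L4+VO": {"stages": [29.48, 29.80, 20.18], "residue": 20.54},
        "L5": {"stages": [24.74, 39.68, 27.10], "residue": 8.48},
        "L5+VO": {"stages": [20.70, 40.41, 16.29], "residue": 22.60},
    }


def reported_spin_hamiltonian() -> pd.DataFrame:
    """Published derived spin-Hamiltonian columns for the five complexes.

    Three cells are internally inconsistent with the study's own formulas
    (see docs/methods.md): the L3+VO A_o (105.67; the formula gives 102.00,
    the printed value duplicates the L4+VO cell), the L3+VO k that follows
    from it, and the L4+VO p (114.00 vs the formula's 114.03).
    """
    rows = [
        ("L1+VO", 1.95, 115.57, 99.67, 1.71, 117.52, 0.796, -0.843, -1.981, 1.959, 0.9357),
        ("L2+VO", 1.96, 114.12, 104.00, 1.93, 115.19, 0.861, -0.724, -1.512, 1.490, 0.9435),
        ("L3+VO", 1.95, 114.28, 105.67, 1.95, 115.19, 0.865, -0.961, -1.985, 1.964, 0.9243),
        ("L4+VO", 1.97, 113.45, 105.67, 2.79, 114.00, 0.895, -0.727, -1.055, 1.033, 0.9395),
        ("L5+VO", 1.96, 112.86, 105.00, 2.24, 115.19, 0.869, -0.841, -1.515, 1.494, 0.9318),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "complex_id", "g_o", "f", "A_o", "G", "p", "k",
            "K2_par", "K2_perp", "alpha2", "beta2",
        ],
    )


def reported_reactivity() -> pd.DataFrame:
    """Published derived reactivity columns (as printed, full precision)."""
    rows = [
        ("L1", -0.0984, 0.09843, 0.124955, -0.12496, 0.049215, 0.024608, 0.158628, 20.31900843),
        ("L1+VO", -0.0089, 0.00888, 0.19989, -0.19989, 0.00444, 0.00222, 4.499551, 225.2252252),
        ("L2", -0.0972, 0.09716, 0.12284, -0.12284, 0.04858, 0.02429, 0.155307, 20.58460272),
        ("L2+VO", -0.0093, 0.00926, 0.197, -0.197, 0.00463, 0.002315, 4.191037, 215.9827214),
        ("L3", -0.156, 0.15598, 0.13453, -0.13453, 0.07799, 0.038995, 0.11603, 12.82215669),
        ("L3+VO", -0.0087, 0.00873, 0.214445, -0.21445, 0.004365, 0.002183, 5.267658, 229.0950745),
        ("L4", -0.1964, 0.19637, 0.154725, -0.15473, 0.098185, 0.049093, 0.121912, 10.18485512),
        ("L4+VO", -0.0089, 0.00888, 0.19989, -0.19989, 0.00444, 0.00222, 4.499551, 225.2252252),
        ("L5", -0.0939, 0.09388, 0.13114, -0.13114, 0.04694, 0.02347, 0.183188, 21.30379207),
        ("L5+VO", -0.0311, 0.03112, 0.18163, -0.18163, 0.01556, 0.00778, 1.060073, 64.26735219),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id", "neg_gap", "gap", "chi", "mu", "eta", "S", "omega", "sigma_abs",
        ],
    )


def reported_xrd() -> dict[str, float]:
    """Published single-peak metrics for the crystalline ligand."""
    return {"d_spacing": 4.1910, "size": 6.003, "dislocation_density": 0.0277}
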