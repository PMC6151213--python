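"""Average atomic masses for formula-weight arithmetic.

The table ships IUPAC conventional (abridged) atomic weights — the values a
microanalysis lab uses for calcd percentages — for the elements that occur in
coordination-compound elemental analysis. It is deliberately small: formula
parsing resolves element symbols against the active table, so a restricted
table keeps strings such as ``CON2`` (carbon + oxygen + dinitrogen, a common
TGA fragment shorthand) from being misread as cobalt compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

#: IUPAC 2021 conventional atomic weights, g/mol.
CONVENTIONAL_WEIGHTS: Mapping[str, float] = MappingProxyType(
    {
        "H": 1.008,
        "B": 10.81,
        "C": 12.011,
        "N": 14.007,
        "O": 15.999,
        "F": 18.998,
        "Na": 22.990,
        "Mg": 24.305,
        "P": 30.974,
        "S": 32.06,
        "Cl": 35.45,
        "K": 39.098,
        "Ca": 40.078,
        "V": 50.9415,
        "Cr": 51.996,
        "Mn": 54.938,
        "Fe": 55.845,
        "Ni": 58.693,
        "Cu": 63.546,
        "Zn": 65.38,
        "Br": 79.904,
        "I": 126.904,
    }
)


class MissingElementError(KeyError):
    """An element has no atomic weight in the active table."""


@dataclass(frozen=True)
class ElementTable:
    """Element symbol -> average atomic mass (g/mol).

    Parameters
    ----------
    atomic_weight
        Mapping of element symbols to positive average atomic masses.
        Defaults to the built-in conventional-weight table.
    """

    atomic_weight: Mapping[str, float] = field(
        default_factory=lambda: CONVENTIONAL_WEIGHTS
    )

    def __post_init__(self) -> None:
        for sym, w in self.atomic_weight.items():
            if not w > 0:
                raise ValueError(f"non-positive atomic weight for {sym!r}: {w}")

    def weight(self, symbol: str) -> float:
        try:
            return self.atomic_weight[symbol]
        except KeyError:
            raise MissingElementError(
                f"no atomic weight for element {symbol!r}"
            ) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.atomic_weight


#: Default table used throughout the package.
DEFAULT_TABLE = ElementTable()
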