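"""Molecular formulas, formula weights, and calcd mass percentages.

Covers the mass bookkeeping behind an elemental-analysis table and a
thermogravimetric (TGA) decomposition scheme: parsing coordination-sphere
formulas such as ``[(VO)2(SO4)2(C25H18N4O)]H2O``, formula weights, calcd
elemental and group percentages, and stage-wise mass-loss percentages with a
running-remainder containment check.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .elements import DEFAULT_TABLE, ElementTable

__all__ = [
    "ChemicalFormula",
    "FormulaParseError",
    "ContainmentError",
    "MassLossStage",
    "parse_formula",
    "formula_weight",
    "elemental_percent",
    "group_percent",
    "mass_loss_percent",
    "residue_percent",
]


class FormulaParseError(ValueError):
    """Raised when a formula string cannot be parsed."""


class ContainmentError(ValueError):
    """Raised when fragments are not contained in their parent composition."""


@dataclass(frozen=True)
class ChemicalFormula:
    """Element -> count composition plus the text it was parsed from."""

    composition: Mapping[str, int]
    source_text: str = ""

    def __post_init__(self) -> None:
        for el, n in self.composition.items():
            if not (isinstance(n, int) and n >= 1):
                raise ValueError(f"count for {el!r} must be a positive integer, got {n}")
        object.__setattr__(self, "composition", dict(self.composition))

    def to_text(self) -> str:
        """Serialize in Hill order (C, H, then alphabetical)."""
        comp = dict(self.composition)
        order: list[str] = []
        for lead in ("C", "H"):
            if lead in comp:
                order.append(lead)
        order.extend(sorted(el for el in comp if el not in ("C", "H")))
        return "".join(f"{el}{comp[el] if comp[el] != 1 else ''}" for el in order)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        return ChemicalFormula(_merge(self.composition, other.composition))

    def __contains__(self, element: str) -> bool:
        return element in self.composition


def _merge(*comps: Mapping[str, int]) -> dict[str, int]:
    out: dict[str, int] = {}
    for comp in comps:
        for el, n in comp.items():
            out[el] = out.get(el, 0) + n
    return out


# --- parsing -----------------------------------------------------------------

_TOKEN = re.compile(r"\s+|\d+|[A-Z][a-z]?|[()\[\]]|[·.*]")


class _Parser:
    """Recursive-descent parser for bracketed / hydrated formulas.

    Grammar (counts default to 1)::

        formula  := unit+ hydrate?
        unit     := element count? | '(' unit+ ')' count? | '[' unit+ ']' count?
        hydrate  := SEP? count? 'H2O'      (SEP one of '·', '.', '*')

    Element symbols are resolved greedily against the element table with a
    one-letter fallback, so ``CON2`` reads as C+O+N2 when Co is not tabulated.
    """

    def __init__(self, text: str, table: ElementTable):
        self.text = text
        self.table = table
        self.pos = 0

    def error(self, msg: str) -> FormulaParseError:
        return FormulaParseError(f"{msg} at position {self.pos} in {self.text!r}")

    def peek(self) -> str | None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1
        if self.pos >= len(self.text):
            return None
        m = _TOKEN.match(self.text, self.pos)
        if m is None:
            raise self.error(f"unexpected character {self.text[self.pos]!r}")
        return m.group()

    def take(self) -> str:
        tok = self.peek()
        assert tok is not None
        self.pos += len(tok)
        return tok

    def count(self) -> int:
        tok = self.peek()
        if tok is not None and tok.isdigit():
            self.take()
            return int(tok)
        return 1

    def element(self, tok: str) -> str:
        if tok in self.table:
            self.pos += len(tok)
            return tok
        if len(tok) == 2 and tok[0] in self.table:
            # greedy two-letter symbol not tabulated; back off to one letter
            self.pos += 1
            return tok[0]
        raise self.error(f"unknown element symbol {tok!r}")

    def units(self, closer: str | None) -> dict[str, int]:
        comp: dict[str, int] = {}
        while True:
            tok = self.peek()
            if tok is None:
                if closer is not None:
                    raise self.error(f"unbalanced brackets: expected {closer!r}")
                return comp
            if tok == closer:
                self.take()
                return comp
            if tok == "(":
                self.take()
                inner = self.units(")")
                n = self.count()  # trailing multiplier, e.g. (SO4)2
                comp = _merge(comp, {el: c * n for el, c in inner.items()})
            elif tok == "[":
                # coordination shell; a digit after ']' is a hydrate count,
                # never a shell multiplier
                self.take()
                comp = _merge(comp, self.units("]"))
            elif tok in ")]":
                raise self.error(f"unbalanced brackets: stray {tok!r}")
            elif tok in "·.*":
                if closer is not None:
                    raise self.error("hydrate separator inside brackets")
                self.take()
            elif tok.isdigit():
                # leading count, e.g. '3H2O' after a shell or '·2H2O':
                # multiplies everything to the end of this bracket level
                self.take()
                n = int(tok)
                rest = self.units(closer)
                return _merge(comp, {el: c * n for el, c in rest.items()})
            elif tok[0].isalpha():
                el = self.element(tok)
                comp = _merge(comp, {el: self.count()})
            else:
                raise self.error(f"unexpected token {tok!r}")


def parse_formula(text: str, table: ElementTable = DEFAULT_TABLE) -> ChemicalFormula:
    """Parse a molecular formula string into a :class:`ChemicalFormula`.

    Accepts plain Hill-style formulas (``C25H18N4O``), parenthesized groups
    with multipliers, a square-bracket coordination shell, and a trailing
    hydrate term written either directly (``...]H2O``, ``...]3H2O``) or after
    a ``·`` separator.
    """
    parser = _Parser(text, table)
    comp = parser.units(None)
    if not comp:
        raise FormulaParseError(f"empty formula {text!r}")
    return ChemicalFormula(comp, source_text=text)


# --- mass arithmetic ---------------------------------------------------------


def formula_weight(f: ChemicalFormula, table: ElementTable = DEFAULT_TABLE) -> float:
    """Formula weight in g/mol (0 for an empty composition)."""
    return sum(n * table.weight(el) for el, n in f.composition.items())


def elemental_percent(
    f: ChemicalFormula, element: str, table: ElementTable = DEFAULT_TABLE
) -> float:
    """Calcd mass percent of *element* in *f*; 0 when the element is absent."""
    if not f.composition:
        raise ValueError("elemental percent of an empty formula is undefined")
    n = f.composition.get(element, 0)
    if n == 0:
        return 0.0
    return 100.0 * n * table.weight(element) / formula_weight(f, table)


def _contains(parent: Mapping[str, int], part: Mapping[str, int]) -> bool:
    return all(parent.get(el, 0) >= n for el, n in part.items())


def group_percent(
    f: ChemicalFormula,
    group: ChemicalFormula,
    n_groups: int = 1,
    table: ElementTable = DEFAULT_TABLE,
) -> float:
    """Calcd mass percent of ``n_groups`` copies of *group* (e.g. SO4, Cl)."""
    if n_groups < 0:
        raise ValueError("n_groups must be >= 0")
    if n_groups == 0:
        return 0.0
    scaled = {el: n * n_groups for el, n in group.composition.items()}
    if not _contains(f.composition, scaled):
        raise ContainmentError(
            f"{n_groups} x {group.to_text()} not contained in {f.to_text()}"
        )
    return 100.0 * n_groups * formula_weight(group, table) / formula_weight(f, table)


@dataclass(frozen=True)
class MassLossStage:
    """One TGA decomposition step: the fragments lost in that step."""

    fragments: Sequence[ChemicalFormula]
    temp_range: tuple[float, float] | None = None
    found_percent: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.fragments) == 0:
            raise ValueError("a decomposition stage must lose at least one fragment")
        object.__setattr__(self, "fragments", tuple(self.fragments))

    def composition(self) -> dict[str, int]:
        return _merge(*(f.composition for f in self.fragments))


def mass_loss_percent(
    parent: ChemicalFormula,
    stage: MassLossStage | Sequence[ChemicalFormula],
    table: ElementTable = DEFAULT_TABLE,
) -> float:
    """Calcd weight-loss percent of one TGA stage relative to *parent*.

    An empty fragment list is allowed here (0 % loss); stage containment
    across successive stages is checked by :func:`residue_percent`.
    """
    frags = stage.fragments if isinstance(stage, MassLossStage) else tuple(stage)
    pw = formula_weight(parent, table)
    if pw <= 0:
        raise ValueError("parent formula weight must be positive")
    return 100.0 * sum(formula_weight(f, table) for f in frags) / pw


def residue_percent(
    parent: ChemicalFormula,
    stages: Iterable[MassLossStage],
    table: ElementTable = DEFAULT_TABLE,
    strict: bool = False,
) -> float:
    """Calcd residue percent after all *stages*: 100 minus the summed losses.

    Containment of each stage in the running remainder is verified
    cumulatively. Published decomposition schemes occasionally over- or
    under-shoot by a few atoms, so violations warn by default and raise only
    with ``strict=True``. A negative residue always raises.
    """
    remainder = dict(parent.composition)
    total_loss = 0.0
    for i, stage in enumerate(stages, 1):
        comp = stage.composition()
        if not _contains(remainder, comp):
            over = {
                el: n - remainder.get(el, 0)
                for el, n in comp.items()
                if n > remainder.get(el, 0)
            }
            msg = f"stage {i} fragments exceed the running remainder by {over}"
            if strict:
                raise ContainmentError(msg)
            warnings.warn(msg, stacklevel=2)
        for el, n in comp.items():
            remainder[el] = remainder.get(el, 0) - n
        total_loss += mass_loss_percent(parent, stage, table)
    residue = 100.0 - total_loss
    if residue < -1e-9:
        raise ContainmentError(
            f"stages overdraw the parent mass: residue {residue:.3f} %"
        )
    return residue
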