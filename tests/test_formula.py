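"""Formula parsing and mass-budget arithmetic."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from perichar import (
    ChemicalFormula,
    ElementTable,
    MassLossStage,
    elemental_percent,
    formula_weight,
    group_percent,
    mass_loss_percent,
    parse_formula,
    residue_percent,
)
from perichar.elements import CONVENTIONAL_WEIGHTS, MissingElementError
from perichar.formula import ContainmentError, FormulaParseError

SO4 = parse_formula("SO4")


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C25H18N4O", {"C": 25, "H": 18, "N": 4, "O": 1}),
        ("H2O", {"H": 2, "O": 1}),
        # bracketed complex equals the element-wise sum of its parts:
        # O = 2 (VO) + 8 (2 SO4) + 1 (ligand) + 1 (hydrate) = 12
        (
            "[(VO)2(SO4)2(C25H18N4O)]H2O",
            {"V": 2, "O": 12, "S": 2, "C": 25, "H": 20, "N": 4},
        ),
        # hydrate count after the shell multiplies only the water term
        (
            "[(VO)2(SO4)2(C25H17N4OCl)]3H2O",
            {"V": 2, "O": 14, "S": 2, "C": 25, "H": 23, "N": 4, "Cl": 1},
        ),
        ("CuSO4·5H2O", {"Cu": 1, "S": 1, "O": 9, "H": 10}),
        # TGA fragment shorthand: no cobalt in the default table
        ("CON2", {"C": 1, "O": 1, "N": 2}),
        ("2SO4", {"S": 2, "O": 8}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).composition == expected


def test_bracketed_composition_is_sum_of_parts():
    parts = ["VO", "VO", "SO4", "SO4", "C25H18N4O", "H2O"]
    total = {}
    for p in parts:
        for el, n in parse_formula(p).composition.items():
            total[el] = total.get(el, 0) + n
    assert parse_formula("[(VO)2(SO4)2(C25H18N4O)]H2O").composition == total


@pytest.mark.parametrize(
    "bad",
    ["", "Xx2O", "[(VO)2", "C25)H18", "(SO4]2"],
)
def test_parse_errors(bad):
    with pytest.raises(FormulaParseError):
        parse_formula(bad)


def test_parse_error_names_the_token():
    with pytest.raises(FormulaParseError, match="Xx"):
        parse_formula("Xx2O")


@pytest.mark.parametrize(
    "text,fw,tol",
    [
        ("C25H18N4O", 390.44, 0.01),
        ("[(VO)2(SO4)2(C25H18N4O)]H2O", 734.46, 0.05),
        ("[(VO)2(SO4)2(C25H17N4OCl)]3H2O", 804.93, 0.05),
    ],
)
def test_formula_weight(text, fw, tol):
    assert formula_weight(parse_formula(text)) == pytest.approx(fw, abs=tol)


def test_formula_weight_empty_and_missing_element():
    assert formula_weight(ChemicalFormula({})) == 0.0
    small = ElementTable({"H": 1.008})
    with pytest.raises(MissingElementError):
        formula_weight(parse_formula("H2O"), small)


@pytest.mark.parametrize(
    "text,element,expected,tol",
    [
        ("C25H18N4O", "C", 76.91, 0.02),
        ("C25H18N4O", "V", 0.0, 0.0),
        ("[(VO)2(SO4)2(C25H18N4O)]H2O", "V", 13.87, 0.02),
    ],
)
def test_elemental_percent(text, element, expected, tol):
    assert elemental_percent(parse_formula(text), element) == pytest.approx(
        expected, abs=max(tol, 1e-12)
    )


def test_elemental_percent_empty_raises():
    with pytest.raises(ValueError):
        elemental_percent(ChemicalFormula({}), "C")


def test_group_percent():
    complex1 = parse_formula("[(VO)2(SO4)2(C25H18N4O)]H2O")
    assert group_percent(complex1, SO4, 2) == pytest.approx(26.16, abs=0.02)
    assert group_percent(complex1, SO4, 0) == 0.0
    chloro = parse_formula("[(VO)2(SO4)2(C25H17N4OCl)]H2O")
    assert group_percent(chloro, parse_formula("Cl"), 1) == pytest.approx(4.61, abs=0.03)
    with pytest.raises(ContainmentError):
        group_percent(complex1, SO4, 3)


def test_mass_loss_percent():
    l1 = parse_formula("C25H18N4O")
    stage = MassLossStage([parse_formula("C6H6"), parse_formula("N2")])
    assert mass_loss_percent(l1, stage) == pytest.approx(27.18, abs=0.05)
    assert mass_loss_percent(l1, []) == 0.0
    complex1 = parse_formula("[(VO)2(SO4)2(C25H18N4O)]H2O")
    st2 = MassLossStage([parse_formula("H2O"), parse_formula("SO4")])
    assert mass_loss_percent(complex1, st2) == pytest.approx(15.53, abs=0.05)


def test_mass_loss_is_additive():
    parent = parse_formula("[(VO)2(SO4)2(C25H18N4O)]H2O")
    a, b = parse_formula("H2O"), parse_formula("SO4")
    both = mass_loss_percent(parent, MassLossStage([a, b]))
    assert both == pytest.approx(
        mass_loss_percent(parent, MassLossStage([a]))
        + mass_loss_percent(parent, MassLossStage([b]))
    )


def test_residue_percent_matches_residue_formula():
    parent = parse_formula("[(VO)2(SO4)2(C25H18N4O)]H2O")
    stages = [
        MassLossStage([parse_formula(t) for t in frags])
        for frags in (["H2O", "SO4"], ["SO4", "C6H6", "N2"], ["C19H12N2"])
    ]
    res = residue_percent(parent, stages)
    assert res == pytest.approx(20.41, abs=0.1)
    assert res == pytest.approx(group_percent(parent, parse_formula("V2O3")), abs=0.01)


def test_residue_zero_when_everything_lost():
    parent = parse_formula("C2H4")
    stages = [MassLossStage([parse_formula("C2H4")])]
    assert residue_percent(parent, stages) == pytest.approx(0.0, abs=1e-12)


def test_residue_overdraw_warns_then_errors():
    parent = parse_formula("CH4")
    over = [MassLossStage([parse_formula("C2H4")])]
    with pytest.warns(UserWarning, match="exceed"):
        with pytest.raises(ContainmentError, match="overdraw"):
            residue_percent(parent, over)
    with pytest.raises(ContainmentError):
        residue_percent(parent, over, strict=True)


# --- properties ---------------------------------------------------------------

composition_st = st.dictionaries(
    st.sampled_from(sorted(CONVENTIONAL_WEIGHTS)),
    st.integers(min_value=1, max_value=60),
    min_size=1,
    max_size=6,
)


@given(composition_st)
def test_elemental_percents_sum_to_100(comp):
    f = ChemicalFormula(comp)
    total = sum(elemental_percent(f, el) for el in comp)
    assert total == pytest.approx(100.0, abs=1e-9)


@given(composition_st)
def test_parse_serialize_roundtrip(comp):
    f = ChemicalFormula(comp)
    assert parse_formula(f.to_text()).composition == comp
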