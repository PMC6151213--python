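"""Spin-Hamiltonian / bonding-parameter derivations for axial vanadyl centers."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from perichar import (
    DdBands,
    EsrTensors,
    beta_squared,
    derive_all,
    dipolar_p,
    distortion_f,
    exchange_G,
    fermi_contact_k,
    isotropic_A,
    isotropic_g,
    orbital_reduction,
    spin_orbit_lambda,
)
from perichar.esr import G_E, alpha_squared_literal

ROW1 = EsrTensors(1.93, 1.96, 167.0, 66.0)
ROW4 = EsrTensors(1.94, 1.98, 171.0, 73.0)
LAM = spin_orbit_lambda(1.93, 15290.0)


def test_tensor_validation():
    with pytest.raises(ValueError):
        EsrTensors(1.4, 1.96, 167.0, 66.0)
    with pytest.raises(ValueError):
        EsrTensors(1.93, 1.96, -167.0, 66.0)
    with pytest.raises(ValueError):
        DdBands(15290.0, 12800.0)  # E2 must exceed E1


@pytest.mark.parametrize(
    "t,expected",
    [(ROW1, 1.95), (EsrTensors(2.0, 2.0, 1.0, 1.0), 2.0), (ROW4, 1.9667)],
)
def test_isotropic_g(t, expected):
    assert isotropic_g(t) == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize(
    "t,expected",
    [(ROW1, 99.67), (EsrTensors(1.9, 1.9, 0.0, 0.0), 0.0), (ROW4, 105.67)],
)
def test_isotropic_A(t, expected):
    assert isotropic_A(t) == pytest.approx(expected, abs=5e-3)


def test_exchange_G():
    assert exchange_G(ROW1) == pytest.approx(1.71, abs=0.01)
    assert exchange_G(ROW4) == pytest.approx(2.79, abs=0.01)
    assert exchange_G(EsrTensors(1.95, 1.95, 100.0, 50.0)) == 1.0
    with pytest.raises(ZeroDivisionError):
        exchange_G(EsrTensors(1.93, G_E, 167.0, 66.0))


def test_distortion_f():
    assert distortion_f(ROW1) == pytest.approx(115.57, abs=0.02)
    assert distortion_f(ROW4) == pytest.approx(113.45, abs=0.02)
    assert distortion_f(EsrTensors(2.0, 2.0, 200.0, 100.0)) == pytest.approx(100.0)
    with pytest.raises(ZeroDivisionError):
        distortion_f(EsrTensors(1.93, 1.96, 0.0, 66.0))


def test_spin_orbit_lambda():
    assert LAM == pytest.approx(138.18, abs=0.05)
    assert spin_orbit_lambda(G_E, 15000.0) == 0.0
    # direct evaluation: (2.0023 - 1.92) * 15873 / 8
    assert spin_orbit_lambda(1.92, 15873.0) == pytest.approx(163.29, abs=0.01)


def test_dipolar_p():
    assert dipolar_p(ROW1, LAM, 12800.0) == pytest.approx(117.52, abs=0.05)
    assert dipolar_p(ROW4, LAM, 12800.0) == pytest.approx(114.00, abs=0.05)
    assert dipolar_p(EsrTensors(1.93, 1.96, 80.0, 80.0), LAM, 12800.0) == 0.0


def test_fermi_contact_k():
    assert fermi_contact_k(99.67, 117.52, 1.95) == pytest.approx(0.796, abs=0.005)
    assert fermi_contact_k(105.67, 114.00, 1.97) == pytest.approx(0.895, abs=0.005)
    assert fermi_contact_k(0.0, 100.0, G_E) == 0.0
    with pytest.raises(ZeroDivisionError):
        fermi_contact_k(99.67, 0.0, 1.95)


def test_orbital_reduction():
    assert orbital_reduction(1.93, 12800.0, LAM, "parallel") == pytest.approx(
        -0.843, abs=0.005
    )
    assert orbital_reduction(1.96, 12800.0, LAM, "perpendicular") == pytest.approx(
        -1.981, abs=0.005
    )
    assert orbital_reduction(2.00277, 12800.0, LAM, "parallel") == 0.0
    with pytest.raises(ZeroDivisionError):
        orbital_reduction(1.93, 12800.0, 0.0, "parallel")


def test_beta_squared():
    assert beta_squared(ROW1, 117.52) == pytest.approx(0.9357, abs=0.002)
    assert beta_squared(EsrTensors(1.92, 1.96, 168.0, 69.0), 115.19) == pytest.approx(
        0.9243, abs=0.002
    )
    # constructed zero: A_par == A_perp and g_par = (5/14) g_perp + (9/14) g_e
    g_perp = 1.96
    g_par = (5.0 / 14.0) * g_perp + (9.0 / 14.0) * G_E
    assert beta_squared(EsrTensors(g_par, g_perp, 100.0, 100.0), 115.0) == pytest.approx(
        0.0, abs=1e-12
    )


def test_alpha_squared_literal():
    # direct evaluation of the printed (incoherent) expression
    assert alpha_squared_literal(0.00003, 0.9357, 138.18) == pytest.approx(
        1.936e-3, rel=1e-3
    )
    assert alpha_squared_literal(G_E, 1.0, 10.0) == 0.0
    assert alpha_squared_literal(0.0, 1.0, G_E / 8.0) == pytest.approx(1.0)


def test_derive_all_row1():
    d = derive_all(ROW1, DdBands(12800.0, 15290.0), LAM)
    assert d.g_o == pytest.approx(1.95, abs=0.005)
    assert d.A_o == pytest.approx(99.67, abs=0.005)
    assert d.G_exchange == pytest.approx(1.71, abs=0.01)
    assert d.f_distortion == pytest.approx(115.57, abs=0.01)
    assert d.p_dipolar == pytest.approx(117.52, abs=0.01)
    assert d.k_fermi == pytest.approx(0.796, abs=0.005)
    assert d.K2_par == pytest.approx(-0.843, abs=0.005)
    assert d.K2_perp == pytest.approx(-1.981, abs=0.005)
    assert d.beta2 == pytest.approx(0.9357, abs=0.002)


def test_derive_all_row5_K2_perp():
    d = derive_all(EsrTensors(1.93, 1.97, 171.0, 72.0), DdBands(12780.0, 15873.0), LAM)
    assert d.K2_perp == pytest.approx(-1.515, abs=0.005)


def test_derive_all_symmetric_tensors():
    # g_par = g_perp = 2.00277 and A_par = A_perp: G = 1, p = 0, both 2K = 0
    t = EsrTensors(2.00277, 2.00277, 80.0, 80.0)
    d = derive_all(t, DdBands(12800.0, 15290.0), LAM)
    assert d.G_exchange == 1.0
    assert d.p_dipolar == 0.0
    assert d.K2_par == 0.0 and d.K2_perp == 0.0
    assert math.isnan(d.k_fermi) and math.isnan(d.beta2)


# --- invariants ----------------------------------------------------------------

tensors_st = st.builds(
    EsrTensors,
    g_par=st.floats(1.90, 1.99),
    g_perp=st.floats(1.90, 1.99),
    A_par=st.floats(120.0, 190.0),
    A_perp=st.floats(40.0, 110.0),
)


@given(tensors_st)
def test_isotropic_values_lie_between_components(t):
    if t.A_par != t.A_perp:
        assert min(t.A_par, t.A_perp) < isotropic_A(t) < max(t.A_par, t.A_perp)
    eps = 1e-12
    assert min(t.g_par, t.g_perp) - eps <= isotropic_g(t) <= max(t.g_par, t.g_perp) + eps


@given(tensors_st, st.floats(0.1, 3.0))
def test_exchange_G_scale_invariant(t, c):
    scaled = EsrTensors(
        G_E + c * (t.g_par - G_E), G_E + c * (t.g_perp - G_E), t.A_par, t.A_perp
    )
    assert exchange_G(scaled) == pytest.approx(exchange_G(t), rel=1e-9)


@given(st.floats(10.0, 150.0), st.floats(10.0, 150.0))
def test_dipolar_p_monotone_in_anisotropy(da1, da2):
    lo, hi = sorted([da1, da2])
    p_lo = dipolar_p(EsrTensors(1.93, 1.96, 40.0 + lo, 40.0), LAM, 12800.0)
    p_hi = dipolar_p(EsrTensors(1.93, 1.96, 40.0 + hi, 40.0), LAM, 12800.0)
    assert p_lo <= p_hi


@given(st.floats(1.9, 2.1), st.sampled_from(["parallel", "perpendicular"]))
def test_orbital_reduction_sign_tracks_g_shift(g, component):
    val = orbital_reduction(g, 12800.0, LAM, component)
    assert math.copysign(1.0, val) == math.copysign(1.0, g - 2.00277) or val == 0.0
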