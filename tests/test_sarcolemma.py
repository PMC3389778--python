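"""Sarcolemmal currents: reversal potentials, gate bounds, transporter
signs, and the allosteric / nucleotide regulations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpmyo import sarcolemma as sar
from gpmyo.constants import RT_OVER_F


def K(p, na_i=7.0, k_i=140.0, ca_i=1e-4, atp=7.9, adp=0.03):
    return dict(na_i=na_i, k_i=k_i, ca_i=ca_i, atp=atp, adp=adp, p=p)


def test_k_currents_vanish_at_reversal(p):
    k_i = 140.0
    e_k = RT_OVER_F * np.log(5.4 / k_i)
    gates = sar.steady_state_gates(e_k, p)
    cur = sar.compute_currents(e_k, gates, **K(p, k_i=k_i))
    for name in ("i_kr", "i_ks", "i_k1", "i_kp", "i_katp"):
        if name == "i_ks":
            continue  # IKs reverses at E_Ks (Na+-permeable), not E_K
        assert getattr(cur, name) == pytest.approx(0.0, abs=1e-12)
    e_ks = RT_OVER_F * np.log((5.4 + 0.01833 * 140.0)
                              / (k_i + 0.01833 * 7.0))
    cur = sar.compute_currents(e_ks, sar.steady_state_gates(e_ks, p),
                               **K(p, k_i=k_i))
    assert cur.i_ks == pytest.approx(0.0, abs=1e-12)


def test_ohmic_na_background_reverses_at_e_na(p):
    na_i = 7.0
    e_na = RT_OVER_F * np.log(140.0 / na_i)
    cur = sar.compute_currents(e_na, sar.steady_state_gates(e_na, p),
                               **K(p, na_i=na_i))
    assert cur.i_nab == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=60, deadline=None)
@given(v=st.floats(-100, 60))
def test_gate_derivatives_keep_gates_in_unit_interval(p, v):
    lo = sar.gate_derivatives(v, np.zeros(sar.N_GATES), p)
    hi = sar.gate_derivatives(v, np.ones(sar.N_GATES), p)
    assert (lo >= 0.0).all()
    assert (hi <= 0.0).all()


@pytest.mark.parametrize("v", [-80.0, -40.0, 0.0, 30.0])
def test_gate_derivatives_vanish_at_steady_state(p, v):
    g = sar.steady_state_gates(v, p)
    d = sar.gate_derivatives(v, g, p)
    assert np.abs(d).max() < 1e-10


def test_iks_variant_changes_current_not_kinetics(p):
    g = sar.steady_state_gates(0.0, p)
    g.xs2 = 0.1  # make the two formulations distinguishable
    p_v = p.with_values(iks_variant=0.0)
    p_z = p.with_values(iks_variant=1.0)
    cv = sar.compute_currents(0.0, g, **K(p_v))
    cz = sar.compute_currents(0.0, g, **K(p_z))
    assert cv.i_ks != pytest.approx(cz.i_ks)
    d_v = sar.gate_derivatives(0.0, g, p_v)
    d_z = sar.gate_derivatives(0.0, g, p_z)
    assert np.array_equal(d_v, d_z)
    with pytest.raises(ValueError):
        sar.gate_derivatives(0.0, g, p, iks_variant="lr91")


def test_ncx_allosteric_factor_saturates(p):
    g = sar.steady_state_gates(-20.0, p)
    ca_hi = 0.05
    i_hi = sar.compute_currents(-20.0, g, **K(p, ca_i=ca_hi)).i_ncx
    # removing the allosteric site (Km -> 0) should match within 0.1%
    p_noallo = p.with_values(ncx_km_ca_act=1e-12)
    i_ref = sar.compute_currents(-20.0, g, **K(p_noallo, ca_i=ca_hi)).i_ncx
    assert i_hi == pytest.approx(i_ref, rel=1e-3)


def test_pumps_strictly_positive(p):
    g = sar.steady_state_gates(-85.0, p)
    cur = sar.compute_currents(-85.0, g, **K(p))
    assert cur.i_nak > 0.0
    assert cur.i_pca > 0.0


def test_ikatp_decreases_with_atp(p):
    g = sar.steady_state_gates(-40.0, p)
    i_low = sar.compute_currents(-40.0, g, **K(p, atp=1.0)).i_katp
    i_high = sar.compute_currents(-40.0, g, **K(p, atp=8.0)).i_katp
    assert i_low > i_high > 0.0


def test_ito_fast_disabled_and_zero_conductance(p):
    g = sar.steady_state_gates(40.0, p)
    assert sar.i_to_fast(40.0, g, p) == 0.0
    p_on = p.with_values(ito_enabled=1.0, gto=0.0)
    cur = sar.compute_currents(40.0, g, **K(p_on))
    assert cur.i_to == 0.0
    p_on = p.with_values(ito_enabled=1.0, gto=0.2)
    g.ito_a, g.ito_i = 0.8, 0.7
    cur = sar.compute_currents(40.0, g, **K(p_on))
    assert cur.i_to > 0.0
    with pytest.raises(ValueError):
        sar.i_to_fast(40.0, g, p.with_values(gto=-0.1))


def test_nonphysical_concentration_rejected(p):
    g = sar.steady_state_gates(0.0, p)
    with pytest.raises(ValueError):
        sar.compute_currents(0.0, g, na_i=-1.0, k_i=140.0, ca_i=1e-4,
                             atp=7.9, adp=0.03, p=p)
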