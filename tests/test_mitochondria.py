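"""Mitochondrial energetics: uniporter/exchanger contracts, pool
conservation, and the Ca2+ stimulation of NADH production."""

import numpy as np
import pytest

from gpmyo import mitochondria as mito


def mk_state(ca_m=2e-4, nadh=0.6, adp_m=0.05, dpsi=170.0, na_m=5.0):
    s = np.array([ca_m, nadh, adp_m, dpsi, na_m,
                  0.1, 0.1, 0.05, 0.05, 0.05, 0.2, 0.05])
    return s


def test_uniporter_scale_and_monotonicity(p):
    assert mito.uniporter_flux(1e-4, 170.0, p, vmuni_scale=0.0) == 0.0
    full = mito.uniporter_flux(1e-4, 170.0, p, vmuni_scale=1.0)
    half = mito.uniporter_flux(1e-4, 170.0, p, vmuni_scale=0.5)
    assert half == pytest.approx(0.5 * full)
    cas = np.geomspace(5e-5, 5e-3, 8)
    fluxes = [mito.uniporter_flux(c, 170.0, p) for c in cas]
    assert all(b > a for a, b in zip(fluxes, fluxes[1:]))
    with pytest.raises(ValueError):
        mito.uniporter_flux(1e-4, 170.0, p, vmuni_scale=1.5)


def test_mncx_requires_matrix_ca(p):
    assert mito.mito_ca_exchanger_flux(0.0, 7.0, 5.0, 170.0, p) == 0.0
    assert mito.mito_ca_exchanger_flux(2e-4, 7.0, 5.0, 170.0, p) > 0.0


def test_nhe_vanishes_at_matched_gradients(p):
    h_i, h_m = p.value("h_i"), p.value("h_m")
    na_i = 7.0
    na_m = na_i * h_m / h_i
    assert mito.mito_nhe_flux(na_m, na_i, p) == pytest.approx(0.0, abs=1e-15)
    assert mito.mito_nhe_flux(2.0 * na_m, na_i, p) > 0.0


def test_tca_intermediates_conserved(p):
    d, *_ = mito.energetics_derivatives(mk_state(), 1e-4, 7.0, 0.03, 7.9, p)
    assert abs(d[mito.IM_ISOC:].sum()) < 1e-18


def test_pool_bounds_rejected(p):
    bad = mk_state(nadh=1.5)  # above the conserved NAD total
    with pytest.raises(ValueError):
        mito.energetics_derivatives(bad, 1e-4, 7.0, 0.03, 7.9, p)


def test_nadh_production_stimulated_by_matrix_ca(p):
    def production(ca_m):
        s = mk_state(ca_m=ca_m)
        d, _, _, _, v_o = mito.energetics_derivatives(s, 1e-4, 7.0, 0.03,
                                                      7.9, p)
        return d[mito.IM_NADH] + v_o  # production = dNADH/dt + consumption
    assert production(2e-3) > production(2e-5)


def test_f1f0_stimulated_by_matrix_adp(p):
    def atp_synthesis(adp_m):
        s = mk_state(adp_m=adp_m)
        d, v_ant, *_ = mito.energetics_derivatives(s, 1e-4, 7.0, 0.03, 7.9, p)
        # dADP_m/dt = ANT - F1F0 - SL  =>  F1F0 + SL = ANT - dADP_m/dt
        return v_ant - d[mito.IM_ADPM]
    assert atp_synthesis(0.3) > atp_synthesis(0.01)


def test_basal_quiescence_without_stimulation(p):
    """Near-zero matrix Ca2+ and ADP: NADH production and ATP synthesis
    both sit below their Ca2+/ADP-stimulated rates."""
    s_basal = mk_state(ca_m=1e-7, adp_m=1e-4)
    d_b, ant_b, _, _, vo_b = mito.energetics_derivatives(s_basal, 1e-7, 7.0,
                                                         0.03, 7.9, p)
    s_act = mk_state(ca_m=2e-3, adp_m=0.5)
    d_a, ant_a, _, _, vo_a = mito.energetics_derivatives(s_act, 1e-3, 7.0,
                                                         0.03, 7.9, p)
    prod_b = d_b[mito.IM_NADH] + vo_b
    prod_a = d_a[mito.IM_NADH] + vo_a
    assert prod_b < prod_a
    synth_b = ant_b - d_b[mito.IM_ADPM]   # F1F0 + substrate-level
    synth_a = ant_a - d_a[mito.IM_ADPM]
    assert synth_b < synth_a
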