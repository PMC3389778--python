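"""Assembled cell model: stability at rest, determinism, invariants of the
paced beat, charge-concentration consistency, and solver convergence."""

import numpy as np
import pytest

from gpmyo import cell
from gpmyo.constants import FARADAY
from gpmyo.params import Parameters


def test_parameter_schema_roundtrip(p):
    d = p.to_dict()
    q = Parameters.from_dict(d)
    assert np.array_equal(p.as_array(), q.as_array())
    with pytest.raises(ValueError):
        bad = {k: dict(v) for k, v in d.items()}
        bad["cell"]["not_a_param"] = {"value": 1.0}
        Parameters.from_dict(bad)


def test_resting_cell_is_stable(p, y1hz):
    """No stimulus for 10 s from end-diastole: dV/dt stays tiny."""
    res = cell.integrate_segments(y1hz, [cell.Segment(duration=10000.0)], p,
                                  dt_out=100.0)
    parr = p.as_array()
    dy = cell._rhs(0.0, res.y[-1], parr, cell.MODE_CC, 0.0, 0.0)
    assert abs(dy[cell.IV]) < 0.01
    assert abs(res.v[-1] - res.v[0]) < 3.0


def test_zero_duration_returns_initial_state(p, y1hz):
    res = cell.integrate_segments(y1hz, [], p)
    assert res.y.shape[0] == 1
    assert np.array_equal(res.y[0], y1hz)


def test_simulation_deterministic(p, y1hz):
    a = cell.simulate_pacing(p, y1hz, 500.0, 1)
    b = cell.simulate_pacing(p, y1hz, 500.0, 1)
    assert np.array_equal(a.y, b.y)


def test_beat_invariants(beat_1hz):
    """Occupancy normalization and gate bounds hold at every sample."""
    occ = beat_1hz.caru_occupancy()
    assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-6
    assert occ.min() > -1e-9
    gates = beat_1hz.y[:, cell.IG0:cell.IG0 + cell.NG]
    assert gates.min() > -1e-6
    assert gates.max() < 1.0 + 1e-6
    conc = beat_1hz.y[:, [cell.ICA_I, cell.ICA_NSR, cell.INA_I, cell.IK_I]]
    assert conc.min() > 0.0


def test_charge_concentration_consistency(p, beat_1hz):
    """Ion bookkeeping matches the membrane equation: the change in total
    intracellular charge over a beat (every compartment, every buffer,
    stimulus assigned to K+) accounts exactly for the change in V."""
    res = beat_1hz
    parr = p.as_array()
    d = res.derived()
    i_total = sum(np.abs(d[k]) for k in ("i_na", "i_kr", "i_ks", "i_k1",
                                         "i_kp", "i_katp", "i_nak", "i_ncx",
                                         "i_pca", "i_cab", "i_nab", "i_to",
                                         "i_cal"))
    # total charge concentration: Na + K + 2*Ca over every compartment,
    # volume-weighted to cytosol; matrix Ca2+ converted from free to total
    vr_sr = p.value("v_sr") / p.value("v_myo")
    vr_m = p.value("v_mito") / p.value("v_myo")
    y0, y1 = res.y[0], res.y[-1]

    def charge(y):
        ca_tot = (y[cell.ICA_I] + y[cell.ILTRPN] + y[cell.IHTRPN]
                  + y[cell.ICMDN]
                  + (y[cell.ICA_NSR] + y[cell.ICSQN]) * vr_sr
                  + y[cell.IMITO0] / p.value("f_ca_m") * vr_m)
        na_tot = y[cell.INA_I] + y[cell.IMITO0 + 4] * vr_m
        return na_tot + y[cell.IK_I] + 2.0 * ca_tot

    conv = parr[cell.P_CM] * 1e-3 / (FARADAY * parr[cell.P_V_MYO])
    dv_from_conc = (charge(y1) - charge(y0)) / conv
    dv_actual = y1[cell.IV] - y0[cell.IV]
    # 1% of the total charge moved across the membrane during the beat
    scale = np.trapezoid(i_total, res.t)
    assert abs(dv_from_conc - dv_actual) / scale < 0.01


def test_pace_to_steady_state_quick_return(p, y1hz):
    y, info = cell.pace_to_steady_state(1000.0, p, y1hz, max_beats=60)
    y2, info2 = cell.pace_to_steady_state(1000.0, p, y, max_beats=60)
    assert info2["n_beats"] <= 2


def test_apd_converges_with_solver_tolerance(p, y1hz):
    """Tightening tolerances 10x changes APD90 by < 0.5 ms."""
    from gpmyo import analysis
    res_a = cell.simulate_pacing(p, y1hz, 1000.0, 1, rtol=1e-6, atol=1e-8)
    res_b = cell.simulate_pacing(p, y1hz, 1000.0, 1, rtol=1e-7, atol=1e-9)
    a = analysis.apd(res_a.t, res_a.v, 0.9)
    b = analysis.apd(res_b.t, res_b.v, 0.9)
    assert abs(a - b) < 0.5


def test_state_io_roundtrip(tmp_path, p, y1hz):
    path = tmp_path / "state.json"
    cell.save_state(y1hz, path, note="test")
    back = cell.load_initial_state(path)
    assert np.allclose(back, y1hz, rtol=0, atol=0)
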