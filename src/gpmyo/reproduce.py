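"""Headline model outputs and the recipes that recompute them.

Each function runs one of the standard protocols on a parameter set and
returns a dict of named metrics.  :data:`REFERENCE_VALUES` records the
published values of these outputs for the reference parameter set, for
side-by-side display by the command-line ``reproduce`` command.
"""

from __future__ import annotations

import numpy as np

from . import analysis, cell, protocols
from .params import Parameters

# published outputs of the reference model (units as printed)
REFERENCE_VALUES = {
    "apd90_1hz_ms": 189.0,
    "ca_delay_ms": 119.0,
    "ryr_po_peak_pct": 2.9,
    "fractional_release_pct": 33.0,
    "subspace_oo_max_um": 45.0,
    "peak_ical_ua_uf": -32.0,
    "peak_ical_potential_mv": 10.0,
    "ryr_flux_peak_potential_mv": 5.0,
    "serca_removal_pct": 65.9,
    "ncx_removal_pct": 28.9,
    "sl_pump_removal_pct": 5.1,
    "mito_bolus_pct": 12.7,
    "recirculation_pct": 69.0,
    "restitution_tau_ms": 165.0,
    "restitution_plateau_ms": 219.0,
    "uniporter_block_ca_peak_pct": 51.0,
    "uniporter_block_mito_transient_pct": -60.0,
}


def steady_1hz_metrics(p: Parameters, y0=None, *, max_beats: int = 300,
                       rtol: float = 1e-7, atol: float = 1e-9) -> dict:
    """Metrics of the steady-state 1 Hz beat."""
    res = protocols.run_protocol(protocols.pacing(1000.0, 1), p, y0,
                                 max_beats=max_beats, rtol=rtol, atol=atol)
    d = res.derived()
    t, v, ca = res.t, res.v, res.ca_i
    kv, kc = int(np.argmax(v)), int(np.argmax(ca))
    fr = analysis.integrated_flux_fractions(res)
    return {
        "apd90_1hz_ms": analysis.apd(t, v, 0.9),
        "ca_delay_ms": float(t[kc] - t[kv]),
        "ca_time_to_peak_ms": float(t[kc] - t[0]),
        "ryr_po_peak_pct": float(d["ryr_open"].max() * 100.0),
        "fractional_release_pct": analysis.fractional_release(res) * 100.0,
        "subspace_oo_max_um": analysis.subspace_oo_max(res) * 1.0e3,
        "avg_subspace_peak_um": float(d["avg_ca_ss"].max() * 1.0e3),
        "ca_peak_um": float(ca[kc] * 1.0e3),
        "ca_dia_um": float(ca[0] * 1.0e3),
        "serca_removal_pct": fr.serca * 100.0,
        "ncx_removal_pct": fr.ncx * 100.0,
        "sl_pump_removal_pct": fr.sl_pump * 100.0,
        "mito_bolus_pct": fr.mito_bolus * 100.0,
        "recirculation_pct": analysis.recirculation_fraction(res) * 100.0,
        "n_beats_to_steady_state": res.meta.get("n_beats"),
    }


def iv_metrics(p: Parameters, y0=None, *, rtol: float = 1e-7,
               atol: float = 1e-9) -> dict:
    """Voltage-clamp I-V family metrics (peak I_CaL, flux-peak potentials)."""
    spec = protocols.voltage_step_family()
    fam = protocols.run_protocol(spec, p, y0, rtol=rtol, atol=atol)
    v, pk_i, pk_l, pk_r = fam.peak_table()
    k = int(np.argmin(pk_i))
    gain = fam.gain_curve()
    # monotone non-increasing gain over 0..+60 mV: largest upward step as
    # a fraction of the maximum gain (0 for a perfectly monotone curve)
    mask = (gain.v_test >= 0) & np.isfinite(gain.gain)
    g = gain.gain[mask]
    viol = (float(np.max(np.diff(g)) / np.max(g))
            if len(g) > 1 and np.max(g) > 0 else 0.0)
    return {
        "peak_ical_ua_uf": float(pk_i[k]),
        "peak_ical_potential_mv": float(v[k]),
        "ryr_flux_peak_potential_mv": float(v[int(np.argmax(pk_r))]),
        "lcc_flux_peak_potential_mv": float(v[int(np.argmax(pk_l))]),
        "gain_monotonicity_violation": viol,
    }


def restitution_metrics(p: Parameters, y0=None, *, max_beats: int = 300,
                        rtol: float = 1e-7, atol: float = 1e-9) -> dict:
    """S1-S2 restitution: single-exponential tau and the plateau APD90."""
    spec = protocols.s1s2_restitution()
    rest = protocols.run_protocol(spec, p, y0, max_beats=max_beats,
                                  rtol=rtol, atol=atol)
    di, a = rest.arrays()
    # single-exponential fit over the experimentally sampled range of
    # diastolic intervals; beyond ~2 s a separate, much slower SR-load
    # component dominates and is reported through the plateau instead
    m = di <= 2000.0
    fit = analysis.fit_single_exponential(di[m], a[m])
    return {
        "restitution_tau_ms": fit.tau,
        "restitution_plateau_ms": float(a[di >= 4000.0].mean())
        if (di >= 4000.0).any() else fit.offset,
        "restitution_fit_offset_ms": fit.offset,
        "restitution_n_captured": int(len(a)),
    }


def uniporter_block_metrics(p: Parameters, y0=None, *, max_beats: int = 300,
                            block_beats: int = 120, rtol: float = 1e-7,
                            atol: float = 1e-9) -> dict:
    """Cytosolic / mitochondrial Ca2+ transient changes with 75% block."""
    ctrl = protocols.run_protocol(protocols.pacing(1000.0, 1), p, y0,
                                  max_beats=max_beats, rtol=rtol, atol=atol)
    y_ss = ctrl.y[-1]
    p_blk = p.with_values(vmuni_scale=0.25)
    y_blk, _ = cell.pace_to_steady_state(1000.0, p_blk, y_ss,
                                         max_beats=block_beats,
                                         rtol=rtol, atol=atol)
    blk = cell.simulate_pacing(p_blk, y_blk, 1000.0, 1, rtol=rtol, atol=atol)

    def amp(res, name):
        x = res.state(name) if name != "ca_i" else res.ca_i
        return float(x.max() - x.min())

    ca_ctrl, ca_blk = ctrl.ca_i.max(), blk.ca_i.max()
    m_ctrl, m_blk = amp(ctrl, "ca_m"), amp(blk, "ca_m")
    return {
        "uniporter_block_ca_peak_pct": float((ca_blk / ca_ctrl - 1.0) * 100.0),
        "uniporter_block_mito_transient_pct":
            float((m_blk / m_ctrl - 1.0) * 100.0),
        "ca_peak_control_um": float(ca_ctrl * 1e3),
        "ca_peak_block_um": float(ca_blk * 1e3),
        "mito_transient_control_um": float(m_ctrl * 1e3),
        "mito_transient_block_um": float(m_blk * 1e3),
    }


RECIPES = {
    "steady-1hz": steady_1hz_metrics,
    "iv-family": iv_metrics,
    "restitution": restitution_metrics,
    "uniporter-block": uniporter_block_metrics,
}
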