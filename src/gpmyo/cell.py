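"""Whole-cell model assembly and stiff integration.

The full state vector (78 ODE states) collects membrane potential, the
Hodgkin-Huxley gates, the 40 joint LCC-RyR occupancies, bulk ionic
concentrations and buffers, the crossbridge states, the mitochondrial
matrix states, and cytosolic nucleotides:

====== ===========================================================
index  meaning
====== ===========================================================
0      V (mV)
1-9    gates: m, h, j, xkr, xs1, xs2, y (LCC VDI), ito_a, ito_i
10-49  CaRU occupancies (lcc_state * 4 + ryr_state)
50-57  ca_i, ca_nsr, na_i, k_i, ltrpn, htrpn, cmdn, csqn (mM)
58-63  crossbridge: n0, n1, p0, p1, p2, p3
64-75  matrix: ca_m, nadh, adp_m, dpsi, na_m, 7 TCA intermediates
76-77  adp_i, crp (mM)
====== ===========================================================

Integration uses LSODA (stiff multistep with internally generated
finite-difference Jacobian) on a uniform 1-ms output grid, split into
segments at stimulus / clamp edges so that every discontinuity coincides
with a solver restart.  Simulations are deterministic for fixed inputs and
tolerances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numba import njit
from scipy.integrate import odeint

from . import caru as _caru
from . import contraction as _xb
from . import mitochondria as _mito
from . import sarcolemma as _sar
from .ca_cycling import _buffer_fluxes, _serca
from .constants import FARADAY
from .params import (  # noqa: F401
    P_ATOT_I, P_CM, P_CMDN_TOT, P_CR_TOT, P_CSQN_TOT, P_FMAX_MN,
    P_HTRPN_TOT, P_KCK,
    P_KEQ_CK, P_LTRPN_TOT, P_MNCX_N_NA, P_STIM_AMP, P_STIM_DUR, P_V_MITO,
    P_V_MYO, P_V_SR, P_V_SS, P_XSEC_AREA, Parameters,
)

# --- state layout ----------------------------------------------------------
IV = 0
IG0 = 1                  # first gate
NG = _sar.N_GATES
ICARU0 = IG0 + NG        # 10
NCARU = _caru.N_STATES
ICA_I = ICARU0 + NCARU   # 50
ICA_NSR = 51
INA_I = 52
IK_I = 53
ILTRPN = 54
IHTRPN = 55
ICMDN = 56
ICSQN = 57
IXB0 = 58
NXB = _xb.N_XB
IMITO0 = IXB0 + NXB      # 64
NMITO = _mito.N_MITO
IADP_I = IMITO0 + NMITO  # 76
ICRP = 77
N_STATES = 78

STATE_NAMES = (
    ["v", "m", "h", "j", "xkr", "xs1", "xs2", "y_lcc", "ito_a", "ito_i"]
    + [f"caru_{i}" for i in range(NCARU)]
    + ["ca_i", "ca_nsr", "na_i", "k_i", "ltrpn", "htrpn", "cmdn", "csqn"]
    + ["xb_n0", "xb_n1", "xb_p0", "xb_p1", "xb_p2", "xb_p3"]
    + ["ca_m", "nadh", "adp_m", "dpsi", "na_m",
       "isoc", "akg", "scoa", "suc", "fum", "mal", "oaa"]
    + ["adp_i", "crp"]
)

# derived-output layout (per sample)
DERIVED_NAMES = (
    "i_na", "i_kr", "i_ks", "i_k1", "i_kp", "i_katp", "i_nak", "i_ncx",
    "i_pca", "i_cab", "i_nab", "i_to", "i_cal", "i_stim",
    "j_lcc_ss", "j_ryr_ss", "j_xfer_cyto", "j_rel_cyto", "j_up",
    "j_ncx_cyto", "j_pca_cyto", "j_cab_cyto", "j_uni_cyto", "j_mncx_cyto",
    "avg_ca_ss", "ca_ss_oo", "ryr_open", "lcc_avail",
    "f_norm", "stress", "v_o2", "atpase",
)
N_DERIVED = len(DERIVED_NAMES)
DIDX = {n: i for i, n in enumerate(DERIVED_NAMES)}

# integration modes
MODE_CC = 0.0   # current clamp
MODE_VC = 1.0   # voltage clamp (linear V ramp within a segment)


@njit(cache=True)
def _rhs(t, y, p, mode, i_stim, v_slope):
    dy = np.zeros(N_STATES)
    v = y[IV]
    gates = y[IG0:IG0 + NG]
    occ = y[ICARU0:ICARU0 + NCARU]
    ca_i = y[ICA_I]
    ca_nsr = y[ICA_NSR]
    na_i = y[INA_I]
    k_i = y[IK_I]
    adp_i = y[IADP_I]
    atp_i = p[P_ATOT_I] - adp_i
    crp = y[ICRP]

    # guard against tiny negative excursions from the solver
    if ca_i < 1e-9:
        ca_i = 1e-9
    if ca_nsr < 1e-9:
        ca_nsr = 1e-9

    # --- sarcolemmal currents and gates ---
    cur = _sar._currents(v, gates, na_i, k_i, ca_i, atp_i, adp_i, p)
    dy[IG0:IG0 + NG] = _sar._gate_derivs(v, gates, p)

    # --- CaRU ---
    A = _caru._build_generator(v, ca_i, ca_nsr, p)
    dy[ICARU0:ICARU0 + NCARU] = A.T @ occ
    j_lcc, j_ryr, i_cal_raw, j_xfer_ss, _ = _caru._fluxes(
        occ, v, ca_i, ca_nsr, p)
    i_cal = gates[6] * i_cal_raw          # VDI availability gate
    # only the LCC source term is gated by VDI; subspace-cytosol diffusion
    # and RyR release are not
    j_xfer_cyto = (j_xfer_ss - (1.0 - gates[6]) * j_lcc) \
        * (p[P_V_SS] / p[P_V_MYO])
    j_rel_sr = j_ryr * (p[P_V_SS] / p[P_V_SR])

    # --- mitochondria ---
    mito = y[IMITO0:IMITO0 + NMITO]
    d_mito, v_ant, j_uni, j_mncx, v_o = _mito._energetics(
        mito, ca_i, na_i, adp_i, atp_i, p)
    dy[IMITO0:IMITO0 + NMITO] = d_mito
    vr_mito = p[P_V_MITO] / p[P_V_MYO]

    # --- contraction ---
    xb = y[IXB0:IXB0 + NXB]
    ltrpn = y[ILTRPN]
    htrpn = y[IHTRPN]
    d_xb, f_norm, atpase = _xb._xb_derivs(xb, ltrpn / p[P_LTRPN_TOT], p)
    dy[IXB0:IXB0 + NXB] = d_xb
    d_l, d_h = _xb._troponin_derivs(ca_i, ltrpn, htrpn, p)
    dy[ILTRPN] = d_l
    dy[IHTRPN] = d_h

    # --- Ca2+ cycling ---
    conv1 = p[P_CM] * 1.0e-3 / (FARADAY * p[P_V_MYO])  # (mM/ms)/(uA/uF), z=1
    j_up = _serca(ca_i, ca_nsr, atp_i, p)
    d_cmdn, d_csqn = _buffer_fluxes(ca_i, ca_nsr, y[ICMDN], y[ICSQN], p)
    dy[ICMDN] = d_cmdn
    dy[ICSQN] = d_csqn
    j_sl_net = conv1 * cur[7] - 0.5 * conv1 * (cur[9] + cur[8])
    j_mito_net = (j_uni - j_mncx) * vr_mito
    dy[ICA_I] = (j_xfer_cyto - j_up + j_sl_net - j_mito_net
                 - d_l - d_h - d_cmdn)
    dy[ICA_NSR] = j_up * (p[P_V_MYO] / p[P_V_SR]) - j_rel_sr - d_csqn

    # --- Na+, K+ ---
    # mito Na+ loop: mNCX imports Na+ to the matrix, NHE exports it
    j_nhe = p[P_MNCX_N_NA] * j_mncx - d_mito[_mito.IM_NAM]
    dy[INA_I] = (-conv1 * (cur[0] + cur[10] + 3.0 * cur[7] + 3.0 * cur[6])
                 + vr_mito * (j_nhe - p[P_MNCX_N_NA] * j_mncx))
    dy[IK_I] = -conv1 * (cur[1] + cur[2] + cur[3] + cur[4] + cur[5]
                         + cur[11] - 2.0 * cur[6] + i_stim)

    # --- cytosolic energetics ---
    cr = p[P_CR_TOT] - crp
    j_ck = p[P_KCK] * (crp * adp_i - atp_i * cr / p[P_KEQ_CK])
    consumption = (atpase + conv1 * cur[6] + 0.5 * conv1 * cur[8]
                   + 0.5 * j_up)
    dy[IADP_I] = consumption - j_ck - v_ant * vr_mito
    dy[ICRP] = -j_ck

    # --- membrane potential ---
    if mode < 0.5:
        total = 0.0
        for k in range(12):
            total += cur[k]
        dy[IV] = -(total + i_cal + i_stim)
    else:
        dy[IV] = v_slope
    return dy


@njit(cache=True)
def _derived_row(y, p, i_stim):
    out = np.zeros(N_DERIVED)
    v = y[IV]
    gates = y[IG0:IG0 + NG]
    occ = y[ICARU0:ICARU0 + NCARU]
    ca_i = max(y[ICA_I], 1e-9)
    ca_nsr = max(y[ICA_NSR], 1e-9)
    na_i = y[INA_I]
    k_i = y[IK_I]
    adp_i = y[IADP_I]
    atp_i = p[P_ATOT_I] - adp_i

    cur = _sar._currents(v, gates, na_i, k_i, ca_i, atp_i, adp_i, p)
    for k in range(12):
        out[k] = cur[k]
    j_lcc, j_ryr, i_cal_raw, j_xfer_ss, avg = _caru._fluxes(
        occ, v, ca_i, ca_nsr, p)
    out[12] = gates[6] * i_cal_raw
    out[13] = i_stim
    out[14] = j_lcc
    out[15] = j_ryr
    out[16] = (j_xfer_ss - (1.0 - gates[6]) * j_lcc) * (p[P_V_SS] / p[P_V_MYO])
    out[17] = j_ryr * (p[P_V_SS] / p[P_V_MYO])
    out[18] = _serca(ca_i, ca_nsr, atp_i, p)
    conv1 = p[P_CM] * 1.0e-3 / (FARADAY * p[P_V_MYO])
    out[19] = conv1 * cur[7]               # NCX Ca2+ flux (influx positive)
    out[20] = -0.5 * conv1 * cur[8]        # SL pump (influx positive, so <0)
    out[21] = -0.5 * conv1 * cur[9]        # background Ca2+ influx
    mito = y[IMITO0:IMITO0 + NMITO]
    d_mito, v_ant, j_uni, j_mncx, v_o = _mito._energetics(
        mito, ca_i, na_i, adp_i, atp_i, p)
    vr_mito = p[P_V_MITO] / p[P_V_MYO]
    out[22] = j_uni * vr_mito
    out[23] = j_mncx * vr_mito
    out[24] = avg
    out[25] = _caru._subspace_ca(True, True, v, ca_i, ca_nsr, p)
    ryr_open = 0.0
    mode_ca = 0.0
    for il in range(_caru.N_LCC):
        for ir in range(_caru.N_RYR):
            pi = occ[il * _caru.N_RYR + ir]
            if ir == _caru.RYR_OPEN_STATE:
                ryr_open += pi
            if il >= 5:
                mode_ca += pi
    out[26] = ryr_open
    out[27] = (1.0 - mode_ca) * gates[6]
    xb = y[IXB0:IXB0 + NXB]
    _, f_norm, atpase = _xb._xb_derivs(xb, y[ILTRPN] / p[P_LTRPN_TOT], p)
    out[28] = f_norm
    out[29] = f_norm * p[P_FMAX_MN] / p[P_XSEC_AREA]
    out[30] = v_o
    out[31] = atpase
    return out


# ---------------------------------------------------------------------------
# segments and integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One integration interval with constant stimulus / linear clamp."""
    duration: float          # ms
    mode: float = MODE_CC
    i_stim: float = 0.0      # uA/uF during the segment (current clamp)
    v_start: float | None = None   # clamp start (voltage clamp)
    v_slope: float = 0.0     # mV/ms (voltage clamp)


@dataclass
class SimulationResult:
    """Uniformly sampled trajectory plus recomputable derived outputs."""
    t: np.ndarray            # ms
    y: np.ndarray            # (n, N_STATES)
    i_stim: np.ndarray       # stimulus trace on the grid
    params: Parameters
    meta: dict = field(default_factory=dict)

    def state(self, name: str) -> np.ndarray:
        return self.y[:, STATE_NAMES.index(name)]

    @property
    def v(self) -> np.ndarray:
        return self.y[:, IV]

    @property
    def ca_i(self) -> np.ndarray:
        return self.y[:, ICA_I]

    def caru_occupancy(self) -> np.ndarray:
        return self.y[:, ICARU0:ICARU0 + NCARU]

    def derived(self) -> dict[str, np.ndarray]:
        parr = _as_array(self.params)
        out = np.empty((len(self.t), N_DERIVED))
        for k in range(len(self.t)):
            out[k] = _derived_row(self.y[k], parr, self.i_stim[k])
        return {name: out[:, i] for i, name in enumerate(DERIVED_NAMES)}

    def to_frame(self, include_derived: bool = True):
        import pandas as pd
        data = {"t": self.t}
        for i, n in enumerate(STATE_NAMES):
            if not n.startswith("caru_"):
                data[n] = self.y[:, i]
        if include_derived:
            data.update(self.derived())
        return pd.DataFrame(data)


def _as_array(p) -> np.ndarray:
    return p.as_array() if isinstance(p, Parameters) else np.asarray(p)


def integrate_segments(y0, segments, p, *, dt_out: float = 1.0,
                       rtol: float = 1e-7, atol: float = 1e-9,
                       t0: float = 0.0) -> SimulationResult:
    """Integrate a list of :class:`Segment` with uniform output sampling."""
    parr = _as_array(p)
    params = p if isinstance(p, Parameters) else None
    y = np.asarray(y0, dtype=float).copy()
    if y.shape != (N_STATES,):
        raise ValueError(f"state vector must have length {N_STATES}")

    first_stim = 0.0
    if segments and segments[0].mode < 0.5:
        first_stim = segments[0].i_stim
    ts = [np.array([t0])]
    ys = [y[None, :].copy()]
    stims = [np.array([first_stim])]
    t_cur = t0
    for seg in segments:
        if seg.duration <= 0.0:
            continue
        n_pts = max(int(round(seg.duration / dt_out)), 1)
        grid = t_cur + np.linspace(0.0, seg.duration, n_pts + 1)
        if seg.mode > 0.5 and seg.v_start is not None:
            y[IV] = seg.v_start
        sol, info = odeint(
            _rhs, y, grid,
            args=(parr, seg.mode, seg.i_stim, seg.v_slope),
            tfirst=True, rtol=rtol, atol=atol, mxstep=100000,
            full_output=True,
        )
        if info["message"] != "Integration successful.":
            raise RuntimeError(
                f"solver failure at t={t_cur:.3f} ms: {info['message']}; "
                f"last state V={y[IV]:.3f}"
            )
        if not np.all(np.isfinite(sol[-1])):
            raise RuntimeError(f"non-finite state at t={t_cur:.3f} ms")
        y = sol[-1].copy()
        ts.append(grid[1:])
        ys.append(sol[1:])
        stims.append(np.full(n_pts, seg.i_stim if seg.mode < 0.5 else 0.0))
        t_cur += seg.duration

    return SimulationResult(
        t=np.concatenate(ts), y=np.vstack(ys), i_stim=np.concatenate(stims),
        params=params if params is not None else parr,
    )


def beat_segments(bcl: float, p, n_beats: int = 1) -> list[Segment]:
    """Current-clamp pacing: rectangular stimulus then rest, per beat."""
    parr = _as_array(p)
    segs = []
    for _ in range(n_beats):
        segs.append(Segment(duration=parr[P_STIM_DUR], mode=MODE_CC,
                            i_stim=parr[P_STIM_AMP]))
        segs.append(Segment(duration=bcl - parr[P_STIM_DUR], mode=MODE_CC))
    return segs


def simulate_pacing(p, y0, bcl: float, n_beats: int, *, dt_out: float = 1.0,
                    rtol: float = 1e-7, atol: float = 1e-9) -> SimulationResult:
    """Current-clamp pacing at fixed basic cycle length."""
    res = integrate_segments(y0, beat_segments(bcl, p, n_beats), p,
                             dt_out=dt_out, rtol=rtol, atol=atol)
    res.meta.update({"bcl": bcl, "n_beats": n_beats})
    return res


def pace_to_steady_state(bcl: float, p, y0, *, tol: float = 1e-4,
                         max_beats: int = 1000, dt_out: float = 1.0,
                         rtol: float = 1e-7, atol: float = 1e-9):
    """Pace until end-diastolic states converge beat to beat.

    Convergence criterion: max over states of |change in end-diastolic
    value| / scale < ``tol`` between consecutive beats, where scale is
    max(|value|, 1e-6).  Returns (state, info dict).
    """
    if bcl <= 0:
        raise ValueError("bcl must be positive")
    segs = beat_segments(bcl, p, 1)
    y = np.asarray(y0, dtype=float).copy()
    residuals = []
    for beat in range(max_beats):
        res = integrate_segments(y, segs, p, dt_out=min(dt_out * 10, bcl / 4),
                                 rtol=rtol, atol=atol)
        y_new = res.y[-1]
        scale = np.maximum(np.abs(y), 1e-6)
        resid = float(np.max(np.abs(y_new - y) / scale))
        residuals.append(resid)
        y = y_new
        if resid < tol:
            return y, {"converged": True, "n_beats": beat + 1,
                       "residuals": residuals}
    import warnings
    warnings.warn(
        f"pacing did not converge in {max_beats} beats "
        f"(residual {residuals[-1]:.2e})"
    )
    return y, {"converged": False, "n_beats": max_beats,
               "residuals": residuals}


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def resting_state(p) -> np.ndarray:
    """A physiologically sensible quiescent state (not paced-in)."""
    parr = _as_array(p)
    y = np.zeros(N_STATES)
    v0 = -86.0
    y[IV] = v0
    g = _sar.steady_state_gates(v0, parr)
    y[IG0:IG0 + NG] = g.as_array()
    occ = np.zeros(NCARU)
    occ[0] = 1.0
    y[ICARU0:ICARU0 + NCARU] = occ
    y[ICA_I] = 1.0e-4
    y[ICA_NSR] = 0.7
    y[INA_I] = 7.0
    y[IK_I] = 140.0
    ca = y[ICA_I]
    y[ILTRPN] = parr[P_LTRPN_TOT] * ca / (ca + 0.0196 / 32.7)
    y[IHTRPN] = parr[P_HTRPN_TOT] * ca / (ca + 3.2e-5 / 2.37)
    y[ICMDN] = parr[P_CMDN_TOT] * ca / (ca + 0.081 / 34.0)
    y[ICSQN] = parr[P_CSQN_TOT] * y[ICA_NSR] / (y[ICA_NSR] + 0.63)
    xb = np.zeros(NXB)
    xb[0] = 1.0
    y[IXB0:IXB0 + NXB] = xb
    # matrix: ca_m, nadh, adp_m, dpsi, na_m, isoc, akg, scoa, suc, fum, mal, oaa
    y[IMITO0:IMITO0 + NMITO] = np.array(
        [2.0e-4, 0.6, 0.05, 160.0, 5.0,
         0.1, 0.1, 0.05, 0.05, 0.05, 0.2, 0.01])
    y[IADP_I] = 0.03
    y[ICRP] = 18.0
    return y


def load_initial_state(path=None) -> np.ndarray:
    """Versioned end-diastolic state obtained by long pre-pacing at 1 Hz."""
    if path is None:
        ref = resources.files("gpmyo.data").joinpath("initial_state_1hz.json")
        with ref.open("r") as fh:
            data = json.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    y = np.array([data["state"][n] for n in STATE_NAMES], dtype=float)
    return y


def save_state(y, path, note: str = ""):
    data = {"note": note,
            "state": {n: float(y[i]) for i, n in enumerate(STATE_NAMES)}}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
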