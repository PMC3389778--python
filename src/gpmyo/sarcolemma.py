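"""Non-dyadic sarcolemmal currents and transporters.

Fast Na+ current and inward rectifier follow the Luo-Rudy lineage; the
delayed rectifier is split into rapid and slow components (I_Kr, I_Ks) with
two selectable I_Ks formulations (the two-gate fast/slow variant and the
older single-gate-squared variant with faster deactivation); the Na+/Ca2+
exchanger uses the allosterically Ca2+-regulated formulation; I_K(ATP)
couples the membrane to nucleotide levels.  Sign convention: all currents in
uA/uF, outward positive; dV/dt = -(sum of currents + I_stim).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import RT_OVER_F
from .params import (  # noqa: F401
    P_CA_O, P_IKS_DEACT_SCALE, P_GCAB, P_GK1, P_GKATP, P_GKP, P_GKR, P_GKS_SCALE, P_GNA, P_GNAB,
    P_GTO, P_IKS_VARIANT, P_INAK_MAX, P_IPCA_MAX, P_ITO_ENABLED, P_K_O,
    P_KM_KO_NAK, P_KM_NAI_NAK, P_KM_PCA, P_NA_O, P_NCX_ETA, P_NCX_KM_CA_ACT,
    P_NCX_KM_CAI, P_NCX_KM_CAO, P_NCX_KM_NAI, P_NCX_KM_NAO, P_NCX_KSAT,
    P_NCX_VMAX, P_TAU_Y0, P_TAU_Y_AMP, P_TAU_Y_VMID, P_TAU_Y_WIDTH,
    P_Y_MIN, P_Y_SLOPE, P_Y_VHALF, Parameters,
)

N_GATES = 9  # m, h, j, xkr, xs1, xs2, y (LCC VDI), ito_a, ito_i

IKS_VISWANATHAN99 = 0
IKS_ZENG95 = 1


@dataclass
class GatingState:
    m: float
    h: float
    j: float
    xkr: float
    xs1: float
    xs2: float
    y: float
    ito_a: float = 0.0
    ito_i: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.h, self.j, self.xkr, self.xs1,
                         self.xs2, self.y, self.ito_a, self.ito_i])


@dataclass
class CurrentSet:
    i_na: float
    i_kr: float
    i_ks: float
    i_k1: float
    i_kp: float
    i_katp: float
    i_nak: float
    i_ncx: float
    i_pca: float
    i_cab: float
    i_nab: float
    i_to: float

    def total(self) -> float:
        return (self.i_na + self.i_kr + self.i_ks + self.i_k1 + self.i_kp
                + self.i_katp + self.i_nak + self.i_ncx + self.i_pca
                + self.i_cab + self.i_nab + self.i_to)


# ---------------------------------------------------------------------------
# jitted kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _safe_ratio(num, den):
    """num/den with the L'Hopital value at a removable singularity."""
    if abs(den) < 1e-12:
        return 0.0
    return num / den


@njit(cache=True)
def _na_gate_rates(v):
    if abs(v + 47.13) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * (v + 47.13) / (1.0 - np.exp(-0.1 * (v + 47.13)))
    bm = 0.08 * np.exp(-v / 11.0)
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp((v + 10.66) / -11.1)))
        aj = 0.0
        bj = (0.3 * np.exp(-2.535e-7 * v)
              / (1.0 + np.exp(-0.1 * (v + 32.0))))
    else:
        ah = 0.135 * np.exp((80.0 + v) / -6.8)
        bh = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
        aj = ((-1.2714e5 * np.exp(0.2444 * v)
               - 3.474e-5 * np.exp(-0.04391 * v)) * (v + 37.78)
              / (1.0 + np.exp(0.311 * (v + 79.23))))
        bj = (0.1212 * np.exp(-0.01052 * v)
              / (1.0 + np.exp(-0.1378 * (v + 40.14))))
    return am, bm, ah, bh, aj, bj


@njit(cache=True)
def _xkr_kinetics(v):
    x_inf = 1.0 / (1.0 + np.exp(-(v + 21.5) / 7.5))
    a = _safe_ratio(0.00138 * (v + 14.2), 1.0 - np.exp(-0.123 * (v + 14.2)))
    if abs(v + 14.2) < 1e-6:
        a = 0.00138 / 0.123
    b = _safe_ratio(0.00061 * (v + 38.9), np.exp(0.145 * (v + 38.9)) - 1.0)
    if abs(v + 38.9) < 1e-6:
        b = 0.00061 / 0.145
    tau = 1.0 / (a + b)
    return x_inf, tau


@njit(cache=True)
def _xs_kinetics(v):
    x_inf = 1.0 / (1.0 + np.exp(-(v - 1.5) / 16.7))
    if abs(v + 30.0) < 1e-6:
        a = 7.19e-5 / 0.148
        b = 1.31e-4 / 0.0687
    else:
        a = 7.19e-5 * (v + 30.0) / (1.0 - np.exp(-0.148 * (v + 30.0)))
        b = 1.31e-4 * (v + 30.0) / (np.exp(0.0687 * (v + 30.0)) - 1.0)
    tau1 = 1.0 / (a + b)
    return x_inf, tau1, 4.0 * tau1


@njit(cache=True)
def _gate_derivs(v, gates, p):
    """Time derivatives of the 9 HH gates."""
    d = np.empty(N_GATES)
    am, bm, ah, bh, aj, bj = _na_gate_rates(v)
    d[0] = am * (1.0 - gates[0]) - bm * gates[0]
    d[1] = ah * (1.0 - gates[1]) - bh * gates[1]
    d[2] = aj * (1.0 - gates[2]) - bj * gates[2]
    xri, taur = _xkr_kinetics(v)
    d[3] = (xri - gates[3]) / taur
    xsi, tau1, tau2 = _xs_kinetics(v)
    # deactivation at diastolic potentials is faster than the activation
    # kinetics extrapolate; the scale is calibrated to APD restitution
    deact = 1.0 + (p[P_IKS_DEACT_SCALE] - 1.0) / (1.0 + np.exp((v + 50.0) / 6.0))
    d[4] = (xsi - gates[4]) / tau1 * deact
    d[5] = (xsi - gates[5]) / tau2 * deact
    # LCC voltage-dependent inactivation gate
    y_inf = (p[P_Y_MIN] + (1.0 - p[P_Y_MIN])
             / (1.0 + np.exp((v - p[P_Y_VHALF]) / p[P_Y_SLOPE])))
    arg = (v - p[P_TAU_Y_VMID]) / p[P_TAU_Y_WIDTH]
    tau_y = p[P_TAU_Y0] + p[P_TAU_Y_AMP] * np.exp(-arg * arg)
    d[6] = (y_inf - gates[6]) / tau_y
    # transient outward K+ current gates (inert when the current is disabled)
    a_inf = 1.0 / (1.0 + np.exp(-(v - 19.0) / 13.0))
    tau_a = 0.493 * np.exp(-v / 62.9) + 2.058
    i_inf = 1.0 / (1.0 + np.exp((v + 19.5) / 5.0))
    tau_i = 15.0 + 30.0 / (1.0 + np.exp((v + 45.0) / 10.0))
    d[7] = (a_inf - gates[7]) / tau_a
    d[8] = (i_inf - gates[8]) / tau_i
    return d


@njit(cache=True)
def _currents(v, gates, na_i, k_i, ca_i, atp, adp, p):
    """All sarcolemmal current densities (uA/uF, outward positive).

    Returns an array [INa, IKr, IKs, IK1, IKp, IKATP, INaK, INCX, IpCa,
    ICab, INab, Ito].
    """
    out = np.zeros(12)
    na_o = p[P_NA_O]
    k_o = p[P_K_O]
    ca_o = p[P_CA_O]
    e_na = RT_OVER_F * np.log(na_o / na_i)
    e_k = RT_OVER_F * np.log(k_o / k_i)
    e_ca = 0.5 * RT_OVER_F * np.log(ca_o / ca_i)

    # fast Na+
    m, h, j = gates[0], gates[1], gates[2]
    out[0] = p[P_GNA] * m * m * m * h * j * (v - e_na)

    # rapid delayed rectifier
    r_kr = 1.0 / (1.0 + np.exp((v + 9.0) / 22.4))
    out[1] = (p[P_GKR] * np.sqrt(k_o / 5.4) * gates[3] * r_kr * (v - e_k))

    # slow delayed rectifier (two runtime-selectable formulations)
    e_ks = RT_OVER_F * np.log((k_o + 0.01833 * na_o)
                              / (k_i + 0.01833 * na_i))
    g_ks = (p[P_GKS_SCALE] * 0.433
            * (1.0 + 0.6 / (1.0 + (3.8e-5 / ca_i) ** 1.4)))
    if p[P_IKS_VARIANT] < 0.5:
        out[2] = g_ks * gates[4] * gates[5] * (v - e_ks)
    else:
        out[2] = g_ks * gates[4] * gates[4] * (v - e_ks)

    # inward rectifier
    ak1 = 1.02 / (1.0 + np.exp(0.2385 * (v - e_k - 59.215)))
    bk1 = ((0.49124 * np.exp(0.08032 * (v - e_k + 5.476))
            + np.exp(0.06175 * (v - e_k - 594.31)))
           / (1.0 + np.exp(-0.5143 * (v - e_k + 4.753))))
    out[3] = (p[P_GK1] * np.sqrt(k_o / 5.4) * ak1 / (ak1 + bk1) * (v - e_k))

    # plateau K+
    out[4] = p[P_GKP] * (v - e_k) / (1.0 + np.exp((7.488 - v) / 5.98))

    # ATP-sensitive K+: open fraction falls steeply with ATP, ADP raises the
    # half-saturation point
    adp_um = adp * 1.0e3
    km_atp = (35.8 + 17.9 * adp_um ** 0.256) * 1.0e-3  # mM
    h_atp = 1.3 + 0.74 * np.exp(-0.09 * adp_um)
    f_atp = 1.0 / (1.0 + (atp / km_atp) ** h_atp)
    out[5] = p[P_GKATP] * (k_o / 5.4) ** 0.24 * f_atp * (v - e_k)

    # Na+/K+ pump
    sigma = (np.exp(na_o / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RT_OVER_F)
                   + 0.0365 * sigma * np.exp(-v / RT_OVER_F))
    out[6] = (p[P_INAK_MAX] * f_nak
              / (1.0 + (p[P_KM_NAI_NAK] / na_i) ** 1.5)
              * k_o / (k_o + p[P_KM_KO_NAK]))

    # Na+/Ca2+ exchanger with allosteric Ca2+ activation
    allo = 1.0 / (1.0 + (p[P_NCX_KM_CA_ACT] / ca_i) ** 2)
    eta = p[P_NCX_ETA]
    ef = np.exp(eta * v / RT_OVER_F)
    er = np.exp((eta - 1.0) * v / RT_OVER_F)
    na_i3 = na_i ** 3
    na_o3 = na_o ** 3
    num = na_i3 * ca_o * ef - na_o3 * ca_i * er
    den = (p[P_NCX_KM_CAO] * na_i3 + p[P_NCX_KM_NAO] ** 3 * ca_i
           + p[P_NCX_KM_NAI] ** 3 * ca_o * (1.0 + ca_i / p[P_NCX_KM_CAI])
           + p[P_NCX_KM_CAI] * na_o3 * (1.0 + na_i3 / p[P_NCX_KM_NAI] ** 3)
           + na_i3 * ca_o + na_o3 * ca_i)
    out[7] = (p[P_NCX_VMAX] * allo * num
              / (den * (1.0 + p[P_NCX_KSAT] * er)))

    # sarcolemmal Ca2+ pump
    out[8] = p[P_IPCA_MAX] * ca_i / (ca_i + p[P_KM_PCA])

    # backgrounds
    out[9] = p[P_GCAB] * (v - e_ca)
    out[10] = p[P_GNAB] * (v - e_na)

    # optional fast transient outward K+
    if p[P_ITO_ENABLED] > 0.5:
        out[11] = p[P_GTO] * gates[7] * gates[8] * (v - e_k)
    return out


# ---------------------------------------------------------------------------
# public operation surface
# ---------------------------------------------------------------------------

def _as_array(p) -> np.ndarray:
    return p.as_array() if isinstance(p, Parameters) else np.asarray(p)


def compute_currents(v: float, gates: GatingState, na_i: float, k_i: float,
                     ca_i: float, atp: float, adp: float, p) -> CurrentSet:
    """All non-dyadic membrane current densities at one instant."""
    for c in (na_i, k_i, ca_i, atp):
        if not (c > 0.0):
            raise ValueError(f"non-physical concentration: {c}")
    g = gates.as_array() if isinstance(gates, GatingState) else np.asarray(gates)
    vals = _currents(v, g, na_i, k_i, ca_i, atp, adp, _as_array(p))
    return CurrentSet(*[float(x) for x in vals])


def gate_derivatives(v: float, gates, p, iks_variant: str | None = None):
    """Time derivatives of all Hodgkin-Huxley gates.

    ``iks_variant`` may override the parameter-file selection
    ('viswanathan99' or 'zeng95'); the variant only changes which gates the
    current formula reads, not the gate kinetics themselves.
    """
    if iks_variant is not None and iks_variant not in (
            "viswanathan99", "zeng95"):
        raise ValueError(f"unknown IKs variant: {iks_variant!r}")
    g = gates.as_array() if isinstance(gates, GatingState) else np.asarray(gates)
    return _gate_derivs(v, g, _as_array(p))


def steady_state_gates(v: float, p) -> GatingState:
    """Gate values at their voltage steady state (derivatives vanish)."""
    parr = _as_array(p)
    am, bm, ah, bh, aj, bj = _na_gate_rates(v)
    xri, _ = _xkr_kinetics(v)
    xsi, _, _ = _xs_kinetics(v)
    y_inf = (parr[P_Y_MIN] + (1.0 - parr[P_Y_MIN])
             / (1.0 + np.exp((v - parr[P_Y_VHALF]) / parr[P_Y_SLOPE])))
    a_inf = 1.0 / (1.0 + np.exp(-(v - 19.0) / 13.0))
    i_inf = 1.0 / (1.0 + np.exp((v + 19.5) / 5.0))
    return GatingState(
        m=am / (am + bm), h=ah / (ah + bh) if (ah + bh) > 0 else 0.0,
        j=aj / (aj + bj) if (aj + bj) > 0 else 0.0,
        xkr=xri, xs1=xsi, xs2=xsi, y=y_inf, ito_a=a_inf, ito_i=i_inf,
    )


def i_to_fast(v: float, gates, p, k_i: float = 140.0) -> float:
    """Optional fast transient outward K+ current (0 when disabled)."""
    parr = _as_array(p)
    if parr[P_GTO] < 0.0:
        raise ValueError("negative conductance")
    if parr[P_ITO_ENABLED] < 0.5:
        return 0.0
    g = gates.as_array() if isinstance(gates, GatingState) else np.asarray(gates)
    e_k = RT_OVER_F * np.log(parr[P_K_O] / k_i)
    return float(parr[P_GTO] * g[7] * g[8] * (v - e_k))
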