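"""Mitochondrial energetics and Ca2+ handling.

A Ca2+-regulated TCA cycle supplies NADH; respiration oxidizes NADH and
pumps protons to maintain the inner-membrane potential (dpsi); the F1F0
ATPase consumes the proton-motive force to phosphorylate matrix ADP; the
adenine nucleotide translocator (ANT) exchanges matrix ATP for cytosolic
ADP; the Ca2+ uniporter (dpsi-driven) and the mitochondrial Na+/Ca2+
exchanger cycle Ca2+ across the inner membrane, with a Na+/H+ exchanger
closing the Na+ loop.  Matrix Ca2+ is strongly buffered (fractional free
buffer coefficient ``f_ca_m``), which is what limits beat-to-beat matrix
Ca2+ variation and makes the mitochondria a low-pass filter of the
cytosolic transient.

All fluxes in this module are referenced to matrix volume (mM/ms); the cell
model converts to cytosolic reference with ``v_mito / v_myo`` in exactly one
place.  NADH + NAD+ and matrix ATP + ADP are conserved pools handled
algebraically.

Matrix-state layout used by the kernels (and by the assembled cell model):
``[ca_m, nadh, adp_m, dpsi, na_m, isoc, akg, scoa, suc, fum, mal, oaa]``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import RT_OVER_F
from .params import (  # noqa: F401
    P_ACCOA, P_ADN_TOT_M, P_CMITO, P_DPSI_F1_HALF, P_DPSI_O_HALF, P_F_ANT,
    P_F_CA_M, P_G_H_LEAK, P_H_I, P_H_M, P_KA_CA_IDH, P_KA_CA_KGDH,
    P_KAPPA_F1, P_KAPPA_O, P_KEQ_FH, P_KM_ADP_SL, P_KM_AKG, P_KM_F1_ADP,
    P_KM_ISOC, P_KM_MAL, P_KM_NAD_IDH, P_KM_NAD_MDH, P_KM_O_NADH,
    P_KM_OAA_CS, P_KM_SCOA, P_KM_SUC, P_MNCX_KM_CA, P_MNCX_KM_NA,
    P_MNCX_N_NA, P_NAD_TOT, P_NH_F1, P_NH_O, P_NH_SDH, P_NHE_KM_H,
    P_NHE_KM_NA, P_UNI_DPSI0, P_UNI_KACT, P_UNI_KTRANS, P_UNI_L,
    P_UNI_NA_EXP, P_VMAX_ANT, P_VMAX_CS, P_VMAX_F1, P_VMAX_FH, P_VMAX_IDH,
    P_VMAX_KGDH, P_VMAX_MDH, P_VMAX_MNCX, P_VMAX_NHE, P_VMAX_O, P_VMAX_SDH,
    P_VMAX_SL, P_VMAX_UNI, P_VMUNI_SCALE, Parameters,
)

N_MITO = 12
(IM_CAM, IM_NADH, IM_ADPM, IM_DPSI, IM_NAM, IM_ISOC, IM_AKG, IM_SCOA,
 IM_SUC, IM_FUM, IM_MAL, IM_OAA) = range(N_MITO)


@njit(cache=True)
def _uniporter(ca_i, dpsi, p):
    """Ca2+ uniporter uptake (matrix-referenced mM/ms), allosteric form."""
    ktrans = p[P_UNI_KTRANS]
    r = ca_i / ktrans
    act = (1.0 + ca_i / p[P_UNI_KACT]) ** p[P_UNI_NA_EXP]
    frac = r * (1.0 + r) ** 3 / ((1.0 + r) ** 4 + p[P_UNI_L] / act)
    z = 2.0 * (dpsi - p[P_UNI_DPSI0]) / RT_OVER_F
    if abs(z) < 1e-6:
        drive = 1.0 + 0.5 * z
    else:
        drive = z / (1.0 - np.exp(-z))
    return p[P_VMUNI_SCALE] * p[P_VMAX_UNI] * frac * drive


@njit(cache=True)
def _mncx(ca_m, na_i, p):
    """Na+-coupled matrix Ca2+ efflux (matrix-referenced mM/ms)."""
    na_frac = (na_i ** p[P_MNCX_N_NA]
               / (p[P_MNCX_KM_NA] ** p[P_MNCX_N_NA] + na_i ** p[P_MNCX_N_NA]))
    return p[P_VMAX_MNCX] * na_frac * ca_m / (ca_m + p[P_MNCX_KM_CA])


@njit(cache=True)
def _nhe(na_m, na_i, p):
    """Na+/H+ exchanger: matrix Na+ efflux (matrix-referenced mM/ms)."""
    num = na_m * p[P_H_I] - na_i * p[P_H_M]
    den = (na_m + na_i + p[P_NHE_KM_NA]) * (p[P_H_I] + p[P_H_M] + p[P_NHE_KM_H])
    return p[P_VMAX_NHE] * num / den


@njit(cache=True)
def _energetics(mito, ca_i, na_i, adp_i, atp_i, p):
    """Matrix-state derivatives plus exported fluxes.

    Returns (d_mito[12], v_ant, j_uni, j_mncx, v_o2) with all fluxes
    matrix-referenced.  ``v_ant`` is the rate of ATP export (= cytosolic ADP
    consumption when converted to cytosolic reference); ``v_o2`` is the
    NADH-linked respiration rate used as the respiration readout.
    """
    d = np.zeros(N_MITO)
    ca_m = mito[IM_CAM]
    nadh = mito[IM_NADH]
    adp_m = mito[IM_ADPM]
    dpsi = mito[IM_DPSI]
    na_m = mito[IM_NAM]
    nad = p[P_NAD_TOT] - nadh
    atp_m = p[P_ADN_TOT_M] - adp_m

    # --- TCA cycle (citrate/aconitase lumped into the CS step) ---
    v_cs = p[P_VMAX_CS] * mito[IM_OAA] / (mito[IM_OAA] + p[P_KM_OAA_CS])
    km_isoc = p[P_KM_ISOC] / (1.0 + ca_m / p[P_KA_CA_IDH])
    v_idh = (p[P_VMAX_IDH] * mito[IM_ISOC] / (mito[IM_ISOC] + km_isoc)
             * nad / (nad + p[P_KM_NAD_IDH]))
    km_akg = p[P_KM_AKG] / (1.0 + ca_m / p[P_KA_CA_KGDH])
    v_kgdh = (p[P_VMAX_KGDH] * mito[IM_AKG] / (mito[IM_AKG] + km_akg)
              * nad / (nad + p[P_KM_NAD_IDH]))
    v_sl = (p[P_VMAX_SL] * mito[IM_SCOA] / (mito[IM_SCOA] + p[P_KM_SCOA])
            * adp_m / (adp_m + p[P_KM_ADP_SL]))
    v_sdh = p[P_VMAX_SDH] * mito[IM_SUC] / (mito[IM_SUC] + p[P_KM_SUC])
    v_fh = p[P_VMAX_FH] * (mito[IM_FUM] - mito[IM_MAL] / p[P_KEQ_FH])
    v_mdh = (p[P_VMAX_MDH] * mito[IM_MAL] / (mito[IM_MAL] + p[P_KM_MAL])
             * nad / (nad + p[P_KM_NAD_MDH]))

    # --- oxidative phosphorylation ---
    v_o = (p[P_VMAX_O] * nadh / (nadh + p[P_KM_O_NADH])
           / (1.0 + np.exp((dpsi - p[P_DPSI_O_HALF]) / p[P_KAPPA_O])))
    v_f1 = (p[P_VMAX_F1] * adp_m / (adp_m + p[P_KM_F1_ADP])
            / (1.0 + np.exp(-(dpsi - p[P_DPSI_F1_HALF]) / p[P_KAPPA_F1])))
    # adenine nucleotide translocator (electrogenic ATP4-/ADP3- exchange)
    ratio = (atp_i * adp_m) / (adp_i * atp_m)
    v_ant = (p[P_VMAX_ANT]
             * (1.0 - ratio * np.exp(-dpsi / RT_OVER_F))
             / ((1.0 + (atp_i / adp_i) * np.exp(-p[P_F_ANT] * dpsi / RT_OVER_F))
                * (1.0 + adp_m / atp_m)))
    v_leak = p[P_G_H_LEAK] * dpsi

    j_uni = _uniporter(ca_i, dpsi, p)
    j_mncx = _mncx(ca_m, na_i, p)
    j_nhe = _nhe(na_m, na_i, p)

    d[IM_CAM] = p[P_F_CA_M] * (j_uni - j_mncx)
    d[IM_NADH] = v_idh + v_kgdh + v_mdh - v_o
    d[IM_ADPM] = v_ant - v_f1 - v_sl
    d[IM_DPSI] = (p[P_NH_O] * v_o + p[P_NH_SDH] * v_sdh
                  - p[P_NH_F1] * v_f1 - v_ant - 2.0 * j_uni
                  - (p[P_MNCX_N_NA] - 2.0) * j_mncx
                  - v_leak) / p[P_CMITO]
    d[IM_NAM] = p[P_MNCX_N_NA] * j_mncx - j_nhe
    d[IM_ISOC] = v_cs - v_idh
    d[IM_AKG] = v_idh - v_kgdh
    d[IM_SCOA] = v_kgdh - v_sl
    d[IM_SUC] = v_sl - v_sdh
    d[IM_FUM] = v_sdh - v_fh
    d[IM_MAL] = v_fh - v_mdh
    d[IM_OAA] = v_mdh - v_cs
    return d, v_ant, j_uni, j_mncx, v_o


# ---------------------------------------------------------------------------
# public operation surface
# ---------------------------------------------------------------------------

def _as_array(p) -> np.ndarray:
    return p.as_array() if isinstance(p, Parameters) else np.asarray(p)


def uniporter_flux(ca_i: float, dpsi: float, p,
                   vmuni_scale: float | None = None) -> float:
    """Uniporter Ca2+ uptake into the matrix (matrix-referenced mM/ms).

    ``vmuni_scale`` (fraction of the control maximal rate) overrides the
    parameter-file value; the block experiment uses 0.25.
    """
    parr = _as_array(p).copy()
    if vmuni_scale is not None:
        if not (0.0 <= vmuni_scale <= 1.0):
            raise ValueError("vmuni_scale must be in [0, 1]")
        parr[P_VMUNI_SCALE] = vmuni_scale
    return float(_uniporter(ca_i, dpsi, parr))


def mito_ca_exchanger_flux(ca_m: float, na_i: float, na_m: float,
                           dpsi: float, p) -> float:
    """Mitochondrial Na+/Ca2+ exchanger: matrix Ca2+ efflux (mM/ms)."""
    if ca_m < 0.0 or na_i < 0.0:
        raise ValueError("concentrations must be non-negative")
    return float(_mncx(ca_m, na_i, _as_array(p)))


def mito_nhe_flux(na_m: float, na_i: float, p) -> float:
    """Mitochondrial Na+/H+ exchanger: matrix Na+ efflux (mM/ms).

    Vanishes when the Na+ gradient equals the H+ gradient
    (na_m / na_i = h_m / h_i), the exchanger's equilibrium.
    """
    if na_m < 0.0 or na_i < 0.0:
        raise ValueError("concentrations must be non-negative")
    return float(_nhe(na_m, na_i, _as_array(p)))


def energetics_derivatives(mito, ca_i: float, na_i: float, adp_i: float,
                           atp_i: float, p):
    """Derivatives of the 12 matrix states plus exported fluxes.

    Returns ``(d_mito, v_ant, j_uni, j_mncx, v_o2)``.  Raises on
    non-physical pool totals.
    """
    parr = _as_array(p)
    mito = np.asarray(mito, dtype=float)
    if mito.shape != (N_MITO,):
        raise ValueError(f"matrix state must have length {N_MITO}")
    if not (0.0 <= mito[IM_NADH] <= parr[P_NAD_TOT]):
        raise ValueError("NADH outside the conserved NAD pool")
    if not (0.0 <= mito[IM_ADPM] <= parr[P_ADN_TOT_M]):
        raise ValueError("ADP_m outside the conserved adenine pool")
    d, v_ant, j_uni, j_mncx, v_o = _energetics(mito, ca_i, na_i, adp_i,
                                               atp_i, parr)
    return d, float(v_ant), float(j_uni), float(j_mncx), float(v_o)
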