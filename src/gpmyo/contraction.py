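"""Isometric force generation (tropomyosin/crossbridge model).

Six-state tropomyosin/crossbridge scheme of the Rice lineage as used in
integrated excitation-contraction/energetics models: nonpermissive states
N0, N1 and permissive states
P0..P3, where P1..P3 (and N1) carry strongly bound crossbridges.  The
permissive/nonpermissive switch is controlled by the fraction of
Ca2+-loaded low-affinity troponin, which couples the force model back into
cytosolic Ca2+ buffering; crossbridge detachment consumes ATP via the
acto-myosin ATPase, which couples it forward into the energetics.
Sarcomere length is fixed (isometric), with no length-dependent activation.

Crossbridge-state layout: ``[n0, n1, p0, p1, p2, p3]`` (occupancies, sum 1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import (  # noqa: F401
    P_BASAL_ATPASE, P_C_ATPASE, P_FMAX_MN, P_FNORM_MAX, P_HTRPN_KOFF,
    P_HTRPN_KON, P_HTRPN_TOT, P_K_PN_BASIC, P_LTRPN_KOFF, P_LTRPN_KON,
    P_LTRPN_TOT, P_N_PERM, P_PERM50, P_XB_F01, P_XB_F12, P_XB_F23, P_XB_G01,
    P_XB_G12, P_XB_G23, P_XSEC_AREA, Parameters,
)

N_XB = 6
IX_N0, IX_N1, IX_P0, IX_P1, IX_P2, IX_P3 = range(N_XB)


@njit(cache=True)
def _xb_derivs(xb, ltrpn_frac, p):
    """Crossbridge-state derivatives, normalized force, ATPase rate."""
    n0, n1, p0, p1, p2, p3 = xb[0], xb[1], xb[2], xb[3], xb[4], xb[5]
    perm = ltrpn_frac
    pn = perm ** p[P_N_PERM]
    hill = pn / (pn + p[P_PERM50] ** p[P_N_PERM])
    k_np = p[P_K_PN_BASIC] * hill
    k_pn = p[P_K_PN_BASIC] * (1.0 - hill)

    f01, f12, f23 = p[P_XB_F01], p[P_XB_F12], p[P_XB_F23]
    g01, g12, g23 = p[P_XB_G01], p[P_XB_G12], p[P_XB_G23]

    d = np.empty(N_XB)
    d[IX_N0] = k_pn * p0 - k_np * n0 + g01 * n1
    d[IX_N1] = k_pn * p1 - k_np * n1 - g01 * n1
    d[IX_P0] = k_np * n0 - k_pn * p0 - f01 * p0 + g01 * p1
    d[IX_P1] = (f01 * p0 - (g01 + f12 + k_pn) * p1 + g12 * p2 + k_np * n1)
    d[IX_P2] = f12 * p1 - (g12 + f23) * p2 + g23 * p3
    d[IX_P3] = f23 * p2 - g23 * p3

    f_norm = (p1 + n1 + 2.0 * p2 + 3.0 * p3) / p[P_FNORM_MAX]
    atpase = (p[P_C_ATPASE] * (g01 * (p1 + n1) + g12 * p2 + g23 * p3)
              + p[P_BASAL_ATPASE])
    return d, f_norm, atpase


@njit(cache=True)
def _troponin_derivs(ca_i, ltrpn, htrpn, p):
    """d/dt of Ca2+-bound low- and high-affinity troponin (mM)."""
    d_l = (p[P_LTRPN_KON] * ca_i * (p[P_LTRPN_TOT] - ltrpn)
           - p[P_LTRPN_KOFF] * ltrpn)
    d_h = (p[P_HTRPN_KON] * ca_i * (p[P_HTRPN_TOT] - htrpn)
           - p[P_HTRPN_KOFF] * htrpn)
    return d_l, d_h


def _as_array(p) -> np.ndarray:
    return p.as_array() if isinstance(p, Parameters) else np.asarray(p)


def crossbridge_derivatives(xb, ca_i: float, ltrpn: float, htrpn: float, p):
    """Crossbridge derivatives plus the couplings to Ca2+ and energetics.

    Returns ``(d_xb, d_ltrpn, d_htrpn, f_norm, atpase)`` where the troponin
    derivatives are the Ca2+ flux into the buffers (fed back to the Ca2+
    balance) and ``atpase`` is ATP consumption in mM/ms.
    """
    xb = np.asarray(xb, dtype=float)
    if xb.shape != (N_XB,):
        raise ValueError(f"crossbridge state must have length {N_XB}")
    if abs(xb.sum() - 1.0) > 1e-6:
        raise AssertionError("crossbridge occupancies do not sum to 1")
    parr = _as_array(p)
    d, f_norm, atpase = _xb_derivs(xb, ltrpn / parr[P_LTRPN_TOT], parr)
    d_l, d_h = _troponin_derivs(ca_i, ltrpn, htrpn, parr)
    return d, float(d_l), float(d_h), float(f_norm), float(atpase)


def normalized_force(xb, p) -> float:
    """Normalized isometric force in [0, 1] for a crossbridge state."""
    parr = _as_array(p)
    _, f_norm, _ = _xb_derivs(np.asarray(xb, dtype=float), 1.0, parr)
    return float(f_norm)


def force_to_stress(f_norm: float, p) -> float:
    """Convert normalized force to stress (mN/mm^2).

    Uses the lineage maximal-force constant and the printed fiber
    cross-sectional area (0.013 mm^2).
    """
    parr = _as_array(p)
    return float(f_norm * parr[P_FMAX_MN] / parr[P_XSEC_AREA])
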