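"""SR uptake, Ca2+ buffering, and the cytosolic / NSR Ca2+ balance.

The junctional SR is merged with the network SR (rapid-refilling
assumption), so the SR is a single compartment filled by SERCa and drained
by RyR release into the dyadic subspaces.  Buffers (calmodulin and the SR
buffer here; troponin in the contraction module) are dynamic ODE states, not
rapid-buffer approximations, so that troponin occupancy can be shared with
the force model and total Ca2+ is exactly conservable.

Volume referencing: every flux entering the cytosolic balance is expressed
per cytosolic volume; SR-referenced quantities are converted with the ratio
``v_myo / v_sr`` at exactly one point (the balance function below).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import (  # noqa: F401
    P_CMDN_KOFF, P_CMDN_KON, P_CMDN_TOT, P_CSQN_KOFF, P_CSQN_KON, P_CSQN_TOT,
    P_SERCA_KFB, P_SERCA_KM_ATP, P_SERCA_KRB, P_SERCA_NFB, P_SERCA_NRB,
    P_SERCA_VMAXF, P_SERCA_VMAXR, P_V_MYO, P_V_SR, Parameters,
)


@njit(cache=True)
def _serca(ca_i, ca_nsr, atp, p):
    """SERCa pump flux, cytosol-referenced mM/ms (positive = uptake)."""
    fb = (ca_i / p[P_SERCA_KFB]) ** p[P_SERCA_NFB]
    rb = (ca_nsr / p[P_SERCA_KRB]) ** p[P_SERCA_NRB]
    f_atp = atp / (atp + p[P_SERCA_KM_ATP])
    return (f_atp * (p[P_SERCA_VMAXF] * fb - p[P_SERCA_VMAXR] * rb)
            / (1.0 + fb + rb))


@njit(cache=True)
def _buffer_fluxes(ca_i, ca_nsr, cmdn, csqn, p):
    """d/dt of bound calmodulin (cytosol) and SR buffer (SR-referenced)."""
    d_cmdn = (p[P_CMDN_KON] * ca_i * (p[P_CMDN_TOT] - cmdn)
              - p[P_CMDN_KOFF] * cmdn)
    d_csqn = (p[P_CSQN_KON] * ca_nsr * (p[P_CSQN_TOT] - csqn)
              - p[P_CSQN_KOFF] * csqn)
    return d_cmdn, d_csqn


def _as_array(p) -> np.ndarray:
    return p.as_array() if isinstance(p, Parameters) else np.asarray(p)


def serca_flux(ca_i: float, ca_nsr: float, atp: float, p) -> float:
    """Forward/reverse SERCa pump flux (mM/ms, cytosol-referenced)."""
    if not (ca_i > 0.0 and ca_nsr > 0.0 and atp > 0.0):
        raise ValueError("concentrations must be positive")
    return float(_serca(ca_i, ca_nsr, atp, _as_array(p)))


def ca_balance(ca_i: float, ca_nsr: float, cmdn: float, csqn: float, *,
               j_xfer_cyto: float, j_rel_sr: float, j_trpn: float,
               j_sl_net: float, j_mito_net: float, atp: float, p):
    """Cytosolic and NSR free-Ca2+ derivatives.

    Flux arguments (all mM/ms): ``j_xfer_cyto`` subspace-to-cytosol transfer
    (cytosol-referenced), ``j_rel_sr`` RyR release out of the SR
    (SR-referenced), ``j_trpn`` net Ca2+ binding to troponin (cytosolic),
    ``j_sl_net`` net sarcolemmal Ca2+ influx (cytosol-referenced),
    ``j_mito_net`` net mitochondrial uptake from cytosol
    (cytosol-referenced).
    """
    parr = _as_array(p)
    j_up = _serca(ca_i, ca_nsr, atp, parr)
    d_cmdn, d_csqn = _buffer_fluxes(ca_i, ca_nsr, cmdn, csqn, parr)
    vr = parr[P_V_MYO] / parr[P_V_SR]
    d_ca_i = (j_xfer_cyto - j_up + j_sl_net - j_mito_net - j_trpn - d_cmdn)
    d_ca_nsr = j_up * vr - j_rel_sr - d_csqn
    return d_ca_i, d_ca_nsr, d_cmdn, d_csqn


def total_sr_ca(ca_nsr: float, csqn: float, p) -> float:
    """Total SR Ca2+ (free + buffered), SR-referenced mM."""
    return float(ca_nsr + csqn)
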