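"""Coupled LCC-RyR Ca2+ release unit (CaRU).

The release unit pairs one L-type Ca2+ channel (LCC) with a cluster of five
simultaneously gating ryanodine receptors (RyRs), represented by a single RyR
whose unitary flux is five times the single-channel value.  LCC gating is a
10-state Markov chain (a 5-state activation/opening chain duplicated in a
"mode normal" and a Ca2+-inactivated "mode Ca"); RyR gating is a 4-state
scheme (closed -> primed -> open -> inactivated -> closed).  The joint chain
therefore has 40 states, indexed ``(lcc_state - 1) * 4 + ryr_state`` to match
the grid layout of the source scheme (0-based in code: ``il * 4 + ir``).

Dyadic subspace Ca2+ equilibrates much faster than any gating process, so for
each of the four open/closed dyad configurations it is given by the algebraic
steady state of the subspace balance

    0 = J_LCC(Ca_ss) + J_RyR(Ca_ss) + (Ca_i - Ca_ss) / tau_ss,

which is linear in ``Ca_ss`` because the LCC flux is GHK-form (linear in the
subspace concentration at fixed voltage) and the RyR flux is proportional to
the NSR-subspace gradient.  Transition rates that sense dyadic Ca2+ (RyR
activation/inactivation, LCC Ca2+-dependent inactivation) use the subspace
concentration of the configuration of their source state; this is what
couples the two channels and produces graded release with voltage-dependent
gain.

Voltage-dependent inactivation of the LCC is carried by a separate
Hodgkin-Huxley availability gate (state ``y`` in the whole-cell model); the
Markov chain carries activation and Ca2+-dependent inactivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import FARADAY, RT_OVER_F
from .params import (  # noqa: F401  (index constants resolved at jit time)
    P_CA_O, P_CM, P_J_L, P_J_R_SINGLE, P_LCC_ALPHA0, P_LCC_BETA0, P_LCC_F,
    P_LCC_F_CA_RATIO, P_LCC_G, P_LCC_KA_CDI, P_LCC_KCDI, P_LCC_OMEGA,
    P_LCC_S_ALPHA,
    P_LCC_S_BETA, P_LCC_V_ALPHA, P_LCC_V_BETA, P_N_CARU, P_RYR_K21, P_RYR_K32,
    P_RYR_K34, P_RYR_K41, P_RYR_KA, P_RYR_KB, P_RYR_KINACT_CA, P_RYR_N_ACT,
    P_TAU_SS,
    P_V_MYO, P_V_SR, P_V_SS, Parameters,
)

N_LCC = 10
N_RYR = 4
N_STATES = N_LCC * N_RYR

LCC_OPEN_STATE = 4      # open state of mode normal (0-based); mode-Ca "open"
                        # state (9) is non-conducting
RYR_OPEN_STATE = 2

RYR_CLUSTER_SIZE = 5.0  # one model RyR stands for a cluster of 5 channels


def joint_index(lcc_state: int, ryr_state: int) -> int:
    """0-based joint index for (lcc_state, ryr_state), each 0-based."""
    return lcc_state * N_RYR + ryr_state


@dataclass(frozen=True)
class DyadConfig:
    """Open/closed macrostate of one dyad."""
    lcc_open: bool
    ryr_open: bool


CONFIGS = (
    DyadConfig(False, False),
    DyadConfig(True, False),
    DyadConfig(False, True),
    DyadConfig(True, True),
)


@dataclass
class CaRUFluxes:
    """Ensemble-average dyadic fluxes and the whole-cell L-type current.

    ``j_lcc`` and ``j_ryr`` are referenced to subspace volume (mM/ms);
    ``i_cal`` is the whole-cell current density in uA/uF (outward positive,
    hence negative for Ca2+ influx).
    """
    j_lcc: float
    j_ryr: float
    i_cal: float


# ---------------------------------------------------------------------------
# jitted kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ghk_terms(v, p):
    """GHK influx decomposition: J_LCC = src - slope * ca_ss.

    Returns (src, slope) with src = j_l * phi * ca_o * exp(-z) and
    slope = j_l * phi, where z = 2 V / (RT/F), phi = z / (1 - exp(-z)).
    """
    z = 2.0 * v / RT_OVER_F
    if abs(z) < 1e-6:
        phi = 1.0 + 0.5 * z          # series limit, keeps C1 continuity
    else:
        phi = z / (1.0 - np.exp(-z))
    src = p[P_J_L] * phi * p[P_CA_O] * np.exp(-z)
    slope = p[P_J_L] * phi
    return src, slope


@njit(cache=True)
def _subspace_ca(lcc_open, ryr_open, v, ca_i, ca_nsr, p):
    """Rapid-equilibrium subspace Ca2+ for one dyad configuration."""
    jr = RYR_CLUSTER_SIZE * p[P_J_R_SINGLE]
    inv_tau = 1.0 / p[P_TAU_SS]
    a = ca_i * inv_tau
    b = inv_tau
    if lcc_open:
        src, slope = _ghk_terms(v, p)
        a += src
        b += slope
    if ryr_open:
        a += jr * ca_nsr
        b += jr
    return a / b


@njit(cache=True)
def _subspace_ca_four(v, ca_i, ca_nsr, p):
    """Subspace Ca2+ for the four macrostates (cc, oc, co, oo)."""
    out = np.empty(4)
    out[0] = _subspace_ca(False, False, v, ca_i, ca_nsr, p)
    out[1] = _subspace_ca(True, False, v, ca_i, ca_nsr, p)
    out[2] = _subspace_ca(False, True, v, ca_i, ca_nsr, p)
    out[3] = _subspace_ca(True, True, v, ca_i, ca_nsr, p)
    return out


@njit(cache=True)
def _lcc_alpha_beta(v, p):
    a = p[P_LCC_ALPHA0] * np.exp((v - p[P_LCC_V_ALPHA]) / p[P_LCC_S_ALPHA])
    b = p[P_LCC_BETA0] * np.exp(-(v - p[P_LCC_V_BETA]) / p[P_LCC_S_BETA])
    return a, b


@njit(cache=True)
def _build_generator(v, ca_i, ca_nsr, p):
    """40x40 transition-rate matrix A, A[i, j] = rate i -> j, rows sum to 0."""
    A = np.zeros((N_STATES, N_STATES))
    ca4 = _subspace_ca_four(v, ca_i, ca_nsr, p)
    alpha, beta = _lcc_alpha_beta(v, p)
    ka = p[P_RYR_KA]
    kb = p[P_RYR_KB]
    kinact = p[P_RYR_KINACT_CA]

    for il in range(N_LCC):
        lcc_open = il == LCC_OPEN_STATE
        for ir in range(N_RYR):
            ryr_open = ir == RYR_OPEN_STATE
            i = il * N_RYR + ir
            cfg = (1 if lcc_open else 0) + (2 if ryr_open else 0)
            ca_ss = ca4[cfg]

            # --- LCC transitions (ryr index fixed) ---
            mode_ca = il >= 5
            s = il - 5 if mode_ca else il            # position within mode
            # activation chain C0-C1-C2-C3
            if s < 3:
                A[i, (il + 1) * N_RYR + ir] += (3.0 - s) * alpha
            if 1 <= s <= 3:
                A[i, (il - 1) * N_RYR + ir] += s * beta
            # opening step C3 <-> O
            if s == 3:
                f = p[P_LCC_F] * (p[P_LCC_F_CA_RATIO] if mode_ca else 1.0)
                A[i, (il + 1) * N_RYR + ir] += f
            if s == 4:
                A[i, (il - 1) * N_RYR + ir] += p[P_LCC_G]
            # mode switching (Ca2+-dependent inactivation); the rate is
            # superlinear at sub-uM Ca2+ so that dyadic release, not
            # resting cytosolic Ca2+, drives inactivation
            if mode_ca:
                A[i, (il - 5) * N_RYR + ir] += p[P_LCC_OMEGA]
            else:
                A[i, (il + 5) * N_RYR + ir] += (p[P_LCC_KCDI] * ca_ss * ca_ss
                                                / (ca_ss + p[P_LCC_KA_CDI]))

            # --- RyR transitions (lcc index fixed) ---
            # activation is steeply Ca2+-dependent so that the dyadic
            # trigger, not resting cytosolic Ca2+, gates release
            ca2 = ca_ss * ca_ss
            if ir == 0:
                A[i, il * N_RYR + 1] += ka * ca_ss ** p[P_RYR_N_ACT]
            elif ir == 1:
                A[i, il * N_RYR + 0] += p[P_RYR_K21]
                A[i, il * N_RYR + 2] += kb * ca2
            elif ir == 2:
                A[i, il * N_RYR + 1] += p[P_RYR_K32]
                A[i, il * N_RYR + 3] += p[P_RYR_K34]
            else:
                r = ca_ss / kinact
                A[i, il * N_RYR + 0] += p[P_RYR_K41] / (1.0 + r * r)

    for i in range(N_STATES):
        s = 0.0
        for j in range(N_STATES):
            if j != i:
                s += A[i, j]
        A[i, i] = -s
    return A


@njit(cache=True)
def _occupancy_derivative(dist, v, ca_i, ca_nsr, p):
    A = _build_generator(v, ca_i, ca_nsr, p)
    return A.T @ dist


@njit(cache=True)
def _fluxes(dist, v, ca_i, ca_nsr, p):
    """Ensemble fluxes.

    Returns (j_lcc, j_ryr, i_cal, j_xfer, avg_ca_ss):
      j_lcc, j_ryr  subspace-referenced mM/ms
      i_cal         uA/uF whole cell
      j_xfer        subspace->cytosol diffusive flux, subspace-referenced
      avg_ca_ss     probability-weighted subspace Ca2+ (mM)
    """
    ca4 = _subspace_ca_four(v, ca_i, ca_nsr, p)
    src, slope = _ghk_terms(v, p)
    jr = RYR_CLUSTER_SIZE * p[P_J_R_SINGLE]
    inv_tau = 1.0 / p[P_TAU_SS]

    j_lcc = 0.0
    j_ryr = 0.0
    j_xfer = 0.0
    avg = 0.0
    for il in range(N_LCC):
        lcc_open = il == LCC_OPEN_STATE
        for ir in range(N_RYR):
            ryr_open = ir == RYR_OPEN_STATE
            i = il * N_RYR + ir
            pi = dist[i]
            if pi == 0.0:
                continue
            cfg = (1 if lcc_open else 0) + (2 if ryr_open else 0)
            ca_ss = ca4[cfg]
            if lcc_open:
                j_lcc += pi * (src - slope * ca_ss)
            if ryr_open:
                j_ryr += pi * jr * (ca_nsr - ca_ss)
            j_xfer += pi * (ca_ss - ca_i) * inv_tau
            avg += pi * ca_ss

    # whole-cell current: flux (mM/ms, subspace-ref) * V_ss(uL) -> nmol/ms;
    # * 2F (C/mmol) -> uC/ms = mA; /Cm(uF) with mA->uA factor 1e3.
    i_cal = -j_lcc * p[P_V_SS] * 2.0 * FARADAY * 1.0e3 / p[P_CM]
    return j_lcc, j_ryr, i_cal, j_xfer, avg


@njit(cache=True)
def _gillespie_pairs(t_grid, v_trace, ca_i_trace, ca_nsr_trace, p, n_pairs,
                     seed):
    """Monte-Carlo simulation of independent LCC-RyR pairs.

    Rates are held constant within each grid interval (the trace sampling is
    assumed fine relative to V and Ca dynamics).  Returns occupancy
    fractions, shape (len(t_grid), 40); pairs all start in joint state 0.
    """
    np.random.seed(seed)
    n_t = len(t_grid)
    occ = np.zeros((n_t, N_STATES))
    states = np.zeros(n_pairs, dtype=np.int64)

    for k in range(n_t):
        for s in range(n_pairs):
            occ[k, states[s]] += 1.0
        if k == n_t - 1:
            break
        A = _build_generator(v_trace[k], ca_i_trace[k], ca_nsr_trace[k], p)
        dt_total = t_grid[k + 1] - t_grid[k]
        for s in range(n_pairs):
            t = 0.0
            st = states[s]
            while True:
                rate = -A[st, st]
                if rate <= 0.0:
                    break
                dt = -np.log(np.random.random()) / rate
                if t + dt > dt_total:
                    break
                t += dt
                # sample destination
                u = np.random.random() * rate
                acc = 0.0
                for j in range(N_STATES):
                    if j == st:
                        continue
                    acc += A[st, j]
                    if acc >= u:
                        st = j
                        break
            states[s] = st
    occ /= n_pairs
    return occ


# ---------------------------------------------------------------------------
# public operation surface
# ---------------------------------------------------------------------------

def _check_conc(*values):
    for v in values:
        if not (v > 0.0) or not np.isfinite(v):
            raise ValueError(f"non-positive or non-finite concentration: {v}")


def _as_array(p) -> np.ndarray:
    return p.as_array() if isinstance(p, Parameters) else np.asarray(p)


def subspace_ca(config: DyadConfig, v: float, ca_i: float, ca_nsr: float,
                p) -> float:
    """Rapid-equilibrium subspace Ca2+ (mM) for one dyad configuration.

    With both channels closed this equals ``ca_i`` exactly: there is no
    source flux and the subspace equilibrates with the cytosol.
    """
    _check_conc(ca_i, ca_nsr)
    if not np.isfinite(v):
        raise ValueError("membrane potential must be finite")
    return float(_subspace_ca(config.lcc_open, config.ryr_open, v, ca_i,
                              ca_nsr, _as_array(p)))


def generator_matrix(v: float, ca_i: float, ca_nsr: float, p) -> np.ndarray:
    """40x40 infinitesimal generator of the joint LCC-RyR chain."""
    _check_conc(ca_i, ca_nsr)
    A = _build_generator(v, ca_i, ca_nsr, _as_array(p))
    if not np.all(np.isfinite(A)):
        bad = np.argwhere(~np.isfinite(A))[0]
        il, ir = divmod(int(bad[0]), N_RYR)
        jl, jr_ = divmod(int(bad[1]), N_RYR)
        raise FloatingPointError(
            f"non-finite rate from (LCC={il}, RyR={ir}) to (LCC={jl}, RyR={jr_})"
        )
    return A


def _check_dist(dist: np.ndarray):
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (N_STATES,):
        raise ValueError(f"occupancy vector must have length {N_STATES}")
    if abs(dist.sum() - 1.0) > 1e-6:
        raise ValueError("occupancy vector is not normalized (|sum-1| > 1e-6)")
    return dist


def caru_fluxes(dist: np.ndarray, v: float, ca_i: float, ca_nsr: float,
                p) -> CaRUFluxes:
    """Ensemble trigger/release fluxes and whole-cell L-type current."""
    dist = _check_dist(dist)
    _check_conc(ca_i, ca_nsr)
    j_lcc, j_ryr, i_cal, _, _ = _fluxes(dist, v, ca_i, ca_nsr, _as_array(p))
    return CaRUFluxes(j_lcc=float(j_lcc), j_ryr=float(j_ryr),
                      i_cal=float(i_cal))


def average_subspace_ca(dist: np.ndarray, v: float, ca_i: float,
                        ca_nsr: float, p) -> float:
    """Probability-weighted subspace Ca2+ over the four dyad macrostates."""
    dist = _check_dist(dist)
    _check_conc(ca_i, ca_nsr)
    _, _, _, _, avg = _fluxes(dist, v, ca_i, ca_nsr, _as_array(p))
    return float(avg)


def occupancy_derivative(dist: np.ndarray, v: float, ca_i: float,
                         ca_nsr: float, p) -> np.ndarray:
    """d(occupancy)/dt under the current generator (master equation)."""
    return _occupancy_derivative(np.asarray(dist, dtype=float), v, ca_i,
                                 ca_nsr, _as_array(p))


def stochastic_pair_oracle(v_trace, ca_i_trace, ca_nsr_trace, p,
                           n_pairs: int, seed: int, t_grid=None) -> np.ndarray:
    """Gillespie simulation of independent LCC-RyR pairs.

    Serves as an independent Monte-Carlo oracle for the deterministic master
    equation: empirical occupancies converge to the ODE solution as
    ``n_pairs`` grows.  Deterministic for a fixed seed.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    v_trace = np.asarray(v_trace, dtype=float)
    ca_i_trace = np.asarray(ca_i_trace, dtype=float)
    ca_nsr_trace = np.asarray(ca_nsr_trace, dtype=float)
    if t_grid is None:
        t_grid = np.arange(len(v_trace), dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    return _gillespie_pairs(t_grid, v_trace, ca_i_trace, ca_nsr_trace,
                            _as_array(p), int(n_pairs), int(seed))
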