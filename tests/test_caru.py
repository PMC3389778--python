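"""Coupled LCC-RyR release unit: generator structure, subspace algebra,
flux contracts, and the Monte-Carlo oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import brentq

from gpmyo import caru
from gpmyo.constants import RT_OVER_F
from gpmyo.params import (P_CA_O, P_J_R_SINGLE, P_TAU_SS, PARAM_NAMES)

V_GRID = [-80.0, -40.0, -20.0, 0.0, 10.0, 40.0, 60.0]
CA_GRID = [(1e-4, 0.7), (1e-3, 0.3), (5e-4, 2.0)]


@pytest.mark.parametrize("v", V_GRID)
@pytest.mark.parametrize("ca_i,ca_nsr", CA_GRID)
def test_generator_rows_sum_to_zero(p, v, ca_i, ca_nsr):
    A = caru.generator_matrix(v, ca_i, ca_nsr, p)
    assert np.abs(A.sum(axis=1)).max() < 1e-12
    off = A - np.diag(np.diag(A))
    assert off.min() >= 0.0


@settings(max_examples=40, deadline=None)
@given(v=st.floats(-90, 60), ca_i=st.floats(5e-5, 5e-3),
       ca_nsr=st.floats(0.05, 3.0))
def test_subspace_closed_closed_equals_cytosol(p, v, ca_i, ca_nsr):
    cfg = caru.DyadConfig(False, False)
    assert caru.subspace_ca(cfg, v, ca_i, ca_nsr, p) == pytest.approx(ca_i)


@settings(max_examples=40, deadline=None)
@given(v=st.floats(-40, 60), ca_i=st.floats(5e-5, 5e-3),
       ca_nsr=st.floats(0.05, 3.0))
def test_subspace_monotone_in_sr_load_when_ryr_open(p, v, ca_i, ca_nsr):
    cfg = caru.DyadConfig(False, True)
    lo = caru.subspace_ca(cfg, v, ca_i, ca_nsr, p)
    hi = caru.subspace_ca(cfg, v, ca_i, ca_nsr * 1.2, p)
    assert hi >= lo


def test_subspace_rejects_nonpositive_concentration(p):
    cfg = caru.DyadConfig(False, False)
    with pytest.raises(ValueError):
        caru.subspace_ca(cfg, 0.0, -1e-4, 0.7, p)
    with pytest.raises(ValueError):
        caru.subspace_ca(cfg, 0.0, 1e-4, 0.0, p)


@pytest.mark.parametrize("lcc_open,ryr_open", [(True, False), (True, True),
                                               (False, True)])
def test_subspace_matches_relaxation_oracle(p, parr, lcc_open, ryr_open):
    """Algebraic value agrees with the steady state of the explicit dyadic
    ODE dCa_ss/dt = J_LCC + J_RyR + J_transfer integrated to convergence."""
    v, ca_i, ca_nsr = 0.0, 1e-4, 0.8
    jr = caru.RYR_CLUSTER_SIZE * parr[P_J_R_SINGLE]
    tau = parr[P_TAU_SS]

    def rhs(t, y):
        ca_ss = y[0]
        src, slope = caru._ghk_terms(v, parr)
        j = (ca_i - ca_ss) / tau
        if lcc_open:
            j += src - slope * ca_ss
        if ryr_open:
            j += jr * (ca_nsr - ca_ss)
        return [j]

    sol = solve_ivp(rhs, [0.0, 5.0], [ca_i], rtol=1e-10, atol=1e-14)
    expected = sol.y[0, -1]
    got = caru.subspace_ca(caru.DyadConfig(lcc_open, ryr_open), v, ca_i,
                           ca_nsr, p)
    assert got == pytest.approx(expected, rel=1e-3)


def test_lcc_flux_vanishes_at_ghk_null_potential(p):
    """j_lcc crosses zero exactly where the GHK driving force vanishes."""
    dist = np.zeros(caru.N_STATES)
    dist[caru.joint_index(caru.LCC_OPEN_STATE, 0)] = 1.0
    ca_i, ca_nsr = 1e-4, 0.8

    def f(v):
        return caru.caru_fluxes(dist, v, ca_i, ca_nsr, p).j_lcc

    v0 = brentq(f, 20.0, 200.0, xtol=1e-10)
    assert abs(f(v0)) < 1e-12
    # the zero coincides with Ca_o * exp(-2 V F / RT) = Ca_ss
    ca_ss = caru.subspace_ca(caru.DyadConfig(True, False), v0, ca_i, ca_nsr, p)
    v_null = 0.5 * RT_OVER_F * np.log(p.value("ca_o") / ca_ss)
    assert v0 == pytest.approx(v_null, abs=1e-6)


def test_fluxes_contract_violations(p):
    dist = np.zeros(caru.N_STATES)
    dist[0] = 0.9  # not normalized
    with pytest.raises(ValueError):
        caru.caru_fluxes(dist, 0.0, 1e-4, 0.8, p)


def test_release_flux_nonnegative_and_scales_with_cluster(p):
    dist = np.full(caru.N_STATES, 1.0 / caru.N_STATES)
    fl = caru.caru_fluxes(dist, 0.0, 1e-4, 0.8, p)
    assert fl.j_ryr >= 0.0
    # unitary cluster flux is exactly 5x the single-channel rate
    assert caru.RYR_CLUSTER_SIZE == 5.0


def test_average_subspace_weighting(p):
    # all closed-closed -> cytosolic Ca2+
    dist = np.zeros(caru.N_STATES)
    dist[caru.joint_index(0, 0)] = 0.6
    dist[caru.joint_index(1, 1)] = 0.4     # still closed-closed macrostate
    assert caru.average_subspace_ca(dist, 0.0, 2e-4, 0.8, p) == \
        pytest.approx(2e-4)
    # 50/50 closed-closed / open-open -> arithmetic mean
    dist = np.zeros(caru.N_STATES)
    dist[caru.joint_index(0, 0)] = 0.5
    dist[caru.joint_index(caru.LCC_OPEN_STATE, caru.RYR_OPEN_STATE)] = 0.5
    cc = caru.subspace_ca(caru.DyadConfig(False, False), 0.0, 2e-4, 0.8, p)
    oo = caru.subspace_ca(caru.DyadConfig(True, True), 0.0, 2e-4, 0.8, p)
    got = caru.average_subspace_ca(dist, 0.0, 2e-4, 0.8, p)
    assert got == pytest.approx(0.5 * (cc + oo))


def test_oracle_frozen_with_zero_rates(p):
    parr = p.as_array().copy()
    for name in ("lcc_alpha0", "lcc_beta0", "lcc_f", "lcc_g", "lcc_kcdi",
                 "lcc_omega", "ryr_ka", "ryr_kb", "ryr_k21", "ryr_k32",
                 "ryr_k34", "ryr_k41"):
        parr[PARAM_NAMES.index(name)] = 0.0
    t = np.linspace(0.0, 50.0, 6)
    const = np.full_like(t, 1e-4)
    occ = caru.stochastic_pair_oracle(np.zeros_like(t), const,
                                      np.full_like(t, 0.8), parr, 1, 7,
                                      t_grid=t)
    assert np.all(occ[:, 0] == 1.0)


def test_oracle_deterministic_for_fixed_seed(p):
    t = np.linspace(0.0, 20.0, 5)
    args = (np.zeros_like(t), np.full_like(t, 1e-4), np.full_like(t, 0.8),
            p, 200, 42)
    a = caru.stochastic_pair_oracle(*args, t_grid=t)
    b = caru.stochastic_pair_oracle(*args, t_grid=t)
    assert np.array_equal(a, b)


def test_oracle_matches_master_equation(p):
    """Gillespie ensemble occupancies agree with exp(At) within 3 SE."""
    v, ca_i, ca_nsr = 0.0, 1e-4, 0.8
    n_pairs = 30000
    t = np.array([0.0, 5.0, 20.0, 100.0])
    occ = caru.stochastic_pair_oracle(np.full_like(t, v),
                                      np.full_like(t, ca_i),
                                      np.full_like(t, ca_nsr), p, n_pairs,
                                      seed=1234, t_grid=t)
    A = caru.generator_matrix(v, ca_i, ca_nsr, p)
    pi = np.zeros(caru.N_STATES)
    pi[0] = 1.0
    lcc_open = np.zeros(caru.N_STATES, dtype=bool)
    ryr_open = np.zeros(caru.N_STATES, dtype=bool)
    for il in range(caru.N_LCC):
        for ir in range(caru.N_RYR):
            i = caru.joint_index(il, ir)
            lcc_open[i] = il == caru.LCC_OPEN_STATE
            ryr_open[i] = ir == caru.RYR_OPEN_STATE
    for k, tk in enumerate(t[1:], start=1):
        ref = pi @ expm(A * tk)
        # physically meaningful aggregates within 3 SE of the binomial noise
        for mask in (lcc_open, ryr_open, ~lcc_open & ~ryr_open):
            p_ref = ref[mask].sum()
            se = np.sqrt(max(p_ref * (1 - p_ref), 1e-12) / n_pairs)
            assert abs(occ[k][mask].sum() - p_ref) <= 3.0 * se + 1e-4, \
                f"t={tk}"
        # and every joint state within 5 SE (120 comparisons overall)
        se_all = np.sqrt(np.maximum(ref * (1 - ref), 1e-12) / n_pairs)
        bad = np.abs(occ[k] - ref) > 5.0 * se_all + 1e-4
        assert not bad.any(), f"t={tk}: states {np.where(bad)[0]}"
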