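"""Markov-model construction, propagation and observable tests."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from navmex.channel import (MODEL, N_FREE, N_STATES, OPEN, A2_STATES,
                            BOUND_STATES, OccupancyState,
                            generator_steady_state)
from navmex.params import ConstructParameters
from navmex.rates import InvalidParameterError, RateLaw, compose


def test_generator_columns_conserve_probability(all_constructs):
    for p in all_constructs.values():
        for v in (-140.0, -85.0, 0.0, 40.0):
            for drug in (0.0, 100.0):
                g = MODEL.build_generator(p, v, drug)
                assert np.abs(g.sum(axis=0)).max() < 1e-12
                off = g - np.diag(np.diag(g))
                assert off.min() >= 0.0


def test_two_state_chain_analytic_steady_state():
    # a = 1 forward, b = 2 backward: pi = (b, a)/(a+b) = (2/3, 1/3)
    g = np.array([[-1.0, 2.0], [1.0, -2.0]])
    p = generator_steady_state(g)
    assert np.allclose(p, [2.0 / 3.0, 1.0 / 3.0], atol=1e-12)


def test_symmetric_two_state_steady_state():
    g = np.array([[-1.0, 1.0], [1.0, -1.0]])
    assert np.allclose(generator_steady_state(g), [0.5, 0.5], atol=1e-12)


def test_drug_free_bound_states_unreachable(wt):
    g = MODEL.build_generator(wt, -80.0, 0.0)
    # no flux into the bound block at zero concentration
    assert np.abs(g[N_FREE:, :N_FREE]).max() == 0.0
    ss = MODEL.steady_state(wt, -80.0, 0.0)
    assert ss.p[N_FREE:].max() == 0.0


def test_drug_free_trajectories_unaffected_by_bound_block(wt):
    """With drug = 0 the 16-state sub-model evolves identically whether or
    not the mirror states are present in the matrix."""
    p0 = MODEL.steady_state(wt, -120.0, 0.0)
    traj = MODEL.propagate(wt, [(30.0, -20.0, 0.0)], p0, sample_dt=1.0)
    g_free = MODEL.build_generator(wt, -20.0, 0.0)[:N_FREE, :N_FREE]
    sol = solve_ivp(lambda t, y: g_free @ y, (0.0, 30.0), p0.p[:N_FREE],
                    method="LSODA", rtol=1e-10, atol=1e-12, t_eval=[30.0])
    assert np.allclose(traj.p[-1, :N_FREE], sol.y[:, -1], atol=1e-8)
    assert traj.p[:, N_FREE:].max() == 0.0


def test_matrix_exponential_matches_stiff_ode(rp):
    """Dual-method oracle: expm stepping vs high-accuracy ODE integration."""
    p0 = MODEL.steady_state(rp, -100.0, 50.0)
    g = MODEL.build_generator(rp, -10.0, 50.0)
    traj = MODEL.propagate(rp, [(10.0, -10.0, 50.0)], p0)
    sol = solve_ivp(lambda t, y: g @ y, (0.0, 10.0), p0.p, method="Radau",
                    rtol=1e-10, atol=1e-13, t_eval=[10.0])
    assert np.abs(traj.p[-1] - sol.y[:, -1]).max() < 1e-8


def test_steady_state_matches_long_relaxation(mr):
    # drug-free: the slowest relaxation is slow-inactivation exit, well
    # inside a 1e5-ms window (bound-state unbinding is far slower and is
    # checked separately at its own timescale)
    ss = MODEL.steady_state(mr, -90.0, 0.0)
    p0 = np.zeros(N_STATES)
    p0[0] = 1.0
    traj = MODEL.propagate(mr, [(1e5, -90.0, 0.0)], p0)
    assert np.abs(traj.p[-1] - ss.p).max() < 1e-6


def test_steady_state_matches_relaxation_with_drug(mr):
    ss = MODEL.steady_state(mr, -90.0, 20.0)
    p0 = np.zeros(N_STATES)
    p0[0] = 1.0
    traj = MODEL.propagate(mr, [(1e8, -90.0, 20.0)], p0)
    assert np.abs(traj.p[-1] - ss.p).max() < 1e-6


def test_propagate_zero_duration_returns_initial(wt):
    p0 = MODEL.steady_state(wt, -120.0, 0.0)
    traj = MODEL.propagate(wt, [(0.0, -120.0, 0.0)], p0)
    assert np.allclose(traj.p[0], p0.p)
    assert traj.p.shape[0] == 1


def test_occupancy_positivity_and_conservation(rp):
    p0 = MODEL.steady_state(rp, -120.0, 100.0)
    traj = MODEL.propagate(
        rp, [(5.0, 0.0, 100.0), (50.0, -120.0, 100.0), (400.0, -10.0, 100.0)],
        p0, sample_dt=0.5)
    assert traj.p.min() >= -1e-9
    assert np.abs(traj.p.sum(axis=1) - 1.0).max() < 1e-9


def test_current_zero_at_reversal_potential(wt):
    p0 = MODEL.steady_state(wt, -120.0, 0.0)
    traj = MODEL.propagate(wt, [(5.0, 65.0, 0.0)], p0, sample_dt=0.1)
    i = MODEL.sodium_current(traj, wt, ena=65.0)
    assert np.abs(i).max() == 0.0


def test_fluorescence_limits(wt):
    p = np.zeros(N_STATES)
    p[0] = 1.0  # all rested
    assert MODEL.fluorescence_signal(p, wt) == 0.0
    p = np.zeros(N_STATES)
    p[list(A2_STATES)] = 1.0 / len(A2_STATES)
    assert MODEL.fluorescence_signal(p, wt) == pytest.approx(wt.w2)


def test_reversibility_residuals_by_construction(all_constructs):
    for p in all_constructs.values():
        res = MODEL.check_reversibility(
            p, v_grid=(-160.0, -80.0, 0.0), drug_grid=(0.0, 75.0))
        assert len(res) > 0
        assert max(res) < 1e-8


def test_reversibility_closed_under_label_rescaling(wt):
    """Rescaling a shared rate law rescales its reversibility-derived
    partners too, so cycle products stay closed (the compensation is
    structural, not numerical)."""
    mod = wt.copy()
    mod.laws["oif"] = mod.laws["oif"].scaled(1.7)
    res = MODEL.check_reversibility(mod, v_grid=(-80.0,), drug_grid=(0.0,))
    assert max(res) < 1e-8


def test_reversibility_detects_single_edge_perturbation(wt):
    """Multiplying one physical edge rate by 1.01 leaves a log(1.01)
    residual on exactly the cycles through that edge."""
    import dataclasses

    from navmex.channel import ChannelModel, IDX

    bad = ChannelModel()
    edges = []
    for e in bad.edges:
        if e.src == IDX["O"] and e.dst == IDX["IF"]:
            fwd = dict(e.fwd)
            fwd["_fudge"] = 1.0
            e = dataclasses.replace(e, fwd=fwd)
        edges.append(e)
    bad.edges = tuple(edges)
    p = wt.copy()
    p.drug["_fudge"] = 1.01
    res = bad.check_reversibility(p, v_grid=(-80.0,), drug_grid=(0.0,))
    assert max(res) == pytest.approx(math.log(1.01), rel=1e-6)


def test_guarded_receptor_no_block_without_diii_activation(wt):
    """If the DIII-VSD cannot reach A2, no drug binding ever occurs."""
    locked = wt.copy()
    for law in ("ax", "ay", "a3"):
        locked.laws[law] = locked.laws[law].scaled(1e-9)
    p0 = np.zeros(N_STATES)
    p0[0] = 1.0
    traj = MODEL.propagate(locked, [(1000.0, -120.0, 1000.0),
                                    (400.0, 0.0, 1000.0)], p0, sample_dt=10.0)
    assert traj.p[:, list(BOUND_STATES)].max() < 1e-9


def test_steady_state_diii_activation_monotone_in_voltage(all_constructs):
    for p in all_constructs.values():
        f = []
        for v in np.arange(-180.0, 1.0, 10.0):
            ss = MODEL.steady_state(p, float(v), 0.0)
            f.append(float(MODEL.fluorescence_signal(ss, p)))
        assert np.all(np.diff(f) > -1e-9)


def test_mean_open_time_positive_and_short(wt):
    mot = MODEL.mean_open_time(wt, 0.0)
    assert 0.0 < mot < 5.0


def test_invalid_voltage_rejected(wt):
    with pytest.raises(InvalidParameterError):
        MODEL.build_generator(wt, float("nan"), 0.0)
    with pytest.raises(InvalidParameterError):
        MODEL.build_generator(wt, -80.0, -5.0)


def test_occupancy_state_validation():
    with pytest.raises(ValueError):
        OccupancyState(p=np.ones(N_STATES))  # sums to 24
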