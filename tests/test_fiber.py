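"""Cable propagation, conduction-velocity measurement and block detection."""

import numpy as np
import pytest

from navmex.fiber import (FiberConfig, FiberResult, conduction_velocity,
                          has_block, run_fiber)


def _travelling_wave(n_cells=40, speed_cells_per_ms=0.5, bcl=400.0):
    """Synthetic wave with a known conduction speed."""
    n_t = int(bcl)
    vm = np.full((n_t, n_cells), -85.0)
    for c in range(n_cells):
        t_arr = int(10 + c / speed_cells_per_ms)
        if t_arr + 50 < n_t:
            vm[t_arr:t_arr + 50, c] = 20.0
    return FiberResult(t=np.arange(n_t, dtype=float), vm=vm, bcl=bcl,
                       dx_cm=0.01)


def test_cv_recovers_constructed_wave_speed():
    res = _travelling_wave(speed_cells_per_ms=0.5)
    # 0.5 cells/ms at dx = 0.01 cm -> 0.005 cm/ms -> 5 cm/s
    cv = conduction_velocity(res, beat=0, from_cell=8, to_cell=32)
    assert cv == pytest.approx(5.0, rel=0.05)


def test_block_detected_when_distal_cells_silent():
    res = _travelling_wave()
    res.vm[:, 30:] = -85.0  # distal cells never activate
    assert has_block(res, 0)
    assert not has_block(_travelling_wave(), 0)


def test_fiber_config_validation():
    with pytest.raises(ValueError):
        FiberConfig(n_cells=2)
    with pytest.raises(ValueError):
        FiberConfig(diffusion=0.0)


def test_no_stimulus_fiber_stays_at_rest(wt):
    """After the coupled model settles onto its own resting point (the
    host initial state belongs to the uncoupled formulation), the quiescent
    fiber shows no further drift."""
    cfg = FiberConfig(n_cells=8, n_beats=2, bcl=1000.0, stim_amplitude=0.0)
    res = run_fiber(wt, cfg)
    settled = res.vm[200:]
    assert np.abs(settled - settled[0]).max() < 0.5
    assert settled.max() < -80.0


def test_wave_propagates_in_small_wt_fiber(wt):
    cfg = FiberConfig(n_cells=12, n_beats=2, bcl=500.0)
    res = run_fiber(wt, cfg)
    times = res.activation_times(1)
    assert np.all(np.isfinite(times))
    interior = times[3:]
    assert np.all(np.diff(interior) >= 0.0)     # ordered activation
    cv = conduction_velocity(res, beat=1, from_cell=4, to_cell=10)
    assert np.isfinite(cv) and cv > 0.0
    assert not has_block(res, 1)


def test_cv_decreases_with_weaker_coupling(wt):
    cvs = []
    for d in (0.00154, 0.00154 / 4.0):
        cfg = FiberConfig(n_cells=12, n_beats=2, bcl=500.0, diffusion=d)
        res = run_fiber(wt, cfg)
        cvs.append(conduction_velocity(res, beat=1, from_cell=4, to_cell=10))
    assert cvs[1] < cvs[0]


def test_uncoupled_fiber_matches_isolated_cell_at_stimulated_end(wt):
    from navmex.myocyte import CellConfig, run_paced_cell

    cfg = FiberConfig(n_cells=6, n_beats=1, bcl=600.0, diffusion=1e-9,
                      stim_cells=6, stim_amplitude=-52.0)
    res = run_fiber(wt, cfg)
    cell_cfg = CellConfig(bcl=600.0, n_beats=1)
    tr = run_paced_cell(wt, cell_cfg)
    assert np.abs(res.vm[:, 0] - tr.vm[:600]).max() < 1.0
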