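"""Paced-cell metrics on constructed fixtures and short host runs."""

import numpy as np
import pytest

from navmex.myocyte import (CellConfig, apd, beat_metrics, detect_eads,
                            max_upstroke, run_paced_cell, steady_apd90)


def _square_ap(duration=300, total=1000, v_rest=-85.0, v_peak=40.0):
    vm = np.full(total, v_rest)
    vm[10:10 + duration] = v_peak
    # brief linear upstroke for a defined dV/dt max
    vm[9] = (v_rest + v_peak) / 2.0
    return vm


def test_apd_on_constructed_square_pulse():
    vm = _square_ap(duration=300)
    assert apd(vm) == pytest.approx(300.0, abs=2.0)


def test_apd_failure_marker_when_no_repolarization():
    vm = np.full(800, -85.0)
    vm[10:] = 20.0  # depolarizes and never comes back
    assert np.isnan(apd(vm))


def test_ead_detection_on_injected_plateau_bump():
    vm = _square_ap(duration=400).astype(float)
    # repolarization ramp with a 10-mV secondary depolarization at t=200
    vm[10:410] = np.linspace(40.0, -60.0, 400)
    # rise must outpace the repolarization ramp to register as an EAD
    vm[200:230] += np.linspace(0.0, 15.0, 30)
    vm[230:280] += np.linspace(15.0, 0.0, 50)
    events = detect_eads(vm)
    assert len(events) == 1
    assert 180 <= events[0] <= 260


def test_monotonic_repolarization_has_no_eads():
    vm = _square_ap(duration=400).astype(float)
    vm[10:410] = np.linspace(40.0, -70.0, 400)
    assert detect_eads(vm) == []


def test_max_upstroke_on_linear_ramp():
    vm = np.full(100, -85.0)
    vm[10:20] = -85.0 + 25.0 * np.arange(10)  # 25 mV/ms
    assert max_upstroke(vm) == pytest.approx(25.0, rel=1e-9)


def test_cell_config_validation():
    with pytest.raises(ValueError):
        CellConfig(bcl=0.5, stim_duration=1.0)
    with pytest.raises(ValueError):
        CellConfig(n_beats=0)


@pytest.mark.parametrize("bcl", [1000.0])
def test_wt_short_run_repolarizes_and_is_deterministic(wt, bcl):
    cfg = CellConfig(bcl=bcl, n_beats=3)
    tr1 = run_paced_cell(wt, cfg)
    tr2 = run_paced_cell(wt, cfg)
    assert np.array_equal(tr1.vm, tr2.vm)          # bit-identical rerun
    m = beat_metrics(tr1)
    assert np.all(np.isfinite(m["apd90"][1:]))
    assert np.all(m["n_eads"] == 0)
    # diastolic potential restored between beats
    assert tr1.vm[int(bcl) - 1] < -75.0
    assert 0.0 <= tr1.diii_activation.min() <= tr1.diii_activation.max() <= 1.0


def test_steady_apd90_excludes_failed_beats(wt):
    cfg = CellConfig(bcl=800.0, n_beats=4)
    tr = run_paced_cell(wt, cfg)
    s = steady_apd90(tr, last=3)
    assert np.isfinite(s) and 100.0 < s < 600.0
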