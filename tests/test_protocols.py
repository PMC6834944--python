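"""Summary-fit self-consistency and protocol-level property tests."""

import numpy as np
import pytest

from navmex import protocols as pr


# -- reduction fits: exact self-recovery ---------------------------------

def test_boltzmann_fit_recovers_exact_curve():
    v = np.arange(-120.0, -19.0, 5.0)
    for vh, k, rising in ((-70.0, 6.5, False), (-55.0, 9.0, True)):
        sign = -1.0 if rising else 1.0
        y = 1.0 / (1.0 + np.exp(sign * (v - vh) / k))
        fit = pr.fit_boltzmann(v, y, rising=rising)
        assert fit.converged
        assert fit["v_half"] == pytest.approx(vh, abs=1e-6)
        assert fit["k"] == pytest.approx(k, abs=1e-6)


def test_hill_fit_recovers_exact_curve():
    c = np.logspace(-1, 3, 12)
    for ic50, h in ((35.0, 1.0), (240.0, 1.6)):
        y = c ** h / (c ** h + ic50 ** h)
        fit = pr.fit_hill(c, y)
        assert fit.converged
        assert fit["ic50"] == pytest.approx(ic50, rel=1e-6)
        assert fit["h"] == pytest.approx(h, rel=1e-6)


def test_single_exponential_fit_exact():
    t = np.linspace(0.0, 100.0, 201)
    y = 0.3 + 0.6 * np.exp(-t / 17.0)
    fit = pr.fit_exponential(t, y, n=1)
    assert fit["tau1"] == pytest.approx(17.0, rel=1e-6)
    assert fit["y_inf"] == pytest.approx(0.3, abs=1e-8)


def test_double_exponential_fit_with_noise_seeded():
    rng = np.random.default_rng(7)
    t = np.linspace(0.0, 300.0, 400)
    y = 0.5 * np.exp(-t / 8.0) + 0.5 * np.exp(-t / 90.0)
    fit = pr.fit_exponential(t, y + rng.normal(0, 0.01, t.shape), n=2)
    assert fit["tau1"] == pytest.approx(8.0, rel=0.05)
    assert fit["tau2"] == pytest.approx(90.0, rel=0.05)


def test_fit_input_validation():
    with pytest.raises(ValueError):
        pr.fit_boltzmann([0, 1], [0, 1])
    with pytest.raises(ValueError):
        pr.fit_hill([1, 10], [0.1, 0.9])


def test_voltage_protocol_validation():
    with pytest.raises(ValueError):
        pr.VoltageProtocol("bad", -120.0, ((0.0, 0.0),), "v", (1.0,))
    with pytest.raises(ValueError):
        pr.VoltageProtocol("bad", -120.0, ((10.0, 0.0),), "v", ())


# -- protocol-level properties -------------------------------------------

def test_gv_curve_same_with_and_without_drug_states(wt):
    """At zero drug the GV curve is independent of the (unreachable)
    drug-bound mirror states."""
    res = pr.run_activation_gv(wt, 0.0)
    assert res.y.max() == pytest.approx(1.0)
    # non-decreasing below saturation
    i_max = int(np.argmax(res.y))
    assert np.all(np.diff(res.y[: i_max + 1]) > -1e-6)


def test_ssa_is_monotone_falling(all_constructs):
    for p in all_constructs.values():
        res = pr.run_ssa(p)
        # the hyperpolarized limb may dip slightly below the maximum: deep
        # prepulses park the DIII-VSD down and the test-pulse peak then pays
        # a ladder-climbing delay; availability still saturates high
        assert res.y[0] > 0.85
        i_max = int(np.argmax(res.y))
        assert res.x[i_max] < -100.0
        assert res.y[-1] < 0.2
        assert np.all(np.diff(res.y[i_max:]) < 0.02)


def test_hek_shift_moves_fitted_vhalf_additively(mr):
    base = pr.run_ssa(mr)
    shifted = pr.run_ssa(mr, hek_shift=15.0)
    assert shifted.fit["v_half"] - base.fit["v_half"] == pytest.approx(15.0, abs=1e-6)


def test_rfi_recovers_toward_unity(wt):
    """Availability recovers monotonically; full recovery is limited only
    by the slow-inactivation tail at the longest intervals."""
    res = pr.run_rfi(wt)
    assert res.y[-1] > 0.8
    assert res.y[0] < 0.5
    assert np.all(np.diff(res.y) > -0.01)


def test_block_curves_bounded_and_monotone(rp):
    for runner in (pr.run_tonic_block, pr.run_udb):
        res = runner(rp, pr.CONC_GRID)
        assert np.all(res.y >= -1e-9) and np.all(res.y <= 1.0 + 1e-9)
        assert np.all(np.diff(res.y) > -0.01)
        assert res.y[0] == pytest.approx(0.0, abs=0.02)


def test_zero_concentration_no_block(wt):
    assert pr.block_at(wt, 0.0, "tonic") == pytest.approx(0.0, abs=1e-9)
    assert pr.run_late_block(wt, 0.0) == pytest.approx(0.0, abs=1e-9)


def test_udb_at_least_as_potent_as_tonic(all_constructs):
    """Use dependence adds block: UDB IC50 <= tonic IC50 per construct."""
    for p in all_constructs.values():
        tonic = pr.run_tonic_block(p, pr.CONC_GRID).fit["ic50"]
        udb = pr.run_udb(p, pr.CONC_GRID).fit["ic50"]
        assert udb <= tonic * 1.05


def test_fluor_activation_normalized_and_rising(rp):
    res = pr.run_fluor_activation(rp, 0.0)
    assert res.y.min() == pytest.approx(0.0) and res.y.max() == pytest.approx(1.0)
    assert res.fit["v_half"] < -100.0
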