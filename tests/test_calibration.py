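"""Targets registry, objective properties, fitting and booster tests."""

import json

import numpy as np
import pytest

from navmex.calibration import (CalibrationTargets, Handle, TargetEntry,
                                TargetValidationError, amplitude_handle,
                                evaluate_quantity, fit_construct,
                                generate_synthetic_clamp_data, load_targets,
                                objective, saturated_diii)
from navmex.params import DIII_LAWS


def test_shipped_registry_loads_and_validates():
    reg = load_targets()
    assert len(reg.entries) >= 25
    for e in reg.entries:
        assert e.quote and e.location and e.tol > 0


def test_registry_rejects_missing_quote():
    with pytest.raises(TargetValidationError):
        CalibrationTargets([TargetEntry(
            id="x", construct="WT", quantity="late_peak_ratio", args={},
            value=0.1, units="%", weight=1.0, tol=0.1, quote="",
            location="somewhere")])


def test_registry_round_trip(tmp_path):
    reg = load_targets()
    out = tmp_path / "targets.json"
    reg.save(out)
    reg2 = load_targets(out)
    assert [e.id for e in reg2.entries] == [e.id for e in reg.entries]
    assert all(a.value == b.value for a, b in zip(reg.entries, reg2.entries))


def test_objective_zero_iff_targets_met(wt):
    reg = load_targets()
    sub = ["wt_late_peak"]
    rep = objective({"WT": wt}, reg, subset=sub)
    sim = rep["residuals"]["wt_late_peak"]["simulated"]
    # construct a registry whose target equals the simulated value
    entries = [TargetEntry("wt_late_peak", "WT", "late_peak_ratio", {},
                           sim, "%", 1.0, 0.1, "q", "l")]
    rep2 = objective({"WT": wt}, CalibrationTargets(entries))
    assert rep2["objective"] == pytest.approx(0.0, abs=1e-20)


def test_objective_quadratic_in_residual(wt):
    sim = evaluate_quantity("late_peak_ratio", {}, "WT", {"WT": wt})
    def obj(offset):
        entries = [TargetEntry("x", "WT", "late_peak_ratio", {},
                               sim + offset, "%", 1.0, 0.1, "q", "l")]
        return objective({"WT": wt}, CalibrationTargets(entries))["objective"]
    assert obj(0.2) == pytest.approx(4.0 * obj(0.1), rel=1e-9)


def test_objective_invariant_to_target_order(wt):
    reg = load_targets()
    sub = ["wt_late_peak", "wt_diii_m120"]
    a = objective({"WT": wt}, reg, subset=sub)["objective"]
    b = objective({"WT": wt}, reg, subset=list(reversed(sub)))["objective"]
    assert a == pytest.approx(b, rel=1e-12)


def test_handles_round_trip(wt):
    p = wt.copy()
    h = amplitude_handle(p, "ax")
    x = h.get(p)
    h.set(p, x)
    assert p.laws["ax"].A == pytest.approx(wt.laws["ax"].A, rel=1e-12)
    hw = Handle("w1", 0.05, 1.0, log=False)
    hw.set(p, 0.37)
    assert p.w1 == 0.37


def test_fit_construct_improves_single_target(wt_initial):
    """A one-handle fit drives the late/peak ratio to its target."""
    reg = load_targets()
    handles = [Handle("late_scale", 0.05, 400.0, log=True)]
    res = fit_construct(wt_initial, reg, handles, subset=["wt_late_peak"],
                        max_nfev=60)
    assert res.converged
    assert abs(res.residuals["wt_late_peak"]["residual"]) < 0.5


def test_synthetic_clamp_data_deterministic_and_noisy(wt):
    a = generate_synthetic_clamp_data(wt, noise_sd=0.02, seed=11)
    b = generate_synthetic_clamp_data(wt, noise_sd=0.02, seed=11)
    c = generate_synthetic_clamp_data(wt, noise_sd=0.0, seed=11)
    for key in a:
        assert np.array_equal(a[key]["y"], b[key]["y"])
    clean = generate_synthetic_clamp_data(wt, noise_sd=0.0, seed=99)
    for key in clean:
        assert np.array_equal(clean[key]["y"], c[key]["y"])
    assert not np.array_equal(a["ssa"]["y"], c["ssa"]["y"])


def test_parameter_recovery_from_noisy_synthetic_curves(wt):
    """Availability V1/2 recovered from sd = 0.02 synthetic data within
    twice the registry tolerance (identifiability check)."""
    from navmex.protocols import fit_boltzmann, run_ssa

    truth = run_ssa(wt).fit["v_half"]
    errs = []
    for seed in range(10):
        data = generate_synthetic_clamp_data(wt, noise_sd=0.02, seed=seed)
        fit = fit_boltzmann(data["ssa"]["x"], data["ssa"]["y"])
        errs.append(abs(fit["v_half"] - truth))
    assert np.median(errs) < 2.0 * 2.0


def test_saturated_diii_only_touches_diii_rates(mr):
    sat = saturated_diii(mr)
    for name in mr.laws:
        if name in ("bx", "by", "b3"):
            assert sat.laws[name].A < mr.laws[name].A
        else:
            assert sat.laws[name].A == mr.laws[name].A
    assert sat.drug == mr.drug
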