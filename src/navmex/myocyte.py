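"""Paced single-myocyte simulation and arrhythmia-trigger metrics.

Couples a calibrated Markov Na+ channel into the ventricular host model,
paces it at a fixed basic cycle length, and reduces the voltage traces to
per-beat metrics: APD90, early-afterdepolarization (EAD) counts, and maximum
upstroke velocity.  The paper-style experiments (drug response at slow
pacing, booster rescue, equivalent-dose finding) are driven from here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from . import host as _host
from .channel import MODEL
from .params import ConstructParameters

EAD_THRESHOLD_MV = 2.0   #: minimum secondary depolarization to call an EAD


@dataclass
class CellConfig:
    """Configuration of a paced-cell run."""

    bcl: float = 2000.0          # ms
    n_beats: int = 100
    drug: float = 0.0            # uM mexiletine
    stim_amplitude: float = -52.0   # A/F
    stim_duration: float = 1.0      # ms
    cl_scale: float = 1.0        # scales the background chloride conductance
    gcl_base: float = 0.01296    # mS/uF at cl_scale = 1 (calibrated)
    gkr_scale: float = 1.0       # rapid delayed-rectifier conductance scale
    gks_scale: float = 0.5       # slow delayed-rectifier conductance scale (calibrated)
    ko: float = 5.4
    nao: float = 140.0
    cao: float = 2.0

    def __post_init__(self) -> None:
        if self.bcl <= self.stim_duration:
            raise ValueError("BCL must exceed the stimulus duration")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")


@dataclass
class APTrace:
    """Sampled membrane potential and observables, one sample per ms."""

    t: np.ndarray
    vm: np.ndarray
    ina: np.ndarray
    diii_activation: np.ndarray
    cai: np.ndarray
    bcl: float
    dvdt_max: np.ndarray          # per beat, from the integrator's fine grid

    @property
    def n_beats(self) -> int:
        return len(self.dvdt_max)

    def beat_slice(self, beat: int) -> slice:
        i0 = int(beat * self.bcl)
        i1 = int((beat + 1) * self.bcl)
        return slice(i0, min(i1, len(self.t)))


def run_paced_cell(params: ConstructParameters, config: CellConfig) -> APTrace:
    """Pace the coupled myocyte; deterministic for a given configuration."""
    arrays = _host.edge_arrays(params)
    p0 = MODEL.steady_state(params, _host.Y0_HOST[0], 0.0).p
    n_samples = int(config.bcl * config.n_beats)
    out_v = np.empty(n_samples)
    out_ina = np.empty(n_samples)
    out_f = np.empty(n_samples)
    out_cai = np.empty(n_samples)
    dvdt_max = np.zeros(config.n_beats)
    _host.run_cell_kernel(
        _host.Y0_HOST.copy(), p0, *arrays,
        params.gna, config.drug, config.gcl_base * config.cl_scale,
        config.gkr_scale, config.gks_scale, params.w1, params.w2,
        config.bcl, config.n_beats,
        config.stim_amplitude, config.stim_duration,
        config.ko, config.nao, config.cao,
        out_v, out_ina, out_f, out_cai, dvdt_max)
    t = np.arange(n_samples, dtype=float)
    return APTrace(t=t, vm=out_v, ina=out_ina, diii_activation=out_f,
                   cai=out_cai, bcl=config.bcl, dvdt_max=dvdt_max)


# ----------------------------------------------------------------------
# Per-beat metrics
# ----------------------------------------------------------------------

def apd(trace_or_vm, beat: int | None = None, level: float = 90.0,
        bcl: float | None = None) -> float:
    """Action-potential duration at ``level``% repolarization (ms).

    Measured from the maximum-dV/dt instant to the crossing of
    ``V_peak - level/100 * (V_peak - V_diastolic)``; returns NaN when the
    beat fails to repolarize before the next stimulus.
    """
    if isinstance(trace_or_vm, APTrace):
        tr = trace_or_vm
        sl = tr.beat_slice(beat if beat is not None else tr.n_beats - 1)
        vm = tr.vm[sl]
        v_dia = tr.vm[sl.start - 1] if sl.start > 0 else vm[0]
    else:
        vm = np.asarray(trace_or_vm, float)
        v_dia = vm[0]
    dv = np.diff(vm)
    if len(dv) == 0 or np.max(vm) - v_dia < 10.0:
        return float("nan")
    i_up = int(np.argmax(dv))
    v_peak = float(np.max(vm[i_up:]))
    v_level = v_peak - (level / 100.0) * (v_peak - v_dia)
    below = np.nonzero(vm[i_up:] <= v_level)[0]
    # skip samples before the upstroke reaches the peak region
    i_peak = i_up + int(np.argmax(vm[i_up:]))
    below = below[below + i_up > i_peak]
    if below.size == 0:
        return float("nan")
    return float(below[0])


def detect_eads(trace_or_vm, beat: int | None = None,
                threshold: float = EAD_THRESHOLD_MV,
                blanking_ms: float = 120.0) -> List[int]:
    """Times (ms, beat-relative) of EADs during repolarization.

    An EAD is a sign change of dV/dt from negative to positive during
    repolarization followed by a depolarization of at least ``threshold``
    mV, occurring above the 90% repolarization level.  The first
    ``blanking_ms`` after the upstroke are excluded so the phase-1
    notch-dome morphology of epicardial cells is not miscounted.
    """
    if isinstance(trace_or_vm, APTrace):
        tr = trace_or_vm
        sl = tr.beat_slice(beat if beat is not None else tr.n_beats - 1)
        vm = tr.vm[sl]
        v_dia = tr.vm[sl.start - 1] if sl.start > 0 else vm[0]
    else:
        vm = np.asarray(trace_or_vm, float)
        v_dia = vm[0]
    if np.max(vm) - v_dia < 10.0:
        return []
    i_up = int(np.argmax(np.diff(vm)))
    i_peak = i_up + int(np.argmax(vm[i_up:]))
    v_peak = vm[i_peak]
    v90 = v_peak - 0.9 * (v_peak - v_dia)
    events: List[int] = []
    i = max(i_peak + 1, i_up + int(blanking_ms))
    n = len(vm)
    while i < n - 1:
        if vm[i] <= v90:
            break
        # local minimum during repolarization
        if vm[i] < vm[i - 1] and vm[i + 1] >= vm[i]:
            j = i + 1
            rise = 0.0
            while j < n and vm[j] >= vm[j - 1] - 1e-12:
                rise = max(rise, vm[j] - vm[i])
                j += 1
            if rise >= threshold and vm[i] > v90:
                events.append(i)
                i = j
                continue
        i += 1
    return events


def max_upstroke(trace_or_vm, beat: int | None = None) -> float:
    """Maximum upstroke velocity dV/dt_max (mV/ms)."""
    if isinstance(trace_or_vm, APTrace):
        tr = trace_or_vm
        b = beat if beat is not None else tr.n_beats - 1
        return float(tr.dvdt_max[b])
    vm = np.asarray(trace_or_vm, float)
    return float(np.max(np.diff(vm)))


def beat_metrics(trace: APTrace) -> Dict[str, np.ndarray]:
    """APD90, EAD count and dV/dt_max for every beat of a run."""
    apds = np.array([apd(trace, b) for b in range(trace.n_beats)])
    eads = np.array([len(detect_eads(trace, b)) for b in range(trace.n_beats)])
    return {"apd90": apds, "n_eads": eads, "dvdt_max": trace.dvdt_max.copy()}


def steady_apd90(trace: APTrace, last: int = 10) -> float:
    """Median APD90 over the last ``last`` beats, excluding failed beats."""
    apds = np.array([apd(trace, b) for b in range(max(0, trace.n_beats - last),
                                                  trace.n_beats)])
    apds = apds[np.isfinite(apds)]
    return float(np.median(apds)) if apds.size else float("nan")


# ----------------------------------------------------------------------
# Dose finding
# ----------------------------------------------------------------------

def dose_finding(params: ConstructParameters,
                 reference_params: ConstructParameters,
                 config: CellConfig,
                 reference_drug: float = 10.0,
                 start: float = 10.0,
                 step: float = 5.0,
                 max_dose: float = 100.0,
                 tolerance: float = 10.0,
                 scan_beats: int | None = None) -> Dict[str, float]:
    """Equivalent monotherapy dose matching a reference (booster) run.

    Scans doses upward in ``step`` increments from ``start`` and returns the
    first dose whose steady-beat APD90 is within ``tolerance`` ms of, or
    below, the reference APD90, with no EADs on the final beats.
    """
    import dataclasses

    ref_cfg = dataclasses.replace(config, drug=reference_drug)
    ref_trace = run_paced_cell(reference_params, ref_cfg)
    ref_apd = steady_apd90(ref_trace)
    scan_cfg_beats = scan_beats if scan_beats is not None else config.n_beats
    dose = start
    result = {"reference_apd90": ref_apd, "equivalent_dose": float("nan")}
    scans = {}
    while dose <= max_dose + 1e-9:
        cfg = dataclasses.replace(config, drug=dose, n_beats=scan_cfg_beats)
        tr = run_paced_cell(params, cfg)
        a = steady_apd90(tr)
        n_ead = len(detect_eads(tr, tr.n_beats - 1))
        scans[dose] = a
        if np.isfinite(a) and a <= ref_apd + tolerance and n_ead == 0:
            result["equivalent_dose"] = dose
            break
        dose += step
    result["scan"] = scans
    return result
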