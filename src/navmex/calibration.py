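"""Calibration of construct parameters to experimental summary statistics.

The registry shipped in ``data/targets.json`` holds the per-construct summary
statistics (availability shifts, DIII-VSD activation anchors and half-maximal
voltages, late/peak current ratios, tonic and use-dependent IC50s,
fluorescence recovery time constants, late-current block) together with the
source quote for each number.  Calibration minimizes tolerance-normalized
residuals between simulated and target statistics; the optimizer acts on
named parameter handles (rate-law amplitudes and slopes, fluorescence
weights, drug-interaction scalars) with bounds derived from the rate-cap
guard.

The in silico "booster" is designed here as well: only the six DIII-VSD
movement rates of the M1652R model are retuned (drug-bound rates and all
other gating parameters frozen) to hyperpolarize availability by 15 mV and
at least double tonic and use-dependent block at 50 uM mexiletine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import protocols as pr
from .channel import MODEL, OPEN
from .params import DIII_LAWS, ConstructParameters
from .rates import RATE_CAP, RateLaw

#: concentration grid used for IC50 evaluation during fitting and reporting
IC50_GRID = np.logspace(-1, 3, 9)


# ----------------------------------------------------------------------
# Targets registry
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TargetEntry:
    id: str
    construct: str
    quantity: str
    args: Dict[str, float]
    value: float
    units: str
    weight: float
    tol: float
    quote: str
    location: str


class TargetValidationError(ValueError):
    pass


@dataclass
class CalibrationTargets:
    entries: List[TargetEntry]

    def __post_init__(self) -> None:
        errors = []
        seen = set()
        for e in self.entries:
            if not e.quote:
                errors.append(f"{e.id}: missing source quote")
            if not e.location:
                errors.append(f"{e.id}: missing source location")
            if e.weight <= 0:
                errors.append(f"{e.id}: weight must be positive")
            if e.tol <= 0:
                errors.append(f"{e.id}: tolerance must be positive")
            if e.id in seen:
                errors.append(f"{e.id}: duplicate id")
            seen.add(e.id)
        if errors:
            raise TargetValidationError("; ".join(errors))

    def for_construct(self, construct: str) -> List[TargetEntry]:
        return [e for e in self.entries if e.construct == construct]

    def by_id(self, target_id: str) -> TargetEntry:
        for e in self.entries:
            if e.id == target_id:
                return e
        raise KeyError(target_id)

    def to_dict(self) -> dict:
        return {"schema_version": 1,
                "targets": [vars(e) | {"args": dict(e.args)} for e in self.entries]}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def load_targets(path: str | Path | None = None) -> CalibrationTargets:
    """Load and validate the targets registry (default: the shipped one)."""
    if path is None:
        ref = resources.files("navmex").joinpath("data/targets.json")
        raw = json.loads(ref.read_text())
    else:
        raw = json.loads(Path(path).read_text())
    if raw.get("schema_version") != 1:
        raise TargetValidationError("unsupported targets schema version")
    entries = []
    for d in raw["targets"]:
        entries.append(TargetEntry(
            id=d["id"], construct=d["construct"], quantity=d["quantity"],
            args=dict(d.get("args", {})), value=float(d["value"]),
            units=d.get("units", ""), weight=float(d.get("weight", 1.0)),
            tol=float(d["tol"]), quote=d.get("quote", ""),
            location=d.get("location", "")))
    return CalibrationTargets(entries)


# ----------------------------------------------------------------------
# Quantity evaluation
# ----------------------------------------------------------------------

def evaluate_quantity(quantity: str, args: Mapping[str, float],
                      construct: str,
                      params_map: Mapping[str, ConstructParameters],
                      cache: Dict | None = None) -> float:
    """Simulate one summary statistic for one construct.

    ``params_map`` supplies the parameters of every construct a relative
    quantity may refer to (e.g. availability shifts versus WT, boosted block
    ratios versus the M1652R baseline).
    """
    cache = cache if cache is not None else {}
    p = params_map[construct]

    def memo(key, fn):
        if key not in cache:
            cache[key] = fn()
        return cache[key]

    if quantity == "ssa_vhalf":
        return memo(("ssa", construct), lambda: pr.run_ssa(p)).fit["v_half"]
    if quantity == "ssa_shift_vs_wt":
        vh = memo(("ssa", construct), lambda: pr.run_ssa(p)).fit["v_half"]
        vh0 = memo(("ssa", "WT"),
                   lambda: pr.run_ssa(params_map["WT"])).fit["v_half"]
        return vh - vh0
    if quantity == "ssa_shift_vs_base":
        vh = memo(("ssa", construct), lambda: pr.run_ssa(p)).fit["v_half"]
        vh0 = memo(("ssa", "M1652R"),
                   lambda: pr.run_ssa(params_map["M1652R"])).fit["v_half"]
        return vh - vh0
    if quantity == "diii_activation":
        return pr.diii_activation_at(p, float(args["v"]))
    if quantity == "rest_po_excess":
        # one-sided guard on the resting window current: log10 excess of the
        # equilibrium open probability at the diastolic potential over a
        # physiological ceiling (stable diastole in the coupled myocyte)
        v = float(args.get("v", -85.0))
        ceiling = float(args.get("ceiling", 3e-5))
        ss = MODEL.steady_state(p, v, 0.0)
        po = max(float(ss.p[OPEN]), 1e-12)
        return max(0.0, math.log10(po / ceiling))
    if quantity == "window_shape_excess":
        # one-sided guard: equilibrium open probability at the plateau
        # take-off voltage must not exceed the 0-mV persistent level, so the
        # late current does not form a re-excitation hump near threshold
        v = float(args.get("v", -35.0))
        po_v = max(float(MODEL.steady_state(p, v, 0.0).p[OPEN]), 1e-12)
        po_0 = max(float(MODEL.steady_state(p, 0.0, 0.0).p[OPEN]), 1e-12)
        return max(0.0, math.log10(po_v / po_0))
    if quantity == "fluor_vhalf":
        drug = float(args.get("drug", 0.0))
        return memo(("fluor", construct, drug),
                    lambda: pr.run_fluor_activation(p, drug)).fit["v_half"]
    if quantity == "late_peak_ratio":
        return memo(("late_peak", construct), lambda: pr.late_peak_ratio(p))
    if quantity == "tonic_ic50":
        return memo(("tonic", construct),
                    lambda: pr.run_tonic_block(p, IC50_GRID)).fit["ic50"]
    if quantity == "udb_ic50":
        return memo(("udb", construct),
                    lambda: pr.run_udb(p, IC50_GRID)).fit["ic50"]
    if quantity == "fluor_recovery_tau":
        drug = float(args.get("drug", 250.0))
        return memo(("fluor_rec", construct, drug),
                    lambda: pr.run_fluor_recovery(p, drug)).fit["tau1"]
    if quantity == "late_block":
        conc = float(args.get("conc", 75.0))
        return memo(("late_block", construct, conc),
                    lambda: pr.run_late_block(p, conc))
    if quantity == "block_ratio_vs_base":
        conc = float(args["conc"])
        proto = args.get("protocol", "tonic")
        b = memo(("block", construct, proto, conc),
                 lambda: pr.block_at(p, conc, proto))
        b0 = memo(("block", "M1652R", proto, conc),
                  lambda: pr.block_at(params_map["M1652R"], conc, proto))
        return b / max(b0, 1e-12)
    raise KeyError(f"unknown quantity {quantity!r}")


def objective(params_map: Mapping[str, ConstructParameters],
              targets: CalibrationTargets,
              subset: Sequence[str] | None = None) -> Dict[str, object]:
    """Weighted sum of squared tolerance-normalized residuals.

    Returns a dict with the scalar ``objective``, per-target simulated
    values and residuals.  The objective is zero iff every simulated
    statistic equals its target, and is invariant to target ordering.
    """
    cache: Dict = {}
    residuals: Dict[str, Dict[str, float]] = {}
    total = 0.0
    for e in targets.entries:
        if subset is not None and e.id not in subset:
            continue
        if e.construct not in params_map:
            continue
        sim = evaluate_quantity(e.quantity, e.args, e.construct, params_map, cache)
        r = (sim - e.value) / e.tol
        residuals[e.id] = {"simulated": sim, "target": e.value,
                           "residual": r, "weight": e.weight}
        total += e.weight * r * r
    return {"objective": total, "residuals": residuals}


# ----------------------------------------------------------------------
# Parameter handles
# ----------------------------------------------------------------------

@dataclass
class Handle:
    """A named, bounded, optionally log-transformed scalar on a parameter set."""

    name: str                       # e.g. "ax.A", "ay.invB", "w1", "drug.phi"
    lo: float
    hi: float
    log: bool = True

    def get(self, p: ConstructParameters) -> float:
        if "." in self.name:
            head, tail = self.name.split(".", 1)
            if head == "drug":
                val = p.drug[tail]
            else:
                law = p.laws[head]
                val = law.A if tail == "A" else law.inv_b
        else:
            val = getattr(p, self.name)
        return math.log(val) if self.log else val

    def set(self, p: ConstructParameters, x: float) -> None:
        val = math.exp(x) if self.log else x
        if "." in self.name:
            head, tail = self.name.split(".", 1)
            if head == "drug":
                p.drug[tail] = val
            else:
                law = p.laws[head]
                if tail == "A":
                    p.laws[head] = RateLaw(val, law.B)
                else:
                    b = math.inf if val == 0 else 1.0 / val
                    p.laws[head] = RateLaw(law.A, b)
        else:
            setattr(p, self.name, val)

    def bounds(self) -> tuple[float, float]:
        if self.log:
            return math.log(self.lo), math.log(self.hi)
        return self.lo, self.hi


def amplitude_handle(p: ConstructParameters, law: str,
                     span: float = 1e4) -> Handle:
    """Amplitude handle whose upper bound respects the rate-cap guard."""
    b = p.laws[law].B
    margin = 0.9 * RATE_CAP
    if math.isinf(b):
        hi = margin
    elif b > 0:
        hi = margin / math.exp(100.0 / b)
    else:
        hi = margin / math.exp(-200.0 / b)
    a0 = p.laws[law].A
    return Handle(f"{law}.A", max(a0 / span, 1e-12), min(hi, a0 * span), log=True)


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

@dataclass
class FitResult:
    params: ConstructParameters
    objective: float
    residuals: Dict[str, Dict[str, float]]
    seed: int
    converged: bool
    n_eval: int
    log: List[str] = field(default_factory=list)


def fit_construct(initial: ConstructParameters,
                  targets: CalibrationTargets,
                  handles: Sequence[Handle],
                  context: Mapping[str, ConstructParameters] | None = None,
                  subset: Sequence[str] | None = None,
                  seed: int = 0,
                  max_nfev: int = 200,
                  penalty: float = 30.0) -> FitResult:
    """Least-squares fit of the handle vector to the (subset of) targets.

    Kd is frozen structurally (it is not a handle), as are all parameters
    without a handle.  Deterministic given the initial parameters, handle
    list and seed.  Invalid parameter regions (rate-cap violations) return a
    large finite penalty residual so the optimizer retreats.
    """
    ctx = dict(context or {})
    work = initial.copy()
    x0 = np.array([h.get(work) for h in handles])
    lo = np.array([h.bounds()[0] for h in handles])
    hi = np.array([h.bounds()[1] for h in handles])
    x0 = np.clip(x0, lo, hi)
    entries = [e for e in targets.entries
               if (subset is None or e.id in subset)]
    n_eval = 0
    log: List[str] = []

    def residual_vec(x: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        trial = work.copy()
        try:
            for h, xi in zip(handles, x):
                h.set(trial, float(xi))
            trial.validate()
            ctx_trial = dict(ctx)
            ctx_trial[trial.construct] = trial
            cache: Dict = {}
            out = []
            for e in entries:
                sim = evaluate_quantity(e.quantity, e.args, e.construct,
                                        ctx_trial, cache)
                out.append(math.sqrt(e.weight) * (sim - e.value) / e.tol)
            return np.asarray(out)
        except Exception as exc:  # invalid region: finite penalty
            log.append(f"penalty at eval {n_eval}: {exc}")
            return np.full(len(entries), penalty)

    sol = least_squares(residual_vec, x0, bounds=(lo, hi), method="trf",
                        diff_step=0.02, max_nfev=max_nfev)
    fitted = work.copy()
    for h, xi in zip(handles, sol.x):
        h.set(fitted, float(xi))
    ctx_final = dict(ctx)
    ctx_final[fitted.construct] = fitted
    sub_ids = [e.id for e in entries]
    rep = objective(ctx_final, targets, subset=sub_ids)
    log.append(f"least_squares status {sol.status}, nfev {sol.nfev}, "
               f"cost {sol.cost:.4g}")
    return FitResult(params=fitted, objective=rep["objective"],
                     residuals=rep["residuals"], seed=seed,
                     converged=sol.status > 0, n_eval=n_eval, log=log)


# ----------------------------------------------------------------------
# Booster design
# ----------------------------------------------------------------------

def saturated_diii(p: ConstructParameters, factor: float = 1000.0
                   ) -> ConstructParameters:
    """Variant with the DIII-VSD biased fully up (backward steps slowed).

    Used as the asymptotic booster limit when exploring how far DIII-VSD
    modulation alone can move availability and block.
    """
    out = p.copy()
    for law in ("bx", "by", "b3"):
        out.laws[law] = out.laws[law].scaled(1.0 / factor)
    out.construct = p.construct + "_diii_saturated"
    return out


def design_booster(mr_fit: ConstructParameters,
                   targets: CalibrationTargets | None = None,
                   reference_conc: float = 50.0,
                   seed: int = 0,
                   max_nfev: int = 120) -> FitResult:
    """Design the in silico mexiletine booster from the fitted M1652R model.

    Only the amplitudes of the six DIII-VSD movement rates (ax, bx, ay, by,
    a3, b3) are free; every drug-bound parameter and all other gating rates
    are bit-identical to the M1652R baseline.  The design objective is the
    one stated for the booster: a 15-mV hyperpolarizing shift of drug-free
    availability and at least a doubling of tonic and use-dependent block at
    the 50-uM reference concentration.  IC50s of the boosted model are
    post-hoc outcomes, not design inputs.
    """
    base_ssa = pr.run_ssa(mr_fit).fit["v_half"]
    base_tonic = pr.block_at(mr_fit, reference_conc, "tonic")
    base_udb = pr.block_at(mr_fit, reference_conc, "udb")

    work = mr_fit.copy()
    work.construct = "M1652R_boosted"
    handles = [amplitude_handle(work, law, span=3e3) for law in DIII_LAWS]
    x0 = np.array([h.get(work) for h in handles])
    lo = np.array([h.bounds()[0] for h in handles])
    hi = np.array([h.bounds()[1] for h in handles])
    x0 = np.clip(x0, lo, hi)
    n_eval = 0
    log: List[str] = []

    def residual_vec(x: np.ndarray) -> np.ndarray:
        nonlocal n_eval
        n_eval += 1
        trial = work.copy()
        try:
            for h, xi in zip(handles, x):
                h.set(trial, float(xi))
            trial.validate()
            shift = pr.run_ssa(trial).fit["v_half"] - base_ssa
            rt = pr.block_at(trial, reference_conc, "tonic") / max(base_tonic, 1e-9)
            ru = pr.block_at(trial, reference_conc, "udb") / max(base_udb, 1e-9)
            # mild pull toward the unmodified rates: among feasible boosters
            # the smallest DIII modification is preferred (tie-break)
            reg = 0.02 * np.linalg.norm(x - x0)
            return np.array([
                (shift + 15.0) / 1.0,
                5.0 * max(0.0, 2.0 - rt),
                5.0 * max(0.0, 2.0 - ru),
                reg,
            ])
        except Exception as exc:
            log.append(f"penalty at eval {n_eval}: {exc}")
            return np.full(4, 30.0)

    sol = least_squares(residual_vec, x0, bounds=(lo, hi), method="trf",
                        diff_step=0.05, max_nfev=max_nfev)
    boosted = work.copy()
    for h, xi in zip(handles, sol.x):
        h.set(boosted, float(xi))

    # post-hoc report: IC50s plus the three untargeted validation predictions
    shift = pr.run_ssa(boosted).fit["v_half"] - base_ssa
    tonic = pr.run_tonic_block(boosted, IC50_GRID)
    udb = pr.run_udb(boosted, IC50_GRID)
    residuals = {
        "ssa_shift": {"simulated": shift, "target": -15.0,
                      "residual": (shift + 15.0) / 2.0, "weight": 1.0},
        "tonic_ratio50": {"simulated":
                          pr.block_at(boosted, reference_conc, "tonic") / base_tonic,
                          "target": 2.0, "residual": 0.0, "weight": 1.0},
        "udb_ratio50": {"simulated":
                        pr.block_at(boosted, reference_conc, "udb") / base_udb,
                        "target": 2.0, "residual": 0.0, "weight": 1.0},
    }
    log.append(f"post-hoc tonic IC50 {tonic.fit['ic50']:.1f} uM, "
               f"UDB IC50 {udb.fit['ic50']:.1f} uM")
    obj = float(sum(r["residual"] ** 2 for r in residuals.values()))
    return FitResult(params=boosted, objective=obj, residuals=residuals,
                     seed=seed, converged=sol.status > 0, n_eval=n_eval, log=log)


# ----------------------------------------------------------------------
# Synthetic clamp data (identifiability testing)
# ----------------------------------------------------------------------

def generate_synthetic_clamp_data(true_params: ConstructParameters,
                                  noise_sd: float = 0.02,
                                  seed: int = 0) -> Dict[str, Dict[str, np.ndarray]]:
    """Noisy availability / activation / fluorescence curves from known
    parameters, for parameter-recovery experiments.

    Additive Gaussian noise on the normalized responses; bit-reproducible
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ssa = pr.run_ssa(true_params)
    gv = pr.run_activation_gv(true_params)
    fl = pr.run_fluor_activation(true_params)
    out = {}
    for name, res in (("ssa", ssa), ("gv", gv), ("fluor_activation", fl)):
        out[name] = {"x": res.x.copy(),
                     "y": res.y + rng.normal(0.0, noise_sd, size=res.y.shape)}
    return out
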