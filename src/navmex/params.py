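"""Construct parameter sets and their JSON serialization.

A :class:`ConstructParameters` bundles the voltage-dependent rate laws of one
channel construct (WT, the LQT3 mutants M1652R / R1626P, or the
booster-modified M1652R), the conductance and fluorescence weights, and the
mexiletine interaction parameters.  The intrinsic dissociation constant of
mexiletine at the local-anesthetic receptor is held at 156 uM for every
construct, so simulated differences in apparent drug affinity arise from
DIII-VSD dynamics and state occupancy alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict

from .rates import InvalidParameterError, RateLaw, laws_from_dict, laws_to_dict

SCHEMA_VERSION = 1
KD_MEXILETINE = 156.0  # uM, fixed across constructs

#: elementary rate-law labels (see channel.py for the topology they live on)
LAW_NAMES = (
    "act1", "act2", "act3", "dea1", "dea2", "dea3",   # activation path
    "gam", "del", "oif", "ise", "isx",                # inactivation
    "ax", "bx", "ay", "by", "a3", "b3",               # DIII-VSD steps
)
#: DIII-VSD movement rates, the booster's only degrees of freedom
DIII_LAWS = ("ax", "bx", "ay", "by", "a3", "b3")

SCALAR_DEFAULTS = {
    "kon_o": 1.0e-3,   # uM^-1 ms^-1, binding from the open state
    "kon_c": 1.0e-4,   # uM^-1 ms^-1, binding from A2 closed states
    "kon_i": 0.0,      # binding from A2 inactivated states (receptor guarded)
    "kd": KD_MEXILETINE,
    "phi": 30.0,       # bound inactivated-state stabilization (modulated receptor)
    "m_act": 1.0,      # bound activation-path kinetic scale
    "m_rec": 0.2,      # bound closed<->inactivated kinetic scale
    "m_is": 1.0,       # bound slow-inactivation kinetic scale
    "m_oif": 1.0,      # bound open<->IF kinetic scale
}


@dataclass
class ConstructParameters:
    construct: str
    laws: Dict[str, RateLaw]
    gna: float = 12.0          # mS/uF
    w1: float = 0.5            # A1 fluorescence weight
    w2: float = 1.0            # A2 (+ bound) fluorescence weight, fixed
    late_scale: float = 1.0    # scales the open<->IF balance (late-current knob)
    drug: Dict[str, float] = field(default_factory=lambda: dict(SCALAR_DEFAULTS))

    def __post_init__(self) -> None:
        missing = [k for k in LAW_NAMES if k not in self.laws]
        if missing:
            raise InvalidParameterError(f"{self.construct}: missing rate laws {missing}")
        merged = dict(SCALAR_DEFAULTS)
        merged.update(self.drug)
        self.drug = merged
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.w2 < self.w1:
            raise InvalidParameterError("fluorescence weights must satisfy w2 >= w1")
        if not (0.0 <= self.w1 <= 1.0 and 0.0 < self.w2 <= 1.0):
            raise InvalidParameterError("fluorescence weights must lie in [0, 1]")
        if self.gna <= 0:
            raise InvalidParameterError("gNa must be positive")
        if self.late_scale <= 0:
            raise InvalidParameterError("late_scale must be positive")
        if abs(self.drug["kd"] - KD_MEXILETINE) > 1e-9:
            raise InvalidParameterError(
                f"intrinsic Kd is fixed at {KD_MEXILETINE} uM for all constructs")
        for k in ("kon_o", "kon_c", "kon_i"):
            if self.drug[k] < 0:
                raise InvalidParameterError(f"{k} must be non-negative")
        for k in ("phi", "m_act", "m_rec", "m_is", "m_oif"):
            if self.drug[k] <= 0:
                raise InvalidParameterError(f"{k} must be positive")
        for name, law in self.laws.items():
            law.validate(f"{self.construct}.{name}")

    # -- evaluation helpers ----------------------------------------------
    def effective_laws(self) -> Dict[str, RateLaw]:
        """Rate laws with the late-current scale folded into dea3.

        Scaling down the final deactivation rate deepens the open-state
        equilibrium at depolarized potentials, producing the slowly
        inactivating (late) current component; it enters every
        reversibility-derived monomial consistently, so cycle closure is
        preserved exactly.
        """
        if self.late_scale == 1.0:
            return self.laws
        out = dict(self.laws)
        out["dea3"] = self.laws["dea3"].scaled(1.0 / self.late_scale)
        return out

    def scalars(self) -> Dict[str, float]:
        return dict(self.drug)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "construct": self.construct,
            "laws": laws_to_dict(self.laws),
            "gna": self.gna,
            "w1": self.w1,
            "w2": self.w2,
            "late_scale": self.late_scale,
            "drug": dict(self.drug),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstructParameters":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise InvalidParameterError(
                f"unsupported parameter schema version {d.get('schema_version')}")
        return cls(
            construct=d["construct"],
            laws=laws_from_dict(d["laws"]),
            gna=float(d["gna"]),
            w1=float(d["w1"]),
            w2=float(d["w2"]),
            late_scale=float(d.get("late_scale", 1.0)),
            drug={k: float(v) for k, v in d.get("drug", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ConstructParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def copy(self) -> "ConstructParameters":
        return ConstructParameters(
            construct=self.construct,
            laws=dict(self.laws),
            gna=self.gna, w1=self.w1, w2=self.w2,
            late_scale=self.late_scale,
            drug=dict(self.drug),
        )


def load_construct(name: str) -> ConstructParameters:
    """Load one of the calibrated parameter files shipped with the package.

    Valid names: WT, M1652R, R1626P, M1652R_boosted.
    """
    ref = resources.files("navmex").joinpath(f"data/params/{name}.json")
    with resources.as_file(ref) as path:
        if not path.exists():
            raise FileNotFoundError(f"no shipped parameter file for construct {name!r}")
        return ConstructParameters.load(path)
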