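"""Starting parameter sets for calibration.

These are physiologically plausible NaV1.5 gating rates (activation settling
within a few hundred microseconds at 0 mV, fast inactivation within ~1 ms,
steady-state availability near -85 mV for WT) with per-construct DIII-VSD
equilibria placed at the experimentally anchored positions.  They are the
deterministic initial guesses from which the calibrated, shipped parameter
files were produced; they are not themselves calibrated models.
"""

from __future__ import annotations

from typing import Dict

from .params import ConstructParameters
from .rates import RateLaw


def _pair(v_half: float, inv_s: float, k0: float, split: float = 0.5
          ) -> tuple[RateLaw, RateLaw]:
    """Forward/backward pair with K(V) = exp(inv_s*(V - v_half)).

    ``split`` is the fraction of the voltage dependence carried by the
    forward rate; both rates equal k0 at V = v_half.
    """
    import math
    inv_bf = split * inv_s
    inv_bb = inv_bf - inv_s
    a_f = k0 * math.exp(-inv_bf * v_half)
    a_b = k0 * math.exp(-inv_bb * v_half)
    bf = math.inf if inv_bf == 0 else 1.0 / inv_bf
    bb = math.inf if inv_bb == 0 else 1.0 / inv_bb
    return RateLaw(a_f, bf), RateLaw(a_b, bb)


def _base_laws() -> Dict[str, RateLaw]:
    laws: Dict[str, RateLaw] = {}
    # Activation path of the gating core (C3-C2-C1-O and the parallel
    # closed-inactivated row).
    laws["act1"], laws["dea1"] = _pair(-43.0, 0.08, 1.2, split=0.52)
    laws["act2"], laws["dea2"] = _pair(-47.0, 0.08, 1.2, split=0.52)
    laws["act3"], laws["dea3"] = _pair(-50.0, 0.07, 2.5, split=0.5)
    # Closed/open -> inactivated balance: equilibrium slope ~7.5 mV sets the
    # availability-curve steepness.
    laws["gam"], laws["del"] = _pair(-82.0, 1 / 7.5, 0.012, split=0.45)
    # O -> IF entry (fast inactivation, tau < 1 ms at 0 mV); recovery IF -> O
    # is reversibility-derived.
    laws["oif"] = RateLaw(2.8, 1e9)
    # Slow inactivation off IF.
    laws["ise"] = RateLaw(0.004, 1e9)
    laws["isx"] = RateLaw(0.004, 1e9)
    # DIII-VSD: first step (R <-> A1), shallow; second step (A1 <-> A2).
    laws["ax"], laws["bx"] = _pair(-115.0, 1 / 12.0, 0.35, split=0.3)
    laws["ay"], laws["by"] = _pair(-78.0, 1 / 9.0, 0.2, split=0.4)
    laws["a3"], laws["b3"] = _pair(-78.0, 1 / 9.0, 0.2, split=0.4)
    return laws


def initial_guess(construct: str) -> ConstructParameters:
    laws = _base_laws()
    w1 = 0.45
    late = 1.0
    if construct == "R1626P":
        # DIII trapped up: both steps hyperpolarized; SSA slightly
        # hyperpolarized; largest late current.
        laws["ax"], laws["bx"] = _pair(-150.0, 1 / 12.0, 0.35, split=0.25)
        laws["ay"], laws["by"] = _pair(-135.0, 1 / 9.0, 0.2, split=0.3)
        laws["a3"], laws["b3"] = _pair(-135.0, 1 / 9.0, 0.2, split=0.3)
        laws["gam"], laws["del"] = _pair(-90.0, 1 / 7.5, 0.012, split=0.42)
        late = 10.0
    elif construct == "M1652R":
        # DIII biased down at rest; SSA depolarized by ~15 mV.
        laws["ax"], laws["bx"] = _pair(-105.0, 1 / 14.0, 0.35, split=0.3)
        laws["ay"], laws["by"] = _pair(-68.0, 1 / 9.0, 0.15, split=0.45)
        laws["a3"], laws["b3"] = _pair(-68.0, 1 / 9.0, 0.15, split=0.45)
        laws["gam"], laws["del"] = _pair(-67.0, 1 / 7.5, 0.012, split=0.45)
        late = 6.7
    elif construct != "WT":
        raise ValueError(f"unknown construct {construct!r}")
    return ConstructParameters(construct=construct, laws=laws, w1=w1,
                               late_scale=late)
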