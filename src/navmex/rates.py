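"""Voltage-dependent transition-rate laws.

Every elementary transition in the channel model follows a single-exponential
voltage dependence ``rate(V) = A * exp(V / B)`` with amplitude ``A`` (ms^-1)
and voltage sensitivity ``B`` (mV).  ``B`` may be signed (negative for rates
that speed up on hyperpolarization) and ``B = inf`` encodes a
voltage-independent rate.  Derived rates (those fixed by microscopic
reversibility) are monomials in the elementary laws, and a monomial of
exponentials is itself of the same functional form, so cycle closure is exact
at every voltage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np

#: Voltage window (mV) over which every rate law must remain finite and bounded.
V_MIN, V_MAX = -200.0, 100.0
#: Numerical guard: no rate may exceed this anywhere in the voltage window.
RATE_CAP = 1.0e3  # ms^-1


class InvalidParameterError(ValueError):
    """A rate law is non-finite, non-positive or exceeds the guard cap."""


@dataclass(frozen=True)
class RateLaw:
    """rate(V) = A * exp(V / B), A in ms^-1, B in mV (B = inf: constant)."""

    A: float
    B: float = math.inf

    def __post_init__(self) -> None:
        if not (self.A > 0.0 and math.isfinite(self.A)):
            raise InvalidParameterError(f"rate amplitude must be positive, got A={self.A}")
        if self.B == 0.0 or math.isnan(self.B):
            raise InvalidParameterError(f"voltage sensitivity B={self.B} is not a valid slope")

    @property
    def inv_b(self) -> float:
        return 0.0 if math.isinf(self.B) else 1.0 / self.B

    def __call__(self, v: float) -> float:
        return self.A * math.exp(self.inv_b * v)

    def validate(self, name: str = "rate") -> None:
        """Check positivity and the RATE_CAP guard over [V_MIN, V_MAX]."""
        for v in (V_MIN, V_MAX):
            r = self(v)
            if not math.isfinite(r) or r <= 0.0:
                raise InvalidParameterError(f"{name}: rate({v:+.0f} mV) = {r} is not finite/positive")
            if r > RATE_CAP:
                raise InvalidParameterError(
                    f"{name}: rate({v:+.0f} mV) = {r:.3g} ms^-1 exceeds cap {RATE_CAP:g}"
                )

    def scaled(self, factor: float) -> "RateLaw":
        return RateLaw(self.A * factor, self.B)


def compose(laws: Mapping[str, RateLaw], monomial: Mapping[str, float]) -> RateLaw:
    """Product of rate laws raised to (signed) integer powers.

    Used for reversibility-derived rates: the result is again A'*exp(V/B')
    with ``A' = prod A_k^e_k`` and ``1/B' = sum e_k / B_k``.
    """
    log_a = 0.0
    inv_b = 0.0
    for name, exp in monomial.items():
        law = laws[name]
        log_a += exp * math.log(law.A)
        inv_b += exp * law.inv_b
    b = math.inf if inv_b == 0.0 else 1.0 / inv_b
    return RateLaw(math.exp(log_a), b)


def equilibrium_pair(v_half: float, slope: float, k0: float, b_kin: float | None = None
                     ) -> tuple[RateLaw, RateLaw]:
    """Forward/backward pair with equilibrium K(V) = exp((V - v_half)/slope).

    ``k0`` is the shared kinetic amplitude: both rates equal ``k0`` at
    ``V = v_half``.  ``b_kin`` optionally skews how the voltage dependence is
    split between the two directions (default: symmetric split, each carrying
    half of 1/slope).  Convenience constructor for calibration.
    """
    if b_kin is None:
        inv_bf = 0.5 / slope
    else:
        inv_bf = 1.0 / b_kin
    inv_bb = inv_bf - 1.0 / slope
    a_f = k0 * math.exp(-inv_bf * v_half)
    a_b = k0 * math.exp(-inv_bb * v_half)
    bf = math.inf if inv_bf == 0 else 1.0 / inv_bf
    bb = math.inf if inv_bb == 0 else 1.0 / inv_bb
    return RateLaw(a_f, bf), RateLaw(a_b, bb)


def laws_to_dict(laws: Dict[str, RateLaw]) -> Dict[str, Dict[str, float]]:
    return {k: {"A": law.A, "B": law.B} for k, law in laws.items()}


def laws_from_dict(d: Mapping[str, Mapping[str, float]]) -> Dict[str, RateLaw]:
    return {k: RateLaw(float(v["A"]), float(v["B"])) for k, v in d.items()}


def rate_table(laws: Mapping[str, RateLaw], v: np.ndarray) -> Dict[str, np.ndarray]:
    """Vectorized evaluation of every law on a voltage grid."""
    return {k: law.A * np.exp(law.inv_b * np.asarray(v)) for k, law in laws.items()}
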