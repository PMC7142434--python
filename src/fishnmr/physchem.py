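"""Closed-form physicochemical indices: cooking loss, WHC, whiteness."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "MassPair",
    "ColorTriplet",
    "cooking_loss",
    "water_holding_capacity",
    "whiteness",
]


@dataclass(frozen=True)
class MassPair:
    """Sample masses in grams before and after a treatment step."""

    before_g: float
    after_g: float

    def __post_init__(self) -> None:
        if not self.before_g > 0:
            raise ValueError(f"before_g must be positive, got {self.before_g}")
        if self.after_g < 0:
            raise ValueError(f"after_g must be >= 0, got {self.after_g}")


@dataclass(frozen=True)
class ColorTriplet:
    """CIELAB-style color reading: L lightness 0-100, a redness, b yellowness."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0 <= self.L <= 100:
            raise ValueError(f"L must be in [0, 100], got {self.L}")


def _mass_loss_pct(m: MassPair, what: str) -> float:
    pct = (m.before_g - m.after_g) / m.before_g * 100.0
    if pct < 0:
        # weight gain (e.g. oil uptake during frying) is information, not an error
        warnings.warn(f"negative {what}: sample gained weight", stacklevel=3)
    return pct


def cooking_loss(m: MassPair) -> float:
    """Cooking loss % = (W_initial - W_final) / W_initial x 100."""
    return _mass_loss_pct(m, "cooking loss")


def water_holding_capacity(m: MassPair) -> float:
    """WHC % = (W_b - W_a) / W_b x 100 across a centrifugation step."""
    return _mass_loss_pct(m, "water-holding capacity")


def whiteness(c: ColorTriplet) -> float:
    """Whiteness index W = 100 - sqrt((100 - L)^2 + a^2 + b^2)."""
    return 100.0 - math.sqrt((100.0 - c.L) ** 2 + c.a**2 + c.b**2)
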