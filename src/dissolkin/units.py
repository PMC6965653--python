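"""Unit conventions and conversions.

Internal working units are hours (time), nanograms (mass), mg/L (analyte
concentration) and cm² (surface area); public interfaces accept and report
the conventional laboratory units (mg, m²/g, mL/h, days).  The
surface-normalized dissolution rate k is carried in ng/cm²/h throughout,
which is the conventional unit of flow-cell dissolution testing.
"""

from __future__ import annotations

import math

__all__ = [
    "LN2",
    "HOURS_PER_DAY",
    "BA_SO4_PER_BA",
    "round_sig",
    "bet_to_cm2_per_ng",
    "cm2_per_ng_to_bet",
    "mg_to_ng",
    "ng_to_ug",
    "hours_to_days",
    "days_to_hours",
]

LN2 = math.log(2.0)
HOURS_PER_DAY = 24.0

#: Stoichiometric mass ratio m(BaSO4)/m(Ba) = 233.39 / 137.33.
BA_SO4_PER_BA = 233.39 / 137.33


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures, ties to even (report display
    convention; internal values always keep full precision)."""
    x = float(x)
    if x == 0 or not math.isfinite(x):
        return x
    from decimal import ROUND_HALF_EVEN, Decimal

    exponent = math.floor(math.log10(abs(x))) - (sig - 1)
    quantum = Decimal(1).scaleb(exponent)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_EVEN))


def bet_to_cm2_per_ng(bet: float) -> float:
    """Convert a BET specific surface area from m²/g to cm²/ng.

    1 m²/g = 1e4 cm² / 1e9 ng = 1e-5 cm²/ng, so e.g. 41 m²/g → 4.1e-4 cm²/ng.
    """
    if not bet > 0:
        raise ValueError(f"BET specific surface area must be positive, got {bet!r}")
    return bet * 1e-5


def cm2_per_ng_to_bet(area: float) -> float:
    """Inverse of :func:`bet_to_cm2_per_ng` (cm²/ng → m²/g)."""
    if not area > 0:
        raise ValueError(f"specific surface area must be positive, got {area!r}")
    return area * 1e5


def mg_to_ng(mg: float) -> float:
    return mg * 1e6


def ng_to_ug(ng: float) -> float:
    return ng * 1e-3


def hours_to_days(hours: float) -> float:
    return hours / HOURS_PER_DAY


def days_to_hours(days: float) -> float:
    return days * HOURS_PER_DAY
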