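"""Lung-clearance rate arithmetic.

Total particle clearance from the rat lung is the sum of mechanical
(macrophage-mediated) clearance and dissolution clearance, both first-order:
``b_tot = b_mech + b_diss``.  Poorly-soluble low-toxicity (PSLT) particles
define the mechanical baseline, with a retention half-time of ~70 days,
i.e. ``b_mech ≈ 0.01/d``.  Subtracting that baseline from an observed total
clearance rate isolates the dissolution component; at steady state under
continuous exposure the total clearance rate is the daily deposited dose
over the equilibrium lung burden.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .units import LN2
from .kinetics import halftime_from_b

__all__ = [
    "B_MECH_PSLT",
    "PSLT_HALF_TIME",
    "InVivoStudy",
    "SteadyStateInput",
    "DissolutionBand",
    "decompose",
    "compose_total_halftime",
    "clearance_from_steady_state",
    "predict_invivo_halftime",
    "grouping_band",
]

#: Mechanical (macrophage-mediated) clearance rate constant for PSLT
#: particles in the rat, 1/d.  The operative rounded constant used in
#: clearance decompositions; the underlying ~70 d retention half-time gives
#: ln2/70 = 0.0099/d.
B_MECH_PSLT = 0.01
PSLT_HALF_TIME = 70.0


@dataclass(frozen=True)
class InVivoStudy:
    """Observed total lung retention decomposed into clearance components.

    Rates are fractional per day; ``dissolution_indistinguishable`` is set
    when the observed clearance is no faster than the mechanical baseline,
    in which case ``b_diss`` is clamped to 0 and the dissolution half-time
    is infinite.
    """

    label: str
    t_half_total: float  # d
    b_tot: float  # 1/d
    b_mech: float  # 1/d
    b_diss: float  # 1/d
    t_half_diss: float  # d
    route: str = ""
    dissolution_indistinguishable: bool = False


@dataclass(frozen=True)
class SteadyStateInput:
    """Deposition/burden pair at clearance equilibrium."""

    daily_deposition: float  # mass/d
    equilibrium_burden: float  # mass, same unit

    def __post_init__(self) -> None:
        if self.daily_deposition < 0:
            raise ValueError("daily deposition must be >= 0")
        if not self.equilibrium_burden > 0:
            raise ValueError("equilibrium burden must be positive")


def decompose(
    t_half_total: float,
    b_mech: float = B_MECH_PSLT,
    label: str = "",
    route: str = "",
) -> InVivoStudy:
    """Split an observed total retention half-time into mechanical and
    dissolution clearance.

    ``b_tot = ln2/t_half_total``; ``b_diss = b_tot − b_mech``.  A negative
    difference means dissolution is indistinguishable from the mechanical
    baseline and is flagged rather than reported as a negative rate.
    """
    if not t_half_total > 0:
        raise ValueError("total retention half-time must be positive")
    if b_mech < 0:
        raise ValueError("mechanical clearance rate must be >= 0")
    b_tot = LN2 / t_half_total
    b_diss = b_tot - b_mech
    flagged = b_diss <= 0
    b_diss = max(b_diss, 0.0)
    return InVivoStudy(
        label=label,
        route=route,
        t_half_total=t_half_total,
        b_tot=b_tot,
        b_mech=b_mech,
        b_diss=b_diss,
        t_half_diss=halftime_from_b(b_diss),
        dissolution_indistinguishable=flagged,
    )


def compose_total_halftime(study: InVivoStudy) -> float:
    """Re-compose the total half-time from the components (exact inverse of
    :func:`decompose` when nothing was clamped)."""
    return predict_invivo_halftime(study.b_diss, study.b_mech)


def clearance_from_steady_state(inp: SteadyStateInput) -> float:
    """Total clearance rate constant (1/d) at deposition/clearance
    equilibrium: daily deposition over equilibrium burden."""
    return inp.daily_deposition / inp.equilibrium_burden


def predict_invivo_halftime(b_diss_abiotic: float, b_mech: float = B_MECH_PSLT) -> float:
    """Predicted total retention half-time (d) when an abiotic dissolution
    rate acts alongside mechanical clearance: ``ln2/(b_diss + b_mech)``."""
    if b_diss_abiotic < 0 or b_mech < 0:
        raise ValueError("rate constants must be >= 0")
    total = b_diss_abiotic + b_mech
    return math.inf if total == 0 else LN2 / total


class DissolutionBand(str, enum.Enum):
    """Decadic grouping bands for surface-normalized dissolution rates."""

    INSIGNIFICANT = "insignificant"  # k < 1 ng/cm²/h
    SLOW = "slow"  # 1 <= k < 10
    PARTIAL = "partial"  # 10 <= k < 100
    FAST = "fast"  # k >= 100, half-times on the order of a day

    @property
    def range_label(self) -> str:
        return {
            DissolutionBand.INSIGNIFICANT: "<1",
            DissolutionBand.SLOW: "[1,10)",
            DissolutionBand.PARTIAL: "[10,100)",
            DissolutionBand.FAST: ">=100",
        }[self]


def grouping_band(k: float) -> DissolutionBand:
    """Assign a dissolution rate (ng/cm²/h) to its decadic grouping band.

    Bands are left-closed: exactly 1.0 falls in [1, 10).
    """
    if k < 0:
        raise ValueError("dissolution rate must be >= 0")
    if k < 1:
        return DissolutionBand.INSIGNIFICANT
    if k < 10:
        return DissolutionBand.SLOW
    if k < 100:
        return DissolutionBand.PARTIAL
    return DissolutionBand.FAST
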