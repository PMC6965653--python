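"""Domain types for flow-cell dissolution experiments.

A dissolution run is described by a :class:`Material` (what was loaded into
the cell), an ordered list of :class:`EluateFraction` records (what came out,
fraction by fraction) and run-level metadata bundled in :class:`FlowCellRun`.
TEM size measurements enter as :class:`SizeSample` diameter lists.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

__all__ = [
    "Geometry",
    "LodPolicy",
    "Material",
    "EluateFraction",
    "FlowCellRun",
    "SizeSample",
    "NM220",
]

#: Time gap between consecutive fractions below which boundaries are snapped
#: together (fraction collectors switch tubes with a small dead time).
GAP_SNAP_H = 1.0 / 60.0


class Geometry(str, enum.Enum):
    """Flow-cell geometry / test format."""

    FLOW_THROUGH = "flow_through"
    FLOW_BY = "flow_by"
    STATIC = "static"
    QUASI_DYNAMIC = "quasi_dynamic"


class LodPolicy(str, enum.Enum):
    """Replacement rule for concentrations below the limit of detection."""

    ZERO = "zero"
    HALF_LOD = "half_lod"
    LOD = "lod"

    def censored_value(self, lod: float) -> float:
        if self is LodPolicy.ZERO:
            return 0.0
        if self is LodPolicy.HALF_LOD:
            return lod / 2.0
        return lod


@dataclass(frozen=True)
class Material:
    """Powder descriptors needed to normalize dissolution data.

    Parameters
    ----------
    initial_mass : float
        Loaded particle mass M0 in mg.
    bet_area : float
        BET specific surface area in m²/g.
    stoich_factor : float
        Mass ratio particle/analyte (e.g. m(BaSO4)/m(Ba) = 1.6995); the
        measured analyte masses are multiplied by this to recover dissolved
        particle mass.
    density : float, optional
        Bulk density in g/cm³ (used only by morphology/simulation).
    d0_median, d0_gsd : float, optional
        Median diameter (nm) and geometric SD of the initial number-weighted
        size distribution.
    """

    name: str
    initial_mass: float
    bet_area: float
    stoich_factor: float
    density: Optional[float] = None
    d0_median: Optional[float] = None
    d0_gsd: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.initial_mass > 0:
            raise ValueError(f"initial_mass must be > 0, got {self.initial_mass!r}")
        if not self.bet_area > 0:
            raise ValueError(f"bet_area must be > 0, got {self.bet_area!r}")
        if not self.stoich_factor > 0:
            raise ValueError(f"stoich_factor must be > 0, got {self.stoich_factor!r}")
        if self.d0_median is not None and not self.d0_median > 0:
            raise ValueError(f"d0_median must be > 0, got {self.d0_median!r}")

    @property
    def initial_mass_ng(self) -> float:
        return self.initial_mass * 1e6


#: The OECD benchmark BaSO4 nanomaterial grade (NM-220): BET 41 m²/g,
#: TEM median diameter ~32 nm, barite density 4.5 g/cm³.
NM220 = Material(
    name="BaSO4 NM-220",
    initial_mass=1.0,
    bet_area=41.0,
    stoich_factor=233.39 / 137.33,
    density=4.5,
    d0_median=32.2,
    d0_gsd=1.54,
)


@dataclass(frozen=True)
class EluateFraction:
    """One collected eluate fraction.

    ``conc`` is the analyte concentration in mg/L, ``volume`` the eluted
    volume in mL over [t_start, t_end] (hours since loading).
    """

    t_start: float
    t_end: float
    conc: float
    volume: float
    below_lod: bool = False

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(
                f"fraction must have t_end > t_start, got [{self.t_start}, {self.t_end}]"
            )
        if self.conc < 0:
            raise ValueError(f"negative concentration {self.conc!r}")
        if self.volume < 0:
            raise ValueError(f"negative volume {self.volume!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)

    @property
    def analyte_mass_ug(self) -> float:
        """Analyte mass in this fraction, µg (mg/L × mL = µg)."""
        return self.conc * self.volume


@dataclass(frozen=True)
class FlowCellRun:
    """A complete dissolution experiment record."""

    material: Material
    geometry: Geometry
    fractions: tuple[EluateFraction, ...]
    medium: str = ""
    temperature: float = 37.0
    residual_solid_mass: Optional[float] = None  # mg
    membrane_mass: Optional[float] = None  # mg, analyte trapped in membrane/cell
    lod: float = 0.01  # mg/L
    mass_tolerance: float = 0.05

    def __post_init__(self) -> None:
        fractions = tuple(sorted(self.fractions, key=lambda f: f.t_start))
        object.__setattr__(self, "fractions", fractions)
        if isinstance(self.geometry, str) and not isinstance(self.geometry, Geometry):
            object.__setattr__(self, "geometry", Geometry(self.geometry))
        self._check_contiguity()
        self._check_mass_plausibility()

    def _check_contiguity(self) -> None:
        healed = []
        prev_end = None
        for i, f in enumerate(self.fractions):
            if prev_end is not None:
                gap = f.t_start - prev_end
                if gap < -1e-9:
                    raise ValueError(f"overlapping intervals at row {i}")
                if gap > GAP_SNAP_H:
                    raise ValueError(
                        f"gap of {gap:.3f} h before row {i} exceeds {GAP_SNAP_H*60:.0f} min"
                    )
                if gap > 1e-12:  # snap small collector dead time
                    f = replace(f, t_start=prev_end)
            healed.append(f)
            prev_end = f.t_end
        object.__setattr__(self, "fractions", tuple(healed))

    def _check_mass_plausibility(self) -> None:
        if not self.fractions:
            return
        eluted_particle_mg = (
            sum(f.analyte_mass_ug for f in self.fractions)
            * self.material.stoich_factor
            * 1e-3
        )
        if eluted_particle_mg > self.material.initial_mass * (1 + self.mass_tolerance):
            raise ValueError(
                f"eluted particle mass {eluted_particle_mg:.3g} mg exceeds loaded "
                f"{self.material.initial_mass:.3g} mg beyond tolerance"
            )

    @property
    def duration(self) -> float:
        """Total test duration T in hours (end of the last fraction)."""
        return self.fractions[-1].t_end if self.fractions else 0.0

    def mass_balance(self) -> Optional[float]:
        """Recovered mass as a fraction of M0, when residuals were recorded.

        Sums eluted analyte (stoichiometry-adjusted), residual solids and
        analyte retained in the membrane; returns None when no residual
        measurement is available.
        """
        if self.residual_solid_mass is None:
            return None
        eluted_particle_mg = (
            sum(f.analyte_mass_ug for f in self.fractions)
            * self.material.stoich_factor
            * 1e-3
        )
        total = eluted_particle_mg + self.residual_solid_mass + (self.membrane_mass or 0.0)
        return total / self.material.initial_mass


@dataclass(frozen=True)
class SizeSample:
    """A list of measured particle diameters (nm), e.g. from TEM counting."""

    diameters: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        diameters = tuple(float(d) for d in self.diameters)
        if len(diameters) < 1:
            raise ValueError("SizeSample requires at least one diameter")
        if any(not d > 0 or not math.isfinite(d) for d in diameters):
            raise ValueError("all diameters must be positive and finite")
        object.__setattr__(self, "diameters", diameters)

    @property
    def n(self) -> int:
        return len(self.diameters)


def censor_concentrations(
    fractions: Sequence[EluateFraction], lod: float, policy: LodPolicy
) -> tuple[EluateFraction, ...]:
    """Apply the LOD censoring policy, flagging affected fractions."""
    policy = LodPolicy(policy)
    out = []
    for f in fractions:
        if f.conc < lod:
            out.append(replace(f, conc=policy.censored_value(lod), below_lod=True))
        else:
            out.append(f)
    return tuple(out)
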