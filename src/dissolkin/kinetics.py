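"""Dissolution-rate evaluation for flow-cell eluate series.

Three complementary evaluations of the same raw eluate data:

* **Cumulative rate** ``k`` (ng/cm²/h): the total dissolved fraction at the
  end of the test divided by test duration and initial specific surface,
  ``k = (M_ion(T)/M0) / (T · BET)``.
* **First-order fit** ``b_diss`` (1/d): ordinary least squares of
  ``ln(retained fraction)`` against time; the half-time is ``t'½ = ln2/b``.
* **Instantaneous rates** ``k(t)`` (ng/cm²/h): per-fraction dissolved mass
  divided by the surface area remaining at the start of the interval,
  ``SA(t) = BET · (M0 − M_ion(t))``, and by the interval length.

The two half-time routes (fit vs. conversion of the cumulative rate via
``t½ = ln2/(k·BET)``) coincide when the release is genuinely first-order
*and* the dissolved fraction is small (the cumulative fraction per unit time
approximates the rate constant only to first order in ``b·T``).

A regime diagnostic classifies each run as first-order, saturated (release
pinned at a solubility ceiling, hence zero-order/linear), mixed, or
insufficient.  The model comparison is done on the per-fraction
concentration series, where measurement errors are independent: first-order
kinetics imply exponentially decaying eluate concentrations, a solubility
ceiling implies constant ones.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import FlowCellRun
from .units import (
    HOURS_PER_DAY,
    LN2,
    bet_to_cm2_per_ng,
    hours_to_days,
    ng_to_ug,
)

__all__ = [
    "Regime",
    "CumulativeSeries",
    "RateSample",
    "FirstOrderFit",
    "KineticsResult",
    "cumulative_dissolved",
    "cumulative_rate_k",
    "fit_first_order",
    "halftime_from_b",
    "b_from_halftime",
    "halftime_from_k",
    "k_from_halftime",
    "instantaneous_rates",
    "diagnose_regime",
    "analyze",
    "nominal_dissolved_fraction",
]

#: AICc margin below which the exponential and constant-concentration models
#: are considered indistinguishable ("mixed" regime).
AICC_MARGIN = 2.0
#: Fractional window around the ceiling concentration that the last third of
#: the fractions must stay inside for a "saturated_linear" verdict.
CEILING_WINDOW = 0.2


class Regime(str, enum.Enum):
    FIRST_ORDER = "first_order"
    SATURATED_LINEAR = "saturated_linear"
    MIXED = "mixed"
    INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class CumulativeSeries:
    """Cumulative dissolved mass at fraction-end times.

    ``dissolved_mass`` is on the particle-mass basis (stoichiometry applied),
    in ng; ``dissolved_fraction`` is relative to M0.  ``daily_release`` is
    the mean release M_ion/T in µg/d over the whole test.
    """

    times: tuple[float, ...]  # h, fraction ends
    dissolved_mass: tuple[float, ...]  # ng, particle basis
    dissolved_fraction: tuple[float, ...]
    daily_release: float  # µg/d
    below_lod: tuple[bool, ...] = ()

    @property
    def final_fraction(self) -> float:
        return self.dissolved_fraction[-1] if self.dissolved_fraction else 0.0

    @property
    def duration(self) -> float:
        return self.times[-1] if self.times else 0.0


@dataclass(frozen=True)
class RateSample:
    """Instantaneous rate for one sampling interval.

    ``sa`` is the remaining surface area (cm²) at the interval start;
    ``sa_over_v_paper`` follows the conventional mixed-unit reporting of
    flow-cell studies (SA in m² divided by flow in cm³/h, printed as
    "h/cm"); ``sa_over_v`` is the dimensionally consistent ratio in
    cm²·h/cm³.
    """

    t_mid: float  # h
    k_inst: float  # ng/cm²/h
    sa: float  # cm²
    sa_over_v_paper: float  # (SA in m²) / (flow in cm³/h)
    sa_over_v: float  # cm² h / cm³
    flow: float  # mL/h


@dataclass(frozen=True)
class FirstOrderFit:
    b_diss: float  # 1/d; 0.0 when non-dissolving
    t_half: float  # d; inf when non-dissolving
    r2: float
    n_used: int
    n_excluded: int = 0
    non_dissolving: bool = False


@dataclass(frozen=True)
class KineticsResult:
    """Rates, half-times and regime classification for one run."""

    k_cum: float  # ng/cm²/h
    b_diss: float  # 1/d
    t_half_fit: float  # d
    t_half_from_k: float  # d
    fit_r2: float
    regime: Regime
    ceiling_conc: float  # mg/L
    daily_release: float  # µg/d
    dissolved_fraction_final: float
    instantaneous: tuple[RateSample, ...] = ()
    non_dissolving: bool = False


# ---------------------------------------------------------------------------
# cumulative evaluation


def cumulative_dissolved(run: FlowCellRun) -> CumulativeSeries:
    """Cumulate the stoichiometry-adjusted dissolved mass over the fractions.

    ``dissolved_mass[j] = stoich_factor · Σ_{i≤j} c_i · vol_i`` (mg/L × mL =
    µg of analyte, converted to ng of particle mass).
    """
    if not run.fractions:
        return CumulativeSeries((), (), (), 0.0, ())
    stoich = run.material.stoich_factor
    m0_ng = run.material.initial_mass_ng
    times, masses, flags = [], [], []
    cum_ng = 0.0
    for f in run.fractions:
        cum_ng += f.analyte_mass_ug * stoich * 1e3  # µg → ng
        times.append(f.t_end)
        masses.append(cum_ng)
        flags.append(f.below_lod)
    total_days = hours_to_days(times[-1])
    daily = ng_to_ug(masses[-1]) / total_days if total_days > 0 else 0.0
    return CumulativeSeries(
        times=tuple(times),
        dissolved_mass=tuple(masses),
        dissolved_fraction=tuple(m / m0_ng for m in masses),
        daily_release=daily,
        below_lod=tuple(flags),
    )


def cumulative_rate_k(dissolved_fraction_final: float, duration_h: float, bet: float) -> float:
    """Cumulative surface-normalized rate ``k = fraction / (T · BET)`` in ng/cm²/h."""
    if not 0 <= dissolved_fraction_final <= 1 + 1e-9:
        raise ValueError(
            f"dissolved fraction must lie in [0, 1], got {dissolved_fraction_final!r}"
        )
    if not duration_h > 0:
        raise ValueError(f"test duration must be positive, got {duration_h!r}")
    return dissolved_fraction_final / (duration_h * bet_to_cm2_per_ng(bet))


# ---------------------------------------------------------------------------
# half-time conversions


def halftime_from_b(b: float) -> float:
    """Half-time in days from a fractional rate constant b (1/d)."""
    if b < 0:
        raise ValueError(f"rate constant must be >= 0, got {b!r}")
    return math.inf if b == 0 else LN2 / b


def b_from_halftime(t_half: float) -> float:
    """Fractional rate constant (1/d) from a half-time (d)."""
    if t_half < 0:
        raise ValueError(f"half-time must be >= 0, got {t_half!r}")
    if t_half == 0:
        raise ValueError("half-time must be positive")
    return 0.0 if math.isinf(t_half) else LN2 / t_half


def halftime_from_k(k: float, bet: float) -> float:
    """Half-time (d) from a surface-normalized rate: ``t½ = ln2/(k·BET)``.

    ``k`` in ng/cm²/h, BET in m²/g; the product k·BET (with BET converted to
    cm²/ng) is a first-order rate constant in 1/h.
    """
    if not k > 0:
        raise ValueError(f"rate must be positive, got {k!r}")
    return hours_to_days(LN2 / (k * bet_to_cm2_per_ng(bet)))


def k_from_halftime(t_half: float, bet: float) -> float:
    """Surface-normalized rate (ng/cm²/h) from a half-time (d); inverse of
    :func:`halftime_from_k`."""
    if not t_half > 0:
        raise ValueError(f"half-time must be positive, got {t_half!r}")
    return LN2 / (t_half * HOURS_PER_DAY * bet_to_cm2_per_ng(bet))


# ---------------------------------------------------------------------------
# first-order fit


def fit_first_order(series: CumulativeSeries) -> FirstOrderFit:
    """OLS of ln(retained fraction) against time, slope → b_diss.

    Uses fraction-end times and a free intercept.  Points with retained
    fraction ≤ 0 and points whose fraction was below the detection limit are
    excluded; fewer than 3 usable points means the fit is not attempted.
    """
    t = np.asarray(series.times, dtype=float)
    r = 1.0 - np.asarray(series.dissolved_fraction, dtype=float)
    flags = (
        np.asarray(series.below_lod, dtype=bool)
        if series.below_lod
        else np.zeros_like(t, dtype=bool)
    )
    usable = (r > 0) & ~flags
    n_excluded = int((~usable).sum())
    if usable.sum() < 3:
        return FirstOrderFit(0.0, math.inf, math.nan, int(usable.sum()), n_excluded, True)
    res = stats.linregress(t[usable], np.log(r[usable]))
    if res.slope >= 0:
        return FirstOrderFit(
            0.0, math.inf, res.rvalue**2, int(usable.sum()), n_excluded, True
        )
    b_per_day = -res.slope * HOURS_PER_DAY
    return FirstOrderFit(
        b_diss=b_per_day,
        t_half=LN2 / b_per_day,
        r2=res.rvalue**2,
        n_used=int(usable.sum()),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# instantaneous rates


def instantaneous_rates(run: FlowCellRun) -> list[RateSample]:
    """Per-fraction rates ``k(t) = ΔM_ion / SA(t_start) / Δt``.

    The surface area is taken at the interval *start* (``SA = BET·(M0 −
    M_ion)`` with M_ion cumulated up to the interval start), so the
    interval's own dissolution does not reduce the surface it is normalized
    by.  Once the solid is exhausted (SA ≤ 0) the remaining intervals are
    omitted with a warning.
    """
    bet_cm2_ng = bet_to_cm2_per_ng(run.material.bet_area)
    m0_ng = run.material.initial_mass_ng
    stoich = run.material.stoich_factor
    samples: list[RateSample] = []
    cum_ng = 0.0
    for i, f in enumerate(run.fractions):
        sa = bet_cm2_ng * (m0_ng - cum_ng)
        if sa <= 0:
            warnings.warn(
                f"solid exhausted before fraction {i}; omitting remaining "
                f"{len(run.fractions) - i} rate samples",
                stacklevel=2,
            )
            break
        dm_ng = f.analyte_mass_ug * stoich * 1e3
        flow = f.volume / f.duration  # mL/h ≡ cm³/h
        sa_m2 = sa * 1e-4
        samples.append(
            RateSample(
                t_mid=f.t_mid,
                k_inst=dm_ng / sa / f.duration,
                sa=sa,
                sa_over_v_paper=sa_m2 / flow if flow > 0 else math.inf,
                sa_over_v=sa / flow if flow > 0 else math.inf,
                flow=flow,
            )
        )
        cum_ng += dm_ng
    return samples


# ---------------------------------------------------------------------------
# regime diagnostics


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, n * 1e-30)
    return n * math.log(rss / n) + 2 * k + (2 * k * (k + 1)) / max(n - k - 1, 1)


def diagnose_regime(
    series: CumulativeSeries,
    run: FlowCellRun,
    aicc_margin: float = AICC_MARGIN,
    ceiling_window: float = CEILING_WINDOW,
) -> tuple[Regime, float]:
    """Classify the release kinetics and estimate the concentration ceiling.

    First-order release implies per-fraction concentrations decaying
    exponentially with time; zero-order (ceiling-limited) release implies a
    linear cumulative mass, i.e. constant concentrations.  Both models are
    fit to ``ln c`` at fraction midpoints and compared by corrected AIC.
    The first collected fraction is excluded (it averages over the cell
    fill/equilibration transient).  A first-order verdict requires the
    exponential model to win by ``aicc_margin`` *and* the fitted decline
    over the observation window to exceed 10% — a statistically preferred
    exponential whose total decline is smaller than that is below the
    resolution at which the two shapes differ.  A saturated verdict
    requires a fitted decline below 10% together with the last third of the
    concentrations lying within ``ceiling_window`` of the ceiling, which is
    estimated as the upper-quartile (75th-percentile) concentration.
    Everything else is mixed.

    Returns ``(regime, ceiling_conc)`` with the ceiling in mg/L.  Note the
    classification sees only the eluate shape: a genuinely first-order but
    very slow release (well under 10% concentration decline over the test)
    is indistinguishable from ceiling-limited release and will be called
    saturated/mixed on shape grounds.
    """
    usable = [f for f in run.fractions if f.conc > 0 and not f.below_lod]
    if len(usable) >= 5:
        usable = [f for f in usable if f is not run.fractions[0]]
    concs = np.array([f.conc for f in usable], dtype=float)
    ceiling = float(np.quantile(concs, 0.75)) if concs.size else 0.0
    n = concs.size
    if n < 4:
        return Regime.INSUFFICIENT, ceiling
    t = np.array([f.t_mid for f in usable], dtype=float)
    y = np.log(concs)

    res = stats.linregress(t, y)
    rss_exp = float(np.sum((y - (res.intercept + res.slope * t)) ** 2))
    rss_const = float(np.sum((y - y.mean()) ** 2))
    # parameter counts include the residual variance
    delta = _aicc(rss_exp, n, 3) - _aicc(rss_const, n, 2)
    span = float(t[-1] - t[0])
    decline = 1.0 - math.exp(res.slope * span) if res.slope < 0 else 0.0

    if delta < -aicc_margin and res.slope < 0 and decline > 0.10:
        return Regime.FIRST_ORDER, ceiling
    if decline <= 0.10:
        last_third = concs[-max(1, n // 3):]
        if ceiling > 0 and np.all(
            np.abs(last_third - ceiling) <= ceiling_window * ceiling
        ):
            return Regime.SATURATED_LINEAR, ceiling
    return Regime.MIXED, ceiling


# ---------------------------------------------------------------------------
# composition


def analyze(run: FlowCellRun) -> KineticsResult:
    """Full kinetic evaluation of one run (cumulative, fit, instantaneous,
    regime)."""
    series = cumulative_dissolved(run)
    if not series.times:
        return KineticsResult(
            k_cum=0.0,
            b_diss=0.0,
            t_half_fit=math.inf,
            t_half_from_k=math.inf,
            fit_r2=math.nan,
            regime=Regime.INSUFFICIENT,
            ceiling_conc=0.0,
            daily_release=0.0,
            dissolved_fraction_final=0.0,
            non_dissolving=True,
        )
    k_cum = cumulative_rate_k(
        min(series.final_fraction, 1.0), series.duration, run.material.bet_area
    )
    fit = fit_first_order(series)
    regime, ceiling = diagnose_regime(series, run)
    if fit.non_dissolving and fit.n_used < 3:
        regime = Regime.INSUFFICIENT
    t_half_from_k = halftime_from_k(k_cum, run.material.bet_area) if k_cum > 0 else math.inf
    return KineticsResult(
        k_cum=k_cum,
        b_diss=fit.b_diss,
        t_half_fit=fit.t_half,
        t_half_from_k=t_half_from_k,
        fit_r2=fit.r2,
        regime=regime,
        ceiling_conc=ceiling,
        daily_release=series.daily_release,
        dissolved_fraction_final=series.final_fraction,
        instantaneous=tuple(instantaneous_rates(run)),
        non_dissolving=fit.non_dissolving,
    )


def nominal_dissolved_fraction(conc_mg_L: float, suspension_mg_mL: float) -> float:
    """Nominal dissolved fraction of a static suspension.

    Measured dissolved analyte-equivalent concentration (mg/L) over the
    nominal suspension concentration (mg/mL ≡ 1000 mg/L); e.g. 8 mg/L in a
    10 mg/mL suspension → 0.0008 (0.08%).
    """
    if not suspension_mg_mL > 0:
        raise ValueError("suspension concentration must be positive")
    if conc_mg_L < 0:
        raise ValueError("measured concentration must be >= 0")
    return conc_mg_L / (suspension_mg_mL * 1e3)
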