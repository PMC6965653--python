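"""Shared test helpers: synthetic analytic eluate runs."""

import math

from dissolkin.datamodel import EluateFraction, FlowCellRun, Geometry, Material, NM220


def make_run(concs, vols=None, bounds=None, material=NM220):
    n = len(concs)
    if bounds is None:
        bounds = [24.0 * i for i in range(n + 1)]
    if vols is None:
        vols = [48.0] * n
    fractions = tuple(
        EluateFraction(bounds[i], bounds[i + 1], concs[i], vols[i]) for i in range(n)
    )
    return FlowCellRun(material=material, geometry=Geometry.FLOW_THROUGH, fractions=fractions)


def exponential_run(b_per_day, m0_mg=1.0, days=7, per_day=1, stoich=1.6995):
    """Fraction concentrations of an exact first-order release."""
    mat = Material(
        name="exp", initial_mass=m0_mg, bet_area=41.0, stoich_factor=stoich,
        density=4.5, d0_median=32.2,
    )
    b = b_per_day / 24.0
    bounds = [24.0 * i / per_day for i in range(days * per_day + 1)]
    concs, vols = [], []
    for t0, t1 in zip(bounds, bounds[1:]):
        released_ug = m0_mg * 1e3 * (math.exp(-b * t0) - math.exp(-b * t1))
        vol = 2.0 * (t1 - t0)
        concs.append(released_ug / stoich / vol)
        vols.append(vol)
    return make_run(concs, vols, bounds, material=mat)
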