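"""Simulate flow-cell dissolution below and at the solubility ceiling.

Runs the mechanistic simulator for a low (0.17 mg) and a high (50 mg)
loading of BaSO4 NM-220 and shows how the same material produces
first-order kinetics in one case and ceiling-limited (zero-order) release
in the other.
"""

from dissolkin import analyze
from dissolkin.simulate import make_fixture, simulate
from dissolkin.units import round_sig

for name in ("subsat_flowthrough", "saturated_flowthrough"):
    cfg = make_fixture(name, seed=42)
    run, _ = simulate(cfg)
    result = analyze(run)
    print(f"{name} (M0 = {cfg.material.initial_mass} mg):")
    print(f"  daily release M_ion/T : {round_sig(result.daily_release)} µg/d")
    print(f"  fitted b_diss         : {round_sig(result.b_diss * 100)} %/d")
    print(f"  eluate ceiling        : {round_sig(result.ceiling_conc)} mg/L")
    print(f"  regime                : {result.regime.value}")
# At 0.17 mg the eluate stays well below the 1 mg/L solubility ceiling and
# ~50% dissolves within a week (first-order).  At 50 mg the eluate is
# pinned at the ceiling: daily release saturates near flow x c_sat
# (2 mL/h x 1 mg/L ~ 48 µg/d of analyte) and the apparent b_diss collapses.
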