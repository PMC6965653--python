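# dissolkin

Dissolution kinetics of nanomaterials in abiotic flow cells — from
eluate-fraction time series to surface-normalized dissolution rates,
first-order half-times, saturation diagnostics, lung-clearance
decomposition and particle-transformation (Ostwald ripening) checks, with a
mechanistic flow-cell simulator for generating synthetic eluate data.

## The problem

Whether an inhaled particle persists in the lung depends on two parallel
first-order clearance routes: mechanical (macrophage-mediated) removal,
with a rate constant b_mech ≈ 0.01/d in the rat (t½ ≈ 70 d), and
dissolution. Static solubility assays grossly understate the dissolution of
sparingly soluble salts such as BaSO₄, because a closed system hits its
solubility ceiling and stops. Continuous-flow (flow-through or flow-by)
cells keep the system away from equilibrium, like the lung does, and the
resulting abiotic dissolution rates predict in vivo retention.

`dissolkin` implements the complete evaluation chain for such experiments:

* **Cumulative rate** (per ISO 19057 conventions):
  `k = (M_ion(T)/M₀) / (T · BET)` in ng/cm²/h, where M_ion(T) is the
  stoichiometry-adjusted dissolved mass cumulated over all eluate fractions
  (Σ cᵢ·Vᵢ·Δtᵢ) and BET the specific surface area.
* **First-order fit**: OLS of ln(retained fraction) vs. time;
  `b_diss = ln2 / t′½`. The two half-time routes,
  `t′½ = ln2/b_diss` and `t½ = ln2/(k·BET)`, coincide for genuinely
  exponential decay at small dissolved fractions.
* **Instantaneous rates**: `k(t) = ΔM_ion / SA(t) / Δt` with
  `SA(t) = BET·(M₀ − M_ion(t))`, plotted against SA/V — for a saturating
  material the points collapse onto a single decreasing relationship; for a
  non-saturating one k(t) is flat.
* **Regime diagnosis**: first-order vs. ceiling-limited (zero-order)
  release, by model comparison on the eluate concentration series, with an
  estimate of the concentration ceiling.
* **Biokinetics**: decomposition `b_diss = b_tot − b_mech` of observed
  retention half-times, steady-state clearance from deposition/burden, the
  decadic grouping bands (<1, 1–10, 10–100, ≥100 ng/cm²/h), and prediction
  of total retention from an abiotic rate.
* **Morphology**: shrinking-sphere prediction `d = d₀(1−f)^⅓` against
  observed TEM size distributions; growth beyond threshold indicates
  dissolution–reprecipitation (Ostwald ripening) instead of shrinkage.
* **Simulator**: a population-balance forward model of the flow cell with a
  solubility ceiling, Gibbs–Thomson curvature term
  `c_s(d) = c_sat·exp(λ/d)`, flow-by membrane exchange, measurement noise
  and LOD censoring — the synthetic stand-in for wet-lab runs.

## Worked example

```python
import dissolkin as dk
from dissolkin.simulate import make_fixture, simulate

run, _ = simulate(make_fixture("subsat_flowthrough", seed=42))
result = dk.analyze(run)
print(result.b_diss, result.t_half_fit, result.regime)
```

Running `python examples/02_simulate_flowcell.py` prints:

```
subsat_flowthrough (M0 = 0.17 mg):
  daily release M_ion/T : 12.3 µg/d
  fitted b_diss         : 10.2 %/d
  eluate ceiling        : 0.199 mg/L
  regime                : first_order
saturated_flowthrough (M0 = 50.0 mg):
  daily release M_ion/T : 84.6 µg/d
  fitted b_diss         : 0.171 %/d
  eluate ceiling        : 1.08 mg/L
  regime                : saturated_linear
```

At 0.17 mg loading the eluate stays well below the 1 mg/L solubility
ceiling: roughly half the material dissolves within a week (b ≈ 10 %/d,
t′½ ≈ 6.8 d) and the kinetics are first-order. At 50 mg the eluate is
pinned at the ceiling: the daily release saturates near flow × c_sat
(2 mL/h × 1 mg/L ≈ 48 µg/d of analyte) and the apparent fractional rate
collapses — the same material now looks "insoluble". The other example
scripts cover eluate CSV analysis (`01`), in vivo clearance decomposition
(`03`: a 9.6 d total retention half-time splits into 6.2 %/d dissolution
plus 1 %/d mechanical clearance) and the ripening morphology check (`04`).

A thin CLI wraps the same functions:

```sh
dissolkin simulate --fixture subsat_flowthrough --seed 42 --out run.csv
dissolkin analyze --eluate run.csv --out report.json
dissolkin invivo --t-half-total 56
dissolkin group --k 10.3
```

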