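# Methods

## Scope and model

`dissolkin` evaluates continuous-flow dissolution experiments and emulates
them. The chain has four parts: (i) kinetic evaluation of eluate-fraction
tables, (ii) a regime diagnostic separating first-order from
ceiling-limited release, (iii) biokinetic arithmetic linking abiotic rates
to lung clearance, and (iv) morphology rules separating uniform shrinkage
from dissolution–reprecipitation. A mechanistic flow-cell simulator serves
as the synthetic-data generator.

## Units and conventions

Internally: time in hours, mass in nanograms, analyte concentration in
mg/L, surface area in cm². Public interfaces use laboratory units (mg,
m²/g, mL/h, days). The surface-normalized rate k is ng/cm²/h; the
conversion BET (m²/g) → cm²/ng is ×10⁻⁵, so 41 m²/g ≡ 4.1·10⁻⁴ cm²/ng.
Rates k are on the particle-mass basis: measured analyte masses are
multiplied by the particle/analyte stoichiometric factor (1.6995 for
BaSO₄/Ba) before any rate is formed. Report displays round to 3
significant figures, ties to even; internal values keep full precision.

## Kinetic evaluation

**Cumulative.** Dissolved mass is the running sum of cᵢ·volᵢ over
fractions, stoichiometry applied; `k = (M_ion(T)/M₀)/(T·BET)` with T the
end of the last fraction. k is invariant under refinement of the sampling
grid for a fixed release profile.

**First-order fit.** OLS of ln(1 − dissolved fraction) at fraction-end
times, free intercept; b_diss = −slope (converted to 1/d), t′½ = ln2/b.
Points with non-positive retained fraction or below-LOD fractions are
excluded; fewer than three usable points yields an "insufficient" flag, a
non-negative slope a "non-dissolving" flag (b = 0, infinite half-time).

**Consistency of the two half-time routes.** t½ = ln2/(k·BET) equals t′½
only when the decay is exponential *and* b·T ≪ 1, because the cumulative
fraction per unit time is (1 − e^(−bT))/T ≈ b only to first order. At
b·T = 0.7 (half of the material dissolved during the test) the conversion
half-time overshoots the fitted one by ~30%. Consistency tests therefore
use slow exact exponentials (b·T ≈ 0.016), where agreement to <1% is a
genuine property, not a tolerance.

**Instantaneous rates.** Per fraction, ΔM_ion/SA/Δt with SA evaluated at
the interval start from SA = BET·(M₀ − M_ion); timestamps are interval
midpoints. Changes of size distribution and shape are deliberately ignored
here; the shrinking-sphere model is used only for morphology predictions.
Two SA/V values are reported: the dimensionally consistent cm²·h/cm³ and
the conventional mixed-unit one (SA in m² over flow in cm³/h, "h/cm"),
under which 1 mg of a 41 m²/g powder at 2 mL/h gives SA/V = 0.0205 h/cm.

## Regime diagnostic

First-order release implies exponentially decaying eluate concentrations;
ceiling-limited (zero-order) release implies constant ones. Both models
are fit to ln c at fraction midpoints — in increment space, where
measurement errors are independent, rather than on cumulative series whose
errors are autocorrelated — and compared by corrected AIC (margin 2). The
first fraction is excluded as the cell fill/equilibration transient. A
first-order verdict additionally requires the fitted decline over the
window to exceed 10%: below that the two shapes differ by less than
realistic measurement resolution, and a statistical preference either way
is noise. A saturated verdict requires a <10% decline plus a plateau: the
last third of the concentrations within 20% of the ceiling, estimated as
the 75th-percentile concentration. Everything else is "mixed". The
classifier sees only eluate shape; a genuinely first-order but very slow
release is indistinguishable from ceiling-limited release and is labelled
by shape. Thresholds (AICc margin 2, decline 10%, plateau window 20%) are
package constants exposed as function arguments.

## Biokinetics

Total lung clearance is the sum of mechanical and dissolution clearance,
both first-order: b_tot = ln2/t½(total), b_diss = b_tot − b_mech with
b_mech = 0.01/d for poorly-soluble low-toxicity particles in the rat
(stored as the operative rounded constant; the underlying ~70 d half-time
gives 0.0099/d). A non-positive difference is flagged
"dissolution-indistinguishable" rather than reported as a negative rate.
At steady state under continuous exposure, b_tot = daily deposition /
equilibrium burden. Grouping bands are decadic and left-closed: <1
(insignificant), [1,10) (slow), [10,100) (partial), ≥100 ng/cm²/h (fast,
half-times of order one day). Species scaling is a pass-through: human
b_mech must be supplied by the user.

## Morphology

Shrinking-sphere prediction d = d₀(1−f)^⅓ for dissolved mass fraction f.
The transformation verdict compares the observed number-weighted median
diameter (TEM counting convention) with that prediction: a ratio above 1.2
is called transformation growth; fewer than 30 measured particles, or an
unknown dissolved fraction, is indeterminate. The 1.2 threshold separates
genuine ripening signatures (observed/predicted well above 1.5 in
flow-cell data) from counting scatter and is configurable.

## Flow-cell simulator

**Population.** `n_bins` (default 64) equal-count quantile bins of a
lognormal number-size distribution (defaults: median 32.2 nm, GSD 1.54,
matching a ±16 nm spread); each bin carries a fixed particle count and a
continuously evolving diameter (moving-bin hybrid). Density default
4.5 g/cm³.

**Fluxes.** Per bin, dmᵢ/dt = −k₀·Aᵢ·f(c/c_s(dᵢ)) with
f(x) = clip(1 − xⁿ, −1, 1) and c_s(d) = c_sat·exp(λ/d). The sharp exponent
n (default 8) encodes surface-reaction-limited dissolution with
reprecipitation near equilibrium: observed flow-cell kinetics stay
first-order even when the eluate reaches a third of the ceiling, which a
linear Noyes–Whitney driving force (n = 1, available by setting the
exponent) cannot reproduce — it would bend those curves by tens of
percent. Above a bin's curvature-corrected solubility the flux reverses
into growth; with λ > 0 this transfers mass from small to large particles
(Ostwald ripening). λ is a visibility knob for curvature physics, not a
fitted physical constant.

**Surface-area closures.** Default `area_model="bet"`: Aᵢ = BET·mᵢ, i.e.
the specific surface stays at its measured value, making sub-saturation
release exactly first-order — consistent with how the analysis equations
treat surface area. Alternative `"geometric"`: Aᵢ = Nᵢπdᵢ², under which
diameters shrink linearly and small particles vanish in finite time. The
geometric closure is what expresses ripening in the size distribution (the
number median can only rise when fines actually disappear), at the cost of
a few-percent deviation from exponential bulk decay; the ripening fixture
uses it, rate-analysis fixtures use the BET closure.

**Solute balances.** Well-mixed compartments. Flow-through: one
compartment flushed at the eluent flow; flow-by: a particle chamber
exchanging with the flushed channel only through a membrane transfer
coefficient (mL/h), which both slows apparent dissolution (dissolved
inventory in transit) and lowers the observable ceiling (default
1.3 mL/h against 3 mL/h flow reproduces a ~0.3 mg/L channel ceiling under
a 1 mg/L chamber ceiling). Eluate fraction concentrations are
flow-weighted means over the sampling interval.

**Integration.** Solid fluxes use start-of-step areas (explicit); the
solute concentration is advanced by backward Euler, solved per step by
bracketed root finding. The solute balance is stiff near the ceiling at
high loadings, where a fully explicit update either oscillates (biasing
eluate concentrations upward by ~15%) or forces prohibitively small steps;
the implicit concentration is L-stable and unconditionally damped. Steps
are halved automatically whenever any bin would lose more than 5% of its
mass (retrying down to 10⁻⁷ h before aborting), and grow back toward the
configured maximum (default 0.05 h). Mass is conserved to round-off by
construction — the solid update, compartment inventories and eluted mass
use the same fluxes — and checked to 10⁻⁶ relative at every fraction
boundary; violation aborts the run. Bins below 1 nm dissolve outright.

**Measurement layer.** Multiplicative lognormal noise with mean one
(default CV 5% for the benchmark fixtures, matching elemental-analysis
repeatability) applied to reported concentrations only, never to state;
LOD censoring (defaults 0.01 mg/L, policy half-LOD) flags affected
fractions. Identical configuration and seed give byte-identical eluate
CSVs.

**Fixtures.** `subsat_flowthrough` (0.17 mg, 2 mL/h, c_sat 1 mg/L,
k₀ = 10.3 ng/cm²/h): eluate peaks near 0.35 mg/L and ~50% dissolves in a
week (t′½ ≈ 6.8 d) — the sub-saturation regime. The intrinsic rate is the
1 mg cumulative value rather than the 0.17 mg row of the benchmark tables:
at 44.7 ng/cm²/h even 0.17 mg would release ~75 µg/d, above the
flow-removal capacity flow·c_sat ≈ 48 µg/d, i.e. that condition is itself
mildly saturated and unusable as a clean recovery fixture.
`saturated_flowthrough` (50 mg, otherwise identical): ceiling-pinned
zero-order release. `flowby` (0.8 mg, 3 mL/h, membrane 1.3 mL/h).
`cuo_like`: no ceiling, no curvature — instantaneous rates flat in SA/V.
`ripening`: flow-by chamber, geometric areas, λ = 4 nm, 90 simulated days.

## What the simulator does and does not emulate

It reproduces first-order sub-saturation release, the concentration
ceiling and zero-order saturated release, the flow-rate proportionality of
saturated release (doubling flow doubles it), the flow-by rate and ceiling
reduction, LOD censoring, measurement noise, and curvature-driven
coarsening under confinement. It does **not** resolve local concentration
gradients: interface velocities are capped near 2k₀/ρ ≈ 1 nm/d at BaSO₄'s
intrinsic rate, so the pronounced coarsening observed in real cells within
~72 h — which implies supersaturated microenvironments inside the particle
bed — only develops over weeks in a well-mixed model, and only in the
confined flow-by chamber; in flow-through the flow washes ions out before
redistribution wins. Passing tests therefore validate the evaluation chain
and the qualitative physics, not sub-cell transport. Temperature and
medium composition enter only as user-set rate/solubility changes; redox
chemistry, protein binding and multi-pool in vivo kinetics are out of
scope.

## Problem sizes

Test-suite simulations use the standard 7-day sampling plan (twelve 2-h
fractions, then daily) at 64 bins; the ripening demonstration runs 90
simulated days. The full suite completes in well under a minute on one
core; noisy parameter-recovery statistics use five seeds.
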