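# Methods

This note documents the models behind `cagereactor`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Equilibrium speciation

**Model.** Components `j` (the cage and up to two guests) with analytical
totals `T_j`; complexes `s` with overall formation constants `β_s` and
integer stoichiometries `ν_sj`. Mass balance:
`T_j = x_j + Σ_s ν_sj β_s Π_k x_k^ν_sk` in the free concentrations `x_j`.
The acetonitrile solvate of the cage is the reference "free host" state;
acetonitrile is never an explicit component, so every `K` and `β` is
defined relative to the solvate. No protonation equilibria, activity
coefficients or ionic-strength corrections: the system is neutral in an
organic solvent at mM concentrations.

**Solver.** Newton iterations on `u = ln x` (positivity by construction)
with the symmetric positive-definite log-space Jacobian
`J_jk = δ_jk x_j + Σ_s ν_sj ν_sk c_s`, a backtracking line search on the
scaled residual norm, and a log-step cap of 5 per iteration. Initial guess
`x = T` (always feasible). Convergence target: relative balance error
≤ 1e−12, accepted up to 1e−9; failure raises an error carrying the last
residual. Components with a total of exactly zero are eliminated together
with every species containing them. With `β` spanning 1e7–1e9 M⁻² and mM
totals the iteration converges in ≲ 30 steps; the test suite cross-checks
it against a nested-bisection brute force and the 1:1 closed form.

**Constants.** Stepwise constants are stored per ordered guest pair;
overall `β` as log10. The published tables give two values for the second
stepwise constant of the alkyne guest (1.2e3 in the running text, 1.3e3 in
the constants table); the text value is the default because it is the one
consistent with the reported cooperativity factor 0.15, and the table
variant ships alongside (`constants.stepwise_constants("table")`).
Reported values are rounded to 2 significant figures; internal math is
full precision.

## Binding-constant estimation

Tight binding plus slow exchange means titrations yield *concentration
ratios* of resolved species (NMR integrals), not chemical-shift isotherms.
The estimation objective is a least-squares comparison of log-ratios,

`χ² = Σ_i ((ln r_sim,i − ln r_obs,i)/σ_i)²`,

because integral errors are multiplicative. The published procedure
("fine-tuning" simulated speciation profiles) does not specify weights or
an algorithm, so this objective is this package's documented choice, not a
transcription. Minimisation: full-factorial scan on a log10(β) grid
(default ±2 log units, 0.1 steps, matching the 1e3–1e5 M⁻¹ span of the
constants) followed by Nelder–Mead refinement; a flat objective across the
scan raises a non-identifiability error instead of returning an arbitrary
grid point. The staged protocol is preserved: homo constants fitted first,
then held fixed while only the heteroternary `β` is free.

**ITC.** The sequential two-site isotherm is simulation-only (no raw
thermograms are available to fit). Injections use displacement
bookkeeping: injecting `dv` into a cell of volume `V₀` expels `dv` at the
pre-injection composition, totals mix linearly, and the heat of injection
is the enthalpy difference between the post-injection equilibrium state
and the retained fraction of the pre-injection state. Cumulative heat then
equals the enthalpy-weighted complex content of the final cell plus all
displaced aliquots — an exact state-function identity the tests verify to
1e−9. The experimental average constant (4.5e4 M⁻¹) came from fitting real
data and is not recomputable; only shape properties are asserted (a single
sigmoid inflecting at a guest/host ratio of 2, collapsing to 1 when the
second site is disabled).

## Kinetic networks

**In-cage model.** Nine species: cage solvate, two free guests, two 1:1
complexes, two 2:1 homocomplexes, the heteroternary (Michaelis) complex,
and the bound product. Six reversible binding steps with
`k_on = 1e7 M⁻¹s⁻¹` for every step and `k_off = k_on/K_step` — only the
ratios are thermodynamically constrained, and the fitted `k_intra` is
verified to move < 1% when the reference on-rate spans 1e6–1e8 M⁻¹s⁻¹.
The heterocomplex forms along both addition orders (two distinct
reversible paths), which is what makes the path-consistency check
meaningful. One irreversible step, ternary → product complex, rate
constant `k_intra`. Two documented switches default to off: the
uncatalysed background reaction (negligible at mM totals) and product
release (product binding K > 1e8 M⁻¹ suppresses turnover).

**Integration.** Stiff implicit integrator (BDF) with analytic mass-action
Jacobian, rtol 1e−8, atol 1e−15 M; rate constants span ~12 orders of
magnitude. Host and guest conservation hold to 1e−7 relative along every
trajectory, and with `k_intra = 0` the long-time state matches the
equilibrium solver to 1e−6 relative — the strongest structural
cross-module test.

**Estimators.** Initial rates: `v₀` per run by linear regression of the
product concentration over the early window (at least 3 points; when a
plateau level is supplied, points below 10% of it), then
`k_intra = Σ v₀ c / Σ c²` — regression through the origin of `v₀` against
the ternary concentration. Full-curve: the irreversible step's rate
constant is the only free parameter; a 25-point logarithmic scan brackets
the optimum (warning if multimodal), then bounded scalar minimisation on
log10(k). The bulk reaction is the two-channel parallel second-order
system; its fit ties the 1,5 channel to the 1,4 channel through the fixed
regioselectivity ratio (default 2:1). `time_to_conversion` inverts the
integrated second-order law exactly (the logarithmic form for unequal
initial concentrations); at 2 mM reactants and k = 5.6e−8 M⁻¹s⁻¹ it gives
≈ 283 years to 1 mM product — the closed-form value, slightly below the
~317-year figure quoted in prose, whose rounding provenance is unclear.

**Acceleration metrics.** `EM = k_intra/k_bulk` exactly;
`ΔS = −R ln(EM/1 M)` with R = 1.9872 cal·mol⁻¹·K⁻¹, T = 298.15 K;
`ΔΔG = T|ΔS|`. EM is reported to 2 significant figures, ΔS to one
decimal.

## Synthetic data

The generators emulate derived concentration-level observables only — no
line shapes, chemical shifts or chromatograms. NMR-like observables carry
5% multiplicative lognormal noise (typical integral precision); HPLC-like
observables 3% additive Gaussian noise relative to the largest signal.
Both levels are assumptions exposed as parameters, since the source does
not state measurement precision. Sampling defaults: titrations at 0.5–2.0
guest equivalents; cage kinetics at 0.5, 1, 2, 4, 8, 12, 24, 36, 48 h;
bulk kinetics 8 points over 10 days at 25 mM.

**Initial-rates runs.** The kinetic runs are characterised by their
measured ternary-complex concentrations (0.54, 0.32, 0.10 mM), which the
speciation model with the published constants does not exactly reproduce
from the stated total compositions. The generator therefore constructs an
exactly equilibrated network state with the ternary complex pinned at the
prescribed value: both free guests at 5 mM (an excess-guest regime that
buffers the ternary concentration), the free cage solved from `β_het`,
and every other complex from its own `β`, so all six equilibria hold by
construction. Runs are sampled at 15-minute intervals over 2 h. Even
noise-free, the estimator carries a small (~4%) downward bias from the
slow drain of the ternary complex over the window — real initial-rate
analyses share this property, and it is well inside the reported
uncertainty band of the rate constant.

**What the tests show.** Parameter-recovery suites (50 seeded replicates)
demonstrate that the estimators are consistent and approximately unbiased
*under the generators' assumptions*: multiplicative/additive noise of the
stated sizes, exactly known compositions, and the model family being
correct. They do not probe baseline drift, peak overlap, integration
subjectivity, or model misspecification in real spectra.

## Problem sizes and tolerances

Default test and acceptance runs use: 50-replicate recovery suites for the
initial-rates and binding estimators, single seeded fits for the
full-curve and bulk estimators (each fit requires ~40 stiff integrations),
30 hypothesis examples for the solver-vs-bisection property, and 200
replicates for the law-of-large-numbers smoke test. Numerical tolerances
are stated inline above; fit tolerances are 1e−10 on log10(k) for scalar
fits and (1e−8, 1e−12) x/f-tolerances for the simplex refinement.
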