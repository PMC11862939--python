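# cagereactor

Quantitative analysis toolkit for molecular "reactor vessels": host–guest
binding equilibria, in-cage reaction kinetics, and acceleration metrics.

The motivating system is an octa-imine bis-calix[4]pyrrole cage whose two
polar hemispheres each bind one *para*-substituted pyridine-*N*-oxide
guest. Pairwise inclusion of an azide-bearing and an alkyne-bearing guest
pre-organises the reacting groups, turning a sluggish bimolecular Huisgen
1,3-dipolar cycloaddition into a fast, regioselective pseudo-unimolecular
reaction inside the cavity — the supramolecular analogue of an enzyme's
Michaelis complex. The package answers the three quantitative questions
such a study poses:

1. **How strong is the binding?** Multi-component equilibrium speciation:
   given components with totals `T_j` and complexes with overall formation
   constants `β_s`, solve the mass balances
   `T_j = x_j + Σ_s ν_sj β_s Π_k x_k^ν_sk` for the free concentrations,
   and estimate stepwise constants `K_1:1`, `K_1:1⇌2:1` by matching
   simulated speciation to NMR-integral concentration ratios. Derived
   metrics: overall constants `β = K₁·K₂`, the cooperativity factor
   `α = 4K₂/K₁`, the disproportionation constant
   `K_dispro = β_het²/(β_AA·β_BB)`, and path-consistency checks.
2. **How fast is the in-cage reaction?** A mass-action network of six
   reversible binding steps (`k_on/k_off = K`) feeding one irreversible
   step, ternary complex → bound product, with rate constant `k_intra`;
   estimated by the initial-rates method (`v₀ = k_intra·[ternary]`) and by
   full-curve least squares, each candidate requiring a stiff ODE
   integration.
3. **How large is the acceleration?** Effective molarity
   `EM = k_intra/k_bulk` (M), with entropy equivalent `ΔS = −R ln(EM/1 M)`
   and free-energy advantage `ΔΔG = T·|ΔS|`, against the bulk second-order
   reference reaction with its fixed 1,4:1,5 regioisomer channel ratio.

A seeded synthetic-data module emulates the statistical structure of the
NMR and HPLC observables (5% multiplicative integral noise, 3% additive
chromatographic noise, sparse 48-hour sampling) so that every estimator is
testable end to end without external data.

## Worked example

Derived binding metrics for the azide/alkyne guest pair from the shipped
stepwise-constant tables, plus the speciation of the 1:2:2 mixture:

```console
$ cagereactor binding-report --pair 4a,5 --out-dir out
{
  "alpha": {
    "4a": 6.2,
    "5": 0.15
  },
  "K_dispro": 3.161290322580645
}
```

`alpha = 6.2` is a weakly positive cooperativity for the second azide
binding; `0.15` a modest negative one for the alkyne. `K_dispro ≈ 3` means
the two homoternary complexes and the heteroternary complex coexist close
to the statistical ratio. The JSON report also contains the speciation of
the 2 mM cage + 4 mM each guest mixture: the 2:1 azide homocomplex at
0.90 mM and the heterocomplex at 0.79 mM — the two species whose NMR
signals dominate that mixture.

Acceleration metrics from the measured rate-constant pair:

```console
$ cagereactor em-report --k-intra 5.0e-5 --k-bulk 5.6e-8 --out-dir out
EM = 890 M | dS = -13.5 e.u. | ddG = 4.0 kcal/mol
```

An effective molarity near 10³ M: the cage makes the cycloaddition as fast
as if the bulk partners were present at ~900 M, an entropic advantage of
about −14 e.u. (≈ 4 kcal·mol⁻¹ at 298 K).

A full simulate-then-fit round trip on synthetic NMR monitoring data:

```console
$ cagereactor simulate --scenario cage-4b5 --seed 11 --out-dir out
wrote 9 time points
$ cagereactor kinetics-fit --data out/cage_4b5.csv --out-dir out
k_intra = 5.1e-05 s^-1
```

The generator used `k_intra = 5.0e-5 s⁻¹`; the full-curve fit recovers it
from the noisy product-complex curve within a few percent.

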