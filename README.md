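# mctipm

Size-structured demographic modelling of competing clonal lineages,
linked to modern coexistence theory.

When conspecific competitors from different climates meet — here,
Southern and Northern *Daphnia magna* clones in warming freshwater —
the outcome of competition is decided by how temperature and crowding
act on each individual vital rate, and by how those effects integrate
across the life cycle. `mctipm` implements that integration end to end:

1. **Vital-rate regressions.** Seven individual-level rates (survival,
   somatic growth, egg carrying, neonate release, clutch size, neonate
   sex ratio, neonate size) are fitted as GLMMs in body size *z*,
   temperature *T*, sympatric density *S*, allopatric density *A* and
   latitude *L*, with a clonal random intercept, over a nested ladder of
   interaction structures compared by ELPD leave-one-out.
2. **Integral projection model.** The fitted rates assemble a daily,
   density- and temperature-dependent 100 × 100 kernel
   K(z′, z; θ) = s(z)^{1/3.5} G(z′, z) + [p_e p_r C p_f](z)/3.5 · D(z′, z)
   whose dominant eigenvalue λ(θ) is the daily population growth rate.
3. **Modern coexistence theory.** Zero-growth isoclines (log λ = 0) over
   competitor densities 1–1000 yield Lotka-Volterra competition
   coefficients α_ij from reciprocal axis intercepts, hence niche
   overlap ρ = √(α₁₂α₂₁/α₁₁α₂₂), competitive ability ratio
   k₁/k₂ = √(α₁₁α₁₂/α₂₂α₂₁), the mutual-invasibility classification,
   and the equilibrium Southern share p_S — all propagated over ≥ 1000
   posterior draws.
4. **Decomposition.** Each rate's contribution to the outcome is
   measured by exchanging that rate's full prediction function between
   latitudes and re-running the chain.

A first-class synthetic-experiment generator (`mctipm.simulate`)
reproduces the reference design — 12 genotypes, 48 monocultures + 66
pairwise-competition aquaria across 14–26 °C, twice-weekly censuses and
two isolated individuals per aquarium over 28 days — from known
ground-truth parameters, so every stage is testable without external
data. See `docs/methods.md` for models, assumptions and limitations.

## Worked example

```python
from mctipm import (ModelSet, analyze_temperature, default_truth,
                    simulate_competition)
from mctipm.standardize import DEFAULT_TEMPERATURE_SCALE as scale

models = ModelSet.from_truth(default_truth())   # or fit_all_rates(...)
for celsius in (18, 22, 26):
    T = float(scale.to_std(celsius))
    out = analyze_temperature(models, T)
    end = simulate_competition(models, T, n_days=100).iloc[-1]
    print(f"{celsius} degC: {out.classification}  rho={out.rho:.2f} "
          f"k1/k2={out.k_ratio:.2f}  p_S={out.p_south:.2f} "
          f"(simulated {end.p_south:.2f})")
```

prints

```
18 degC: stable_coexistence  rho=0.52 k1/k2=1.13  p_S=0.44 (simulated 0.46)
22 degC: stable_coexistence  rho=0.51 k1/k2=0.94  p_S=0.54 (simulated 0.55)
26 degC: stable_coexistence  rho=0.53 k1/k2=0.80  p_S=0.65 (simulated 0.65)
```

Both lineages inhibit themselves about twice as strongly as they inhibit
each other (ρ ≈ 0.5), so they coexist stably at every temperature, but
the competitive-ability ratio k₁/k₂ falls from 1.13 to 0.80 as it
warms: the Southern lineage's equilibrium share rises from 44% at 18 °C
to 65% at 26 °C. The dynamic 100-day projection agrees with the isocline
intersection, confirming the linear approximation behind the α's.

The same analysis from a synthetic experiment rather than the truth:

```bash
mctipm run-all --out report --seed 1     # generate -> fit -> coexist -> decompose
```

writes `individuals.csv`, `census.csv`, fitted models, a
`coexistence.json` with per-temperature classifications, quantiles and
posterior classification fractions, a `decomposition.csv`, and a
provenance manifest. Individual stages are available as `mctipm
generate|fit|kernel|coexist|decompose`.

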