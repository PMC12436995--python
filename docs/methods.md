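# Methods

## The scientific problem

Two sets of clonal *Daphnia magna* lineages — "Southern" and "Northern",
collected at different latitudes — compete in small aquaria across a
temperature gradient. The question is whether temperature changes which
lineage wins, whether the pair can coexist stably, and which individual
vital rate carries any temperature-dependent advantage. The package
answers this by combining a size-structured integral projection model
(IPM), parameterized from individual-level regressions with sympatric and
allopatric densities as covariates, with the niche-overlap /
competitive-ability framing of modern coexistence theory (MCT).

## Vital-rate regressions

Seven rates are modelled per individual observation interval:

| rate | family / link | response |
|---|---|---|
| survival | binomial, logit | survived the 3–4 day interval |
| somatic growth | gaussian, identity | mm/day size increment |
| egg carrying | binomial, logit | eggs present at interval start |
| neonate release | binomial, logit | clutch released, given eggs |
| clutch size | poisson, log | neonates per clutch |
| female probability | binomial (clutch trials), logit | female neonates per clutch |
| neonate size | gaussian, identity | neonate length, mm |

Covariates: standardized body size `z` (mm mapped linearly from
[0.3, 4] to [−2.5, 2.5]), standardized temperature `T` (design
temperatures 14/18/22/26 °C, mean 20, SD √20), sympatric and allopatric
densities `S`, `A` as raw counts per 1.5 L aquarium, a Southern-latitude
indicator `L`, and male sex (survival and growth only; reproduction is
fitted on females). Candidate fixed-effect structures form a nested
ladder M1–M5 from purely additive to three-way `T×L×S` / `T×L×A`
interactions (14–15 fixed effects). A clonal random intercept (12
levels) is always included. Sympatric/allopatric densities are obtained
by splitting census counts with a no-intercept logistic genotype-
frequency model (`logit p_South = d·β₁ + u_aquarium + d·T·β₂`), anchored
at p = 0.5 on day 0; single-latitude aquaria assign the whole count to
the resident latitude.

### Inference

Models are fitted by maximum a posteriori estimation with a Gaussian
(Laplace) approximation at the mode supplying ≥ 1000 posterior draws.
The random-intercept SD is estimated by an EM-style update using the
Laplace posterior variance of the group effects
(σ²_u ← mean_j(û_j² + Var(u_j))), which avoids the degenerate σ_u → 0
collapse of joint MAP estimation; fixed effects carry weakly
informative Normal priors autoscaled per column (SD = 2.5/sd(x_j),
capped at 10), so raw-count density covariates are regularized on the
same footing as standardized ones. The inner step is damped Newton with
analytic Hessians — an exact ridge solve for Gaussian responses.
Structure comparison uses ELPD leave-one-out cross-validation
approximated by Pareto-smoothed importance sampling over the draws
(`arviz.psislw`); ties break toward fewer parameters. The default
pipeline selects each rate's structure by ELPD before projecting:
high-order latitude × temperature × density interactions sit near the
identification limit of an experiment of this size, and carrying an
unsupported, noisily estimated interaction into the IPM distorts the
coexistence analysis far more than omitting it. Simulation-based
recovery suites in the tests verify that coefficient signs and interval
coverage behave as intended at the experimental sample sizes.

## The IPM kernel

A daily, female-only kernel on 100 midpoint size classes over
z ∈ [−2.5, 2.5]:

    K = P + F
    P[i,j] = s(z_j)^(1/3.5) · Pr{class i | Normal(z_j + g(z_j)/0.74, σ_g²)}
    F[i,j] = pe·pr·C·pf(z_j)/3.5 · Pr{class i | Normal(φ(z_j), σ_φ²)}

Survival is fitted on the interval scale and converted to daily by the
3.5th root (3.5 days = mean census interval; a config constant). The
reproduction product is likewise divided by 3.5. Class masses are Normal
CDF differences at class edges; mass beyond the size limits is added to
the first/last class, which makes the survival-mass identity
`colsum(P) = daily survival` hold to ~1e−15 and is verified at 1e−12.
Growth means add the fitted mm/day increment to the current size
(`growth_mode="increment"`); a literal reading in which the growth model
predicts the next size directly is available as
`growth_mode="absolute"`. σ_g is fitted on per-day increments and is
therefore a per-day SD. Random genotype effects are set to zero
throughout kernel prediction ("the average genotype").

The dominant eigenvalue λ is the daily growth rate. Public calls use a
dense eigendecomposition; the isocline scans use warm-started power
iteration with an automatic fallback, which agrees with the dense result
to 1e−8 relative.

## Coexistence analysis

For each latitude and temperature, the zero-growth isocline (log λ = 0)
is located by Brent root-finding in own-density at 25 log-spaced
competitor densities on [1, 1000] individuals; points with no root in
range are omitted. A least-squares line through the points gives axis
intercepts whose reciprocals are the Lotka-Volterra competition
coefficients α_ij, hence ρ = √(α₁₂α₂₁/α₁₁α₂₂) and
k₁/k₂ = √(α₁₁α₁₂/α₂₂α₂₁). Classification uses the strict invasion
conditions (α₁₁ > α₂₁ and α₂₂ > α₁₂ ⇔ ρ < k₁/k₂ < 1/ρ); boundary ties
count as non-coexistence. Four labels are kept (stable coexistence, two
exclusions, priority effect) rather than folding priority effects into
the exclusions.

The equilibrium is the intersection of the two fitted lines. When the
classification is a one-sided exclusion the interior intersection (if
any) is a saddle, so the reported state is the winner's single-genotype
equilibrium (p_S ∈ {0, 1}); for priority effects the interior point (the
separatrix) is retained as the summary. A latitude that cannot grow
even at density (1, 1) has no isocline; the draw is classified as
exclusion of that latitude (if neither latitude is viable, the one with
the lower low-density λ is reported excluded — a degenerate case that
does not arise under the default generator).

Because true IPM isoclines need not be linear, the line fit's R² is
reported, and a 100-day two-genotype projection (updating each
latitude's kernel with current female totals each day, starting from
6 juveniles per latitude drawn from the low-density neonate-size
distribution) provides a linearity-free check; under the default
generator both routes agree within 5% at the competition temperatures.
Posterior uncertainty is propagated by re-running the whole chain per
draw; draws with absent isoclines are classified and counted, never
dropped. Inside the draw loop the isocline grid is thinned to 12 points
(the line is insensitive to grid density; this bounds run time).

## Decomposition

A vital rate's contribution is measured by exchanging that rate's entire
prediction function between latitudes — implemented by flipping the
latitude indicator that rate sees, so all `L` main effects and `L×T`,
`L×S`, `L×A`, `T×L×S`, `T×L×A` interactions travel with the swap, while
S and A keep their own-vs-other meaning; Gaussian residual variances
travel with the function. Swapping the same rate twice restores the
original set, and swapping all seven is a full latitude exchange
(p_S → 1 − p_S), both verified in tests. Contributions are reported as
shifts in the median equilibrium Southern proportion with 5/25/50/75/95%
quantile bands over draws; rate contributions need not sum to the total.

## The synthetic experiment generator

The generator emulates the reference design: 12 genotypes (2 latitudes ×
2 ponds × 3 clones), every genotype alone (12 founders) at 14/18/22/26 °C,
all 66 unordered pairs once (6 + 6 founders) stratified randomly across
18/22/26 °C, censuses on days {0,3,7,10,14,17,21,24,28}, two individuals
isolated per aquarium per interval, destructive genotyping of isolated
individuals from day 14, sizes in [0.3, 4] mm.

Simulation is individual-based in daily steps: survival applies daily as
the 3.5th root of the interval-scale probability, growth adds a mm/day
increment with daily Gaussian noise, and clutch release is a daily
Bernoulli event with probability pe·pr/3.5 producing a Poisson clutch,
binomially sexed, with Normal neonate sizes. Isolated individuals'
interval observations are drawn directly from the generating GLMMs at
interval-start covariates — so the observation rows match the fitted
regression families exactly — and their fate over the interval is forced
to match the observation. Males are counted in S and A but do not
reproduce; the IPM correspondingly tracks females and uses female totals
as densities in its own projections.

### Default generating parameters

The defaults encode the qualitative biology the analysis targets:
negative sympatric effects on growth, egg carrying, clutch size and
female probability; negative allopatric effects on growth and clutch
size; positive density effects on neonate size; temperature-intensified
competition (negative `T×S`, `T×A` in reproduction), hence carrying
capacities falling from ≈ 360 (18 °C) to ≈ 240 (32 °C) females per
aquarium; and a Southern advantage that grows with temperature, carried
by `L×T` terms in egg carrying and clutch size plus a sign-reversing
`T×L×A` interaction in neonate female probability (cross-latitude
crowding promotes male production in Southern clones when cold and in
Northern clones when warm). Magnitudes were calibrated once so that
populations of 12 founders approach equilibrium within the 28-day
experiment (low-density λ ≈ 1.4/day at 18 °C — fast, food-rich
laboratory conditions), equilibrium densities stay well inside the
[1, 1000] isocline window, and the equilibrium Southern share rises from
≈ 0.44 at 18 °C through ≈ 0.65 at 26 °C to ≈ 0.81 at 32 °C, with stable
coexistence at all experimental temperatures. Density dependence is
deliberately concentrated in the log-link clutch channel: a log-linear
recruitment response makes the true isoclines close to linear, which is
also the regime in which reciprocal-intercept competition coefficients
are a faithful summary. Residual SDs are σ_g = 0.035 mm/day and
σ_φ = 0.055 mm; clonal random-intercept SDs are 0.006–0.2 on the link
scales.

What the generator does *not* emulate: video-based abundance estimation
error (censuses are exact counts), genotyping error, within-latitude
clonal niche differences (clone effects are random intercepts only),
egg-state dynamics between censuses (egg carrying is drawn
cross-sectionally), food or medium dynamics, and sexual (ephippial) egg
fate. Passing tests therefore demonstrate that the estimation and
projection machinery is correct under the assumed statistical structure,
not that the structure captures every feature of real aquaria.

## Numerical and design choices

- Isocline root-finding: Brent on [1, 1000], |log λ| tolerance 1e−6;
  grid 25 points (12 inside draw loops).
- Power iteration: relative tolerance 1e−11, 500-iteration cap, dense
  eigendecomposition fallback.
- Laplace draws use the analytic Hessian at the mode; indefinite
  Hessians are repaired by eigenvalue clipping at 1e−10.
- "Identifiable effect size" in recovery suites: |β| × partial SD of the
  design column (residualized on the other columns), divided by the
  residual SD for Gaussian rates — the per-observation signal-to-noise
  that governs estimator precision; marginal column SDs overstate the
  information carried by collinear interaction columns.
- Temperature standardization uses the design mean/SD, so 32 °C maps to
  T_std ≈ 2.68; predictions there are extrapolations and are flagged in
  the report bundle.
- Problem sizes in the validation suites (2000 records × 100 replicates
  for coefficient recovery, 241 samples × 50 replicates for the
  frequency model, 100 posterior draws per temperature for the
  temperature trend — pooled over 5 replicate experiments in the
  reproduction script — and 100 random parameter sets for the analytic
  cross-check) were chosen to estimate each property with comfortable
  Monte-Carlo margin at single-workstation scale.
- The temperature trend of the equilibrium Southern share is a
  generator-level property; a single simulated experiment recovers its
  strict ordering most but not all of the time, because competitor clone
  quality is confounded with allopatric density in the stated design
  (nothing adjusts for *which* clones generate the density an individual
  experiences), so occasional large spurious latitude × density
  coefficients arise. Replicate experiments with majority voting
  average this confounding out; it is the main reason posterior
  classification uncertainty is substantial at this experiment size.

## Known limitations

- The Laplace approximation understates tail mass relative to full
  MCMC; recovery suites validate signs and coverage at the simulated
  sample sizes, not extreme quantiles.
- The EM variance-component update shrinks σ_u somewhat with only 12
  clones; σ_u is reported but plays no role in downstream prediction
  (random effects are zeroed there).
- Competition coefficients inherit any isocline curvature; R² below
  ≈ 0.99 is a warning that the reciprocal-intercept summary is strained.
- The equilibrium proportion of a priority-effect draw is the interior
  separatrix point, not a long-run outcome.
- With an experiment of this size (~1800 observation rows), posterior
  uncertainty in the coexistence classification is substantial; the
  per-draw classification fractions, not the point estimate, are the
  meaningful summary.
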