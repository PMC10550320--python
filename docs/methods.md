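# Methods

## Model and conventions

The trait is additive over `L` haploid biallelic loci with equal effects
(0 for `a`, `γ > 0` for `A`); fitness is Gaussian stabilizing selection
`W(Z) = exp[−σ(t)/2 (Z − Z_opt(t))²]` with a step change of optimum (and
optionally of `σ`) between generations −1 and 0.  Time is discrete;
schedules are evaluated at the parents' generation when offspring are
sampled.  The ancestral optimum is tied to the initialization:
`Z_opt⁰ = (L − d)γ`, with `d` loci starting from the `a` majority allele
(the beneficial variation).  Diploidy, dominance, unequal effects,
pleiotropy and population structure are out of scope.

Parameters and defaults:

| parameter | meaning | units | default |
| --- | --- | --- | --- |
| `L` | loci in the trait basis | – | – |
| `gamma` | locus effect size | trait units | – |
| `Ne` | population size | individuals | – |
| `mu`, `nu` | forward / back mutation per locus | per generation | `nu = mu` |
| `sigma_before/after` | selection strength | (trait units)⁻² | `after = before` |
| `zopt0`, `zopt_new` | optima around the shift | trait units | – |
| `cz_values` | phenotypic waypoints | mutational steps (γ) | – |
| LE burn-in | equilibration before the shift | generations | `8 Ne` |
| IB burn-in | idem, individual-based | generations | `20 Ne` |

Population-scaled rates (`Θᵢ = 2Ne μᵢ`, `Θ_bg = 2Ne μ (d−1)`) are always
derived from per-generation inputs, never entered directly.

## Wright–Fisher simulator under linkage equilibrium

Per generation and locus: deterministic bidirectional mutation
`p → p(1−ν) + (1−p)μ`, then selection + drift as a `Binomial(Ne, p w/(p w + 1 − p))`
draw, where the `A` sampling weight is
`w = exp[σγ((Z_opt − Z̄) − (γ/2)(1 − 2p))]` (full model) or
`w = exp[σγ(Z_opt − Z̄)]` (directional-only model).  Loci interact only
through the trait mean `Z̄`, which is computed once per generation from the
pre-mutation parental state.  Whether `Z̄` is taken pre- or post-mutation
is a free convention; mutation perturbs `Z̄` by `O(Lμγ)`
per generation, so the choice is immaterial, and the pre-mutation
convention is fixed for reproducibility.

Runs either equilibrate for `8 Ne` generations under the ancestral optimum
to reach mutation–selection–drift balance ("from SGV"), or start
monomorphic at the majority alleles (`from_sgv=False`) for
new-mutation-only scenarios.  The no-SGV case is an initialization flag
rather than a `σ → ∞` limit, for numerical robustness.  Doubling the
burn-in does not change the SGV summaries beyond noise in our checks.

All replicates of a run advance in lockstep as a `(R, L)` array under a
single RNG stream spawned from the master seed.  This makes a run
bit-reproducible given its seed and configuration (a per-replicate stream
would be needed only to re-run a *single* replicate in isolation, which
the individual-based simulator supports).  Replicates that never reach a
waypoint within `max_generations` are flagged incomplete, excluded from
marginals, and counted in a reported completion rate.

## Individual-based simulator

`Ne` binary genomes on one linear chromosome; per generation: individual
fitnesses `W(Z)`, `Ne` pairs via stochastic acceptance (uniform proposal,
accept with `W/W_max`, `W_max` recomputed each generation), one recombinant
offspring per pair, then population-level mutation with a
`Poisson(Ne L μ)` number of uniformly chosen cells toggled.  Parents are
drawn independently with replacement (selfing allowed at probability
`1/Ne` — the model does not forbid it).  Crossovers fall independently
with probability `r` in each of the `L−1` intervals, which is
distributionally identical to drawing a `Binomial(L−1, r)` crossover count
and placing it uniformly without replacement; the offspring alternates
parental segments starting from a fair coin.  Genomes are stored as a
dense `uint8` matrix; allele frequencies are exact rationals `k/Ne`.
Mutation toggles alleles symmetrically, so the IB engine requires
`μ = ν` (the symmetric case used throughout).

The genetic variance `v_g = Var[Z]/γ²` (across individuals) and the genic
variance `v_g^LE = Σᵢ pᵢ(1−pᵢ)` are recorded at every waypoint;
`v_g < v_g^LE` diagnoses negative linkage disequilibrium, which builds up
once recombination is weaker than selection (`r ≲ σγ²`).

## Establishment phase: Yule process

Beneficial lineages that escape stochastic loss are modeled as a
multi-type Yule process: new immortal lines seeded at locus `i`
proportional to `Θᵢ` and splits of existing lines proportional to their
count.  The establishment probability multiplies *all* rates equally (all
loci have the same effect), so it cancels under a time rescaling and is
never computed.  The embedded jump chain is a Pólya urn with initial
weights `Θ`; line-count ratios converge to ratios of independent
`Gamma(Θᵢ)` variables — an inverted Dirichlet law.

## Deterministic phase and the conditioned joint distribution

Under pure directional selection, `u̇ᵢ = σγ uᵢ (Z_opt − Z̄)` for the odds
`uᵢ = pᵢ/(1−pᵢ)`, so every ratio `uᵢ/uⱼ` is a constant of motion.  The
establishment-phase ratio distribution therefore holds at any later
waypoint, and conditioning on `Σᵢ pᵢ = c_Z` pins the configuration down.
The joint density of `(p₂, …, p_d)` (with `p₁` implied) is obtained by
pushing the inverted-Dirichlet density of `(u₂/u₁, …, u_d/u₁)` through the
constraint map; we re-derived the Jacobian and verified that the result
reduces exactly to the closed-form two-locus marginal, integrates to one
(by adaptive quadrature up to `d = 4`), and matches the sampler.  No
selection parameter appears anywhere in this module — structurally
matching the theory's selection-independence.

Numerics: densities are evaluated in log space (stable for `Θ` up to
~10³ and near-boundary frequencies).  Sampling uses `Gᵢ ~ Gamma(Θᵢ)` and a
safeguarded Newton solve of `Σ λGᵢ/(1+λGᵢ) = c_Z` (monotone concave map;
start below the root; bisection fallback), with `|Σpᵢ − c_Z| ≤ 10⁻¹⁰`.
Gamma draws that underflow to zero at tiny `Θᵢ` are clamped to the
smallest positive normal float.  Direct quadrature of the joint density is
provided only as an oracle for `d ≤ 4`; marginals for larger `d` go
through the sampler.

## Pheno-time snapshots and waypoint projection

Snapshots record the first integer generation at which `Z̄` crosses a
waypoint, so `Σpᵢ` overshoots `c_Z` by up to one generation's change
(order `σγ² · (Z_opt − Z̄) · v_g` per γ).  When comparing simulations
against the theory (which conditions on the trait mean exactly), snapshots
are first projected onto the waypoint along the directional flow: a common
rescaling of all odds — the same scalar solve as the sampler — moves the
recorded state to `Σpᵢ = c_Z` while preserving every odds ratio.
Frequencies exactly 0 or 1 are fixed points of the flow and are left
untouched.  The projection is exact for the directional-only model and a
first-order correction for the full model.

## Ordered marginals and summary statistics

Within each replicate, loci are sorted by descending `A` frequency (stable
sort; ties — real events at rational `k/Ne` — break by locus index); the
`L − d` ancestral-majority loci are discarded by default, and rank-wise
distributions are pooled across replicates (rank 1 = major locus).
Histograms use 50 equal-width bins on [0, 1] shared across ranks, avoiding
kernel choices.  Regime classification from `Θ_bg` uses half-open
intervals at 0.1 and 10; the labels are advisory — the transition is
gradual.  The trait cumulants `v_g = Σ pᵢ(1−pᵢ)` and
`κ₃ = Σ pᵢ(1−pᵢ)(1−2pᵢ)` (units `γ²`, `γ³`) are reported along waypoint
schedules; with half-step waypoints included, their series exposes the
period-γ oscillation of the joint distribution (pronounced in the sweep
regime, where a lone allele crossing `p = 0.5` mid-step maximizes the
variance; weak in the shift regime).

## What the synthetic scenarios emulate — and what they do not

The package generates its own study conditions; there is no external data.
The canonical scenarios are (i) a three-locus trait adapting from new
mutation only across `Z_opt: 0 → 3γ`, sampled at `c_Z = 1`, across
`Θ_bg = 0.01 … 100`; (ii) traits of 10 (or more) loci with a mid-range or
near-boundary ancestral optimum, adapting from standing variation; and
(iii) the same 10-locus trait with linkage, `r = 0.5 … 0.001`.  Equal
locus effects and equal mutation rates are assumptions, not
simplifications of convenience: the theory's permutation symmetry rests on
them.  Passing tests therefore demonstrate internal consistency of theory
and simulation under these symmetric conditions; they do not speak to
unequal effect sizes, dominance, pleiotropy, or structured populations.

## Problem sizes and design choices in the checks

Reference-scale experiments use populations of 10⁴–10⁵ replicates; the
test suite and `scripts/acceptance.py` run reduced versions chosen so the
relevant effect is still unambiguous: linkage-equilibrium runs use
`Ne = 10⁴` with 100–2000 replicates (the theory's drift asymptotics
degrade visibly below `Ne ≈ 10³`, so the LE comparisons keep the
population large — it is cheap, as all replicates advance in lockstep);
individual-based runs use `Ne = 500` with 15–100 replicates.  Statistical
comparisons use two-sample Kolmogorov–Smirnov tests at family level
α = 0.01 (Bonferroni across frequency ranks) and chi-square tests against
quadrature-integrated bin masses, restricted to bins fully inside the
support where the density is smooth.  Where a supplementary extension of
the theory would be needed — the rescaling that accounts for segregating
deleterious variation at high mutation rates — the package deliberately
exposes only the beneficial-variation distribution, valid when deleterious
standing variation is negligible (strong stabilizing selection and/or
`Θ_bg ≲ 1`); comparisons from standing variation are therefore run in that
region.

## Known limitations

- The conditioned joint distribution covers the rapid, directional phase
  only; allele sorting near the new optimum (disruptive selection) is not
  modeled, and full-model simulations show the expected small boundary
  push relative to the directional-only model (disruptive/directional
  strength ratio up to 1/4 two steps from the optimum).
- High mutation rates with weak selection (standing minor frequencies
  ≳ 0.1) violate the establishment-phase assumptions; deviations there are
  expected and documented in the regime checks.
- Long-range adaptation of a small trait basis depletes the supply of
  fresh loci; the architecture is only quasi-stable, captured by the
  effective background rate `Θ_bg,eff = Θ_bg · remaining/initial`.
- No spatial structure, migration, or linked neutral diversity.
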