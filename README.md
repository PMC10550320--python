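# oligoadapt

Forward simulation and analytical theory of **oligogenic adaptation** of a
quantitative trait.

When a trait under stabilizing selection adapts to a sudden shift of its
optimum, how does the phenotypic response decompose into allele-frequency
changes at the underlying loci?  Population genetics pictures sequential
selective sweeps; quantitative genetics pictures subtle, collective
frequency shifts at many loci.  `oligoadapt` implements a framework that
covers both endpoints and the oligogenic middle ground, for researchers in
population and quantitative genetics who want to simulate, predict, and
classify *adaptive architectures*.

## Model

A haploid, panmictic population of size `Ne` carries an additive trait
controlled by `L` biallelic loci of equal effect `γ`:

    Z = Σᵢ ηᵢ γ,      ηᵢ ∈ {0, 1}

under Gaussian stabilizing selection with time-dependent optimum,

    W(Z) = exp[ −σ(t)/2 · (Z − Z_opt(t))² ].

At `t = 0` the optimum jumps from `Z_opt⁰` to `Z_opt_new`.  Mutation is
bidirectional (`μ`, `ν` per locus per generation).  Before the shift, `d`
loci carry the low (`a`) majority allele — the *beneficial variation* once
the optimum moves up.  Allele frequencies are recorded in **pheno-time**:
at the first generation where the trait mean crosses
`Z̄ = Z_opt⁰ + c_Z γ`, for a schedule of waypoints `c_Z`.  The joint
distribution of the frequencies across evolutionary replicates at such a
waypoint is the *adaptive architecture*, visualized through
frequency-ordered (major / minor-locus) marginal distributions.

The analytical core describes the stochastic establishment phase by a
multi-type Yule process (seeding rate `Θᵢ = 2Neμᵢ` per locus, split rate 1
after time rescaling), giving inverted-Dirichlet distributed ratios of
allelic odds `uᵢ = pᵢ/(1−pᵢ)`.  Because pure directional selection on an
additive trait leaves all odds ratios invariant, this distribution is
transported unchanged to any waypoint, where conditioning on
`Σᵢ pᵢ = c_Z` yields the joint allele-frequency distribution in closed
form — independent of every selection parameter.  Sampling uses the gamma
representation: draw `Gᵢ ~ Gamma(Θᵢ)`, solve `Σᵢ λGᵢ/(1+λGᵢ) = c_Z` for
`λ`, set `pᵢ = λGᵢ/(1+λGᵢ)`.

The single most important predictor of the architecture type is the
**background mutation rate** `Θ_bg = 2Neμ(d−1)`: single sweeps for
`Θ_bg ≲ 0.1`, partial sweeps for intermediate values, and collective
frequency shifts for `Θ_bg ≳ 10`.

## What is in the package

| module | contents |
| --- | --- |
| `model_core` | trait/fitness model, parameter containers |
| `wf_le_sim` | Wright–Fisher simulator under linkage equilibrium (full and directional-only selection models) |
| `ib_sim` | individual-based simulator with recombination on a linear chromosome |
| `yule_analytics` | Yule process, conditioned joint/marginal densities, gamma-representation sampler |
| `architecture_stats` | `Θ_bg`, regime classification, ordered marginals, trait cumulants |
| `cli_io` | YAML configs, TSV/JSON snapshot I/O, manifests |

## Worked example

Compare a simulated architecture with the analytical prediction for a
three-locus trait adapting by one mutational step from new mutations only
(`Θ_bg = 1`, partial-sweep regime):

```python
import numpy as np
from oligoadapt import (TraitModel, StopSchedule, WfRunConfig, run_wf,
                        ordered_from_matrix, ordered_marginal_theory,
                        classify_regime, theta_bg)

ne = 10_000
model = TraitModel(L=3, gamma=1.0, Ne=ne, mu=1/(2*ne*2),
                   sigma_before=100/ne, zopt0=0.0, zopt_new=3.0)
cfg = WfRunConfig(model=model, stops=StopSchedule(cz_values=(1.0,)),
                  directional_only=True, from_sgv=False,
                  replicate_count=2000, seed=1)
sim = ordered_from_matrix(run_wf(cfg).freqs[:, 0, :])
theory = ordered_marginal_theory([0.5, 0.5, 0.5], 1.0, 20_000,
                                 np.random.default_rng(2))

tbg = theta_bg(ne, model.mu, 3)
print(f"theta_bg = {tbg:.2f}  regime: {classify_regime(tbg)}")
for k, label in enumerate(sim.rank_labels()):
    print(f"{label:7s} sim mean p = {sim.rank(k).mean():.3f}   "
          f"theory mean p = {theory.rank(k).mean():.3f}")
```

Output:

```
theta_bg = 1.00  regime: partial
major   sim mean p = 0.600   theory mean p = 0.598
minor1  sim mean p = 0.307   theory mean p = 0.306
minor2  sim mean p = 0.101   theory mean p = 0.096
```

The major locus carries most of the adaptive change (~0.60 of the one-step
response), but both minor loci contribute — partial sweeps, exactly as the
regime label says.  The simulated rank means agree with the selection-free
analytical prediction to within Monte-Carlo error.

The same runs are available from the shell:

```bash
oligoadapt wf-sim --config examples/three_locus.yaml --out runs/wf
oligoadapt theory --theta 0.5,0.5,0.5 --cz 1.0 -n 20000 --out runs/theory
oligoadapt stats --snapshots runs/wf --stop 1.0 --out runs/stats
```

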