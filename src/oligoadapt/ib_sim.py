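"""Individual-based forward simulator on a linear chromosome.

Tracks ``Ne`` haploid binary genomes of length ``L`` explicitly, so linkage
disequilibrium between the selected loci can build up (the linkage-
equilibrium simulator in :mod:`oligoadapt.wf_le_sim` cannot represent it).
The life cycle per generation:

1. individual fitnesses from Gaussian stabilizing selection on trait values;
2. ``Ne`` mating pairs, both parents drawn independently by *stochastic
   acceptance* (repeatedly pick a uniform individual, accept with
   probability ``W / W_max``), each pair producing a single recombinant
   offspring;
3. recombination: crossovers fall independently with probability ``r`` in
   each of the ``L - 1`` inter-locus intervals (equivalently: a
   Binomial(L-1, r) number of crossovers placed uniformly without
   replacement), and the offspring alternates parental segments starting
   from a fair-coin choice of initial parent;
4. population-level bidirectional mutation: the total number of flipped
   (individual, locus) cells is Poisson with mean ``Ne * L * mu``.

Loci are equally spaced, so the recombination probability between loci at
distance ``delta`` intervals is the odd-crossover sum
``r_delta = sum_k C(delta, 2k+1) r^(2k+1) (1-r)^(delta-2k-1)``, which equals
the closed form ``(1 - (1-2r)^delta)/2`` and is always >= r.

Replicates are independent runs with child RNG streams spawned from the
master seed; within a replicate the generation step is vectorized over
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .architecture_stats import ArchitectureSample
from .model_core import StopSchedule, TraitModel

__all__ = [
    "LinkageMap",
    "HaploidPopulation",
    "IbRunConfig",
    "recomb_prob",
    "stochastic_acceptance_choose",
    "recombine",
    "mutate_population",
    "ib_generation",
    "genic_and_genetic_variance",
    "run_ib",
]


@dataclass(frozen=True)
class LinkageMap:
    """Equally spaced loci on one chromosome; ``r`` per adjacent interval."""

    r: float
    L: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"recombination rate must be in [0, 0.5], got {self.r}")
        if self.L < 1:
            raise ValueError("L must be positive")


@dataclass
class HaploidPopulation:
    """``Ne`` binary genomes (rows); entry 1 means the ``A`` allele."""

    genomes: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.genomes = np.ascontiguousarray(self.genomes, dtype=np.uint8)
        if self.genomes.ndim != 2:
            raise ValueError("genomes must be an Ne x L matrix")
        if self.genomes.max(initial=0) > 1:
            raise ValueError("genome entries must be in {0, 1}")

    @property
    def Ne(self) -> int:
        return self.genomes.shape[0]

    @property
    def L(self) -> int:
        return self.genomes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Column means; exact rationals k/Ne."""
        return self.genomes.mean(axis=0)

    def trait_values(self, model: TraitModel) -> np.ndarray:
        return model.gamma * self.genomes.sum(axis=1)


@dataclass(frozen=True)
class IbRunConfig:
    """Configuration of an individual-based run."""

    model: TraitModel
    stops: StopSchedule
    r: float = 0.5
    from_sgv: bool = True
    equilibration_generations: int | None = None
    replicate_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.equilibration_generations is None:
            object.__setattr__(
                self, "equilibration_generations", 20 * self.model.Ne
            )
        if self.equilibration_generations < 0:
            raise ValueError("equilibration_generations must be >= 0")
        if self.model.nu != self.model.mu:
            raise ValueError(
                "the individual-based mutation scheme toggles alleles "
                "bidirectionally at a single rate; it requires mu == nu"
            )

    @property
    def linkage(self) -> LinkageMap:
        return LinkageMap(r=self.r, L=self.model.L)


def recomb_prob(delta: int, r: float) -> float:
    """Recombination probability between loci ``delta`` intervals apart.

    Sums the probabilities of an odd number of crossovers among ``delta``
    independent intervals; equals ``(1 - (1 - 2r)**delta) / 2`` and satisfies
    ``recomb_prob(delta, r) >= r`` with equality at ``delta = 1``.
    """
    if delta < 1:
        raise ValueError(f"delta must be >= 1, got {delta}")
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"r must be in [0, 0.5], got {r}")
    k = np.arange(0, (delta - 1) // 2 + 1)
    odd = 2 * k + 1
    return float(np.sum(comb(delta, odd) * r**odd * (1.0 - r) ** (delta - odd)))


def stochastic_acceptance_choose(
    fitness: np.ndarray, rng: np.random.Generator
) -> int:
    """Fitness-proportional choice of one individual by stochastic acceptance."""
    fitness = np.asarray(fitness, dtype=float)
    wmax = fitness.max()
    if wmax <= 0.0:
        raise ValueError("all fitnesses are zero; no parent can be chosen")
    n = len(fitness)
    while True:
        i = int(rng.integers(n))
        if rng.random() * wmax < fitness[i]:
            return i


def _choose_parents(
    fitness: np.ndarray, n_picks: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized stochastic acceptance: ``n_picks`` independent indices."""
    wmax = fitness.max()
    if wmax <= 0.0:
        raise ValueError("all fitnesses are zero; no parent can be chosen")
    n = len(fitness)
    out = np.empty(n_picks, dtype=np.int64)
    filled = 0
    while filled < n_picks:
        m = n_picks - filled
        cand = rng.integers(n, size=m)
        acc = rng.random(m) * wmax < fitness[cand]
        k = int(acc.sum())
        out[filled : filled + k] = cand[acc]
        filled += k
    return out


def _segment_masks(
    n_offspring: int, L: int, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n, L) masks: True where the second parent contributes."""
    start = rng.integers(0, 2, size=(n_offspring, 1))
    if L == 1 or r == 0.0:
        return np.broadcast_to(start == 1, (n_offspring, L))
    cross = rng.random((n_offspring, L - 1)) < r
    seg = np.zeros((n_offspring, L), dtype=np.int64)
    np.cumsum(cross, axis=1, out=seg[:, 1:])
    return (seg + start) % 2 == 1


def recombine(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    linkage: LinkageMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single recombinant offspring from two parental genomes."""
    a = np.asarray(parent_a)
    b = np.asarray(parent_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("parents must be 1-d genomes of equal length")
    mask = _segment_masks(1, linkage.L, linkage.r, rng)[0]
    return np.where(mask, b, a).astype(np.uint8)


def mutate_population(
    pop: HaploidPopulation, model: TraitModel, rng: np.random.Generator
) -> HaploidPopulation:
    """Toggle a Poisson(Ne * L * mu) number of uniformly chosen cells."""
    m = rng.poisson(pop.Ne * pop.L * model.mu)
    if m:
        cells = rng.integers(pop.Ne * pop.L, size=m)
        hits = np.bincount(cells, minlength=pop.Ne * pop.L).astype(np.uint8)
        pop.genomes ^= (hits & 1).reshape(pop.Ne, pop.L)
    return pop


def ib_generation(
    pop: HaploidPopulation,
    model: TraitModel,
    linkage: LinkageMap,
    rng: np.random.Generator,
) -> HaploidPopulation:
    """One full life cycle: selection, recombination, mutation."""
    Ne = pop.Ne
    Z = pop.trait_values(model)
    sigma, zopt = model.sigma(pop.t), model.zopt(pop.t)
    W = np.exp(-0.5 * sigma * (Z - zopt) ** 2)
    parents = _choose_parents(W, 2 * Ne, rng)
    A = pop.genomes[parents[:Ne]]
    B = pop.genomes[parents[Ne:]]
    mask = _segment_masks(Ne, pop.L, linkage.r, rng)
    offspring = np.where(mask, B, A)
    new_pop = HaploidPopulation(genomes=offspring, t=pop.t + 1)
    return mutate_population(new_pop, model, rng)


def genic_and_genetic_variance(
    pop: HaploidPopulation, model: TraitModel
) -> tuple[float, float]:
    """Genetic variance ``vg`` and genic (LE) variance ``vg_le``, in gamma^2.

    ``vg`` is the realized variance of individual trait values across the
    population; ``vg_le = sum_i p_i (1 - p_i)`` is what it would be under
    linkage equilibrium.  ``vg < vg_le`` diagnoses negative LD.
    """
    counts = pop.genomes.sum(axis=1).astype(float)
    vg = float(np.var(counts))
    p = pop.allele_frequencies()
    vg_le = float(np.sum(p * (1.0 - p)))
    return vg, vg_le


def _initial_population(
    model: TraitModel, rng: np.random.Generator
) -> HaploidPopulation:
    """Monomorphic start matching Zbar = zopt0: d random loci at a (0)."""
    genomes = np.ones((model.Ne, model.L), dtype=np.uint8)
    a_loci = rng.choice(model.L, size=model.d, replace=False)
    genomes[:, a_loci] = 0
    return HaploidPopulation(genomes=genomes, t=0)


def _run_one_replicate(
    config: IbRunConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    model = config.model
    stops = config.stops
    linkage = config.linkage
    thresholds = model.zopt0 + np.asarray(stops.cz_values) * model.gamma
    n_stops = len(stops.cz_values)

    pop = _initial_population(model, rng)
    if config.from_sgv:
        pop.t = -config.equilibration_generations
        for _ in range(config.equilibration_generations):
            pop = ib_generation(pop, model, linkage, rng)
    sgv = pop.allele_frequencies()

    freqs = np.full((n_stops, model.L), np.nan)
    generations = np.full(n_stops, -1, dtype=int)
    completed = np.zeros(n_stops, dtype=bool)
    vg = np.full(n_stops, np.nan)
    vg_le = np.full(n_stops, np.nan)

    k = 0
    while k < n_stops and pop.t <= stops.max_generations:
        zbar = model.gamma * float(pop.genomes.mean(axis=0).sum())
        while k < n_stops and zbar >= thresholds[k]:
            freqs[k] = pop.allele_frequencies()
            generations[k] = pop.t
            completed[k] = True
            vg[k], vg_le[k] = genic_and_genetic_variance(pop, model)
            k += 1
        if k == n_stops:
            break
        pop = ib_generation(pop, model, linkage, rng)
    return freqs, generations, completed, vg, vg_le, sgv


def run_ib(config: IbRunConfig) -> ArchitectureSample:
    """Run all replicates; each gets an independent spawned RNG stream."""
    model = config.model
    n_stops = len(config.stops.cz_values)
    R = config.replicate_count
    freqs = np.full((R, n_stops, model.L), np.nan)
    generations = np.full((R, n_stops), -1, dtype=int)
    completed = np.zeros((R, n_stops), dtype=bool)
    vg = np.full((R, n_stops), np.nan)
    vg_le = np.full((R, n_stops), np.nan)
    sgv = np.full((R, model.L), np.nan)

    streams = np.random.SeedSequence(config.seed).spawn(R)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        freqs[i], generations[i], completed[i], vg[i], vg_le[i], sgv[i] = (
            _run_one_replicate(config, rng)
        )

    return ArchitectureSample(
        freqs=freqs,
        cz_values=config.stops.cz_values,
        generations=generations,
        completed=completed,
        vg=vg,
        vg_le=vg_le,
        sgv=sgv,
        config={
            "simulator": "ib",
            "r": config.r,
            "from_sgv": config.from_sgv,
            "Ne": model.Ne,
            "L": model.L,
            "d": model.d,
            "gamma": model.gamma,
            "mu": model.mu,
            "nu": model.nu,
            "sigma_before": model.sigma_before,
            "sigma_after": model.sigma_after,
            "zopt0": model.zopt0,
            "zopt_new": model.zopt_new,
            "seed": config.seed,
            "replicate_count": config.replicate_count,
            "equilibration_generations": config.equilibration_generations,
            "max_generations": config.stops.max_generations,
        },
    )
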