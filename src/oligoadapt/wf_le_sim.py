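"""Wright-Fisher forward simulator under linkage equilibrium.

Each locus is resampled independently every generation by binomial sampling
of ``Ne`` allele copies; loci are coupled only through the population trait
mean, which enters the per-locus selection weight.  The per-generation life
cycle is: bidirectional mutation, then selection + drift via binomial
sampling, with the trait mean taken from the parental (pre-mutation) state.

Two selection models are supported.  The *full* model weights the ``A``
allele (relative to ``a`` normalized to 1) by

    w = exp[ sigma(t) * gamma * ((Zopt(t) - Zbar) - (gamma/2) * (1 - 2 p)) ]

whose bracket combines a directional term (distance of the mean from the
optimum) and a disruptive term that pushes frequencies toward the
boundaries.  The *directional-only* model drops the disruptive term; it is
the regime in which the Yule/inverted-Dirichlet theory is exact.

Runs start from mutation-selection-drift balance (burn-in of 8 Ne
generations under the ancestral optimum by default) or, with
``from_sgv=False``, from a monomorphic population at the majority alleles.
After the optimum shift at generation 0, all allele frequencies are recorded
at the first generation where the trait mean crosses each phenotypic
waypoint ("pheno-time" sampling).

All replicates advance in lockstep as a ``(replicates, L)`` array driven by
a single RNG stream spawned from the master seed; a run is bit-reproducible
given its seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture_stats import ArchitectureSample
from .model_core import FrequencyState, StopSchedule, TraitModel

__all__ = [
    "WfRunConfig",
    "selection_weight",
    "mutation_update",
    "wf_generation",
    "equilibrate",
    "run_to_phenotime",
    "run_wf",
]


@dataclass(frozen=True)
class WfRunConfig:
    """Configuration of a linkage-equilibrium Wright-Fisher run."""

    model: TraitModel
    stops: StopSchedule
    directional_only: bool = False
    from_sgv: bool = True
    equilibration_generations: int | None = None
    replicate_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.equilibration_generations is None:
            object.__setattr__(
                self, "equilibration_generations", 8 * self.model.Ne
            )
        if self.equilibration_generations < 0:
            raise ValueError("equilibration_generations must be >= 0")


def selection_weight(
    p, zbar, t: int, model: TraitModel, directional_only: bool = False
):
    """Wrightian sampling weight of the ``A`` allele relative to ``a``.

    ``p`` may be scalar, a length-L vector, or a (R, L) batch; ``zbar``
    broadcasts against the leading axes.  The weight is 1 exactly when the
    bracketed selection term vanishes.
    """
    p = np.asarray(p, dtype=float)
    zbar = np.asarray(zbar, dtype=float)
    if zbar.ndim and p.ndim == zbar.ndim + 1:
        zbar = zbar[..., None]
    g = model.gamma
    term = model.zopt(t) - zbar
    if not directional_only:
        term = term - 0.5 * g * (1.0 - 2.0 * p)
    w = np.exp(model.sigma(t) * g * term)
    return w if w.ndim else float(w)


def mutation_update(p, mu: float, nu: float):
    """Deterministic mutation step ``p -> p (1 - nu) + (1 - p) mu``.

    Fixed point at ``mu / (mu + nu)`` (0.5 for equal rates).
    """
    p = np.asarray(p, dtype=float)
    out = p * (1.0 - nu) + (1.0 - p) * mu
    return out if out.ndim else float(out)


def _step(
    p: np.ndarray,
    t: int,
    model: TraitModel,
    directional_only: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation on a frequency array (any shape with locus last axis)."""
    zbar = model.gamma * np.sum(p, axis=-1)
    pm = mutation_update(p, model.mu, model.nu)
    w = selection_weight(pm, zbar, t, model, directional_only)
    # normalized post-selection expected frequency; a-allele weight is 1
    psel = pm * w / (pm * w + (1.0 - pm))
    return rng.binomial(model.Ne, psel) / model.Ne


def wf_generation(
    state: FrequencyState,
    model: TraitModel,
    directional_only: bool = False,
    rng: np.random.Generator | None = None,
) -> FrequencyState:
    """Advance one Wright-Fisher generation (mutation, then selection+drift).

    The trait mean entering the selection weight is computed once from the
    current (pre-mutation) state and shared by all loci.
    """
    rng = np.random.default_rng() if rng is None else rng
    p = _step(state.p, state.t, model, directional_only, rng)
    return FrequencyState(p=p, t=state.t + 1)


def _initial_frequencies(model: TraitModel, replicates: int) -> np.ndarray:
    """Majority-allele start: d loci at p=0 (a-majority), L-d at p=1."""
    p = np.ones((replicates, model.L))
    p[:, : model.d] = 0.0
    return p


def equilibrate(config: WfRunConfig, rng: np.random.Generator) -> FrequencyState:
    """Burn in to mutation-selection-drift balance under the ancestral optimum.

    Starts from the majority-allele configuration and runs the configured
    number of generations (default 8 Ne) at ``t < 0``; returns the state at
    ``t = 0``, the generation of the environmental change.
    """
    p = _initial_frequencies(config.model, config.replicate_count)
    for _ in range(config.equilibration_generations):
        p = _step(p, -1, config.model, config.directional_only, rng)
    return FrequencyState(p=p, t=0)


def run_to_phenotime(
    state: FrequencyState, config: WfRunConfig, rng: np.random.Generator
) -> ArchitectureSample:
    """Simulate past the optimum shift, snapshotting at each waypoint.

    For every ``cz`` in the stop schedule, the full frequency vector of each
    replicate is recorded at the first generation (including t = 0) where
    ``Zbar >= zopt0 + cz * gamma``.  Replicates that never reach a waypoint
    within ``max_generations`` are flagged incomplete (NaN snapshot), never
    silently dropped.
    """
    model = config.model
    stops = config.stops
    p = np.atleast_2d(np.array(state.p, dtype=float, copy=True))
    R, L = p.shape
    n_stops = len(stops.cz_values)
    thresholds = model.zopt0 + np.asarray(stops.cz_values) * model.gamma

    freqs = np.full((R, n_stops, L), np.nan)
    generations = np.full((R, n_stops), -1, dtype=int)
    completed = np.zeros((R, n_stops), dtype=bool)
    next_stop = np.zeros(R, dtype=int)  # index of next pending waypoint
    sgv = p.copy()

    t = state.t
    while True:
        zbar = model.gamma * np.sum(p, axis=1)
        # record every waypoint crossed at this generation (may be several)
        while True:
            pending = next_stop < n_stops
            hit = pending & (zbar >= thresholds[np.minimum(next_stop, n_stops - 1)])
            if not np.any(hit):
                break
            idx = np.flatnonzero(hit)
            freqs[idx, next_stop[idx], :] = p[idx]
            generations[idx, next_stop[idx]] = t
            completed[idx, next_stop[idx]] = True
            next_stop[idx] += 1
        active = np.flatnonzero(next_stop < n_stops)
        if active.size == 0 or t - state.t >= stops.max_generations:
            break
        p[active] = _step(p[active], t, model, config.directional_only, rng)
        t += 1

    return ArchitectureSample(
        freqs=freqs,
        cz_values=stops.cz_values,
        generations=generations,
        completed=completed,
        sgv=sgv,
        config={
            "simulator": "wf_le",
            "directional_only": config.directional_only,
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
            "max_generations": stops.max_generations,
        },
    )


def run_wf(config: WfRunConfig) -> ArchitectureSample:
    """Full pipeline: (optional) equilibration, optimum shift, pheno-time run."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    if config.from_sgv:
        state = equilibrate(config, rng)
    else:
        state = FrequencyState(
            p=_initial_frequencies(config.model, config.replicate_count), t=0
        )
    return run_to_phenotime(state, config, rng)
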