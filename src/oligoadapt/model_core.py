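"""Trait/fitness model and parameter containers shared by simulators and analytics.

The trait is additive over ``L`` biallelic haploid loci with equal effects:
allele ``a_i`` contributes 0, allele ``A_i`` contributes ``gamma``, so an
individual's trait value is ``Z = gamma * (number of A alleles)``.  Wrightian
fitness is Gaussian stabilizing selection toward a (possibly time-dependent)
optimum, ``W(Z) = exp[-(sigma(t)/2) (Z - Zopt(t))^2]``.  At generation 0 the
optimum jumps from its ancestral value ``zopt0`` to ``zopt_new >= zopt0``
(sudden-shift scenario); the selection strength may also change at that point.

Before the shift, ``d`` of the loci carry the ``a`` majority allele (these hold
the *beneficial variation* once the optimum moves up) and the remaining
``L - d`` loci carry the ``A`` majority allele, which places the ancestral
trait mean at ``zopt0 = (L - d) * gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraitModel",
    "FrequencyState",
    "StopSchedule",
    "trait_mean",
    "gaussian_fitness",
    "disruptive_directional_ratio",
]


@dataclass(frozen=True)
class TraitModel:
    """Static parameterization of the trait, selection and mutation model.

    Parameters
    ----------
    L
        Number of loci in the genetic basis of the trait.
    gamma
        Effect size of the ``A`` allele, in trait units.
    Ne
        Haploid population size.
    mu
        Per-locus forward mutation probability per generation (``a -> A``).
    nu
        Per-locus back-mutation probability (``A -> a``).  Defaults to ``mu``
        (the symmetric case, for which ``theta_i / 2 = Ne * mu``).
    sigma_before, sigma_after
        Selection strength (inverse-squared trait units) before and from the
        environmental change at generation 0.  ``sigma_after`` defaults to
        ``sigma_before``.
    zopt0, zopt_new
        Ancestral and new trait optimum.  The sudden shift happens between
        generation -1 and 0.
    d
        Number of loci initialized with the ``a`` majority allele (beneficial
        variation).  If omitted it is inferred from ``zopt0`` via
        ``d = L - zopt0 / gamma``.
    """

    L: int
    gamma: float
    Ne: int
    mu: float
    nu: float | None = None
    sigma_before: float = 1.0
    sigma_after: float | None = None
    zopt0: float = 0.0
    zopt_new: float = 0.0
    d: int | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be a positive integer, got {self.L}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.Ne < 1:
            raise ValueError(f"Ne must be a positive integer, got {self.Ne}")
        if self.nu is None:
            object.__setattr__(self, "nu", self.mu)
        if not (0.0 <= self.mu <= 1.0 and 0.0 <= self.nu <= 1.0):
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.sigma_after is None:
            object.__setattr__(self, "sigma_after", self.sigma_before)
        if self.sigma_before <= 0 or self.sigma_after <= 0:
            raise ValueError("selection strength sigma must be positive")
        if self.zopt_new < self.zopt0:
            raise ValueError("zopt_new must be >= zopt0 (upward shift scenario)")
        if self.d is None:
            d = self.L - self.zopt0 / self.gamma
            if abs(d - round(d)) > 1e-9:
                raise ValueError(
                    "zopt0 must equal (L - d) * gamma for an integer d; "
                    f"got zopt0={self.zopt0}, gamma={self.gamma}, L={self.L}"
                )
            object.__setattr__(self, "d", int(round(d)))
        if not 0 <= self.d <= self.L:
            raise ValueError(f"d must satisfy 0 <= d <= L, got d={self.d}")
        if abs((self.L - self.d) * self.gamma - self.zopt0) > 1e-9 * max(1.0, self.gamma):
            raise ValueError(
                f"inconsistent initialization: zopt0={self.zopt0} but "
                f"(L - d) * gamma = {(self.L - self.d) * self.gamma}"
            )

    def sigma(self, t: int) -> float:
        """Selection strength at generation ``t`` (step schedule)."""
        return self.sigma_before if t < 0 else self.sigma_after

    def zopt(self, t: int) -> float:
        """Trait optimum at generation ``t`` (step schedule)."""
        return self.zopt0 if t < 0 else self.zopt_new

    @property
    def theta_locus(self) -> float:
        """Population-scaled per-locus mutation rate ``theta = 2 Ne mu``."""
        return 2.0 * self.Ne * self.mu


@dataclass
class FrequencyState:
    """Linkage-equilibrium state: vector of ``A`` allele frequencies.

    ``p`` may be a 1-d vector of length ``L`` (one replicate) or a 2-d array
    of shape ``(n_replicates, L)`` for lockstep replicate batches.
    """

    p: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0.0) or np.any(self.p > 1.0):
            raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class StopSchedule:
    """Phenotypic waypoints at which allele frequencies are recorded.

    ``cz_values`` are the stopping points in units of mutational steps (gamma)
    above the ancestral optimum: frequencies are snapshot at the first
    generation where the trait mean crosses ``zopt0 + cz * gamma``.
    """

    cz_values: tuple[float, ...]
    max_generations: int = 1_000_000

    def __post_init__(self) -> None:
        cz = tuple(float(c) for c in self.cz_values)
        object.__setattr__(self, "cz_values", cz)
        if len(cz) == 0:
            raise ValueError("at least one stopping point is required")
        if any(c <= 0 for c in cz):
            raise ValueError("stopping points must be positive")
        if any(b <= a for a, b in zip(cz, cz[1:])):
            raise ValueError("stopping points must be strictly ascending")
        if self.max_generations < 1:
            raise ValueError("max_generations must be positive")


def trait_mean(state: FrequencyState, model: TraitModel) -> float | np.ndarray:
    """Population trait mean ``Zbar = gamma * sum_i p_i``.

    For a batch state of shape ``(R, L)`` returns one mean per replicate.
    """
    return model.gamma * np.sum(state.p, axis=-1)


def gaussian_fitness(Z, t: int, model: TraitModel):
    """Gaussian stabilizing fitness ``W(Z) = exp[-(sigma(t)/2)(Z - Zopt(t))^2]``.

    Equals 1 exactly at the optimum and decreases symmetrically with the
    distance from it; invariant under joint translation of ``Z`` and the
    optimum.
    """
    Z = np.asarray(Z, dtype=float)
    w = np.exp(-0.5 * model.sigma(t) * (Z - model.zopt(t)) ** 2)
    return w if w.ndim else float(w)


def disruptive_directional_ratio(
    zbar: float, t: int, model: TraitModel, n_grid: int = 10_001
) -> float:
    """Maximal strength of the disruptive selection term relative to directional.

    In the single-locus dynamics the selection coefficient contains a
    directional part, ``Zopt(t) - Zbar``, and a disruptive part,
    ``(gamma/2)(1 - 2 p)``.  This returns
    ``max_p |(gamma/2)(1 - 2p)| / |Zopt(t) - Zbar|``, maximized numerically
    over the frequency range; it quantifies how strongly the full model can
    deviate from the directional-only dynamics at the given trait mean.
    """
    gap = model.zopt(t) - zbar
    if gap == 0:
        raise ValueError("trait mean is at the optimum; directional term vanishes")
    p = np.linspace(0.0, 1.0, n_grid)
    disruptive = np.abs(0.5 * model.gamma * (1.0 - 2.0 * p))
    return float(np.max(disruptive) / abs(gap))
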