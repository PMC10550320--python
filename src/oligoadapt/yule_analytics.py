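"""Analytical theory of the adaptive architecture.

During the early *establishment phase* of adaptation, beneficial mutant
lineages that escape stochastic loss are tracked by a multi-type Yule
process: new immortal lines are seeded at locus ``i`` at rate ``theta_i``
(the population-scaled mutation rate ``2 Ne mu_i``) and every existing line
splits at rate 1.  The establishment probability itself cancels out of the
sequence of events under a time rescaling, so no selection parameter enters.
The limiting line counts per locus behave like independent
``Gamma(theta_i)`` variables, hence the vector of count *ratios* follows an
inverted Dirichlet distribution.

During the subsequent deterministic phase, pure directional selection on an
additive trait preserves the ratios of allelic odds ``u_i = p_i/(1-p_i)``
(the time derivative of ``u_i/u_j`` vanishes), so the establishment-phase
ratio distribution is transported unchanged to any later phenotypic
waypoint.  Conditioning on the trait mean having advanced ``cz`` mutational
steps imposes ``sum_i p_i = cz``, which pins down the configuration on each
ratio ray.  Sampling is therefore exact and cheap: draw
``G_i ~ Gamma(theta_i)`` independently, solve the scalar equation
``sum_i lam*G_i/(1 + lam*G_i) = cz`` for ``lam > 0``, and set
``p_i = lam*G_i / (1 + lam*G_i)``.

Closed-form densities are provided for the joint distribution of the
``d - 1`` free frequencies (any ``d``) and for the two-locus marginal; both
are evaluated in log space to survive large ``theta`` (up to ~1e3) and
near-boundary frequencies.  No operation in this module accepts a selection
parameter: the architecture conditioned on the trait mean depends on the
mutation rates only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import gammaln

from .architecture_stats import OrderedMarginalSet, ordered_from_matrix

__all__ = [
    "YuleState",
    "yule_simulate",
    "yule_simulate_batch",
    "solve_lambda",
    "sample_joint",
    "joint_frequency_density",
    "two_locus_marginal_density",
    "integrate_joint_density",
    "ordered_marginal_theory",
]

_TINY = np.finfo(float).tiny  # clamp for Gamma draws that underflow to 0


def _validate_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or theta.size < 2:
        raise ValueError("theta must be a vector of length >= 2")
    if np.any(theta <= 0) or not np.all(np.isfinite(theta)):
        raise ValueError("all theta entries must be positive and finite")
    return theta


@dataclass
class YuleState:
    """Immortal-line counts per locus at the end of a Yule run."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def yule_simulate(
    theta, n_lines: int, rng: np.random.Generator
) -> YuleState:
    """Run the multi-type Yule process until ``n_lines`` immortal lines exist.

    The embedded jump chain is simulated: when ``k_i`` lines exist at locus
    ``i`` (total ``K``), the next event is a new mutation at locus ``i`` with
    probability ``theta_i / (sum(theta) + K)`` or a split of an existing line
    at locus ``i`` with probability ``k_i / (sum(theta) + K)``.  Both event
    types add one line, so the chain is a Polya urn with initial weights
    ``theta``.
    """
    theta = _validate_theta(theta)
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    counts = np.zeros(len(theta), dtype=np.int64)
    for total in range(n_lines):
        w = theta + counts
        u = rng.random() * (theta.sum() + total)
        counts[np.searchsorted(np.cumsum(w), u, side="right")] += 1
    return YuleState(counts=counts)


def yule_simulate_batch(
    theta, n_lines: int, n_runs: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized replicate Yule runs; returns (n_runs, d) final counts."""
    theta = _validate_theta(theta)
    if n_lines < 1 or n_runs < 1:
        raise ValueError("n_lines and n_runs must be >= 1")
    d = len(theta)
    counts = np.zeros((n_runs, d), dtype=np.int64)
    rows = np.arange(n_runs)
    for total in range(n_lines):
        w = theta[None, :] + counts
        cum = np.cumsum(w, axis=1)
        u = rng.random(n_runs) * (theta.sum() + total)
        idx = (u[:, None] >= cum).sum(axis=1)
        counts[rows, idx] += 1
    return counts


def solve_lambda(G, cz: float, tol: float = 1e-12, max_iter: int = 200):
    """Solve ``sum_i lam*G_i/(1 + lam*G_i) = cz`` for ``lam > 0``.

    ``G`` is a positive vector of length ``d`` or an ``(n, d)`` batch; the
    map is strictly increasing and concave in ``lam``, so safeguarded Newton
    from below converges monotonically.  The returned ``lam`` satisfies
    ``|sum_i p_i - cz| <= 1e-10`` elementwise.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    n, d = G.shape
    if not np.all(np.isfinite(G)) or np.any(G <= 0):
        raise ValueError("G must be finite and strictly positive")
    if not 0.0 < cz < d:
        raise ValueError(f"cz must lie in (0, d); got cz={cz}, d={d}")

    # start below the root: with equal G the root is cz / (g (d - cz));
    # using the max of G keeps the start on the lower side
    lam = cz / ((d - cz) * G.max(axis=1))
    for _ in range(max_iter):
        x = lam[:, None] * G
        f = np.sum(x / (1.0 + x), axis=1)
        df = np.sum(G / (1.0 + x) ** 2, axis=1)
        delta = (cz - f) / df
        lam = lam + delta
        if np.all(np.abs(cz - f) <= tol):
            break
    x = lam[:, None] * G
    resid = np.abs(np.sum(x / (1.0 + x), axis=1) - cz)
    if np.any(resid > 1e-10):
        # bisection fallback for pathological spreads of G
        bad = np.flatnonzero(resid > 1e-10)
        for i in bad:
            lo, hi = 0.0, max(lam[i], 1.0)
            while np.sum(hi * G[i] / (1.0 + hi * G[i])) < cz:
                hi *= 2.0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if np.sum(mid * G[i] / (1.0 + mid * G[i])) < cz:
                    lo = mid
                else:
                    hi = mid
            lam[i] = 0.5 * (lo + hi)
    return lam if n > 1 else float(lam[0])


def sample_joint(
    theta, cz: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` architectures conditioned on the trait mean.

    Returns an ``(n, d)`` array of frequencies with ``sum_i p_i = cz`` (to
    solver tolerance 1e-10) in every row, distributed according to the
    transported inverted-Dirichlet law.  Gamma draws that underflow to zero
    (possible for very small ``theta_i``) are clamped to the smallest
    positive normal float.
    """
    theta = _validate_theta(theta)
    d = len(theta)
    if not 0.0 < cz < d:
        raise ValueError(f"cz must lie in (0, d); got cz={cz}, d={d}")
    if n < 1:
        raise ValueError("n must be >= 1")
    G = np.maximum(rng.gamma(shape=theta, size=(n, d)), _TINY)
    lam = np.atleast_1d(solve_lambda(G, cz))
    x = lam[:, None] * G
    return x / (1.0 + x)


def joint_frequency_density(p_minor, cz: float, theta) -> np.ndarray:
    """Joint density of the ``d - 1`` free frequencies given the trait mean.

    Arguments are the frequencies ``(p_2, ..., p_d)``; the first frequency
    is implied by the constraint, ``p_1 = cz - sum_k p_k``.  Accepts a
    single point (length ``d - 1``) or an ``(m, d - 1)`` batch.  Returns 0
    outside the support (all ``p_i`` and the implied ``p_1`` in (0, 1)).

    The density is the inverted-Dirichlet law of the odds ratios
    ``u_i/u_1`` pushed through the constraint map; evaluated in log space.
    """
    theta = _validate_theta(theta)
    d = len(theta)
    if not 0.0 < cz < d:
        raise ValueError(f"cz must lie in (0, d); got cz={cz}, d={d}")
    pm = np.atleast_2d(np.asarray(p_minor, dtype=float))
    if pm.shape[1] != d - 1:
        raise ValueError(f"expected {d - 1} free frequencies, got {pm.shape[1]}")

    S = pm.sum(axis=1)
    p1 = cz - S
    ok = (
        np.all((pm > 0.0) & (pm < 1.0), axis=1) & (p1 > 0.0) & (p1 < 1.0)
    )
    out = np.zeros(len(pm))
    if np.any(ok):
        pmk = pm[ok]
        p1k = p1[ok]
        q1 = 1.0 - p1k
        u1 = p1k / q1
        u = pmk / (1.0 - pmk)
        T = u.sum(axis=1)
        th_minor = theta[1:]
        logC = gammaln(theta.sum()) - gammaln(theta).sum()
        logdens = (
            logC
            + np.sum(
                (th_minor - 1.0) * np.log(pmk)
                - (th_minor + 1.0) * np.log(1.0 - pmk),
                axis=1,
            )
            + np.log1p(np.sum(pmk * (1.0 - pmk), axis=1) / (p1k * q1))
            - theta[0] * np.log1p(T / u1)
            - theta[1:].sum() * np.log(u1 + T)
        )
        out[ok] = np.exp(logdens)
    return out if np.asarray(p_minor).ndim > 1 else float(out[0])


def two_locus_marginal_density(p, cz: float, theta1: float, theta2: float):
    """Closed-form marginal density of the second-locus frequency (d = 2).

    Support is ``p in (max(0, cz - 1), min(1, cz))``; returns 0 outside.
    """
    if theta1 <= 0 or theta2 <= 0:
        raise ValueError("theta1 and theta2 must be positive")
    if not 0.0 < cz < 2.0:
        raise ValueError(f"cz must lie in (0, 2); got {cz}")
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    lo, hi = max(0.0, cz - 1.0), min(1.0, cz)
    ok = (p > lo) & (p < hi)
    out = np.zeros_like(p)
    if np.any(ok):
        pk = p[ok]
        a = cz - pk          # implied first-locus frequency
        b = 1.0 - pk
        c = 1.0 + pk - cz    # 1 - a
        num = pk * b + a * c
        den = cz - 2.0 * pk * a
        logdens = (
            gammaln(theta1 + theta2)
            - gammaln(theta1)
            - gammaln(theta2)
            + np.log(num)
            - (theta1 + theta2) * np.log(den)
            + (theta1 - 1.0) * np.log(a * b)
            + (theta2 - 1.0) * np.log(c * pk)
        )
        out[ok] = np.exp(logdens)
    return float(out[0]) if scalar else out


def integrate_joint_density(theta, cz: float, **quad_kwargs) -> float:
    """Numerical mass of the joint density over its support (oracle, d <= 4).

    Direct ``(d - 1)``-fold adaptive quadrature; intended as an independent
    check of normalization and of the sampler, not as a route to marginals
    for large ``d``.
    """
    theta = _validate_theta(theta)
    d = len(theta)
    if d > 4:
        raise ValueError("quadrature oracle is limited to d <= 4")
    opts = {"epsabs": 1e-10, "epsrel": 1e-10}
    opts.update(quad_kwargs)

    if d == 2:
        lo, hi = max(0.0, cz - 1.0), min(1.0, cz)
        val, _ = integrate.quad(
            lambda p: joint_frequency_density([[p]], cz, theta)[0],
            lo,
            hi,
            epsabs=opts["epsabs"],
            epsrel=opts["epsrel"],
            limit=200,
        )
        return float(val)

    def density(*args):
        return joint_frequency_density([list(args)], cz, theta)[0]

    # free frequencies p_2..p_d each in (0,1), implied p_1 = cz - sum in (0,1)
    def bounds_last(*fixed):
        s = sum(fixed)
        lo = max(0.0, cz - 1.0 - s)
        hi = min(1.0, cz - s)
        return (lo, max(lo, hi))  # empty slice collapses to zero width

    ranges = [bounds_last] + [(0.0, 1.0)] * (d - 2)
    val, _ = integrate.nquad(
        density, ranges, opts=[{"epsabs": opts["epsabs"], "epsrel": opts["epsrel"]}] * (d - 1)
    )
    return float(val)


def project_to_waypoint(freqs, cz: float) -> np.ndarray:
    """Transport frequency vectors along the directional flow to ``sum p = cz``.

    Under pure directional selection all allelic odds ``u_i = p_i/(1-p_i)``
    are rescaled by a common factor as the trait mean moves, so the unique
    flow trajectory through a recorded state crosses the exact waypoint at
    the odds scaling ``lam`` solving ``sum_i lam*u_i/(1 + lam*u_i) = cz``.
    This removes the within-generation overshoot of discrete-time snapshots
    (which record the first integer generation past the waypoint) when
    comparing simulations against the conditioned theory.  Frequencies
    exactly 0 or 1 are fixed points of the flow and are left untouched.
    """
    p = np.atleast_2d(np.asarray(freqs, dtype=float))
    out = p.copy()
    ones = (p >= 1.0).sum(axis=1)
    for i in range(len(p)):
        seg = (p[i] > 0.0) & (p[i] < 1.0)
        target = cz - ones[i]
        if not np.any(seg):
            continue
        if target <= 0.0:
            # fixed loci alone already meet the waypoint: the backward flow
            # sends every segregating frequency to the lower boundary
            out[i, seg] = 0.0
            continue
        if target >= seg.sum():
            raise ValueError(
                f"waypoint cz={cz} unreachable along the flow through row {i}"
            )
        u = p[i, seg] / (1.0 - p[i, seg])
        lam = solve_lambda(u[None, :], target)
        x = lam * u
        out[i, seg] = x / (1.0 + x)
    return out if np.asarray(freqs).ndim > 1 else out[0]


def ordered_marginal_theory(
    theta, cz: float, n: int, rng: np.random.Generator, bins: int = 50
) -> OrderedMarginalSet:
    """Rank-ordered marginals of the theory: sample, sort descending, pool."""
    samples = sample_joint(theta, cz, n, rng)
    return ordered_from_matrix(samples, keep=None, bins=bins)
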