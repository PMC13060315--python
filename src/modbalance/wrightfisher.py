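"""Discrete-generation Wright-Fisher simulation for all four GPFMs.

Each generation applies three phases in order: mutation, recombination,
selection.  Mutation counts are Poisson with rates computed from the
start-of-generation state; recombination (``rho = 1``) randomly pairs all
individuals and swaps their second chromosome (loci ``L1+1..2L`` on the
pleiotropic map, the trait/latent second coordinate otherwise); selection
resamples the population by multinomial draws with probabilities proportional
to Wrightian fitness ``W = exp(F)``.

Populations are stored as flat numpy arrays so a generation costs a handful
of vectorized O(N) operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gpfm import (
    FitnessParams,
    GPFMSpec,
    NestedParams,
    discretize_modular,
    discordant_counts_from_traits,
    draw_pleiotropic_angles,
    greedy_pleiotropic_bits,
)

__all__ = [
    "Population",
    "WfRun",
    "initialize_population",
    "mutation_phase",
    "recombination_phase",
    "selection_phase",
    "run_wf",
]


@dataclass
class Population:
    """N individual genetic states with cached traits.

    ``counts`` holds 1-allele counts per chromosome for the modular and
    discordant maps (shape ``(N, 2)``); ``bits`` the explicit genomes for the
    pleiotropic map (``(N, 2L)``); ``x`` the per-individual trait pairs.  For
    the nested FGM the traits themselves are the state.
    """

    spec: GPFMSpec
    a: FitnessParams
    x: np.ndarray  # (N, 2) trait cache
    counts: np.ndarray | None = None  # (N, 2) modular/discordant
    bits: np.ndarray | None = None  # (N, 2L) pleiotropic
    angles: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.x.shape[0]

    def fitness(self) -> np.ndarray:
        return -((self.x[:, 0] / self.a.a1) ** 2) - (self.x[:, 1] / self.a.a2) ** 2

    def recompute_traits(self) -> np.ndarray:
        """Traits recomputed from the genetic state (cache verification)."""
        return _traits_from_state(self)

    def refresh_cache(self) -> None:
        self.x = self.recompute_traits()


def _traits_from_state(pop: Population) -> np.ndarray:
    spec = pop.spec
    if spec.model == "pleiotropic":
        g = pop.bits.astype(float)
        return spec.delta * np.column_stack((g @ np.cos(pop.angles), g @ np.sin(pop.angles)))
    if spec.model == "modular":
        return -spec.delta * pop.counts.astype(float)
    if spec.model == "discordant":
        y = -spec.delta * pop.counts.astype(float)
        c1, c2 = math.cos(spec.theta1), math.cos(spec.theta2)
        s1, s2 = math.sin(spec.theta1), math.sin(spec.theta2)
        return np.column_stack((y[:, 0] * c1 + y[:, 1] * c2, y[:, 0] * s1 + y[:, 1] * s2))
    return pop.x.copy()  # nested: traits are the state


def initialize_population(spec: GPFMSpec, a: FitnessParams, x0, N: int) -> Population:
    """Monomorphic population at the model-specific representation of ``x0``.

    Pleiotropic: angles drawn once from ``spec.angle_seed``; the genome is
    built greedily, flipping loci in index order whenever the flip reduces
    the Euclidean distance to ``x0``.  Modular/nested: traits rounded to the
    nearest delta-multiple, clamped to <= 0.  Discordant: latent solve, then
    lattice rounding with both chromosomes forced to carry >= 1 deleterious
    allele.
    """
    if N < 1:
        raise ValueError("population size must be positive")
    if spec.model == "pleiotropic":
        angles = draw_pleiotropic_angles(spec.genome_size, spec.angle_seed)
        bits0 = greedy_pleiotropic_bits(angles, spec.delta, x0)
        bits = np.tile(bits0, (N, 1))
        pop = Population(spec, a, x=np.zeros((N, 2)), bits=bits, angles=angles)
        pop.refresh_cache()
        return pop
    if spec.model == "modular":
        st = discretize_modular(x0, spec.delta, spec.L1, spec.L2)
        counts = np.tile(np.array([st.b1, st.b2], dtype=np.int64), (N, 1))
    elif spec.model == "discordant":
        st = discordant_counts_from_traits(
            x0, spec.theta1, spec.theta2, spec.delta, spec.L1, spec.L2
        )
        counts = np.tile(np.array([st.c1, st.c2], dtype=np.int64), (N, 1))
    elif spec.model == "nested":
        xi = [min(round(v / spec.delta) * spec.delta, 0.0) for v in x0]
        pop = Population(spec, a, x=np.tile(np.asarray(xi, dtype=float), (N, 1)))
        return pop
    else:  # pragma: no cover - guarded by GPFMSpec
        raise ValueError(spec.model)
    pop = Population(spec, a, x=np.zeros((N, 2)), counts=counts)
    pop.refresh_cache()
    return pop


def _weighted_individuals(rng, weights: np.ndarray, size: int) -> np.ndarray:
    tot = weights.sum()
    return rng.choice(len(weights), size=size, p=weights / tot)


def mutation_phase(pop: Population, mu: float, rng: np.random.Generator) -> Population:
    """Apply one generation's worth of Poisson mutation events in place."""
    if mu == 0.0:
        return pop
    spec, N = pop.spec, pop.N
    if spec.model == "pleiotropic":
        U = 2.0 * mu * (spec.genome_size // 2)
        n_events = rng.poisson(N * U)
        if n_events:
            inds = rng.integers(N, size=n_events)
            loci = rng.integers(spec.genome_size, size=n_events)
            cosv, sinv = np.cos(pop.angles), np.sin(pop.angles)
            for j, ell in zip(inds, loci):  # sequential: same-site hits must toggle
                sign = 1.0 - 2.0 * pop.bits[j, ell]
                pop.x[j, 0] += spec.delta * sign * cosv[ell]
                pop.x[j, 1] += spec.delta * sign * sinv[ell]
                pop.bits[j, ell] ^= 1
    elif spec.model in ("modular", "discordant"):
        L = (spec.L1, spec.L2)
        for k in (0, 1):
            b = pop.counts[:, k].astype(float)
            n_ben = rng.poisson(mu * b.sum())
            if n_ben:
                hit = _weighted_individuals(rng, b, n_ben)
                np.subtract.at(pop.counts[:, k], hit, 1)
            d_start = np.maximum(L[k] - b, 0.0)  # deleterious supply at start of generation
            n_del = rng.poisson(mu * d_start.sum())
            if n_del:
                hit = _weighted_individuals(rng, d_start, n_del)
                np.add.at(pop.counts[:, k], hit, 1)
        np.clip(pop.counts, 0, [spec.L1, spec.L2], out=pop.counts)
        pop.refresh_cache()
    elif spec.model == "nested":
        params = NestedParams(spec.basal_step, spec.n1, spec.n2)
        U = 2.0 * mu * (spec.genome_size // 2)
        mean = -params.m**2 / 2.0
        for k in (0, 1):
            n_events = rng.poisson(N * U / 2.0)
            if not n_events:
                continue
            inds = rng.integers(N, size=n_events)
            ni = params.n_i(k + 1)
            for j in inds:  # sd depends on the individual's current trait
                xi = pop.x[j, k]
                sd = params.m * math.sqrt(2.0 * abs(xi) / ni)
                eff = rng.normal(mean, sd)
                pop.x[j, k] = min(pop.x[j, k] + eff, 0.0)
    return pop


def recombination_phase(pop: Population, rho: float, rng: np.random.Generator) -> Population:
    """Free inter-chromosome reassortment: random perfect pairing, swap of the
    second chromosome within each pair.  ``rho = 0`` is the identity; with odd
    N one individual is left unpaired."""
    if rho == 0:
        return pop
    if rho != 1:
        raise ValueError("recombination rate must be 0 or 1")
    N = pop.N
    perm = rng.permutation(N)
    n_pairs = N // 2
    ai, bi = perm[:n_pairs], perm[n_pairs : 2 * n_pairs]
    spec = pop.spec
    if spec.model == "pleiotropic":
        tmp = pop.bits[ai, spec.L1 :].copy()
        pop.bits[ai, spec.L1 :] = pop.bits[bi, spec.L1 :]
        pop.bits[bi, spec.L1 :] = tmp
        pop.refresh_cache()
    elif spec.model in ("modular", "discordant"):
        tmp = pop.counts[ai, 1].copy()
        pop.counts[ai, 1] = pop.counts[bi, 1]
        pop.counts[bi, 1] = tmp
        pop.refresh_cache()
    else:  # nested: trait x2 is the second-chromosome content
        tmp = pop.x[ai, 1].copy()
        pop.x[ai, 1] = pop.x[bi, 1]
        pop.x[bi, 1] = tmp
    return pop


def selection_phase(pop: Population, rng: np.random.Generator) -> Population:
    """Multinomial resampling with probabilities proportional to W = exp(F)."""
    F = pop.fitness()
    w = np.exp(F - F.max())
    p = w / w.sum()
    counts = rng.multinomial(pop.N, p)
    idx = np.repeat(np.arange(pop.N), counts)
    pop.x = pop.x[idx]
    if pop.counts is not None:
        pop.counts = pop.counts[idx]
    if pop.bits is not None:
        pop.bits = pop.bits[idx]
    return pop


@dataclass
class WfRun:
    """Per-generation record of population means for one replicate."""

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    F: np.ndarray
    terminated: bool
    truncated: bool
    seed: int

    @property
    def ratio(self) -> np.ndarray:
        return self.x2 / self.x1


def run_wf(
    spec: GPFMSpec,
    a: FitnessParams,
    N: int,
    mu: float,
    rho: float,
    x0,
    F_f: float = -0.01,
    seed: int = 0,
    max_generations: int = 2_000_000,
    cache_check_every: int = 100,
) -> WfRun:
    """Simulate one Wright-Fisher replicate until mean fitness reaches ``F_f``
    or the max-generations guard fires (run flagged ``truncated``)."""
    if N <= 0 or mu < 0:
        raise ValueError("invalid population size or mutation rate")
    rng = np.random.default_rng(seed)
    pop = initialize_population(spec, a, x0, N)
    ts, x1s, x2s, Fs = [], [], [], []

    def record(g):
        ts.append(float(g))
        x1s.append(float(pop.x[:, 0].mean()))
        x2s.append(float(pop.x[:, 1].mean()))
        Fs.append(float(pop.fitness().mean()))

    record(0)
    terminated = Fs[-1] >= F_f
    gen = 0
    while not terminated and gen < max_generations:
        gen += 1
        mutation_phase(pop, mu, rng)
        recombination_phase(pop, rho, rng)
        selection_phase(pop, rng)
        if cache_check_every and gen % cache_check_every == 0:
            fresh = pop.recompute_traits()
            if not np.allclose(fresh, pop.x, atol=1e-9):  # pragma: no cover
                raise AssertionError("trait cache drifted from genetic state")
            pop.x = fresh
        record(gen)
        terminated = Fs[-1] >= F_f
    return WfRun(
        t=np.asarray(ts),
        x1=np.asarray(x1s),
        x2=np.asarray(x2s),
        F=np.asarray(Fs),
        terminated=terminated,
        truncated=not terminated,
        seed=seed,
    )
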