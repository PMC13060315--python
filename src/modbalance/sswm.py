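"""Gillespie simulation of the successive-mutations (SSWM) adaptive walk.

In the strong-selection weak-mutation regime (``N * U_b << 1``) the population
is monomorphic between fixation events.  The engine draws the waiting time to
the next beneficial mutation from an exponential distribution with rate
``N * U_b``, draws the mutation from the model-specific supply, evaluates its
exact selection coefficient and fixes it with Kimura's probability
``(1 - exp(-2s)) / (1 - exp(-2Ns))``; lost mutations advance time only.
Deleterious and neutral mutations never enter the walk.  The run terminates
when mean fitness reaches ``F_f`` or the beneficial supply is exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gpfm import (
    FitnessParams,
    GPFMSpec,
    NestedParams,
    PleiotropicGenome,
    _pleiotropic_flip_effects,
    discretize_modular,
    discordant_counts_from_traits,
    draw_pleiotropic_angles,
    greedy_pleiotropic_bits,
    malthusian_fitness,
    nested_effect_distribution,
)

__all__ = ["kimura_fixation_probability", "run_sswm", "SswmRun"]


def kimura_fixation_probability(s: float, N: int) -> float:
    """Fixation probability of a beneficial mutation, (1-e^-2s)/(1-e^-2Ns)."""
    if not s > 0:
        raise ValueError("Kimura fixation lottery requires s > 0")
    if N < 2:
        raise ValueError("population size must be at least 2")
    return float(-np.expm1(-2.0 * s) / -np.expm1(-2.0 * N * s))


@dataclass
class SswmRun:
    """Record of one SSWM walk: state at t=0 and after every fixation."""

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    F: np.ndarray
    terminated: bool  # reached the target fitness contour
    supply_exhausted: bool
    n_proposed: int
    seed: int

    @property
    def ratio(self) -> np.ndarray:
        return self.x2 / self.x1


# Per-model walker objects share a tiny interface:
#   supply() -> genome-wide beneficial rate U_b
#   propose(rng) -> (exact s, apply) where apply() commits the mutation
class _ModularWalker:
    def __init__(self, state, a):
        self.b = [state.b1, state.b2]
        self.delta = state.delta
        self.a = (a.a1, a.a2)

    def traits(self):
        return -self.delta * self.b[0], -self.delta * self.b[1]

    def supply(self, mu):
        return mu * (self.b[0] + self.b[1])

    def propose(self, rng):
        tot = self.b[0] + self.b[1]
        i = 0 if rng.random() < self.b[0] / tot else 1
        # exact fitness difference of a +delta step on trait i
        s = (self.delta / self.a[i]) ** 2 * (2 * self.b[i] - 1)

        def apply():
            self.b[i] -= 1

        return s, apply


class _DiscordantWalker:
    def __init__(self, state, a):
        self.c = [state.c1, state.c2]
        self.delta = state.delta
        self.th = (state.theta1, state.theta2)
        self.a = a

    def traits(self):
        y1, y2 = -self.delta * self.c[0], -self.delta * self.c[1]
        x1 = y1 * math.cos(self.th[0]) + y2 * math.cos(self.th[1])
        x2 = y1 * math.sin(self.th[0]) + y2 * math.sin(self.th[1])
        return x1, x2

    def supply(self, mu):
        # Every 1 -> 0 flip counts toward the supply; draws with exact s <= 0
        # are treated as lost (see _step).  If no available flip is actually
        # beneficial the caller terminates.
        if not self._any_beneficial():
            return 0.0
        return mu * (self.c[0] + self.c[1])

    def _s_of(self, k):
        x = self.traits()
        e = (self.delta * math.cos(self.th[k]), self.delta * math.sin(self.th[k]))
        from .gpfm import selection_coefficient

        return selection_coefficient(x, e, self.a, mode="exact")

    def _any_beneficial(self):
        return any(self.c[k] > 0 and self._s_of(k) > 0 for k in (0, 1))

    def propose(self, rng):
        tot = self.c[0] + self.c[1]
        k = 0 if rng.random() < self.c[0] / tot else 1
        s = self._s_of(k)

        def apply():
            self.c[k] -= 1

        return s, apply


class _PleiotropicWalker:
    def __init__(self, genome: PleiotropicGenome, a):
        self.genome = genome
        self.a = a
        self._x = list(genome.traits())
        self._refresh()

    def traits(self):
        return self._x[0], self._x[1]

    def _refresh(self):
        s, idx = _pleiotropic_flip_effects(self.genome, self.a)
        self._ben = idx
        self._s = s

    def supply(self, mu):
        return mu * len(self._ben)

    def propose(self, rng):
        ell = int(self._ben[rng.integers(len(self._ben))])
        s = float(self._s[ell])

        def apply():
            g = self.genome
            sign = 1.0 - 2.0 * g.bits[ell]
            self._x[0] += g.delta * sign * math.cos(g.angles[ell])
            self._x[1] += g.delta * sign * math.sin(g.angles[ell])
            g.bits[ell] ^= 1
            self._refresh()

        return s, apply


class _NestedWalker:
    def __init__(self, x0, params: NestedParams, U: float, a):
        self.x = [float(x0[0]), float(x0[1])]
        self.p = params
        self.U = U  # genome-wide mutation rate 2*mu*L
        self.a = a

    def traits(self):
        return self.x[0], self.x[1]

    def _tails(self):
        out = []
        for i in (1, 2):
            xi = self.x[i - 1]
            if xi >= 0:
                out.append(None)
            else:
                out.append(nested_effect_distribution(xi, self.p, i))
        return out

    def supply(self, mu):
        tails = self._tails()
        return (self.U / 2.0) * sum(t.p_beneficial for t in tails if t is not None)

    def propose(self, rng):
        tails = self._tails()
        p = np.array([0.0 if t is None else t.p_beneficial for t in tails])
        i = int(rng.random() >= p[0] / p.sum())
        t = tails[i]
        # effect conditional on being beneficial: inverse-CDF on the upper tail
        from scipy.stats import norm

        u = rng.random()
        eff = float(norm.isf(u * t.p_beneficial, loc=t.mean, scale=t.sd))
        eff = min(eff, -self.x[i])  # the latent FGM cannot overshoot the optimum
        new = (self.x[0] + eff, self.x[1]) if i == 0 else (self.x[0], self.x[1] + eff)
        s = malthusian_fitness(new, self.a) - malthusian_fitness(tuple(self.x), self.a)

        def apply():
            self.x[i] += eff

        return s, apply


def _make_walker(spec: GPFMSpec, a: FitnessParams, x0, angle_rng_seed=None):
    if spec.model == "modular":
        return _ModularWalker(discretize_modular(x0, spec.delta, spec.L1, spec.L2), a)
    if spec.model == "discordant":
        st = discordant_counts_from_traits(
            x0, spec.theta1, spec.theta2, spec.delta, spec.L1, spec.L2
        )
        return _DiscordantWalker(st, a)
    if spec.model == "pleiotropic":
        seed = spec.angle_seed if spec.angle_seed is not None else angle_rng_seed
        angles = draw_pleiotropic_angles(spec.genome_size, seed)
        bits = greedy_pleiotropic_bits(angles, spec.delta, x0)
        return _PleiotropicWalker(PleiotropicGenome(bits, angles, spec.delta), a)
    if spec.model == "nested":
        params = NestedParams(spec.basal_step, spec.n1, spec.n2)
        # round to the delta lattice and clamp, as for the modular map
        x_init = tuple(min(round(xi / spec.delta) * spec.delta, 0.0) for xi in x0)
        return _NestedWalker(x_init, params, 0.0, a)  # U filled in by run_sswm
    raise ValueError(spec.model)


def run_sswm(
    spec: GPFMSpec,
    a: FitnessParams,
    N: int,
    mu: float,
    x0,
    F_f: float = -0.01,
    seed: int = 0,
    max_events: int = 10_000_000,
    t_max: float | None = None,
) -> SswmRun:
    """Simulate one SSWM adaptive walk on the chosen GPFM.

    ``x0`` is the target initial trait pair; the walker performs the
    model-specific initialization (greedy genome construction, lattice
    rounding, latent-state solve).  Returns the trajectory recorded at t=0
    and at every fixation.
    """
    if N <= 0 or mu <= 0:
        raise ValueError("population size and mutation rate must be positive")
    rng = np.random.default_rng(seed)
    walker = _make_walker(spec, a, x0, angle_rng_seed=seed)
    if spec.model == "nested":
        walker.U = mu * spec.genome_size  # genome-wide rate U = 2*mu*L

    t = 0.0
    ts, x1s, x2s, Fs = [0.0], [], [], []
    x = walker.traits()
    x1s.append(x[0])
    x2s.append(x[1])
    Fs.append(malthusian_fitness(x, a))
    terminated = Fs[-1] >= F_f
    supply_exhausted = False
    n_prop = 0

    while not terminated:
        Ub = walker.supply(mu)
        if Ub <= 0.0:
            supply_exhausted = True
            break
        rate = N * Ub
        # between a lost mutation and the next draw the state (hence U_b) is
        # unchanged, so the waiting times compose; draw proposals until one
        # fixes, accumulating exponential waits at the cached rate
        fixed = False
        while True:
            t += rng.exponential(1.0 / rate)
            if t_max is not None and t > t_max:
                break
            n_prop += 1
            if n_prop > max_events:
                raise RuntimeError("SSWM run exceeded max_events without terminating")
            s, apply = walker.propose(rng)
            if s > 0 and rng.random() < kimura_fixation_probability(s, N):
                apply()
                fixed = True
                break
            # lost (or non-beneficial draw): state unchanged
            if s <= 0 and not _still_has_beneficial(walker):
                supply_exhausted = True
                break
        if not fixed:
            break
        x = walker.traits()
        F = malthusian_fitness(x, a)
        ts.append(t)
        x1s.append(x[0])
        x2s.append(x[1])
        Fs.append(F)
        terminated = F >= F_f

    return SswmRun(
        t=np.asarray(ts),
        x1=np.asarray(x1s),
        x2=np.asarray(x2s),
        F=np.asarray(Fs),
        terminated=terminated,
        supply_exhausted=supply_exhausted,
        n_proposed=n_prop,
        seed=seed,
    )


def _still_has_beneficial(walker) -> bool:
    """Guard against spinning forever when every available draw is s <= 0."""
    if isinstance(walker, _DiscordantWalker):
        return walker._any_beneficial()
    return True
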