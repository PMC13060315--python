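"""Closed-form and semi-analytical trait-trajectory predictions.

The mean trajectory of an adapting population obeys ``dx/dt = r(x)`` with a
regime-specific rate vector:

* SSWM on the pleiotropic map: ``r_i = -beta_i x_i`` with
  ``beta_i = N U delta^2 / a_i^2`` -- gradient ascent, exponential divergence
  of the performance ratio ``R = x2/x1``.
* SSWM on the modular map: ``r_i = alpha_i x_i^2`` with
  ``alpha_i = 4 N mu delta / a_i^2`` -- hyperbolic approach to the
  module-selection balance line ``x1/a1^2 = x2/a2^2`` (equal fitness
  benefits, ``s1 = s2``), balance ratio ``a2^2/a1^2``.
* Concurrent mutations with complete linkage: a piecewise clonal-interference
  approximation built on the Desai-Fisher rate of adaptation ``fDF``.
* Concurrent mutations with free recombination: the two modules adapt
  independently at rate ``fDF``; R converges slowly to ``a2/a1``.
* SSWM on the discordant map: latent-chromosome dynamics whose performance
  ratio converges to ``tan(theta1)`` or to a third root ``R3`` of a cubic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .gpfm import FitnessParams, malthusian_fitness, solve_latent

__all__ = [
    "RateModel",
    "BalancePrediction",
    "DiscordantEquilibria",
    "TheoryTrajectory",
    "pleiotropic_sswm_prediction",
    "modular_sswm_prediction",
    "desai_fisher_rate",
    "fdf_in_domain",
    "clonal_interference_rates",
    "free_recombination_prediction",
    "discordant_equilibria",
    "make_rate_model",
    "integrate_rate_model",
]

REGIMES = (
    "sswm-pleiotropic",
    "sswm-modular",
    "ci-linked",
    "free-recombination",
    "discordant-sswm",
)


@dataclass(frozen=True)
class RateModel:
    """Instantaneous rate field r(x) for one dynamical regime."""

    regime: str
    rate: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    def __call__(self, x) -> np.ndarray:
        return self.rate(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class BalancePrediction:
    """Equilibrium performance ratio(s) of a regime."""

    ratio: float
    description: str = ""


def pleiotropic_sswm_prediction(x0, t, N: int, U: float, delta: float, a: FitnessParams):
    """Gradient-ascent solution x_i(t) = x_i0 * exp(-beta_i t)."""
    t = np.asarray(t, dtype=float)
    b1 = N * U * delta**2 / a.a1**2
    b2 = N * U * delta**2 / a.a2**2
    return x0[0] * np.exp(-b1 * t), x0[1] * np.exp(-b2 * t)


def modular_sswm_prediction(x0, t, N: int, mu: float, delta: float, a: FitnessParams):
    """Hyperbolic SSWM solution x_i(t) = x_i0 / (1 - alpha_i x_i0 t) and the
    residual of the conserved hyperbola
    ``a1^2/x10 - a1^2/x1 - (a2^2/x20 - a2^2/x2)`` along it (identically 0)."""
    t = np.asarray(t, dtype=float)
    al1 = 4.0 * N * mu * delta / a.a1**2
    al2 = 4.0 * N * mu * delta / a.a2**2
    x1 = x0[0] / (1.0 - al1 * x0[0] * t)
    x2 = x0[1] / (1.0 - al2 * x0[1] * t)
    resid = (a.a1**2 / x0[0] - a.a1**2 / x1) - (a.a2**2 / x0[1] - a.a2**2 / x2)
    return x1, x2, resid


def desai_fisher_rate(s: float, Ub: float, N: float) -> float:
    """Desai-Fisher rate of fitness gain at beneficial mutation-selection
    balance: s^2 (2 log(Ns) - log(s/Ub)) / log^2(s/Ub)."""
    if s <= 0 or Ub <= 0 or N <= 0:
        raise ValueError("fDF requires positive s, Ub, N")
    ls = math.log(s / Ub)
    return s**2 * (2.0 * math.log(N * s) - ls) / ls**2


def fdf_in_domain(s: float, Ub: float, N: float) -> bool:
    """Concurrent-mutations validity: N*s > 1 and s/Ub > 1."""
    return N * s > 1.0 and s / Ub > 1.0


def clonal_interference_rates(
    x, N: int, mu: float, delta: float, a: FitnessParams, D: float = 100.0
) -> np.ndarray:
    """Piecewise trait-improvement rates in the linked concurrent regime.

    Each module's isolated rate ``v_i' = fDF(s_i, U_bi, N)`` is compared to
    the other's.  Below ``1/D`` the module stalls (rate 0); above ``D`` it
    adapts as in isolation; in between both modules share an effective
    selection coefficient ``s~ = (s1^2 + s2^2)/(s1 + s2)`` with rescaled
    supplies ``U~_bi`` solving ``fDF(s~, U~_bi, N) = v_i'``.
    """
    x = np.asarray(x, dtype=float)
    r = np.zeros(2)
    s = np.array([2.0 * delta * abs(x[i]) / (a.a1, a.a2)[i] ** 2 for i in (0, 1)])
    Ub = np.array([mu * abs(x[i]) / delta for i in (0, 1)])
    active = (x < 0) & (s > 0) & (Ub > 0)
    if not active.any():
        return r
    if active.sum() == 1:
        i = int(np.flatnonzero(active)[0])
        r[i] = (delta / s[i]) * desai_fisher_rate(s[i], Ub[i], N)
        return r
    v = np.array([desai_fisher_rate(s[i], Ub[i], N) for i in (0, 1)])
    for i in (0, 1):
        ratio = v[i] / v[1 - i]
        if ratio < 1.0 / D:
            r[i] = 0.0
        elif ratio > D:
            r[i] = (delta / s[i]) * v[i]
        else:
            st = (s[0] ** 2 + s[1] ** 2) / (s[0] + s[1])
            Ut = np.array([_solve_effective_supply(st, v[j], N) for j in (0, 1)])
            r[i] = (delta / s[i]) * (Ut[i] / Ut.sum()) * desai_fisher_rate(st, Ut.sum(), N)
    return r


def _solve_effective_supply(s_eff: float, target_v: float, N: int) -> float:
    """Solve fDF(s_eff, U, N) = target_v for U by monotone root-finding in log U."""

    def f(logU):
        return desai_fisher_rate(s_eff, math.exp(logU), N) - target_v

    lo, hi = math.log(1e-18), 0.0
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ArithmeticError(
            f"effective-supply root not bracketed: f({lo})={flo:.3g}, f({hi})={fhi:.3g}"
        )
    return math.exp(brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16))


def free_recombination_prediction(x0, t, N: int, mu: float, delta: float, a: FitnessParams):
    """Independent-module trajectories in the freely recombining concurrent
    regime, with the slow convergence of R to a2/a1.

    Returns ``(x1, x2, R, valid)`` where ``valid`` flags, per trait and time,
    the domain condition ``2 log(-x_i) + A_i > 0``.
    """
    t = np.asarray(t, dtype=float)
    out_x, valid = [], []
    for i, ai in enumerate((a.a1, a.a2)):
        g = free_recombination_gamma(mu, delta, ai)
        A = free_recombination_A(N, mu, ai)
        xi = -np.exp(-A / 2.0 + (math.log(-x0[i]) + A / 2.0) * np.exp(-2.0 * g * t))
        out_x.append(xi)
        valid.append(2.0 * np.log(-xi) + A > 0)
    R = out_x[1] / out_x[0]
    return out_x[0], out_x[1], R, np.array(valid)


def free_recombination_gamma(mu: float, delta: float, ai: float) -> float:
    """gamma_i = 2 delta^2 / (a_i^2 log^2(2 delta^2 / (mu a_i^2)))."""
    return 2.0 * delta**2 / (ai**2 * math.log(2.0 * delta**2 / (mu * ai**2)) ** 2)


def free_recombination_A(N: int, mu: float, ai: float) -> float:
    """A_i = log(2 N^2 mu / a_i^2)."""
    return math.log(2.0 * N**2 * mu / ai**2)


@dataclass(frozen=True)
class DiscordantEquilibria:
    """Roots of the cubic governing dR/dt on the discordant map."""

    R1: float  # tan(theta1), admissibility boundary and possible attractor
    R2: float  # tan(theta2), repelling boundary
    R3: float  # interior balance ratio
    theta1: float
    theta2: float
    a: FitnessParams

    def cubic(self, R: float) -> float:
        """P(R) up to the positive prefactor; sign(dR/dt) = sign(P(R))."""
        th1, th2 = self.theta1, self.theta2
        pref = (
            (math.sin(th2) - math.sin(th1))
            * math.cos(th1)
            * math.cos(th2)
            / math.sin(th2 - th1)
        )
        return pref * (R - self.R1) * (R - self.R2) * (R - self.R3)

    def rdot(self, R: float, x1: float, N: int, mu: float, delta: float) -> float:
        """dR/dt = -alpha2 * x1 * P(R) at an admissible ratio."""
        if not (self.R1 <= R <= self.R2):
            raise ValueError(f"ratio {R} outside admissible interval [{self.R1}, {self.R2}]")
        alpha2 = 4.0 * N * mu * delta / self.a.a2**2
        return -alpha2 * x1 * self.cubic(R)

    @property
    def attractor(self) -> float:
        """The ratio the walk converges to: R3 when it lies inside
        (R1, R2), otherwise R1."""
        if self.R1 < self.R3 < self.R2:
            return self.R3
        return self.R1


def discordant_equilibria(theta1: float, theta2: float, a: FitnessParams) -> DiscordantEquilibria:
    """Equilibrium performance ratios of the discordant-module SSWM dynamics."""
    if not theta1 < theta2:
        raise ValueError("require theta1 < theta2")
    R3 = (
        a.a2**2
        / a.a1**2
        * (math.cos(theta1) - math.cos(theta2))
        / (math.sin(theta2) - math.sin(theta1))
    )
    return DiscordantEquilibria(
        R1=math.tan(theta1),
        R2=math.tan(theta2) if theta2 < math.pi / 2 else math.inf,
        R3=R3,
        theta1=theta1,
        theta2=theta2,
        a=a,
    )


def make_rate_model(
    regime: str,
    N: int,
    mu: float,
    delta: float,
    a: FitnessParams,
    L: int | None = None,
    theta1: float | None = None,
    theta2: float | None = None,
    D: float = 100.0,
) -> RateModel:
    """Build the rate field r(x) for one of the five analytic regimes.

    ``L`` (loci per chromosome) is needed for the pleiotropic genome-wide
    rate ``U = 2 mu L``.  Rates are clamped to 0 once a trait reaches 0;
    theory trajectories never push traits positive.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")

    if regime == "sswm-pleiotropic":
        if L is None:
            raise ValueError("pleiotropic regime requires the chromosome length L")
        U = 2.0 * mu * L
        beta = np.array([N * U * delta**2 / a.a1**2, N * U * delta**2 / a.a2**2])

        def rate(x):
            return np.where(x < 0, -beta * x, 0.0)

    elif regime == "sswm-modular":
        alpha = np.array([4.0 * N * mu * delta / a.a1**2, 4.0 * N * mu * delta / a.a2**2])

        def rate(x):
            return np.where(x < 0, alpha * x**2, 0.0)

    elif regime == "ci-linked":

        def rate(x):
            return clonal_interference_rates(x, N, mu, delta, a, D=D)

    elif regime == "free-recombination":
        gam = np.array(
            [free_recombination_gamma(mu, delta, a.a1), free_recombination_gamma(mu, delta, a.a2)]
        )
        A = np.array([free_recombination_A(N, mu, a.a1), free_recombination_A(N, mu, a.a2)])

        def rate(x):
            with np.errstate(invalid="ignore"):
                r = np.where(x < 0, -gam * x * (2.0 * np.log(-x) + A), 0.0)
            return np.maximum(np.nan_to_num(r, nan=0.0), 0.0)

    else:  # discordant-sswm
        if theta1 is None or theta2 is None:
            raise ValueError("discordant regime requires chromosome angles")
        c = np.array([math.cos(theta1), math.cos(theta2)])
        sn = np.array([math.sin(theta1), math.sin(theta2)])

        def rate(x):
            try:
                y = np.array(solve_latent(x, theta1, theta2))
            except ValueError:
                return np.zeros(2)
            grad = x[0] * c / a.a1**2 + x[1] * sn / a.a2**2
            ydot = np.where(y < 0, 4.0 * N * mu * delta * y * grad, 0.0)
            ydot = np.maximum(ydot, 0.0)
            return np.array([ydot @ c, ydot @ sn])

    return RateModel(
        regime=regime,
        rate=rate,
        params=dict(N=N, mu=mu, delta=delta, a=a, L=L, theta1=theta1, theta2=theta2, D=D),
    )


@dataclass
class TheoryTrajectory:
    """Numerically integrated mean trajectory under a rate model."""

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    F: np.ndarray
    stalled: bool

    @property
    def ratio(self) -> np.ndarray:
        return self.x2 / self.x1


def integrate_rate_model(
    model: RateModel,
    x0,
    F_f: float,
    a: FitnessParams,
    rtol: float = 1e-8,
    n_points: int = 512,
    t_max: float | None = None,
) -> TheoryTrajectory:
    """Integrate dx/dt = r(x) until the fitness contour ``F_f`` is reached.

    Uses adaptive RK45 with a terminal event on the contour; when both rates
    vanish before the contour is reached the trajectory is returned with the
    ``stalled`` flag set.  The horizon is grown geometrically unless
    ``t_max`` is given.
    """
    x0 = np.asarray(x0, dtype=float)
    if not np.all(x0 < 0):
        raise ValueError("initial traits must both be negative")
    if malthusian_fitness(x0, a) >= F_f:
        return TheoryTrajectory(
            np.array([0.0]), x0[:1], x0[1:], np.array([malthusian_fitness(x0, a)]), False
        )

    def contour(t, x):
        return malthusian_fitness(x, a) - F_f

    contour.terminal = True
    contour.direction = 1

    horizons = [t_max] if t_max is not None else [10.0**k for k in range(3, 13)]
    sol = None
    for T in horizons:
        sol = solve_ivp(
            lambda t, x: model(x),
            (0.0, T),
            x0,
            rtol=rtol,
            atol=1e-12,
            dense_output=True,
            events=contour,
            method="RK45",
        )
        if sol.t_events[0].size:
            break
        r_end = model(sol.y[:, -1])
        if np.all(np.abs(r_end) < 1e-15):
            ts = np.linspace(0.0, sol.t[-1], n_points)
            xs = sol.sol(ts)
            return TheoryTrajectory(ts, xs[0], xs[1], malthusian_fitness(xs, a), stalled=True)
    t_end = sol.t_events[0][0] if sol.t_events[0].size else sol.t[-1]
    ts = np.linspace(0.0, t_end, n_points)
    xs = sol.sol(ts)
    xs = np.minimum(xs, 0.0)
    return TheoryTrajectory(
        ts, xs[0], xs[1], malthusian_fitness(xs, a), stalled=not sol.t_events[0].size
    )
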