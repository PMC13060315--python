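"""Genotype-phenotype-fitness maps (GPFMs) for two-trait adaptation.

The phenotype-fitness map is a concave quadratic (Fisher-geometric) function of
two trait values ``x = (x1, x2)``, each measuring the performance of one
functional module relative to its optimum at 0::

    F(x) = -(x1 / a1)**2 - (x2 / a2)**2

with Malthusian fitness ``F = log W``.  Smaller ``a_i`` means stronger
selection on module ``i``.  Four genotype-phenotype maps feed this fitness
function:

* **pleiotropic** -- an explicit binary genome of ``2L`` loci; locus ``l``
  carries a fixed angle ``theta_l ~ Uniform[0, 2pi)`` and flipping its allele
  displaces the phenotype by ``+-delta * (cos theta_l, sin theta_l)``, so
  every mutation moves both traits (universal pleiotropy).
* **modular** -- loci on chromosome ``i`` affect only trait ``i``; the trait
  lives on the lattice ``{0, -delta, ..., -L_i * delta}`` and is fully
  described by the count ``b_i`` of 1-alleles.
* **discordant** -- each chromosome ``k`` carries a latent state
  ``y_k = -delta * c_k`` and contributes to both traits in a fixed ratio set
  by a chromosome angle ``theta_k in [0, pi/2]``.
* **nested** -- each trait is itself a Fisher-geometric model in ``n_i``
  basal dimensions; mutational effects on ``x_i`` are approximately normal
  with mean ``-m**2/2`` and standard deviation ``m * sqrt(2|x_i|/n_i)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "FitnessParams",
    "GPFMSpec",
    "TraitState",
    "PleiotropicGenome",
    "ModularState",
    "DiscordantState",
    "NestedParams",
    "NestedEffect",
    "InadmissibleTargetError",
    "malthusian_fitness",
    "solve_initial_traits",
    "pleiotropic_traits",
    "selection_coefficient",
    "beneficial_set_pleiotropic",
    "modular_beneficial_supply",
    "discordant_traits",
    "solve_latent",
    "nested_effect_distribution",
    "draw_pleiotropic_angles",
    "greedy_pleiotropic_bits",
    "discretize_modular",
    "discordant_counts_from_traits",
]


class InadmissibleTargetError(ValueError):
    """Target trait vector cannot be represented by the chosen GPFM."""


@dataclass(frozen=True)
class FitnessParams:
    """Selection scales of the two modules (smaller = stronger selection)."""

    a1: float = 1.0
    a2: float = 0.5

    def __post_init__(self) -> None:
        if not (self.a1 > 0 and self.a2 > 0):
            raise ValueError("selection scales a1, a2 must be positive")


@dataclass(frozen=True)
class GPFMSpec:
    """Which genotype-phenotype map is in force, with its parameters.

    ``sigma`` is recorded for configuration provenance only; nothing
    consumes it.
    """

    model: str
    delta: float = 0.1
    L1: int = 200
    L2: int = 200
    theta1: float | None = None  # discordant chromosome angles
    theta2: float | None = None
    m: float | None = None  # nested basal step; defaults to sqrt(2*delta)
    n1: int = 10
    n2: int = 10
    angle_seed: int | None = None  # pleiotropic theta_l draw
    sigma: float | None = None

    _MODELS = ("pleiotropic", "modular", "discordant", "nested")

    def __post_init__(self) -> None:
        if self.model not in self._MODELS:
            raise ValueError(f"unknown GPFM model {self.model!r}; expected one of {self._MODELS}")
        if self.delta <= 0:
            raise ValueError("mutational step delta must be positive")
        if self.model == "discordant":
            if self.theta1 is None or self.theta2 is None:
                raise ValueError("discordant model requires theta1 and theta2")
            if not (0.0 <= self.theta1 < self.theta2 <= math.pi / 2):
                raise ValueError("require 0 <= theta1 < theta2 <= pi/2")

    @property
    def basal_step(self) -> float:
        """Nested-FGM step magnitude m, calibrated so that m**2/2 = delta."""
        return self.m if self.m is not None else math.sqrt(2.0 * self.delta)

    @property
    def genome_size(self) -> int:
        return self.L1 + self.L2


@dataclass(frozen=True)
class TraitState:
    """A point in trait space with its Malthusian fitness."""

    x1: float
    x2: float
    a: FitnessParams

    @property
    def F(self) -> float:
        return malthusian_fitness((self.x1, self.x2), self.a)

    @property
    def ratio(self) -> float:
        """Module performance ratio R = x2/x1."""
        return self.x2 / self.x1


def malthusian_fitness(x, a: FitnessParams):
    """Quadratic Malthusian fitness F(x) = -(|x1|/a1)^2 - (|x2|/a2)^2.

    Accepts scalars or arrays for the trait pair. F <= 0 with equality only
    at the optimum x = (0, 0).
    """
    x1, x2 = x
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("trait values must be finite")
    out = -((x1 / a.a1) ** 2) - (x2 / a.a2) ** 2
    if out.ndim == 0:
        return float(out)
    return out


def solve_initial_traits(F0: float, R0: float, a: FitnessParams) -> tuple[float, float]:
    """Trait pair with fitness ``F0 < 0`` and performance ratio ``x2/x1 = R0``.

    Both components are negative; closed form
    ``x1 = -sqrt(-F0 / (1/a1^2 + R0^2/a2^2))``, ``x2 = R0 * x1``.
    """
    if not F0 < 0:
        raise ValueError("target fitness F0 must be negative")
    if not R0 > 0:
        raise ValueError("performance ratio R0 must be positive")
    x1 = -math.sqrt(-F0 / (1.0 / a.a1**2 + R0**2 / a.a2**2))
    return x1, R0 * x1


# ---------------------------------------------------------------------------
# Pleiotropic map
# ---------------------------------------------------------------------------


@dataclass
class PleiotropicGenome:
    """Explicit binary genome whose loci carry fixed pleiotropic angles."""

    bits: np.ndarray
    angles: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.bits.shape != self.angles.shape:
            raise ValueError("bits and angles must have equal length")
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    def traits(self) -> tuple[float, float]:
        return pleiotropic_traits(self)


def pleiotropic_traits(genome: PleiotropicGenome) -> tuple[float, float]:
    """Additive traits x1 = delta * sum g_l cos(theta_l), x2 = ... sin(theta_l)."""
    g = genome.bits.astype(float)
    x1 = genome.delta * float(g @ np.cos(genome.angles))
    x2 = genome.delta * float(g @ np.sin(genome.angles))
    return x1, x2


def draw_pleiotropic_angles(n_loci: int, seed: int | None) -> np.ndarray:
    """Per-locus angles theta_l ~ Uniform[0, 2pi), fixed for a whole study."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 2.0 * math.pi, size=n_loci)


def greedy_pleiotropic_bits(angles: np.ndarray, delta: float, x0) -> np.ndarray:
    """Initial genome: sweep loci in index order, flipping 0 -> 1 whenever the
    flip reduces the Euclidean distance to the target ``x0``."""
    tx, ty = float(x0[0]), float(x0[1])
    bits = np.zeros(len(angles), dtype=np.uint8)
    x1 = x2 = 0.0
    for ell, th in enumerate(angles):
        nx1 = x1 + delta * math.cos(th)
        nx2 = x2 + delta * math.sin(th)
        if (nx1 - tx) ** 2 + (nx2 - ty) ** 2 < (x1 - tx) ** 2 + (x2 - ty) ** 2:
            bits[ell] = 1
            x1, x2 = nx1, nx2
    return bits


def selection_coefficient(x, effect, a: FitnessParams, mode: str = "exact") -> float:
    """Fitness effect of a mutation displacing the phenotype by ``effect``.

    ``exact`` is the literal fitness difference F(x + effect) - F(x); the
    ``linearized`` form drops the term quadratic in the displacement and is
    valid when the step is small compared to |x_i|.
    """
    x1, x2 = float(x[0]), float(x[1])
    e1, e2 = float(effect[0]), float(effect[1])
    if not all(map(math.isfinite, (x1, x2, e1, e2))):
        raise ValueError("trait values and effects must be finite")
    if mode == "exact":
        return malthusian_fitness((x1 + e1, x2 + e2), a) - malthusian_fitness((x1, x2), a)
    if mode == "linearized":
        return -2.0 * (x1 * e1 / a.a1**2 + x2 * e2 / a.a2**2)
    raise ValueError(f"unknown mode {mode!r}")


def beneficial_set_pleiotropic(genome: PleiotropicGenome, a: FitnessParams) -> np.ndarray:
    """Indices of loci whose flip has a strictly positive exact fitness effect."""
    _, idx = _pleiotropic_flip_effects(genome, a)
    return idx


def _pleiotropic_flip_effects(genome: PleiotropicGenome, a: FitnessParams):
    """Exact selection coefficients of flipping every locus, plus the
    beneficial subset. Vectorized over the genome."""
    x1, x2 = pleiotropic_traits(genome)
    sign = 1.0 - 2.0 * genome.bits.astype(float)  # 0 -> +1, 1 -> -1
    e1 = genome.delta * sign * np.cos(genome.angles)
    e2 = genome.delta * sign * np.sin(genome.angles)
    s = (
        -(((x1 + e1) / a.a1) ** 2)
        - ((x2 + e2) / a.a2) ** 2
        + (x1 / a.a1) ** 2
        + (x2 / a.a2) ** 2
    )
    return s, np.flatnonzero(s > 0.0)


# ---------------------------------------------------------------------------
# Modular map
# ---------------------------------------------------------------------------


@dataclass
class ModularState:
    """Lattice state of the concordant modular map: x_i = -delta * b_i."""

    b1: int
    b2: int
    L1: int
    L2: int
    delta: float

    def __post_init__(self) -> None:
        if not (0 <= self.b1 <= self.L1 and 0 <= self.b2 <= self.L2):
            raise ValueError("allele counts must satisfy 0 <= b_i <= L_i")

    def traits(self) -> tuple[float, float]:
        return -self.delta * self.b1, -self.delta * self.b2


def modular_beneficial_supply(state: ModularState) -> tuple[int, int]:
    """Counts of available beneficial mutations per module, b_i = |x_i|/delta."""
    return state.b1, state.b2


def discretize_modular(x0, delta: float, L1: int, L2: int) -> ModularState:
    """Round each target trait to the nearest delta-multiple, clamped to <= 0."""
    b = []
    for xi, L in zip(x0, (L1, L2)):
        bi = int(round(max(-float(xi), 0.0) / delta))
        b.append(min(bi, L))
    return ModularState(b[0], b[1], L1, L2, delta)


# ---------------------------------------------------------------------------
# Discordant-module map
# ---------------------------------------------------------------------------


@dataclass
class DiscordantState:
    """Latent chromosome counts; y_k = -delta * c_k feed both traits."""

    c1: int
    c2: int
    theta1: float
    theta2: float
    delta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta1 < self.theta2 <= math.pi / 2):
            raise ValueError("require 0 <= theta1 < theta2 <= pi/2")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("chromosome counts must be non-negative")

    def latent(self) -> tuple[float, float]:
        return -self.delta * self.c1, -self.delta * self.c2

    def traits(self) -> tuple[float, float]:
        return discordant_traits(self)


def discordant_traits(state: DiscordantState) -> tuple[float, float]:
    y1, y2 = state.latent()
    x1 = y1 * math.cos(state.theta1) + y2 * math.cos(state.theta2)
    x2 = y1 * math.sin(state.theta1) + y2 * math.sin(state.theta2)
    return x1, x2


def solve_latent(x0, theta1: float, theta2: float) -> tuple[float, float]:
    """Invert the 2x2 linear chromosome-to-trait map.

    Raises :class:`ValueError` when the system is singular (theta1 == theta2)
    and :class:`InadmissibleTargetError` when the solution would require a
    positive latent state (target outside the admissible cone).
    """
    det = math.sin(theta2 - theta1)
    if abs(det) < 1e-12:
        raise ValueError("singular chromosome geometry: theta1 == theta2")
    A = np.array(
        [
            [math.cos(theta1), math.cos(theta2)],
            [math.sin(theta1), math.sin(theta2)],
        ]
    )
    y = np.linalg.solve(A, np.asarray(x0, dtype=float))
    if np.any(y > 1e-9):
        raise InadmissibleTargetError(
            f"target {tuple(np.asarray(x0, float))} lies outside the cone "
            f"[tan(theta1), tan(theta2)]"
        )
    return float(y[0]), float(y[1])


def discordant_counts_from_traits(
    x0, theta1: float, theta2: float, delta: float, L1: int, L2: int, min_count: int = 1
) -> DiscordantState:
    """Map a target trait pair to lattice chromosome counts.

    Counts are rounded to the delta-lattice and clamped to at least
    ``min_count`` (both chromosomes must carry a deleterious allele) and at
    most ``L_k``.
    """
    y1, y2 = solve_latent(x0, theta1, theta2)
    c1 = min(max(int(round(-y1 / delta)), min_count), L1)
    c2 = min(max(int(round(-y2 / delta)), min_count), L2)
    return DiscordantState(c1, c2, theta1, theta2, delta)


# ---------------------------------------------------------------------------
# Nested Fisher's geometric model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NestedParams:
    """Basal-space step magnitude and dimensionalities of the nested FGM."""

    m: float
    n1: int = 10
    n2: int = 10

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("basal step m must be positive")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("basal dimensionalities must be >= 1")

    @classmethod
    def calibrated(cls, delta: float, n1: int = 10, n2: int = 10) -> "NestedParams":
        """Match the modular step size: m**2 / 2 = delta."""
        return cls(math.sqrt(2.0 * delta), n1, n2)

    def n_i(self, i: int) -> int:
        return self.n1 if i == 1 else self.n2


@dataclass(frozen=True)
class NestedEffect:
    """Normal law of a random mutation's effect on one functional trait."""

    mean: float
    sd: float
    p_beneficial: float


def nested_effect_distribution(xi: float, p: NestedParams, i: int = 1) -> NestedEffect:
    """Effect distribution of a mutation hitting module ``i`` at performance ``xi``.

    The effect on x_i is approximately Normal(-m^2/2, m*sqrt(2|x_i|/n_i));
    ``p_beneficial`` is the upper tail mass above zero. Degenerates at the
    optimum, hence ``xi < 0`` is required.
    """
    if not xi < 0:
        raise ValueError("nested effect distribution requires xi < 0")
    ni = p.n_i(i)
    mean = -p.m**2 / 2.0
    sd = p.m * math.sqrt(2.0 * abs(xi) / ni)
    return NestedEffect(mean, sd, float(norm.sf(0.0, loc=mean, scale=sd)))
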