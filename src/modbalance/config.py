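"""Structured run configuration (TOML) for simulations and predictions."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass

from .gpfm import FitnessParams, GPFMSpec, solve_initial_traits

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one replicate needs: GPFM, selection scales, population
    genetics, initial condition and termination."""

    spec: GPFMSpec
    a: FitnessParams
    N: int
    mu: float
    rho: float
    x0: tuple[float, float]
    F_f: float
    max_generations: int
    replicates: int
    seed: int

    def replicate_seed(self, r: int) -> int:
        """Replicate r runs with root seed + r (documented, reproducible)."""
        return self.seed + r


def load_config(path) -> RunConfig:
    """Parse a TOML run configuration.

    Sections: ``[gpfm]`` (model, delta, L1, L2, a1, a2, and the
    model-specific keys theta1/theta2, n1/n2/m, angle_seed, sigma),
    ``[population]`` (N, mu, rho) and ``[run]`` (either ``x0 = [x1, x2]`` or
    the contour pair ``F0``/``R0``; plus F_f, max_generations, replicates,
    seed).
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    g = raw.get("gpfm", {})
    a = FitnessParams(a1=float(g.pop("a1", 1.0)), a2=float(g.pop("a2", 0.5)))
    spec = GPFMSpec(
        model=g["model"],
        delta=float(g.get("delta", 0.1)),
        L1=int(g.get("L1", 200)),
        L2=int(g.get("L2", 200)),
        theta1=g.get("theta1"),
        theta2=g.get("theta2"),
        m=g.get("m"),
        n1=int(g.get("n1", 10)),
        n2=int(g.get("n2", 10)),
        angle_seed=g.get("angle_seed"),
        sigma=g.get("sigma"),
    )
    p = raw.get("population", {})
    run = raw.get("run", {})
    if "x0" in run:
        x0 = tuple(float(v) for v in run["x0"])
    else:
        x0 = solve_initial_traits(float(run.get("F0", -1.39)), float(run.get("R0", 1.25)), a)
    return RunConfig(
        spec=spec,
        a=a,
        N=int(p.get("N", 10_000)),
        mu=float(p.get("mu", 5e-9)),
        rho=float(p.get("rho", 0.0)),
        x0=x0,
        F_f=float(run.get("F_f", -0.01)),
        max_generations=int(run.get("max_generations", 2_000_000)),
        replicates=int(run.get("replicates", 250)),
        seed=int(run.get("seed", 0)),
    )
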