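# Methods

## The model

`modbalance` studies how the architecture of the genotype-phenotype-fitness
map (GPFM) shapes trait evolution during adaptation to a constant
environment. Fitness is a concave quadratic function of two module
performances `x = (x1, x2)`:

    F(x) = -(x1/a1)^2 - (x2/a2)^2,        W = exp(F)

with the optimum at the origin and `a_i` setting how strongly selection acts
on module `i` (smaller `a_i` = stronger selection; the standard configuration
is `a1 = 1`, `a2 = 1/2`). Four genotype-phenotype maps feed this function:

* **Pleiotropic** — an explicit genome of `2L` biallelic loci; locus `l`
  carries a fixed angle `theta_l ~ Uniform[0, 2*pi)` and flipping it
  displaces the phenotype by `+-delta*(cos theta_l, sin theta_l)`. Every
  mutation moves both traits (universal pleiotropy).
* **Modular** — chromosome `i` encodes trait `i` only; `x_i = -delta*b_i`
  where `b_i` counts 1-alleles, so traits live on a lattice and the supply of
  beneficial mutations in module `i` is exactly `b_i`.
* **Discordant-module** — each chromosome `k` has a latent state
  `y_k = -delta*c_k` contributing to both traits through a fixed angle
  `theta_k in [0, pi/2]`; variational and functional modules no longer
  coincide. The performance ratio `R = x2/x1` is confined to
  `[tan theta_1, tan theta_2]`.
* **Nested** — each trait is itself a Fisher-geometric model in `n_i` basal
  dimensions; mutational effects on `x_i` are approximately
  `Normal(-m^2/2, m*sqrt(2|x_i|/n_i))`. The calibration `m = sqrt(2*delta)`
  makes the mean effect magnitude equal to the modular step `delta`.

## Dynamics

Two engines generate trajectories:

* **SSWM / Gillespie** (`modbalance.sswm`): valid when `N*U_b << 1`. The
  population is a single point in trait space; waiting times to the next
  beneficial mutation are exponential with rate `N*U_b`, the drawn mutation
  fixes with Kimura's probability `(1-exp(-2s))/(1-exp(-2Ns))` (evaluated on
  the exact fitness difference), and fixation is instantaneous. Deleterious
  and neutral mutations never enter. On the discordant map the per-paper
  supply counts every 1→0 flip, but a drawn flip whose exact `s` is
  non-positive is treated as lost; if no available flip is beneficial the run
  stops with a `supply_exhausted` flag.
* **Wright-Fisher** (`modbalance.wrightfisher`): discrete generations with
  three phases in order — Poisson mutation (rates from the start-of-generation
  state), optional free inter-chromosome reassortment (`rho = 1`: random
  perfect pairing, swap of the second chromosome; odd `N` leaves one
  individual unpaired), and multinomial selection with probabilities
  proportional to `exp(F)`. Allele counts are clamped to `[0, L_k]`; events
  aimed at a saturated individual are discarded. Per-individual trait caches
  are revalidated against the genetic state every 100 generations.

Runs are initialized on a fitness contour (`F0 = -1.39` by default) at a
chosen performance ratio `R0` and stop when mean fitness reaches
`F_f = -0.01`, or at a configurable max-generations guard (the run is then
flagged `truncated`, never silently cut).

## Theory

`modbalance.theory` provides the mean-field rate models `dx/dt = r(x)`:

| regime | rate | consequence |
|---|---|---|
| SSWM, pleiotropic | `r_i = -beta_i x_i`, `beta_i = N U delta^2/a_i^2` | gradient ascent; `R` diverges exponentially |
| SSWM, modular | `r_i = alpha_i x_i^2`, `alpha_i = 4 N mu delta/a_i^2` | hyperbolic approach to the balance line `x1/a1^2 = x2/a2^2` |
| concurrent, linked | piecewise clonal-interference approximation on the Desai-Fisher rate `fDF(s, U_b, N) = s^2 (2 log(Ns) - log(s/U_b)) / log^2(s/U_b)` | stalling of the slower module, then balance |
| concurrent, free recombination | `r_i = -gamma_i x_i (2 log(-x_i) + A_i)` | slow convergence of `R` to `a2/a1` |
| SSWM, discordant | latent-chromosome rates | `R` converges to `tan theta_1` or to the cubic root `R3 = (a2^2/a1^2)(cos th1 - cos th2)/(sin th2 - sin th1)` |

The clonal-interference model compares each module's isolated rate
`v_i' = fDF(s_i, U_bi, N)`; below a ratio `1/D` the module stalls, above `D`
it adapts as in isolation, and in between both share an effective selection
coefficient `s~ = (s1^2+s2^2)/(s1+s2)` with rescaled supplies found by a
bracketed Brent root-find in `log U` (function tolerance ~1e-14; `fDF` is
monotone in `U_b`, so the bracket `[1e-18, 1]` is guaranteed when a solution
exists). `D = 100` by default; trajectories for `D` in `{30, 100, 300}`
agree within 5%, which the suite checks. The generic integrator uses
`scipy.solve_ivp` (RK45, rtol 1e-8) with a terminal event on the target
fitness contour and a stalled flag when both rates vanish first.

On the equal-fitness-benefits line `s1 = s2` the shared branch reduces
exactly to `r2/r1 = |x2|/|x1|`, making the line a fixed point of the ratio
dynamics (`dR/dt = 0` to 1e-8 in the tests — limited only by root-find
tolerance).

## Ensemble statistics and the balance estimator

Replicates are resampled onto a common uniform grid spanning
`[0, shortest replicate duration]` (501 points by default, i.e. a step of
1/500 of the shortest duration); SSWM event records are piecewise constant,
so last-value-carried-forward is exact. The mean-log-ratio series excludes,
per grid time, replicates where either trait exceeds `-delta` (unstable
logarithms near the optimum) and omits times with fewer than 40 contributors.
Because trait 2 is optimized faster, this exclusion preferentially drops
small-`R` replicates and biases the late-time estimate upward — a property
the suite verifies on constructed ensembles.

That bias makes the raw late-time log-ratio series a poor measure of the
balance ratio at the scaled-down ensemble sizes used here. The package
therefore estimates the convergence ratio from the ensemble-mean trait path:
`R(t) = <x2>/<x1>` is averaged over the final quartile of the grid truncated
where `<x1>` rises above `-(a1^2/a2^2)*delta = -4*delta`. Beyond that depth
a balanced trait 2 would sit within one mutational step of its optimum, so
the balance ratio is not representable on the trait lattice and near-optimum
end effects (which push `R` toward the lattice ratios 0.5 and 1) dominate.
The balance measurements use the deep-trait-1 contour start (`R0 = 0.16`,
or `R0 = 0.31` on the discordant map where `0.16` lies outside the
admissible cone) because the observable balanced stretch requires
`|x1| >= 4*delta`; from shallow starts the ensemble meets the exclusion
boundary before the balance locus is reachable.

## Validation scales and what the tests show

Simulation-based checks run at reduced problem sizes chosen so the whole
suite fits comfortably on one CPU: balance convergence at `N = 10^3` with
100 replicates per regime (the balance prediction is independent of `N`);
trajectory-theory comparisons at the full `N = 10^4`, `mu = 5e-9` SSWM
parameters with 100 replicates; Wright-Fisher gradient-ascent tracking at
`N = 500`, `2L = 200`.

Two quantitative caveats are intrinsic to the model, not artifacts of
scaling:

* The SSWM mean-field theory uses the weak-selection fixation probability
  `2s`, while the simulator uses Kimura's expression. At the standard
  parameters, selection coefficients reach `s ~ 0.2-0.45` early in a run,
  where the two differ by 20-35%. Trajectory-theory agreement within 10% is
  therefore checked on the contour starts whose comparison windows
  (`|x_i| >= 5*delta`) keep `s` moderate (`R0 = 0.625` and `2.5` for the
  modular map, `1.25` for the pleiotropic map); from the deepest printed
  start (`R0 = 0.16`, `|x1| ~ 1.1`) the accumulated deviation reaches
  ~10-23% and the closed forms should be treated as leading-order only.
* Cross-engine consistency (Wright-Fisher vs SSWM at matched parameters) is
  checked under strong symmetric selection with rare mutations
  (`delta = 0.3`, `a1 = a2`, `N*U_b ~ 3e-3`), where sweeps are much faster
  than waits. At the literal low-supply settings one might pick naively
  (e.g. `N = 100` with `N*U_b = 0.05`), the product of the mutation supply
  and the sweep duration is of order one and weakly selected deleterious
  mutations (`|Ns| ~ 9`) fix by drift, so the two engines legitimately
  diverge — the Wright-Fisher model is then simulating physics the SSWM
  abstraction excludes.

## The synthetic mutation-table generator

`spectrum.synth_mutation_table` emulates the schema of pooled
evolve-and-resequence mutation calls (population, gene, genomic position,
appearance time, PASS status, coding flag) with a two-epoch structure: before
the epoch boundary (17,500 generations of a 60,000-generation course) genic
mutations fall on a focal set of 10 genes with probability 0.6 and uniformly
otherwise; after it they are uniform over all 300 genes. Defaults produce
1,500 mutations across six populations with 5% non-PASS and 5% non-coding
rows so the quality filters are exercised. Appearance times are uniform
within each epoch. The generator does **not** emulate hitchhiking linkage,
per-population correlation structure, unequal gene lengths, or clustered
appearance times within sweeps — so passing pipeline tests demonstrate
correctness of the windowing/rarefaction/bootstrap machinery, not robustness
to those real-data features.

The sliding-window analysis pools populations, uses half-open windows
`[w, w + span)` anchored at generation 0 and shifted by 2,500 generations,
and generates only windows fully covered by the observed time span (a window
reaching past the last observation would have a systematically truncated
span). Windows with at least 20 mutations qualify; every qualifying window
is subsampled without replacement at the minimum qualifying count, 2,000
times, and the mean and 2.5/97.5 percentile interval of the inverse Simpson
index `1/D` are reported at the window midpoint. Multi-hit filtering keeps
genes with at least `k` independent mutations pooled across populations.

## Numerical choices and degenerate inputs

* Exact fitness differences (not linearized coefficients) drive both
  engines; the linearized forms exist for theory comparison, and the
  difference is exactly the dropped quadratic term, which the suite bounds.
* A `+delta` modular step from `x_i in (-delta/2, 0)` is deleterious under
  the exact form and is honored as such (no clamping of `s`).
* Nested-FGM effects are truncated so a trait never overshoots zero (the
  latent geometry cannot overshoot; the normal law is an approximation to
  it), and the effect distribution degenerates at `x_i = 0`, where the
  supply is treated as zero.
* Rates in all theory objects are clamped to zero once a trait reaches the
  optimum; theory trajectories never push traits positive.
* Replicate `r` of an ensemble uses root seed + `r`; the per-locus angle
  table of the pleiotropic map is drawn once from its own `angle_seed` and
  shared across replicates and initial conditions.

## Known limitations

Within-chromosome recombination, more than two functional modules,
non-quadratic phenotype-fitness maps, fluctuating environments and explicit
lineage tracking are out of scope. The clonal-interference approximation's
stalling threshold is a hard switch at `v_i'/v_j' = 1/D` (no smooth
interpolation), and the concurrent-regime theory assumes both modules stay
far enough from their optima that `2*log(-x_i) + A_i > 0`; breaches are
flagged per component rather than raised.
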