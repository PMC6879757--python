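# Methods

## The barrier process

The model is phenomenological: between two diverging prokaryotic lineages,
each locus is either still subject to gene conversion (in which case its
substitutions are repeatedly reverted toward the population consensus and
contribute nothing to long-term divergence) or has crossed the
recombination barrier and diverges freely at the substitution rate. No
attempt is made to model the molecular mechanism of the barrier; the object
of inference is the time course of its spread, `f(t)`, the recombining
fraction of the genome at time `t` since the common ancestor, governed by

    df/dt = -R(f, t) f,  f(0) = 1.

The hazard `R` defines the scenario. Closed forms are used throughout:

| scenario             | hazard            | f(t)                           | tau_inf                          |
|----------------------|-------------------|--------------------------------|----------------------------------|
| power_law            | λ tᵞ              | exp(-λ t^{γ+1}/(γ+1))          | Γ(1+1/β)/c^{1/β}, β=γ+1, c=λ/β   |
| linear               | λ₁ t              | exp(-λ₁ t²/2)                  | sqrt(π/(2λ₁))                    |
| linear_plus_constant | λ₀ + λ₁ t         | exp(-λ₀t - λ₁t²/2)             | sqrt(π/(2λ₁))·erfcx(λ₀/sqrt(2λ₁))|
| autocatalytic        | λ₀ - λ₁ f         | (1+e^{-φ})·σ(φ(1-ξt/τ_∞))      | parameter                        |

with σ the logistic function and, for the autocatalytic scenario, the
normalizer ξ = (1+e^{-φ}) ln(1+e^{φ})/φ chosen so that the observable
divergence `G(t) = t - τ(t)` satisfies G(0) = 0 and G'(0) = 0. The
(λ₀, λ₁) ↔ (τ_∞, φ) mapping follows from the Bernoulli transform of the
logistic ODE (`g = 1/f` obeys `dg/dt = λ₀ g - λ₁`): r = λ₁/λ₀ = σ(φ),
λ₀ = φξ/τ_∞. The linear-plus-constant delay uses the scaled complementary
error function `erfcx` to avoid overflow.

The printed form of the governing equation is sometimes written without the
minus sign; the convention adopted here (`df/dt = -R f`, hazard `R ≥ 0`) is
the only one consistent with a decaying recombining fraction and a
non-negative crossing density `P(t) = -df/dt`.

Units: all times and divergences are carried in substitutions-per-site
units (μ = 1 internally). The pairwise factor 2 (`Δ = 2μ(t - τ(t))`) is
applied only at the pairwise-divergence interface, never inside tree-height
maps.

### Numerical oracles and conditioning

The test suite checks every closed form against an independent numeric path
(stiff-capable `solve_ivp` at rtol 1e-9 for `f`; adaptive quadrature at
rtol 1e-9 for `τ`). Two conditioning limits are intrinsic, not
implementation artifacts:

* For sharp autocatalytic sigmoids the crossing time is exponentially
  sensitive to the initial condition (relative conditioning ~ e^φ), so no
  double-precision initial-value integration can track the transition
  beyond φ ≈ 8. The oracle therefore integrates the linear
  Bernoulli-transformed equation, and oracle comparisons are made at
  moderate sharpness (φ ≤ 5), the regime the analyses here operate in.
* Inversion of `G` is ill-conditioned wherever `G' = 1 - f` is at machine
  zero, i.e. for loci/heights still deep inside the fully recombining
  regime with large φ: the observed divergence simply carries no
  information about the true time there. Round-trip accuracy guarantees
  (1e-6 relative) apply for τ_∞ up to the tree depth and φ ≤ 15.

`G⁻¹` is computed by 70 bracketed bisection steps on
`[d, d + τ_∞]` (valid since `t - τ_∞ ≤ G(t) ≤ t`), vectorized over unique
query values.

## Gene-content model and decay curves

Gene turnover is a birth-death process with an effectively infinite gene
pool: genome-wide gain flux balances per-gene exponential loss (rate λ per
unit tree distance), giving a stationary genome of `x` families and an
expected `k`-genome intersection `I_k = x e^{-λ D_k}` where `D_k` is the
total branch length of the subtree spanning the `k` genomes (stem above
their MRCA excluded). The key property is independence of `k`: plots of
the normalized intersection against `D_k` collapse onto one curve whenever
branch lengths are proportional to the turnover clock. Recombination-driven
compression of terminal branches breaks the collapse in a
subset-size-dependent way, which is what the separation statistic detects.

Decay curves are built per subset size `k` (default k = 2..min(8, n-1));
all subsets are enumerated when at most `max_subsets_per_k` (default 2000)
exist, otherwise that many distinct subsets are drawn with a seeded
generator. Each per-`k` point cloud is smoothed with a least-squares cubic
B-spline with 5 knots placed at the minimum, 25th/50th/75th percentiles and
maximum of the x-values. The fit carries a very small curvature penalty,
`1e-6 · n · ∫ s''(x)² dx`: the penalty is exactly zero for straight lines
and perturbs well-supported fits at or below the 1e-3 level, but it
suppresses the unbounded ringing an unpenalized few-knot cubic develops
across gaps in the x-distribution — gaps that compressed trees create
systematically, because pair distances pile up near zero (terminal
compression) and at the tree depth. Fitting the full point multiset through
a design matrix also makes the procedure continuous under floating-point
jitter of branch lengths, where a strictly-increasing-x spline routine
would silently collapse tied abscissae and reweight the fit.

The separation between curves is the RMS vertical distance

    S² = Σ_pairs ∫ (f_k - f_k')² dx / Σ_pairs (b - a)

integrated over each pair's common x-interval; pairs with disjoint domains
are skipped from both sums. The effect of tree correction is summarized by
the relative change `(S_orig - S_corr)/max(S_orig, S_corr)` (defined as 0
when both are zero) and tested across groups by a sign-flip permutation
test on the median relative change: swapping a group's original/corrected
labels flips its sign; all `2^m` assignments are enumerated when feasible
(otherwise 10⁶ seeded draws, with the observed assignment included in the
reference set).

## Gene-content tree estimation

Branch lengths congruent with the turnover clock are estimated by maximum
likelihood under a two-state (presence/absence) continuous-time Markov
model on the fixed sequence-tree topology: gain rate `g`, loss rate `l`,
stationary root distribution π₁ = g/(g+l), and a discrete-gamma mixture
(4 equal-probability categories, category means from the incomplete-gamma
identity so they average exactly to 1) applying a single shared rate
multiplier to both g and l per family. Likelihoods come from Felsenstein
pruning, vectorized over the unique presence/absence patterns (at most 2ⁿ
for n genomes, typically far fewer than the family count). Because real
profiles never contain all-absent families, each family's likelihood is by
default conditioned on presence in at least one leaf.

Branch lengths are optimized coordinate-wise (bounded scalar minimization
per branch against cached above/below partial likelihoods, recomputed after
each update), cycling together with the gamma shape and the gain fraction
g/(g+l) until the log-likelihood improves by less than 1e-6. The chain's
time scale and rate scale are redundant, so g+l = 2 is fixed internally.

Reported branch lengths are in expected gain+loss events per *resident*
family: `t · (g π₀/π₁ + l)`. Normalizing per resident gene (rather than per
profile row) keeps the unit well defined in the infinite-pool limit — on
profiles generated by infinite-pool turnover the ML gain fraction correctly
runs toward zero with the pool size implicit, and the per-row event rate
degenerates while the per-resident rate converges to the simulation's true
value (loss + balancing gain flux = 2λ per unit distance). Simulation
checks recover branch lengths proportional to true times with slope within
10% of 1 at 2000 families.

## Fitting the delay

For matched trees (same topology, sequence branch lengths vs gene-content
branch lengths) all unordered leaf-pair distances are collected into a
scatter with sequence distance `x` as the independent variable. A pair that
split `t` ago has `x = 2G(t)` and expected gene-content distance `y = 2at`,
so the fitted model is `y = a · 2 G_θ⁻¹(x/2)`. The amplitude `a` is linear
and profiled out in closed form; the barrier parameters are optimized by
multi-start Nelder-Mead in O(1)-scaled coordinates (τ in units of the
largest observed distance, φ and the linear-plus-constant component delays
on log scales), with a coarse pass over the full start grid (τ/max x ∈
{0.1, 0.5, 1, 2} × φ ∈ {1, 5, 20}) and full optimization plus a final
polish from the best starts. Scenarios are compared by
`AIC = 2k + n(ln(2π RSS/n) + 1)` with `a` counted in `k`.

The 95% CI for τ_∞ profiles the RSS: bounds solve
`RSS(τ) = RSS* (1 + 1.96²/(n-1))`, re-optimizing the remaining parameters
at each fixed τ, with the threshold anchored to the profile's own value at
the optimum so the crossing stays bracketed even when RSS* is at numerical
zero. When the threshold is not crossed below 10× the largest observed
distance the upper bound is reported as unbounded — the regime where most
of the group is still bound by recombination. Pairwise points share tree
branches and are statistically dependent; as is conventional for this
analysis the dependence is ignored and `n` is the raw pair count, so the
nominal 95% CI is approximate (simulation coverage ≈ 90%, checked in the
acceptance script).

A heuristic power law `y = b xᵅ` is fitted alongside, by nonlinear least
squares on the original scale (not log-log) so its RSS and AIC are
comparable with the scenario fits; zero-x points are excluded with a
warning.

## Tree correction

Non-ultrametric trees have no single node height, so the correction uses
subtree-weighted parental heights accumulated from tips to root
(`H_i = b_i` and `w_i = b_i` at leaves; `H_i = Σw_c H_c/Σw_c + b_i`,
`w_i = Σw_c + b_i` at internal nodes — written for binary nodes, the same
weighted average extends to polytomies). Corrected heights are
`H̃_i = G⁻¹(H_i)`; corrected branch lengths are rebuilt tips-to-root with
the weights recomputed from corrected lengths at each step. On ultrametric
trees this is the exact inverse of the compression map, and
round-tripping recovers branch lengths to 1e-6 relative. On noisy
non-ultrametric input a corrected branch can come out negative; it is
clipped to zero with a logged warning. The forward (compression) map —
every node height mapped through `G` — is restricted to ultrametric input
and exists for simulation and testing; real non-ultrametric trees are only
ever corrected, not compressed.

## Relative rates and dispersion

Per family, gene distances are regressed through the origin on the group's
tree distances; the slope is the family's rate relative to the group
average, with uncentered R² < 0.9 discarding the rare families whose
relationship is non-linear (gene replacement). Slopes are then divided by
the family's mean slope across groups. The standard deviation of these
doubly-corrected rates within a group estimates the coefficient of
variation of the times over which the group's genes have been diverging:
genes cross the barrier at different times, and the longer the delay, the
more those crossing times disperse. Simulations with gene-specific crossing
times drawn from the crossing density reproduce the identity to ~10% in
aggregate; per-group ratios at 100 families fluctuate by ±15%, driven by
clipping at shallow splits and by the R² filter removing late-crossing
families.

With a single group the across-group family normalization is degenerate
(all relative rates equal 1); the dispersion analysis requires at least two
groups, and its scale invariance under rescaling of gene distances is exact
when the rescaling is uniform across groups.

## Synthetic data

The generators produce every input the pipeline consumes, under known
ground truth, fully determined by one master seed (sub-seeds via
`SeedSequence.spawn`):

* **Trees**: pure-birth (Yule) with the requested number of leaves,
  rescaled so every root-to-tip path equals the target depth. Yule is the
  simplest seeded choice for a clonal ultrametric phylogeny; none of the
  analyses depend on the tree prior.
* **Profiles**: the root genome holds the stationary family count; along a
  branch of length `d` each family survives with probability `e^{-λd}` and
  `Poisson(x(1-e^{-λd}))` new, unique families are gained (computed by
  thinning: only gains that survive to the branch end are generated, since
  within-branch gain-and-loss is unobservable). Lost families are never
  regained on a lineage. An optional two-class mode (slow/fast λ) tags
  families for masking, mirroring MGE/ORFan-style robustness checks.
* **Compressed sequence trees**: node heights mapped through `G` — the
  observation model for a sequence tree under the barrier process.
* **Per-family distance matrices**: each family draws one barrier-crossing
  time `u` from the crossing density (right-censored at the tree depth) and
  a mean-1 gamma rate multiplier; a pair with split height `t` gets
  distance `2m·max(0, t-u)`. Crossing times are drawn once per family, not
  per pair: the barrier is a property of a locus between diverging
  populations, and pairs on a clonal tree inherit it clipped at their
  split.

What the generator does *not* emulate: within-population polymorphism and
equilibrium diversity (assumed negligible; with appreciable equilibrium
diversity the fitted delays become lower bounds), alignment and
distance-estimation noise in the per-family matrices, rate variation along
sequences, gene transfer between the sampled lineages (the infinite-pool
assumption), and short-lived neutral/deleterious gene dynamics beyond what
the loss-rate classes capture. Passing tests therefore demonstrate the
internal consistency and statistical behavior of the estimators under the
model's own assumptions, not robustness to real-data artifacts.

## Problem sizes and defaults

Study conditions used in tests and the acceptance script: 16-genome groups
at depth 0.2 substitutions/site with x = 2000 families and λ = 5 for
gene-content analyses; 20-leaf trees at depth 0.3 with τ_∞ = 0.1, φ = 5,
a = 20 and 5% multiplicative noise for fit-recovery studies; 8 groups of
20 genomes × 100 families for the dispersion identity; decay curves with
k = 2..5 and at most 2000 subsets per k. These sizes give stable statistics
(replicate-to-replicate slope SD ≈ 0.15 on λ = 5; dispersion/CV mean ratio
within 10%) while keeping any single analysis in the seconds-to-a-minute
range.

Other defaults: ODE/quadrature tolerances 1e-9; fit convergence 1e-10-level
on scaled coordinates with ≥ 5 (up to 12) starts; branch-length optimizer
tolerance 1e-6 log-likelihood units, branches bounded by 50 chain-time
units; permutation default 10⁶ draws with exhaustive enumeration whenever
2^m ≤ 10⁶; subset-sampling cap 2000 per k; spline curvature penalty 1e-6
per point. Decay-slope regressions in tests are restricted to
D ≤ ln(20)/λ — a covariate restriction, avoiding the selection bias of
filtering on the observed intersection — because beyond it the expected
intersection falls under ~5% of a genome and the log scale is dominated by
count noise and zero-truncation.

## Known limitations

* Correction cannot recover time that left no trace: where `G` is flat to
  machine precision (deep recombining regime, sharp sigmoids), corrected
  heights are lower bounds with large uncertainty.
* The CI formula inherits the pairwise-dependence approximation; coverage
  is approximate by construction.
* The gain/loss estimator fixes the topology and does not map events to
  branches per family; it replaces an external phylogenomic tool
  functionally (proportionality of branch lengths to time), without
  aiming for numerical agreement with any particular implementation.
* `compress_tree` requires ultrametric input by design; correction handles
  non-ultrametric trees via the weighted-average machinery but may clip
  negative branches on noisy input.
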