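# recbarrier

Tools for quantifying the delay of the sequence-based molecular clock
relative to the gene-turnover clock in closely related prokaryotic genomes,
and for attributing that delay to the gradual spread of barriers to
homologous recombination.

## The problem

Groups of closely related bacteria and archaea can be dated with two clocks:
the familiar molecular clock (nucleotide substitutions per site in core
genes) and a gene-turnover clock (gene gains and losses per family, read off
a phyletic presence/absence profile). In many groups the two disagree at
short times: genes are gained and lost briskly from the very start, but
sequence divergence only begins to accumulate after a transient. The
phenomenological explanation modeled here is gene conversion: while a locus
can still recombine with the rest of the population, its substitutions are
repeatedly erased, so it contributes nothing to long-term divergence until
it crosses the *recombination barrier*.

Writing `f(t)` for the fraction of the genome still recombining at time `t`
after the common ancestor, with hazard `R`:

```
df/dt = -R(f, t) f,   f(0) = 1
```

the pairwise sequence divergence of two genomes grows as

```
Δ(t) = 2μ (t - τ(t)),      τ(t) = ∫₀ᵗ f(u) du
```

so the molecular clock runs late by a concave, saturating delay `τ(t)` with
long-time limit `τ_∞` — the amount of divergence (substitutions per site)
erased by recombination. Four hazard scenarios are supported: constant,
power-law in time (`λ tᵞ`), linear plus constant (`λ₀ + λ₁ t`), and
*autocatalytic* (`λ₀ - λ₁ f`), in which barrier spread accelerates as more
of the genome becomes isolated and `f(t)` declines sigmoidally.

The package provides:

* **`barrier_model`** — closed forms and numeric oracles for `f`, the
  crossing density `P(t) = -df/dt`, the delay `τ(t)`, and the observable
  divergence map `G(t) = t - τ(t)` with its inverse.
* **`gainloss_tree`** — maximum-likelihood gene-content tree branch lengths
  from a phyletic profile (two-state gain/loss Markov model, discrete-gamma
  rate variation, ascertainment correction), on the fixed sequence-tree
  topology.
* **`clock_fit`** — fits `y = a·G⁻¹(x)` to the scatter of matched pairwise
  distances (sequence tree vs gene-content tree), compares scenarios by
  `AIC = 2k + n(ln(2π RSS/n) + 1)`, and profiles the RSS for a 95% CI on
  `τ_∞` (reported as unbounded above when the group is still mostly bound by
  recombination).
* **`tree_correction`** — undoes the compression of terminal branches:
  weighted-average parental heights are mapped through `G⁻¹` and branch
  lengths rebuilt from tips to root.
* **`gene_content`** — gene-content decay curves: the fraction of families
  shared by `k` genomes against the total subtree length `D_k`, which under
  neutral turnover collapses onto `x·e^(-λ D_k)` for every `k`; spline
  smoothing, the RMS curve-separation statistic `S`, and a sign-flip
  permutation test for the effect of tree correction.
* **`relative_rates`** — per-family relative evolutionary rates
  (zero-intercept regression against tree distances, R² ≥ 0.9 filter,
  family- and group-wise normalization) and their dispersion, which under
  the barrier model equals the coefficient of variation of per-gene
  divergence times.
* **`synthetic_data`** — fully seeded generators for every input: Yule
  trees, infinite-pool gain/loss profiles, barrier-compressed sequence
  trees, and per-family distance matrices with gene-specific
  barrier-crossing times.

## Worked example

Simulate a 16-genome group (tree depth 0.2 substitutions/site, ~2000 gene
families with per-gene loss rate λ = 5, autocatalytic barrier with
τ_∞ = 0.06 and sharpness φ = 5), then run the full pipeline — gene-content
tree estimation, scenario fitting, tree correction, decay-curve separation:

```sh
recbarrier simulate --seed 42 --out demo/
recbarrier run --config run.yaml     # seq_tree: demo/seq_tree.nwk, profile: demo/profile.tsv
```

or in Python:

```python
from recbarrier.synthetic_data import SimulationConfig, simulate_bundle, write_bundle
from recbarrier.cli_io import RunConfig, run_pipeline

write_bundle(simulate_bundle(SimulationConfig(seed=42)), "demo")
summary = run_pipeline(RunConfig(seq_tree="demo/seq_tree.nwk",
                                 profile="demo/profile.tsv",
                                 out_dir="demo_run", seed=1))
```

The summary for this seed reads:

```
best_scenario: autocatalytic
tau_inf: 0.0580   (95% CI 0.0557 – 0.0604; simulated truth 0.06)
phi:     5.10     (truth 5)
a:       10.02    (gene-turnover events per substitution; 2λ = 10 expected)
separation: S_original 0.0399 -> S_corrected 0.0083  (relative change +0.79)

scenario ranking        ΔAIC
autocatalytic           0.00
linear                171.73
linear_plus_constant  173.89
power-law heuristic   350.79
constant              357.30
```

Read: the sequence tree's terminal branches under-report ~0.058
substitutions/site of divergence erased by recombination; AIC decisively
prefers the autocatalytic barrier-spread scenario; and correcting the tree
with the fitted parameters collapses the per-`k` gene-content decay curves
(separation drops by 79%), as the turnover model predicts for a tree whose
branch lengths are proportional to true time.

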