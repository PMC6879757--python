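"""Synthetic genome-evolution data with known ground truth.

Generates every input the analysis pipeline consumes, under the same
statistical assumptions the analysis makes:

* a clonal ultrametric phylogeny (pure-birth/Yule, rescaled to a target
  root-to-tip depth in substitutions per site);
* a phyletic profile simulated by infinite-pool gene gain and per-gene
  exponential loss along the tree (optionally with slow and fast rate
  classes), so the expected k-genome intersection decays as
  ``x exp(-lambda D_k)``;
* an "observed" sequence tree obtained by compressing the true tree's node
  heights through the barrier model's observable-divergence map (terminal
  branches shrink by the clock delay, deep branches are nearly preserved);
* per-family pairwise sequence distance matrices in which each family draws
  its own barrier-crossing time from the crossing density and a rate
  multiplier, so a pair that split ``t`` ago accumulates
  ``2 m max(0, t - u)`` substitutions in that family — the source of rate
  over-dispersion in strongly delayed groups.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .barrier_model import BarrierParams, sample_crossing_times
from .gene_content import GeneContentParams, PhyleticProfile
from .tree_correction import compress_tree, node_heights

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_gene_content",
    "simulate_sequence_tree",
    "simulate_gene_divergences",
    "simulate_bundle",
    "write_bundle",
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic group of genomes.

    Defaults mirror a typical well-sampled group of closely related
    prokaryotes: 16 genomes, tree depth 0.2 substitutions/site, ~2000 gene
    families with per-gene loss rate lambda = 5 per unit tree distance, and
    an autocatalytic barrier with a delay of 30% of the tree depth and
    sharpness phi = 5.
    """

    n_genomes: int = 16
    depth: float = 0.2
    gene_content: GeneContentParams = field(
        default_factory=lambda: GeneContentParams(x=2000.0, lam=5.0))
    barrier: BarrierParams = field(
        default_factory=lambda: BarrierParams.autocatalytic(tau_inf=0.06, phi=5.0))
    n_families_rates: int = 100
    rate_cv: float = 0.0  # CV of the per-family substitution-rate multiplier
    turnover_per_substitution: float = 20.0  # gene-content events per subs/site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 3:
            raise ValueError("need at least 3 genomes")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


def simulate_tree(n_genomes: int, depth: float, seed: int) -> dendropy.Tree:
    """Seeded pure-birth (Yule) tree with ``n_genomes`` leaves, rescaled so
    every root-to-tip path equals ``depth``."""
    if n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    rng = np.random.default_rng(seed)
    # forward simulation: split a random active lineage at each event
    birth_times = [0.0, 0.0]  # start at the root split: two lineages at t=0
    t = 0.0
    events = []  # (time, lineage index to split)
    k = 2
    while k < n_genomes:
        t += rng.exponential(1.0 / k)
        events.append((t, int(rng.integers(k))))
        k += 1
    t_end = t + rng.exponential(1.0 / n_genomes)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    children = [root.new_child(), root.new_child()]
    birth = {id(c): 0.0 for c in children}
    for when, idx in events:
        node = children[idx]
        c1, c2 = node.new_child(), node.new_child()
        node.edge.length = when - birth[id(node)]
        birth[id(c1)] = birth[id(c2)] = when
        children[idx] = c1
        children.append(c2)
    for c in children:
        c.edge.length = t_end - birth[id(c)]
    for i, c in enumerate(children):
        c.taxon = taxa.new_taxon(label=f"g{i + 1}")
    # rescale to the requested depth
    scale = depth / t_end
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    tree.is_rooted = True
    return tree


def simulate_gene_content(tree: dendropy.Tree, params: GeneContentParams,
                          seed: int) -> PhyleticProfile:
    """Infinite-pool gain / per-gene loss simulation along the tree.

    The root genome holds the stationary number of families per class; on a
    branch of tree-distance ``d`` each present family survives with
    probability ``exp(-lam d)`` and ``Poisson(x (1 - exp(-lam d)))`` new
    families (each unique, surviving to the branch end) are gained, which
    keeps the genome size stationary in expectation.  Families gained and
    lost within a single branch are never observable and are not generated.
    Lost families are never regained on a lineage (infinite pool).
    """
    rng = np.random.default_rng(seed)
    classes = params.classes()
    next_id = [0]
    family_class: dict = {}

    def new_families(ci: int, count: int) -> list:
        start = next_id[0]
        next_id[0] += count
        ids = list(range(start, start + count))
        for fid in ids:
            family_class[fid] = ci
        return ids

    root_sets = []
    for ci, (x, lam) in enumerate(classes):
        root_sets.append(new_families(ci, int(round(x))))
    leaf_content: dict = {}

    def walk(node, content):
        for child in node.child_nodes():
            d = 0.0 if child.edge.length is None else float(child.edge.length)
            child_content = []
            for ci, (x, lam) in enumerate(classes):
                present = content[ci]
                keep_p = np.exp(-lam * d)
                keep = np.asarray(present)[rng.uniform(size=len(present)) < keep_p] \
                    if len(present) else np.array([], dtype=int)
                n_new = rng.poisson(x * (1.0 - keep_p))
                child_content.append(list(keep) + new_families(ci, int(n_new)))
            if child.is_leaf():
                leaf_content[child.taxon.label] = [set(c) for c in child_content]
            else:
                walk(child, child_content)

    walk(tree.seed_node, root_sets)
    genomes = sorted(leaf_content)
    observed = sorted(set().union(*[set().union(*leaf_content[g]) for g in genomes]))
    fam_index = {fid: i for i, fid in enumerate(observed)}
    matrix = np.zeros((len(observed), len(genomes)), dtype=np.int8)
    for j, g in enumerate(genomes):
        for cset in leaf_content[g]:
            for fid in cset:
                matrix[fam_index[fid], j] = 1
    flags = None
    if len(classes) > 1:
        names = ("slow", "fast")
        flags = [names[family_class[fid]] for fid in observed]
    return PhyleticProfile(matrix, [f"fam{fid:06d}" for fid in observed], genomes, flags)


def simulate_sequence_tree(tree: dendropy.Tree, barrier: BarrierParams) -> dendropy.Tree:
    """Observed sequence-based tree: the true tree with node heights pushed
    through the barrier model's forward divergence map."""
    return compress_tree(tree, barrier)


def simulate_gene_divergences(tree: dendropy.Tree, barrier: BarrierParams,
                              n_families: int, seed: int,
                              rate_cv: float = 0.0) -> tuple[list, np.ndarray, np.ndarray]:
    """Per-family pairwise distance matrices under gene-specific barrier crossing.

    Each family draws one barrier-crossing time ``u`` (shared by all pairs;
    censored at the tree depth) and a mean-1 gamma rate multiplier ``m`` with
    coefficient of variation ``rate_cv`` (0 means all multipliers are 1).
    For a leaf pair whose split height is ``t`` the family's distance is
    ``2 m max(0, t - u)``.

    Returns ``(matrices, crossing_times, multipliers)`` where ``matrices`` is
    a list of labeled DataFrames.
    """
    rng = np.random.default_rng(seed)
    heights = node_heights(tree)
    depth = max(heights.values())
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    # pairwise split heights
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(leaves)
    split = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            split[i, j] = split[j, i] = 0.5 * pdm.distance(taxa[leaves[i]], taxa[leaves[j]])
    u = sample_crossing_times(barrier, n_families, rng, t_max=depth)
    if rate_cv > 0:
        shape = 1.0 / rate_cv**2
        m = rng.gamma(shape, 1.0 / shape, size=n_families)
    else:
        m = np.ones(n_families)
    matrices = []
    for fam in range(n_families):
        d = 2.0 * m[fam] * np.maximum(0.0, split - u[fam])
        np.fill_diagonal(d, 0.0)
        matrices.append(pd.DataFrame(d, index=leaves, columns=leaves))
    return matrices, u, m


def simulate_bundle(config: SimulationConfig) -> dict:
    """Run all generators with sub-seeds derived from the master seed.

    Returns a dict with the true tree, compressed sequence tree, phyletic
    profile, gene-content "true clock" tree (branch lengths = true time x
    turnover rate), per-family distance matrices, crossing times, rate
    multipliers and the ground-truth parameters.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    tree = simulate_tree(config.n_genomes, config.depth, seeds[0])
    profile = simulate_gene_content(tree, config.gene_content, seeds[1])
    seq_tree = simulate_sequence_tree(tree, config.barrier)
    gc_tree = tree.clone(depth=1)
    for e in gc_tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= config.turnover_per_substitution
    matrices, u, m = simulate_gene_divergences(
        tree, config.barrier, config.n_families_rates, seeds[2], config.rate_cv)
    return {
        "config": config,
        "true_tree": tree,
        "seq_tree": seq_tree,
        "gc_tree": gc_tree,
        "profile": profile,
        "distance_matrices": matrices,
        "crossing_times": u,
        "rate_multipliers": m,
    }


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Serialize a simulated bundle: Newick trees, TSV profile and matrices,
    and a truth JSON with all ground-truth parameters."""
    from . import cli_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cli_io.write_newick(bundle["true_tree"], out / "true_tree.nwk")
    cli_io.write_newick(bundle["seq_tree"], out / "seq_tree.nwk")
    cli_io.write_newick(bundle["gc_tree"], out / "gc_tree.nwk")
    cli_io.write_profile(bundle["profile"], out / "profile.tsv")
    mat_dir = out / "families"
    mat_dir.mkdir(exist_ok=True)
    for i, df in enumerate(bundle["distance_matrices"]):
        cli_io.write_distance_matrix(df, mat_dir / f"fam{i:04d}.tsv")
    cfg = bundle["config"]
    truth = {
        "n_genomes": cfg.n_genomes,
        "depth": cfg.depth,
        "barrier": cfg.barrier.to_dict(),
        "gene_content": {"x": cfg.gene_content.x, "lam": cfg.gene_content.lam,
                         "two_class": cfg.gene_content.two_class},
        "turnover_per_substitution": cfg.turnover_per_substitution,
        "rate_cv": cfg.rate_cv,
        "seed": cfg.seed,
        "crossing_times": [float(v) for v in bundle["crossing_times"]],
        "rate_multipliers": [float(v) for v in bundle["rate_multipliers"]],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
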