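"""Maximum-likelihood gene-content tree branch lengths from phyletic profiles.

Each gene family's presence/absence pattern across genomes is modeled as a
two-state continuous-time Markov chain on a fixed rooted topology, with gain
rate ``g`` (absent -> present) and loss rate ``l`` (present -> absent).
Transition probabilities over a branch of length ``t`` at family rate ``r``
follow the standard closed form::

    P(0 -> 1) = pi1 (1 - exp(-(g + l) r t))
    P(1 -> 0) = pi0 (1 - exp(-(g + l) r t))

with the stationary distribution ``pi1 = g / (g + l)`` at the root.
Rate heterogeneity across families is handled by a discrete-gamma mixture
(default 4 equal-probability categories with mean-1 rates; a single shared
multiplier scales gain and loss together).  Because real profiles never
contain families absent from every genome, each family's likelihood is by
default conditioned on the family being present in at least one leaf
(ascertainment correction).

Branch lengths are optimized one at a time by bounded scalar minimization
over cycles of the whole tree (optionally together with the gamma shape and
the gain fraction), with the topology fixed, and are reported in
expected-events units: ``t (g pi0 + l pi1)`` gain+loss events per family per
branch.  The chain time scale and the rate scale are redundant, so ``g + l =
2`` is fixed internally; the event-unit lengths are invariant to that
choice.

Likelihoods are computed by Felsenstein pruning, vectorized across families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import dendropy
import numpy as np
from scipy import optimize, special, stats

from .gene_content import PhyleticProfile

__all__ = [
    "GainLossModel",
    "BranchLengthEstimate",
    "discrete_gamma_rates",
    "profile_loglik",
    "optimize_branch_lengths",
]

_MAX_BRANCH = 50.0


def _gamma_rates_cached(shape: float, n_categories: int) -> np.ndarray:
    key = (shape, n_categories)
    hit = _GAMMA_CACHE.get(key)
    if hit is None:
        hit = discrete_gamma_rates(shape, n_categories)
        if len(_GAMMA_CACHE) > 4096:
            _GAMMA_CACHE.clear()
        _GAMMA_CACHE[key] = hit
    return hit


_GAMMA_CACHE: dict = {}


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability discrete-gamma categories (mean 1).

    Category boundaries at the quantiles i/K of Gamma(shape, 1/shape); each
    category's rate is the conditional mean within its bin, computed from the
    incomplete-gamma identity so the category means average exactly to 1.
    """
    if n_categories < 1:
        raise ValueError("need at least one category")
    if n_categories == 1:
        return np.ones(1)
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    probs = np.arange(1, n_categories) / n_categories
    cuts = stats.gamma.ppf(probs, a=shape, scale=1.0 / shape)
    # E[X | bin] = (F_{a+1}(upper) - F_{a+1}(lower)) * K  for mean-1 gamma
    upper = np.concatenate([cuts, [np.inf]])
    lower = np.concatenate([[0.0], cuts])
    f = special.gammainc(shape + 1.0, shape * upper) - special.gammainc(shape + 1.0, shape * lower)
    return f * n_categories


@dataclass(frozen=True)
class GainLossModel:
    """Two-state gain/loss model with discrete-gamma rate variation."""

    gain_rate: float = 1.0
    loss_rate: float = 1.0
    n_categories: int = 4
    gamma_shape: float = 1.0
    ascertainment: bool = True

    def __post_init__(self) -> None:
        if self.gain_rate <= 0 or self.loss_rate <= 0:
            raise ValueError("gain and loss rates must be positive")
        if self.n_categories >= 2 and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def pi(self) -> np.ndarray:
        s = self.gain_rate + self.loss_rate
        return np.array([self.loss_rate / s, self.gain_rate / s])

    @property
    def event_rate(self) -> float:
        """Expected gain+loss events per *resident* family per unit branch time.

        The genome-wide event flux at stationarity is ``N (g pi0 + l pi1)``
        over ``N pi1`` resident families, i.e. ``g pi0/pi1 + l`` per gene
        actually carried by a genome.  Normalizing per resident gene keeps the
        unit well-defined in the infinite-pool limit (``g -> 0`` with a huge
        family pool), which is the regime real phyletic profiles put the
        model in.
        """
        pi0, pi1 = self.pi
        return self.gain_rate * pi0 / pi1 + self.loss_rate

    def category_rates(self) -> np.ndarray:
        return _gamma_rates_cached(self.gamma_shape, self.n_categories)

    def transition_matrices(self, t: float) -> np.ndarray:
        """P[c, i, j] for each gamma category c over a branch of length t."""
        rates = self.category_rates()
        s = self.gain_rate + self.loss_rate
        pi0, pi1 = self.pi
        decay = np.exp(-s * rates * t)  # (C,)
        P = np.empty((rates.size, 2, 2))
        P[:, 0, 1] = pi1 * (1.0 - decay)
        P[:, 0, 0] = 1.0 - P[:, 0, 1]
        P[:, 1, 0] = pi0 * (1.0 - decay)
        P[:, 1, 1] = 1.0 - P[:, 1, 0]
        return P


@dataclass
class BranchLengthEstimate:
    """Optimized gene-content tree plus fit diagnostics."""

    tree: dendropy.Tree  # branch lengths in expected gain+loss events per family
    log_likelihood: float
    model: GainLossModel
    converged: bool
    n_cycles: int
    chain_lengths: dict = field(default_factory=dict)  # leaf/edge label -> raw chain time


class _PruningWorkspace:
    """Tree flattened to arrays for vectorized pruning over families."""

    def __init__(self, tree: dendropy.Tree, profile: PhyleticProfile):
        leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if leaf_labels != set(profile.genome_ids):
            raise ValueError("profile genomes and tree leaves do not match")
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.is_leaf = np.array([n.is_leaf() for n in self.nodes])
        self.parent = np.array([
            -1 if n.parent_node is None else self.index[id(n.parent_node)]
            for n in self.nodes])
        self.lengths = np.array([
            0.0 if n.edge.length is None else float(n.edge.length)
            for n in self.nodes])
        # collapse families to unique presence/absence patterns with counts:
        # the likelihood only depends on the pattern spectrum, and for n
        # genomes there are at most 2^n patterns regardless of family count
        leaf_order = [n.taxon.label for i, n in enumerate(self.nodes) if self.is_leaf[i]]
        full = profile.columns(leaf_order)  # (families, leaves) in postorder leaf order
        patterns, counts = np.unique(full, axis=0, return_counts=True)
        self.pattern_counts = counts.astype(float)
        self.leaf_state = {}
        col = 0
        for i, n in enumerate(self.nodes):
            if self.is_leaf[i]:
                self.leaf_state[i] = patterns[:, col]
                col += 1
        self.n_families = profile.n_families
        self.n_patterns = patterns.shape[0]
        self.root = len(self.nodes) - 1
        self._leaf_partials: dict = {}

    def _leaf_below(self, i: int, C: int) -> np.ndarray:
        key = (i, C)
        hit = self._leaf_partials.get(key)
        if hit is None:
            lp = np.zeros((C, self.n_patterns, 2))
            lp[:, np.arange(self.n_patterns), self.leaf_state[i]] = 1.0
            self._leaf_partials[key] = hit = lp
        return hit

    def loglik(self, model: GainLossModel, lengths: Optional[np.ndarray] = None) -> float:
        if lengths is None:
            lengths = self.lengths
        C = model.n_categories
        pi = model.pi
        # partial[c, f, s]: likelihood of data below node given state s, category c
        partials = [None] * len(self.nodes)
        absent = [None] * len(self.nodes)  # same, conditioning on all-absent data
        for i, node_is_leaf in enumerate(self.is_leaf):
            if node_is_leaf:
                partials[i] = self._leaf_below(i, C)
                ab = np.zeros((C, 1, 2))
                ab[:, 0, 0] = 1.0
                absent[i] = ab
            else:
                partials[i] = np.ones((C, self.n_patterns, 2))
                absent[i] = np.ones((C, 1, 2))
        # accumulate children into parents (postorder => children before parents);
        # no underflow rescaling: with <=2 states and the tree sizes this model
        # targets (tens of leaves), per-family likelihoods stay far above the
        # double-precision floor
        for i in range(len(self.nodes) - 1):
            P = model.transition_matrices(lengths[i])  # (C,2,2)
            p = self.parent[i]
            contrib = np.einsum("cij,cfj->cfi", P, partials[i])
            partials[p] = partials[p] * contrib
            absent[p] = absent[p] * np.einsum("cij,cfj->cfi", P, absent[i])
        root_lik = partials[self.root] @ pi  # (C, F)
        fam_lik = root_lik.mean(axis=0)  # equal-probability categories
        if model.ascertainment:
            absent_lik = (absent[self.root] @ pi).mean(axis=0)  # (1,)
            denom = 1.0 - float(absent_lik[0])
            if denom <= 0:
                return -np.inf
            fam_lik = fam_lik / denom
        if np.any(fam_lik <= 0):
            return -np.inf
        return float(np.log(fam_lik) @ self.pattern_counts)

    def _passes(self, model: GainLossModel, lengths: np.ndarray) -> tuple:
        """Up (below-subtree) and down (outside-subtree) partials for every node.

        ``below[i][c, f, s]`` is the likelihood of the data in i's subtree
        given state ``s`` at node i; ``above[i][c, f, s_p]`` the likelihood of
        all other data given state ``s_p`` at i's *parent*, root prior
        included.  The total likelihood then factorizes through any single
        branch as ``sum above[i] P_i below[i]``, which lets a branch length be
        re-optimized in O(families) without re-traversing the tree.
        The all-absent pattern (for ascertainment) is carried alongside.
        """
        C = model.n_categories
        pi = model.pi
        n = len(self.nodes)
        below = [None] * n
        below_abs = [None] * n
        child_msg = [None] * n  # P_i @ below[i], the message branch i sends up
        child_msg_abs = [None] * n
        for i in range(n):
            if self.is_leaf[i]:
                below[i] = self._leaf_below(i, C)
                ab = np.zeros((C, 1, 2))
                ab[:, 0, 0] = 1.0
                below_abs[i] = ab
            else:
                below[i] = np.ones((C, self.n_patterns, 2))
                below_abs[i] = np.ones((C, 1, 2))
        for i in range(n - 1):
            P = model.transition_matrices(lengths[i])
            child_msg[i] = np.einsum("cij,cfj->cfi", P, below[i])
            child_msg_abs[i] = np.einsum("cij,cfj->cfi", P, below_abs[i])
            p = self.parent[i]
            below[p] = below[p] * child_msg[i]
            below_abs[p] = below_abs[p] * child_msg_abs[i]
        above = [None] * n
        above_abs = [None] * n
        children: dict = {}
        for i in range(n - 1):
            children.setdefault(self.parent[i], []).append(i)
        # D[p]: outside-subtree(p) likelihood given state at p, prior included
        D = [None] * n
        D_abs = [None] * n
        D[self.root] = np.broadcast_to(pi, (C, 1, 2))
        D_abs[self.root] = np.broadcast_to(pi, (C, 1, 2))
        for p in range(n - 1, -1, -1):
            if self.is_leaf[p]:
                continue
            kids = children.get(p, [])
            for i in kids:
                sib = D[p]
                sib_abs = D_abs[p]
                for j in kids:
                    if j != i:
                        sib = sib * child_msg[j]
                        sib_abs = sib_abs * child_msg_abs[j]
                above[i] = sib
                above_abs[i] = sib_abs
                if not self.is_leaf[i]:
                    P = model.transition_matrices(lengths[i])
                    D[i] = np.einsum("cfi,cij->cfj", sib, P)
                    D_abs[i] = np.einsum("cfi,cij->cfj", sib_abs, P)
        return below, below_abs, above, above_abs

    def branch_loglik(self, model: GainLossModel, below_i, below_abs_i,
                      above_i, above_abs_i, t: float) -> float:
        """Log-likelihood as a function of one branch length, others fixed."""
        P = model.transition_matrices(t)
        fam_lik = np.einsum("cfi,cij,cfj->cf", above_i, P, below_i).mean(axis=0)
        if model.ascertainment:
            ab = np.einsum("cfi,cij,cfj->cf", above_abs_i, P, below_abs_i).mean(axis=0)
            denom = 1.0 - float(ab[0])
            if denom <= 0:
                return -np.inf
            fam_lik = fam_lik / denom
        if np.any(fam_lik <= 0):
            return -np.inf
        return float(np.log(fam_lik) @ self.pattern_counts)


def profile_loglik(model: GainLossModel, tree: dendropy.Tree,
                   profile: PhyleticProfile) -> float:
    """Gamma-mixture pruning log-likelihood of the profile on the tree."""
    return _PruningWorkspace(tree, profile).loglik(model)


def optimize_branch_lengths(model: GainLossModel, tree: dendropy.Tree,
                            profile: PhyleticProfile,
                            optimize_shape: bool = True,
                            optimize_gain_fraction: bool = True,
                            tol: float = 1e-6,
                            max_cycles: int = 30) -> BranchLengthEstimate:
    """Coordinate-wise ML optimization of branch lengths on a fixed topology.

    Cycles over branches (bounded 1-D optimization each), then over the gamma
    shape and the gain fraction g/(g+l) if requested, until the
    log-likelihood improves by less than ``tol``.  The returned tree carries
    branch lengths in expected gain+loss events per family.
    """
    if profile.n_families < 2:
        raise ValueError("need at least two gene families")
    ws = _PruningWorkspace(tree, profile)
    # g + l = 2 internally (time scale anchor); start from the supplied ratio
    s = model.gain_rate + model.loss_rate
    model = replace(model, gain_rate=2.0 * model.gain_rate / s,
                    loss_rate=2.0 * model.loss_rate / s)
    lengths = np.where(ws.lengths > 0, ws.lengths, 1e-3)
    lengths[ws.root] = 0.0
    prev = ws.loglik(model, lengths)
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        for i in range(len(ws.nodes) - 1):
            below, below_abs, above, above_abs = ws._passes(model, lengths)

            def f(b):
                return -ws.branch_loglik(model, below[i], below_abs[i],
                                         above[i], above_abs[i], b)

            res = optimize.minimize_scalar(f, bounds=(0.0, _MAX_BRANCH),
                                           method="bounded",
                                           options={"xatol": 1e-8})
            if -res.fun >= ws.branch_loglik(model, below[i], below_abs[i],
                                            above[i], above_abs[i], lengths[i]):
                lengths[i] = float(res.x)
        if optimize_gain_fraction:
            def fg(logit_rho):
                rho = special.expit(logit_rho)
                m2 = replace(model, gain_rate=2.0 * rho, loss_rate=2.0 * (1.0 - rho))
                return -ws.loglik(m2, lengths)
            res = optimize.minimize_scalar(fg, bounds=(-12.0, 12.0), method="bounded",
                                           options={"xatol": 1e-8})
            rho = float(special.expit(res.x))
            model = replace(model, gain_rate=2.0 * rho, loss_rate=2.0 * (1.0 - rho))
        if optimize_shape and model.n_categories >= 2:
            def fs(log_shape):
                m2 = replace(model, gamma_shape=float(np.exp(log_shape)))
                return -ws.loglik(m2, lengths)
            res = optimize.minimize_scalar(fs, bounds=(np.log(0.05), np.log(100.0)),
                                           method="bounded", options={"xatol": 1e-6})
            model = replace(model, gamma_shape=float(np.exp(res.x)))
        cur = ws.loglik(model, lengths)
        if cur - prev < tol:
            converged = True
            prev = cur
            break
        prev = cur
    if not converged:
        warnings.warn("branch-length optimization did not converge; "
                      "returning best-so-far", RuntimeWarning)
    out = tree.clone(depth=1)
    out_nodes = list(out.postorder_node_iter())
    chain = {}
    for i, node in enumerate(out_nodes):
        if node.parent_node is None:
            continue
        node.edge.length = lengths[i] * model.event_rate
        key = node.taxon.label if node.is_leaf() and node.taxon else f"node{i}"
        chain[key] = float(lengths[i])
    return BranchLengthEstimate(tree=out, log_likelihood=prev, model=model,
                                converged=converged, n_cycles=cycle,
                                chain_lengths=chain)
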