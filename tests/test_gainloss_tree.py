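"""Gain/loss likelihood: pruning vs enumeration, and branch-length recovery."""

import itertools

import numpy as np
import pytest

from recbarrier.gainloss_tree import (GainLossModel, discrete_gamma_rates,
                                      optimize_branch_lengths, profile_loglik)
from recbarrier.gene_content import GeneContentParams, PhyleticProfile
from recbarrier.synthetic_data import simulate_gene_content, simulate_tree

from conftest import tree_from


def brute_force_loglik(model, tree, profile):
    """Sum the likelihood over every internal-state assignment explicitly."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    pi = model.pi
    rates = model.category_rates()
    pmats = {id(n): model.transition_matrices(n.edge.length or 0.0)
             for n in nodes if n.parent_node is not None}

    def pattern_lik(states):
        total = 0.0
        for c in range(len(rates)):
            for assign in itertools.product([0, 1], repeat=len(internal)):
                amap = dict(zip(internal, assign))
                amap.update(states)
                p = pi[amap[tree.seed_node]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    p *= pmats[id(n)][c][amap[n.parent_node], amap[n]]
                total += p
        return total / len(rates)

    absent = pattern_lik({n: 0 for n in leaves}) if model.ascertainment else 0.0
    out = 0.0
    for f in range(profile.n_families):
        states = {n: int(profile.columns([n.taxon.label])[f, 0]) for n in leaves}
        lik = pattern_lik(states)
        if model.ascertainment:
            lik /= 1.0 - absent
        out += np.log(lik)
    return out


SMALL_TOPOLOGIES = [
    "(A:0.2,B:0.5);",
    "(A:0.2,B:0.5,C:0.1);",                      # root polytomy
    "((A:0.3,B:0.7):0.2,C:0.5);",
    "((A:0.3,B:0.7):0.2,(C:0.5,D:0.1):0.4);",
    "(((A:0.1,B:0.2):0.3,C:0.4):0.2,D:0.6);",    # pectinate
    "((A:0.2,B:0.2,C:0.2):0.3,D:0.4);",          # internal polytomy
    "(((A:0.1,B:0.2):0.3,(C:0.4,D:0.2):0.1):0.2,E:0.6);",
    "((((A:0.1,B:0.2):0.1,C:0.3):0.1,D:0.4):0.1,E:0.5);",
]


def random_profile(labels, n_families, rng):
    while True:
        m = rng.integers(0, 2, size=(n_families, len(labels)))
        m = m[m.sum(axis=1) > 0]
        if len(m) >= 2:
            return PhyleticProfile(m, [f"f{i}" for i in range(len(m))], labels)


class TestPruningOracle:
    @pytest.mark.parametrize("newick", SMALL_TOPOLOGIES)
    def test_matches_enumeration(self, newick):
        tree = tree_from(newick)
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        import zlib

        rng = np.random.default_rng(zlib.crc32(newick.encode()))
        profile = random_profile(labels, 12, rng)
        model = GainLossModel(gain_rate=float(rng.uniform(0.2, 2.0)),
                              loss_rate=float(rng.uniform(0.2, 2.0)),
                              n_categories=4,
                              gamma_shape=float(rng.uniform(0.3, 3.0)))
        got = profile_loglik(model, tree, profile)
        want = brute_force_loglik(model, tree, profile)
        assert got == pytest.approx(want, abs=1e-10)

    def test_ascertainment_off_also_matches(self):
        tree = tree_from(SMALL_TOPOLOGIES[3])
        rng = np.random.default_rng(17)
        profile = random_profile(["A", "B", "C", "D"], 10, rng)
        model = GainLossModel(gain_rate=0.6, loss_rate=1.4, n_categories=1,
                              ascertainment=False)
        assert profile_loglik(model, tree, profile) == pytest.approx(
            brute_force_loglik(model, tree, profile), abs=1e-10)


class TestLikelihoodLimits:
    def test_long_branch_stationary_independence(self):
        # two leaves on immensely long branches: P(1,1) -> pi1^2
        tree = tree_from("(A:500,B:500);")
        p = PhyleticProfile(np.array([[1, 1], [1, 0]]), ["f1", "f2"], ["A", "B"])
        model = GainLossModel(gain_rate=1.0, loss_rate=1.0, n_categories=1,
                              ascertainment=False)
        ll = profile_loglik(model, tree, p)
        # family 1: pi1^2 = 0.25; family 2: pi1*pi0 = 0.25
        assert ll == pytest.approx(2 * np.log(0.25), abs=1e-9)

    def test_zero_branches_present_everywhere(self):
        tree = tree_from("((A:0,B:0):0,C:0);")
        p = PhyleticProfile(np.ones((3, 3), dtype=int), ["f1", "f2", "f3"],
                            ["A", "B", "C"])
        model = GainLossModel(gain_rate=1.0, loss_rate=3.0, n_categories=1,
                              ascertainment=False)
        pi1 = 0.25
        assert profile_loglik(model, tree, p) == pytest.approx(3 * np.log(pi1))

    def test_invariance_to_family_and_genome_order(self):
        tree = tree_from(SMALL_TOPOLOGIES[3])
        rng = np.random.default_rng(23)
        m = rng.integers(0, 2, size=(15, 4))
        m = m[m.sum(axis=1) > 0]
        labels = ["A", "B", "C", "D"]
        model = GainLossModel(gain_rate=0.8, loss_rate=1.2)
        base = profile_loglik(model, tree,
                              PhyleticProfile(m, [f"f{i}" for i in range(len(m))], labels))
        perm = rng.permutation(len(m))
        shuffled_rows = profile_loglik(
            model, tree,
            PhyleticProfile(m[perm], [f"f{i}" for i in perm], labels))
        cols = [2, 0, 3, 1]
        shuffled_cols = profile_loglik(
            model, tree,
            PhyleticProfile(m[:, cols], [f"f{i}" for i in range(len(m))],
                            [labels[c] for c in cols]))
        assert shuffled_rows == pytest.approx(base, abs=1e-10)
        assert shuffled_cols == pytest.approx(base, abs=1e-10)

    def test_label_mismatch_rejected(self):
        tree = tree_from("(A:0.2,B:0.5);")
        p = PhyleticProfile(np.array([[1, 1]]), ["f1"], ["A", "X"])
        with pytest.raises(ValueError):
            profile_loglik(GainLossModel(), tree, p)


class TestGammaCategories:
    def test_mean_one(self):
        for shape in (0.2, 1.0, 5.0):
            rates = discrete_gamma_rates(shape, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(rates) > 0)

    def test_single_category_is_unit(self):
        assert discrete_gamma_rates(1.0, 1) == pytest.approx([1.0])


class TestBranchOptimization:
    def test_identical_profiles_drive_lengths_to_zero(self):
        tree = simulate_tree(6, 0.2, seed=51)
        genomes = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        p = PhyleticProfile(np.ones((40, 6), dtype=int),
                            [f"f{i}" for i in range(40)], genomes)
        est = optimize_branch_lengths(GainLossModel(n_categories=1), tree, p,
                                      optimize_shape=False)
        lengths = [e.length for e in est.tree.preorder_edge_iter()
                   if e.length is not None]
        assert max(lengths) < 1e-3

    def test_recovers_proportional_branch_lengths(self):
        lam = 5.0
        tree = simulate_tree(8, 0.25, seed=52)
        prof = simulate_gene_content(tree, GeneContentParams(x=800, lam=lam),
                                     seed=53)
        est = optimize_branch_lengths(GainLossModel(), tree, prof)
        x, y = [], []
        for nt, ne in zip(tree.postorder_node_iter(),
                          est.tree.postorder_node_iter()):
            if nt.parent_node is None:
                continue
            x.append(nt.edge.length * 2 * lam)  # true events per resident family
            y.append(ne.edge.length)
        x, y = np.array(x), np.array(y)
        slope = float(x @ y) / float(x @ x)
        assert slope == pytest.approx(1.0, abs=0.2)
        # per-branch estimates on a small tree are noisy; proportionality only
        assert np.corrcoef(x, y)[0, 1] > 0.7

    def test_pairwise_overlap_consistency(self):
        # gene-content tree distances (gain+loss events per resident family)
        # track the loss-only overlap decay: d_gc ~ 2 * (-ln overlap), with the
        # gain flux and estimation noise allowing a modest excess
        import itertools
        import warnings as _warnings

        lam = 4.0
        tree = simulate_tree(5, 0.12, seed=61)
        prof = simulate_gene_content(tree, GeneContentParams(x=3000, lam=lam),
                                     seed=62)
        from recbarrier.gene_content import intersection
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            est = optimize_branch_lengths(GainLossModel(), tree, prof)
        pdm = est.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in est.tree.taxon_namespace}
        for a, b in itertools.combinations(prof.genome_ids, 2):
            _, overlap = intersection(prof, [a, b])
            d_gc = pdm.distance(taxa[a], taxa[b])
            assert d_gc == pytest.approx(2.0 * (-np.log(overlap)), rel=0.3)
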