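import dendropy
import numpy as np
import pytest

from recbarrier import (BarrierParams, GeneContentParams, PhyleticProfile,
                        simulate_gene_content, simulate_tree)


def tree_from(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


@pytest.fixture
def balanced4():
    return tree_from("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def pectinate4():
    return tree_from("(((A:1,B:1):1,C:1):1,D:1);")


@pytest.fixture
def autocat():
    return BarrierParams.autocatalytic(tau_inf=0.1, phi=5.0)


@pytest.fixture(scope="session")
def sim_tree16():
    return simulate_tree(16, 0.2, seed=31)


@pytest.fixture(scope="session")
def sim_profile16(sim_tree16):
    return simulate_gene_content(sim_tree16, GeneContentParams(x=1000, lam=5.0), seed=32)


@pytest.fixture
def toy_profile():
    # families: a in all, b in g1+g2, c in g1
    return PhyleticProfile(
        np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]]),
        ["a", "b", "c"], ["g1", "g2", "g3"],
    )
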