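"""Branch-length correction for recombination-erased sequence variation.

Gene conversion during early divergence makes the terminal branches of
sequence-based phylogenies appear shorter than the true evolutionary times,
while deep internal branches are nearly unaffected (the delays of parent and
child node heights cancel).  Given fitted barrier parameters this module
undoes that compression: node heights measured from the tips are mapped
through the inverse of the observable-divergence function ``G`` and branch
lengths are rebuilt from the corrected heights.

On non-ultrametric trees a node has no single height; following the
weighted-average construction, the *parental height* ``H_i`` (distance from
node i's parent to the tips) is accumulated from tips to root as::

    H_i = b_i                                   (leaves)
    H_i = sum_c(w_c H_c) / sum_c(w_c) + b_i     (internal nodes)

with weights ``w_i = b_i`` for leaves and ``w_i = sum_c(w_c) + b_i``
otherwise, i.e. the weight of a node is the total branch length of its
subtree plus its own branch.  Written for binary trees, the formulas extend
verbatim to polytomies.

The forward (compression) map is also provided, restricted to ultrametric
inputs, for simulation and round-trip testing.

Trees are ``dendropy.Tree`` objects throughout; topology, rooting and labels
are always preserved.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

from .barrier_model import BarrierParams, DivergenceMap

__all__ = [
    "parental_heights",
    "correct_tree",
    "compress_tree",
    "is_ultrametric",
    "node_heights",
    "tree_depth",
]


def _require_rooted(tree: dendropy.Tree) -> None:
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) < 2:
        raise ValueError("a rooted tree with at least two children at the root is required")


def _edge_length(node: dendropy.Node) -> float:
    b = node.edge.length
    return 0.0 if b is None else float(b)


def node_heights(tree: dendropy.Tree, tol: float = 1e-8) -> dict:
    """Height of every node above the tips of an ultrametric tree."""
    _require_rooted(tree)
    heights: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
        else:
            child_tops = [heights[c] + _edge_length(c) for c in node.child_nodes()]
            if max(child_tops) - min(child_tops) > tol * max(1.0, max(child_tops)):
                raise ValueError(
                    "tree is not ultrametric: children of a node reach different heights"
                )
            heights[node] = float(np.mean(child_tops))
    return heights


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-8) -> bool:
    try:
        node_heights(tree, tol=tol)
    except ValueError:
        return False
    return True


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    _require_rooted(tree)
    depth: dict = {tree.seed_node: 0.0}
    best = 0.0
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + _edge_length(node)
            if node.is_leaf():
                best = max(best, depth[node])
    return best


def parental_heights(tree: dendropy.Tree) -> dict:
    """Weighted-average parental heights H_i and subtree weights w_i.

    Returns a dict mapping each non-root node to ``(H_i, w_i)``.  For leaves
    ``H_i = w_i = b_i``; for internal nodes the height is the subtree-weighted
    average of the children's heights plus the node's own branch length.
    """
    _require_rooted(tree)
    out: dict = {}
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        b = _edge_length(node)
        if node.is_leaf():
            out[node] = (b, b)
        else:
            children = node.child_nodes()
            wsum = sum(out[c][1] for c in children)
            if wsum > 0:
                avg = sum(out[c][1] * out[c][0] for c in children) / wsum
            else:
                avg = 0.0
            out[node] = (avg + b, wsum + b)
    return out


def correct_tree(tree: dendropy.Tree, params: BarrierParams) -> dendropy.Tree:
    """Undo the recombination-driven compression of a sequence-based tree.

    Parental heights are mapped through the inverse observable-divergence
    function, and corrected branch lengths are rebuilt from tips to root with
    the weights recomputed from the corrected lengths at every step.  Exact on
    ultrametric trees (where the height map is the exact inverse of the
    compression); on noisy non-ultrametric trees a corrected branch length can
    come out negative, in which case it is clipped to zero with a warning.
    """
    dmap = DivergenceMap(params)
    corrected = tree.clone(depth=1)
    hw = parental_heights(corrected)
    nodes = [n for n in corrected.postorder_node_iter() if n is not corrected.seed_node]
    h_obs = np.array([hw[n][0] for n in nodes])
    h_true = np.asarray(dmap.inverse(h_obs))
    h_corr = dict(zip(nodes, h_true))

    new_b: dict = {}
    new_w: dict = {}
    n_clipped = 0
    for node in corrected.postorder_node_iter():
        if node is corrected.seed_node:
            continue
        if node.is_leaf():
            b = h_corr[node]
            new_b[node] = b
            new_w[node] = b
        else:
            children = node.child_nodes()
            wsum = sum(new_w[c] for c in children)
            avg = (sum(new_w[c] * h_corr[c] for c in children) / wsum) if wsum > 0 else 0.0
            b = h_corr[node] - avg
            if b < 0:
                n_clipped += 1
                b = 0.0
            new_b[node] = b
            new_w[node] = wsum + b
    if n_clipped:
        warnings.warn(
            f"correction produced {n_clipped} negative branch length(s); clipped to 0",
            RuntimeWarning,
        )
    for node, b in new_b.items():
        node.edge.length = b
    return corrected


def compress_tree(tree: dendropy.Tree, params: BarrierParams) -> dendropy.Tree:
    """Apply the forward divergence map to an ultrametric tree's node heights.

    Every node at height ``h`` above the tips is moved to ``G(h)``; branch
    lengths become differences of mapped heights.  This is the observation
    model for a sequence-based tree under the barrier process, used by the
    simulator and for round-trip testing.  Non-ultrametric input is rejected
    (heights are ill-defined there; correction, not compression, is what real
    non-ultrametric trees need).
    """
    heights = node_heights(tree)  # raises on non-ultrametric input
    dmap = DivergenceMap(params)
    compressed = tree.clone(depth=1)
    orig_nodes = list(tree.preorder_node_iter())
    comp_nodes = list(compressed.preorder_node_iter())
    mapped = {}
    for onode, cnode in zip(orig_nodes, comp_nodes):
        mapped[cnode] = float(dmap.forward(heights[onode] + _edge_length(onode)) -
                              dmap.forward(heights[onode]))
    for cnode in comp_nodes:
        if cnode is not compressed.seed_node and cnode.edge.length is not None:
            cnode.edge.length = mapped[cnode]
    return compressed
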