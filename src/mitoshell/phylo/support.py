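"""Bootstrap supports, branch collapsing and Robinson–Foulds comparison.

Supports live on internal nodes as ``node.support`` (percentage of
replicate trees containing the same bipartition) and are mirrored into
``node.label`` so Newick output shows them as internal node labels.
"""
from __future__ import annotations

import logging
import math

import dendropy
import numpy as np

from .nj import UndefinedDistanceError

logger = logging.getLogger(__name__)


def leaf_label_set(tree: dendropy.Tree) -> set:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def tree_bipartitions(tree: dendropy.Tree, restrict=None,
                      positive_length_only: bool = False) -> set:
    """Non-trivial bipartitions as canonical frozensets.

    Each internal edge yields the side of its leaf set not containing the
    alphabetically smallest taxon; with ``restrict`` the bipartition is
    first projected onto that taxon subset. With ``positive_length_only``
    internal edges of zero length are treated as unresolved (they carry no
    signal and count toward no bipartition).
    """
    taxa = leaf_label_set(tree)
    if restrict is not None:
        taxa = taxa & set(restrict)
    if len(taxa) < 4:
        return set()
    anchor = min(taxa)
    out = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        if positive_length_only and not (node.edge.length or 0.0) > 0.0:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()} & taxa
        if not (2 <= len(side) <= len(taxa) - 2):
            continue
        if anchor in side:
            side = taxa - side
        out.add(frozenset(side))
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree, restrict=None) -> int:
    """Robinson–Foulds (symmetric difference) distance on shared taxa."""
    shared = leaf_label_set(t1) & leaf_label_set(t2)
    if restrict is not None:
        shared &= set(restrict)
    return len(tree_bipartitions(t1, shared) ^ tree_bipartitions(t2, shared))


def bootstrap_support(labels, alignment: np.ndarray, builder, n_reps: int,
                      seed: int = 0, tree: dendropy.Tree | None = None) -> dendropy.Tree:
    """Attach column-resampling bootstrap supports to a tree.

    ``builder(alignment) -> tree`` reconstructs a tree from an
    (n_samples, n_sites) code matrix; replicate ``r`` draws its columns with
    the seed ``seed + r``. Replicates whose reconstruction fails on
    undefined distances are dropped (and counted in the returned tree's
    ``bootstrap_info``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if tree is None:
        tree = builder(alignment)
    L = alignment.shape[1]
    counts: dict = {}
    dropped = 0
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, L, size=L)
        try:
            rep = builder(alignment[:, cols])
        except UndefinedDistanceError as err:
            dropped += 1
            logger.debug("bootstrap replicate %d dropped: %s", r, err)
            continue
        for bp in tree_bipartitions(rep, positive_length_only=True):
            counts[bp] = counts.get(bp, 0) + 1
    used = n_reps - dropped
    taxa = leaf_label_set(tree)
    anchor = min(taxa)
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if not (2 <= len(side) <= len(taxa) - 2):
            continue
        if anchor in side:
            side = taxa - side
        sup = 100.0 * counts.get(frozenset(side), 0) / used if used else math.nan
        node.support = sup
        node.label = str(int(round(sup))) if not math.isnan(sup) else None
    tree.bootstrap_info = {"n_reps": n_reps, "dropped": dropped, "used": used}
    return tree


def collapse_branches(tree: dendropy.Tree, threshold: float = 35.0) -> dendropy.Tree:
    """Contract internal edges whose support is strictly below ``threshold``.

    Leaf edges are never touched; the operation is idempotent.
    """
    out = tree.clone(depth=1)
    for node in list(out.preorder_node_iter()):
        if node is out.seed_node or node.is_leaf():
            continue
        sup = getattr(node, "support", None)
        if sup is not None and not math.isnan(sup) and sup < threshold:
            node.edge.collapse()
    if hasattr(tree, "bootstrap_info"):
        out.bootstrap_info = dict(tree.bootstrap_info)
    return out


def mean_internal_support(tree: dendropy.Tree) -> float:
    sups = [
        node.support
        for node in tree.postorder_node_iter()
        if node is not tree.seed_node and not node.is_leaf()
        and getattr(node, "support", None) is not None
        and not math.isnan(node.support)
    ]
    return float(np.mean(sups)) if sups else math.nan
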