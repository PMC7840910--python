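"""Saitou–Nei neighbour joining with deterministic tie-breaking.

Ties in the Q criterion are resolved toward the lexicographically smallest
(label_i, label_j) pair, where a cluster is named by its smallest leaf
label; negative branch lengths are clamped to zero. The result is an
unrooted dendropy tree (trifurcating at the final join).
"""
from __future__ import annotations

import math

import dendropy
import numpy as np

from .distance import DistanceMatrix


class UndefinedDistanceError(ValueError):
    """Raised when the input matrix contains undefined (NaN) entries."""


def nj_tree(dist: DistanceMatrix,
            taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    bad = dist.undefined_pairs()
    if bad:
        raise UndefinedDistanceError(
            f"undefined distance between {bad[0][0]} and {bad[0][1]}"
            + (f" (+{len(bad) - 1} more pairs)" if len(bad) > 1 else "")
        )
    labels = list(dist.labels)
    n = len(labels)
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    if n == 1:
        tree.seed_node.taxon = tns.require_taxon(label=labels[0])
        return tree

    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.require_taxon(label=lab))
        nodes.append(node)
    reps = list(labels)  # smallest leaf label per cluster
    D = dist.values.astype(float).copy()
    active = list(range(n))

    def _join(i_pos: int, j_pos: int, vi: float, vj: float):
        i, j = active[i_pos], active[j_pos]
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(vi, 0.0)
        nodes[j].edge.length = max(vj, 0.0)
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        return len(nodes) - 1

    while len(active) > 3:
        na = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        best = None
        for ti, tj in ties:
            if ti >= tj:
                continue
            key = tuple(sorted((reps[active[ti]], reps[active[tj]])))
            if best is None or key < best[0]:
                best = (key, int(ti), int(tj))
        _, ip, jp = best
        dij = sub[ip, jp]
        vi = 0.5 * dij + (r[ip] - r[jp]) / (2.0 * (na - 2))
        vj = dij - vi
        new_idx = _join(ip, jp, vi, vj)
        # distances from the new cluster to the remaining ones
        D = np.pad(D, ((0, 1), (0, 1)))
        for kp, k in enumerate(active):
            if kp in (ip, jp):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (sub[ip, kp] + sub[jp, kp] - dij)
        i, j = active[ip], active[jp]
        active = [k for k in active if k not in (i, j)] + [new_idx]

    root = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        dij, dik, djk = D[i, j], D[i, k], D[j, k]
        vi = 0.5 * (dij + dik - djk)
        vj = 0.5 * (dij + djk - dik)
        vk = 0.5 * (dik + djk - dij)
        for idx, v in ((i, vi), (j, vj), (k, vk)):
            root.add_child(nodes[idx])
            nodes[idx].edge.length = max(v, 0.0)
    elif len(active) == 2:
        i, j = active
        d = max(D[i, j], 0.0)
        root.add_child(nodes[i])
        root.add_child(nodes[j])
        nodes[i].edge.length = d / 2.0
        nodes[j].edge.length = d / 2.0
    tree.seed_node = root
    tree.is_rooted = False
    return tree
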