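"""General time-reversible substitution model: pruning likelihood and a
coordinate-ascent maximum-likelihood fit.

The rate matrix is parameterised by stationary frequencies pi and six
exchangeabilities (AC, AG, AT, CG, CT, GT), normalised to one expected
substitution per unit branch length. N (and any ambiguity) enters the
pruning partials as a vector of ones; all alignment columns, constant sites
included, contribute to the likelihood.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .distance import tn93_matrix, DistanceMatrix
from .nj import nj_tree

_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_TRANSITIONS = {(0, 2), (1, 3)}  # AG, CT


@dataclass
class GtrParams:
    """Stationary frequencies and exchangeabilities of a GTR model."""

    pi: np.ndarray
    rates: np.ndarray  # AC, AG, AT, CG, CT, GT

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.pi.shape != (4,) or self.rates.shape != (6,):
            raise ValueError("pi must have 4 entries and rates 6")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("stationary frequencies must sum to 1")
        if (self.pi <= 0).any():
            raise ValueError("stationary frequencies must be positive")
        if (self.rates < 0).any():
            raise ValueError("exchangeabilities must be non-negative")
        self._eig = None

    def q_matrix(self) -> np.ndarray:
        """Rate matrix normalised to mean substitution rate 1."""
        Q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _PAIRS):
            Q[i, j] = r * self.pi[j]
            Q[j, i] = r * self.pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.pi, np.diag(Q)))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / mu

    def _eigendecomposition(self):
        if self._eig is None:
            Q = self.q_matrix()
            sq = np.sqrt(self.pi)
            S = (sq[:, None] * Q) / sq[None, :]  # symmetric similar matrix
            w, U = np.linalg.eigh((S + S.T) / 2.0)
            V = U / sq[:, None]
            Vinv = U.T * sq[None, :]
            self._eig = (w, V, Vinv)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt)."""
        w, V, Vinv = self._eigendecomposition()
        P = (V * np.exp(w * t)[None, :]) @ Vinv
        return np.clip(P, 0.0, None)

    def ts_tv_ratio(self) -> float:
        """Instantaneous transition/transversion rate ratio."""
        ts = tv = 0.0
        for r, (i, j) in zip(self.rates, _PAIRS):
            flow = 2.0 * r * self.pi[i] * self.pi[j]
            if (i, j) in _TRANSITIONS:
                ts += flow
            else:
                tv += flow
        return ts / tv if tv > 0 else math.inf


def compress_alignment(codes: np.ndarray):
    """Collapse identical columns; returns (patterns, weights)."""
    patterns, weights = np.unique(codes, axis=1, return_counts=True)
    return patterns, weights.astype(float)


def _leaf_partial(column: np.ndarray) -> np.ndarray:
    part = np.zeros((len(column), 4))
    known = column < 4
    part[np.arange(len(column))[known], column[known]] = 1.0
    part[~known] = 1.0
    return part


def gtr_loglik(tree: dendropy.Tree, labels, codes: np.ndarray,
               params: GtrParams) -> float:
    """Felsenstein pruning log-likelihood over all sites.

    ``labels``/``codes`` give the alignment rows; tree leaves must carry
    taxa whose labels appear in ``labels``.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    patterns, weights = compress_alignment(codes)
    npat = patterns.shape[1]

    logscale = np.zeros(npat)

    def partial(node) -> np.ndarray:
        nonlocal logscale
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in idx:
                raise ValueError(f"leaf {lab!r} missing from alignment")
            return _leaf_partial(patterns[idx[lab]])
        part = np.ones((npat, 4))
        for child in node.child_nodes():
            t = child.edge.length if child.edge.length is not None else 0.0
            P = params.transition_matrix(max(t, 0.0))
            part = part * (partial(child) @ P.T)
        mx = part.max(axis=1)
        mx[mx == 0.0] = 1.0
        logscale = logscale + np.log(mx)
        return part / mx[:, None]

    root_part = partial(tree.seed_node)
    site_l = root_part @ params.pi
    return float(np.dot(weights, np.log(site_l) + logscale))


def _empirical_frequencies(codes: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    counts = np.bincount(codes[codes < 4].ravel(), minlength=4).astype(float)
    counts += pseudocount
    return counts / counts.sum()


def _iter_branch_nodes(tree):
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        yield node


def _nni_candidates(tree):
    """(node, child, sibling) triples describing one NNI swap each."""
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        parent = node.parent_node
        siblings = [s for s in parent.child_nodes() if s is not node]
        for child in list(node.child_nodes()):
            for sib in siblings:
                yield node, child, sib


def ml_fit(labels, codes: np.ndarray, start_tree: dendropy.Tree | None = None,
           start_rates=None, seed: int = 0, max_rounds: int = 50,
           tol: float = 1e-6, nni: bool = True, max_branch: float = 10.0):
    """Fit branch lengths and GTR exchangeabilities by coordinate ascent.

    Stationary frequencies are fixed at the empirical base composition.
    Returns ``(tree, params, report)``; the log-likelihood is non-decreasing
    across iterations and ``report['converged']`` records whether the
    improvement fell below ``tol`` within ``max_rounds``.
    """
    if start_tree is None:
        dm = tn93_matrix(labels, codes)
        # TN93 can be undefined on extreme pairs; fall back to p-distance
        if dm.undefined_pairs():
            vals = np.zeros_like(dm.values)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    a, b = codes[i], codes[j]
                    ok = (a < 4) & (b < 4)
                    vals[i, j] = vals[j, i] = (
                        (a[ok] != b[ok]).mean() if ok.any() else 0.0
                    )
            dm = DistanceMatrix(labels=list(labels), values=vals)
        tree = nj_tree(dm)
    else:
        tree = start_tree.clone(depth=1)
    for node in _iter_branch_nodes(tree):
        if node.edge.length is None or node.edge.length <= 0:
            node.edge.length = 1e-4

    pi = _empirical_frequencies(codes)
    rates = np.ones(6) if start_rates is None else np.asarray(start_rates, float).copy()

    def make_params(r):
        return GtrParams(pi=pi, rates=np.asarray(r, dtype=float))

    def loglik(r=None):
        return gtr_loglik(tree, labels, codes, make_params(rates if r is None else r))

    cur = loglik()
    trace = [cur]
    converged = False
    for _ in range(max_rounds):
        start = cur
        # branch lengths
        for node in _iter_branch_nodes(tree):
            old = node.edge.length
            def f(t, node=node):
                node.edge.length = t
                return -loglik()
            res = minimize_scalar(f, bounds=(1e-9, max_branch), method="bounded",
                                  options={"xatol": 1e-8})
            cand = -res.fun
            if cand >= cur:
                node.edge.length = float(res.x)
                cur = cand
            else:
                node.edge.length = old
        # exchangeabilities (GT fixed at 1)
        for k in range(5):
            def g(logr, k=k):
                r = rates.copy()
                r[k] = math.exp(logr)
                return -loglik(r)
            res = minimize_scalar(g, bounds=(math.log(1e-4), math.log(1e4)),
                                  method="bounded", options={"xatol": 1e-6})
            cand = -res.fun
            if cand >= cur:
                rates[k] = math.exp(float(res.x))
                cur = cand
        # NNI pass: accept improving swaps
        if nni:
            improved = True
            guard = 0
            while improved and guard < 20:
                improved = False
                guard += 1
                for node, child, sib in list(_nni_candidates(tree)):
                    parent = node.parent_node
                    if child.parent_node is not node or sib.parent_node is not parent:
                        continue
                    node.remove_child(child)
                    parent.remove_child(sib)
                    node.add_child(sib)
                    parent.add_child(child)
                    cand = loglik()
                    if cand > cur + 1e-12:
                        cur = cand
                        improved = True
                    else:
                        node.remove_child(sib)
                        parent.remove_child(child)
                        node.add_child(child)
                        parent.add_child(sib)
        trace.append(cur)
        if cur - start < tol:
            converged = True
            break

    report = {"loglik": cur, "trace": trace, "converged": converged,
              "ts_tv_ratio": make_params(rates).ts_tv_ratio()}
    return tree, make_params(rates), report
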