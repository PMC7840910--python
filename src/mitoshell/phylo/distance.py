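"""Tamura–Nei (TN93) distances under pairwise deletion.

TN93 separates the two transition classes (A<->G, C<->T) from transversions
and allows unequal base frequencies. Base frequencies are estimated from the
pooled pair of sequences after pairwise deletion of sites where either
sequence is N (per-pair frequencies, matching the distance being a property
of the pair; alignment-wide frequencies are available via the ``freqs``
argument).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..core import A, C, G, T

#: minimum fraction of alignment columns both sequences must share for a
#: distance to be defined
MIN_OVERLAP_FRAC = 0.05


@dataclass
class PairCounts:
    """Sufficient statistics of one sequence pair under pairwise deletion."""

    n_valid: int
    p1: float  # proportion of A<->G differences
    p2: float  # proportion of C<->T differences
    q: float  # proportion of transversion differences
    pi: np.ndarray  # pooled base frequencies (A, C, G, T)

    @property
    def pi_r(self) -> float:
        return float(self.pi[A] + self.pi[G])

    @property
    def pi_y(self) -> float:
        return float(self.pi[C] + self.pi[T])


def pair_counts(a: np.ndarray, b: np.ndarray) -> PairCounts:
    """Count transition/transversion proportions for one pair of code arrays."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        return PairCounts(0, 0.0, 0.0, 0.0, np.full(4, np.nan))
    aa = a[valid].astype(np.int64)
    bb = b[valid].astype(np.int64)
    joint = np.bincount(aa * 4 + bb, minlength=16).reshape(4, 4)
    p1 = (joint[A, G] + joint[G, A]) / n
    p2 = (joint[C, T] + joint[T, C]) / n
    diff = n - np.trace(joint)
    q = (diff - joint[A, G] - joint[G, A] - joint[C, T] - joint[T, C]) / n
    pooled = (joint.sum(axis=1) + joint.sum(axis=0)) / (2.0 * n)
    return PairCounts(n, float(p1), float(p2), float(q), pooled)


def tn93_from_counts(pc: PairCounts) -> float:
    """Evaluate the TN93 estimator; NaN when a logarithm argument is <= 0
    or the base composition is degenerate for an observed difference class."""
    if pc.n_valid == 0:
        return math.nan
    if pc.p1 == 0.0 and pc.p2 == 0.0 and pc.q == 0.0:
        return 0.0
    pi_a, pi_c, pi_g, pi_t = (float(x) for x in pc.pi)
    pi_r, pi_y = pc.pi_r, pc.pi_y
    if pi_r <= 0.0 or pi_y <= 0.0:
        return math.nan

    ag = pi_a * pi_g
    tc = pi_t * pi_c
    d = 0.0
    # purine transition term
    if ag > 0.0:
        k1 = 2.0 * ag / pi_r
        w1 = 1.0 - pi_r * pc.p1 / (2.0 * ag) - pc.q / (2.0 * pi_r)
        if w1 <= 0.0:
            return math.nan
        d -= k1 * math.log(w1)
    elif pc.p1 > 0.0:
        return math.nan
    # pyrimidine transition term
    if tc > 0.0:
        k2 = 2.0 * tc / pi_y
        w2 = 1.0 - pi_y * pc.p2 / (2.0 * tc) - pc.q / (2.0 * pi_y)
        if w2 <= 0.0:
            return math.nan
        d -= k2 * math.log(w2)
    elif pc.p2 > 0.0:
        return math.nan
    # transversion term
    k3 = 2.0 * (pi_r * pi_y
                - (ag * pi_y / pi_r if pi_r > 0 else 0.0)
                - (tc * pi_r / pi_y if pi_y > 0 else 0.0))
    w3 = 1.0 - pc.q / (2.0 * pi_r * pi_y)
    if w3 <= 0.0:
        return math.nan
    d -= k3 * math.log(w3)
    return d


def tn93_distance(a: np.ndarray, b: np.ndarray,
                  alignment_length: int | None = None,
                  min_overlap_frac: float = MIN_OVERLAP_FRAC) -> float:
    """TN93 distance for one pair; NaN when undefined.

    The distance is undefined when the pair shares fewer than
    ``floor(min_overlap_frac * alignment_length)`` called sites.
    """
    L = alignment_length if alignment_length is not None else len(a)
    pc = pair_counts(a, b)
    if pc.n_valid < math.floor(min_overlap_frac * L):
        return math.nan
    return tn93_from_counts(pc)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix; NaN marks undefined entries."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def undefined_pairs(self) -> list:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out


def tn93_matrix(labels, alignment: np.ndarray,
                min_overlap_frac: float = MIN_OVERLAP_FRAC) -> DistanceMatrix:
    """All-pairs TN93 matrix from an (n_samples, n_sites) code matrix."""
    n, L = alignment.shape
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tn93_distance(alignment[i], alignment[j], alignment_length=L,
                              min_overlap_frac=min_overlap_frac)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels=list(labels), values=vals)
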