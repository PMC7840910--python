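"""Diagnostic-SNP haplogroup delineation and marker subsetting.

A haplogroup is a well-supported clade whose members share at least
``min_diag`` diagnostic SNPs: sites where every member with a called base
carries the same non-reference allele, at least two members are called, and
no non-member's called base equals that allele. Diagnostic alleles are
polarised against the mapping reference so that the complement of a clade
does not trivially inherit "diagnostic" reference alleles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..core import N, decode
from ..processing import ConsensusSequence
from .support import collapse_branches

logger = logging.getLogger(__name__)


@dataclass
class Haplogroup:
    label: str
    members: list
    diagnostic_snps: list  # [(pos_1based, allele_char), ...]
    support: float


@dataclass
class HaplogroupAssignment:
    """Per-sample haplogroup calls plus per-haplogroup evidence."""

    assignments: dict  # sample -> label or 'UNASSIGNED'
    groups: dict  # label -> Haplogroup

    def members(self, label: str) -> list:
        return self.groups[label].members

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\thaplogroup\tsupport\tn_diagnostic\n")
            for sample, label in self.assignments.items():
                if label == "UNASSIGNED":
                    fh.write(f"{sample}\tUNASSIGNED\tNA\tNA\n")
                else:
                    g = self.groups[label]
                    fh.write(f"{sample}\t{label}\t{g.support:.0f}\t"
                             f"{len(g.diagnostic_snps)}\n")


def _diagnostic_columns(snp_matrix, member_rows, other_rows):
    """Vectorised fixed-inside / absent-outside scan over matrix columns."""
    M = snp_matrix.alleles
    sub = M[member_rows]
    called = sub != N
    n_called = called.sum(axis=0)
    lo = np.where(called, sub, 9).min(axis=0)
    hi = np.where(called, sub, -1).max(axis=0)
    fixed = (n_called >= 2) & (lo == hi) & (hi < 4)
    allele = hi.astype(np.uint8)
    nonref = allele != snp_matrix.ref_alleles
    if len(other_rows):
        conflict = (M[other_rows] == allele[None, :]).any(axis=0)
    else:
        conflict = np.zeros(M.shape[1], dtype=bool)
    cols = np.where(fixed & nonref & ~conflict)[0]
    return [(int(snp_matrix.positions1[c]), decode(allele[c: c + 1])) for c in cols]


def call_haplogroups(tree, snp_matrix, min_diag: int = 2,
                     min_support: float = 35.0) -> HaplogroupAssignment:
    """Delineate haplogroups from a support-annotated tree and SNP matrix.

    Candidate clades are monophyletic groups of the collapsed tree with
    support >= ``min_support`` (nodes without recorded support count as
    fully supported, e.g. on truth trees); among candidates with at least
    ``min_diag`` diagnostic SNPs, maximal disjoint clades are accepted
    largest-first. Samples outside every accepted clade are UNASSIGNED.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()
              if lf.taxon is not None]
    if not leaves:
        raise ValueError("empty tree")
    samples = [s for s in snp_matrix.samples if s in set(leaves)]
    sample_index = {s: i for i, s in enumerate(snp_matrix.samples)}
    if not samples:
        raise ValueError("no tree leaf appears in the SNP matrix")

    work = collapse_branches(tree, min_support)
    candidates = []
    seen = set()
    for node in work.postorder_node_iter():
        if node.is_leaf() or node is work.seed_node:
            continue
        sup = getattr(node, "support", None)
        sup = 100.0 if sup is None else sup
        if sup < min_support:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()} & set(samples)
        # the tree is unrooted: each internal edge offers both of its sides
        # as candidate monophyletic groups
        for members in (side, set(samples) - side):
            members = sorted(members)
            key = tuple(members)
            if len(members) < 2 or len(members) >= len(samples) or key in seen:
                continue
            seen.add(key)
            candidates.append((members, sup))

    accepted = []
    taken: set = set()
    for members, sup in sorted(candidates, key=lambda c: (-len(c[0]), c[0])):
        if taken & set(members):
            continue
        member_rows = [sample_index[s] for s in members]
        other_rows = [sample_index[s] for s in samples if s not in set(members)]
        diag = _diagnostic_columns(snp_matrix, member_rows, other_rows)
        if len(diag) >= min_diag:
            accepted.append(Haplogroup(
                label=f"HG{len(accepted) + 1:02d}", members=members,
                diagnostic_snps=diag, support=sup,
            ))
            taken |= set(members)

    assignments = {s: "UNASSIGNED" for s in samples}
    for g in accepted:
        for s in g.members:
            assignments[s] = g.label
    for s, label in assignments.items():
        if label == "UNASSIGNED":
            logger.info("sample %s not assigned to any haplogroup", s)
    return HaplogroupAssignment(assignments=assignments,
                                groups={g.label: g for g in accepted})


def extract_marker(consensus_seqs, region) -> list:
    """Restrict a consensus alignment to a 1-based closed interval.

    Samples with zero called bases inside the region are dropped (logged),
    mirroring marker-gene analyses where sequences without data in the
    fragment are removed automatically.
    """
    start, end = region
    if start > end:
        raise ValueError(f"inverted interval {region}")
    if start < 1:
        raise ValueError("interval is 1-based; start must be >= 1")
    out = []
    for cons in consensus_seqs:
        if end > len(cons.sequence):
            raise ValueError("interval exceeds alignment length")
        sub = cons.sequence[start - 1: end]
        if set(sub) <= {"N"}:
            logger.info("sample %s has no called base in %s, dropped",
                        cons.sample_id, region)
            continue
        out.append(ConsensusSequence(
            sample_id=cons.sample_id, sequence=sub,
            depth=cons.depth[start - 1: end] if cons.depth is not None else None,
        ))
    return out
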