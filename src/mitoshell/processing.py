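"""Ancient-DNA read processing against a circular mitochondrial reference.

The mapper performs *exact* minimum-mismatch placement on the doubled
reference (circular semantics), made fast by a pigeonhole seed index:
a read that aligns with at most ``k = ceil(0.1 * len)`` mismatches must
contain at least one of ``k + 1`` disjoint exact seeds, so collecting seed
hits and verifying candidates with vectorised mismatch counts recovers the
true optimum; reads without seed hits fall back to an exhaustive scan.

Downstream: PCR-duplicate removal by identical placement, terminal-damage
profiling, pileup, minimum-depth majority consensus and the cohort
variable-site (SNP) matrix on which per-sample missingness is defined.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import A, C, G, N, T, ReferenceGenome, revcomp


@dataclass
class Alignment:
    """Placement of one read on the circular reference.

    ``start`` is a 0-based offset in ``[0, L)``; ``end = start + len(read)``
    may exceed ``L`` only for origin-spanning placements. ``bases`` holds the
    read codes in sequencing (read) orientation.
    """

    read_id: str
    start: int
    end: int
    strand: str
    n_mismatches: int
    mapped: bool
    bases: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.end - self.start

    def ref_oriented_bases(self) -> np.ndarray:
        """Read codes oriented along the reference strand."""
        return self.bases if self.strand == "+" else revcomp(self.bases)


def mismatch_ceiling(read_length: int) -> int:
    return math.ceil(0.1 * read_length)


class CircularMapper:
    """Minimum-mismatch placement on a doubled circular reference."""

    MIN_SEED = 5

    def __init__(self, ref: ReferenceGenome):
        self.ref = ref
        self.L = len(ref)
        self.doubled = np.concatenate([ref.codes, ref.codes]).astype(np.int64)
        self._indexes: dict = {}

    def _seed_index(self, s: int):
        """Sorted base-4 keys of all length-``s`` windows of the doubled ref."""
        if s not in self._indexes:
            n = len(self.doubled) - s + 1
            vals = np.zeros(n, dtype=np.int64)
            for j in range(s):
                vals = vals * 4 + self.doubled[j: j + n]
            order = np.argsort(vals, kind="stable")
            self._indexes[s] = (vals[order], order.astype(np.int64))
        return self._indexes[s]

    def _candidates(self, codes: np.ndarray) -> np.ndarray:
        m = len(codes)
        k = mismatch_ceiling(m)
        s = m // (k + 1)
        if s < self.MIN_SEED:
            return np.arange(self.L)
        keys, positions = self._seed_index(s)
        cands = []
        for i in range(k + 1):
            seed = codes[i * s: (i + 1) * s]
            if (seed >= 4).any():
                continue
            key = 0
            for b in seed:
                key = key * 4 + int(b)
            lo = np.searchsorted(keys, key, side="left")
            hi = np.searchsorted(keys, key, side="right")
            if hi > lo:
                cands.append((positions[lo:hi] - i * s) % self.L)
        if not cands:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(cands))

    def _best_placement(self, codes: np.ndarray):
        """(mismatches, start) of the best placement for one orientation."""
        m = len(codes)
        cands = self._candidates(codes)
        if len(cands) == 0:
            return None
        windows = self.doubled[cands[:, None] + np.arange(m)[None, :]]
        mm = (windows != codes[None, :]).sum(axis=1)
        order = np.lexsort((cands, mm))
        best = order[0]
        return int(mm[best]), int(cands[best])

    def map_read(self, read_id: str, codes: np.ndarray) -> Alignment:
        m = len(codes)
        k = mismatch_ceiling(m)
        best = None  # (mm, start, strand_rank, strand, oriented codes)
        for rank, (strand, oriented) in enumerate(
            (("+", codes.astype(np.int64)), ("-", revcomp(codes).astype(np.int64)))
        ):
            hit = self._best_placement(oriented)
            if hit is None:
                continue
            mm, start = hit
            cand = (mm, start, rank)
            if best is None or cand < best[:3]:
                best = (mm, start, rank, strand)
        if best is None:
            # no exact seed anywhere: by pigeonhole every placement exceeds
            # the mismatch ceiling, so the read is unmapped
            return Alignment(read_id, 0, m, "+", m, False, codes)
        mm, start, _, strand = best
        return Alignment(
            read_id=read_id,
            start=start,
            end=start + m,
            strand=strand,
            n_mismatches=mm,
            mapped=mm <= k,
            bases=codes,
        )


def map_reads_circular(reads, ref: ReferenceGenome) -> list:
    """Map reads (both strands) to their minimum-mismatch circular placement.

    Ties are broken by smallest wrapped start, then '+' before '-'.
    """
    from .core import encode

    mapper = CircularMapper(ref)
    out = []
    for r in reads:
        codes = encode(r.bases) if isinstance(r.bases, str) else r.bases
        out.append(mapper.map_read(r.id, codes))
    return out


def deduplicate(alignments) -> list:
    """Keep one representative per (start, end, strand) placement.

    The representative is the alignment with the most called (non-N) bases;
    ties go to the lexicographically smallest read id.
    """
    groups: dict = {}
    for aln in alignments:
        key = (aln.start, aln.end, aln.strand)
        called = int((aln.bases != N).sum())
        cand = (-called, aln.read_id, aln)
        if key not in groups or cand[:2] < groups[key][:2]:
            groups[key] = cand
    return [groups[k][2] for k in sorted(groups)]


@dataclass
class DamageProfile:
    """Terminal misincorporation frequencies in read orientation.

    ``ct5[i]`` is the frequency of reference-C positions read as T at 5'
    offset ``i``; ``ga3[j]`` the G→A frequency at 3' offset ``j``. Offsets
    with zero opportunities are reported as NaN.
    """

    window: int
    ct5: np.ndarray
    ga3: np.ndarray
    n5: np.ndarray  # opportunities (denominators)
    n3: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("offset\tct_5p\tn_5p\tga_3p\tn_3p\n")
            for i in range(self.window):
                c = "NA" if np.isnan(self.ct5[i]) else f"{self.ct5[i]:.6f}"
                g = "NA" if np.isnan(self.ga3[i]) else f"{self.ga3[i]:.6f}"
                fh.write(f"{i}\t{c}\t{int(self.n5[i])}\t{g}\t{int(self.n3[i])}\n")


def damage_profile(alignments, ref: ReferenceGenome, window: int = 25) -> DamageProfile:
    """Profile C→T (5') and G→A (3') rates from mapped alignments."""
    if window < 1:
        raise ValueError("window must be >= 1")
    doubled = np.concatenate([ref.codes, ref.codes])
    num5 = np.zeros(window)
    den5 = np.zeros(window)
    num3 = np.zeros(window)
    den3 = np.zeros(window)
    for aln in alignments:
        if not aln.mapped:
            continue
        refseg = doubled[aln.start: aln.end]
        if aln.strand == "-":
            refseg = revcomp(refseg)
        read = aln.bases
        m = len(read)
        w = min(window, m)
        is_c = refseg[:w] == C
        num5[:w] += is_c & (read[:w] == T)
        den5[:w] += is_c
        tail_ref = refseg[m - w:][::-1]
        tail_read = read[m - w:][::-1]
        is_g = tail_ref == G
        num3[:w] += is_g & (tail_read == A)
        den3[:w] += is_g
    with np.errstate(invalid="ignore", divide="ignore"):
        ct5 = np.where(den5 > 0, num5 / np.maximum(den5, 1), np.nan)
        ga3 = np.where(den3 > 0, num3 / np.maximum(den3, 1), np.nan)
    return DamageProfile(window=window, ct5=ct5, ga3=ga3, n5=den5, n3=den3)


@dataclass
class Pileup:
    """Per-position base counts (A, C, G, T) after deduplication."""

    counts: np.ndarray  # (L, 4) int

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def build_pileup(alignments, ref: ReferenceGenome) -> Pileup:
    """Accumulate reference-oriented base counts; N bases are ignored and
    origin-spanning alignments wrap around."""
    L = len(ref)
    pos_chunks = []
    base_chunks = []
    for aln in alignments:
        if not aln.mapped:
            continue
        bases = aln.ref_oriented_bases()
        positions = (aln.start + np.arange(len(bases))) % L
        called = bases != N
        pos_chunks.append(positions[called])
        base_chunks.append(bases[called])
    counts = np.zeros((L, 4), dtype=np.int64)
    if pos_chunks:
        pos = np.concatenate(pos_chunks)
        base = np.concatenate(base_chunks)
        np.add.at(counts, (pos, base), 1)
    return Pileup(counts=counts)


@dataclass
class ConsensusSequence:
    """Per-sample consensus call over the full reference length."""

    sample_id: str
    sequence: str
    depth: np.ndarray

    def __len__(self) -> int:
        return len(self.sequence)


def call_consensus(
    pileup: Pileup,
    ref: ReferenceGenome,
    sample_id: str,
    min_depth: int = 3,
    majority: float = 0.5,
) -> ConsensusSequence:
    """Majority consensus with an N mask below ``min_depth``.

    A site is called iff depth >= min_depth and the most frequent base has
    frequency strictly above ``majority``; strict ties are N.
    """
    from .core import decode

    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    counts = pileup.counts
    depth = counts.sum(axis=1)
    top = counts.max(axis=1)
    arg = counts.argmax(axis=1)
    tie = (counts == top[:, None]).sum(axis=1) > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    called = (depth >= min_depth) & (frac > majority) & ~tie
    seq = np.where(called, arg, N).astype(np.uint8)
    return ConsensusSequence(sample_id=sample_id, sequence=decode(seq), depth=depth)


@dataclass
class SnpMatrix:
    """Cohort variable-site matrix over {A, C, G, T, N}.

    Sites are the union over samples of positions whose called base differs
    from the reference; per-sample missingness is the percentage of these
    sites at which the sample is N.
    """

    samples: list
    positions1: np.ndarray  # 1-based reference coordinates
    alleles: np.ndarray  # (n_samples, n_sites) codes
    ref_alleles: np.ndarray  # (n_sites,) codes

    @property
    def n_sites(self) -> int:
        return len(self.positions1)

    def row(self, sample: str) -> np.ndarray:
        return self.alleles[self.samples.index(sample)]

    def missingness(self, sample: str) -> float:
        return missingness(self, sample)

    def missingness_all(self) -> dict:
        return {s: missingness(self, s) for s in self.samples}

    def subset_samples(self, keep) -> "SnpMatrix":
        idx = [self.samples.index(s) for s in keep]
        return SnpMatrix(
            samples=list(keep),
            positions1=self.positions1,
            alleles=self.alleles[idx],
            ref_alleles=self.ref_alleles,
        )

    def to_tsv(self, path) -> None:
        from .core import decode

        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(str(p) for p in self.positions1) + "\n")
            fh.write("REF\t" + "\t".join(decode(self.ref_alleles)) + "\n")
            for s, row in zip(self.samples, self.alleles):
                fh.write(s + "\t" + "\t".join(decode(row)) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "SnpMatrix":
        from .core import encode

        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            positions = np.array([int(p) for p in header[1:]])
            ref_line = fh.readline().rstrip("\n").split("\t")
            ref = encode("".join(ref_line[1:]))
            samples, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                samples.append(parts[0])
                rows.append(encode("".join(parts[1:])))
        return cls(samples=samples, positions1=positions,
                   alleles=np.stack(rows), ref_alleles=ref)


def extract_snps(consensus_seqs, ref: ReferenceGenome) -> SnpMatrix:
    """Variable-site matrix from a set of consensus sequences."""
    from .core import encode

    L = len(ref)
    samples = [c.sample_id for c in consensus_seqs]
    mat = np.stack([encode(c.sequence) for c in consensus_seqs])
    if mat.shape[1] != L:
        raise ValueError("consensus length does not match reference length")
    called = mat != N
    variable = ((mat != ref.codes[None, :]) & called).any(axis=0)
    positions = np.where(variable)[0]
    return SnpMatrix(
        samples=samples,
        positions1=positions + 1,
        alleles=mat[:, positions],
        ref_alleles=ref.codes[positions],
    )


def missingness(snp_matrix: SnpMatrix, sample: str) -> float:
    """Percentage of the cohort's variable sites at which ``sample`` is N."""
    if sample not in snp_matrix.samples:
        raise KeyError(sample)
    if snp_matrix.n_sites == 0:
        return float("nan")
    row = snp_matrix.row(sample)
    return 100.0 * float((row == N).sum()) / snp_matrix.n_sites
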