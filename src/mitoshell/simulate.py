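"""Synthetic ancient-DNA cohort generator.

Emulates the data underlying a museum-shell mitogenome study: a circular
reference of ~16 kb, a cohort of individual mitogenomes organised into
haplogroups defined by diagnostic SNPs (plus private SNPs per individual),
and short single-end reads carrying terminal cytosine-deamination damage of
the kind left behind by UDG-half library preparation.

The generator is SNP-only (no indels), so every simulated genome shares the
reference coordinate system and downstream consensus sequences are aligned
by construction.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .core import A, C, G, N, T, ReferenceGenome, SequenceRead, decode, encode, revcomp

#: default haplogroup structure: four groups with sizes echoing a
#: North-European flat-oyster cohort (Wadden Sea / North Sea /
#: South-East Atlantic / North-East Atlantic).
DEFAULT_GROUPS = (("WS", 8, 4), ("NS", 10, 4), ("SEA", 13, 4), ("NEA", 4, 3))

#: constant placeholder base quality (the pipeline never filters on quality)
QUAL_CHAR = chr(37 + 33)

MIN_FRAGMENT = 30


@dataclass
class DamageModel:
    """Terminal deamination model with geometric decay.

    C→T substitutions are applied at 5' offset ``i`` with probability
    ``d5_max * lam**i`` for ``i < window``; G→A mirrors this at the 3' end.
    The defaults emulate residual UDG-half damage.
    """

    d5_max: float = 0.3
    d3_max: float = 0.3
    lam: float = 0.5
    window: int = 25

    def __post_init__(self) -> None:
        if not (0.0 <= self.d5_max <= 1.0 and 0.0 <= self.d3_max <= 1.0):
            raise ValueError("damage probabilities must lie in [0, 1]")
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lam must lie in (0, 1)")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    def rate_5p(self, offset: int | np.ndarray) -> np.ndarray:
        """Expected C→T rate at a 5' offset (closed form)."""
        off = np.asarray(offset)
        return np.where(off < self.window, self.d5_max * self.lam**off, 0.0)

    def rate_3p(self, offset: int | np.ndarray) -> np.ndarray:
        off = np.asarray(offset)
        return np.where(off < self.window, self.d3_max * self.lam**off, 0.0)


@dataclass
class SimulationConfig:
    """Study-condition parameters for a synthetic cohort."""

    genome_length: int = 16356
    gc_content: float = 0.36
    groups: tuple = DEFAULT_GROUPS
    private_snps_per_individual: int = 3
    population_of_individual: dict | None = None
    read_length: int = 75
    mean_fragment_length: int = 60
    coverage_per_sample: float | dict = 10.0
    seq_error_rate: float = 0.001
    damage: DamageModel = field(default_factory=DamageModel)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must lie in [0, 1]")
        if not (0.0 <= self.seq_error_rate <= 1.0):
            raise ValueError("seq_error_rate must lie in [0, 1]")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")
        for label, n, n_diag in self.groups:
            if n < 1:
                raise ValueError(f"group {label}: size must be >= 1")
            if n_diag < 0:
                raise ValueError(f"group {label}: n_diagnostic_snps must be >= 0")
        if self.private_snps_per_individual < 0:
            raise ValueError("private_snps_per_individual must be >= 0")
        lo, hi = MIN_FRAGMENT, 2 * self.read_length
        if not (lo < self.mean_fragment_length < (lo + hi) / 2):
            raise ValueError(
                f"mean_fragment_length must lie in ({lo}, {(lo + hi) / 2}) for "
                f"a truncated-geometric fragment model on [{lo}, {hi}]"
            )

    def coverage_for(self, sample_id: str) -> float:
        if isinstance(self.coverage_per_sample, dict):
            return float(self.coverage_per_sample[sample_id])
        return float(self.coverage_per_sample)


@dataclass
class TrueIndividual:
    """A simulated individual genome with its ground truth."""

    id: str
    genome: str
    haplogroup: str
    population: str
    variant_sites: list  # [(pos0, alt_base_char), ...]


@dataclass
class SimulatedCohort:
    """Ground truth for one simulated cohort."""

    reference: ReferenceGenome
    individuals: list
    diagnostic_sites: dict  # label -> [(pos0, alt_base_char), ...]
    config: SimulationConfig


def default_population_map(groups=DEFAULT_GROUPS) -> dict:
    """Population labels for the default cohort.

    Mirrors the study design: one population ('WaddenSea') private for the
    WS haplogroup but sharing NS with a second population, and two
    populations ('Atlantic', 'Mediterranean') drawn from a common
    SEA + NEA pool, giving a true-null population pair.
    """
    mapping = {}
    splits = {
        "WS": [("WaddenSea", None)],
        "NS": [("WaddenSea", 5), ("NorthSea", None)],
        "SEA": [("Atlantic", 7), ("Mediterranean", None)],
        "NEA": [("Atlantic", 2), ("Mediterranean", None)],
    }
    for label, n, _ in groups:
        plan = splits.get(label, [(label, None)])
        idx, used = 0, 0
        for i in range(n):
            pop, cap = plan[idx]
            mapping[f"{label}{i + 1:02d}"] = pop
            used += 1
            if cap is not None and used >= cap and idx < len(plan) - 1:
                idx, used = idx + 1, 0
    return mapping


def generate_reference(length: int, gc: float = 0.36, seed: int = 1,
                       ref_id: str = "ref_mito") -> ReferenceGenome:
    """Draw a random circular reference with the requested GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    return ReferenceGenome(id=ref_id, sequence=decode(codes), circular=True)


def generate_population(ref: ReferenceGenome, cfg: SimulationConfig) -> SimulatedCohort:
    """Build individual genomes organised into diagnostic-SNP haplogroups.

    Diagnostic sites are disjoint between haplogroups; every member of a
    group carries all of that group's diagnostic alleles, while private SNPs
    are drawn independently per individual from the remaining sites.
    """
    L = len(ref)
    n_diag_total = sum(g[2] for g in cfg.groups)
    n_private_max = sum(g[1] for g in cfg.groups) * cfg.private_snps_per_individual
    if n_diag_total + n_private_max >= L:
        raise ValueError("requested variants exceed available sites")

    rng = np.random.default_rng([cfg.seed, 0xD1A6])
    diag_positions = rng.choice(L, size=n_diag_total, replace=False)
    pop_map = cfg.population_of_individual or default_population_map(cfg.groups)

    diagnostic_sites: dict = {}
    offset = 0
    individuals = []
    other_bases = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.uint8)
    for label, n, n_diag in cfg.groups:
        sites = np.sort(diag_positions[offset: offset + n_diag])
        offset += n_diag
        alts = [other_bases[ref.codes[p], rng.integers(3)] for p in sites]
        diagnostic_sites[label] = [(int(p), decode(np.array([a], dtype=np.uint8)))
                                   for p, a in zip(sites, alts)]
        for i in range(n):
            sid = f"{label}{i + 1:02d}"
            genome = ref.codes.copy()
            variants = []
            for (p, a_char), a in zip(diagnostic_sites[label], alts):
                genome[p] = a
                variants.append((p, a_char))
            if cfg.private_snps_per_individual:
                k = cfg.private_snps_per_individual
                cand = rng.choice(L, size=min(L, k + n_diag_total + 8), replace=False)
                avail = cand[~np.isin(cand, diag_positions)][:k]
                for p in avail:
                    a = other_bases[genome[p], rng.integers(3)]
                    genome[p] = a
                    variants.append((int(p), decode(np.array([a], dtype=np.uint8))))
            individuals.append(
                TrueIndividual(
                    id=sid,
                    genome=decode(genome),
                    haplogroup=label,
                    population=pop_map.get(sid, label),
                    variant_sites=sorted(variants),
                )
            )
    return SimulatedCohort(reference=ref, individuals=individuals,
                           diagnostic_sites=diagnostic_sites, config=cfg)


def _fragment_pmf(mean: float, lo: int, hi: int):
    """Truncated-geometric fragment-length pmf on [lo, hi] with given mean."""
    ks = np.arange(lo, hi + 1)

    def mean_for(p):
        w = (1 - p) ** (ks - lo)
        w = w / w.sum()
        return float((ks * w).sum())

    p = brentq(lambda p: mean_for(p) - mean, 1e-9, 1 - 1e-9)
    w = (1 - p) ** (ks - lo)
    return ks, w / w.sum()


def _expected_read_length(cfg: SimulationConfig) -> float:
    ks, pmf = _fragment_pmf(cfg.mean_fragment_length, MIN_FRAGMENT, 2 * cfg.read_length)
    return float((np.minimum(ks, cfg.read_length) * pmf).sum())


def simulate_reads(individual: TrueIndividual, cfg: SimulationConfig) -> list:
    """Simulate damaged single-end reads from one individual.

    Fragments are drawn uniformly from the circular genome (they may span
    the origin); the read is the first ``min(read_length, fragment)`` bases
    of either strand. Deamination damage is applied first, then uniform
    sequencing error. The read id records the truth as
    ``sample:index|start|strand|length``.
    """
    coverage = cfg.coverage_for(individual.id)
    if coverage <= 0:
        return []
    L = cfg.genome_length
    genome = encode(individual.genome)
    doubled = np.concatenate([genome, genome])
    dam = cfg.damage

    rng = np.random.default_rng([cfg.seed, zlib.crc32(individual.id.encode())])
    ks, pmf = _fragment_pmf(cfg.mean_fragment_length, MIN_FRAGMENT, 2 * cfg.read_length)
    exp_len = float((np.minimum(ks, cfg.read_length) * pmf).sum())
    n_reads = int(round(coverage * L / exp_len))

    frag_lens = rng.choice(ks, size=n_reads, p=pmf)
    starts = rng.integers(0, L, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)  # 0 -> '+', 1 -> '-'

    reads = []
    for ridx in range(n_reads):
        f = int(frag_lens[ridx])
        s = int(starts[ridx])
        frag = doubled[s: s + f]
        if strands[ridx]:
            frag = revcomp(frag)
        m = min(cfg.read_length, f)
        bases = frag[:m].copy()

        w = min(dam.window, m)
        # 5' C->T
        off5 = np.arange(w)
        hit = (bases[:w] == C) & (rng.random(w) < dam.d5_max * dam.lam**off5)
        bases[:w][hit] = T
        # 3' G->A (offset measured from the 3' end)
        off3 = np.arange(w)
        tail = bases[m - w:][::-1]
        hit3 = (tail == G) & (rng.random(w) < dam.d3_max * dam.lam**off3)
        tail[hit3] = A
        bases[m - w:] = tail[::-1]

        if cfg.seq_error_rate > 0:
            err = rng.random(m) < cfg.seq_error_rate
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
                bases[err] = (bases[err] + shift) % 4

        strand = "-" if strands[ridx] else "+"
        # reference start of the sequenced part: a '-' read is the revcomp of
        # the fragment, so it covers the fragment's last m bases
        ref_start = s if strand == "+" else (s + f - m) % L
        rid = f"{individual.id}:{ridx}|{ref_start}|{strand}|{m}"
        reads.append(SequenceRead(id=rid, bases=decode(bases), quals=QUAL_CHAR * m))
    return reads


# ---------------------------------------------------------------------------
# text outputs

def write_fasta(path, records, width: int = 70) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_fastq(path, reads) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{r.quals}\n")


def masked_snp_cohort(group_of_sample: dict, missingness_target: dict,
                      n_sites: int = 800, core_sites_per_group: int = 4,
                      invariant_core: int = 48, carrier_prob: float = 0.2,
                      seed: int = 0):
    """Construct a SNP matrix with controlled per-sample missingness.

    Builds group-structured allele patterns directly (no reads). A core of
    sites is called in *all* samples — emulating universally recoverable
    high-coverage positions, which in real shotgun data arise from shared
    mappability/coverage structure: per group, ``core_sites_per_group``
    diagnostic sites (reference C, members carry T) plus ``invariant_core``
    cohort-fixed sites where every sample differs from the reference, in a
    balanced base mix so TN93 stays well-defined even for pairs whose only
    overlap is the core. The remaining sites are group-associated
    low-frequency alleles (each member carries one with probability
    ``carrier_prob``; alt bases rotate over G, C, T so no single difference
    class saturates). Per-sample random masking then sets sites to N until
    each sample reaches its missingness target (percent of sites). The
    lowest-missingness sample of each group anchors its group's sites —
    carrying them all, unmasked — so every site keeps a called
    non-reference allele.
    """
    from .processing import SnpMatrix

    samples = list(group_of_sample)
    groups = sorted(set(group_of_sample.values()))
    n_diag = core_sites_per_group * len(groups)
    n_core = n_diag + invariant_core
    if n_core >= n_sites:
        raise ValueError("core sites must leave room for private sites")
    rng = np.random.default_rng(seed)

    core_of = {g: range(i * core_sites_per_group, (i + 1) * core_sites_per_group)
               for i, g in enumerate(groups)}
    site_group = {}
    site_alt = {}
    alt_cycle = np.array([G, C, T], dtype=np.uint8)
    for j, site in enumerate(range(n_core, n_sites)):
        site_group[site] = groups[j % len(groups)]
        site_alt[site] = alt_cycle[(j // len(groups)) % 3]

    ref_alleles = np.zeros(n_sites, dtype=np.uint8)  # default ref = A
    ref_alleles[:n_diag] = C  # diagnostic sites: ref C, members T
    alleles = np.zeros((len(samples), n_sites), dtype=np.uint8)
    alleles[:, :n_diag] = C
    # cohort-fixed core: everyone carries the same non-reference base, in a
    # balanced rotation over A, C, G, T
    fixed_bases = np.array([A, C, G, T], dtype=np.uint8)[
        np.arange(invariant_core) % 4
    ]
    ref_alleles[n_diag: n_core] = np.where(fixed_bases == G, A, G)
    alleles[:, n_diag: n_core] = fixed_bases[None, :]

    for i, s in enumerate(samples):
        g = group_of_sample[s]
        alleles[i, list(core_of[g])] = T
        own_sites = [p for p, pg in site_group.items() if pg == g]
        carried = [p for p in own_sites if rng.random() < carrier_prob]
        for p in carried:
            alleles[i, p] = site_alt[p]

    n_maskable = n_sites - n_core
    for i, s in enumerate(samples):
        n_mask = int(round(missingness_target[s] / 100.0 * n_sites))
        if n_mask > n_maskable:
            raise ValueError(
                f"sample {s}: missingness target {missingness_target[s]}% "
                "not reachable with the universally-called core"
            )
        chosen = rng.permutation(np.arange(n_core, n_sites))[:n_mask]
        alleles[i, chosen] = N

    # repair: every site must keep >=1 called non-reference allele; flip the
    # allele of a called group member where masking removed all carriers
    # (changes no N, so per-sample missingness is untouched)
    order = {s: missingness_target[s] for s in samples}
    for p in range(n_core, n_sites):
        col = alleles[:, p]
        if (col == site_alt[p]).any():
            continue
        g = site_group[p]
        callable_members = [i for i, s in enumerate(samples)
                            if group_of_sample[s] == g and col[i] != N]
        if not callable_members:
            callable_members = [i for i in range(len(samples)) if col[i] != N]
        if not callable_members:  # everyone masked: unmask one group member
            callable_members = [min(
                (i for i, s in enumerate(samples) if group_of_sample[s] == g),
                key=lambda i: order[samples[i]],
            )]
        pick = min(callable_members, key=lambda i: order[samples[i]])
        alleles[pick, p] = site_alt[p]

    return SnpMatrix(
        samples=samples,
        positions1=np.arange(1, n_sites + 1),
        alleles=alleles,
        ref_alleles=ref_alleles,
    )


def sweep_benchmark_cohort(seed: int = 0):
    """A 65-sample masked cohort for missing-data sweep studies.

    37 samples span 0–88 % missingness and 28 exceed 90 %, mirroring a
    museum-shell cohort in which 37 sequences pass a 90 % missing-SNP filter
    while 28 are removed. Returns (snp_matrix, group_of_sample).
    """
    sizes = {"G1": 17, "G2": 16, "G3": 16, "G4": 16}
    samples = [f"{g}_{i + 1:02d}" for g, n in sizes.items() for i in range(n)]
    group_of_sample = {s: s.split("_")[0] for s in samples}
    # interleave groups so every missingness stratum mixes all four groups
    order = [f"{g}_{i + 1:02d}" for i in range(max(sizes.values()))
             for g, n in sizes.items() if i < n]
    low = np.linspace(0.0, 88.0, 37)
    high = np.linspace(90.5, 91.8, 28)
    targets = {}
    for k, s in enumerate(order):
        targets[s] = float(low[k]) if k < 37 else float(high[k - 37])
    mat = masked_snp_cohort(group_of_sample, targets, n_sites=800,
                            core_sites_per_group=4, invariant_core=48, seed=seed)
    return mat, group_of_sample


def truth_tables(cohort: SimulatedCohort):
    """Return (sample table, variant table) as pandas DataFrames."""
    import pandas as pd

    rows = [
        {
            "sample_id": ind.id,
            "haplogroup": ind.haplogroup,
            "population": ind.population,
            "n_variants": len(ind.variant_sites),
        }
        for ind in cohort.individuals
    ]
    ref = cohort.reference
    vrows = [
        {
            "sample_id": ind.id,
            "pos_1based": p + 1,
            "ref": ref.sequence[p],
            "alt": alt,
        }
        for ind in cohort.individuals
        for p, alt in ind.variant_sites
    ]
    return pd.DataFrame(rows), pd.DataFrame(vrows)
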