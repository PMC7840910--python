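# Methods

This note documents the models, estimators and design choices behind
mitoshell, in the order data flows through the pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort model

The generator replaces unavailable museum material with a fully
ground-truthed stand-in. Its defaults are the study conditions the rest of
the package is exercised under.

**Reference.** A random circular sequence, default 16 356 bp at 36 % GC —
the length and composition of a flat-oyster mitogenome. Positions are
i.i.d.; real mitogenomes have gene structure and strand asymmetry, which
nothing downstream depends on.

**Haplogroups.** Four groups of 8/10/13/4 individuals (labels WS, NS, SEA,
NEA), each defined by 3–4 diagnostic SNPs: sites drawn without replacement,
disjoint between groups, where every member carries the same non-reference
allele. Each individual additionally receives 3 private SNPs at
non-diagnostic positions. Evolution is SNP-only (no indels): the real
analysis is mapping-based against a single reference, so keeping all
genomes in reference coordinates loses nothing and keeps every downstream
coordinate exact.

**Populations.** Population labels are assigned independently of
haplogroups so mixtures can be simulated. The default map mirrors the
study design: "WaddenSea" holds the entire private WS group plus half of
NS; "NorthSea" the other half of NS; "Atlantic" and "Mediterranean" are
both drawn from the common SEA+NEA pool, giving one truly differentiated
population and one true-null population pair.

**Reads.** Fragment lengths follow a geometric distribution truncated to
[30, 2·read_length] with configurable mean (default 60 bp) — ancient-DNA
fragment distributions are short-skewed and no exact family is identifiable
from typical reports. Fragments start uniformly on the circle (they may
span the origin), either strand with probability ½; the read is the first
min(75, fragment) bases. The read count is chosen so the expected yield is
coverage × genome length.

**Damage.** Terminal deamination with geometric decay: C→T at 5′ offset i
with probability d₅·λ^i (i < window), G→A mirrored at the 3′ end; defaults
d₅ = d₃ = 0.3, λ = 0.5, window 25. This is the standard Briggs-style shape
of UDG-half residual damage and is closed-form testable; the true magnitude
in any particular shell series is unknown, so these defaults are
placeholders, not calibrations. Uniform sequencing error (default 10⁻³) is
applied after damage. Base qualities are a constant Q37 placeholder — the
pipeline never filters on quality. A read's id records its true placement
(`sample:index|start|strand|length`), which the mapping round-trip tests
consume.

**Masked SNP cohorts.** For sweep studies a second constructor builds SNP
matrices directly, with exact per-sample missingness targets. Two
deliberate design features: (i) a universally-called core (per-group
diagnostic sites plus cohort-fixed sites in a balanced A/C/G/T rotation)
emulates the shared coverage structure of real shotgun data and keeps TN93
defined even for pairs whose only overlap is the core; (ii) group-private
alleles are carried by only ~20 % of members and rotate over G/C/T alt
bases — on a variable-sites-only matrix, group-*fixed* private alleles
would put whole-group divergence in one TN93 difference class and saturate
the logarithms. The 65-sample benchmark instance spans 0–88 % missingness
for 37 samples and 90.5–91.8 % for 28, so a 90 % filter retains exactly 37.

## Read processing

**Circular mapping.** Exact minimum-mismatch placement of each read (both
strands) on the doubled reference, coordinates reported modulo L. A read
is unmapped when its best placement exceeds ⌈0.1·length⌉ mismatches — a
stand-in for the unstated stringency of standard aDNA mappers. Exactness
at speed comes from the pigeonhole principle: with mismatch ceiling k, the
read is cut into k+1 disjoint seeds; any placement within the ceiling
matches at least one seed exactly (N counts as a mismatch, and seeds
containing N are skipped, which preserves the argument). Seed hits are
gathered from a sorted base-4 index of all reference windows and candidates
are verified with vectorised mismatch counts; reads whose seeds would be
shorter than 5 bp fall back to an exhaustive scan. Ties break toward the
smallest wrapped start, then '+' strand. Damage is not scored specially:
UDG-half damage is terminal and sparse, and a damaged base simply costs one
mismatch.

**Deduplication.** One representative per (start, end, strand) triple —
the criterion used by standard aDNA duplicate removers. The representative
is the alignment with the most called bases, ties to the smallest read id;
the operation is idempotent.

**Damage profiling.** Per 5′ offset i: the fraction of reference-C
positions read as T among reads covering that offset (3′: G→A), computed
in read orientation from mapped alignments. Offsets with zero
opportunities report NaN, never 0.

**Consensus.** Per site: the most frequent base if depth ≥ 3 *and* its
frequency strictly exceeds ½, else N; exact ties are N. The published
pipeline states only the 3× floor; the strict majority and tie→N choices
favour N, matching the heavy use of N in the original consensus set.

**SNP matrix and missingness.** Variable sites are the union over samples
of called-and-non-reference positions; each sample's missingness is the
percentage of those sites at which it is N. The union definition (rather
than a per-sample VCF denominator) is the only one under which per-sample
percentages are comparable across a cohort.

## Phylogenetics

**TN93.** Estimated per pair under pairwise deletion, with base
frequencies from the pooled pair (a per-pair property; alignment-wide
frequencies can be supplied instead). A distance is undefined when the
pair shares fewer than ⌊0.05·alignment length⌋ called sites or any
logarithm argument is non-positive; undefined entries are NaN, and tree
building refuses matrices containing them, naming the offending pair.

**Neighbour joining.** Standard Saitou–Nei Q-criterion; ties break toward
the lexicographically smallest pair of cluster names (a cluster is named
by its smallest leaf label), so results are label-order invariant.
Negative branch lengths are clamped to zero. The output is an unrooted
tree with a trifurcating final join.

**Bootstrap.** Columns resampled with replacement; replicate r uses seed
seed+r. An internal edge's support is the percentage of usable replicates
containing the same bipartition; a replicate bipartition is counted only
if its edge length is positive (a zero-length edge is an unresolved tie
carrying no signal — without this rule, deterministic tie-breaking would
manufacture 100 % support from identical sequences). Replicates whose
distance matrix contains undefined entries are dropped and counted.
Branches with support strictly below 35 % are collapsed; the collapse is
idempotent and never touches leaf edges.

**GTR maximum likelihood.** Stationary frequencies fixed at the empirical
base composition; six exchangeabilities with GT as the reference rate; Q
normalised to one expected substitution per unit branch length and
exponentiated via the symmetric similarity transform. Pruning treats N as
missing data (partial vector of ones) and includes all sites, constant
ones too; per-node rescaling guards against underflow. Fitting is
coordinate ascent — bounded scalar optimisation of each branch length and
each free exchangeability — plus an NNI pass accepting improving swaps,
until the round gain falls below 10⁻⁶ or a round cap; the log-likelihood
is non-decreasing by construction. No rate heterogeneity (no Γ): the
original analysis used all sites with a single rate class. Supports for
the ML topology are taken from distance-bootstrap replicates (default 500)
mapped onto its bipartitions; full per-replicate ML refits of ~40-taxon
trees are beyond a single-CPU pure-Python budget, and on the synthetic
cohorts NJ and ML topologies agree.

**Missingness sweep.** For thresholds 95→60 in 5 % steps: retain samples
at or below the threshold (sets are nested by construction), build a
TN93/NJ tree with bootstrap supports, record mean internal support and the
Robinson–Foulds distance to the previous threshold's tree on shared taxa.
Thresholds retaining fewer than four samples, or whose distance matrix has
undefined entries, are recorded but carry no tree. The selected threshold
is the largest one whose mean support is within 2 points of the maximum —
the most inclusive near-optimal choice. "Compare phylogenies" has no
published operationalisation; mean support plus RF distance is this
package's.

**Haplogroups.** Candidate clades are both sides of every internal edge
(the tree is unrooted) of the support-collapsed tree with support ≥ 35 %.
A site is diagnostic for a clade iff at least two members have called
bases, every called member carries the same allele, that allele differs
from the reference, and no non-member's called base equals it. Tolerating
N lets heavily masked samples join clades; requiring ≥ 2 called members
stops singleton clades from qualifying trivially; polarising against the
reference stops the complement of a real clade from inheriting
"diagnostic" reference alleles. Clades with ≥ 2 diagnostic sites are
accepted largest-first, disjointly; remaining samples are UNASSIGNED.
Haplogroup labels (HG01, …) are arbitrary; correctness is a statement
about member sets.

## Population genetics

Sequence information is reduced to haplogroup membership — within-group
nucleotide diversity is deliberately discarded; unassigned samples are
carried as their own private alleles.

**Estimators.** For a k-population count table with frequencies p_ij:
H_S = (1/k)Σ_j(1−Σ_i p_ij²), H_T = 1−Σ_i p̄_i² (unweighted means), naive
G_ST = (H_T−H_S)/H_T, defined as 0 when H_T = 0. The Nei–Chesser
haploid correction uses the harmonic mean ñ: H_S′ = ñ/(ñ−1)·H_S,
H_T′ = H_T + H_S′/(ñk). Jost's D = (k/(k−1))·(H_T′−H_S′)/(1−H_S′);
negative D estimates (a finite-sample artifact visible for identical
populations) are truncated to 0. Both G_ST variants are reported side by
side throughout.

**Multilocus (sequence) mode.** Feeding per-haplogroup representative
sequences — each replicated once per individual — through a multilocus
G_ST implementation aggregates per-site diversities as
(ΣH_T − ΣH_S)/ΣH_T, with per-site sample sizes equal to the called
individuals at that site and sites requiring ≥ 2 called per population.
Single-locus haplogroup counts do **not** reproduce the published pairwise
matrix under any count vector or estimator variant; the multilocus
corrected estimator does, which identifies it as the computation actually
behind those values.

**Representative substitution.** Per haplogroup, the member with the
fewest N (ties: higher mean depth, then smallest id) is copied once per
member, preserving sample ids — after which within-haplogroup distances
are exactly 0.

**Permutation tests.** Individuals' labels are reshuffled between the two
populations preserving sizes; p is the plain proportion of permuted
statistics ≥ observed (no +1 correction, matching published p-values such
as 0.004 at 1000 permutations). When the number of distinct assignments
C(n, n₁) does not exceed the permutation budget, the test enumerates them
exactly. Populations with fewer than 4 individuals are excluded from
pairwise analyses.

**Published-matrix reconstruction.** The per-population haplogroup counts
behind the published pairwise matrix are not shipped with the study, so
they are recovered as an inverse problem: enumerate count vectors
consistent with the published sizes and allele lists (singleton alleles
fixed at 1); a vector is feasible when non-negative per-site bipartition
counts reproducing every pairwise value exist (LP feasibility — each
published value is one homogeneous linear constraint on the pattern
counts); integer pattern counts within 5×10⁻⁵ of all six values are then
found by mixed-integer programming. One such configuration (counts
WaddenSea NS=12/WS=8, England NS=1/NEA=1/singleton/SEA=4, Atlantic
NEA=2/SEA=6, Mediterranean singleton/SEA=3; 335 variable sites over 11
bipartition classes) is frozen in `data/oyster1870s_counts_synthetic.json`,
clearly labelled synthetic: it is *a* configuration reproducing the
published matrix, not recovered field data. The acceptance script re-runs
the LP count-vector search at run time and recomputes the matrix through
the ordinary popgen code path.

## Pipeline

Stages (simulate → process → phylo → popgen) share one master seed; every
stage's randomness is derived from it (sweep seed+1000, NJ bootstrap
+2000, ML supports +3000, permutations +4000), so reruns are
byte-identical, which the report's sha256 digests make checkable. Stage
failures abort with the stage name and rename partial outputs to
`*.partial`. The CLI (`mitoshell simulate|process|phylo|popgen|run-all|validate`)
is a thin layer over these library calls; exit codes are 0/1/2 for
success/config error/data error.

## Problem sizes and what the tests show

Unit and acceptance tests run the full chain on 2–5 kb genomes and the
acceptance script on the full 16 356 bp reference with 35 individuals at
10× coverage; the damage-recovery check uses ~10⁵ reads and the sweep
benchmark 65 samples × 800 sites. Passing tests demonstrate internal
correctness of every estimator against independent oracles and full
recovery under the generator's assumptions — clean circular reference,
SNP-only divergence, uniform fragment starts, geometric terminal damage.
They do not certify behaviour under features the generator omits:
contamination, heteroplasmy, indels and structural variation, reference
bias, mappability structure, or per-cycle error profiles.

## Known limitations

* The mapper is exhaustive-exact but single-reference and ungapped; reads
  from regions absent in the reference cannot be placed.
* TN93 saturates (undefined) for deeply diverged pairs on variable-site
  matrices; the sweep records such thresholds instead of guessing.
* ML support values are distance-bootstrap approximations (above).
* The recovered count configuration is one member of the feasible set;
  population sizes in the published matrix cannot be fully reconciled with
  the published sequence count from the main-text numbers alone.
* Damage magnitudes are plausible defaults, not calibrated to any
  particular shell series.
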