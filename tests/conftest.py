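import numpy as np
import pytest

from mitoshell.core import encode
from mitoshell.simulate import (
    DamageModel,
    SimulationConfig,
    generate_population,
    generate_reference,
)


@pytest.fixture(scope="session")
def small_ref():
    """A 3 kb circular reference — large enough that 75-mers are unique."""
    return generate_reference(length=3000, gc=0.36, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_ref):
    """Four tiny haplogroups on the 3 kb reference, no sequencing reads."""
    cfg = SimulationConfig(
        genome_length=3000,
        groups=(("WS", 3, 3), ("NS", 4, 3), ("SEA", 4, 3), ("NEA", 2, 3)),
        private_snps_per_individual=2,
        coverage_per_sample=10.0,
        seq_error_rate=0.0,
        seed=11,
    )
    return generate_population(small_ref, cfg)


@pytest.fixture(scope="session")
def clean_config():
    """Damage-free, error-free read simulation config on the 3 kb genome."""
    return SimulationConfig(
        genome_length=3000,
        groups=(("WS", 2, 2), ("NS", 2, 2)),
        private_snps_per_individual=0,
        coverage_per_sample=8.0,
        seq_error_rate=0.0,
        damage=DamageModel(d5_max=0.0, d3_max=0.0, lam=0.5, window=25),
        seed=5,
    )


def hamming(a: str, b: str) -> int:
    return int((encode(a) != encode(b)).sum())


def scan_diagnostic_sites(cohort):
    """Brute-force oracle: a site is diagnostic for a group iff every member
    carries the same non-reference allele there and no non-member does."""
    ref = cohort.reference.codes
    genomes = {ind.id: encode(ind.genome) for ind in cohort.individuals}
    groups = {}
    for ind in cohort.individuals:
        groups.setdefault(ind.haplogroup, []).append(ind.id)
    found = {}
    for label, members in groups.items():
        non_members = [i for i in genomes if i not in members]
        sites = []
        for pos in range(len(ref)):
            alleles = {genomes[m][pos] for m in members}
            if len(alleles) != 1:
                continue
            a = alleles.pop()
            if a == ref[pos]:
                continue
            if any(genomes[o][pos] == a for o in non_members):
                continue
            sites.append(pos)
        found[label] = sites
    return found
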