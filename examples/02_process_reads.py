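"""Process damaged reads for one sample: circular mapping, duplicate
removal, damage profiling and 3x-consensus calling.

The damage table should show the simulated geometric decay (30% C->T at
the first 5' position, halving per position); the consensus N fraction
reflects sites below the 3-read depth floor.
"""
from mitoshell.processing import (
    build_pileup,
    call_consensus,
    damage_profile,
    deduplicate,
    map_reads_circular,
)
from mitoshell.simulate import (
    SimulationConfig,
    generate_population,
    generate_reference,
    simulate_reads,
)

cfg = SimulationConfig(genome_length=5000, groups=(("WS", 1, 3),),
                       coverage_per_sample=8.0, seed=4)
ref = generate_reference(cfg.genome_length, cfg.gc_content, seed=cfg.seed)
cohort = generate_population(ref, cfg)
ind = cohort.individuals[0]

reads = simulate_reads(ind, cfg)
alignments = map_reads_circular(reads, ref)
mapped = [a for a in alignments if a.mapped]
dedup = deduplicate(mapped)
print(f"{len(reads)} reads: {len(mapped)} mapped, "
      f"{len(mapped) - len(dedup)} duplicates removed")

profile = damage_profile(dedup, ref, window=6)
print("\n5' offset  C->T freq   3' offset  G->A freq")
for i in range(6):
    print(f"{i:<10} {profile.ct5[i]:.3f}       {i:<10} {profile.ga3[i]:.3f}")

pileup = build_pileup(dedup, ref)
consensus = call_consensus(pileup, ref, ind.id, min_depth=3)
n_frac = consensus.sequence.count("N") / len(consensus.sequence)
print(f"\nconsensus {ind.id}: mean depth {pileup.depth.mean():.1f}x, "
      f"{100 * n_frac:.1f}% N (sites failing the 3x/majority rule)")
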