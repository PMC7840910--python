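"""Circular mapping, dedup, damage profiling, consensus and SNP extraction."""
import math

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from mitoshell.core import N, ReferenceGenome, encode, revcomp, revcomp_str
from mitoshell.processing import (
    Alignment,
    ConsensusSequence,
    Pileup,
    build_pileup,
    call_consensus,
    damage_profile,
    deduplicate,
    extract_snps,
    map_reads_circular,
    missingness,
)
from mitoshell.simulate import (
    DamageModel,
    SimulationConfig,
    generate_population,
    generate_reference,
    simulate_reads,
)


def naive_map(codes, ref):
    """Oracle: exhaustive minimum-mismatch search on the doubled reference."""
    L = len(ref)
    doubled = np.concatenate([ref.codes, ref.codes]).astype(np.int64)
    best = None
    m = len(codes)
    for rank, oriented in enumerate((codes.astype(np.int64),
                                     revcomp(codes).astype(np.int64))):
        win = sliding_window_view(doubled, m)[:L]
        mm = (win != oriented[None, :]).sum(axis=1)
        i = int(np.lexsort((np.arange(L), mm))[0])
        cand = (int(mm[i]), i, rank)
        if best is None or cand < best:
            best = cand
    mm, start, rank = best
    return mm, start, "+-"[rank], mm <= math.ceil(0.1 * m)


def mkread(rid, bases):
    from mitoshell.core import SequenceRead

    return SequenceRead(id=rid, bases=bases, quals="F" * len(bases))


class TestMapping:
    def test_exact_read_maps_to_origin_position(self, small_ref):
        read = mkread("r1", small_ref.sequence[100:160])
        aln = map_reads_circular([read], small_ref)[0]
        assert (aln.start, aln.strand, aln.n_mismatches, aln.mapped) == (100, "+", 0, True)

    def test_origin_spanning_read(self, small_ref):
        L = len(small_ref)
        seq = (small_ref.sequence * 2)[L - 30: L + 30]
        aln = map_reads_circular([mkread("r1", seq)], small_ref)[0]
        assert (aln.start, aln.n_mismatches) == (L - 30, 0)
        assert aln.end == L + 30  # wrapped placement

    def test_reverse_complement_same_start(self, small_ref):
        fwd = small_ref.sequence[500:560]
        aln = map_reads_circular([mkread("r1", revcomp_str(fwd))], small_ref)[0]
        assert (aln.start, aln.strand) == (500, "-")

    def test_agrees_with_naive_oracle(self, small_ref):
        rng = np.random.default_rng(42)
        reads = []
        # genuine reads with a few injected mismatches, plus pure junk
        for i in range(40):
            start = int(rng.integers(0, len(small_ref)))
            m = int(rng.integers(30, 76))
            seq = list((small_ref.sequence * 2)[start: start + m])
            for _ in range(int(rng.integers(0, 4))):
                j = int(rng.integers(0, m))
                seq[j] = "ACGT"[int(rng.integers(4))]
            s = "".join(seq)
            if rng.random() < 0.5:
                s = revcomp_str(s)
            reads.append(mkread(f"real{i}", s))
        for i in range(10):
            s = "".join("ACGT"[int(rng.integers(4))] for _ in range(60))
            reads.append(mkread(f"junk{i}", s))
        alns = map_reads_circular(reads, small_ref)
        for read, aln in zip(reads, alns):
            mm, start, strand, mapped = naive_map(encode(read.bases), small_ref)
            assert aln.mapped == mapped
            if mapped:
                assert (aln.n_mismatches, aln.start, aln.strand) == (mm, start, strand)

    def test_mapping_round_trip(self, small_ref, clean_config):
        # zero damage, zero error: >=99.9% of reads recover (start, strand)
        cohort = generate_population(small_ref, clean_config)
        ind = cohort.individuals[0]
        reads = simulate_reads(ind, clean_config)
        alns = map_reads_circular(reads, small_ref)
        ok = 0
        for r, aln in zip(reads, alns):
            _, start, strand, _ = r.id.split("|")
            ok += aln.mapped and aln.start == int(start) and aln.strand == strand
        assert ok / len(reads) >= 0.999

    def test_empty_read_set(self, small_ref):
        assert map_reads_circular([], small_ref) == []


class TestDeduplicate:
    @staticmethod
    def _aln(rid, start, end, strand, bases=None):
        m = end - start
        b = encode("A" * m) if bases is None else bases
        return Alignment(rid, start, end, strand, 0, True, b)

    def test_unique_placements_unchanged(self):
        alns = [self._aln(f"r{i}", i * 10, i * 10 + 50, "+") for i in range(5)]
        assert set(a.read_id for a in deduplicate(alns)) == {a.read_id for a in alns}

    def test_five_sharing_one_survivor(self):
        alns = [self._aln(f"r{i}", 7, 57, "-") for i in range(5)]
        out = deduplicate(alns)
        assert len(out) == 1
        assert out[0].read_id == "r0"  # lexicographic tie-break

    def test_most_called_bases_wins(self):
        gappy = encode("ANNNA" + "A" * 45)
        full = encode("A" * 50)
        alns = [self._aln("a_gappy", 0, 50, "+", gappy),
                self._aln("z_full", 0, 50, "+", full)]
        assert deduplicate(alns)[0].read_id == "z_full"

    def test_survivor_count_matches_triple_set(self):
        rng = np.random.default_rng(1)
        alns = []
        for i in range(200):
            start = int(rng.integers(0, 20))
            m = int(rng.integers(1, 4)) * 10
            strand = "+-"[int(rng.integers(2))]
            alns.append(self._aln(f"r{i}", start, start + m, strand))
        expected = len({(a.start, a.end, a.strand) for a in alns})
        assert len(deduplicate(alns)) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        alns = [self._aln(f"r{i}", int(rng.integers(5)), int(rng.integers(5)) + 50, "+")
                for i in range(30)]
        once = deduplicate(alns)
        assert deduplicate(once) == once


class TestDamageProfile:
    def test_damage_free_all_zero(self, small_ref, clean_config):
        cohort = generate_population(small_ref, clean_config)
        reads = simulate_reads(cohort.individuals[0], clean_config)
        alns = map_reads_circular(reads, small_ref)
        prof = damage_profile(alns, small_ref, window=10)
        assert np.nanmax(prof.ct5) == 0.0
        assert np.nanmax(prof.ga3) == 0.0

    def test_window_size(self, small_ref, clean_config):
        cohort = generate_population(small_ref, clean_config)
        reads = simulate_reads(cohort.individuals[0], clean_config)[:50]
        alns = map_reads_circular(reads, small_ref)
        prof = damage_profile(alns, small_ref, window=25)
        assert len(prof.ct5) == len(prof.ga3) == 25

    def test_recovers_simulated_rates(self, small_ref):
        dam = DamageModel(d5_max=0.3, d3_max=0.3, lam=0.5, window=25)
        cfg = SimulationConfig(
            genome_length=3000, groups=(("A", 1, 0),), private_snps_per_individual=0,
            coverage_per_sample=400.0, seq_error_rate=0.0, damage=dam, seed=3,
        )
        cohort = generate_population(small_ref, cfg)
        reads = simulate_reads(cohort.individuals[0], cfg)
        alns = map_reads_circular(reads, small_ref)
        prof = damage_profile(alns, small_ref, window=5)
        for off in (0, 1):
            expected = dam.d5_max * dam.lam**off
            se = math.sqrt(expected * (1 - expected) / prof.n5[off])
            assert abs(prof.ct5[off] - expected) < 3 * se
            expected3 = dam.d3_max * dam.lam**off
            se3 = math.sqrt(expected3 * (1 - expected3) / prof.n3[off])
            assert abs(prof.ga3[off] - expected3) < 3 * se3

    def test_zero_denominator_is_nan(self):
        ref = ReferenceGenome(id="r", sequence="ATTA" * 30)  # no C anywhere
        aln = Alignment("x", 0, 20, "+", 0, True, ref.codes[:20].copy())
        prof = damage_profile([aln], ref, window=3)
        assert np.isnan(prof.ct5).all()  # no C opportunities at all


class TestPileupConsensus:
    def test_single_alignment_increments_its_span(self, small_ref):
        aln = Alignment("r", 10, 70, "+", 0, True, small_ref.codes[10:70].copy())
        pile = build_pileup([aln], small_ref)
        assert (pile.depth > 0).sum() == 60
        assert pile.depth[10:70].min() == 1

    def test_uncovered_position_zero(self, small_ref):
        pile = build_pileup([], small_ref)
        assert pile.depth.sum() == 0

    def test_mean_depth_near_requested_coverage(self, small_ref, clean_config):
        cohort = generate_population(small_ref, clean_config)
        ind = cohort.individuals[0]
        reads = simulate_reads(ind, clean_config)
        alns = map_reads_circular(reads, small_ref)
        pile = build_pileup(alns, small_ref)
        assert abs(pile.depth.mean() / clean_config.coverage_for(ind.id) - 1) < 0.1

    def test_origin_spanning_contributes_wrapped(self, small_ref):
        L = len(small_ref)
        bases = np.concatenate([small_ref.codes[L - 30:], small_ref.codes[:30]])
        aln = Alignment("r", L - 30, L + 30, "+", 0, True, bases)
        pile = build_pileup([aln], small_ref)
        assert pile.depth[:30].min() == 1 and pile.depth[L - 30:].min() == 1

    @pytest.mark.parametrize(
        "column,expected",
        [
            ({"T": 2}, "N"),  # below the 3x floor
            ({"T": 3}, "T"),  # at the floor
            ({"C": 2, "T": 2}, "N"),  # strict tie
            ({"C": 3, "T": 1}, "C"),  # majority at depth 4
            ({"C": 2, "T": 1, "G": 1}, "N"),  # 0.5 majority is strict
        ],
    )
    def test_consensus_rules(self, column, expected):
        ref = ReferenceGenome(id="r", sequence="ACGT")
        counts = np.zeros((4, 4), dtype=np.int64)
        for base, n in column.items():
            counts[0, "ACGT".index(base)] = n
        cons = call_consensus(Pileup(counts), ref, "s")
        assert cons.sequence[0] == expected

    def test_every_called_base_has_min_depth(self, small_ref, clean_config):
        cohort = generate_population(small_ref, clean_config)
        ind = cohort.individuals[0]
        alns = deduplicate(map_reads_circular(simulate_reads(ind, clean_config), small_ref))
        pile = build_pileup(alns, small_ref)
        cons = call_consensus(pile, small_ref, ind.id, min_depth=3)
        called = encode(cons.sequence) != N
        assert (pile.depth[called] >= 3).all()


def _cons(sample_id, seq):
    return ConsensusSequence(sample_id=sample_id, sequence=seq,
                             depth=np.full(len(seq), 5))


class TestSnpMatrix:
    def test_single_mismatch_pos_is_1based(self):
        ref = ReferenceGenome(id="r", sequence="ACGTACGTAC")
        sample = _cons("s1", "ACGTTCGTAC")  # mismatch at 1-based pos 5
        mat = extract_snps([sample, _cons("s2", ref.sequence)], ref)
        assert list(mat.positions1) == [5]

    def test_reference_identical_sample_contributes_nothing(self):
        ref = ReferenceGenome(id="r", sequence="ACGTACGTAC")
        a = _cons("a", ref.sequence)
        b = _cons("b", "ACGTACGTAT")
        mat = extract_snps([a, b], ref)
        assert mat.n_sites == 1
        assert mat.row("a")[0] == ref.codes[-1]  # all-reference at others' sites

    def test_union_matches_column_scan_oracle(self, small_cohort):
        ref = small_cohort.reference
        seqs = [_cons(i.id, i.genome) for i in small_cohort.individuals]
        mat = extract_snps(seqs, ref)
        stacked = np.stack([encode(i.genome) for i in small_cohort.individuals])
        oracle = sum(
            1 for col in range(stacked.shape[1])
            if ((stacked[:, col] != ref.codes[col]) & (stacked[:, col] != N)).any()
        )
        assert mat.n_sites == oracle

    def test_inconsistent_lengths_rejected(self):
        ref = ReferenceGenome(id="r", sequence="ACGTACGTAC")
        with pytest.raises(ValueError):
            extract_snps([_cons("a", "ACGT")], ref)

    @pytest.mark.parametrize(
        "row,expected",
        [("TTTTTTTTTT", 0.0), ("N" * 10, 100.0), ("NNNTTTTTTT", 30.0)],
    )
    def test_missingness_values(self, row, expected):
        ref = ReferenceGenome(id="r", sequence="A" * 10)
        mat = extract_snps([_cons("x", "T" * 10), _cons("y", row)], ref)
        assert missingness(mat, "y") == pytest.approx(expected)

    def test_missingness_no_sites_nan(self):
        ref = ReferenceGenome(id="r", sequence="ACGT")
        mat = extract_snps([_cons("x", ref.sequence)], ref)
        assert math.isnan(missingness(mat, "x"))


class TestEndToEndRecovery:
    def test_alleles_recovered_at_truth_sites(self, small_ref):
        cfg = SimulationConfig(
            genome_length=3000,
            groups=(("WS", 2, 3), ("NS", 2, 3)),
            private_snps_per_individual=2,
            coverage_per_sample=10.0,
            seq_error_rate=0.0,
            damage=DamageModel(d5_max=0.2, d3_max=0.2, lam=0.5, window=25),
            seed=13,
        )
        cohort = generate_population(small_ref, cfg)
        for ind in cohort.individuals:
            reads = simulate_reads(ind, cfg)
            alns = deduplicate(map_reads_circular(reads, small_ref))
            pile = build_pileup(alns, small_ref)
            cons = call_consensus(pile, small_ref, ind.id, min_depth=3)
            codes = encode(cons.sequence)
            truth = encode(ind.genome)
            checked = matched = 0
            for pos, _ in ind.variant_sites:
                if pile.depth[pos] >= 3 and codes[pos] != N:
                    checked += 1
                    matched += codes[pos] == truth[pos]
            if checked:
                assert matched / checked >= 0.99
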