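"""Gene-diversity differentiation: G_ST, Jost's D, permutation tests."""
import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from mitoshell.popgen import (
    _allele_gst_statistic,
    allele_counts,
    group_populations,
    gst_nei,
    gst_nei_sequences,
    jost_d,
    jost_d_sequences,
    pairwise_matrix,
    permutation_test,
    representative_substitution,
)


def rational_gst(count_rows, corrected=False):
    """Exact-arithmetic oracle for the two-population G_ST variants."""
    k = len(count_rows)
    sizes = [sum(row) for row in count_rows]
    freqs = [[Fraction(c, n) for c in row] for row, n in zip(count_rows, sizes)]
    hs = sum(1 - sum(f * f for f in row) for row in freqs) / Fraction(k)
    pbar = [sum(col) / Fraction(k) for col in zip(*freqs)]
    ht = 1 - sum(p * p for p in pbar)
    if not corrected:
        return float((ht - hs) / ht) if ht else 0.0
    ntilde = Fraction(k) / sum(Fraction(1, n) for n in sizes)
    hs_c = ntilde / (ntilde - 1) * hs
    ht_c = ht + hs_c / (ntilde * k)
    return float((ht_c - hs_c) / ht_c) if ht_c else 0.0


def rational_jost_d(count_rows):
    k = len(count_rows)
    sizes = [sum(row) for row in count_rows]
    freqs = [[Fraction(c, n) for c in row] for row, n in zip(count_rows, sizes)]
    hs = sum(1 - sum(f * f for f in row) for row in freqs) / Fraction(k)
    pbar = [sum(col) / Fraction(k) for col in zip(*freqs)]
    ht = 1 - sum(p * p for p in pbar)
    ntilde = Fraction(k) / sum(Fraction(1, n) for n in sizes)
    hs_c = ntilde / (ntilde - 1) * hs
    ht_c = ht + hs_c / (ntilde * k)
    return float(Fraction(k, k - 1) * (ht_c - hs_c) / (1 - hs_c))


def table(rows, alleles=None):
    alleles = alleles or [f"a{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))],
                        columns=alleles)


class TestGst:
    def test_identical_frequencies_zero(self):
        res = gst_nei(table([[6, 4], [6, 4]]))
        assert res.gst == pytest.approx(0.0, abs=1e-15)

    def test_complete_fixation(self):
        res = gst_nei(table([[10, 0], [0, 10]]))
        assert res.h_s == 0.0
        assert res.h_t == pytest.approx(0.5)
        assert res.gst == 1.0

    @pytest.mark.parametrize(
        "rows",
        [
            [[8, 12, 0, 0], [0, 0, 3, 1]],
            [[20, 0, 5, 2], [1, 3, 3, 1]],
            [[5, 5], [2, 8]],
            [[12, 8, 0], [1, 1, 5]],
        ],
    )
    def test_matches_rational_oracle(self, rows):
        res = gst_nei(table(rows))
        assert res.gst == pytest.approx(rational_gst(rows), abs=1e-12)
        assert res.gst_corrected == pytest.approx(
            rational_gst(rows, corrected=True), abs=1e-12)

    def test_bounds_and_relabelling_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            rows = rng.integers(0, 12, size=(2, 4))
            rows[:, 0] += 1  # nonempty populations
            res = gst_nei(table(rows.tolist()))
            assert 0.0 <= res.gst <= 1.0
            perm = rng.permutation(4)
            res2 = gst_nei(table(rows[:, perm].tolist()))
            assert res2.gst == pytest.approx(res.gst, abs=1e-12)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            gst_nei(table([[0, 0], [3, 1]]))


class TestJostD:
    def test_identical_populations_zero(self):
        assert jost_d(table([[5, 5], [5, 5]])) == pytest.approx(0.0, abs=1e-12)

    def test_fixation_limit_approaches_one(self):
        assert jost_d(table([[500, 0], [0, 500]])) == pytest.approx(1.0, abs=5e-3)

    def test_three_allele_toy_matches_hand_formula(self):
        rows = [[4, 3, 1], [1, 2, 5]]
        assert jost_d(table(rows)) == pytest.approx(rational_jost_d(rows), abs=1e-12)


class TestSequenceMode:
    def test_matches_single_locus_on_one_column(self):
        # one variable column: sequence mode must equal the count-table path
        seqs = np.array([[0], [0], [1], [1], [1], [2]], dtype=np.uint8)
        rows = [np.arange(3), np.arange(3, 6)]
        res_seq = gst_nei_sequences(seqs, rows)
        res_tab = gst_nei(table([[2, 1, 0], [0, 2, 1]]))
        assert res_seq.gst == pytest.approx(res_tab.gst, abs=1e-12)
        assert res_seq.gst_corrected == pytest.approx(res_tab.gst_corrected, abs=1e-12)
        assert jost_d_sequences(seqs, rows) == pytest.approx(
            jost_d(table([[2, 1, 0], [0, 2, 1]])), abs=1e-12)

    def test_aggregation_over_sites_is_ratio_of_sums(self):
        rng = np.random.default_rng(2)
        seqs = rng.integers(0, 3, size=(8, 30)).astype(np.uint8)
        rows = [np.arange(4), np.arange(4, 8)]
        res = gst_nei_sequences(seqs, rows)
        num = den = 0.0
        for col in range(30):
            r = gst_nei_sequences(seqs[:, col: col + 1], rows)
            num += r.h_t - r.h_s
            den += r.h_t
        assert res.gst == pytest.approx(num / den, abs=1e-12)

    def test_substitution_makes_within_group_distance_zero(self):
        rng = np.random.default_rng(1)
        groups = {}
        for g in ("X", "Y"):
            members = []
            for i in range(4):
                seq = rng.integers(0, 4, size=50).astype(np.uint8)
                n_missing = int(rng.integers(0, 10))
                members.append((f"{g}{i}", seq, n_missing, 5.0))
            groups[g] = members
        expanded, chosen = representative_substitution(groups)
        for g, members in groups.items():
            rep_id = chosen[g]
            rep_seq = dict((m[0], m[1]) for m in members)[rep_id]
            best_missing = min(m[2] for m in members)
            assert dict((m[0], m[2]) for m in members)[rep_id] == best_missing
            for m in members:
                np.testing.assert_array_equal(expanded[m[0]], rep_seq)

    def test_group_of_eight_yields_eight_copies(self):
        seq = np.zeros(10, dtype=np.uint8)
        groups = {"A": [(f"s{i}", seq, i, 1.0) for i in range(8)]}
        expanded, chosen = representative_substitution(groups)
        assert len(expanded) == 8
        assert chosen["A"] == "s0"  # fewest N


class TestGroupPopulations:
    def test_merge_and_exclusion(self):
        locs = {f"s{i}": loc for i, loc in enumerate(
            ["Germany", "Denmark", "Germany", "Denmark", "Netherlands",
             "England", "England", "England", "England"])}
        rules = {"Germany": "WaddenSea", "Denmark": "WaddenSea",
                 "Netherlands": "Netherlands", "England": "England"}
        pm = group_populations(locs, rules, min_n=4)
        assert pm.population_of["s0"] == "WaddenSea"
        assert "Netherlands" in pm.excluded  # n=1 < 4
        assert set(pm.retained) == {"WaddenSea", "England"}

    def test_min_n_one_keeps_everything(self):
        pm = group_populations({"a": "X", "b": "Y"}, {"X": "X", "Y": "Y"}, min_n=1)
        assert pm.excluded == []

    def test_unmapped_location_named_in_error(self):
        with pytest.raises(KeyError, match="Atlantis"):
            group_populations({"a": "Atlantis"}, {"X": "X"})


class TestPermutation:
    def test_exact_three_vs_three_matches_enumeration_oracle(self):
        items = ["A", "A", "B", "A", "B", "B"]
        stat = _allele_gst_statistic("naive")
        res = permutation_test(items, 3, stat, method="exact")
        assert res["n_permutations"] == 20
        # independent oracle with the rational G_ST
        obs = rational_gst([[2, 1], [1, 2]])
        hits = 0
        for combo in itertools.combinations(range(6), 3):
            g1 = [items[i] for i in combo]
            g2 = [items[i] for i in range(6) if i not in combo]
            c1 = [g1.count("A"), g1.count("B")]
            c2 = [g2.count("A"), g2.count("B")]
            if rational_gst([c1, c2]) >= obs - 1e-12:
                hits += 1
        assert res["p_value"] == pytest.approx(hits / 20)

    def test_monte_carlo_agrees_with_exact(self):
        items = ["A", "A", "B", "A", "B", "B"]
        stat = _allele_gst_statistic("naive")
        exact = permutation_test(items, 3, stat, method="exact")["p_value"]
        mc = permutation_test(items, 3, stat, n_perm=10_000, seed=5,
                              method="permute")
        se = math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc["p_value"] - exact) <= 3 * se

    def test_default_n_permutations_is_1000(self):
        items = ["A"] * 12 + ["B"] * 12
        res = permutation_test(items, 12, _allele_gst_statistic("naive"),
                               seed=1, method="permute")
        assert res["n_permutations"] == 1000

    def test_degenerate_all_same_allele_p_one(self):
        items = ["A"] * 10
        res = permutation_test(items, 5, _allele_gst_statistic("naive"),
                               n_perm=50, seed=0)
        assert res["p_value"] == 1.0

    def test_type_i_error_rate_near_alpha(self):
        # two populations drawn from one allele pool: rejection ~ alpha
        rng = np.random.default_rng(17)
        stat = _allele_gst_statistic("naive")
        alpha, runs, rejected = 0.05, 400, 0
        for run in range(runs):
            pool = rng.choice(["A", "B", "C"], size=14, p=[0.5, 0.3, 0.2])
            res = permutation_test(list(pool), 7, stat, n_perm=200,
                                   seed=run, method="permute")
            rejected += res["p_value"] < alpha
        se = math.sqrt(alpha * (1 - alpha) / runs)
        assert rejected / runs <= alpha + 3 * se

    def test_seed_determinism(self):
        items = ["A", "B"] * 8
        stat = _allele_gst_statistic("corrected")
        r1 = permutation_test(items, 8, stat, n_perm=300, seed=9, method="permute")
        r2 = permutation_test(items, 8, stat, n_perm=300, seed=9, method="permute")
        assert r1 == r2


class TestPairwiseMatrix:
    @staticmethod
    def _toy_cohort():
        alleles = {}
        population_of = {}
        spec = {"P1": ["X"] * 5 + ["Y"] * 2, "P2": ["Y"] * 6,
                "P3": ["Z"] * 4 + ["X"], "P4": ["Z"] * 3 + ["W"]}
        for pop, labs in spec.items():
            for i, a in enumerate(labs):
                s = f"{pop}_s{i}"
                alleles[s] = a
                population_of[s] = pop
        return alleles, population_of

    def test_four_populations_six_results(self):
        alleles, pops = self._toy_cohort()
        results, mat = pairwise_matrix(alleles, pops, ["P1", "P2", "P3", "P4"],
                                       n_perm=100, seed=0)
        assert len(results) == 6
        assert math.isnan(mat.loc["P1", "P1"])
        # lower triangle G_ST, upper triangle p-values
        assert 0.0 <= mat.loc["P2", "P1"] <= 1.0
        assert 0.0 <= mat.loc["P1", "P2"] <= 1.0

    def test_gst_bounded_by_one(self):
        alleles, pops = self._toy_cohort()
        results, _ = pairwise_matrix(alleles, pops, ["P1", "P2", "P3", "P4"],
                                     n_perm=50, seed=1)
        assert max(r.gst for r in results) <= 1.0
        assert max(r.gst_corrected for r in results) <= 1.0 + 1e-12

    def test_monotone_in_divergence(self):
        # parameter recovery: G_ST increases with allele-frequency divergence
        rng = np.random.default_rng(3)
        from scipy.stats import spearmanr

        deltas = [0.0, 0.2, 0.5]
        mean_gst = []
        for delta in deltas:
            vals = []
            for rep in range(100):
                p1 = np.array([0.5, 0.5])
                p2 = np.array([0.5 + delta / 2, 0.5 - delta / 2])
                c1 = rng.multinomial(20, p1)
                c2 = rng.multinomial(20, p2)
                if c1.min() == 20 or c2.min() == 20:
                    continue
                vals.append(gst_nei(table([c1.tolist(), c2.tolist()])).gst)
            mean_gst.append(np.mean(vals))
        rho, _ = spearmanr(deltas, mean_gst)
        assert rho == 1.0
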