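"""Haplogroup-as-allele population differentiation.

Gene-diversity based differentiation between populations of mitochondrial
sequences whose information content has been reduced to haplogroup
membership: within- and total gene diversity (H_S, H_T), Nei's G_ST (naive
and Nei–Chesser bias-corrected, haploid sample-size correction with the
harmonic mean ñ), Jost's D, and permutation tests that reshuffle individual
labels between two populations.

Two input granularities are supported. A single-locus count table treats
each haplogroup label as one allele. A sequence mode treats every alignment
column as a locus (allele = base, N dropped per site) and aggregates
diversities over loci as (ΣH_T − ΣH_S)/ΣH_T — this is what feeding
replicated per-haplogroup representative sequences to a multilocus G_ST
implementation computes.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import N

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# population grouping

@dataclass
class PopulationMap:
    """Sample → population assignment after location merging."""

    population_of: dict
    retained: list
    excluded: list

    def samples_in(self, population: str) -> list:
        return [s for s, p in self.population_of.items() if p == population]


def group_populations(location_of_sample: dict, merge_rules: dict,
                      min_n: int = 4) -> PopulationMap:
    """Merge sampling locations into populations and apply the minimum-size
    rule for pairwise analyses.

    ``merge_rules`` maps location → population label; every location of an
    analysed sample must be covered. Populations with fewer than ``min_n``
    individuals are excluded from pairwise analyses (but stay mapped).
    """
    population_of = {}
    for sample, loc in location_of_sample.items():
        if loc not in merge_rules:
            raise KeyError(f"location {loc!r} has no population merge rule")
        population_of[sample] = merge_rules[loc]
    sizes: dict = {}
    for p in population_of.values():
        sizes[p] = sizes.get(p, 0) + 1
    retained = sorted(p for p, n in sizes.items() if n >= min_n)
    excluded = sorted(p for p, n in sizes.items() if n < min_n)
    for p in excluded:
        logger.info("population %s excluded (n=%d < %d)", p, sizes[p], min_n)
    return PopulationMap(population_of=population_of, retained=retained,
                         excluded=excluded)


# ---------------------------------------------------------------------------
# representative substitution

def representative_substitution(groups: dict) -> tuple:
    """Replace every member's sequence by its haplogroup representative.

    ``groups`` maps haplogroup label → list of (sample_id, sequence_codes,
    n_missing, mean_depth). The representative is the member with the fewest
    missing (N) sites; ties fall to higher mean depth, then to the
    lexicographically smallest id. Returns (expanded, representatives):
    ``expanded`` maps every sample id to a copy of its group's
    representative sequence, ``representatives`` maps group → chosen id.
    """
    expanded = {}
    chosen = {}
    for label, members in groups.items():
        if not members:
            logger.info("haplogroup %s has no members, skipped", label)
            continue
        rep = min(members, key=lambda m: (m[2], -(m[3] if m[3] is not None else 0.0),
                                          m[0]))
        chosen[label] = rep[0]
        for sample_id, *_ in members:
            expanded[sample_id] = rep[1]
    return expanded, chosen


# ---------------------------------------------------------------------------
# diversity statistics

@dataclass
class GstResult:
    h_s: float
    h_t: float
    gst: float  # naive
    h_s_corrected: float
    h_t_corrected: float
    gst_corrected: float
    n_tilde: float
    k: int


def _harmonic_mean(sizes) -> float:
    sizes = [float(s) for s in sizes]
    return len(sizes) / sum(1.0 / s for s in sizes)


def _diversities(freqs: np.ndarray) -> tuple:
    """(H_S, H_T) from a (k populations × alleles) frequency matrix with
    unweighted mean frequencies in H_T."""
    h_s = float(np.mean(1.0 - (freqs**2).sum(axis=1)))
    pbar = freqs.mean(axis=0)
    h_t = float(1.0 - (pbar**2).sum())
    return h_s, h_t


def _gst_core(arr: np.ndarray) -> GstResult:
    sizes = arr.sum(axis=1)
    k = arr.shape[0]
    freqs = arr / sizes[:, None]
    h_s, h_t = _diversities(freqs)
    gst = (h_t - h_s) / h_t if h_t > 0 else 0.0

    ntilde = _harmonic_mean(sizes)
    if ntilde > 1:
        h_s_c = ntilde / (ntilde - 1.0) * h_s
    else:
        h_s_c = math.nan
    h_t_c = h_t + h_s_c / (ntilde * k) if not math.isnan(h_s_c) else math.nan
    gst_c = ((h_t_c - h_s_c) / h_t_c
             if not math.isnan(h_t_c) and h_t_c > 0 else 0.0)
    return GstResult(h_s=h_s, h_t=h_t, gst=gst, h_s_corrected=h_s_c,
                     h_t_corrected=h_t_c, gst_corrected=gst_c,
                     n_tilde=ntilde, k=k)


def gst_nei(counts: pd.DataFrame) -> GstResult:
    """Nei's G_ST for a populations × alleles count table.

    Returns both the naive estimator (H_T − H_S)/H_T and the Nei–Chesser
    bias-corrected variant for haploid data:
    H_S' = ñ/(ñ−1)·H_S, H_T' = H_T + H_S'/(ñ·k). H_T = 0 (no variation)
    yields G_ST = 0 by convention.
    """
    arr = counts.to_numpy(dtype=float)
    sizes = arr.sum(axis=1)
    if (sizes <= 0).any():
        bad = counts.index[sizes <= 0][0]
        raise ValueError(f"population {bad!r} has no individuals")
    return _gst_core(arr)


def jost_d(counts: pd.DataFrame) -> float:
    """Jost's D from the corrected diversities: (k/(k−1))·(H_T'−H_S')/(1−H_S').

    Finite-sample correction can push the estimate slightly negative for
    identical populations; negative values are truncated to 0 (the
    conventional reporting for differentiation measures).
    """
    res = gst_nei(counts)
    if math.isnan(res.h_s_corrected) or res.h_s_corrected >= 1.0:
        return math.nan
    k = res.k
    d = (k / (k - 1.0)) * (res.h_t_corrected - res.h_s_corrected) / (
        1.0 - res.h_s_corrected
    )
    return max(d, 0.0)


def allele_counts(alleles_of_sample: dict, population_of: dict,
                  populations=None) -> pd.DataFrame:
    """Populations × alleles count table from per-sample allele labels."""
    pops = populations or sorted(set(population_of.values()))
    alleles = sorted(set(alleles_of_sample.values()))
    table = pd.DataFrame(0, index=pops, columns=alleles, dtype=int)
    for sample, allele in alleles_of_sample.items():
        pop = population_of.get(sample)
        if pop in table.index:
            table.loc[pop, allele] += 1
    return table


# ---------------------------------------------------------------------------
# sequence (multilocus) mode

def _site_frequency_stats(seqs: np.ndarray, pop_rows: list) -> tuple:
    """Per-site (H_S, H_T, H_S', H_T') sums over usable sites.

    ``seqs``: (n_samples, L) code matrix; ``pop_rows``: list of row-index
    arrays, one per population. A site is usable when every population has
    at least two called (non-N) individuals there.
    """
    k = len(pop_rows)
    L = seqs.shape[1]
    counts = np.stack([
        np.stack([(seqs[rows] == b).sum(axis=0) for b in range(4)], axis=1)
        for rows in pop_rows
    ])  # (k, L, 4)
    sizes = counts.sum(axis=2)  # (k, L) called individuals
    usable = (sizes >= 2).all(axis=0)
    if not usable.any():
        return 0.0, 0.0, 0.0, 0.0, 0
    counts = counts[:, usable, :].astype(float)
    sizes = sizes[:, usable].astype(float)
    freqs = counts / sizes[:, :, None]
    h_s = (1.0 - (freqs**2).sum(axis=2)).mean(axis=0)  # (sites,)
    pbar = freqs.mean(axis=0)
    h_t = 1.0 - (pbar**2).sum(axis=1)
    ntilde = k / (1.0 / sizes).sum(axis=0)
    h_s_c = ntilde / (ntilde - 1.0) * h_s
    h_t_c = h_t + h_s_c / (ntilde * k)
    return (float(h_s.sum()), float(h_t.sum()), float(h_s_c.sum()),
            float(h_t_c.sum()), int(usable.sum()))


def gst_nei_sequences(seqs: np.ndarray, pop_rows: list) -> GstResult:
    """Multilocus Nei G_ST over alignment columns: (ΣH_T − ΣH_S)/ΣH_T."""
    hs, ht, hs_c, ht_c, n_used = _site_frequency_stats(seqs, pop_rows)
    gst = (ht - hs) / ht if ht > 0 else 0.0
    gst_c = (ht_c - hs_c) / ht_c if ht_c > 0 else 0.0
    sizes = [len(r) for r in pop_rows]
    denom = n_used if n_used else 1
    return GstResult(h_s=hs / denom, h_t=ht / denom, gst=gst,
                     h_s_corrected=hs_c / denom, h_t_corrected=ht_c / denom,
                     gst_corrected=gst_c, n_tilde=_harmonic_mean(sizes),
                     k=len(pop_rows))


def jost_d_sequences(seqs: np.ndarray, pop_rows: list) -> float:
    """Multilocus Jost D from mean corrected diversities across used sites."""
    hs, ht, hs_c, ht_c, n_used = _site_frequency_stats(seqs, pop_rows)
    if n_used == 0:
        return math.nan
    hs_m, ht_m = hs_c / n_used, ht_c / n_used
    if hs_m >= 1.0:
        return math.nan
    k = len(pop_rows)
    return max((k / (k - 1.0)) * (ht_m - hs_m) / (1.0 - hs_m), 0.0)


# ---------------------------------------------------------------------------
# permutation testing

def permutation_test(items: list, n1: int, statistic, n_perm: int = 1000,
                     seed: int = 0, method: str = "auto") -> dict:
    """Permutation p-value for a two-population statistic.

    ``items`` are the pooled individuals (first ``n1`` observed in
    population 1); ``statistic(group1, group2) -> float`` is recomputed
    under reshuffles that preserve the population sizes. The p-value is the
    plain proportion of permuted statistics >= the observed one.

    ``method='exact'`` enumerates all C(n, n1) assignments; ``'auto'``
    enumerates when that count does not exceed ``n_perm``.
    """
    n = len(items)
    if not (0 < n1 < n):
        raise ValueError("both populations need at least one individual")
    obs = statistic(items[:n1], items[n1:])
    n_exact = math.comb(n, n1)
    use_exact = method == "exact" or (method == "auto" and n_exact <= n_perm)

    if use_exact:
        hits = 0
        for combo in itertools.combinations(range(n), n1):
            in1 = set(combo)
            g1 = [items[i] for i in combo]
            g2 = [items[i] for i in range(n) if i not in in1]
            if statistic(g1, g2) >= obs - 1e-12:
                hits += 1
        return {"p_value": hits / n_exact, "observed": obs,
                "n_permutations": n_exact, "method": "exact"}

    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(idx)
        g1 = [items[i] for i in idx[:n1]]
        g2 = [items[i] for i in idx[n1:]]
        if statistic(g1, g2) >= obs - 1e-12:
            hits += 1
    return {"p_value": hits / n_perm, "observed": obs,
            "n_permutations": n_perm, "method": "permutation"}


def _allele_gst_statistic(estimator: str = "corrected"):
    def stat(g1, g2):
        alleles = {a: i for i, a in enumerate(dict.fromkeys(list(g1) + list(g2)))}
        arr = np.zeros((2, len(alleles)))
        for a in g1:
            arr[0, alleles[a]] += 1
        for a in g2:
            arr[1, alleles[a]] += 1
        res = _gst_core(arr)
        return res.gst_corrected if estimator == "corrected" else res.gst
    return stat


# ---------------------------------------------------------------------------
# pairwise matrices

@dataclass
class DifferentiationResult:
    pair: tuple
    h_s: float
    h_t: float
    gst: float
    gst_corrected: float
    jost_d: float
    p_value: float
    n_permutations: int
    seed: int


def pairwise_matrix(alleles_of_sample: dict, population_of: dict,
                    populations: list, n_perm: int = 1000, seed: int = 0,
                    estimator: str = "corrected",
                    sequences: dict | None = None) -> tuple:
    """All unordered population pairs: G_ST, Jost's D and permutation p.

    With ``sequences`` (sample → code array) the statistics are computed in
    multilocus sequence mode; otherwise haplogroup labels act as alleles of
    a single locus. Returns (results, matrix DataFrame) where the matrix
    carries G_ST in the lower triangle and p-values in the upper one.
    """
    if len(populations) < 2:
        raise ValueError("need at least two retained populations")
    results = []
    mat = pd.DataFrame(np.nan, index=populations, columns=populations)
    for i, pa in enumerate(populations):
        for pb in populations[i + 1:]:
            sa = sorted(s for s, p in population_of.items() if p == pa)
            sb = sorted(s for s, p in population_of.items() if p == pb)
            if sequences is not None:
                pooled = [sequences[s] for s in sa + sb]

                def stat(g1, g2):
                    seqs = np.stack(g1 + g2)
                    rows = [np.arange(len(g1)), np.arange(len(g1), len(seqs))]
                    res = gst_nei_sequences(seqs, rows)
                    return (res.gst_corrected if estimator == "corrected"
                            else res.gst)

                seqs = np.stack(pooled)
                rows = [np.arange(len(sa)), np.arange(len(sa), len(seqs))]
                res = gst_nei_sequences(seqs, rows)
                d = jost_d_sequences(seqs, rows)
                perm = permutation_test(pooled, len(sa), stat, n_perm=n_perm,
                                        seed=seed, method="auto")
            else:
                pooled = [alleles_of_sample[s] for s in sa + sb]
                table = allele_counts(
                    {s: alleles_of_sample[s] for s in sa + sb},
                    population_of, populations=[pa, pb])
                res = gst_nei(table)
                d = jost_d(table)
                perm = permutation_test(pooled, len(sa),
                                        _allele_gst_statistic(estimator),
                                        n_perm=n_perm, seed=seed, method="auto")
            gval = res.gst_corrected if estimator == "corrected" else res.gst
            results.append(DifferentiationResult(
                pair=(pa, pb), h_s=res.h_s, h_t=res.h_t, gst=res.gst,
                gst_corrected=res.gst_corrected, jost_d=d,
                p_value=perm["p_value"], n_permutations=perm["n_permutations"],
                seed=seed,
            ))
            mat.loc[pb, pa] = gval
            mat.loc[pa, pb] = perm["p_value"]
    return results, mat
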