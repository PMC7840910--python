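"""Missing-data threshold sweep for phylogeny robustness.

For each missingness threshold t (descending, e.g. 95 % down to 60 % in 5 %
steps) the sweep retains samples whose percentage of uncalled SNP-matrix
sites is at most t, rebuilds a TN93/NJ tree with bootstrap supports, and
records the mean internal support plus the Robinson–Foulds distance to the
previous threshold's tree on shared taxa. The selected threshold is the
largest (most inclusive) t whose mean support comes within
``support_window`` points of the best mean support across thresholds.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .distance import tn93_matrix
from .nj import nj_tree
from .support import bootstrap_support, mean_internal_support, rf_distance

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (95, 90, 85, 80, 75, 70, 65, 60)


@dataclass
class SweepRow:
    threshold: float
    retained: list
    status: str  # ok | too_few_samples | undefined_distances
    mean_support: float = math.nan
    rf_to_previous: float = math.nan
    tree: object = None

    @property
    def n_retained(self) -> int:
        return len(self.retained)


@dataclass
class SweepReport:
    rows: list
    selected_threshold: float
    n_reps: int
    seed: int

    def row(self, threshold) -> SweepRow:
        for r in self.rows:
            if r.threshold == threshold:
                return r
        raise KeyError(threshold)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tn_retained\tstatus\tmean_support\trf_to_previous"
                     "\tselected\n")
            for r in self.rows:
                ms = "NA" if math.isnan(r.mean_support) else f"{r.mean_support:.2f}"
                rf = "NA" if math.isnan(r.rf_to_previous) else f"{r.rf_to_previous:.0f}"
                sel = "*" if r.threshold == self.selected_threshold else ""
                fh.write(f"{r.threshold}\t{r.n_retained}\t{r.status}\t{ms}\t{rf}\t{sel}\n")


def missingness_sweep(snp_matrix, thresholds=DEFAULT_THRESHOLDS, n_reps: int = 100,
                      seed: int = 0, min_samples: int = 4,
                      support_window: float = 2.0) -> SweepReport:
    thresholds = list(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly descending")
    miss = snp_matrix.missingness_all()

    rows = []
    prev_tree = None
    for t_index, t in enumerate(thresholds):
        retained = [s for s in snp_matrix.samples if miss[s] <= t]
        if len(retained) < min_samples:
            logger.info("sweep threshold %s: only %d samples, skipped", t, len(retained))
            rows.append(SweepRow(threshold=t, retained=retained,
                                 status="too_few_samples"))
            continue
        sub = snp_matrix.subset_samples(retained)
        dm = tn93_matrix(sub.samples, sub.alleles)
        if dm.undefined_pairs():
            logger.info(
                "sweep threshold %s: %d undefined distance pairs, no tree",
                t, len(dm.undefined_pairs()),
            )
            rows.append(SweepRow(threshold=t, retained=retained,
                                 status="undefined_distances"))
            continue

        def builder(aln, labels=tuple(retained)):
            return nj_tree(tn93_matrix(labels, aln))

        tree = bootstrap_support(retained, sub.alleles, builder, n_reps=n_reps,
                                 seed=seed + 1000 * t_index, tree=nj_tree(dm))
        row = SweepRow(threshold=t, retained=retained, status="ok",
                       mean_support=mean_internal_support(tree), tree=tree)
        if prev_tree is not None:
            row.rf_to_previous = rf_distance(tree, prev_tree)
        rows.append(row)
        prev_tree = tree

    ok = [r for r in rows if r.status == "ok" and not math.isnan(r.mean_support)]
    if ok:
        best = max(r.mean_support for r in ok)
        selected = max(r.threshold for r in ok if r.mean_support >= best - support_window)
    else:
        selected = math.nan
    return SweepReport(rows=rows, selected_threshold=selected, n_reps=n_reps, seed=seed)
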