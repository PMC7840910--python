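"""Pipeline orchestration: simulate → process → phylo → popgen.

One declarative config drives all stages; every random choice derives from
the master seed, so a rerun with the same config and seed reproduces
byte-identical text outputs. Each stage reads either the in-memory results
of the previous stage or, when run standalone, the files an earlier run
left in the output directory.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .core import encode
from .phylo import (
    bootstrap_support,
    call_haplogroups,
    collapse_branches,
    mean_internal_support,
    missingness_sweep,
    ml_fit,
    nj_tree,
    tn93_matrix,
)
from .popgen import group_populations, pairwise_matrix, representative_substitution
from .processing import (
    SnpMatrix,
    build_pileup,
    call_consensus,
    damage_profile,
    deduplicate,
    extract_snps,
    map_reads_circular,
)
from .simulate import (
    SimulationConfig,
    generate_population,
    generate_reference,
    simulate_reads,
    truth_tables,
    write_fasta,
    write_fastq,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters; the defaults are the study's printed settings."""

    outdir: str = "mitoshell_run"
    seed: int = 1
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "process": True, "phylo": True, "popgen": True})
    simulation: dict = field(default_factory=dict)
    min_depth: int = 3
    majority: float = 0.5
    damage_window: int = 25
    sweep_thresholds: list = field(
        default_factory=lambda: [95, 90, 85, 80, 75, 70, 65, 60])
    nj_reps: int = 100
    ml_reps: int = 500
    run_ml: bool = True
    ml_rounds: int = 8
    collapse_support: float = 35.0
    min_diag: int = 2
    n_perm: int = 1000
    min_pop_n: int = 4
    threads: int = 1  # advisory only
    merge_rules: dict = field(default_factory=dict)

    def validate(self) -> list:
        """Range checks; returns diagnostics [{level, field, message}, ...]."""
        diags = []

        def err(fieldname, message):
            diags.append({"level": "error", "field": fieldname, "message": message})

        if self.min_depth < 1:
            err("min_depth", "must be >= 1 (consensus depth floor)")
        if not (0.0 <= self.majority < 1.0):
            err("majority", "must lie in [0, 1)")
        if not (0.0 <= self.collapse_support <= 100.0):
            err("collapse_support", "must lie in [0, 100]")
        if self.n_perm < 1:
            err("n_perm", "must be >= 1")
        if self.nj_reps < 1:
            err("nj_reps", "must be >= 1")
        if self.ml_reps < 1:
            err("ml_reps", "must be >= 1")
        if self.min_pop_n < 1:
            err("min_pop_n", "must be >= 1")
        if self.min_diag < 1:
            err("min_diag", "must be >= 1")
        if self.damage_window < 1:
            err("damage_window", "must be >= 1")
        ts = list(self.sweep_thresholds)
        if any(b >= a for a, b in zip(ts, ts[1:])):
            err("sweep_thresholds", "must be strictly descending")
        if self.stages.get("simulate"):
            try:
                SimulationConfig(**{**self.simulation, "seed": self.seed})
            except (TypeError, ValueError) as exc:
                err("simulation", str(exc))
        return diags


_KNOWN_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path) -> tuple:
    """Parse a YAML config; returns (config_or_None, diagnostics)."""
    diags = []
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        return None, [{"level": "fatal", "field": "",
                       "message": f"cannot read config: {exc}"}]
    raw = raw or {}
    if not isinstance(raw, dict):
        return None, [{"level": "fatal", "field": "",
                       "message": "config must be a mapping"}]
    for key in sorted(set(raw) - _KNOWN_KEYS):
        diags.append({"level": "warning", "field": key,
                      "message": "unknown key ignored"})
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in _KNOWN_KEYS})
    diags.extend(cfg.validate())
    return cfg, diags


def validate_config(path) -> list:
    """Diagnostics for a config file (schema + range violations)."""
    _, diags = load_config(path)
    return diags


@dataclass
class RunReport:
    seed: int
    parameters: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def save(self, path) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            return str(o)

        Path(path).write_text(
            json.dumps({"seed": self.seed, "parameters": self.parameters,
                        "stages": self.stages, "warnings": self.warnings},
                       indent=2, default=default) + "\n")


def _digests(paths: dict) -> dict:
    return {name: {"path": str(p), "sha256": mio.sha256_of(p)}
            for name, p in paths.items()}


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg, out: Path, state: dict, written: list) -> dict:
    sim_cfg = SimulationConfig(**{**cfg.simulation, "seed": cfg.seed})
    ref = generate_reference(sim_cfg.genome_length, sim_cfg.gc_content,
                             seed=sim_cfg.seed)
    cohort = generate_population(ref, sim_cfg)
    outputs = {}
    ref_path = out / "reference.fasta"
    write_fasta(ref_path, [(ref.id, ref.sequence)])
    written.append(ref_path)
    outputs["reference"] = ref_path

    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    n_reads = 0
    for ind in cohort.individuals:
        reads = simulate_reads(ind, sim_cfg)
        n_reads += len(reads)
        p = reads_dir / f"{ind.id}.fastq"
        write_fastq(p, reads)
        written.append(p)
        outputs[f"reads/{ind.id}"] = p

    samples_df, variants_df = truth_tables(cohort)
    truth_path = out / "truth_samples.tsv"
    samples_df.to_csv(truth_path, sep="\t", index=False)
    var_path = out / "truth_variants.tsv"
    variants_df.to_csv(var_path, sep="\t", index=False)
    written.extend([truth_path, var_path])
    outputs["truth_samples"] = truth_path
    outputs["truth_variants"] = var_path

    state.update(ref=ref, cohort=cohort, sim_cfg=sim_cfg)
    return {
        "parameters": {"genome_length": sim_cfg.genome_length,
                       "groups": list(map(list, sim_cfg.groups)),
                       "read_length": sim_cfg.read_length,
                       "seed": sim_cfg.seed},
        "counts": {"samples_in": len(cohort.individuals),
                   "samples_retained": len(cohort.individuals),
                   "samples_filtered": 0, "total_reads": n_reads},
        "outputs": _digests(outputs),
    }


def _stage_process(cfg, out: Path, state: dict, written: list) -> dict:
    if "ref" not in state:
        state["ref"] = mio.read_reference(out / "reference.fasta")
    ref = state["ref"]
    if "cohort" in state:
        sample_reads = {
            ind.id: simulate_reads(ind, state["sim_cfg"])
            for ind in state["cohort"].individuals
        }
    else:
        sample_reads = {
            p.stem: mio.read_fastq(p) for p in sorted((out / "reads").glob("*.fastq"))
        }
    if not sample_reads:
        raise PipelineError("process", "no reads found")

    sam_dir = out / "alignments"
    vcf_dir = out / "vcf"
    sam_dir.mkdir(exist_ok=True)
    vcf_dir.mkdir(exist_ok=True)
    outputs = {}
    consensus = []
    all_dedup = []
    n_in = n_mapped = n_dup = 0
    for sample, reads in sample_reads.items():
        alns = map_reads_circular(reads, ref)
        mapped = [a for a in alns if a.mapped]
        dedup = deduplicate(mapped)
        n_in += len(alns)
        n_mapped += len(mapped)
        n_dup += len(mapped) - len(dedup)
        all_dedup.extend(dedup)
        sam_path = sam_dir / f"{sample}.sam"
        mio.write_sam(sam_path, alns, ref)
        written.append(sam_path)
        pile = build_pileup(dedup, ref)
        cons = call_consensus(pile, ref, sample, min_depth=cfg.min_depth,
                              majority=cfg.majority)
        consensus.append(cons)
        vcf_path = vcf_dir / f"{sample}.vcf"
        mio.write_vcf(vcf_path, cons, ref)
        written.append(vcf_path)

    prof = damage_profile(all_dedup, ref, window=cfg.damage_window)
    prof_path = out / "damage_profile.tsv"
    prof.to_tsv(prof_path)
    written.append(prof_path)
    outputs["damage_profile"] = prof_path

    cons_path = out / "consensus.fasta"
    write_fasta(cons_path, [(c.sample_id, c.sequence) for c in consensus])
    written.append(cons_path)
    outputs["consensus"] = cons_path

    matrix = extract_snps(consensus, ref)
    mat_path = out / "snp_matrix.tsv"
    matrix.to_tsv(mat_path)
    written.append(mat_path)
    outputs["snp_matrix"] = mat_path

    miss_path = out / "missingness.tsv"
    mio.write_tsv(miss_path, ["sample", "missingness_pct"],
                  [(s, f"{matrix.missingness(s):.3f}") for s in matrix.samples])
    written.append(miss_path)
    outputs["missingness"] = miss_path

    state.update(consensus=consensus, snp_matrix=matrix, damage=prof)
    return {
        "parameters": {"min_depth": cfg.min_depth, "majority": cfg.majority,
                       "damage_window": cfg.damage_window},
        "counts": {"samples_in": len(sample_reads),
                   "samples_retained": len(sample_reads),
                   "samples_filtered": 0,
                   "reads_in": n_in, "reads_mapped": n_mapped,
                   "duplicates_removed": n_dup,
                   "n_variable_sites": matrix.n_sites},
        "outputs": _digests(outputs),
    }


def _stage_phylo(cfg, out: Path, state: dict, written: list) -> dict:
    if "snp_matrix" not in state:
        state["snp_matrix"] = SnpMatrix.from_tsv(out / "snp_matrix.tsv")
    matrix = state["snp_matrix"]
    warnings = []

    sweep = missingness_sweep(matrix, thresholds=cfg.sweep_thresholds,
                              n_reps=cfg.nj_reps, seed=cfg.seed + 1000)
    sweep_path = out / "sweep.tsv"
    sweep.to_tsv(sweep_path)
    written.append(sweep_path)

    ok_rows = [r for r in sweep.rows if r.status == "ok"]
    if not ok_rows:
        raise PipelineError("phylo", "no sweep threshold produced a tree")
    selected = sweep.selected_threshold
    row = sweep.row(selected)
    retained = row.retained
    sub = matrix.subset_samples(retained)

    def builder(aln, labels=tuple(retained)):
        return nj_tree(tn93_matrix(list(labels), aln))

    nj = bootstrap_support(retained, sub.alleles, builder, n_reps=cfg.nj_reps,
                           seed=cfg.seed + 2000)
    nj_collapsed = collapse_branches(nj, cfg.collapse_support)
    nj_path = out / "nj_tree.nwk"
    mio.write_newick(nj_path, nj_collapsed)
    written.append(nj_path)

    final_tree = nj_collapsed
    ml_info = None
    if cfg.run_ml:
        if "consensus" in state:
            keep = [c for c in state["consensus"] if c.sample_id in set(retained)]
            labels = [c.sample_id for c in keep]
            aln = np.stack([encode(c.sequence) for c in keep])
        else:
            labels = list(retained)
            aln = sub.alleles
        ml_tree, params, ml_report = ml_fit(labels, aln, start_tree=nj,
                                            max_rounds=cfg.ml_rounds)
        ml_tree = bootstrap_support(retained, sub.alleles, builder,
                                    n_reps=cfg.ml_reps, seed=cfg.seed + 3000,
                                    tree=ml_tree)
        final_tree = collapse_branches(ml_tree, cfg.collapse_support)
        ml_path = out / "ml_tree.nwk"
        mio.write_newick(ml_path, final_tree)
        written.append(ml_path)
        ml_info = {"loglik": ml_report["loglik"],
                   "converged": ml_report["converged"],
                   "ts_tv_ratio": ml_report["ts_tv_ratio"],
                   "bootstrap_reps": cfg.ml_reps}
        if not ml_report["converged"]:
            warnings.append("ML fit hit the round cap before convergence")

    haplo = call_haplogroups(final_tree, sub, min_diag=cfg.min_diag,
                             min_support=cfg.collapse_support)
    haplo_path = out / "haplogroups.tsv"
    haplo.to_tsv(haplo_path)
    written.append(haplo_path)
    diag_path = out / "diagnostic_snps.tsv"
    mio.write_tsv(diag_path, ["haplogroup", "pos_1based", "allele"],
                  [(label, pos, allele)
                   for label, g in haplo.groups.items()
                   for pos, allele in g.diagnostic_snps])
    written.append(diag_path)

    n_unassigned = sum(1 for v in haplo.assignments.values() if v == "UNASSIGNED")
    state.update(haplogroups=haplo, retained=retained, tree=final_tree,
                 sweep=sweep)
    outputs = {"sweep": sweep_path, "nj_tree": nj_path,
               "haplogroups": haplo_path, "diagnostic_snps": diag_path}
    if cfg.run_ml:
        outputs["ml_tree"] = out / "ml_tree.nwk"
    return {
        "parameters": {"sweep_thresholds": list(cfg.sweep_thresholds),
                       "nj_reps": cfg.nj_reps, "ml_reps": cfg.ml_reps,
                       "collapse_support": cfg.collapse_support,
                       "min_diag": cfg.min_diag,
                       "selected_threshold": selected},
        "counts": {"samples_in": len(matrix.samples),
                   "samples_retained": len(retained),
                   "samples_filtered": len(matrix.samples) - len(retained),
                   "n_haplogroups": len(haplo.groups),
                   "n_unassigned": n_unassigned,
                   "mean_support": mean_internal_support(final_tree)},
        "outputs": _digests(outputs),
        "ml": ml_info,
        "warnings": warnings,
    }


def _stage_popgen(cfg, out: Path, state: dict, written: list) -> dict:
    if "haplogroups" not in state:
        raise PipelineError("popgen", "phylo stage results missing")
    haplo = state["haplogroups"]
    consensus = {c.sample_id: c for c in state.get("consensus", [])}

    # locations: simulated truth populations unless a merge table is given
    if "cohort" in state:
        location_of = {i.id: i.population for i in state["cohort"].individuals
                       if i.id in haplo.assignments}
    else:
        location_of = {s: s.split("_")[0] for s in haplo.assignments}
    merge = cfg.merge_rules or {loc: loc for loc in set(location_of.values())}
    pm = group_populations(location_of, merge, min_n=cfg.min_pop_n)
    if len(pm.retained) < 2:
        raise PipelineError("popgen", "fewer than two retained populations")

    # haplogroup-as-allele labels; unassigned samples become private alleles
    alleles_of = {}
    for sample, label in haplo.assignments.items():
        alleles_of[sample] = label if label != "UNASSIGNED" else sample

    sequences = None
    if consensus:
        groups = {}
        for label, g in haplo.groups.items():
            groups[label] = [
                (s, encode(consensus[s].sequence),
                 consensus[s].sequence.count("N"),
                 float(consensus[s].depth.mean()))
                for s in g.members if s in consensus
            ]
        expanded, chosen = representative_substitution(groups)
        sequences = dict(expanded)
        for sample, label in haplo.assignments.items():
            if label == "UNASSIGNED" and sample in consensus:
                sequences[sample] = encode(consensus[sample].sequence)
        sequences = {s: seq for s, seq in sequences.items()
                     if s in pm.population_of}

    pop_of = {s: p for s, p in pm.population_of.items() if p in pm.retained
              and s in alleles_of and (sequences is None or s in sequences)}
    results, matrix = pairwise_matrix(
        alleles_of, pop_of, pm.retained, n_perm=cfg.n_perm,
        seed=cfg.seed + 4000, estimator="corrected", sequences=sequences,
    )
    mat_path = out / "popgen_matrix.tsv"
    matrix.to_csv(mat_path, sep="\t", na_rep="-")
    written.append(mat_path)
    json_path = out / "popgen_results.json"
    Path(json_path).write_text(json.dumps([
        {"pair": list(r.pair), "gst": r.gst, "gst_corrected": r.gst_corrected,
         "jost_d": r.jost_d, "p_value": r.p_value,
         "n_permutations": r.n_permutations, "seed": r.seed}
        for r in results
    ], indent=2) + "\n")
    written.append(json_path)

    state.update(popgen_results=results, popgen_matrix=matrix)
    return {
        "parameters": {"n_perm": cfg.n_perm, "min_pop_n": cfg.min_pop_n,
                       "estimator": "corrected",
                       "mode": "sequences" if sequences else "counts"},
        "counts": {"samples_in": len(haplo.assignments),
                   "samples_retained": len(pop_of),
                   "samples_filtered": len(haplo.assignments) - len(pop_of),
                   "populations_retained": len(pm.retained),
                   "pairs": len(results)},
        "outputs": _digests({"matrix": mat_path, "results": json_path}),
    }


_STAGES = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "phylo": _stage_phylo,
    "popgen": _stage_popgen,
}


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order; see module docstring."""
    problems = cfg.validate()
    errors = [d for d in problems if d["level"] in ("error", "fatal")]
    if errors:
        raise ValueError("invalid config: " + "; ".join(
            f"{d['field']}: {d['message']}" for d in errors))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed, parameters=dataclasses.asdict(cfg))
    state: dict = {}
    for stage in ("simulate", "process", "phylo", "popgen"):
        if not cfg.stages.get(stage, False):
            continue
        written: list = []
        logger.info("running stage %s", stage)
        try:
            section = _STAGES[stage](cfg, out, state, written)
        except PipelineError:
            _mark_partial(written)
            raise
        except Exception as exc:
            _mark_partial(written)
            raise PipelineError(stage, str(exc)) from exc
        report.stages[stage] = section
        report.warnings.extend(section.pop("warnings", []))
    report.save(out / "run_report.json")
    return report


def _mark_partial(written) -> None:
    for p in written:
        p = Path(p)
        if p.exists():
            p.rename(p.with_name(p.name + ".partial"))
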