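"""Pipeline orchestration: one config, seeded stages, one run report.

Stages (simulate -> preprocess -> quantify -> de -> discover -> targets
-> clinstats) execute in dependency order; every stage writes its
outputs under the run directory and contributes a section to the JSON
run report.  A single master seed derives per-stage seeds so partial
reruns stay reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simdata, preprocess, alignquant, diffexpr, novelmir, targets
from . import clinstats
from .io import iter_fastq, write_fasta, write_bed, BedInterval

STAGES = ("simulate", "preprocess", "quantify", "de", "discover",
          "targets", "clinstats")


class DependencyError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline thresholds and stage toggles in one place."""
    outdir: str = "mirseq_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulation
    n_known_mirnas: int = 10
    n_novel_mirnas: int = 1
    chrom_length: int = 50000
    mean_depth: int = 5000
    nb_dispersion: float = 0.05
    planted_fold_changes: dict = field(
        default_factory=lambda: {"mir-001": 4.0, "mir-002": 0.25})
    # preprocessing
    adapter: str = simdata.DEFAULT_ADAPTER
    min_q: int = 20
    min_len: int = 17
    max_len: int = 35
    # alignment
    max_mismatch: int = 1
    kmer: int = 8
    min_locus_overlap: float = 0.9
    # differential expression
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    min_reads: int = 3
    # novel discovery
    min_cluster_reads: int = 4
    flank: int = 70
    mfe_threshold: float = -20.0
    min_mature_paired: float = 0.75
    # targets
    score_threshold: float = 150.0
    # cohort
    n_patients: int = 200
    cohort_shifts: dict = field(
        default_factory=lambda: {"mir-132": 1.5, "mir-147b": 1.5,
                                 "mir-99a": -1.5, "mir-218": -1.5,
                                 "mir-30d": -1.5, "mir-24": -1.5,
                                 "mir-625": -1.5})
    survival_hazard_ratios: dict = field(
        default_factory=lambda: {"mir-132": 2.5})
    percentile_high: float = 0.75
    percentile_low: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived deterministically from the master."""
        return int(np.random.SeedSequence(
            [self.seed, STAGES.index(stage)]).generate_state(1)[0]
            % (2 ** 31))


def render_table1(summaries: list[alignquant.LibrarySummary]
                  ) -> pd.DataFrame:
    """Library-summary table in the standard row order.

    Rows: raw reads, preprocessed reads, mapped total + percent, then
    each class with total and percent (adapter percent to 4 decimals),
    then the >= 1 / >= 3 expressed-miRNA counts.  Zero-read libraries
    render their percentages as NA.
    """
    if not summaries:
        raise ValueError("no summaries to render")
    cols = {}
    for s in summaries:
        pct = s.percentages()

        def fmt(v, nd=2):
            return "NA" if v is None else f"{v:.{nd}f}"

        cols[s.library] = [
            s.total_raw, s.after_preprocessing,
            s.mapped_total, fmt(pct["mapped_total"]),
            s.mapped_mirna, fmt(pct["mapped_mirna"]),
            s.mapped_trna, fmt(pct["mapped_trna"]),
            s.mapped_rrna, fmt(pct["mapped_rrna"]),
            s.mapped_adapter, fmt(pct["mapped_adapter"], 4),
            s.expressed_mirnas_ge1, s.expressed_mirnas_ge3,
        ]
    index = ["total_raw_reads", "reads_after_preprocessing",
             "mapped_total", "mapped_total_pct",
             "mapped_mirna", "mapped_mirna_pct",
             "mapped_trna", "mapped_trna_pct",
             "mapped_rrna", "mapped_rrna_pct",
             "mapped_adapter", "mapped_adapter_pct",
             "expressed_mirnas_ge1", "expressed_mirnas_ge3"]
    return pd.DataFrame(cols, index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    ctx: dict = {}

    def enabled(stage: str) -> bool:
        return stage in config.stages

    def need(stage: str, key: str):
        if key not in ctx:
            raise DependencyError(
                f"stage output {key!r} missing; run stage {stage!r} first")
        return ctx[key]

    if enabled("simulate"):
        _stage_simulate(config, out, ctx, report)
    else:
        _load_simulated(out, ctx)
    if enabled("preprocess"):
        _stage_preprocess(config, out, ctx, report)
    if enabled("quantify"):
        need("preprocess", "clean_libs")
        _stage_quantify(config, out, ctx, report)
    if enabled("de"):
        need("quantify", "counts")
        _stage_de(config, out, ctx, report)
    if enabled("discover"):
        need("quantify", "genome_hits")
        _stage_discover(config, out, ctx, report)
    if enabled("targets"):
        _stage_targets(config, out, ctx, report)
    if enabled("clinstats"):
        _stage_clinstats(config, out, ctx, report)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _stage_simulate(config, out, ctx, report):
    gspec = simdata.ToyGenomeSpec(
        n_known_mirnas=config.n_known_mirnas,
        n_novel_mirnas=config.n_novel_mirnas,
        chrom_length=config.chrom_length,
        rng_seed=config.stage_seed("simulate"))
    toy = simdata.generate_toy_genome(gspec)
    rspec = simdata.ReadSimSpec(
        mean_depth=config.mean_depth,
        nb_dispersion=config.nb_dispersion,
        planted_fold_changes=dict(config.planted_fold_changes),
        adapter_sequence=config.adapter,
        rng_seed=config.stage_seed("simulate") + 1)
    paths, truth = simdata.simulate_reads(toy, rspec, out / "reads")
    write_fasta(toy.genome, out / "genome.fasta")
    write_fasta(toy.mature, out / "mature.fasta")
    write_fasta(toy.precursors, out / "precursors.fasta")
    write_fasta(toy.trna, out / "trna.fasta")
    write_fasta(toy.rrna, out / "rrna.fasta")
    write_bed(toy.known_mirna_bed(), out / "known_mirnas.bed")
    write_bed(toy.feature_bed(), out / "features.bed")
    truth.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
    ctx.update(toy=toy, read_paths=paths, truth=truth, read_spec=rspec)
    report["simulate"] = {
        "libraries": sorted(paths),
        "n_known_mirnas": len(toy.mature),
        "n_novel_mirnas": len(toy.novel_mature),
        "total_reads": int(truth["count"].sum()),
    }


def _load_simulated(out, ctx):
    from .io import read_fasta, read_bed
    needed = ["genome.fasta", "mature.fasta", "trna.fasta", "rrna.fasta",
              "known_mirnas.bed"]
    if not all((out / n).exists() for n in needed):
        raise DependencyError("simulate outputs missing; enable the "
                              "'simulate' stage or provide its files")
    reads = sorted((out / "reads").glob("*.fastq")) \
        if (out / "reads").exists() else []
    ctx.update(
        genome=read_fasta(out / "genome.fasta"),
        mature=read_fasta(out / "mature.fasta"),
        trna=read_fasta(out / "trna.fasta"),
        rrna=read_fasta(out / "rrna.fasta"),
        known_bed=read_bed(out / "known_mirnas.bed"),
        read_paths={p.stem: p for p in reads})


def _stage_preprocess(config, out, ctx, report):
    paths = ctx.get("read_paths")
    if not paths:
        raise DependencyError("no read libraries for preprocessing")
    clean_dir = out / "clean"
    clean_dir.mkdir(exist_ok=True)
    stats = {}
    clean_libs = {}
    for lib, path in sorted(paths.items()):
        cp, st = preprocess.preprocess_library(
            path, config.adapter, config.min_q,
            clean_dir / f"{lib}.clean.fastq",
            config.min_len, config.max_len)
        stats[lib] = st
        clean_libs[lib] = [(t.split()[0], s) for t, s, _ in iter_fastq(cp)]
    with open(out / "preprocess_stats.json", "w") as fh:
        json.dump({lib: st.as_dict() for lib, st in stats.items()}, fh,
                  indent=2)
    ctx.update(clean_libs=clean_libs, preprocess_stats=stats)
    report["preprocess"] = {lib: st.as_dict() for lib, st in stats.items()}


def _stage_quantify(config, out, ctx, report):
    toy = ctx.get("toy")
    if toy is not None:
        mature, trna, rrna = toy.mature, toy.trna, toy.rrna
        genome, known_bed = toy.genome, toy.known_mirna_bed()
    else:
        mature, trna, rrna = ctx["mature"], ctx["trna"], ctx["rrna"]
        genome, known_bed = ctx["genome"], ctx["known_bed"]
    class_counts, matrix, genome_hits = alignquant.classify_and_count(
        ctx["clean_libs"], mature, trna, rrna, config.adapter,
        genome, known_bed, config.max_mismatch, config.kmer,
        config.min_locus_overlap)
    expressed = alignquant.expressed_mirna_counts(matrix)
    summaries = []
    for lib in sorted(class_counts):
        summaries.append(alignquant.summarize_library(
            lib, ctx["preprocess_stats"][lib], class_counts[lib],
            int(expressed.loc[lib, "expressed_ge1"]),
            int(expressed.loc[lib, "expressed_ge3"])))
    table1 = render_table1(summaries)
    table1.to_csv(out / "library_summary.tsv", sep="\t")
    matrix.rounded().to_csv(out / "counts.tsv", sep="\t")
    pd.DataFrame([h.__dict__ for h in genome_hits]).to_csv(
        out / "genome_hits.tsv", sep="\t", index=False)
    ctx.update(counts=matrix.rounded(), matrix=matrix,
               genome_hits=genome_hits, summaries=summaries)
    report["quantify"] = {
        "class_counts": class_counts,
        "mapped_totals": matrix.mapped_totals,
    }


def _stage_de(config, out, ctx, report):
    counts = ctx["counts"]
    conditions = {c: c.rsplit("_", 1)[0] for c in counts.columns}
    names = sorted(set(conditions.values()))
    if len(names) != 2:
        raise DependencyError(f"expected two conditions, got {names}")
    res = diffexpr.run_de(counts, conditions, names[0], names[1],
                          config.min_reads)
    up, down = diffexpr.call_de(res, config.p_threshold,
                                config.fc_threshold, config.min_reads)
    corr = diffexpr.replicate_correlation(counts, conditions)
    res.to_csv(out / "de_results.tsv", sep="\t")
    corr.to_csv(out / "replicate_correlation.tsv", sep="\t", index=False)
    ctx.update(de_results=res, de_up=up, de_down=down)
    report["de"] = {
        "n_tested": int(len(res)), "n_up": len(up), "n_down": len(down),
        "up": up, "down": down,
        "mean_replicate_r": float(corr["pearson_r"].mean()),
    }


def _stage_discover(config, out, ctx, report):
    toy = ctx.get("toy")
    genome = toy.genome if toy is not None else ctx["genome"]
    known = (toy.known_mirna_bed() if toy is not None
             else ctx["known_bed"])
    other = ([f.to_bed() for f in toy.features
              if f.ftype in ("trna", "rrna")] if toy is not None else [])
    table, cands = novelmir.discover_novel(
        ctx["genome_hits"], known, genome,
        min_count=config.min_cluster_reads, flank=config.flank,
        mfe_threshold=config.mfe_threshold,
        min_mature_paired=config.min_mature_paired,
        other_annotations=other)
    table.to_csv(out / "novel_candidates.tsv", sep="\t", index=False)
    if not table.empty:
        passing = sorted((c for c in cands if c.overall_pass),
                         key=lambda c: c.delta_g)
        write_fasta({r.candidate_id: c.precursor
                     for r, c in zip(table.itertuples(), passing)},
                    out / "novel_precursors.fasta")
        write_bed([BedInterval(r.chrom, r.mature_start, r.mature_end,
                               r.candidate_id, r.read_count, r.strand)
                   for r in table.itertuples()],
                  out / "novel_mature.bed")
        with open(out / "novel_structures.txt", "w") as fh:
            for r, c in zip(table.itertuples(), passing):
                fh.write(f">{r.candidate_id} dG={c.delta_g}\n"
                         f"{c.precursor}\n{c.structure}\n")
    ctx.update(novel_table=table, novel_candidates=cands)
    report["discover"] = {
        "n_clusters": len(cands),
        "n_passing": int(len(table)),
        "best_delta_g": (float(table["delta_g"].min())
                         if not table.empty else None),
    }


def _stage_targets(config, out, ctx, report):
    # predict targets of the discovered novel miRNA(s) on a synthetic
    # UTR set with planted sites
    table = ctx.get("novel_table")
    mirnas: dict[str, str] = {}
    if table is not None and not table.empty:
        for r in table.itertuples():
            mirnas[r.candidate_id] = r.consensus
    toy = ctx.get("toy")
    if toy is not None:
        for mid in list(toy.mature)[:2]:
            mirnas[mid] = toy.mature[mid]
    if not mirnas:
        report["targets"] = {"n_mirnas": 0, "n_sites": 0}
        return
    uspec = simdata.UTRSimSpec(rng_seed=config.stage_seed("targets"))
    utrs, truth = simdata.generate_utrs(mirnas, uspec)
    write_fasta(utrs, out / "utrs.fasta")
    truth.to_csv(out / "utr_truth.tsv", sep="\t", index=False)
    sites = []
    for mid, seq in sorted(mirnas.items()):
        sites.extend(targets.predict_targets(
            mid, seq, utrs, score_threshold=config.score_threshold,
            mfe_threshold=config.mfe_threshold))
    stab = targets.sites_table(sites)
    stab.to_csv(out / "target_sites.tsv", sep="\t", index=False)
    ctx.update(target_sites=sites)
    report["targets"] = {"n_mirnas": len(mirnas),
                         "n_sites": int(len(stab))}


def _stage_clinstats(config, out, ctx, report):
    cspec = simdata.CohortSimSpec(
        n_patients=config.n_patients,
        planted_mirna_shifts=dict(config.cohort_shifts),
        node_effect_mirnas={"mir-132": 1.0, "mir-147b": 1.0,
                            "mir-30d": -1.0},
        survival_hazard_ratios=dict(config.survival_hazard_ratios),
        rng_seed=config.stage_seed("clinstats"))
    cohort = simdata.simulate_cohort(cspec)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    table = cohort.set_index("patient_id")
    filtered, removed = clinstats.filter_cohort(table)
    mirnas = clinstats.expression_columns(filtered)
    expr = np.log2(filtered[mirnas] + 1.0)
    retained, flagged = clinstats.cluster_outliers(expr)
    kept = filtered.loc[retained]

    groups = pd.Series(np.where(kept["p53_status"] == "missense",
                                "mutant", "wildtype"), index=kept.index)
    mt = clinstats.moderated_t(kept[mirnas], groups)
    sig = mt.table[mt.table["pval"] < config.p_threshold]

    node = kept[kept["node_status"].isin(["N+", "N0"])]
    node_tests = {}
    rocs = {}
    for mir in sorted(config.cohort_shifts):
        if mir not in node.columns:
            continue
        pos = node.loc[node["node_status"] == "N+", mir]
        neg = node.loc[node["node_status"] == "N0", mir]
        u, p = clinstats.mann_whitney(pos, neg)
        node_tests[mir] = {"U": u, "p": p}
        roc = clinstats.roc_auc(node[mir],
                                (node["node_status"] == "N+").astype(int))
        rocs[mir] = {"auc": roc.auc, "p": roc.pvalue}

    surv = {}
    for mir in sorted(config.survival_hazard_ratios):
        if mir not in kept.columns:
            continue
        hi, lo, lr = clinstats.survival_by_expression(
            kept, mir, config.percentile_high, config.percentile_low)
        surv[mir] = {"hazard_ratio": lr.hazard_ratio,
                     "log_rank_p": lr.pvalue,
                     "median_high": hi.median, "median_low": lo.median}

    result = {
        "removed": removed,
        "outliers_flagged": list(map(str, flagged)),
        "n_group_test": {"mutant": int((groups == "mutant").sum()),
                         "wildtype": int((groups == "wildtype").sum())},
        "n_node": {"N+": int((node["node_status"] == "N+").sum()),
                   "N0": int((node["node_status"] == "N0").sum())},
        "significant_mirnas": list(sig.index),
        "node_tests": node_tests, "roc": rocs, "survival": surv,
    }
    with open(out / "clinstats.json", "w") as fh:
        json.dump(result, fh, indent=2, default=float)
    ctx.update(cohort=cohort, clinstats=result)
    report["clinstats"] = result
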