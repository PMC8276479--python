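"""End-to-end orchestration: simulate/load -> filter -> CNVRs -> copy-number
matrix -> V_ST + Kruskal-Wallis -> dual-criterion calls -> clustering
(-> enrichment when annotations are supplied), with a machine-readable run
report whose counts are recomputable from the written artifacts alone.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Any

import pandas as pd

from . import cluster as cl
from . import cnvr as cb
from . import enrich as en
from . import io as cio
from . import popdiff as pd_stats
from .simulate import SimConfig, simulate, truth_eval, write_simulation

log = logging.getLogger("cnvpd")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "out_dir": "cnvpd_run",
    "simulate": {},  # SimConfig overrides; omit and set "inputs" to load real data
    "inputs": None,  # {"calls_dir":…, "meta":…, "genome":…} for pre-called data
    "filter": {"min_len_bp": 1000, "max_pvalue": 1e-3, "max_q0": 0.5},
    "merge": {"min_reciprocal": 0.5, "mode": "single"},
    "recurrence": {"min_individuals": 3},
    "vst": {"grouping": "group", "exclude_singletons": True},
    "diff": {"vst_quantile": 0.99, "extreme_quantile": 0.999, "kw_alpha": 0.01},
    "cluster": {"enabled": True, "n_boot": 100, "method": "average", "use": "presence"},
    "enrich": {"genes": None, "qtl": None, "term2gene": None},
}


@dataclass
class RunReport:
    seed: int
    thresholds: dict[str, Any] = field(default_factory=dict)
    counts: dict[str, Any] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run(config: dict | None = None) -> RunReport:
    """Execute the pipeline per ``config`` (missing sections take defaults).

    Reruns with identical config and inputs produce byte-identical
    artifacts: every random stage is driven by the single top-level seed.
    """
    cfg = _merge_config(config)
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    report = RunReport(seed=cfg["seed"])
    t0 = time.perf_counter()

    def stage(name):
        # timers go to the log only, keeping report.json reproducible
        log.info("stage %s done at %.3fs", name, time.perf_counter() - t0)

    # --- inputs -----------------------------------------------------------
    if cfg.get("inputs"):
        inp = cfg["inputs"]
        for key in ("calls_dir", "meta", "genome"):
            if not inp.get(key):
                raise ValueError(f"inputs.{key} is required when loading call data")
        genome = cio.read_genome(inp["genome"])
        metas = cio.read_sample_meta(inp["meta"])
        raw_calls = []
        for m in metas:
            path = os.path.join(inp["calls_dir"], f"{m.individual_id}.cnvnator.tsv")
            raw_calls.extend(cio.read_cnvnator_calls(path, m.individual_id))
        truth = None
        cnvr_prefix = "CNVR"
    else:
        sim_cfg = SimConfig(seed=cfg["seed"], **cfg.get("simulate") or {})
        result = simulate(sim_cfg)
        write_simulation(result, os.path.join(out_dir, "simdata"))
        genome, metas = result.genome, result.metas
        raw_calls = result.all_calls()
        truth = result.truth
        cnvr_prefix = "CNVR"
    stage("inputs")
    individuals = [m.individual_id for m in metas]
    report.counts["individuals"] = len(individuals)
    report.counts["raw_calls"] = len(raw_calls)

    # --- filter + CNVRs ----------------------------------------------------
    filtered = cb.filter_calls(raw_calls, genome=genome, **cfg["filter"])
    report.counts["filtered_calls"] = len(filtered)
    cnvrs = cb.merge_calls(filtered, id_prefix=cnvr_prefix, **cfg["merge"])
    report.counts["cnvrs_merged"] = len(cnvrs)
    cnvrs = cb.recurrence_filter(cnvrs, **cfg["recurrence"])
    report.counts["cnvrs"] = len(cnvrs)
    coverage = cb.total_coverage_bp(cnvrs)
    report.counts["cnvr_total_bp"] = coverage
    report.counts["autosome_bp"] = genome.autosome_length
    report.counts["cnvr_pct_autosome"] = round(
        100.0 * coverage / genome.autosome_length, 4
    )
    cnvr_bed = os.path.join(out_dir, "cnvrs.bed")
    cio.write_cnvr_bed(cnvrs, cnvr_bed)
    cio.write_cnvr_membership(cnvrs, os.path.join(out_dir, "cnvr_members.tsv"))
    stage("cnvrs")

    # --- copy-number matrix -------------------------------------------------
    matrix = cb.genotype_cnvrs(cnvrs, individuals)
    cio.write_matrix(
        matrix,
        os.path.join(out_dir, "copy_number.tsv"),
        os.path.join(out_dir, "presence.tsv"),
    )
    stage("matrix")

    # --- differentiation stats ----------------------------------------------
    vst_long, vst_mean = pd_stats.pairwise_vst_matrix(matrix, metas, **cfg["vst"])
    vst_long.to_csv(os.path.join(out_dir, "vst_pairwise.tsv"), sep="\t", index=False)
    vst_mean.to_csv(os.path.join(out_dir, "vst_mean_matrix.tsv"), sep="\t")
    kw = pd_stats.kruskal_wallis_table(matrix, metas)
    kw.to_csv(os.path.join(out_dir, "kruskal_wallis.tsv"), sep="\t", index=False)
    diff, thresholds = pd_stats.call_differentiated(vst_long, kw, **cfg["diff"])
    diff.to_csv(os.path.join(out_dir, "differentiated.tsv"), sep="\t", index=False)
    report.thresholds = {
        "vst": {str(k): v for k, v in thresholds.items()},
        **{k: cfg[k] for k in ("filter", "merge", "recurrence", "diff")},
    }
    report.counts["differentiated_cnvrs"] = int(diff["differentiated"].sum())
    stage("stats")

    # --- truth scoring (synthetic runs only) ---------------------------------
    if truth is not None:
        ev = truth_eval(diff, cnvrs, truth)
        report.counts["truth_differentiated_loci"] = ev.n_truth_differentiated
        report.counts["recall"] = round(ev.recall, 4)
        report.counts["precision"] = round(ev.precision, 4)

    # --- clustering -----------------------------------------------------------
    if cfg["cluster"].get("enabled", True):
        ccfg = cfg["cluster"]
        data = cl.presence_vectors(matrix, use=ccfg.get("use", "presence"))
        tree = cl.bootstrap_support(
            data,
            individuals,
            n_boot=ccfg.get("n_boot", 100),
            seed=cfg["seed"],
            method=ccfg.get("method", "average"),
        )
        with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
            fh.write(tree.to_newick() + "\n")
        tree.support_table().to_csv(
            os.path.join(out_dir, "support.tsv"), sep="\t", index=False
        )
        stage("cluster")

    # --- enrichment (optional annotations) -------------------------------------
    ecfg = cfg["enrich"]
    if ecfg.get("genes"):
        genes = en.exclude_gene_symbols(cio.read_features(ecfg["genes"]))
        overlaps = en.overlap_features(cnvrs, genes)
        diff_ids = set(diff.loc[diff["differentiated"], "cnvr_id"])
        gene_hits = overlaps[overlaps["cnvr_id"].isin(diff_ids)]
        best = en.most_significant_cnvr_per_gene(overlaps, kw) if len(overlaps) else None
        if best is not None:
            best.to_csv(os.path.join(out_dir, "gene_cnvr.tsv"), sep="\t", index=False)
        report.counts["genes_overlapping_cnvrs"] = int(overlaps["feature_id"].nunique())
        report.counts["diff_cnvrs_with_genes"] = int(gene_hits["cnvr_id"].nunique())
        report.counts["genes_on_diff_cnvrs"] = int(gene_hits["feature_id"].nunique())
        if ecfg.get("term2gene"):
            t2g = pd.read_csv(ecfg["term2gene"], sep="\t")
            sel_counts, n_sel = en.term_gene_counts(
                t2g, gene_hits["feature_id"].unique()
            )
            tot_counts, n_tot = en.term_gene_counts(
                t2g, (g.feature_id for g in genes)
            )
            results = en.binomial_representation(
                sel_counts, tot_counts, n_selected=n_sel, n_total=n_tot
            )
            en.enrichment_table(results).to_csv(
                os.path.join(out_dir, "go_enrichment.tsv"), sep="\t", index=False
            )
    if ecfg.get("qtl"):
        qtl = cio.read_features(ecfg["qtl"])
        qtl_overlaps = en.overlap_features(cnvrs, qtl)
        hit_ids = set(qtl_overlaps["feature_id"])
        sel = en.category_counts([q for q in qtl if q.feature_id in hit_ids])
        tot = en.category_counts(qtl)
        results = en.binomial_representation(
            sel, tot, n_selected=len(hit_ids), n_total=len(qtl)
        )
        en.enrichment_table(results).to_csv(
            os.path.join(out_dir, "qtl_enrichment.tsv"), sep="\t", index=False
        )
        report.counts["qtl_overlapping_cnvrs"] = len(hit_ids)
    stage("enrich")

    # --- digests + report --------------------------------------------------------
    for name in sorted(os.listdir(out_dir)):
        path = os.path.join(out_dir, name)
        if os.path.isfile(path) and name != "report.json":
            report.digests[name] = cio.sha256_file(path)
    report.to_json(os.path.join(out_dir, "report.json"))
    return report


def recount_from_artifacts(out_dir) -> dict[str, int]:
    """Recompute the headline counts from written artifacts (consistency
    check: the report holds no state the artifacts do not)."""
    counts = {}
    bed = pd.read_csv(
        os.path.join(out_dir, "cnvrs.bed"),
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "cnvr_id", "n_carriers", "type"],
    )
    counts["cnvrs"] = len(bed)
    diff = pd.read_csv(os.path.join(out_dir, "differentiated.tsv"), sep="\t")
    counts["differentiated_cnvrs"] = int(diff["differentiated"].sum())
    spans = bed.sort_values(["chrom", "start"])
    total = 0
    for _, grp in spans.groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
    counts["cnvr_total_bp"] = int(total)
    return counts
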