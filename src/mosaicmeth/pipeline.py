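"""End-to-end orchestration: filter -> smooth -> paired stats -> candidate
regions -> combine -> finalize -> cluster -> annotate/enrich.

A single :class:`PipelineConfig` (loadable from YAML) names the input files
and carries every stage's parameters; :func:`run_pipeline` executes the
stages in order, writes each intermediate under the output directory and
returns the in-memory result bundle.  Reports echo the bookkeeping style of
a WGBS study: sites/reads before and after each filter, hyper/hypo
percentages, region length and CpG-count summaries.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering, combine, dmr, enrichment, filtering, meth_io, smoothing

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    output_dir: str = "mosaicmeth_out"
    calls: dict[str, str] = field(default_factory=dict)  # replicate -> path
    samples: dict[str, dict] = field(default_factory=dict)
    # replicate -> {mother: int, treatment: NF|CR}
    annotation: Optional[str] = None
    vcf: Optional[str] = None
    reads: Optional[str] = None
    go_map: Optional[str] = None
    go_parents: Optional[str] = None
    seed: int = 0
    collapse_strands: bool = False
    filtering: dict = field(default_factory=dict)
    smoothing: dict = field(default_factory=dict)
    dmr: dict = field(default_factory=dict)
    combine: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=False)

    def validate(self) -> None:
        for rep, p in self.calls.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"calls file for {rep}: {p}")
            if rep not in self.samples:
                raise ValueError(f"replicate {rep} missing from samples table")
        for name in ("annotation", "vcf", "reads", "go_map", "go_parents"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def default_config() -> PipelineConfig:
    """A config with every stage parameter spelled out at its default."""
    cfg = PipelineConfig()
    cfg.filtering = dict(min_reads=6, min_replicates_per_treatment=2,
                         mask_g_position=True, strict_variant_missing=False)
    cfg.smoothing = dict(min_cpgs_in_window=70, min_window_bp=1000, degree=2)
    cfg.dmr = dict(t_cut=4.6, min_cpgs=3, min_abs_meandiff=0.1, site_fdr=0.05,
                   max_gap_bp=300, variance_floor_quantile=0.75,
                   q_method="BH", require_site_fdr=False)
    cfg.combine = dict(bin_width=50, max_lag=500, alpha=0.05)
    cfg.clustering = dict(n_boot=500)
    cfg.enrichment = dict(alpha=0.01, algorithm="classic")
    return cfg


@dataclass
class PipelineResult:
    matrix_raw: meth_io.MethylationCallMatrix
    matrix_filtered: meth_io.MethylationCallMatrix
    conversion_report: Optional[filtering.ConversionReport]
    global_summary: filtering.GlobalMethylationSummary
    profile: smoothing.SmoothedProfile
    test_result: dmr.PairedTestResult
    candidates: list
    filtered_candidates: list
    combined: list
    final_dmrs: list
    dendrogram: Optional[clustering.SupportedDendrogram]
    overlaps: list
    genes_by_direction: dict
    enrichment_results: dict
    summary: dict
    stage_counts: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, object] = {}

    # ---- load ------------------------------------------------------------
    records = {
        rep: meth_io.read_cytosine_report(path)
        for rep, path in config.calls.items()
    }
    metadata = pd.DataFrame.from_dict(config.samples, orient="index")
    metadata.index.name = "replicate"
    matrix_raw = meth_io.assemble_matrix(records, metadata)
    if config.collapse_strands:
        matrix_raw = meth_io.collapse_strands(matrix_raw)
    stage_counts["sites_input"] = matrix_raw.n_sites

    # ---- stage: filter ---------------------------------------------------
    fcfg = dict(config.filtering)
    conversion_report = None
    if config.reads:
        reads = pd.read_csv(config.reads, sep="\t")
        _retained, conversion_report = filtering.filter_nonconverted_reads(reads)
        conversion_report.per_replicate.to_csv(
            outdir / "conversion_report.tsv", sep="\t"
        )
    matrix = matrix_raw
    if config.vcf:
        variants = meth_io.read_vcf(config.vcf)
        passing = filtering.hard_filter_variants(
            variants, strict=fcfg.get("strict_variant_missing", False)
        )
        stage_counts["variants_total"] = len(variants)
        stage_counts["variants_passing"] = len(passing)
        matrix, n_masked = filtering.mask_polymorphic_cpgs(
            matrix, passing, mask_g_position=fcfg.get("mask_g_position", True)
        )
        stage_counts["sites_masked_polymorphic"] = n_masked
    rule = filtering.CoverageRule(
        min_reads=fcfg.get("min_reads", 6),
        min_replicates_per_treatment=fcfg.get("min_replicates_per_treatment", 2),
    )
    matrix = filtering.apply_coverage_rule(matrix, rule)
    stage_counts["sites_after_coverage_rule"] = matrix.n_sites

    global_summary = filtering.global_methylation(matrix)
    pd.DataFrame({
        "global_cpg_pct": global_summary.per_replicate_pct,
    }).to_csv(outdir / "global_methylation.tsv", sep="\t")

    # ---- stage: smooth ---------------------------------------------------
    scfg = smoothing.SmootherConfig(**{
        k: v for k, v in config.smoothing.items()
        if k in ("min_cpgs_in_window", "min_window_bp", "degree",
                 "iterative_logistic")
    })
    profile = smoothing.smooth_matrix(matrix, scfg)

    # ---- stage: paired stats + candidates ---------------------------------
    dcfg = dict(config.dmr)
    test_result = dmr.paired_t_per_cpg(
        profile,
        variance_floor_quantile=dcfg.get("variance_floor_quantile", 0.75),
        q_method=dcfg.get("q_method", "BH"),
    )
    thresholds = dmr.DmrFilterThresholds(
        t_cut=dcfg.get("t_cut", 4.6),
        min_cpgs=dcfg.get("min_cpgs", 3),
        min_abs_meandiff=dcfg.get("min_abs_meandiff", 0.1),
        site_fdr=dcfg.get("site_fdr", 0.05),
        max_gap_bp=dcfg.get("max_gap_bp", 300),
    )
    candidates = dmr.find_candidate_regions(test_result, thresholds)
    filtered_candidates = dmr.filter_candidates(
        candidates, thresholds,
        require_site_fdr=dcfg.get("require_site_fdr", False),
    )
    stage_counts["candidate_regions"] = len(candidates)
    stage_counts["filtered_candidates"] = len(filtered_candidates)
    meth_io.write_regions(candidates, outdir / "candidates.tsv", "TSV")
    meth_io.write_regions(filtered_candidates,
                          outdir / "filtered_candidates.tsv", "TSV")

    # ---- stage: combine + finalize ----------------------------------------
    ccfg = dict(config.combine)
    acf = combine.estimate_acf(
        test_result, bin_width=ccfg.get("bin_width", 50),
        max_lag=ccfg.get("max_lag", 500),
    )
    pd.DataFrame({
        "lag_lo": acf.bin_edges[:-1], "lag_hi": acf.bin_edges[1:],
        "rho": acf.rho, "n_pairs": acf.n_pairs,
    }).to_csv(outdir / "acf.tsv", sep="\t", index=False)
    combined = combine.combine_regions(candidates, test_result, acf)
    final_dmrs = combine.finalize_dmrs(
        combined, filtered_candidates, alpha=ccfg.get("alpha", 0.05)
    )
    stage_counts["final_dmrs"] = len(final_dmrs)
    meth_io.write_regions(combined, outdir / "combined_regions.tsv", "TSV")
    meth_io.write_regions(final_dmrs, outdir / "final_dmrs.tsv", "TSV")
    meth_io.write_regions(final_dmrs, outdir / "final_dmrs.bed", "BED")

    # per-CpG table for volcano-style plotting
    pd.DataFrame({
        "scaffold": test_result.sites["scaffold"],
        "position": test_result.sites["position"],
        "mean_diff": test_result.mean_diff,
        "t": test_result.t,
        "p": test_result.p,
        "q": test_result.q,
    }).to_csv(outdir / "per_cpg_stats.tsv", sep="\t", index=False)

    # ---- stage: cluster ----------------------------------------------------
    kcfg = dict(config.clustering)
    dendrogram = None
    if matrix.n_replicates >= 3:
        dendrogram = clustering.cluster_matrix(
            matrix, n_boot=kcfg.get("n_boot", 500), seed=config.seed
        )
        (outdir / "dendrogram.nwk").write_text(dendrogram.to_newick() + "\n")

    # ---- stage: annotate / enrich ------------------------------------------
    overlaps, genes_by_direction = [], {"hyper": set(), "hypo": set()}
    enrichment_results: dict[str, list] = {}
    if config.annotation:
        annotation = _read_annotation(config.annotation)
        overlaps, genes_by_direction = enrichment.overlap_dmrs_genes(
            final_dmrs, annotation
        )
        pd.DataFrame([o.__dict__ for o in overlaps]).to_csv(
            outdir / "dmr_gene_overlaps.tsv", sep="\t", index=False
        )
        if config.go_map and config.go_parents:
            go_map = enrichment.read_go_map(config.go_map)
            parents, namespace = enrichment.read_go_parents(config.go_parents)
            universes = enrichment.build_universes(matrix_raw, annotation)
            ecfg = dict(config.enrichment)
            for direction, genes in genes_by_direction.items():
                for label, universe in universes.items():
                    res = enrichment.fisher_enrichment(
                        genes, universe, go_map, parents, namespace,
                        alpha=ecfg.get("alpha", 0.01),
                        algorithm=ecfg.get("algorithm", "classic"),
                    )
                    key = f"{direction}_{label}"
                    enrichment_results[key] = res
                    enrichment.enrichment_table(res).to_csv(
                        outdir / f"enrichment_{direction}_{label.replace('>=', 'ge')}.tsv",
                        sep="\t", index=False,
                    )

    summary = summarize_run(final_dmrs, overlaps)
    pd.Series(summary).to_csv(outdir / "summary.tsv", sep="\t", header=False)
    pd.Series(stage_counts).to_csv(outdir / "stage_counts.tsv", sep="\t",
                                   header=False)

    return PipelineResult(
        matrix_raw=matrix_raw, matrix_filtered=matrix,
        conversion_report=conversion_report, global_summary=global_summary,
        profile=profile, test_result=test_result, candidates=candidates,
        filtered_candidates=filtered_candidates, combined=combined,
        final_dmrs=final_dmrs, dendrogram=dendrogram, overlaps=overlaps,
        genes_by_direction=genes_by_direction,
        enrichment_results=enrichment_results, summary=summary,
        stage_counts=stage_counts,
    )


def _read_annotation(path) -> meth_io.GeneAnnotation:
    path = str(path)
    if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        return meth_io.GeneAnnotation.from_gff3(path)
    return meth_io.GeneAnnotation.from_bed12(path)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def pct(part: int, whole: int) -> int:
    """Integer-rounded percentage (half away from zero), 0 when whole = 0."""
    if whole == 0:
        return 0
    return int(np.floor(100.0 * part / whole + 0.5))


def summarize_counts(
    n_total: int,
    n_hyper: int,
    n_intergenic: int,
    exonic_by_direction: dict[str, tuple[int, int]] | None = None,
) -> dict:
    """Percentage arithmetic over final-DMR counts.

    ``exonic_by_direction`` maps direction -> (n_exonic_genes, n_genes).
    """
    n_hypo = n_total - n_hyper
    out = {
        "n_total": n_total,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": pct(n_hyper, n_total),
        "pct_hypo": pct(n_hypo, n_total),
        "n_intergenic": n_intergenic,
        "pct_intergenic": pct(n_intergenic, n_total),
    }
    for direction, (n_ex, n_genes) in (exonic_by_direction or {}).items():
        out[f"n_genes_{direction}"] = n_genes
        out[f"n_exonic_genes_{direction}"] = n_ex
        out[f"pct_exonic_{direction}"] = pct(n_ex, n_genes)
    return out


def summarize_run(final_dmrs: list, overlaps: list) -> dict:
    """Reporting-style summary of the final DMR set.

    Counts and integer-rounded percentages of hyper/hypo regions and
    gene-overlapping vs intergenic regions, per-direction exonic gene
    fractions, and region length / CpG-count means and ranges.
    """
    n_total = len(final_dmrs)
    if n_total == 0:
        return {"n_total": 0, "note": "empty final DMR set"}
    n_hyper = sum(1 for r in final_dmrs if r.direction == "hyper")
    overlapped = {(o.scaffold, o.dmr_start, o.dmr_end) for o in overlaps}
    n_intergenic = sum(
        1 for r in final_dmrs
        if (r.scaffold, r.start, r.end) not in overlapped
    )
    exonic_by_direction = {}
    for direction in ("hyper", "hypo"):
        genes = {o.gene_id for o in overlaps if o.direction == direction}
        exonic = {
            o.gene_id for o in overlaps
            if o.direction == direction and o.overlap_class in ("exonic", "mixed")
        }
        exonic_by_direction[direction] = (len(exonic), len(genes))
    out = summarize_counts(n_total, n_hyper, n_intergenic, exonic_by_direction)

    lengths = [meth_io.region_length(r.start, r.end) for r in final_dmrs]
    cpgs = [r.n_cpgs for r in final_dmrs]
    for direction in ("hyper", "hypo"):
        ls = [meth_io.region_length(r.start, r.end) for r in final_dmrs
              if r.direction == direction]
        if ls:
            out[f"mean_length_{direction}"] = float(np.mean(ls))
    out.update({
        "length_mean": float(np.mean(lengths)),
        "length_min": int(min(lengths)),
        "length_max": int(max(lengths)),
        "cpgs_mean": float(np.mean(cpgs)),
        "cpgs_min": int(min(cpgs)),
        "cpgs_max": int(max(cpgs)),
    })
    return out
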