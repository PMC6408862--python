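"""Self-validation studies on synthetic data with planted ground truth.

Each study builds a dataset under fixed, documented conditions, runs the
relevant pipeline stages, and reports recovery/calibration metrics:

* :func:`dmr_recovery_study` — one scaffold, ~2x10^4 CpGs, six pairs at
  10x coverage, 20 planted DMRs of 5-10 CpGs with a 0.25 mean difference
  and a 0.3 (logit) mother effect; measures sensitivity (planted regions
  overlapped by a final DMR) and the observed false-discovery proportion
  (final DMRs overlapping no planted region).
* :func:`null_calibration_study` — the same generator with no planted
  effects, across seeds; reports final DMR counts (which should hover
  near zero).
* :func:`clustering_study` — no treatment effect and a dominant mother
  effect; checks that every mother's NF/CR pair forms a cherry and
  reports the weakest pair's bootstrap support.
* :func:`conversion_filter_study` — 3% unconverted reads; compares the
  global methylation estimate before and after the non-conversion read
  filter against the generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import clustering, combine, dmr, filtering, simulate, smoothing
from .smoothing import desk_scale_config


def study_config(seed: int, n_dmrs: int = 20,
                 mother_sd: float = 0.3) -> simulate.SimulationConfig:
    """The benchmark generator conditions (one 1-Mbp scaffold, ~2x10^4
    CpGs at 20/kbp, six pairs, 10x coverage)."""
    return simulate.SimulationConfig(
        n_scaffolds=1, scaffold_length=1_000_000, n_genes=100,
        cpg_density=20.0, n_pairs=6, coverage_mean=10.0,
        n_dmrs=n_dmrs, dmr_effect=(0.25, 0.25), dmr_width=(5, 10),
        mother_sd=mother_sd, conversion_failure_rate=0.0, n_snps=0,
        seed=seed,
    )


def _detect(matrix, thresholds=None):
    profile = smoothing.smooth_matrix(matrix, desk_scale_config())
    result = dmr.paired_t_per_cpg(profile)
    th = thresholds or dmr.DmrFilterThresholds()
    candidates = dmr.find_candidate_regions(result, th)
    filtered = dmr.filter_candidates(candidates, th)
    if not filtered:
        return result, candidates, filtered, []
    acf = combine.estimate_acf(result)
    combined = combine.combine_regions(candidates, result, acf)
    final = combine.finalize_dmrs(combined, filtered)
    return result, candidates, filtered, final


def _overlaps(region, truth_row) -> bool:
    return (region.scaffold == truth_row.scaffold
            and region.start <= truth_row.end
            and region.end >= truth_row.start)


@dataclass
class RecoveryReport:
    n_planted: int
    n_final: int
    n_recovered: int
    n_false: int

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 0.0

    @property
    def false_discovery_proportion(self) -> float:
        return self.n_false / self.n_final if self.n_final else 0.0


def dmr_recovery_study(seed: int = 1) -> RecoveryReport:
    cfg = study_config(seed)
    _model, truth, matrix, _ = simulate.simulate_dataset(cfg)
    _res, _cands, _filt, final = _detect(matrix)
    planted = list(truth.dmrs.itertuples(index=False))
    n_recovered = sum(
        any(_overlaps(r, t) for r in final) for t in planted
    )
    n_false = sum(
        not any(_overlaps(r, t) for t in planted) for r in final
    )
    return RecoveryReport(len(planted), len(final), n_recovered, n_false)


def null_calibration_study(seeds) -> list[int]:
    counts = []
    for seed in seeds:
        cfg = study_config(seed, n_dmrs=0)
        _model, _truth, matrix, _ = simulate.simulate_dataset(cfg)
        _res, _cands, _filt, final = _detect(matrix)
        counts.append(len(final))
    return counts


@dataclass
class ClusteringReport:
    n_cherries: int
    n_pairs: int
    min_pair_support: float


def clustering_study(seed: int = 1, n_boot: int = 500,
                     mother_sd: float = 1.0) -> ClusteringReport:
    cfg = study_config(seed, n_dmrs=0, mother_sd=mother_sd)
    _model, _truth, matrix, _ = simulate.simulate_dataset(cfg)
    dend = clustering.cluster_matrix(matrix, n_boot=n_boot, seed=seed)
    cherries = clustering.mother_pairs_are_cherries(dend, matrix.samples)
    supports = [
        dend.pair_support(tuple(grp.index))
        for _m, grp in matrix.samples.groupby("mother")
    ]
    return ClusteringReport(sum(cherries.values()), len(cherries),
                            float(min(supports)))


@dataclass
class ConversionReport:
    truth_pct: float
    prefilter_pct: float
    postfilter_pct: float

    @property
    def prefilter_bias(self) -> float:
        return self.prefilter_pct - self.truth_pct

    @property
    def postfilter_error(self) -> float:
        return abs(self.postfilter_pct - self.truth_pct)


def conversion_filter_study(seed: int = 1) -> ConversionReport:
    cfg = simulate.SimulationConfig(
        scaffold_length=150_000, n_genes=15, n_dmrs=3,
        conversion_failure_rate=0.03, n_snps=0, seed=seed,
    )
    model, truth, matrix, reads = simulate.simulate_dataset(cfg, reads=True)
    truth_pct = 100.0 * float(np.mean(truth.levels))
    pre = 100.0 * matrix.meth.sum() / matrix.coverage.sum()
    retained, _report = filtering.filter_nonconverted_reads(reads)
    clean = simulate.aggregate_reads(retained, model, matrix.samples,
                                     cfg.read_length)
    post = 100.0 * clean.meth.sum() / clean.coverage.sum()
    return ConversionReport(truth_pct, float(pre), float(post))


def global_methylation_study(seed: int = 1) -> float:
    """Global CpG methylation (%) of a default-conditions dataset."""
    cfg = study_config(seed)
    _model, _truth, matrix, _ = simulate.simulate_dataset(cfg)
    return 100.0 * float(matrix.meth.sum() / matrix.coverage.sum())
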