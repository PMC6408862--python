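"""Pre-statistics filters on methylation calls.

Four filters run before any smoothing or testing, mirroring standard WGBS
quality control for an organism with negligible non-CpG methylation:

1. reads containing any methylated CHH/CHG call are discarded as
   bisulphite-unconverted;
2. variants are hard-filtered with the usual GATK-style SNP thresholds;
3. CpG sites sitting on a passing C/T polymorphism (or G/A on the G of the
   dinucleotide) are masked — a T allele is miscalled as unmethylated C;
4. a coverage rule keeps a site only if enough replicates per treatment
   reach a minimum read depth.

The module also computes per-replicate global CpG methylation and the
paired t-test comparing treatments at the global level.

Note on hard filters: the thresholds are phrased as keep-conditions in the
GATK documentation ("QD > 2" etc.); here they are implemented as the
equivalent exclusion bounds — a variant FAILS if QD < qd_min, FS > fs_max,
MQ < mq_min, MQRankSum < mqranksum_min or ReadPosRankSum <
readposranksum_min.  A missing annotation passes that criterion by default
(GATK-consistent); ``strict=True`` makes missing values fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .meth_io import MethylationCallMatrix

logger = logging.getLogger(__name__)

CALL_ALPHABET = set("zZxXhH")


@dataclass
class VariantThresholds:
    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0


@dataclass
class CoverageRule:
    min_reads: int = 6
    min_replicates_per_treatment: int = 2

    def __post_init__(self):
        if self.min_reads < 1 or self.min_replicates_per_treatment < 1:
            raise ValueError("coverage rule parameters must be >= 1")


@dataclass
class ConversionReport:
    """Per-replicate bookkeeping of the non-conversion read filter."""

    per_replicate: pd.DataFrame
    # columns: n_reads, n_removed, pct_removed, noncpg_pct_methylated,
    #          conversion_efficiency_pct


@dataclass
class GlobalMethylationSummary:
    per_replicate_pct: pd.Series  # global CpG methylation, percent
    t_statistic: float
    p_value: float
    df: int


# ---------------------------------------------------------------------------

def filter_nonconverted_reads(
    read_table: pd.DataFrame,
) -> tuple[pd.DataFrame, ConversionReport]:
    """Drop whole reads that contain any methylated CHH/CHG call (X or H).

    Returns the retained reads and a per-replicate report with the fraction
    of reads removed and the percentage of non-CpG calls that were
    methylated before filtering; 100 minus that figure is the bisulphite
    conversion efficiency.
    """
    calls = read_table["calls"]
    for idx, s in calls.items():
        bad = set(s) - CALL_ALPHABET
        if bad:
            raise ValueError(
                f"read {idx}: unknown call symbol(s) {sorted(bad)!r}"
            )
    has_noncpg_meth = calls.str.contains(r"[XH]", regex=True)

    rows = []
    for rep, grp in read_table.groupby("replicate", sort=True):
        joined = "".join(grp["calls"])
        n_noncpg_meth = sum(joined.count(c) for c in "XH")
        n_noncpg = n_noncpg_meth + sum(joined.count(c) for c in "xh")
        pct = 100.0 * n_noncpg_meth / n_noncpg if n_noncpg else 0.0
        removed = int(has_noncpg_meth[grp.index].sum())
        rows.append((rep, len(grp), removed,
                     100.0 * removed / len(grp) if len(grp) else 0.0,
                     pct, 100.0 - pct))
    report = pd.DataFrame(
        rows,
        columns=["replicate", "n_reads", "n_removed", "pct_removed",
                 "noncpg_pct_methylated", "conversion_efficiency_pct"],
    ).set_index("replicate")
    retained = read_table[~has_noncpg_meth].reset_index(drop=True)
    return retained, ConversionReport(report)


def hard_filter_variants(
    variants: pd.DataFrame,
    thresholds: VariantThresholds | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Keep variants passing every hard-filter criterion (see module note)."""
    t = thresholds or VariantThresholds()

    def crit(col, op, bound):
        v = variants[col]
        fails = op(v, bound)
        if strict:
            fails = fails | v.isna()
        else:
            fails = fails.fillna(False)
        return fails

    failing = (
        crit("QD", pd.Series.lt, t.qd_min)
        | crit("FS", pd.Series.gt, t.fs_max)
        | crit("MQ", pd.Series.lt, t.mq_min)
        | crit("MQRankSum", pd.Series.lt, t.mqranksum_min)
        | crit("ReadPosRankSum", pd.Series.lt, t.readposranksum_min)
    )
    n_missing_all = int(variants[["QD", "FS", "MQ", "MQRankSum",
                                  "ReadPosRankSum"]].isna().all(axis=1).sum())
    if n_missing_all and not strict:
        logger.info("%d variants had no hard-filter annotations (passed)",
                    n_missing_all)
    return variants[~failing].reset_index(drop=True)


def mask_polymorphic_cpgs(
    matrix: MethylationCallMatrix,
    variants: pd.DataFrame,
    mask_g_position: bool = True,
) -> tuple[MethylationCallMatrix, int]:
    """Remove CpG sites invalidated by a C/T (or G/A) polymorphism.

    A forward-strand site at position p is removed when a passing SNP with
    ref C / alt T sits at p, or (with ``mask_g_position``, the default) a
    ref G / alt A SNP sits at p+1 — reverse-strand reads report methylation
    at the G, where an A allele is miscalled unmethylated.  Reverse-strand
    sites are handled mirror-image.  Returns the filtered matrix and the
    number of sites removed.
    """
    ct = set(
        zip(variants.loc[(variants["ref"] == "C") & (variants["alt"] == "T"),
                         "scaffold"],
            variants.loc[(variants["ref"] == "C") & (variants["alt"] == "T"),
                         "position"])
    )
    ga = set(
        zip(variants.loc[(variants["ref"] == "G") & (variants["alt"] == "A"),
                         "scaffold"],
            variants.loc[(variants["ref"] == "G") & (variants["alt"] == "A"),
                         "position"])
    )
    scaf = matrix.sites["scaffold"].to_numpy()
    pos = matrix.sites["position"].to_numpy()
    strand = matrix.sites["strand"].to_numpy()
    removed = np.zeros(len(pos), dtype=bool)
    for i in range(len(pos)):
        if strand[i] == "-":
            hit = (scaf[i], pos[i]) in ga or (
                mask_g_position and (scaf[i], pos[i] - 1) in ct
            )
        else:
            hit = (scaf[i], pos[i]) in ct or (
                mask_g_position and (scaf[i], pos[i] + 1) in ga
            )
        removed[i] = hit
    n_removed = int(removed.sum())
    if len(pos):
        logger.info("masked %d/%d CpG sites (%.2f%%) at polymorphic positions",
                    n_removed, len(pos), 100.0 * n_removed / len(pos))
    return matrix.subset_sites(~removed), n_removed


def apply_coverage_rule(
    matrix: MethylationCallMatrix,
    rule: CoverageRule | None = None,
) -> MethylationCallMatrix:
    """Keep sites with >= min_reads coverage in >= min_replicates of BOTH
    treatments."""
    rule = rule or CoverageRule()
    cov = matrix.coverage
    keep = np.ones(matrix.n_sites, dtype=bool)
    for trt in ("NF", "CR"):
        idx = matrix.replicate_indices(trt)
        if len(idx) == 0:
            raise ValueError(f"no {trt} replicates in matrix")
        n_ok = (cov[:, idx] >= rule.min_reads).sum(axis=1)
        keep &= n_ok >= rule.min_replicates_per_treatment
    return matrix.subset_sites(keep)


def global_methylation(matrix: MethylationCallMatrix) -> GlobalMethylationSummary:
    """Per-replicate global CpG methylation (%) and the paired t-test.

    The global level is the coverage-weighted percentage
    100 * sum(meth) / sum(meth + unmeth) per replicate; the paired t-test is
    run on the per-mother CR - NF differences with n_pairs - 1 degrees of
    freedom.
    """
    cov_tot = matrix.coverage.sum(axis=0).astype(float)
    if (cov_tot == 0).any():
        raise ValueError("replicate with zero total coverage")
    pct = pd.Series(
        100.0 * matrix.meth.sum(axis=0) / cov_tot, index=matrix.samples.index
    )
    nf_idx, cr_idx, _mothers = matrix.pair_columns()
    if len(nf_idx) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diffs = pct.iloc[cr_idx].to_numpy() - pct.iloc[nf_idx].to_numpy()
    n = len(diffs)
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        mean = float(np.mean(diffs))
        t_stat = 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t_stat = float(np.mean(diffs) / (sd / np.sqrt(n)))
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    return GlobalMethylationSummary(pct, t_stat, p, n - 1)
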