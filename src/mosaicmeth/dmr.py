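"""Per-CpG paired t-statistics on smoothed levels and candidate DMRs.

The paired design (one normal-food and one calorie-restricted replicate per
mother) is exploited by testing the per-mother difference of smoothed
levels at each CpG.  Per-site standard deviations are floored at a
genome-wide quantile (default the 75th percentile) before forming the
t-statistic — the usual "local correction" that stops near-zero sampling
variances from inflating t at sparsely covered sites.

Candidate regions are maximal runs of consecutive CpGs whose t-statistics
all exceed the symmetric cut-off with a common sign, broken by scaffold
change or an inter-CpG gap above ``max_gap_bp``; they are then filtered on
CpG count and absolute region mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from statsmodels.stats.multitest import multipletests

from .smoothing import SmoothedProfile


@dataclass
class PairedTestResult:
    sites: pd.DataFrame
    mean_diff: np.ndarray      # CR - NF, smoothed scale
    sd: np.ndarray             # of pair differences, after flooring
    raw_sd: np.ndarray         # before flooring
    t: np.ndarray
    p: np.ndarray              # two-tailed
    q: np.ndarray
    df: int
    sd_floor: float


@dataclass
class DmrFilterThresholds:
    t_cut: float = 4.6
    min_cpgs: int = 3
    min_abs_meandiff: float = 0.1
    site_fdr: float = 0.05
    max_gap_bp: int = 300

    def __post_init__(self):
        if self.t_cut <= 0:
            raise ValueError("t_cut must be positive")


@dataclass
class CandidateRegion:
    scaffold: str
    start: int                 # 1-based inclusive, first member CpG
    end: int                   # last member CpG
    n_cpgs: int
    direction: str             # 'hyper' | 'hypo' (CR vs NF)
    mean_diff: float           # mean of member per-CpG mean differences
    member_idx: np.ndarray = field(repr=False, default=None)
    n_cpgs_site_fdr: int = 0   # members with q < site_fdr (annotation)


def paired_t_per_cpg(
    profile: SmoothedProfile,
    variance_floor_quantile: float = 0.75,
    q_method: str = "BH",
) -> PairedTestResult:
    """Paired t-test of CR - NF smoothed levels at every CpG.

    d_k = smoothed(CR_k) - smoothed(NF_k) for mother k; the sd of the d_k is
    floored at the genome-wide ``variance_floor_quantile`` of per-site sds;
    t = mean(d) / (sd_floored / sqrt(n)); p is two-tailed with
    df = n_pairs - 1.  Where the floor itself is zero (degenerate input) t
    is set to 0.
    """
    samples = profile.samples
    mothers = sorted(samples["mother"].unique())
    if len(mothers) == 0:
        raise ValueError("no pairs in profile")
    pos = {rep: i for i, rep in enumerate(samples.index)}
    nf_cols, cr_cols = [], []
    for m in mothers:
        rows = samples[samples["mother"] == m]
        nf = rows[rows["treatment"] == "NF"]
        cr = rows[rows["treatment"] == "CR"]
        if len(nf) != 1 or len(cr) != 1:
            raise ValueError(f"mother {m} is not a complete NF/CR pair")
        nf_cols.append(pos[nf.index[0]])
        cr_cols.append(pos[cr.index[0]])
    n = len(mothers)
    if n < 2:
        raise ValueError("need >= 2 pairs for a paired t-test")

    d = profile.levels[:, cr_cols] - profile.levels[:, nf_cols]
    mean_diff = d.mean(axis=1)
    raw_sd = d.std(axis=1, ddof=1)
    floor = float(np.quantile(raw_sd, variance_floor_quantile))
    sd = np.maximum(raw_sd, floor)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean_diff / (sd / np.sqrt(n)), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    q = p_to_q(p, method=q_method)
    return PairedTestResult(profile.sites, mean_diff, sd, raw_sd, t, p, q,
                            n - 1, floor)


def storey_pi0(p: np.ndarray) -> float:
    """Estimate the null proportion pi0 by the smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a lambda grid
    0.05..0.95; a cubic smoothing spline is evaluated at the largest lambda
    and the result clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if np.allclose(pi0_lam, pi0_lam[0]):
        pi0 = pi0_lam[-1]
    else:
        spline = UnivariateSpline(lam, pi0_lam, k=3)
        pi0 = float(spline(lam[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def p_to_q(p: np.ndarray, method: str = "BH") -> np.ndarray:
    """Convert p-values to q-values (BH, or BH scaled by Storey's pi0)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if method.upper() == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method.lower() == "storey":
        return np.minimum(storey_pi0(p) * multipletests(p, method="fdr_bh")[1],
                          1.0)
    raise ValueError(f"unknown q-value method {method!r}")


def find_candidate_regions(
    result: PairedTestResult,
    thresholds: DmrFilterThresholds | None = None,
) -> list[CandidateRegion]:
    """Maximal same-sign runs of CpGs beyond the t cut-off.

    A run breaks at a sign change, a sub-threshold site, a scaffold change,
    or an inter-CpG gap greater than ``max_gap_bp``.
    """
    th = thresholds or DmrFilterThresholds()
    t = result.t
    scaf = result.sites["scaffold"].to_numpy()
    pos = result.sites["position"].to_numpy()
    sign = np.where(t > th.t_cut, 1, np.where(t < -th.t_cut, -1, 0))

    regions: list[CandidateRegion] = []
    start = None
    for i in range(len(t) + 1):
        boundary = (
            i == len(t)
            or sign[i] == 0
            or (start is not None and (
                sign[i] != sign[start]
                or scaf[i] != scaf[i - 1]
                or pos[i] - pos[i - 1] > th.max_gap_bp
            ))
        )
        if start is not None and boundary:
            idx = np.arange(start, i)
            regions.append(_make_region(result, idx, sign[start], th))
            start = None
        if i < len(t) and sign[i] != 0 and start is None:
            start = i
    return regions


def _make_region(result, idx, sign, th):
    md = float(result.mean_diff[idx].mean())
    return CandidateRegion(
        scaffold=result.sites["scaffold"].iloc[idx[0]],
        start=int(result.sites["position"].iloc[idx[0]]),
        end=int(result.sites["position"].iloc[idx[-1]]),
        n_cpgs=len(idx),
        direction="hyper" if sign > 0 else "hypo",
        mean_diff=md,
        member_idx=idx,
        n_cpgs_site_fdr=int((result.q[idx] < th.site_fdr).sum()),
    )


def filter_candidates(
    regions: list[CandidateRegion],
    thresholds: DmrFilterThresholds | None = None,
    require_site_fdr: bool = False,
) -> list[CandidateRegion]:
    """Keep regions with >= min_cpgs CpGs and |mean difference| strictly
    greater than min_abs_meandiff.

    ``require_site_fdr`` additionally demands at least min_cpgs member CpGs
    with q below ``site_fdr`` (off by default; region selection follows the
    t cut-off narrative).
    """
    th = thresholds or DmrFilterThresholds()
    kept = [
        r for r in regions
        if r.n_cpgs >= th.min_cpgs and abs(r.mean_diff) > th.min_abs_meandiff
    ]
    if require_site_fdr:
        kept = [r for r in kept if r.n_cpgs_site_fdr >= th.min_cpgs]
    return kept
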