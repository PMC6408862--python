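"""Autocorrelation-aware combination of per-CpG p-values into region
p-values, and the final DMR intersection.

The validation stage follows the comb-p recipe: (1) estimate the
autocorrelation of z-transformed p-values as a function of genomic lag;
(2) combine each candidate region's member p-values with the
Stouffer-Liptak-Kechris statistic, whose denominator inflates with the
summed pairwise correlations; (3) adjust the combined p-values across
regions by Benjamini-Hochberg.  Final DMRs are the filtered candidates
whose combined, corrected p-value clears the significance level.

Conventions: z_i = Phi^-1(1 - p_i) (small p -> large z); pairwise rho is
looked up from the lag bin holding the pair's distance, distances beyond
the last bin get rho = 0, and negative rho is clipped to 0, which keeps the
denominator >= sqrt(n) and the combination conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dmr import CandidateRegion, PairedTestResult

logger = logging.getLogger(__name__)

_P_EPS = 1e-15
MIN_PAIRS_PER_BIN = 10


@dataclass
class AcfModel:
    """Correlation of z-scores by genomic-lag bin."""

    bin_edges: np.ndarray      # len n_bins + 1; bins are [lo, hi)
    rho: np.ndarray            # per bin, clipped later at lookup
    n_pairs: np.ndarray        # pairs observed per bin

    def lookup(self, distance: np.ndarray | float) -> np.ndarray:
        """Rho for site-pair distances; beyond the last bin -> 0."""
        distance = np.atleast_1d(np.asarray(distance, dtype=float))
        idx = np.searchsorted(self.bin_edges, distance, side="right") - 1
        out = np.zeros(len(distance))
        ok = (idx >= 0) & (idx < len(self.rho))
        out[ok] = self.rho[idx[ok]]
        return out


@dataclass
class CombinedRegion(CandidateRegion):
    p_combined: float = np.nan
    p_corrected: float = np.nan
    significant: bool = False


def _z(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, _P_EPS, 1 - _P_EPS))


def estimate_acf(
    result: PairedTestResult,
    bin_width: int = 50,
    max_lag: int = 500,
) -> AcfModel:
    """Pearson correlation of z = Phi^-1(1-p) over same-scaffold site pairs
    binned by distance.

    Bins with fewer than 10 pairs, or with constant z on either margin, get
    rho = 0 (logged).
    """
    if len(result.p) < 2:
        raise ValueError("need at least 2 sites to estimate autocorrelation")
    edges = np.arange(1, max_lag + bin_width + 1, bin_width)
    edges = edges[edges <= max_lag + 1]
    if edges[-1] != max_lag + 1:
        edges = np.append(edges, max_lag + 1)
    n_bins = len(edges) - 1
    z = _z(result.p)
    scaf = result.sites["scaffold"].to_numpy()
    pos = result.sites["position"].to_numpy()

    pairs_a: list[list[float]] = [[] for _ in range(n_bins)]
    pairs_b: list[list[float]] = [[] for _ in range(n_bins)]
    for sc in pd.unique(scaf):
        sel = np.flatnonzero(scaf == sc)
        p_sc = pos[sel]
        z_sc = z[sel]
        for a_i in range(len(sel)):
            jhi = np.searchsorted(p_sc, p_sc[a_i] + max_lag, side="right")
            for b_j in range(a_i + 1, jhi):
                d = p_sc[b_j] - p_sc[a_i]
                b = int(np.searchsorted(edges, d, side="right")) - 1
                if 0 <= b < n_bins:
                    pairs_a[b].append(z_sc[a_i])
                    pairs_b[b].append(z_sc[b_j])

    rho = np.zeros(n_bins)
    n_pairs = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        a, c = np.asarray(pairs_a[b]), np.asarray(pairs_b[b])
        n_pairs[b] = len(a)
        if len(a) < MIN_PAIRS_PER_BIN:
            logger.info("lag bin %d has %d < %d pairs; rho = 0",
                        b, len(a), MIN_PAIRS_PER_BIN)
            continue
        if np.std(a) == 0 or np.std(c) == 0:
            logger.info("constant z in lag bin %d; rho = 0", b)
            continue
        rho[b] = float(np.corrcoef(a, c)[0, 1])
    return AcfModel(edges.astype(float), rho, n_pairs)


def stouffer_liptak(p: np.ndarray, rho_matrix: np.ndarray | None = None) -> float:
    """Combine p-values with a correlation-adjusted Stouffer statistic.

    combined z = sum(z_i) / sqrt(n + 2 * sum_{i<j} rho_ij);
    combined p = 1 - Phi(z).  With rho = 0 this is the classic Stouffer
    combination.  p-values at 0 or 1 are clamped to a machine-safe epsilon.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    n = len(p)
    if n == 0:
        raise ValueError("no p-values to combine")
    if ((p <= 0) | (p >= 1)).any():
        logger.debug("clamping %d boundary p-values", int(((p <= 0) | (p >= 1)).sum()))
    z = _z(p)
    if rho_matrix is None:
        off_diag = 0.0
    else:
        rho_matrix = np.clip(np.asarray(rho_matrix, dtype=float), 0.0, None)
        off_diag = float(np.triu(rho_matrix, k=1).sum())
    denom = np.sqrt(n + 2.0 * off_diag)
    return float(stats.norm.sf(z.sum() / denom))


def _region_rho_matrix(region: CandidateRegion, pos: np.ndarray,
                       acf: AcfModel) -> np.ndarray:
    idx = region.member_idx
    p = pos[idx].astype(float)
    dist = np.abs(p[:, None] - p[None, :])
    rho = acf.lookup(dist.ravel()).reshape(dist.shape)
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, 0.0, None)


def combine_regions(
    candidates: list[CandidateRegion],
    result: PairedTestResult,
    acf: AcfModel,
) -> list[CombinedRegion]:
    """Assign a Stouffer-Liptak combined p to every (unfiltered) candidate
    and BH-adjust across all combined p-values.

    The candidates passed here should be the full unfiltered set, so that
    the multiplicity adjustment spans every tested region.
    """
    pos = result.sites["position"].to_numpy()
    combined: list[CombinedRegion] = []
    p_vals = []
    for reg in candidates:
        if reg.member_idx is None or len(reg.member_idx) == 0:
            logger.warning("region %s:%d-%d has no member p-values; skipped",
                           reg.scaffold, reg.start, reg.end)
            continue
        rho = _region_rho_matrix(reg, pos, acf)
        pc = stouffer_liptak(result.p[reg.member_idx], rho)
        combined.append(CombinedRegion(
            **{f: getattr(reg, f) for f in (
                "scaffold", "start", "end", "n_cpgs", "direction",
                "mean_diff", "member_idx", "n_cpgs_site_fdr")},
            p_combined=pc,
        ))
        p_vals.append(pc)
    if combined:
        corrected = multipletests(np.array(p_vals), method="fdr_bh")[1]
        for reg, pc in zip(combined, corrected):
            reg.p_corrected = float(pc)
    return combined


def finalize_dmrs(
    combined: list[CombinedRegion],
    filtered_candidates: list[CandidateRegion],
    alpha: float = 0.05,
) -> list[CombinedRegion]:
    """Intersect filtered candidates with significant combined regions.

    A filtered candidate survives when a combined region with the same
    interval has corrected p < alpha.  The returned regions carry the
    combined/corrected p-values and the significance flag.
    """
    by_interval = {
        (r.scaffold, r.start, r.end): r for r in combined
    }
    final = []
    for cand in filtered_candidates:
        reg = by_interval.get((cand.scaffold, cand.start, cand.end))
        if reg is None:
            continue
        if reg.p_corrected < alpha:
            final.append(replace(reg, significant=True))
    return final


def find_peak_regions(
    result: PairedTestResult,
    seed_p: float = 0.05,
    extend_p: float = 0.1,
    max_gap_bp: int = 300,
) -> list[CandidateRegion]:
    """Standalone low-p peak finder (off the main path).

    Seeds at CpGs with p < seed_p and extends across neighbours with
    p < extend_p within ``max_gap_bp``; provided for completeness, the main
    pipeline combines over the t-statistic candidate regions instead.
    """
    p = result.p
    scaf = result.sites["scaffold"].to_numpy()
    pos = result.sites["position"].to_numpy()
    n = len(p)
    used = np.zeros(n, dtype=bool)
    regions = []
    for i in np.argsort(p):
        if used[i] or p[i] >= seed_p:
            continue
        lo = hi = i
        while lo > 0 and not used[lo - 1] and scaf[lo - 1] == scaf[lo] \
                and pos[lo] - pos[lo - 1] <= max_gap_bp and p[lo - 1] < extend_p:
            lo -= 1
        while hi < n - 1 and not used[hi + 1] and scaf[hi + 1] == scaf[hi] \
                and pos[hi + 1] - pos[hi] <= max_gap_bp and p[hi + 1] < extend_p:
            hi += 1
        idx = np.arange(lo, hi + 1)
        used[idx] = True
        md = float(result.mean_diff[idx].mean())
        regions.append(CandidateRegion(
            scaffold=scaf[i], start=int(pos[lo]), end=int(pos[hi]),
            n_cpgs=len(idx), direction="hyper" if md > 0 else "hypo",
            mean_diff=md, member_idx=idx,
        ))
    regions.sort(key=lambda r: (r.scaffold, r.start))
    return regions
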