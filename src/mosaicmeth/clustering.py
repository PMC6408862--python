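"""Hierarchical clustering of replicates with bootstrap support.

Replicates are compared by the Pearson correlation of their per-CpG raw
methylation proportions (zero-coverage cells excluded pairwise), turned
into the distance 1 - r, and clustered with the Ward.D2 criterion.  Node
support is the bootstrap probability (BP): CpG sites are resampled with
replacement, the tree rebuilt, and BP is the fraction of bootstrap trees
containing the same leaf bipartition.

Ward.D2 is implemented directly via the Lance-Williams recurrence on
squared distances (merge height = sqrt of the updated squared distance),
with a deterministic tie-break: among equally close cluster pairs the one
whose smallest member index is lowest (then the second index) merges first.
This matches R's ``hclust(method="ward.D2")`` and scipy's ``linkage(...,
'ward')`` on a precomputed distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meth_io import MethylationCallMatrix


@dataclass
class ReplicateDistanceMatrix:
    labels: list[str]
    distances: np.ndarray  # symmetric, zero diagonal, 1 - Pearson r

    def __post_init__(self):
        d = self.distances
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("invalid distance matrix")


@dataclass
class SupportedDendrogram:
    labels: list[str]
    merges: np.ndarray        # scipy-style linkage matrix (n-1, 4)
    support: dict[frozenset, float]  # leaf bipartition -> BP
    n_boot: int

    def node_bipartitions(self) -> list[frozenset]:
        return _bipartitions(self.merges, self.labels)

    def pair_support(self, pair: tuple[str, str]) -> float:
        return self.support.get(frozenset(pair), 0.0)

    def is_cherry(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in set(_bipartitions(self.merges, self.labels))

    def to_newick(self) -> str:
        return _to_newick(self.merges, self.labels, self.support)


# ---------------------------------------------------------------------------

def pairwise_correlation(props: np.ndarray) -> np.ndarray:
    """Pearson correlation between replicate columns, NaN cells excluded
    pairwise.  ``props`` is (n_sites, n_replicates) with NaN at zero
    coverage."""
    valid = ~np.isnan(props)
    x = np.nan_to_num(props)
    r = props.shape[1]
    m = valid.astype(float)
    n = m.T @ m                        # shared sites per pair
    sx = x.T @ m                       # sum of x over shared sites (per pair)
    sxy = x.T @ x
    sxx = (x * x).T @ m
    corr = np.empty((r, r))
    for i in range(r):
        for j in range(r):
            nn = n[i, j]
            if nn < 2:
                raise ValueError(
                    f"replicates {i} and {j} share fewer than 2 covered sites"
                )
            mx, my = sx[i, j] / nn, sx[j, i] / nn
            cov = sxy[i, j] / nn - mx * my
            vx = sxx[i, j] / nn - mx * mx
            vy = sxx[j, i] / nn - my * my
            if vx <= 0 or vy <= 0:
                raise ValueError(
                    f"replicate {i if vx <= 0 else j} has zero variance "
                    "over shared sites"
                )
            corr[i, j] = cov / np.sqrt(vx * vy)
    return corr


def correlation_distance(
    props: np.ndarray, labels: list[str]
) -> ReplicateDistanceMatrix:
    """1 - Pearson correlation over pairwise-shared covered sites."""
    corr = pairwise_correlation(np.asarray(props, dtype=float))
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return ReplicateDistanceMatrix(list(labels), d)


def matrix_proportions(matrix: MethylationCallMatrix) -> np.ndarray:
    return matrix.proportions()


# ---------------------------------------------------------------------------

def ward_d2_tree(distances: np.ndarray) -> np.ndarray:
    """Agglomerate with the Ward.D2 criterion; returns a linkage matrix.

    Lance-Williams on squared distances:
    d2(k, i+j) = ((n_i+n_k) d2(k,i) + (n_j+n_k) d2(k,j) - n_k d2(i,j))
                 / (n_i+n_j+n_k);
    merge height = sqrt(d2) of the merged pair.  Deterministic lowest-index
    tie-breaking.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    d2 = d ** 2
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    current = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best, best_key = None, None
        for a_i in range(len(active)):
            for b_j in range(a_i + 1, len(active)):
                i, j = active[a_i], active[b_j]
                key = (min(i, j), max(i, j))
                val = current[key]
                tie = (val, min_leaf[i], min_leaf[j]) if min_leaf[i] < min_leaf[j] \
                    else (val, min_leaf[j], min_leaf[i])
                if best is None or tie < best:
                    best, best_key = tie, (i, j)
        i, j = best_key
        height = np.sqrt(current[(min(i, j), max(i, j))])
        merges[step] = [min(i, j), max(i, j), height, sizes[i] + sizes[j]]
        ni, nj = sizes[i], sizes[j]
        dij = current[(min(i, j), max(i, j))]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = current[(min(i, k), max(i, k))]
            djk = current[(min(j, k), max(j, k))]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            current[(min(k, next_id), max(k, next_id))] = new
        active = [a for a in active if a not in (i, j)] + [next_id]
        sizes[next_id] = ni + nj
        min_leaf[next_id] = min(min_leaf[i], min_leaf[j])
        next_id += 1
    return merges


def _bipartitions(merges: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for step, (a, b, _h, _s) in enumerate(merges):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        out.append(merged)
    return out


def _to_newick(merges: np.ndarray, labels: list[str],
               support: dict[frozenset, float] | None = None) -> str:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    node_str: dict[int, str] = {i: labels[i] for i in range(n)}
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    for step, (a, b, h, _s) in enumerate(merges):
        a, b = int(a), int(b)
        node = n + step
        members[node] = members[a] | members[b]
        la = (h - height[a]) / 2.0
        lb = (h - height[b]) / 2.0
        label = ""
        if support is not None and members[node] in support:
            label = f"{support[members[node]]:.2f}"
        node_str[node] = f"({node_str[a]}:{la:.4f},{node_str[b]}:{lb:.4f}){label}"
        height[node] = h
    return node_str[n + len(merges) - 1] + ";"


# ---------------------------------------------------------------------------

def bootstrap_support(
    props: np.ndarray,
    labels: list[str],
    n_boot: int = 500,
    seed: int = 0,
) -> SupportedDendrogram:
    """Site-resampling bootstrap probabilities for every internal node.

    The site order is canonicalised before resampling (the RNG draws row
    indices), so permuting input rows together with a fixed seed leaves the
    support values unchanged.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    props = np.asarray(props, dtype=float)
    dist = correlation_distance(props, labels)
    merges = ward_d2_tree(dist.distances)
    parts = _bipartitions(merges, labels)
    internal = [p for p in parts if 1 < len(p) < len(labels)]
    counts = {p: 0 for p in internal}

    rng = np.random.default_rng(seed)
    n_sites = props.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_sites, size=n_sites)
        try:
            bdist = correlation_distance(props[idx], labels)
        except ValueError:
            continue  # degenerate resample
        bparts = set(_bipartitions(ward_d2_tree(bdist.distances), labels))
        for p in internal:
            if p in bparts:
                counts[p] += 1
    support = {p: counts[p] / n_boot for p in internal}
    return SupportedDendrogram(list(labels), merges, support, n_boot)


def cluster_matrix(
    matrix: MethylationCallMatrix,
    n_boot: int = 500,
    seed: int = 0,
) -> SupportedDendrogram:
    """Cluster a call matrix's replicates by raw proportion profiles."""
    return bootstrap_support(
        matrix.proportions(), list(matrix.samples.index), n_boot, seed
    )


def mother_pairs_are_cherries(
    dendrogram: SupportedDendrogram, samples: pd.DataFrame
) -> dict[int, bool]:
    """For each mother, is her NF/CR pair an immediate sister pair?"""
    out = {}
    for m, grp in samples.groupby("mother"):
        pair = tuple(grp.index)
        out[int(m)] = len(pair) == 2 and dendrogram.is_cherry(pair)
    return out
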