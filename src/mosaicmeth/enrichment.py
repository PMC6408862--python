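"""DMR-gene overlap, gene universes, and GO-term enrichment.

DMRs are intersected with gene and exon intervals (1-based inclusive at
both ends); an overlap is exonic if any exon is hit, intronic if only
intron sequence is hit, mixed if both.  Gene universes for enrichment are
built from raw, pre-smoothing methylation: a CpG counts as methylated when
its pooled methylated count across replicates is greater than zero, and a
gene joins the ">=1" / ">=3" universes according to its count of such
CpGs.

Enrichment is a one-sided hypergeometric (Fisher) test per GO term after
up-propagating gene annotations to every ancestor term.  Two algorithms
are offered: ``classic`` tests each term independently; ``elim`` walks the
hierarchy bottom-up and removes the genes of significantly enriched child
terms from their ancestors before testing them, which decorrelates nested
terms.  No multiple-testing correction is applied; terms are flagged at
alpha = 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .meth_io import GeneAnnotation, MethylationCallMatrix

logger = logging.getLogger(__name__)


@dataclass
class DmrGeneOverlap:
    dmr_id: str
    scaffold: str
    dmr_start: int
    dmr_end: int
    direction: str
    gene_id: str
    overlap_class: str        # exonic | intronic | mixed
    exon_hit: str             # e.g. "2 of 8", "" for intronic
    strand: str


@dataclass
class GeneUniverse:
    label: str                # "all" | ">=1" | ">=3"
    genes: frozenset


@dataclass
class EnrichmentResult:
    go_id: str
    namespace: str
    n_interest_with_term: int
    n_interest: int
    n_universe_with_term: int
    n_universe: int
    p: float
    significant: bool


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def _gene_trees(annotation: GeneAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gid, g in annotation.genes.iterrows():
        # half-open tree coordinates: [start, end + 1)
        trees.setdefault(g["scaffold"], IntervalTree()).addi(
            g["start"], g["end"] + 1, gid
        )
    return trees


def overlap_dmrs_genes(
    regions, annotation: GeneAnnotation
) -> tuple[list[DmrGeneOverlap], dict[str, set]]:
    """Intersect DMRs with genes and classify each overlap.

    Returns the overlap records and, per direction, the non-redundant set
    of overlapped gene ids (the enrichment input).
    """
    trees = _gene_trees(annotation)
    overlaps: list[DmrGeneOverlap] = []
    by_direction: dict[str, set] = {"hyper": set(), "hypo": set()}
    for k, reg in enumerate(regions):
        tree = trees.get(reg.scaffold)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(reg.start, reg.end + 1)):
            gid = hit.data
            exons = annotation.gene_exons(gid)
            hit_exons = [
                int(row.exon_index) for row in exons.itertuples(index=False)
                if row.start <= reg.end and row.end >= reg.start
            ]
            exon_cover = sum(
                min(reg.end, row.end) - max(reg.start, row.start) + 1
                for row in exons.itertuples(index=False)
                if row.start <= reg.end and row.end >= reg.start
            )
            total_cover = (min(reg.end, hit.end - 1)
                           - max(reg.start, hit.begin) + 1)
            if not hit_exons:
                klass, exon_str = "intronic", ""
            elif exon_cover >= total_cover:
                klass = "exonic"
                exon_str = f"{min(hit_exons)} of {annotation.n_exons(gid)}"
            else:
                klass = "mixed"
                exon_str = f"{min(hit_exons)} of {annotation.n_exons(gid)}"
            overlaps.append(DmrGeneOverlap(
                dmr_id=f"dmr{k + 1:04d}",
                scaffold=reg.scaffold,
                dmr_start=reg.start,
                dmr_end=reg.end,
                direction=reg.direction,
                gene_id=gid,
                overlap_class=klass,
                exon_hit=exon_str,
                strand=annotation.genes.loc[gid, "strand"],
            ))
            by_direction.setdefault(reg.direction, set()).add(gid)
    return overlaps, by_direction


# ---------------------------------------------------------------------------
# universes
# ---------------------------------------------------------------------------

def build_universes(
    matrix: MethylationCallMatrix,
    annotation: GeneAnnotation,
    thresholds: tuple[int, int] = (1, 3),
    per_replicate: bool = False,
) -> dict[str, GeneUniverse]:
    """Three nested gene universes from raw (pre-smoothing) methylation.

    A CpG counts as methylated when its pooled methylated count across
    replicates is greater than zero.  ``per_replicate=True`` uses a
    stricter per-replicate reading instead: the site must carry at least
    one methylated call in a majority of replicates.
    """
    if per_replicate:
        meth_site = (matrix.meth > 0).sum(axis=1) > matrix.n_replicates / 2
    else:
        meth_site = matrix.meth.sum(axis=1) > 0
    scaf = matrix.sites["scaffold"].to_numpy()
    pos = matrix.sites["position"].to_numpy()
    counts: dict[str, int] = {gid: 0 for gid in annotation.genes.index}
    for gid, g in annotation.genes.iterrows():
        sel = (scaf == g["scaffold"]) & (pos >= g["start"]) & (pos <= g["end"])
        counts[gid] = int(meth_site[sel].sum())
    all_genes = frozenset(annotation.genes.index)
    lo, hi = thresholds
    return {
        "all": GeneUniverse("all", all_genes),
        f">={lo}": GeneUniverse(
            f">={lo}", frozenset(g for g, c in counts.items() if c >= lo)),
        f">={hi}": GeneUniverse(
            f">={hi}", frozenset(g for g, c in counts.items() if c >= hi)),
    }


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def read_go_map(path) -> dict[str, set]:
    """Two-column TSV gene id -> GO id; returns gene -> term set."""
    out: dict[str, set] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            gene, term = line.rstrip("\n").split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


def read_go_parents(path) -> tuple[dict[str, set], dict[str, str]]:
    """Three-column TSV term, parent, namespace -> (parents, namespaces)."""
    parents: dict[str, set] = {}
    namespace: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            term, parent, ns = line.rstrip("\n").split("\t")[:3]
            parents.setdefault(term, set()).add(parent)
            namespace[term] = ns
            namespace.setdefault(parent, ns)
    return parents, namespace


def _ancestors(term: str, parents: dict[str, set]) -> set:
    out, stack = set(), [term]
    while stack:
        t = stack.pop()
        for p in parents.get(t, ()):  # terms without parents are root-attached
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def propagate_annotations(
    go_map: dict[str, set], parents: dict[str, set]
) -> dict[str, set]:
    """Term -> gene set after up-propagation to every ancestor term."""
    term_genes: dict[str, set] = {}
    for gene, terms in go_map.items():
        closed = set()
        for t in terms:
            closed.add(t)
            closed |= _ancestors(t, parents)
        for t in closed:
            term_genes.setdefault(t, set()).add(gene)
    return term_genes


def _term_depth(parents: dict[str, set]) -> dict[str, int]:
    depth: dict[str, int] = {}

    def get(t):
        if t not in depth:
            ps = parents.get(t, ())
            depth[t] = 0 if not ps else 1 + max(get(p) for p in ps)
        return depth[t]

    for t in set(parents) | {p for ps in parents.values() for p in ps}:
        get(t)
    return depth


def fisher_enrichment(
    interest: set,
    universe: GeneUniverse,
    go_map: dict[str, set],
    parents: dict[str, set],
    namespace: dict[str, str] | None = None,
    alpha: float = 0.01,
    algorithm: str = "classic",
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment per GO term.

    ``interest`` is intersected with the universe.  For ``elim``, terms are
    processed from deepest to shallowest; when a term comes out significant
    its annotated genes are removed from all its ancestors before those are
    tested.
    """
    if algorithm not in ("classic", "elim"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    namespace = namespace or {}
    uni = set(universe.genes)
    inter = set(interest) & uni
    term_genes = propagate_annotations(
        {g: t for g, t in go_map.items() if g in uni}, parents
    )
    depth = _term_depth(parents)
    order = sorted(term_genes, key=lambda t: (-depth.get(t, 0), t))

    eliminated: dict[str, set] = {t: set() for t in term_genes}
    results = []
    N, n_draw = len(uni), len(inter)
    for term in order:
        genes_term = (term_genes[term] & uni) - eliminated[term]
        K = len(genes_term)
        k = len(genes_term & inter)
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n_draw))
        sig = p < alpha
        results.append(EnrichmentResult(
            go_id=term,
            namespace=namespace.get(term, "?"),
            n_interest_with_term=k,
            n_interest=n_draw,
            n_universe_with_term=K,
            n_universe=N,
            p=p,
            significant=sig,
        ))
        if algorithm == "elim" and sig:
            for anc in _ancestors(term, parents):
                if anc in eliminated:
                    eliminated[anc] |= genes_term
    results.sort(key=lambda r: r.p)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
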