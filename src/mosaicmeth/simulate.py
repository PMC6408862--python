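"""Synthetic WGBS call-level data with the structure of a sparse,
"mosaic" invertebrate methylome.

The generator emulates the statistical features the downstream analysis
relies on: global CpG methylation below 1% concentrated in clusters inside
gene bodies, a paired clonal design in which the mother (pair) effect on the
methylation profile exceeds the treatment effect, 8-12x coverage, a few
percent of reads left unconverted by the bisulphite treatment (every
cytosine on such a read is called methylated, in CpG and non-CpG contexts
alike), C/T-polymorphic CpG sites that corrupt methylation calls, and
planted differentially methylated regions (DMRs) with 10-35% mean
differences, ~35% of them hypermethylated in the treated (CR) group.

Treatment and mother effects combine additively on the logit scale; the
planted DMR shift is applied on the proportion scale and clipped to [0, 1]
before the logit transform.

Two sampling routes produce the count matrix.  The count-level route draws
per-site coverage and binomial methylated counts directly (with unconverted
reads folded in analytically) and is used at the 2x10^4-CpG study scale.
The read-level route emits one row per read with a Bismark-extractor-style
call string (z/Z CpG, x/X CHG, h/H CHH; lower case = unmethylated) and
derives the matrix by aggregating reads; it exists to exercise the
non-conversion filter.  Both routes implement the same generative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import meth_io
from .meth_io import GeneAnnotation, MethylationCallMatrix, sort_sites

_EPS = 1e-6


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_scaffolds: int = 1
    scaffold_length: int = 1_000_000
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (3, 8)
    cpg_density: float = 20.0              # CpGs per kbp
    frac_methylated_sites: float = 0.007   # of gene-body CpGs drawn "high"
    high_beta_params: tuple[float, float] = (6.0, 2.0)
    low_beta_params: tuple[float, float] = (0.2, 150.0)
    methylated_cluster_cpgs: tuple[int, int] = (3, 20)
    n_pairs: int = 6
    coverage_mean: float = 10.0
    coverage_model: str = "poisson"        # or "negative-binomial"
    coverage_dispersion: float = 5.0       # NB size parameter
    mother_sd: float = 0.3                 # random mother effect, logit scale
    n_dmrs: int = 20
    dmr_effect: tuple[float, float] = (0.10, 0.35)
    dmr_width: tuple[int, int] = (3, 20)   # CpGs per planted region
    frac_hyper: float = 0.35
    conversion_failure_rate: float = 0.03
    n_snps: int = 0                        # C/T- or G/A-confounded CpGs
    read_length: int = 100
    noncpg_per_read: float = 8.0           # mean CHH/CHG cytosines per read
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_methylated_sites", "frac_hyper",
                     "conversion_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.dmr_width[0] < 1:
            raise ValueError("dmr_width minimum must be >= 1")
        if not 0.0 <= self.dmr_effect[0] <= self.dmr_effect[1] <= 1.0:
            raise ValueError("dmr_effect range invalid")
        if self.coverage_model not in ("poisson", "negative-binomial"):
            raise ValueError(f"unknown coverage_model {self.coverage_model!r}")
        if self.cpg_density <= 0 or self.scaffold_length <= 0:
            raise ValueError("cpg_density and scaffold_length must be positive")


@dataclass
class GenomeModel:
    """Scaffolds, gene/exon intervals and annotated CpG positions."""

    scaffold_lengths: dict[str, int]
    annotation: GeneAnnotation
    cpgs: pd.DataFrame  # scaffold, position, strand, genic, exonic, gene_id, baseline

    @property
    def n_cpgs(self) -> int:
        return len(self.cpgs)

    def expected_global_methylation(self) -> float:
        """Mean of the realised per-site baseline mixture, as a proportion."""
        return float(self.cpgs["baseline"].mean())


@dataclass
class SimulationTruth:
    """Planted ground truth for recovery testing."""

    dmrs: pd.DataFrame        # scaffold, start, end, direction, effect, n_cpgs
    snps: pd.DataFrame        # scaffold, position(site), snp_position, ref, alt
    levels: Optional[np.ndarray] = None  # per-site x replicate true levels
    decoy_variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["scaffold", "position", "ref", "alt"]
        )
    )

    @property
    def masked_sites(self) -> set[tuple[str, int]]:
        return set(zip(self.snps["scaffold"], self.snps["position"]))


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

def build_genome_model(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenomeModel:
    """Lay out scaffolds, genes/exons and CpG sites, and draw baselines.

    Gene bodies tile roughly half of each scaffold.  Target-fraction runs of
    consecutive exonic CpGs are assigned "high" baseline methylation drawn
    from the high beta component; everything else draws from the low
    component, yielding the mosaic pattern.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    genes_per_scaffold = _split_counts(config.n_genes, config.n_scaffolds)
    scaffold_lengths: dict[str, int] = {}
    gene_rows, exon_rows = [], []
    cpg_frames = []

    for s in range(config.n_scaffolds):
        name = f"scaffold{s + 1:05d}"
        length = config.scaffold_length
        scaffold_lengths[name] = length
        n_g = genes_per_scaffold[s]

        # non-overlapping genes on a jittered grid, ~50% genome coverage
        if n_g > 0:
            slot = length // n_g
            gene_len = max(200, int(0.5 * slot))
            if slot < gene_len + 10 or gene_len < 60:
                raise ValueError(
                    f"scaffold length {length} too short for {n_g} genes"
                )
            for g in range(n_g):
                lo = g * slot + 1
                start = int(lo + rng.integers(0, slot - gene_len - 1))
                end = start + gene_len - 1
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"gene{len(gene_rows) + 1:05d}"
                gene_rows.append((gid, name, start, end, strand))
                exon_rows.extend(_draw_exons(gid, start, end, strand, config, rng))

        # CpG positions: uniform draws, unique, spaced >= 2 bp
        n_cpg = int(round(config.cpg_density * length / 1000.0))
        pos = np.unique(rng.integers(1, length, size=n_cpg))
        pos = pos[np.concatenate(([True], np.diff(pos) >= 2))]
        cpg_frames.append(pd.DataFrame({
            "scaffold": name,
            "position": pos.astype(np.int64),
            "strand": "+",
        }))

    genes_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "scaffold", "start", "end", "strand"]
    ).set_index("gene_id")
    exons_df = pd.DataFrame(
        exon_rows, columns=["gene_id", "exon_index", "start", "end"]
    )
    annotation = GeneAnnotation(genes_df, exons_df)

    cpgs = pd.concat(cpg_frames, ignore_index=True)
    cpgs = sort_sites(cpgs)
    cpgs["genic"] = False
    cpgs["exonic"] = False
    cpgs["gene_id"] = ""
    for gid, g in genes_df.iterrows():
        in_gene = (
            (cpgs["scaffold"] == g["scaffold"])
            & (cpgs["position"] >= g["start"])
            & (cpgs["position"] <= g["end"])
        )
        cpgs.loc[in_gene, ["genic", "gene_id"]] = [True, gid]
    for row in exons_df.itertuples(index=False):
        g = genes_df.loc[row.gene_id]
        in_exon = (
            (cpgs["scaffold"] == g["scaffold"])
            & (cpgs["position"] >= row.start)
            & (cpgs["position"] <= row.end)
        )
        cpgs.loc[in_exon, "exonic"] = True

    _assign_baselines(cpgs, config, rng)
    return GenomeModel(scaffold_lengths, annotation, cpgs)


def _split_counts(total: int, bins: int) -> list[int]:
    base, rem = divmod(total, bins)
    return [base + (1 if i < rem else 0) for i in range(bins)]


def _draw_exons(gid, start, end, strand, config, rng):
    k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    length = end - start + 1
    n_seg = 2 * k - 1  # exon, intron, exon, ...
    if length < n_seg * 2:
        k, n_seg = 1, 1
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False)) \
        if n_seg > 1 else np.array([], dtype=int)
    bounds = np.concatenate(([0], cuts, [length]))
    segments = [
        (start + int(bounds[i]), start + int(bounds[i + 1]) - 1)
        for i in range(n_seg)
    ]
    exon_iv = segments[::2]  # even segments are exons
    if strand == "-":
        exon_iv = exon_iv[::-1]
    return [(gid, i, s, e) for i, (s, e) in enumerate(exon_iv, start=1)]


def _assign_baselines(cpgs: pd.DataFrame, config: SimulationConfig,
                      rng: np.random.Generator) -> None:
    """Mark clustered exonic CpG runs as "high" and draw beta baselines."""
    n = len(cpgs)
    high = np.zeros(n, dtype=bool)
    n_genic = int(cpgs["genic"].sum())
    target = int(round(config.frac_methylated_sites * n_genic))

    runs = _exonic_runs(cpgs)
    lo, hi = config.methylated_cluster_cpgs
    n_high, attempts = 0, 0
    while n_high < target and runs and attempts < 50 * max(1, config.n_genes):
        attempts += 1
        r0, r1 = runs[rng.integers(len(runs))]
        width = int(rng.integers(lo, hi + 1))
        if r1 - r0 + 1 < lo:
            continue
        width = min(width, r1 - r0 + 1)
        s = int(rng.integers(r0, r1 - width + 2))
        seg = slice(s, s + width)
        if high[seg].any():
            continue
        high[seg] = True
        n_high += width

    baseline = rng.beta(*config.low_beta_params, size=n)
    if high.any():
        baseline[high] = rng.beta(*config.high_beta_params, size=int(high.sum()))
    cpgs["high"] = high
    cpgs["baseline"] = baseline


def _exonic_runs(cpgs: pd.DataFrame) -> list[tuple[int, int]]:
    """Maximal runs of consecutive row indices that are exonic CpGs of one gene."""
    exonic = cpgs["exonic"].to_numpy()
    gene = cpgs["gene_id"].to_numpy()
    scaf = cpgs["scaffold"].to_numpy()
    runs, start = [], None
    n = len(cpgs)
    for i in range(n):
        if not exonic[i]:
            if start is not None:
                runs.append((start, i - 1))
                start = None
        elif start is None:
            start = i
        elif gene[i] != gene[i - 1] or scaf[i] != scaf[i - 1]:
            runs.append((start, i - 1))
            start = i
    if start is not None:
        runs.append((start, n - 1))
    return runs


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------

def plant_dmrs(model: GenomeModel, config: SimulationConfig,
               rng: np.random.Generator | None = None) -> SimulationTruth:
    """Plant disjoint DMRs on runs of consecutive exonic CpGs.

    Direction is hyper (methylation gained under CR) with probability
    ``frac_hyper``.  Hypomethylated regions need headroom to lose signal, so
    their member sites are re-drawn from the high beta component before the
    effect is subtracted.  The shifted CR-group level is clipped to [0, 1].
    Also plants ``n_snps`` C/T (or G/A at the following G) polymorphisms on
    CpG sites outside the planted DMRs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cpgs = model.cpgs
    runs = _exonic_runs(cpgs)
    lo_w, hi_w = config.dmr_width
    taken = np.zeros(len(cpgs), dtype=bool)
    dmr_rows = []
    member_idx: list[np.ndarray] = []

    for d in range(config.n_dmrs):
        placed = False
        for _attempt in range(2000):
            if not runs:
                break
            r0, r1 = runs[rng.integers(len(runs))]
            if r1 - r0 + 1 < lo_w:
                continue
            width = int(rng.integers(lo_w, min(hi_w, r1 - r0 + 1) + 1))
            s = int(rng.integers(r0, r1 - width + 2))
            seg = np.arange(s, s + width)
            if taken[seg].any():
                continue
            taken[seg] = True
            direction = "hyper" if rng.random() < config.frac_hyper else "hypo"
            effect = float(rng.uniform(*config.dmr_effect))
            if direction == "hypo":
                # ensure headroom: members get high baselines
                cpgs.loc[cpgs.index[seg], "baseline"] = rng.beta(
                    *config.high_beta_params, size=width
                )
                cpgs.loc[cpgs.index[seg], "high"] = True
            dmr_rows.append((
                cpgs["scaffold"].iloc[s],
                int(cpgs["position"].iloc[s]),
                int(cpgs["position"].iloc[s + width - 1]),
                direction, effect, width,
            ))
            member_idx.append(seg)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place DMR {d + 1}/{config.n_dmrs}: not enough "
                f"disjoint exonic CpG runs of width >= {lo_w}"
            )

    dmrs = pd.DataFrame(
        dmr_rows,
        columns=["scaffold", "start", "end", "direction", "effect", "n_cpgs"],
    )
    dmrs.attrs["member_idx"] = member_idx

    # SNP confounders on CpG sites outside DMRs
    snp_rows = []
    free = np.flatnonzero(~taken)
    if config.n_snps > 0:
        if len(free) < config.n_snps:
            raise RuntimeError("not enough CpG sites free of DMRs for SNPs")
        chosen = rng.choice(free, size=config.n_snps, replace=False)
        for i in np.sort(chosen):
            sc = cpgs["scaffold"].iloc[i]
            p = int(cpgs["position"].iloc[i])
            if rng.random() < 0.5:
                snp_rows.append((sc, p, p, "C", "T"))
            else:  # G/A on the following G of the dinucleotide
                snp_rows.append((sc, p, p + 1, "G", "A"))
    snps = pd.DataFrame(
        snp_rows, columns=["scaffold", "position", "snp_position", "ref", "alt"]
    )
    return SimulationTruth(dmrs=dmrs, snps=snps)


# ---------------------------------------------------------------------------
# counts and reads
# ---------------------------------------------------------------------------

def _replicate_table(n_pairs: int) -> pd.DataFrame:
    rows = []
    for m in range(1, n_pairs + 1):
        rows.append((f"NF{m}", m, "NF"))
        rows.append((f"CR{m}", m, "CR"))
    return pd.DataFrame(
        rows, columns=["replicate", "mother", "treatment"]
    ).set_index("replicate")


def true_levels(model: GenomeModel, truth: SimulationTruth,
                config: SimulationConfig,
                rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-site x per-replicate methylation levels under the effect model."""
    cpgs = model.cpgs
    n = len(cpgs)
    samples = _replicate_table(config.n_pairs)

    base_nf = cpgs["baseline"].to_numpy(dtype=float)
    base_cr = base_nf.copy()
    site_key = dict(
        ((sc, p), i)
        for i, (sc, p) in enumerate(zip(cpgs["scaffold"], cpgs["position"]))
    )
    scaffolds = cpgs["scaffold"].to_numpy()
    positions = cpgs["position"].to_numpy()
    for reg in truth.dmrs.itertuples(index=False):
        seg = np.flatnonzero(
            (scaffolds == reg.scaffold)
            & (positions >= reg.start)
            & (positions <= reg.end)
        )
        shift = reg.effect if reg.direction == "hyper" else -reg.effect
        base_cr[seg] = np.clip(base_cr[seg] + shift, 0.0, 1.0)

    mother_eff = rng.normal(0.0, config.mother_sd, size=(n, config.n_pairs))
    levels = np.empty((n, len(samples)))
    for j, (rep, row) in enumerate(samples.iterrows()):
        base = base_cr if row["treatment"] == "CR" else base_nf
        logit = np.log(np.clip(base, _EPS, 1 - _EPS) /
                       (1 - np.clip(base, _EPS, 1 - _EPS)))
        logit = logit + mother_eff[:, row["mother"] - 1]
        levels[:, j] = 1.0 / (1.0 + np.exp(-logit))

    # heterozygous C/T (or G/A) SNP: the alternate allele's reads are
    # miscalled as unmethylated C, halving the apparent level
    for sc, p in truth.masked_sites:
        i = site_key.get((sc, p))
        if i is not None:
            levels[i, :] *= 0.5
    return levels, samples


def simulate_counts(
    truth: SimulationTruth,
    model: GenomeModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    reads: bool = False,
) -> tuple[MethylationCallMatrix, Optional[pd.DataFrame]]:
    """Draw the observed count matrix (and optionally the read-level table).

    With ``reads=False`` coverage and methylated counts are drawn per site,
    and unconverted reads are folded in analytically: of ``c`` reads at a
    site, ``u ~ Binomial(c, f)`` are unconverted and always methylated, the
    rest are methylated with the site/replicate true level.  With
    ``reads=True`` individual reads with call strings are generated and the
    matrix is their aggregation; the marginal distribution of the counts is
    the same.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    levels, samples = true_levels(model, truth, config, rng)
    truth.levels = levels
    if reads:
        return _simulate_reads(levels, samples, model, config, rng)

    n, r = levels.shape
    cov = _draw_coverage(config, rng, (n, r))
    f = config.conversion_failure_rate
    unconv = rng.binomial(cov, f) if f > 0 else np.zeros_like(cov)
    meth = rng.binomial(cov - unconv, levels) + unconv
    unmeth = cov - meth
    matrix = MethylationCallMatrix(
        model.cpgs[meth_io.SITE_COLUMNS].copy(), meth, unmeth, samples
    )
    return matrix, None


def _draw_coverage(config, rng, shape):
    if config.coverage_model == "poisson":
        return rng.poisson(config.coverage_mean, size=shape)
    size = config.coverage_dispersion
    p = size / (size + config.coverage_mean)
    return rng.negative_binomial(size, p, size=shape)


def _simulate_reads(levels, samples, model, config, rng):
    """Read-level route: uniform read starts, per-read call strings."""
    cpgs = model.cpgs
    rows = []
    n_sites = len(cpgs)
    meth = np.zeros((n_sites, len(samples)), dtype=np.int64)
    cov = np.zeros_like(meth)
    L = config.read_length
    scaffold_offsets = {}
    # per-scaffold site index ranges
    for sc, grp in cpgs.groupby("scaffold", sort=False):
        scaffold_offsets[sc] = (grp.index[0], grp.index[-1] + 1)

    for j, rep in enumerate(samples.index):
        for sc, length in model.scaffold_lengths.items():
            lo, hi = scaffold_offsets.get(sc, (0, 0))
            pos = cpgs["position"].to_numpy()[lo:hi]
            n_reads = int(round(config.coverage_mean * length / L))
            starts = rng.integers(1, max(2, length - L + 1), size=n_reads)
            starts.sort()
            unconv = rng.random(n_reads) < config.conversion_failure_rate
            i0 = np.searchsorted(pos, starts)
            i1 = np.searchsorted(pos, starts + L)  # sites in [start, start+L)
            n_noncpg = rng.poisson(config.noncpg_per_read, size=n_reads)
            for k in range(n_reads):
                site_idx = np.arange(i0[k], i1[k])
                if unconv[k]:
                    cpg_calls = np.ones(len(site_idx), dtype=bool)
                else:
                    cpg_calls = rng.random(len(site_idx)) < levels[lo + site_idx, j]
                meth[lo + site_idx, j] += cpg_calls
                cov[lo + site_idx, j] += 1
                chars = ["Z" if c else "z" for c in cpg_calls]
                for _ in range(n_noncpg[k]):
                    ctx = "x" if rng.random() < 1 / 3 else "h"
                    chars.append(ctx.upper() if unconv[k] else ctx)
                rows.append((rep, sc, int(starts[k]), "".join(chars)))

    read_table = pd.DataFrame(
        rows, columns=["replicate", "scaffold", "start", "calls"]
    )
    matrix = MethylationCallMatrix(
        cpgs[meth_io.SITE_COLUMNS].copy(), meth, cov - meth, samples
    )
    return matrix, read_table


def aggregate_reads(read_table: pd.DataFrame, model: GenomeModel,
                    samples: pd.DataFrame,
                    read_length: int) -> MethylationCallMatrix:
    """Rebuild the per-site count matrix from a (possibly filtered) read table.

    Only CpG calls (z/Z) are counted; the k-th z/Z character of a read is
    matched to the k-th CpG site within [start, start + read_length).
    """
    cpgs = model.cpgs
    n_sites = len(cpgs)
    meth = np.zeros((n_sites, len(samples)), dtype=np.int64)
    cov = np.zeros_like(meth)
    pos_by_scaffold = {
        sc: (grp.index[0], grp["position"].to_numpy())
        for sc, grp in cpgs.groupby("scaffold", sort=False)
    }
    rep_col = {rep: j for j, rep in enumerate(samples.index)}
    for row in read_table.itertuples(index=False):
        j = rep_col[row.replicate]
        off, pos = pos_by_scaffold[row.scaffold]
        i0 = np.searchsorted(pos, row.start)
        cpg_calls = [c for c in row.calls if c in "zZ"]
        for k, c in enumerate(cpg_calls):
            i = off + i0 + k
            cov[i, j] += 1
            if c == "Z":
                meth[i, j] += 1
    return MethylationCallMatrix(
        cpgs[meth_io.SITE_COLUMNS].copy(), meth, cov - meth, samples
    )


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, reads: bool = False):
    """Convenience: genome model -> truth -> counts in one call."""
    rng = np.random.default_rng(config.seed)
    model = build_genome_model(config, rng)
    truth = plant_dmrs(model, config, rng)
    matrix, read_table = simulate_counts(truth, model, config, rng, reads=reads)
    return model, truth, matrix, read_table


def emit_dataset(matrix: MethylationCallMatrix,
                 truth: SimulationTruth,
                 model: GenomeModel,
                 outdir,
                 read_table: Optional[pd.DataFrame] = None) -> dict[str, Path]:
    """Write the simulated dataset in the pipeline's on-disk formats.

    Per-replicate Bismark cytosine reports, the gene annotation as BED12,
    planted variants as minimal VCF v4.2 (passing GATK-style annotations),
    truth tables as TSV/BED, the sample sheet, and the read-level call table
    when present.
    """
    outdir = Path(outdir)
    (outdir / "calls").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for j, rep in enumerate(matrix.samples.index):
        p = outdir / "calls" / f"{rep}.CpG_report.txt"
        meth_io.write_cytosine_report(p, matrix.sites, matrix.meth[:, j],
                                      matrix.unmeth[:, j])
        paths[f"calls/{rep}"] = p

    paths["samples"] = outdir / "samples.tsv"
    matrix.samples.to_csv(paths["samples"], sep="\t")

    paths["genes"] = outdir / "genes.bed"
    model.annotation.to_bed12(paths["genes"])

    # variants: planted SNPs pass every hard-filter threshold
    var_rows = [
        dict(scaffold=r.scaffold, position=int(r.snp_position), ref=r.ref,
             alt=r.alt, QD=25.0, FS=5.0, MQ=60.0, MQRankSum=0.0,
             ReadPosRankSum=0.0)
        for r in truth.snps.itertuples(index=False)
    ]
    for r in truth.decoy_variants.itertuples(index=False):
        var_rows.append(dict(scaffold=r.scaffold, position=int(r.position),
                             ref=r.ref, alt=r.alt, QD=1.0, FS=80.0, MQ=20.0,
                             MQRankSum=-20.0, ReadPosRankSum=-10.0))
    variants = pd.DataFrame(
        var_rows, columns=["scaffold", "position", "ref", "alt", "QD", "FS",
                           "MQ", "MQRankSum", "ReadPosRankSum"]
    ).sort_values(["scaffold", "position"])
    paths["vcf"] = outdir / "variants.vcf"
    meth_io.write_vcf(paths["vcf"], variants,
                      contigs=sorted(model.scaffold_lengths))

    paths["truth_dmrs"] = outdir / "truth_dmrs.tsv"
    truth.dmrs.to_csv(paths["truth_dmrs"], sep="\t", index=False)
    paths["truth_dmrs_bed"] = outdir / "truth_dmrs.bed"
    with open(paths["truth_dmrs_bed"], "w") as out:
        for r in truth.dmrs.itertuples(index=False):
            out.write(f"{r.scaffold}\t{r.start - 1}\t{r.end}\t"
                      f"{r.direction}\t0\t.\n")

    if read_table is not None:
        paths["reads"] = outdir / "reads.tsv"
        read_table.to_csv(paths["reads"], sep="\t", index=False)
    return paths


def emit_synthetic_ontology(annotation: GeneAnnotation, outdir,
                            rng: np.random.Generator,
                            enriched_genes: Optional[list[str]] = None
                            ) -> tuple[Path, Path]:
    """Write a small synthetic GO-like ontology for demo/enrichment runs.

    Two namespaces, a three-level term hierarchy, random gene-term
    assignments, plus one term concentrated on *enriched_genes* so an
    enrichment run has something to find.  Purely synthetic stand-in for a
    real GO annotation table.
    """
    outdir = Path(outdir)
    genes = list(annotation.genes.index)
    parents = []
    leaf_terms = []
    for ns in ("BP", "MF"):
        root = f"SYN:{ns}0000"
        for i in range(1, 4):
            mid = f"SYN:{ns}{i:04d}"
            parents.append((mid, root, ns))
            for k in range(1, 3):
                leaf = f"SYN:{ns}{i:04d}{k}"
                leaf_terms.append(leaf)
                parents.append((leaf, mid, ns))
    go_map = []
    for g in genes:
        for t in rng.choice(leaf_terms, size=rng.integers(1, 4), replace=False):
            go_map.append((g, t))
    if enriched_genes:
        target = leaf_terms[0]
        for g in enriched_genes:
            go_map.append((g, target))
    go_map = sorted(set(go_map))
    map_path = outdir / "synthetic_go_map.tsv"
    with open(map_path, "w") as out:
        for g, t in go_map:
            out.write(f"{g}\t{t}\n")
    parent_path = outdir / "synthetic_go_parents.tsv"
    with open(parent_path, "w") as out:
        for child, parent, ns in parents:
            out.write(f"{child}\t{parent}\t{ns}\n")
    return map_path, parent_path
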