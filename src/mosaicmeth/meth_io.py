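"""Readers, writers and core containers for methylation-call data.

All genomic coordinates inside the package are 1-based inclusive, the
convention of Bismark cytosine reports.  BED output converts to 0-based
half-open at the boundary, and BED input converts back.  Region length is
defined as ``end - start``.

Forward- and reverse-strand CpG calls are kept as separate sites by default;
:func:`collapse_strands` merges the C of a CpG (position p, ``+``) with the G
(position p+1, ``-``) when a dinucleotide-level view is wanted.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["scaffold", "position", "strand"]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# per-site records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpGSiteRecord:
    """One cytosine with its methylated / unmethylated read counts."""

    scaffold: str
    position: int  # 1-based position of the C on the reported strand
    strand: str    # '+', '-' or '.' when unknown (coverage format)
    meth_count: int
    unmeth_count: int

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError("negative counts")


def read_cytosine_report(path, context: str = "CG") -> list[CpGSiteRecord]:
    """Parse a Bismark cytosine report, keeping one cytosine context.

    The report is 7-column TSV: chromosome, 1-based position, strand, count
    methylated, count unmethylated, context (CG/CHG/CHH), trinucleotide.
    Records whose context differs from *context* are dropped.
    """
    records: list[CpGSiteRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, "
                    f"got {len(fields)}"
                )
            scaffold, pos, strand, meth, unmeth, ctx, _tri = fields
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            if ctx != context:
                continue
            try:
                records.append(
                    CpGSiteRecord(scaffold, int(pos), strand, int(meth), int(unmeth))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        logger.warning("no %s records found in %s", context, path)
    return records


def read_coverage_file(path) -> list[CpGSiteRecord]:
    """Parse a Bismark coverage file (chrom, start, end, %meth, meth, unmeth).

    The percentage column is ignored in favour of the counts but checked for
    consistency (warn if it disagrees by more than 0.1).  Strand is unknown
    in this format and recorded as ``'.'``.
    """
    records: list[CpGSiteRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            scaffold, start, end, pct, meth, unmeth = fields
            if int(start) != int(end):
                raise ValueError(
                    f"{path}:{lineno}: start != end; CpG-resolution input expected"
                )
            rec = CpGSiteRecord(scaffold, int(start), ".", int(meth), int(unmeth))
            if rec.coverage > 0:
                derived = 100.0 * rec.meth_count / rec.coverage
                if abs(derived - float(pct)) > 0.1:
                    warnings.warn(
                        f"{path}:{lineno}: % column {pct} disagrees with "
                        f"counts-derived {derived:.3f}"
                    )
            records.append(rec)
    if not records:
        logger.warning("no records found in %s", path)
    return records


# ---------------------------------------------------------------------------
# call matrix
# ---------------------------------------------------------------------------

@dataclass
class MethylationCallMatrix:
    """Per-CpG methylated/unmethylated counts across replicates.

    ``sites`` has columns scaffold, position, strand and is sorted by
    (scaffold lexicographic, position numeric).  ``meth`` / ``unmeth`` are
    (n_sites, n_replicates) integer arrays aligned to ``sites`` rows and
    ``samples`` rows.  ``samples`` is indexed by replicate id and carries
    ``mother`` and ``treatment`` (``NF`` / ``CR``) columns.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    unmeth: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self):
        self.meth = np.asarray(self.meth)
        self.unmeth = np.asarray(self.unmeth)
        if self.meth.shape != self.unmeth.shape:
            raise ValueError("meth/unmeth shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count arrays do not match sites x samples")

    # -- basic views -------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_replicates(self) -> int:
        return len(self.samples)

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def proportions(self) -> np.ndarray:
        """Raw methylation proportions; NaN where coverage is zero."""
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.meth / cov, np.nan)

    def replicate_indices(self, treatment: str) -> np.ndarray:
        return np.flatnonzero((self.samples["treatment"] == treatment).to_numpy())

    def subset_sites(self, mask: np.ndarray) -> "MethylationCallMatrix":
        mask = np.asarray(mask)
        return MethylationCallMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask],
            self.unmeth[mask],
            self.samples,
        )

    # -- paired design -----------------------------------------------------
    def validate_paired(self) -> None:
        """Require exactly one NF and one CR replicate per mother."""
        for trt in ("NF", "CR"):
            if (self.samples["treatment"] == trt).sum() == 0:
                raise ValueError(f"no {trt} replicates present")
        tab = self.samples.groupby("mother")["treatment"].apply(
            lambda s: sorted(s.tolist())
        )
        bad = [m for m, t in tab.items() if t != ["CR", "NF"]]
        if bad:
            raise ValueError(f"unpaired mothers: {bad}")

    def pair_columns(self) -> tuple[np.ndarray, np.ndarray, list]:
        """Column indices of (NF, CR) replicates, mother-aligned."""
        self.validate_paired()
        mothers = sorted(self.samples["mother"].unique())
        nf_idx, cr_idx = [], []
        positions = {rep: i for i, rep in enumerate(self.samples.index)}
        for m in mothers:
            rows = self.samples[self.samples["mother"] == m]
            nf_idx.append(positions[rows[rows["treatment"] == "NF"].index[0]])
            cr_idx.append(positions[rows[rows["treatment"] == "CR"].index[0]])
        return np.array(nf_idx), np.array(cr_idx), mothers


def sort_sites(sites: pd.DataFrame) -> pd.DataFrame:
    return sites.sort_values(
        ["scaffold", "position", "strand"], kind="mergesort"
    ).reset_index(drop=True)


def assemble_matrix(
    records_per_replicate: dict[str, Sequence[CpGSiteRecord]],
    metadata: pd.DataFrame,
    paired: bool = True,
) -> MethylationCallMatrix:
    """Union replicate-level site records into one count matrix.

    *metadata* is indexed by replicate id with ``mother`` and ``treatment``
    columns; every replicate in *records_per_replicate* must appear.  A site
    absent from a replicate gets counts (0, 0).
    """
    missing = set(records_per_replicate) - set(metadata.index)
    if missing:
        raise ValueError(f"replicates without metadata: {sorted(missing)}")
    reps = [r for r in metadata.index if r in records_per_replicate]
    if not reps:
        raise ValueError("no replicates supplied")

    keyed: dict[str, dict[tuple, CpGSiteRecord]] = {}
    all_keys: set[tuple] = set()
    for rep in reps:
        d: dict[tuple, CpGSiteRecord] = {}
        for rec in records_per_replicate[rep]:
            key = (rec.scaffold, rec.position, rec.strand)
            if key in d:
                raise ValueError(f"duplicate site {key} in replicate {rep}")
            d[key] = rec
        keyed[rep] = d
        all_keys.update(d)

    sites = sort_sites(
        pd.DataFrame(sorted(all_keys), columns=SITE_COLUMNS)
    )
    keys = list(zip(sites["scaffold"], sites["position"], sites["strand"]))
    meth = np.zeros((len(keys), len(reps)), dtype=np.int64)
    unmeth = np.zeros_like(meth)
    for j, rep in enumerate(reps):
        d = keyed[rep]
        for i, key in enumerate(keys):
            rec = d.get(key)
            if rec is not None:
                meth[i, j] = rec.meth_count
                unmeth[i, j] = rec.unmeth_count
    matrix = MethylationCallMatrix(sites, meth, unmeth, metadata.loc[reps])
    if paired:
        matrix.validate_paired()
    return matrix


def collapse_strands(matrix: MethylationCallMatrix) -> MethylationCallMatrix:
    """Merge +strand C at p with -strand G-side call at p+1 into one site."""
    sites = matrix.sites
    pos = sites["position"].to_numpy()
    scaf = sites["scaffold"].to_numpy()
    strand = sites["strand"].to_numpy()
    # map every site onto the forward C position of its dinucleotide
    anchor = np.where(strand == "-", pos - 1, pos)
    key = pd.DataFrame({"scaffold": scaf, "position": anchor})
    grouped = key.groupby(["scaffold", "position"], sort=True).indices
    new_sites, meth_rows, unmeth_rows = [], [], []
    for (sc, p), idx in grouped.items():
        new_sites.append((sc, p, "+"))
        meth_rows.append(matrix.meth[list(idx)].sum(axis=0))
        unmeth_rows.append(matrix.unmeth[list(idx)].sum(axis=0))
    df = pd.DataFrame(new_sites, columns=SITE_COLUMNS)
    order = df.sort_values(
        ["scaffold", "position", "strand"], kind="mergesort"
    ).index.to_numpy()
    sites_df = df.loc[order].reset_index(drop=True)
    meth = np.vstack(meth_rows)[order]
    unmeth = np.vstack(unmeth_rows)[order]
    return MethylationCallMatrix(sites_df, meth, unmeth, matrix.samples)


def write_cytosine_report(path, sites: pd.DataFrame, meth: np.ndarray,
                          unmeth: np.ndarray) -> None:
    """Write one replicate's counts as a Bismark cytosine report."""
    with open(path, "w") as out:
        for i, row in enumerate(sites.itertuples(index=False)):
            out.write(
                f"{row.scaffold}\t{row.position}\t{row.strand}\t"
                f"{int(meth[i])}\t{int(unmeth[i])}\tCG\tCGN\n"
            )


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene and exon intervals, 1-based inclusive.

    ``genes``: DataFrame indexed by gene id with scaffold, start, end, strand.
    ``exons``: DataFrame with gene_id, exon_index (1-based, transcription
    order), start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self):
        for gid, grp in self.exons.groupby("gene_id"):
            g = self.genes.loc[gid]
            if (grp["start"] < g["start"]).any() or (grp["end"] > g["end"]).any():
                raise ValueError(f"exons of {gid} extend outside gene interval")

    def n_exons(self, gene_id: str) -> int:
        return int((self.exons["gene_id"] == gene_id).sum())

    def gene_exons(self, gene_id: str) -> pd.DataFrame:
        return self.exons[self.exons["gene_id"] == gene_id].sort_values("exon_index")

    @classmethod
    def from_bed12(cls, path) -> "GeneAnnotation":
        genes, exons = [], []
        with _open_text(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                if len(f) < 12:
                    raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
                scaffold, start0, end, name, _score, strand = f[:6]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                gstart = int(start0) + 1  # to 1-based inclusive
                genes.append((name, scaffold, gstart, int(end), strand))
                block_iv = [
                    (gstart + off, gstart + off + size - 1)
                    for off, size in zip(offsets, sizes)
                ]
                # exon index 1 = first exon in transcription order
                if strand == "-":
                    block_iv = block_iv[::-1]
                for k, (s, e) in enumerate(block_iv, start=1):
                    exons.append((name, k, s, e))
                if n_blocks != len(sizes):
                    raise ValueError(f"{path}:{lineno}: blockCount mismatch")
        genes_df = pd.DataFrame(
            genes, columns=["gene_id", "scaffold", "start", "end", "strand"]
        ).set_index("gene_id")
        exons_df = pd.DataFrame(exons, columns=["gene_id", "exon_index", "start", "end"])
        return cls(genes_df, exons_df)

    @classmethod
    def from_gff3(cls, path) -> "GeneAnnotation":
        """Read gene/exon features from GFF3 (gene + exon rows, ID/Parent)."""
        genes, exon_rows = [], []
        with _open_text(path) as handle:
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) != 9:
                    continue
                scaffold, _src, ftype, start, end, _score, strand, _frame, attrs = f
                attrd = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                if ftype == "gene":
                    genes.append((attrd["ID"], scaffold, int(start), int(end), strand))
                elif ftype == "exon":
                    exon_rows.append((attrd["Parent"], int(start), int(end), strand))
        genes_df = pd.DataFrame(
            genes, columns=["gene_id", "scaffold", "start", "end", "strand"]
        ).set_index("gene_id")
        exons = []
        df = pd.DataFrame(exon_rows, columns=["gene_id", "start", "end", "strand"])
        for gid, grp in df.groupby("gene_id"):
            grp = grp.sort_values("start", ascending=grp["strand"].iloc[0] != "-")
            for k, row in enumerate(grp.itertuples(index=False), start=1):
                exons.append((gid, k, row.start, row.end))
        exons_df = pd.DataFrame(exons, columns=["gene_id", "exon_index", "start", "end"])
        return cls(genes_df, exons_df)

    def to_bed12(self, path) -> None:
        with open(path, "w") as out:
            for gid, g in self.genes.iterrows():
                ex = self.gene_exons(gid).sort_values("start")
                sizes = ",".join(str(e - s + 1) for s, e in zip(ex["start"], ex["end"]))
                offsets = ",".join(str(s - g["start"]) for s in ex["start"])
                out.write(
                    f"{g['scaffold']}\t{g['start'] - 1}\t{g['end']}\t{gid}\t0\t"
                    f"{g['strand']}\t{g['start'] - 1}\t{g['end']}\t0\t{len(ex)}\t"
                    f"{sizes}\t{offsets}\n"
                )


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def read_vcf(path) -> pd.DataFrame:
    """Read SNVs from a VCF into a DataFrame.

    Indels and multi-allelic records are counted, logged and skipped.
    Missing hard-filter annotations come back as NaN.  Columns: scaffold,
    position, ref, alt, QD, FS, MQ, MQRankSum, ReadPosRankSum.
    """
    keys = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"]
    rows, skipped = [], 0
    save = pysam.set_verbosity(0)  # silence missing-contig-header warnings
    try:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                alts = rec.alts or ()
                if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                    skipped += 1
                    continue
                info = dict(rec.info)
                rows.append(
                    [rec.chrom, rec.pos, rec.ref, alts[0]]
                    + [float(info[k]) if k in info else np.nan for k in keys]
                )
    finally:
        pysam.set_verbosity(save)
    if skipped:
        logger.info("skipped %d non-SNV/multiallelic VCF records", skipped)
    return pd.DataFrame(
        rows, columns=["scaffold", "position", "ref", "alt"] + keys
    )


def write_vcf(path, variants: pd.DataFrame, contigs: Iterable[str] = ()) -> None:
    """Write a minimal VCF v4.2 with the GATK hard-filter INFO keys."""
    keys = ["QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum"]
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            out.write(f"##contig=<ID={c}>\n")
        for k in keys:
            out.write(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            info = ";".join(
                f"{k}={getattr(row, k):g}"
                for k in keys
                if pd.notna(getattr(row, k, np.nan))
            )
            out.write(
                f"{row.scaffold}\t{row.position}\t.\t{row.ref}\t{row.alt}\t50\t"
                f"PASS\t{info or '.'}\n"
            )


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

REGION_TSV_COLUMNS = [
    "scaffold", "start", "end", "length", "direction", "n_cpgs",
    "mean_diff", "p_combined", "p_corrected",
]


def region_length(start: int, end: int) -> int:
    """Region length convention: end - start (1-based inclusive bounds)."""
    return end - start


def read_regions_tsv(path) -> pd.DataFrame:
    """Read back a region TSV written by :func:`write_regions`."""
    return pd.read_csv(path, sep="\t")


def write_regions(regions, path, fmt: str = "TSV") -> None:
    """Write DMR-like regions as BED6 (0-based half-open) or TSV.

    Regions may be any objects with scaffold/start/end/direction/n_cpgs/
    mean_diff attributes and optionally p_combined/p_corrected.
    """
    fmt = fmt.upper()
    if fmt not in ("BED", "TSV"):
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as out:
        if fmt == "TSV":
            out.write("\t".join(REGION_TSV_COLUMNS) + "\n")
            for r in regions:
                out.write(
                    f"{r.scaffold}\t{r.start}\t{r.end}\t"
                    f"{region_length(r.start, r.end)}\t{r.direction}\t{r.n_cpgs}\t"
                    f"{r.mean_diff:.6g}\t"
                    f"{getattr(r, 'p_combined', float('nan')):.6g}\t"
                    f"{getattr(r, 'p_corrected', float('nan')):.6g}\n"
                )
        else:
            for r in regions:
                score = getattr(r, "p_corrected", None)
                score = 0 if score is None or np.isnan(score) else min(
                    1000, int(round(-10 * np.log10(max(score, 1e-300))))
                )
                out.write(
                    f"{r.scaffold}\t{r.start - 1}\t{r.end}\t"
                    f"{r.direction}_{r.n_cpgs}cpg\t{score}\t.\n"
                )
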