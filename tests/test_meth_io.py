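"""IO: format parsing, matrix assembly, coordinate conventions, round-trips."""

import gzip

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicmeth import meth_io
from mosaicmeth.meth_io import (
    CpGSiteRecord,
    GeneAnnotation,
    assemble_matrix,
    collapse_strands,
    read_coverage_file,
    read_cytosine_report,
    read_vcf,
    region_length,
    sort_sites,
    write_regions,
    write_vcf,
)

from conftest import tiny_matrix


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestCytosineReport:
    def test_basic_line_parses(self, tmp_path):
        p = _write(tmp_path, "r.txt", "sc1\t100\t+\t3\t7\tCG\tCGT\n")
        (rec,) = read_cytosine_report(p)
        assert rec == CpGSiteRecord("sc1", 100, "+", 3, 7)
        assert rec.coverage == 10

    def test_context_filter_drops_non_cpg(self, tmp_path):
        p = _write(tmp_path, "r.txt",
                   "sc1\t100\t+\t3\t7\tCG\tCGT\n"
                   "sc1\t120\t+\t1\t7\tCHH\tCAT\n")
        assert len(read_cytosine_report(p)) == 1
        assert len(read_cytosine_report(p, context="CHH")) == 1

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = _write(tmp_path, "r.txt", "")
        with caplog.at_level("WARNING"):
            assert read_cytosine_report(p) == []
        assert "no CG records" in caplog.text

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "r.txt", "sc1\t100\t+\t3\t7\tCG\tCGT\nbad line\n")
        with pytest.raises(ValueError, match=":2"):
            read_cytosine_report(p)

    def test_unknown_strand_rejected(self, tmp_path):
        p = _write(tmp_path, "r.txt", "sc1\t100\t*\t3\t7\tCG\tCGT\n")
        with pytest.raises(ValueError, match="strand"):
            read_cytosine_report(p)

    def test_gzip_accepted(self, tmp_path):
        p = tmp_path / "r.txt.gz"
        with gzip.open(p, "wt") as out:
            out.write("sc1\t100\t+\t3\t7\tCG\tCGT\n")
        assert len(read_cytosine_report(p)) == 1


class TestCoverageFile:
    def test_basic_line(self, tmp_path):
        p = _write(tmp_path, "c.cov", "sc1\t100\t100\t30.0\t3\t7\n")
        (rec,) = read_coverage_file(p)
        assert (rec.scaffold, rec.position, rec.strand) == ("sc1", 100, ".")
        assert (rec.meth_count, rec.unmeth_count) == (3, 7)

    def test_inconsistent_percent_warns(self, tmp_path):
        p = _write(tmp_path, "c.cov", "sc1\t100\t100\t90.0\t3\t7\n")
        with pytest.warns(UserWarning, match="disagrees"):
            read_coverage_file(p)

    def test_interval_wider_than_one_base_rejected(self, tmp_path):
        p = _write(tmp_path, "c.cov", "sc1\t100\t101\t30.0\t3\t7\n")
        with pytest.raises(ValueError, match="CpG-resolution"):
            read_coverage_file(p)


class TestAssembleMatrix:
    META = pd.DataFrame(
        {"mother": [1, 1], "treatment": ["NF", "CR"]},
        index=pd.Index(["NF1", "CR1"], name="replicate"),
    )

    def test_union_semantics(self):
        a = [CpGSiteRecord("sc1", p, "+", 1, 1) for p in (100, 200, 300)]
        b = [CpGSiteRecord("sc1", p, "+", 2, 2) for p in (200, 300, 400, 500)]
        m = assemble_matrix({"NF1": a, "CR1": b}, self.META)
        assert m.n_sites == 5
        # NF1 missing 400,500 -> zero coverage there
        assert m.coverage[3, 0] == 0 and m.coverage[3, 1] == 4

    def test_duplicate_site_rejected(self):
        recs = [CpGSiteRecord("sc1", 100, "+", 1, 1)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            assemble_matrix({"NF1": recs, "CR1": []}, self.META)

    def test_unpaired_mother_rejected(self):
        meta = pd.DataFrame(
            {"mother": [1, 2, 3, 1, 2], "treatment": ["NF"] * 3 + ["CR"] * 2},
            index=pd.Index([f"r{i}" for i in range(5)], name="replicate"),
        )
        recs = {f"r{i}": [CpGSiteRecord("sc1", 100, "+", 1, 1)] for i in range(5)}
        with pytest.raises(ValueError, match="unpaired"):
            assemble_matrix(recs, meta)

    def test_sorting_is_total_and_stable(self):
        recs = [CpGSiteRecord(sc, p, "+", 0, 1)
                for sc, p in [("sc2", 50), ("sc1", 900), ("sc1", 20)]]
        m = assemble_matrix({"NF1": recs, "CR1": recs}, self.META)
        assert list(m.sites["scaffold"]) == ["sc1", "sc1", "sc2"]
        assert list(m.sites["position"]) == [20, 900, 50]


class TestRegions:
    class R:
        def __init__(self, scaffold, start, end, direction="hypo",
                     n_cpgs=5, mean_diff=-0.2, p_corrected=0.01):
            self.scaffold, self.start, self.end = scaffold, start, end
            self.direction, self.n_cpgs = direction, n_cpgs
            self.mean_diff, self.p_corrected = mean_diff, p_corrected
            self.p_combined = p_corrected / 2

    def test_bed_uses_zero_based_half_open(self, tmp_path):
        p = tmp_path / "r.bed"
        write_regions([self.R("sc", 76729, 77106)], p, "BED")
        assert p.read_text().split("\t")[1:3] == ["76728", "77106"]

    def test_published_interval_lengths(self):
        # length convention end - start over the printed DMR intervals
        assert region_length(76729, 77106) == 377
        assert region_length(77694, 77926) == 232
        assert region_length(534741, 534857) == 116

    def test_tsv_length_column(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_regions([self.R("sc", 76729, 77106)], p, "TSV")
        df = meth_io.read_regions_tsv(p)
        assert df.loc[0, "length"] == 377

    def test_empty_region_list_gives_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_regions([], p, "TSV")
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("scaffold")


class TestAnnotation:
    def test_bed12_round_trip(self, tmp_path, published_style_annotation):
        p = tmp_path / "genes.bed"
        published_style_annotation.to_bed12(p)
        back = GeneAnnotation.from_bed12(p)
        pd.testing.assert_frame_equal(
            back.genes.sort_index(), published_style_annotation.genes.sort_index()
        )
        for gid in published_style_annotation.genes.index:
            a = published_style_annotation.gene_exons(gid).reset_index(drop=True)
            b = back.gene_exons(gid).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)

    def test_exons_outside_gene_rejected(self):
        genes = pd.DataFrame(
            [("g1", "sc1", 100, 200, "+")],
            columns=["gene_id", "scaffold", "start", "end", "strand"],
        ).set_index("gene_id")
        exons = pd.DataFrame(
            [("g1", 1, 90, 150)],
            columns=["gene_id", "exon_index", "start", "end"],
        )
        with pytest.raises(ValueError, match="outside"):
            GeneAnnotation(genes, exons)

    def test_gff3_reader(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "sc1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1\n"
            "sc1\tsrc\texon\t100\t200\t.\t+\t.\tParent=g1\n"
            "sc1\tsrc\texon\t300\t500\t.\t+\t.\tParent=g1\n"
        )
        ann = GeneAnnotation.from_gff3(_write(tmp_path, "a.gff3", text))
        assert ann.genes.loc["g1", "start"] == 100
        assert list(ann.gene_exons("g1")["exon_index"]) == [1, 2]


class TestVcf:
    def test_round_trip_and_snv_filtering(self, tmp_path):
        df = pd.DataFrame({
            "scaffold": ["sc1", "sc1"],
            "position": [100, 200],
            "ref": ["C", "G"],
            "alt": ["T", "A"],
            "QD": [25.0, np.nan],
            "FS": [5.0, np.nan],
            "MQ": [60.0, np.nan],
            "MQRankSum": [0.0, np.nan],
            "ReadPosRankSum": [0.0, np.nan],
        })
        p = tmp_path / "v.vcf"
        write_vcf(p, df, contigs=["sc1"])
        back = read_vcf(p)
        assert len(back) == 2
        assert back.loc[0, "QD"] == 25.0
        assert np.isnan(back.loc[1, "QD"])

    def test_indels_skipped(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "sc1\t100\t.\tC\tT\t50\tPASS\t.\n"
            "sc1\t200\t.\tCA\tC\t50\tPASS\t.\n"
            "sc1\t300\t.\tC\tT,G\t50\tPASS\t.\n"
        )
        assert len(read_vcf(p)) == 1


def test_collapse_strands_merges_dinucleotide():
    m = tiny_matrix([[3], [5]], [[7], [5]], positions=[100, 101])
    m.sites.loc[1, "strand"] = "-"
    collapsed = collapse_strands(m)
    assert collapsed.n_sites == 1
    assert collapsed.meth[0, 0] == 8 and collapsed.unmeth[0, 0] == 12


@settings(max_examples=25, deadline=None)
@given(
    counts=st.lists(
        st.tuples(st.integers(0, 50), st.integers(0, 50)),
        min_size=1, max_size=20,
    )
)
def test_cytosine_report_round_trip(tmp_path_factory, counts):
    """Write-then-read reproduces counts and coordinates exactly."""
    tmp = tmp_path_factory.mktemp("rt")
    sites = sort_sites(pd.DataFrame({
        "scaffold": "sc1",
        "position": np.arange(1, len(counts) + 1) * 37,
        "strand": "+",
    }))
    meth = np.array([c[0] for c in counts])
    unmeth = np.array([c[1] for c in counts])
    p = tmp / "rep.txt"
    meth_io.write_cytosine_report(p, sites, meth, unmeth)
    back = read_cytosine_report(p)
    assert [r.meth_count for r in back] == list(meth)
    assert [r.unmeth_count for r in back] == list(unmeth)
    assert [r.position for r in back] == list(sites["position"])
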