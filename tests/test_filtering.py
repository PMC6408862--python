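"""Pre-statistics filters: non-conversion reads, variant hard filter, SNP
masking, the coverage rule, global methylation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mosaicmeth import filtering, simulate
from mosaicmeth.filtering import (
    CoverageRule,
    VariantThresholds,
    apply_coverage_rule,
    filter_nonconverted_reads,
    global_methylation,
    hard_filter_variants,
    mask_polymorphic_cpgs,
)

from conftest import tiny_matrix


def _reads(*calls):
    return pd.DataFrame({
        "replicate": ["NF1"] * len(calls),
        "scaffold": ["sc1"] * len(calls),
        "start": np.arange(1, len(calls) + 1) * 10,
        "calls": list(calls),
    })


class TestNonConversionFilter:
    def test_cpg_only_read_retained(self):
        retained, _ = filter_nonconverted_reads(_reads("zZz"))
        assert len(retained) == 1

    def test_read_with_methylated_chh_or_chg_removed(self):
        retained, _ = filter_nonconverted_reads(_reads("zHx", "zZx", "ZXz"))
        assert list(retained["calls"]) == ["zZx"]

    def test_conversion_efficiency_definition(self):
        """97 clean non-CpG calls and 3 methylated ones -> 3% non-CpG
        methylation, 97% conversion efficiency."""
        calls = ["h" * 97 + "HHH"]
        _, report = filter_nonconverted_reads(_reads(*calls))
        row = report.per_replicate.loc["NF1"]
        assert row["noncpg_pct_methylated"] == pytest.approx(3.0)
        assert row["conversion_efficiency_pct"] == pytest.approx(97.0)

    def test_removed_fraction_reported(self):
        _, report = filter_nonconverted_reads(
            _reads(*(["zH"] * 3 + ["zz"] * 97)))
        assert report.per_replicate.loc["NF1", "pct_removed"] == pytest.approx(3.0)

    def test_unknown_symbol_names_the_read(self):
        with pytest.raises(ValueError, match="read 0"):
            filter_nonconverted_reads(_reads("zQz"))


class TestHardFilter:
    def _df(self, **overrides):
        base = dict(scaffold="sc1", position=100, ref="C", alt="T",
                    QD=30.0, FS=10.0, MQ=60.0, MQRankSum=0.0,
                    ReadPosRankSum=0.0)
        base.update(overrides)
        return pd.DataFrame([base])

    def test_good_variant_passes(self):
        assert len(hard_filter_variants(self._df())) == 1

    @pytest.mark.parametrize("field,value", [
        ("QD", 1.5), ("FS", 70.0), ("MQ", 30.0),
        ("MQRankSum", -13.0), ("ReadPosRankSum", -9.0),
    ])
    def test_each_threshold_fails_a_variant(self, field, value):
        assert len(hard_filter_variants(self._df(**{field: value}))) == 0

    def test_missing_annotations_pass_by_default(self):
        df = self._df(QD=np.nan, FS=np.nan, MQ=np.nan, MQRankSum=np.nan,
                      ReadPosRankSum=np.nan)
        assert len(hard_filter_variants(df)) == 1
        assert len(hard_filter_variants(df, strict=True)) == 0


class TestSnpMasking:
    def _variants(self, rows):
        return pd.DataFrame(
            rows, columns=["scaffold", "position", "ref", "alt"]
        )

    def test_ct_snp_on_c_position_removes_site(self):
        m = tiny_matrix([[1], [1]], [[1], [1]], positions=[100, 200])
        filtered, n = mask_polymorphic_cpgs(
            m, self._variants([("sc1", 100, "C", "T")]))
        assert n == 1 and list(filtered.sites["position"]) == [200]

    def test_distant_snp_keeps_site(self):
        m = tiny_matrix([[1]], [[1]], positions=[100])
        _, n = mask_polymorphic_cpgs(
            m, self._variants([("sc1", 150, "G", "A")]))
        assert n == 0

    def test_ga_snp_on_following_g_removes_site(self):
        """A G/A polymorphism at the G of the dinucleotide corrupts
        reverse-strand calls, so the CpG is dropped; simulate the
        reverse-strand miscall to confirm the direction of the bias."""
        m = tiny_matrix([[1]], [[1]], positions=[100])
        _, n = mask_polymorphic_cpgs(
            m, self._variants([("sc1", 101, "G", "A")]))
        assert n == 1
        # reverse-strand reads report the G-side cytosine: on the A allele
        # the base is A, read as unmethylated after conversion logic, so a
        # heterozygote halves the apparent level (downward bias)
        rng = np.random.default_rng(0)
        level = 0.8
        allele_is_a = rng.random(10_000) < 0.5
        calls = np.where(allele_is_a, 0.0, rng.random(10_000) < level)
        assert calls.mean() == pytest.approx(level / 2, abs=0.02)

    def test_ga_masking_can_be_disabled(self):
        m = tiny_matrix([[1]], [[1]], positions=[100])
        _, n = mask_polymorphic_cpgs(
            m, self._variants([("sc1", 101, "G", "A")]), mask_g_position=False)
        assert n == 0

    def test_reverse_strand_site_mirrors_rule(self):
        m = tiny_matrix([[1], [1]], [[1], [1]], positions=[101, 301])
        m.sites["strand"] = "-"
        # G/A on the site itself masks it; C/T at p-1 masks via G-rule
        filtered, n = mask_polymorphic_cpgs(
            m, self._variants([("sc1", 101, "G", "A"), ("sc1", 300, "C", "T")]))
        assert n == 2

    def test_masks_exactly_planted_snp_sites(self, small_dataset):
        model, truth, matrix = small_dataset
        variants = pd.DataFrame({
            "scaffold": truth.snps["scaffold"],
            "position": truth.snps["snp_position"],
            "ref": truth.snps["ref"],
            "alt": truth.snps["alt"],
        })
        filtered, n = mask_polymorphic_cpgs(matrix, variants)
        assert n == len(truth.snps)
        remaining = set(zip(filtered.sites["scaffold"],
                            filtered.sites["position"]))
        assert remaining.isdisjoint(truth.masked_sites)


class TestCoverageRule:
    def _matrix(self, nf, cr):
        meth = np.zeros((1, 12), dtype=int)
        unmeth = np.array([list(nf) + list(cr)])
        return tiny_matrix(meth, unmeth)

    def test_two_deep_replicates_per_treatment_keep_site(self):
        m = self._matrix([6, 6, 2, 0, 3, 1], [7, 9, 0, 0, 0, 0])
        assert apply_coverage_rule(m).n_sites == 1

    def test_one_deep_replicate_in_a_treatment_drops_site(self):
        m = self._matrix([6, 5, 5, 5, 5, 5], [9, 9, 9, 9, 9, 9])
        assert apply_coverage_rule(m).n_sites == 0

    def test_uncovered_site_dropped(self):
        m = self._matrix([0] * 6, [0] * 6)
        assert apply_coverage_rule(m).n_sites == 0

    def test_masking_and_coverage_rule_commute(self, small_dataset):
        model, truth, matrix = small_dataset
        variants = pd.DataFrame({
            "scaffold": truth.snps["scaffold"],
            "position": truth.snps["snp_position"],
            "ref": truth.snps["ref"],
            "alt": truth.snps["alt"],
        })
        a = apply_coverage_rule(mask_polymorphic_cpgs(matrix, variants)[0])
        b = mask_polymorphic_cpgs(apply_coverage_rule(matrix), variants)[0]
        pd.testing.assert_frame_equal(a.sites, b.sites)
        np.testing.assert_array_equal(a.meth, b.meth)


class TestGlobalMethylation:
    def test_percentage_definition(self):
        # 7 methylated of 1000 calls -> 0.7%
        meth = np.full((1, 12), 7)
        unmeth = np.full((1, 12), 993)
        summary = global_methylation(tiny_matrix(meth, unmeth))
        np.testing.assert_allclose(summary.per_replicate_pct, 0.7)

    def test_identical_treatments_give_p_one(self):
        meth = np.tile([5], (1, 12))
        unmeth = np.tile([95], (1, 12))
        summary = global_methylation(tiny_matrix(meth, unmeth))
        assert summary.t_statistic == 0.0 and summary.p_value == 1.0

    def test_matches_closed_form_paired_t(self):
        """Pair differences [0.1,0.2,0.15,0.05,0.1,0.1] (%): the closed-form
        paired t is 5.534 with two-tailed p 0.00265 at 5 df."""
        diffs = np.array([0.1, 0.2, 0.15, 0.05, 0.1, 0.1])
        nf_pct = np.full(6, 0.5)
        cr_pct = nf_pct + diffs
        # build counts realising those percentages exactly at coverage 1e5
        total = 100_000
        meth = np.array([[int(round(p / 100 * total))
                          for p in np.concatenate([nf_pct, cr_pct])]])
        unmeth = total - meth
        summary = global_methylation(tiny_matrix(meth, unmeth))
        t_oracle = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(6))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=5)
        assert t_oracle == pytest.approx(5.534, abs=5e-3)
        assert summary.t_statistic == pytest.approx(t_oracle, rel=1e-6)
        assert summary.p_value == pytest.approx(p_oracle, rel=1e-6)
        assert summary.p_value == pytest.approx(0.00265, abs=2e-4)
        assert summary.df == 5

    def test_single_pair_rejected(self):
        m = tiny_matrix(np.ones((1, 2)), np.ones((1, 2)))
        with pytest.raises(ValueError, match="2 pairs"):
            global_methylation(m)


class TestConversionFilterEfficacy:
    def test_filtering_removes_upward_bias(self):
        """With 3% unconverted reads the raw global estimate is inflated by
        about 3 percentage points; removing flagged reads and re-aggregating
        restores the truth within 0.1 points."""
        cfg = simulate.SimulationConfig(
            scaffold_length=100_000, n_genes=10, n_dmrs=2,
            conversion_failure_rate=0.03, n_snps=0, seed=17,
        )
        model, truth, matrix, reads = simulate.simulate_dataset(cfg, reads=True)
        truth_pct = 100.0 * np.mean(truth.levels)
        pre = 100.0 * matrix.meth.sum() / matrix.coverage.sum()
        retained, report = filter_nonconverted_reads(reads)
        clean = simulate.aggregate_reads(retained, model, matrix.samples,
                                         cfg.read_length)
        post = 100.0 * clean.meth.sum() / clean.coverage.sum()
        assert pre - truth_pct >= 1.0
        assert abs(post - truth_pct) <= 0.1
        eff = report.per_replicate["conversion_efficiency_pct"]
        assert ((eff > 95) & (eff < 99)).all()
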