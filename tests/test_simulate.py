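"""Generator: determinism, genome layout, planted effects, count model,
dataset emission round-trips."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from mosaicmeth import meth_io, simulate
from mosaicmeth.simulate import (
    SimulationConfig,
    build_genome_model,
    plant_dmrs,
    simulate_counts,
    simulate_dataset,
)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("frac_methylated_sites", 1.5),
        ("conversion_failure_rate", -0.1),
        ("n_pairs", 1),
        ("dmr_width", (0, 5)),
        ("coverage_model", "magic"),
        ("dmr_effect", (0.5, 0.2)),
    ])
    def test_invalid_config_rejected(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_scaffold_too_short_for_genes(self):
        cfg = SimulationConfig(scaffold_length=500, n_genes=50)
        with pytest.raises(ValueError, match="too short"):
            build_genome_model(cfg)


class TestGenomeModel:
    def test_cpg_positions_within_bounds_and_increasing(self):
        cfg = SimulationConfig(scaffold_length=10_000, n_genes=2,
                               cpg_density=20.0, seed=7)
        model = build_genome_model(cfg)
        pos = model.cpgs["position"].to_numpy()
        assert pos.min() >= 1 and pos.max() <= 10_000
        assert (np.diff(pos) > 0).all()
        # ~200 expected from the density; uniqueness trims a little
        assert 150 <= len(pos) <= 210

    def test_same_seed_same_positions(self):
        cfg = SimulationConfig(scaffold_length=50_000, n_genes=5, seed=3)
        a = build_genome_model(cfg).cpgs
        b = build_genome_model(cfg).cpgs
        pd.testing.assert_frame_equal(a, b)

    def test_gene_intervals_inside_scaffold(self, small_dataset):
        model, _truth, _matrix = small_dataset
        for _gid, g in model.annotation.genes.iterrows():
            assert 1 <= g["start"] <= g["end"] <= model.scaffold_lengths[g["scaffold"]]

    def test_no_methylated_fraction_keeps_global_low(self):
        """With frac_methylated_sites=0 the mixture collapses to the low
        beta component, whose analytic mean puts global methylation below
        1 percent."""
        cfg = SimulationConfig(scaffold_length=500_000, n_genes=50,
                               frac_methylated_sites=0.0, n_dmrs=0, seed=11)
        model = build_genome_model(cfg)
        a, b = cfg.low_beta_params
        analytic = a / (a + b)
        assert analytic < 0.01
        assert model.expected_global_methylation() == pytest.approx(
            analytic, abs=5e-4)


class TestPlantedTruth:
    def test_no_dmrs_means_identical_treatment_levels(self):
        cfg = SimulationConfig(scaffold_length=100_000, n_genes=10,
                               n_dmrs=0, mother_sd=0.0, n_snps=0, seed=1)
        rng = np.random.default_rng(1)
        model = build_genome_model(cfg, rng)
        truth = plant_dmrs(model, cfg, rng)
        assert truth.dmrs.empty
        levels, samples = simulate.true_levels(model, truth, cfg, rng)
        nf = levels[:, (samples["treatment"] == "NF").to_numpy()]
        cr = levels[:, (samples["treatment"] == "CR").to_numpy()]
        np.testing.assert_allclose(nf.mean(axis=1), cr.mean(axis=1))

    def test_hypo_effect_arithmetic_and_clipping(self):
        """A hypo region with baseline b and effect e puts the CR level at
        b - e; a hyper effect from a high baseline clips at 1."""
        cfg = SimulationConfig(scaffold_length=100_000, n_genes=10,
                               n_dmrs=3, mother_sd=0.0, n_snps=0,
                               dmr_effect=(0.2, 0.2), seed=2)
        rng = np.random.default_rng(2)
        model = build_genome_model(cfg, rng)
        truth = plant_dmrs(model, cfg, rng)
        levels, samples = simulate.true_levels(model, truth, cfg, rng)
        cr_cols = (samples["treatment"] == "CR").to_numpy()
        scaf = model.cpgs["scaffold"].to_numpy()
        pos = model.cpgs["position"].to_numpy()
        base = model.cpgs["baseline"].to_numpy()
        for reg in truth.dmrs.itertuples(index=False):
            seg = np.flatnonzero((scaf == reg.scaffold) & (pos >= reg.start)
                                 & (pos <= reg.end))
            shift = reg.effect if reg.direction == "hyper" else -reg.effect
            expected = np.clip(base[seg] + shift, 0.0, 1.0)
            # mother_sd = 0 so replicate levels equal the treatment levels
            got = levels[seg][:, cr_cols].mean(axis=1)
            np.testing.assert_allclose(got, np.clip(expected, 1e-6, 1 - 1e-6),
                                       atol=1e-9)

    def test_planted_dmrs_are_disjoint(self, small_dataset):
        _model, truth, _matrix = small_dataset
        ivs = sorted(
            (r.scaffold, r.start, r.end)
            for r in truth.dmrs.itertuples(index=False)
        )
        for (s1, a1, b1), (s2, a2, b2) in zip(ivs, ivs[1:]):
            assert s1 != s2 or b1 < a2

    def test_infeasible_placement_raises(self):
        cfg = SimulationConfig(scaffold_length=20_000, n_genes=2,
                               n_dmrs=500, seed=1)
        model = build_genome_model(cfg)
        with pytest.raises(RuntimeError, match="could not place"):
            plant_dmrs(model, cfg)


class TestCounts:
    def test_mean_coverage_matches_configuration(self, small_dataset):
        _model, _truth, matrix = small_dataset
        assert matrix.coverage.mean() == pytest.approx(10.0, abs=0.5)

    def test_mother_correlation_exceeds_treatment_correlation(self):
        """With a strong mother effect and no treatment effect the NF/CR
        profiles of one mother correlate more than same-treatment profiles
        of different mothers."""
        cfg = SimulationConfig(scaffold_length=500_000, n_genes=50,
                               n_dmrs=0, mother_sd=1.0, n_snps=0,
                               conversion_failure_rate=0.0, seed=9)
        _model, _truth, matrix, _ = simulate_dataset(cfg)
        props = matrix.proportions()
        df = pd.DataFrame(props, columns=matrix.samples.index)
        corr = df.corr()
        within_pair = np.mean([
            corr.loc[f"NF{m}", f"CR{m}"] for m in range(1, 7)
        ])
        across = np.mean([
            corr.loc[f"NF{m}", f"NF{k}"]
            for m in range(1, 7) for k in range(m + 1, 7)
        ])
        assert within_pair > across

    def test_zero_conversion_failure_leaves_no_noncpg_methylation(self):
        cfg = SimulationConfig(scaffold_length=50_000, n_genes=5,
                               conversion_failure_rate=0.0, n_dmrs=0,
                               n_snps=0, seed=4)
        _m, _t, _mat, reads = simulate_dataset(cfg, reads=True)
        joined = "".join(reads["calls"])
        assert "X" not in joined and "H" not in joined

    def test_global_methylation_matches_analytic_expectation(self):
        """Weighted global methylation of an emitted >=10^4-CpG dataset at
        10x lies within 0.2 percentage points of the realised mixture
        mean."""
        cfg = SimulationConfig(scaffold_length=600_000, n_genes=60,
                               n_dmrs=0, n_snps=0,
                               conversion_failure_rate=0.0, seed=12)
        model, _truth, matrix, _ = simulate_dataset(cfg)
        assert model.n_cpgs >= 10_000
        observed = 100.0 * matrix.meth.sum() / matrix.coverage.sum()
        expected = 100.0 * model.expected_global_methylation()
        assert observed == pytest.approx(expected, abs=0.2)

    def test_exchangeability_under_null(self):
        """With zero effects and zero mother sd, per-site proportions are
        exchangeable across replicates: the paired-difference statistic is
        symmetric, so its sign is a fair coin at covered sites."""
        cfg = SimulationConfig(scaffold_length=400_000, n_genes=40,
                               n_dmrs=0, mother_sd=0.0, n_snps=0,
                               conversion_failure_rate=0.0, seed=21)
        model, truth, matrix, _ = simulate_dataset(cfg)
        props = matrix.proportions()
        nf = props[:, matrix.replicate_indices("NF")]
        cr = props[:, matrix.replicate_indices("CR")]
        d = np.nanmean(cr, axis=1) - np.nanmean(nf, axis=1)
        nonzero = d[np.abs(d) > 1e-12]
        assert len(nonzero) >= 500
        frac_pos = (nonzero > 0).mean()
        se = 0.5 / np.sqrt(len(nonzero))
        assert abs(frac_pos - 0.5) < 3 * se + 0.01

    def test_negative_binomial_coverage_dispersion(self):
        cfg = SimulationConfig(scaffold_length=100_000, n_genes=10,
                               coverage_model="negative-binomial",
                               coverage_dispersion=2.0, n_dmrs=0, n_snps=0,
                               seed=5)
        _m, _t, matrix, _ = simulate_dataset(cfg)
        cov = matrix.coverage
        assert cov.mean() == pytest.approx(10.0, abs=0.6)
        # NB variance mu + mu^2/size = 10 + 50 = 60 >> Poisson's 10
        assert cov.var() > 30


class TestEmission:
    def test_emit_then_parse_round_trips(self, small_dataset, tmp_path):
        model, truth, matrix = small_dataset
        paths = simulate.emit_dataset(matrix, truth, model, tmp_path)
        records = {
            rep: meth_io.read_cytosine_report(paths[f"calls/{rep}"])
            for rep in matrix.samples.index
        }
        back = meth_io.assemble_matrix(records, matrix.samples)
        np.testing.assert_array_equal(back.meth, matrix.meth)
        np.testing.assert_array_equal(back.unmeth, matrix.unmeth)
        pd.testing.assert_frame_equal(back.sites, matrix.sites)

    def test_truth_bed_has_one_record_per_dmr(self, small_dataset, tmp_path):
        model, truth, matrix = small_dataset
        paths = simulate.emit_dataset(matrix, truth, model, tmp_path)
        n_lines = len(paths["truth_dmrs_bed"].read_text().splitlines())
        assert n_lines == len(truth.dmrs)

    def test_vcf_contains_every_planted_snp(self, small_dataset, tmp_path):
        model, truth, matrix = small_dataset
        paths = simulate.emit_dataset(matrix, truth, model, tmp_path)
        vcf = meth_io.read_vcf(paths["vcf"])
        in_vcf = set(zip(vcf["scaffold"], vcf["position"]))
        for r in truth.snps.itertuples(index=False):
            assert (r.scaffold, r.snp_position) in in_vcf

    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(scaffold_length=50_000, n_genes=5, n_dmrs=2,
                               n_snps=5, seed=33)
        for sub in ("a", "b"):
            model, truth, matrix, _ = simulate_dataset(cfg)
            simulate.emit_dataset(matrix, truth, model, tmp_path / sub)
        a, b = tmp_path / "a", tmp_path / "b"
        for rel in ["genes.bed", "variants.vcf", "truth_dmrs.tsv",
                    "samples.tsv", "calls/NF1.CpG_report.txt",
                    "calls/CR6.CpG_report.txt"]:
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel
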