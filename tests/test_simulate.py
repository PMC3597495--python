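"""Synthetic cohort generator: determinism, calibration, ground truth."""

import numpy as np
import pytest
from scipy import stats

from rarecnv import io
from rarecnv.errors import ConfigError, GenerationError
from rarecnv.expression import de_test
from rarecnv.simulate import (
    SimulationConfig,
    carrier_map,
    generate_cohort,
    generate_expression,
    generate_gene_annotation,
    generate_mlpa,
    generate_snp_track,
)


class TestConfig:
    def test_invalid_values_name_the_field(self):
        with pytest.raises(ConfigError, match="n_cases"):
            SimulationConfig(n_cases=-1).validate()
        with pytest.raises(ConfigError, match="pathogenic_fraction"):
            SimulationConfig(pathogenic_fraction=1.5).validate()
        with pytest.raises(ConfigError, match="size_log_sd"):
            SimulationConfig(size_log_sd=0.0).validate()

    def test_unknown_yaml_field_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("n_cases: 5\nbogus_field: 1\n")
        with pytest.raises(ConfigError, match="bogus_field"):
            SimulationConfig.from_yaml(p)


class TestCohort:
    def test_same_seed_reproduces_byte_identical_output(self, tmp_path,
                                                        small_config):
        paths = []
        for run in ("a", "b"):
            cohort = generate_cohort(small_config)
            p = tmp_path / f"{run}.tsv"
            io.write_segments(cohort.case_calls, p)
            io.write_ped(cohort.samples, cohort.trios, tmp_path / f"{run}.ped")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "a.ped").read_bytes() == (tmp_path / "b.ped").read_bytes()

    def test_different_seeds_differ(self, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a = generate_cohort(small_config).case_calls
        b = generate_cohort(other).case_calls
        assert not a.equals(b)

    def test_no_spikes_no_pool_gives_empty_truth(self):
        cfg = SimulationConfig(
            seed=1, n_cases=10, n_controls=10, pathogenic_fraction=0.0,
            polymorphic_pool_size=0, n_genes=20,
        )
        cohort = generate_cohort(cfg)
        assert not cohort.truth.spiked_cnv_ids
        assert not cohort.truth.polymorphic_cnv_ids

    def test_call_counts_poisson_with_configured_mean(self):
        cfg = SimulationConfig(
            seed=3, n_cases=100, n_controls=0, pathogenic_fraction=0.0,
            polymorphic_pool_size=0, n_genes=50, mean_calls_per_sample=20.0,
        )
        cohort = generate_cohort(cfg)
        total = len(cohort.case_calls)
        mean = 100 * 20.0
        assert abs(total - mean) <= 3 * np.sqrt(mean)

    def test_spikes_absent_from_controls_and_trios_exist(self, small_cohort):
        spikes = small_cohort.case_calls[
            small_cohort.case_calls.call_id.isin(small_cohort.truth.spiked_cnv_ids)
        ]
        controls = small_cohort.control_calls
        for s in spikes.itertuples(index=False):
            same = controls[
                (controls.chrom == s.chrom)
                & (controls.cnv_type == s.cnv_type)
                & (controls.start < s.end)
                & (controls.end > s.start)
            ]
            for c in same.itertuples(index=False):
                ov = min(c.end, s.end) - max(c.start, s.start)
                assert ov / (s.end - s.start) <= 0.95
        children = {t.child_id for t in small_cohort.trios}
        cases = {s for s, r in small_cohort.samples.items() if r.group == "case"}
        assert children == cases

    def test_inheritance_labels_partition_spikes(self, small_cohort):
        truth = small_cohort.truth
        assert set(truth.spike_inheritance) == truth.spiked_cnv_ids
        assert set(truth.spike_inheritance.values()) <= {
            "de_novo", "inherited_affected",
        }

    def test_polymorphic_pool_common_in_controls(self, small_cohort):
        # carrier rate 0.3 x 80 controls: every pool locus expects ~24
        controls = small_cohort.control_calls
        for chrom, start, end, cnv_type in small_cohort.truth.polymorphic_loci:
            carriers = controls[
                (controls.chrom == chrom)
                & (controls.start == start)
                & (controls.end == end)
            ].sample_id.nunique()
            assert carriers > 15


class TestGenes:
    def test_zero_genes_empty(self):
        assert generate_gene_annotation(SimulationConfig(n_genes=0)) == []

    def test_non_overlapping_with_exons_inside(self):
        cfg = SimulationConfig(
            seed=5, n_genes=100, n_chromosomes=1, chromosome_length_bp=10_000_000
        )
        genes = generate_gene_annotation(cfg)
        assert len(genes) == 100
        by_chrom = sorted(genes, key=lambda g: (g.chrom, g.start))
        for a, b in zip(by_chrom, by_chrom[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start
        for g in genes:
            assert all(g.start <= s < e <= g.end for s, e in g.exons)

    def test_genome_too_small_raises(self):
        cfg = SimulationConfig(
            n_genes=1000, n_chromosomes=1, chromosome_length_bp=1_000_000
        )
        with pytest.raises(GenerationError):
            generate_gene_annotation(cfg)

    def test_hi_flag_rate_within_binomial_interval(self):
        cfg = SimulationConfig(seed=11, n_genes=1000, n_chromosomes=4,
                               chromosome_length_bp=100_000_000)
        genes = generate_gene_annotation(cfg)
        # uniform percentile: ~10% expected below the 10th percentile
        n_low = sum(g.hi_percentile < 10.0 for g in genes)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.10)
        assert lo <= n_low <= hi


class TestExpression:
    def test_noiseless_gain_shift_is_exact(self):
        cfg = SimulationConfig(seed=2, n_genes=4, expression_noise_sd=0.0,
                               expression_baseline_sd=0.0)
        genes = generate_gene_annotation(cfg)
        carriers = {genes[0].gene_id: ("gain", {"P1"})}
        mat = generate_expression(carriers, genes, ["P1", "C1", "C2"], cfg)
        row = mat.loc[genes[0].gene_id]
        assert row["P1"] - row["C1"] == pytest.approx(np.log2(1.5))
        assert mat.loc[genes[1].gene_id, "P1"] == mat.loc[genes[1].gene_id, "C1"]

    def test_loss_shift_recovered_within_3_se(self):
        cfg = SimulationConfig(seed=4, n_genes=2, expression_noise_sd=0.3)
        genes = generate_gene_annotation(cfg)
        carriers = [f"P{i}" for i in range(50)]
        others = [f"C{i}" for i in range(50)]
        mat = generate_expression(
            {genes[0].gene_id: ("loss", set(carriers))}, genes,
            carriers + others, cfg,
        )
        row = mat.loc[genes[0].gene_id]
        diff = row[carriers].mean() - row[others].mean()
        se = 0.3 * np.sqrt(2 / 50)
        assert abs(diff - (-1.0)) <= 3 * se

    def test_null_matrix_p_values_uniform(self):
        cfg = SimulationConfig(seed=6, n_genes=200, expression_noise_sd=0.3)
        genes = generate_gene_annotation(cfg)
        samples = [f"S{i}" for i in range(20)]
        mat = generate_expression({}, genes, samples, cfg)
        ps = [
            de_test(mat.loc[g.gene_id], samples[:10], samples[10:])[1]
            for g in genes
        ]
        frac = np.mean(np.array(ps) < 0.05)
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.05) / 200
        assert lo <= frac <= hi

    def test_unknown_carrier_sample_rejected(self):
        cfg = SimulationConfig(seed=2, n_genes=2)
        genes = generate_gene_annotation(cfg)
        with pytest.raises(ConfigError):
            generate_expression(
                {genes[0].gene_id: ("gain", {"NOPE"})}, genes, ["S1"], cfg
            )


class TestSnpTrack:
    def test_empty_count_empty_table(self):
        df = generate_snp_track(SimulationConfig(n_snps=0))
        assert df.empty

    def test_signal_locus_contains_sub_level_snp(self):
        cfg = SimulationConfig(seed=8, n_snps=500)
        df = generate_snp_track(cfg, [("chr1", 10_000, 20_000, 1e-14)])
        inside = df[(df.chrom == "chr1") & (df.pos >= 10_000) & (df.pos < 20_000)]
        assert (inside.p < 1e-14).any()

    def test_background_minimum_has_order_statistic_scale(self):
        cfg = SimulationConfig(seed=9, n_snps=10_000)
        df = generate_snp_track(cfg)
        # min of n uniforms ~ Exp(n): between 1/(n*1000) and ~10/n say
        assert 1e-8 < df.p.min() < 1.5e-3

    def test_locus_outside_genome_rejected(self):
        cfg = SimulationConfig(n_snps=10)
        with pytest.raises(ConfigError):
            generate_snp_track(cfg, [("chr99", 0, 1000)])


class TestMlpaGeneration:
    def test_noiseless_ratios_match_copy_state(self, small_cohort):
        import dataclasses

        cfg = dataclasses.replace(small_cohort.config, mlpa_noise_sd=0.0)
        calls = small_cohort.case_calls.head(20)
        ml = generate_mlpa(calls, cfg)
        expected = calls.copy_state.to_numpy() / 2.0
        assert np.allclose(ml.ratio.to_numpy(), expected)
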