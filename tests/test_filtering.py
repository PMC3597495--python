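"""Polymorphism filter cascade: overlap maths, stage logic, properties."""

import numpy as np
import pytest

from rarecnv.core import CNVCall, GeneModel, calls_to_frame
from rarecnv.filtering import (
    ControlIndex,
    FilterConfig,
    GeneIndex,
    control_carrier_count,
    exonic_filter,
    gene_coverage_excluded,
    run_cascade,
    size_overlap_fraction,
)
from .oracles import carrier_count_oracle


def call(sample, chrom, start, end, state=1):
    return CNVCall(sample, chrom, start, end, state)


class TestOverlapFraction:
    def test_identical_intervals(self):
        a = call("A", "chr1", 1000, 2000)
        assert size_overlap_fraction(a, call("B", "chr1", 1000, 2000)) == 1.0

    def test_disjoint_and_cross_chromosome(self):
        a = call("A", "chr1", 1000, 2000)
        assert size_overlap_fraction(a, call("B", "chr1", 3000, 4000)) == 0.0
        assert size_overlap_fraction(a, call("B", "chr2", 1000, 2000)) == 0.0

    def test_half_overlap_is_asymmetric(self):
        a = call("A", "chr1", 1000, 2000)
        b = call("B", "chr1", 1500, 3000)
        assert size_overlap_fraction(a, b) == 0.5
        assert size_overlap_fraction(b, a) == pytest.approx(1 / 3)


class TestCarrierCount:
    def test_no_controls(self):
        idx = ControlIndex(calls_to_frame([]))
        assert control_carrier_count(call("Q", "chr1", 0, 1000), idx, FilterConfig()) == 0

    def test_identical_calls_in_twenty_controls(self):
        controls = calls_to_frame(
            [call(f"C{i}", "chr1", 5000, 9000) for i in range(20)]
        )
        q = call("Q", "chr1", 5000, 9000)
        assert control_carrier_count(q, ControlIndex(controls), FilterConfig()) == 20

    def test_same_type_matching_only(self):
        controls = calls_to_frame(
            [call(f"C{i}", "chr1", 5000, 9000, state=3) for i in range(20)]
        )
        q = call("Q", "chr1", 5000, 9000, state=1)  # loss vs gain controls
        assert control_carrier_count(q, ControlIndex(controls), FilterConfig()) == 0

    def test_matches_quadratic_oracle_on_random_cohort(self, rng):
        controls = []
        for i in range(50):
            for _ in range(rng.integers(1, 5)):
                s = int(rng.integers(0, 90_000))
                e = s + int(rng.integers(500, 12_000))
                controls.append(call(f"C{i}", "chr1", s, e, int(rng.choice([1, 3]))))
        idx = ControlIndex(calls_to_frame(controls))
        cfg = FilterConfig()
        tuples = [(c.sample_id, c.chrom, c.start, c.end, c.cnv_type) for c in controls]
        for _ in range(30):
            s = int(rng.integers(0, 90_000))
            q = call("Q", "chr1", s, s + int(rng.integers(500, 12_000)),
                     int(rng.choice([1, 3])))
            expected = carrier_count_oracle(
                (q.sample_id, q.chrom, q.start, q.end, q.cnv_type),
                tuples,
                cfg.overlap_fraction,
            )
            assert control_carrier_count(q, idx, cfg) == expected

    def test_tightening_fraction_never_finds_more_carriers(self, rng):
        controls = calls_to_frame(
            [
                call(
                    f"C{i}",
                    "chr1",
                    int(rng.integers(0, 50_000)),
                    int(rng.integers(50_000, 100_000)),
                )
                for i in range(30)
            ]
        )
        idx = ControlIndex(controls)
        q = call("Q", "chr1", 20_000, 60_000)
        counts = [
            control_carrier_count(q, idx, FilterConfig(overlap_fraction=f))
            for f in (0.5, 0.7, 0.9, 0.95, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)


GENES = [
    GeneModel("G1", "chr1", 10_000, 20_000, ((10_000, 12_000),)),
    GeneModel("G2", "chr1", 40_000, 50_000, ((44_000, 46_000),)),
]


class TestGeneCoverage:
    def _index_with_covering_controls(self, n, span=(9_000, 21_000)):
        return ControlIndex(
            calls_to_frame([call(f"C{i}", "chr1", *span) for i in range(n)])
        )

    def test_single_gene_covered_in_15_controls_removed(self):
        idx = self._index_with_covering_controls(15)
        q = call("Q", "chr1", 9_500, 22_000)
        assert gene_coverage_excluded(q, idx, GeneIndex(GENES), FilterConfig())

    def test_one_uncovered_gene_keeps_the_call(self):
        idx = self._index_with_covering_controls(20)  # covers G1 only
        q = call("Q", "chr1", 9_500, 45_000)  # overlaps G1 and G2
        assert not gene_coverage_excluded(q, idx, GeneIndex(GENES), FilterConfig())

    def test_gene_free_call_is_not_removed_here(self):
        idx = self._index_with_covering_controls(20)
        q = call("Q", "chr1", 25_000, 30_000)
        assert not gene_coverage_excluded(q, idx, GeneIndex(GENES), FilterConfig())

    def test_fourteen_covering_controls_insufficient(self):
        idx = self._index_with_covering_controls(14)
        q = call("Q", "chr1", 9_500, 22_000)
        assert not gene_coverage_excluded(q, idx, GeneIndex(GENES), FilterConfig())


class TestExonicFilter:
    def test_whole_gene_span_kept(self):
        assert exonic_filter(call("Q", "chr1", 9_000, 21_000), GeneIndex(GENES))

    def test_intronic_only_dropped(self):
        # G1's exon is [10000, 12000); the call sits past it inside the gene
        assert not exonic_filter(call("Q", "chr1", 13_000, 19_000), GeneIndex(GENES))

    def test_intergenic_dropped(self):
        assert not exonic_filter(call("Q", "chr1", 25_000, 30_000), GeneIndex(GENES))


class TestCascade:
    def test_empty_case_set(self, small_cohort):
        out, rep = run_cascade(
            calls_to_frame([]), small_cohort.control_calls, small_cohort.genes
        )
        assert out.empty
        assert all(n_in == 0 and n_out == 0 for _, n_in, n_out in rep.stages)

    def test_report_counts_monotone_and_reasons_unique(self, small_cohort):
        out, rep = run_cascade(
            small_cohort.case_calls, small_cohort.control_calls, small_cohort.genes
        )
        counts = [n_in for _, n_in, _ in rep.stages] + [rep.stages[-1][2]]
        assert counts == sorted(counts, reverse=True)
        n_excluded = len(small_cohort.case_calls) - len(out)
        assert len(rep.exclusions) == n_excluded  # one first-failing stage each

    def test_polymorphic_pool_removed_spikes_kept(self, small_cohort):
        # pool carrier rate 0.3 of 80 controls = ~24 carriers > 15
        out, rep = run_cascade(
            small_cohort.case_calls, small_cohort.control_calls, small_cohort.genes
        )
        survivors = set(out.call_id)
        assert not survivors & small_cohort.truth.polymorphic_cnv_ids
        assert small_cohort.truth.spiked_cnv_ids <= survivors

    def test_cascade_is_idempotent(self, small_cohort):
        out1, _ = run_cascade(
            small_cohort.case_calls, small_cohort.control_calls, small_cohort.genes
        )
        out2, _ = run_cascade(
            out1, small_cohort.control_calls, small_cohort.genes
        )
        assert out1.call_id.tolist() == out2.call_id.tolist()

    def test_y_chromosome_and_small_calls_fail_at_calling_stage(self):
        cases = calls_to_frame(
            [
                call("P1", "chrY", 0, 100_000),
                call("P2", "chr1", 0, 5_000),  # below 10 kb
            ]
        )
        out, rep = run_cascade(cases, calls_to_frame([]), GENES)
        assert out.empty
        assert set(rep.exclusions.values()) == {"calling"}
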