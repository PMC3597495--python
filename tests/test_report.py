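"""Evidence aggregation, candidate rule and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rarecnv import io
from rarecnv.core import CNVCall, GeneModel
from rarecnv.report import (
    EvidenceProfile,
    breakpoint_disrupted_genes,
    build_evidence_profile,
    candidate_rule,
    carrier_vs_rest_sds_test,
    render_report,
    subgroup_fisher,
    summarize_cohort,
)
from .oracles import rank_sum_two_sided_oracle


def profile(**kw):
    return EvidenceProfile(cnv_id="x", **kw)


class TestCandidateRule:
    def test_de_novo_with_mgi_genes_passes(self):
        assert candidate_rule("de_novo", profile(n_mgi_growth_genes=3))

    def test_inherited_unaffected_fails_despite_flags(self):
        ev = profile(
            known_short_stature_genes=["SHOX"],
            n_mgi_growth_genes=2,
            n_growth_function_genes=2,
            n_decipher_matches=1,
        )
        assert not candidate_rule("inherited_unaffected", ev)

    def test_de_novo_without_any_flag_fails(self):
        assert not candidate_rule("de_novo", profile())

    def test_maternal_paternal_labels_count_as_inherited(self):
        ev = profile(n_decipher_matches=1)
        assert candidate_rule("maternal", ev)
        assert candidate_rule("paternal", ev)

    def test_monotone_adding_evidence_never_unselects(self):
        base = profile(n_growth_function_genes=1)
        assert candidate_rule("de_novo", base)
        more = profile(
            n_growth_function_genes=1,
            n_mgi_growth_genes=4,
            known_short_stature_genes=["GH1"],
            n_decipher_matches=2,
        )
        assert candidate_rule("de_novo", more)


class TestBreakpointGenes:
    CNV = CNVCall("P1", "chr1", 100_000, 200_000, 1)

    def g(self, gid, start, end):
        return GeneModel(gid, "chr1", start, end, ((start, start + 100),))

    def test_fully_inside_not_disrupted(self):
        assert breakpoint_disrupted_genes(self.CNV, [self.g("A", 120_000, 150_000)]) == []

    def test_spanning_start_only_disrupted(self):
        assert breakpoint_disrupted_genes(self.CNV, [self.g("A", 90_000, 110_000)]) == ["A"]

    def test_spanning_both_ends_not_disrupted(self):
        assert breakpoint_disrupted_genes(self.CNV, [self.g("A", 50_000, 300_000)]) == []


class TestSummaries:
    def test_table_fixture_reproduces_group_means(self):
        df = io.load_table2_fixture()
        cand = df.rename(columns={"patient": "sample_id"})
        summary = summarize_cohort(cand[["inheritance", "size_kb"]])
        g = summary.groups
        assert g["total"].n == 20
        assert g["de_novo"].n == 7 and g["inherited"].n == 13
        assert round(g["total"].mean_size_kb) == 2030
        assert round(g["de_novo"].mean_size_kb) == 2594
        assert round(g["inherited"].mean_size_kb) == 1727

    def test_empty_candidate_set_gives_zeros(self):
        empty = pd.DataFrame(columns=["inheritance", "size_kb"])
        summary = summarize_cohort(empty)
        assert all(gr.n == 0 for gr in summary.groups.values())

    def test_phenotype_splits_from_sample_records(self, small_cohort):
        spikes = small_cohort.case_calls[
            small_cohort.case_calls.call_id.isin(small_cohort.truth.spiked_cnv_ids)
        ].copy()
        spikes["inheritance"] = spikes.call_id.map(
            small_cohort.truth.spike_inheritance
        )
        summary = summarize_cohort(spikes, small_cohort.samples)
        tot = summary.groups["total"]
        assert tot.n == len(spikes)
        assert tot.n_male + tot.n_female == tot.n
        assert tot.mean_height_sds < -2.0


class TestRankSum:
    def test_identical_multisets_p_one(self):
        assert carrier_vs_rest_sds_test([1, 2, 3], [3, 1, 2]) == 1.0

    def test_separated_triples_exact_p_point_one(self):
        assert carrier_vs_rest_sds_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            pool = rng.choice(1000, size=10, replace=False).astype(float)
            x, y = pool[:4], pool[4:]
            assert carrier_vs_rest_sds_test(x, y) == pytest.approx(
                rank_sum_two_sided_oracle(x, y), abs=1e-12
            )

    def test_exact_and_asymptotic_agree_at_moderate_n(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.3, 1, 15)
        p_asym = carrier_vs_rest_sds_test(x, y)  # n=30 -> asymptotic
        p_exact = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
        assert abs(p_asym - p_exact) < 0.02

    def test_carriers_shorter_than_rest_detected(self, small_cohort):
        carriers = {
            small_cohort.truth.spike_sample[c]
            for c in small_cohort.truth.spiked_cnv_ids
        }
        sds_c = [small_cohort.samples[s].height_sds for s in carriers]
        rest = [
            r.height_sds
            for s, r in small_cohort.samples.items()
            if r.group == "case" and s not in carriers
        ]
        # carrier SDS is generated 0.6 SD lower on average
        assert np.mean(sds_c) < np.mean(rest)


class TestSubgroupFisherAndRender:
    def test_subgroup_fisher_counts(self):
        carrier = [True] * 5 + [False] * 15
        pheno = [True, True, True, False, False] + [False] * 15
        odds, p = subgroup_fisher(carrier, pheno)
        assert odds == np.inf and p < 0.05

    def test_render_empty_is_header_only(self):
        table = render_report([])
        assert table.empty and len(table.columns) > 10

    def test_render_fixture_style_profiles(self, small_cohort):
        from rarecnv.core import frame_to_calls

        spikes = small_cohort.case_calls[
            small_cohort.case_calls.call_id.isin(small_cohort.truth.spiked_cnv_ids)
        ]
        profiles = [
            build_evidence_profile(
                c,
                small_cohort.truth.spike_inheritance[c.call_id],
                small_cohort.genes,
            )
            for c in frame_to_calls(spikes)
        ]
        table = render_report(profiles)
        assert len(table) == len(spikes)
        assert list(table.columns) == list(render_report([]).columns)
        assert (table.n_genes >= table.n_hi_genes).all()
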