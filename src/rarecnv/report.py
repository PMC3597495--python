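"""Per-CNV lines-of-evidence aggregation and cohort summaries.

A candidate CNV is retained when its inheritance supports pathogenicity —
de novo, or inherited from the likewise affected parent — AND at least one
line of gene-level evidence is present: a known human growth gene, a gene
with a murine growth-phenotype knockout, a functional candidate gene, or
overlap with a patient-database imbalance annotated with short stature.
Syndrome-region overlap is reported but does not gate the rule.

Cohort summaries (group sizes, sex split, mean height SDS, mean CNV size,
phenotype splits) are computed at full precision and rounded only for
display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .burden import fisher_exact_2x2
from .core import GeneModel, SampleRecord
from .segregation import DE_NOVO, INHERITED_AFFECTED

REPORT_COLUMNS = [
    "cnv_id",
    "sample_id",
    "inheritance",
    "cnv_type",
    "chrom",
    "start",
    "end",
    "size_kb",
    "n_genes",
    "known_short_stature_genes",
    "md_syndrome_overlap",
    "n_growth_function_genes",
    "n_growth_tissue_genes",
    "n_decipher_matches",
    "n_diff_expressed",
    "n_expr_genes",
    "n_mgi_growth_genes",
    "gwas_min_p",
    "breakpoint_disrupted_genes",
    "n_hi_genes",
    "candidate",
]

INHERITED_LABELS = {INHERITED_AFFECTED, "maternal", "paternal", "inherited"}


@dataclass
class EvidenceProfile:
    """One CNV's lines of evidence (one report row)."""

    cnv_id: str
    sample_id: str = ""
    inheritance: str = ""
    cnv_type: str = ""
    chrom: str = ""
    start: int = 0
    end: int = 0
    size_kb: float = 0.0
    n_genes: int = 0
    known_short_stature_genes: list[str] = field(default_factory=list)
    md_syndrome_overlap: str | None = None
    n_growth_function_genes: int = 0
    n_growth_tissue_genes: int = 0
    n_decipher_matches: int = 0
    n_diff_expressed: int | None = None
    n_expr_genes: int | None = None
    n_mgi_growth_genes: int = 0
    gwas_min_p: float | None = None
    breakpoint_disrupted_genes: list[str] = field(default_factory=list)
    n_hi_genes: int = 0


def breakpoint_disrupted_genes(cnv, genes: Iterable[GeneModel]) -> list[str]:
    """Genes spanning exactly one CNV boundary (start XOR end).

    A gene fully inside the CNV, or enclosing it entirely, is dosage-altered
    but not breakpoint-disrupted.
    """
    out = []
    for g in genes:
        if g.chrom != cnv.chrom:
            continue
        spans_start = g.start < cnv.start < g.end
        spans_end = g.start < cnv.end < g.end
        if spans_start ^ spans_end:
            out.append(g.gene_id)
    return out


def build_evidence_profile(
    cnv,
    inheritance: str,
    genes: Iterable[GeneModel],
    hi_cutoff_percentile: float = 10.0,
    gwas_min_p: float | None = None,
    expression_table: pd.DataFrame | None = None,
    md_syndrome_overlap: str | None = None,
) -> EvidenceProfile:
    """Aggregate gene-level flags over the genes overlapped by one CNV."""
    genes = [
        g
        for g in genes
        if g.chrom == cnv.chrom and g.start < cnv.end and g.end > cnv.start
    ]
    n_de, n_expr = None, None
    if expression_table is not None and len(expression_table):
        in_cnv = expression_table[
            expression_table["gene_id"].isin({g.gene_id for g in genes})
        ]
        if len(in_cnv):
            n_de = int(in_cnv["concordant"].sum())
            n_expr = len(in_cnv)
    return EvidenceProfile(
        cnv_id=cnv.call_id,
        sample_id=cnv.sample_id,
        inheritance=inheritance,
        cnv_type=cnv.cnv_type,
        chrom=cnv.chrom,
        start=cnv.start,
        end=cnv.end,
        size_kb=cnv.size_kb,
        n_genes=len(genes),
        known_short_stature_genes=[g.gene_id for g in genes if g.growth_gene],
        md_syndrome_overlap=md_syndrome_overlap,
        n_growth_function_genes=sum(g.functional_candidate for g in genes),
        n_growth_tissue_genes=sum(g.growth_tissue_expressed for g in genes),
        n_decipher_matches=sum(g.decipher_overlap for g in genes),
        n_diff_expressed=n_de,
        n_expr_genes=n_expr,
        n_mgi_growth_genes=sum(g.mgi_growth for g in genes),
        gwas_min_p=gwas_min_p,
        breakpoint_disrupted_genes=breakpoint_disrupted_genes(cnv, genes),
        n_hi_genes=sum(g.hi_percentile < hi_cutoff_percentile for g in genes),
    )


def candidate_rule(inheritance: str, evidence: EvidenceProfile) -> bool:
    """Retained iff segregation supports pathogenicity and at least one
    gene-level line of evidence is present.

    Segregation: de novo, or inherited from the likewise affected parent.
    Evidence lines: (a) a known human growth gene, (b) a murine
    growth-phenotype gene, (c) a functional candidate gene, (d) a
    patient-database short-stature overlap.
    """
    if inheritance != DE_NOVO and inheritance not in INHERITED_LABELS:
        return False
    return bool(
        evidence.known_short_stature_genes
        or evidence.n_mgi_growth_genes > 0
        or evidence.n_growth_function_genes > 0
        or evidence.n_decipher_matches > 0
    )


@dataclass
class GroupSummary:
    n: int = 0
    n_male: int | None = None
    n_female: int | None = None
    mean_height_sds: float | None = None
    mean_size_kb: float | None = None
    n_proportionate: int | None = None
    n_disproportionate: int | None = None
    n_syndromic: int | None = None
    n_isolated: int | None = None
    n_prenatal: int | None = None
    n_postnatal: int | None = None


@dataclass
class CohortSummary:
    groups: dict[str, GroupSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: vars(g) for name, g in self.groups.items()}
        )


def _group_of(label: str) -> str:
    return "de_novo" if label == DE_NOVO else "inherited"


def summarize_cohort(
    candidates: pd.DataFrame,
    samples: Mapping[str, SampleRecord] | None = None,
) -> CohortSummary:
    """Summarize the candidate set overall and by segregation group.

    ``candidates`` needs ``inheritance`` and ``size_kb`` columns; phenotype
    splits additionally need a ``sample_id`` column and the sample records.
    Maternal/paternal labels count as inherited. An empty candidate set
    yields a summary of zeros.
    """
    summary = CohortSummary()
    masks = {
        "total": pd.Series(True, index=candidates.index),
        "de_novo": candidates["inheritance"].map(_group_of) == "de_novo"
        if len(candidates)
        else pd.Series(dtype=bool),
        "inherited": candidates["inheritance"].map(_group_of) == "inherited"
        if len(candidates)
        else pd.Series(dtype=bool),
    }
    for name, mask in masks.items():
        sub = candidates[mask] if len(candidates) else candidates
        g = GroupSummary(n=len(sub))
        if len(sub):
            g.mean_size_kb = float(sub["size_kb"].mean())
        if samples is not None and "sample_id" in candidates.columns and len(sub):
            recs = [samples[s] for s in sub["sample_id"]]
            g.n_male = sum(r.sex == "M" for r in recs)
            g.n_female = sum(r.sex == "F" for r in recs)
            sds = [r.height_sds for r in recs if r.height_sds is not None]
            g.mean_height_sds = float(np.mean(sds)) if sds else None
            g.n_proportionate = sum(r.proportionate is True for r in recs)
            g.n_disproportionate = sum(r.proportionate is False for r in recs)
            g.n_syndromic = sum(r.syndromic is True for r in recs)
            g.n_isolated = sum(r.syndromic is False for r in recs)
            g.n_prenatal = sum(r.prenatal_onset is True for r in recs)
            g.n_postnatal = sum(r.prenatal_onset is False for r in recs)
        summary.groups[name] = g
    return summary


def carrier_vs_rest_sds_test(carrier_sds, rest_sds) -> float:
    """Two-sided rank-sum (Wilcoxon-Mann-Whitney) p-value.

    Exact enumeration for combined n <= 20 without ties; the normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(list(carrier_sds), dtype=float)
    y = np.asarray(list(rest_sds), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def subgroup_fisher(carrier_flags, phenotype_flags) -> tuple[float, float]:
    """Fisher 2x2 of candidate-carrier status against a phenotype flag."""
    carrier = np.asarray(carrier_flags, dtype=bool)
    pheno = np.asarray(phenotype_flags, dtype=bool)
    if carrier.shape != pheno.shape:
        raise ValueError("flag vectors must have equal length")
    a = int((carrier & pheno).sum())
    b = int((carrier & ~pheno).sum())
    c = int((~carrier & pheno).sum())
    d = int((~carrier & ~pheno).sum())
    return fisher_exact_2x2([[a, b], [c, d]])


def render_report(profiles: Iterable[EvidenceProfile]) -> pd.DataFrame:
    """Deterministic report table, one row per CNV, fixed column order."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "cnv_id": p.cnv_id,
                "sample_id": p.sample_id,
                "inheritance": p.inheritance,
                "cnv_type": p.cnv_type,
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "size_kb": p.size_kb,
                "n_genes": p.n_genes,
                "known_short_stature_genes": ",".join(p.known_short_stature_genes)
                or "-",
                "md_syndrome_overlap": p.md_syndrome_overlap or "-",
                "n_growth_function_genes": p.n_growth_function_genes,
                "n_growth_tissue_genes": p.n_growth_tissue_genes,
                "n_decipher_matches": p.n_decipher_matches,
                "n_diff_expressed": p.n_diff_expressed
                if p.n_diff_expressed is not None
                else "n/a",
                "n_expr_genes": p.n_expr_genes if p.n_expr_genes is not None else "n/a",
                "n_mgi_growth_genes": p.n_mgi_growth_genes,
                "gwas_min_p": p.gwas_min_p if p.gwas_min_p is not None else "n/a",
                "breakpoint_disrupted_genes": ",".join(p.breakpoint_disrupted_genes)
                or "-",
                "n_hi_genes": p.n_hi_genes,
                "candidate": candidate_rule(p.inheritance, p),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
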