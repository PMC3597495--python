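"""Filtering cascade from raw CNV calls to rare, gene-affecting candidates.

Stages, in order (each call's first failing stage is recorded):

1. ``calling``      — minimum size (10 kb), minimum marker support, and
                      removal of excluded chromosomes (the Y by default,
                      where array calling is unreliable).
2. ``candidate_size`` — candidate floor, default 50 kb (the resolution at
                      which independent validation is reliable). Ties at
                      the floor are kept.
3. ``polymorphism``  — calls whose size overlaps same-type calls by more
                      than 95% in more than 15 control samples are removed
                      as common polymorphisms.
4. ``gene_coverage`` — calls below the 95% overlap criterion but whose
                      overlapped genes are each fully contained in calls of
                      at least 15 control samples are removed.
5. ``exonic``        — calls touching no exon (intronic or intergenic only)
                      are removed.

Overlap fractions are computed relative to the query (patient) call; a
reciprocal mode requiring the fraction in both directions is available via
``FilterConfig.reciprocal``. Matching is always same-type (gain with gain,
loss with loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .core import CNVCall, GeneModel, overlap_length
from .errors import ConfigError

STAGES = ("calling", "candidate_size", "polymorphism", "gene_coverage", "exonic")


@dataclass
class FilterConfig:
    min_size_kb: float = 50.0
    calling_min_size_kb: float = 10.0
    min_markers: int = 5
    overlap_fraction: float = 0.95
    max_control_carriers: int = 15  # exclusion when carrier count > this
    require_exonic: bool = True
    exclude_chrom: frozenset = frozenset({"chrY", "Y"})
    reciprocal: bool = False

    def validate(self) -> None:
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ConfigError("overlap_fraction must be in (0, 1]")
        if self.max_control_carriers < 0 or self.min_markers < 0:
            raise ConfigError("counts must be >= 0")
        if self.min_size_kb < 0 or self.calling_min_size_kb < 0:
            raise ConfigError("size thresholds must be >= 0")


@dataclass
class FilterReport:
    """Per-stage funnel counts and per-call exclusion reasons."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)  # call_id -> stage

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s, "n_in": a, "n_out": b} for s, a, b in self.stages
            ],
            "n_excluded_per_stage": {
                s: sum(1 for v in self.exclusions.values() if v == s)
                for s in STAGES
            },
        }


def size_overlap_fraction(a, b) -> float:
    """Fraction of call ``a`` covered by call ``b`` (asymmetric; 0 if on
    different chromosomes)."""
    if a.chrom != b.chrom:
        return 0.0
    return overlap_length(a.start, a.end, b.start, b.end) / (a.end - a.start)


class ControlIndex:
    """Per-(chromosome, type) interval index over control calls."""

    def __init__(self, control_calls: pd.DataFrame):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for r in control_calls.itertuples(index=False):
            key = (r.chrom, r.cnv_type)
            tree = self._trees.get(key)
            if tree is None:
                tree = self._trees[key] = IntervalTree()
            tree.addi(int(r.start), int(r.end), str(r.sample_id))

    def carrier_count(self, cnv, config: FilterConfig) -> int:
        """Distinct control samples with a same-type call overlapping the
        query by more than ``config.overlap_fraction`` of the query size
        (and of the control call too, in reciprocal mode)."""
        tree = self._trees.get((cnv.chrom, cnv.cnv_type))
        if tree is None:
            return 0
        qsize = cnv.end - cnv.start
        carriers: set[str] = set()
        for iv in tree.overlap(cnv.start, cnv.end):
            ov = overlap_length(cnv.start, cnv.end, iv.begin, iv.end)
            if ov / qsize <= config.overlap_fraction:
                continue
            if config.reciprocal and ov / (iv.end - iv.begin) <= config.overlap_fraction:
                continue
            carriers.add(iv.data)
        return len(carriers)

    def samples_containing(self, chrom: str, cnv_type: str, start: int, end: int) -> int:
        """Distinct control samples with a same-type call fully containing
        the interval ``[start, end)``."""
        tree = self._trees.get((chrom, cnv_type))
        if tree is None:
            return 0
        return len(
            {iv.data for iv in tree.overlap(start, end) if iv.begin <= start and iv.end >= end}
        )


class GeneIndex:
    """Interval indexes over gene spans and exons."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = genes
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for g in genes:
            gt = self._gene_trees.setdefault(g.chrom, IntervalTree())
            gt.addi(g.start, g.end, g)
            et = self._exon_trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                et.addi(s, e, g.gene_id)

    def overlapping_genes(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)), key=lambda g: g.start)

    def touches_exon(self, chrom: str, start: int, end: int) -> bool:
        tree = self._exon_trees.get(chrom)
        return tree is not None and bool(tree.overlap(start, end))


def control_carrier_count(cnv, index: ControlIndex, config: FilterConfig) -> int:
    return index.carrier_count(cnv, config)


def gene_coverage_excluded(
    cnv, index: ControlIndex, gene_index: GeneIndex, config: FilterConfig
) -> bool:
    """True iff every gene overlapped by the query is fully contained in
    same-type control calls of at least ``max_control_carriers`` distinct
    control samples each.

    A call overlapping no genes returns False: gene-free calls are handled
    by the exonic stage, and letting the vacuous case trigger removal here
    would double-count exclusion reasons.
    """
    genes = gene_index.overlapping_genes(cnv.chrom, cnv.start, cnv.end)
    if not genes:
        return False
    return all(
        index.samples_containing(g.chrom, cnv.cnv_type, g.start, g.end)
        >= config.max_control_carriers
        for g in genes
    )


def exonic_filter(cnv, gene_index: GeneIndex) -> bool:
    """Keep iff the call intersects at least one exon interval."""
    return gene_index.touches_exon(cnv.chrom, cnv.start, cnv.end)


def run_cascade(
    case_calls: pd.DataFrame,
    control_calls: pd.DataFrame,
    genes: list[GeneModel],
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the full cascade to a case call table.

    Returns the surviving calls and a :class:`FilterReport` whose stage
    counts are monotonically non-increasing and whose exclusion map records
    each removed call's first failing stage.
    """
    config = config or FilterConfig()
    config.validate()
    report = FilterReport()
    df = case_calls.reset_index(drop=True)

    # stage 1+2: vectorized size/marker/chromosome prefilters
    n_in = len(df)
    keep = (
        (df["size_kb"] >= config.calling_min_size_kb)
        & (df["n_markers"] >= config.min_markers)
        & ~df["chrom"].isin(config.exclude_chrom)
    )
    for cid in df.loc[~keep, "call_id"]:
        report.exclusions[cid] = "calling"
    df = df[keep]
    report.stages.append(("calling", n_in, len(df)))

    n_in = len(df)
    keep = df["size_kb"] >= config.min_size_kb
    for cid in df.loc[~keep, "call_id"]:
        report.exclusions[cid] = "candidate_size"
    df = df[keep]
    report.stages.append(("candidate_size", n_in, len(df)))

    index = ControlIndex(control_calls)
    gene_index = GeneIndex(genes)

    n_in = len(df)
    keep_rows = []
    for row in df.itertuples(index=False):
        if index.carrier_count(row, config) > config.max_control_carriers:
            report.exclusions[row.call_id] = "polymorphism"
        else:
            keep_rows.append(row)
    df = pd.DataFrame(keep_rows, columns=df.columns) if keep_rows else df.iloc[0:0]
    report.stages.append(("polymorphism", n_in, len(df)))

    n_in = len(df)
    keep_rows = []
    for row in df.itertuples(index=False):
        if gene_coverage_excluded(row, index, gene_index, config):
            report.exclusions[row.call_id] = "gene_coverage"
        else:
            keep_rows.append(row)
    df = pd.DataFrame(keep_rows, columns=df.columns) if keep_rows else df.iloc[0:0]
    report.stages.append(("gene_coverage", n_in, len(df)))

    n_in = len(df)
    if config.require_exonic:
        keep_rows = []
        for row in df.itertuples(index=False):
            if exonic_filter(row, gene_index):
                keep_rows.append(row)
            else:
                report.exclusions[row.call_id] = "exonic"
        df = pd.DataFrame(keep_rows, columns=df.columns) if keep_rows else df.iloc[0:0]
    report.stages.append(("exonic", n_in, len(df)))

    return df.reset_index(drop=True), report
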