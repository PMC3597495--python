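"""Core domain types shared across the pipeline.

All genomic intervals in this package are 0-based, half-open ``[start, end)``.
Conversion from other conventions happens only at I/O boundaries
(:mod:`rarecnv.io`).

Copy-number calls carry an integer copy state relative to the diploid state 2:
states below 2 are losses (deletions), states above 2 are gains
(duplications). State 2 is not a call and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import pandas as pd

from .errors import RareCNVError

GAIN = "gain"
LOSS = "loss"

#: Column order of the canonical in-memory call table.
CALL_COLUMNS = [
    "call_id",
    "sample_id",
    "chrom",
    "start",
    "end",
    "copy_state",
    "cnv_type",
    "n_markers",
    "size_kb",
]


def cnv_type_of(copy_state: int) -> str:
    if copy_state > 2:
        return GAIN
    if copy_state < 2:
        return LOSS
    raise RareCNVError("copy_state 2 is the diploid state, not a CNV call")


@dataclass(frozen=True)
class CNVCall:
    """One copy-number segment observed in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_state: int
    n_markers: int = 5
    call_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise RareCNVError(
                f"CNV call must have end > start, got [{self.start}, {self.end})"
            )
        if self.copy_state < 0 or self.copy_state == 2:
            raise RareCNVError(
                f"copy_state must be a non-negative integer != 2, got {self.copy_state}"
            )
        if not self.call_id:
            object.__setattr__(
                self,
                "call_id",
                f"{self.sample_id}:{self.chrom}:{self.start}-{self.end}",
            )

    @property
    def cnv_type(self) -> str:
        return cnv_type_of(self.copy_state)

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def size_kb(self) -> float:
        return (self.end - self.start) / 1000.0


@dataclass(frozen=True)
class SampleRecord:
    """Individual metadata: cohort group, sex, height SDS and phenotype flags.

    ``height_sds`` is the height standard-deviation score (dimensionless);
    it may be ``None`` for controls, which carry no height requirement.
    """

    sample_id: str
    group: str  # "case" | "control"
    sex: str = "U"  # "M" | "F" | "U"
    height_sds: float | None = None
    affected: bool = False
    proportionate: bool | None = None
    syndromic: bool | None = None
    prenatal_onset: bool | None = None
    learning_disability: bool | None = None

    def __post_init__(self) -> None:
        if self.group not in ("case", "control", "parent"):
            raise RareCNVError(f"unknown sample group {self.group!r}")


@dataclass(frozen=True)
class Trio:
    """Parent-offspring linkage with parental affection status."""

    child_id: str
    mother_id: str
    father_id: str
    mother_affected: bool = False
    father_affected: bool = False

    def __post_init__(self) -> None:
        ids = {self.child_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise RareCNVError(
                f"trio members must be distinct: {self.child_id}, "
                f"{self.mother_id}, {self.father_id}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene span with exon intervals and prioritization evidence flags.

    Boolean flags mark membership in externally curated evidence classes
    (known human growth gene, murine growth-phenotype knockout, functional
    candidate, expression in growth-relevant tissue, overlap with a
    patient-database imbalance). ``hi_percentile`` is the haploinsufficiency
    score percentile in [0, 100]; low values predict dosage sensitivity.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    growth_gene: bool = False
    mgi_growth: bool = False
    functional_candidate: bool = False
    growth_tissue_expressed: bool = False
    decipher_overlap: bool = False
    hi_percentile: float = 50.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise RareCNVError(f"gene {self.gene_id}: end <= start")
        if not self.exons:
            raise RareCNVError(f"gene {self.gene_id}: needs at least one exon")
        for s, e in self.exons:
            if e <= s or s < self.start or e > self.end:
                raise RareCNVError(
                    f"gene {self.gene_id}: exon [{s}, {e}) outside span "
                    f"[{self.start}, {self.end}) or malformed"
                )
        if not 0.0 <= self.hi_percentile <= 100.0:
            raise RareCNVError(
                f"gene {self.gene_id}: hi_percentile must be in [0, 100]"
            )


def calls_to_frame(calls: Iterable[CNVCall]) -> pd.DataFrame:
    """Tabulate calls into the canonical call table (one row per call)."""
    rows = [
        (
            c.call_id,
            c.sample_id,
            c.chrom,
            c.start,
            c.end,
            c.copy_state,
            c.cnv_type,
            c.n_markers,
            c.size_kb,
        )
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if df.empty:
        df = df.astype(
            {
                "start": "int64",
                "end": "int64",
                "copy_state": "int64",
                "n_markers": "int64",
                "size_kb": "float64",
            }
        )
    return df


def frame_to_calls(df: pd.DataFrame) -> list[CNVCall]:
    return [
        CNVCall(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            copy_state=int(r.copy_state),
            n_markers=int(r.n_markers),
            call_id=str(r.call_id),
        )
        for r in df.itertuples(index=False)
    ]


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))
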