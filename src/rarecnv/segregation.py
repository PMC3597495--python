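"""Trio segregation of candidate CNVs, MLPA confirmation and de novo rates.

A child call is matched against parental calls of the same type; a parental
call matching more than half of the child interval (configurable) counts as
transmission. The lenient default match fraction of 0.5 — rather than the
0.95 used for population-frequency filtering — reflects that breakpoint
estimates jitter between platforms and that parental confirmation is often
based on a single MLPA probe.

MLPA relative quantities classify as deletion below 0.75 and duplication
above 1.25, with the boundaries themselves reading as normal (the
thresholds are strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .core import CNVCall
from .errors import RareCNVError
from .filtering import size_overlap_fraction

DE_NOVO = "de_novo"
INHERITED_AFFECTED = "inherited_affected"
INHERITED_UNAFFECTED = "inherited_unaffected"
UNRESOLVED = "unresolved"

MLPA_DELETION_MAX = 0.75
MLPA_DUPLICATION_MIN = 1.25


@dataclass
class InheritanceCall:
    cnv_id: str
    category: str
    transmitting_parent: str | None = None

    def __post_init__(self) -> None:
        if self.category in (INHERITED_AFFECTED, INHERITED_UNAFFECTED):
            if not self.transmitting_parent:
                raise RareCNVError("inherited call requires a transmitting parent")
        elif self.transmitting_parent is not None:
            raise RareCNVError(f"{self.category} call cannot name a parent")


@dataclass
class DeNovoRateModel:
    """Population expectation for de novo CNVs per haploid genome per
    generation (default 6e-3); each patient contributes two haploid
    genomes."""

    rate_per_haploid_genome: float = 6e-3
    n_patients: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.rate_per_haploid_genome < 1.0:
            raise RareCNVError("rate must be in (0, 1)")
        if self.n_patients < 0:
            raise RareCNVError("n_patients must be >= 0")

    @property
    def n_haploid_genomes(self) -> int:
        return 2 * self.n_patients

    @property
    def expected_count(self) -> float:
        return self.n_haploid_genomes * self.rate_per_haploid_genome


def _parent_match(child, parent_calls, match_fraction: float) -> bool:
    for p in parent_calls:
        if p.cnv_type != child.cnv_type:
            continue
        if size_overlap_fraction(child, p) >= match_fraction:
            return True
    return False


def classify_inheritance(
    child_cnv,
    mother_calls,
    father_calls,
    mother_affected: bool,
    father_affected: bool,
    match_fraction: float = 0.5,
) -> InheritanceCall:
    """Classify one child CNV from parental call sets.

    ``mother_calls``/``father_calls`` are iterables of calls (array- or
    MLPA-derived); pass ``None`` for a parent with no data, which yields
    ``unresolved`` rather than an error. A match in any affected parent
    wins over a match in an unaffected one.
    """
    if mother_calls is None or father_calls is None:
        return InheritanceCall(child_cnv.call_id, UNRESOLVED)
    in_mother = _parent_match(child_cnv, mother_calls, match_fraction)
    in_father = _parent_match(child_cnv, father_calls, match_fraction)
    if not in_mother and not in_father:
        return InheritanceCall(child_cnv.call_id, DE_NOVO)
    candidates = []
    if in_mother:
        candidates.append(("mother", mother_affected))
    if in_father:
        candidates.append(("father", father_affected))
    for parent, affected in candidates:
        if affected:
            return InheritanceCall(child_cnv.call_id, INHERITED_AFFECTED, parent)
    return InheritanceCall(child_cnv.call_id, INHERITED_UNAFFECTED, candidates[0][0])


def classify_cohort(
    candidate_calls: pd.DataFrame,
    parent_calls: pd.DataFrame,
    trios,
    match_fraction: float = 0.5,
) -> pd.DataFrame:
    """Classify every candidate call of every trio child.

    Returns the candidate table with ``inheritance`` and
    ``transmitting_parent`` columns appended. Children without a trio are
    ``unresolved``.
    """
    from .core import frame_to_calls

    trio_by_child = {t.child_id: t for t in trios}
    by_parent: dict[str, list] = {}
    for c in frame_to_calls(parent_calls):
        by_parent.setdefault(c.sample_id, []).append(c)
    records = []
    for child in frame_to_calls(candidate_calls):
        trio = trio_by_child.get(child.sample_id)
        if trio is None:
            records.append((child.call_id, UNRESOLVED, None))
            continue
        call = classify_inheritance(
            child,
            by_parent.get(trio.mother_id, []),
            by_parent.get(trio.father_id, []),
            trio.mother_affected,
            trio.father_affected,
            match_fraction,
        )
        parent_id = {
            "mother": trio.mother_id,
            "father": trio.father_id,
            None: None,
        }[call.transmitting_parent]
        records.append((call.cnv_id, call.category, parent_id))
    ann = pd.DataFrame(
        records, columns=["call_id", "inheritance", "transmitting_parent"]
    )
    return candidate_calls.merge(ann, on="call_id", how="left")


def mlpa_classify(ratio: float) -> str:
    """Classify a relative probe quantity: deletion below 0.75, duplication
    above 1.25, otherwise normal."""
    if ratio <= 0:
        raise RareCNVError(f"probe ratio must be positive, got {ratio}")
    if ratio < MLPA_DELETION_MAX:
        return "deletion"
    if ratio > MLPA_DUPLICATION_MIN:
        return "duplication"
    return "normal"


def mlpa_confirm(calls: pd.DataFrame, mlpa: pd.DataFrame) -> pd.DataFrame:
    """Match MLPA probes to calls by sample and locus overlap and report
    whether each call's expected direction is confirmed."""
    rows = []
    for r in calls.itertuples(index=False):
        expected = "duplication" if r.cnv_type == "gain" else "deletion"
        probes = mlpa[mlpa["sample_id"] == r.sample_id]
        confirmed = None
        for p in probes.itertuples(index=False):
            chrom, span = p.locus.split(":")
            s, e = (int(x) for x in span.split("-"))
            if chrom == r.chrom and s < r.end and e > r.start:
                confirmed = mlpa_classify(p.ratio) == expected
                break
        rows.append((r.call_id, expected, confirmed))
    return pd.DataFrame(rows, columns=["call_id", "expected", "mlpa_confirmed"])


def de_novo_enrichment(
    observed: int, model: DeNovoRateModel, method: str = "poisson"
) -> float:
    """Upper-tail probability of at least ``observed`` de novo CNVs under
    the population rate model.

    ``poisson`` uses the tail of Poisson(2 n r); ``binomial`` the tail of
    Binomial(2n, r); ``fisher_vs_expected`` a one-sided Fisher test of
    observed versus (rounded) expected counts against haploid genomes.
    """
    if observed < 0:
        raise RareCNVError("observed count must be >= 0")
    if observed == 0:
        return 1.0
    n2 = model.n_haploid_genomes
    mu = model.expected_count
    if method == "poisson":
        return float(stats.poisson.sf(observed - 1, mu))
    if method == "binomial":
        return float(stats.binom.sf(observed - 1, n2, model.rate_per_haploid_genome))
    if method == "fisher_vs_expected":
        expected = int(round(mu))
        table = [[observed, n2 - observed], [expected, n2 - expected]]
        return float(stats.fisher_exact(table, alternative="greater")[1])
    raise RareCNVError(f"unknown de novo enrichment method {method!r}")
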