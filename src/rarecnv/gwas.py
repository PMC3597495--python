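"""Intersection of candidate CNVs with a per-SNP association track.

The multiple-testing threshold is derived from the number of SNPs that fall
inside the union of the candidate intervals (joint counting across CNVs),
alpha / n_tests. A CNV is flagged significant when its minimum contained
SNP p-value is below that bound. Enrichment of significant-locus-containing
CNVs over chance is assessed by a Monte-Carlo null that re-places
size-matched random intervals uniformly on the genome and re-counts.

SNP containment uses the package-wide 0-based half-open convention: a SNP
exactly at a CNV's end coordinate is outside it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import PlacementError, RareCNVError

#: conventional genome-wide bound for CNV association, 0.05 over the
#: approximate count of copy-number polymorphisms >= 50 kb per genome
GENOMEWIDE_CNV_ALPHA = 0.05 / 2000


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise RareCNVError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise RareCNVError("n_tests must be >= 1")
    return alpha / n_tests


def _snp_arrays(snps: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in snps.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        order = np.argsort(pos, kind="stable")
        out[chrom] = (pos[order], sub["p"].to_numpy(float)[order])
    return out


def summarize_overlap(
    cnvs: pd.DataFrame, snps: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-CNV SNP counts, minimum p, and significance calls.

    ``n_tests`` is the number of SNPs inside the union of the candidate
    intervals; the same derived threshold applies to every CNV. Columns:
    ``n_snps_in_cnv``, ``min_p`` (NaN when empty), ``significant`` (vs the
    derived Bonferroni bound) and ``genomewide_significant`` (vs the
    conventional 2.5e-5 CNV bound).
    """
    by_chrom = _snp_arrays(snps)
    n_snps_col, min_p_col = [], []
    union_hits: set[tuple[str, int]] = set()
    for r in cnvs.itertuples(index=False):
        arr = by_chrom.get(r.chrom)
        if arr is None:
            n_snps_col.append(0)
            min_p_col.append(np.nan)
            continue
        pos, p = arr
        lo = np.searchsorted(pos, r.start, side="left")
        hi = np.searchsorted(pos, r.end, side="left")  # end excluded
        n_snps_col.append(int(hi - lo))
        min_p_col.append(float(p[lo:hi].min()) if hi > lo else np.nan)
        union_hits.update((r.chrom, int(x)) for x in pos[lo:hi])
    n_tests = len(union_hits)
    out = cnvs.copy().reset_index(drop=True)
    out["n_snps_in_cnv"] = n_snps_col
    out["min_p"] = min_p_col
    if n_tests > 0:
        thr = bonferroni_threshold(alpha, n_tests)
        out["bonferroni_alpha"] = thr
        out["significant"] = pd.Series(min_p_col) < thr
    else:
        out["bonferroni_alpha"] = np.nan
        out["significant"] = False
    out["genomewide_significant"] = pd.Series(min_p_col) < GENOMEWIDE_CNV_ALPHA
    out.attrs["n_tests"] = n_tests
    return out


def overlap_enrichment(
    n_significant: int,
    cnvs: pd.DataFrame,
    snps: pd.DataFrame,
    chrom_lengths: dict[str, int],
    threshold: float,
    n_draws: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo p for observing >= ``n_significant`` CNVs containing a
    sub-threshold SNP under random size-matched placement.

    Each draw re-places every candidate interval uniformly on the genome
    (chromosome chosen proportional to the space that fits it) and counts
    intervals containing at least one SNP with p < ``threshold``. The +1
    correction keeps the p-value strictly positive.
    """
    if n_significant == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    sizes = (cnvs["end"] - cnvs["start"]).to_numpy(np.int64)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    if sizes.max() > lengths.max():
        raise PlacementError(
            f"interval of {sizes.max()} bp exceeds the longest chromosome"
        )
    # sorted positions of sub-threshold SNPs per chromosome
    sub = snps[snps["p"] < threshold]
    hit_pos = {
        chrom: np.sort(s["pos"].to_numpy(np.int64))
        for chrom, s in sub.groupby("chrom", sort=False)
    }
    exceed = 0
    for _ in range(n_draws):
        count = 0
        for size in sizes:
            room = np.maximum(lengths - size, 0)
            total = room.sum()
            if total == 0:
                raise PlacementError("no chromosome can host the interval")
            ci = np.searchsorted(np.cumsum(room), rng.integers(0, total),
                                 side="right")
            start = int(rng.integers(0, room[ci]))
            pos = hit_pos.get(chroms[ci])
            if pos is not None and np.searchsorted(pos, start + size, "left") > np.searchsorted(pos, start, "left"):
                count += 1
        if count >= n_significant:
            exceed += 1
    return (1.0 + exceed) / (1.0 + n_draws)
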