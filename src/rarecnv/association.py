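"""Genome-wide copy-number association via pseudomarkers.

Pseudomarkers are placed at the distinct endpoints of all CNV segments
(cases and controls pooled). At each marker a sample is a carrier of a
given type iff it has a call of that type whose half-open interval contains
the marker position — so a segment's own start is a carrier position and
its end is not.

Association at each marker is a Pearson chi-squared statistic (no
continuity correction) on the 2x2 carrier-by-group table, with significance
assessed by label permutation: p = (1 + #{chi2_perm >= chi2_obs}) /
(1 + n_perm), which can never be zero. By default one set of label
permutations is shared across markers within a run (faster and preserves
between-marker correlation); independent per-marker permutations and exact
exhaustive enumeration over all case/control relabelings are available.
Gains and losses are separate test families, but the Bonferroni correction
is applied over the union of markers tested across both.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import RareCNVError


@dataclass
class MarkerAssociationResult:
    chrom: str
    position: int
    cnv_type: str
    n_case_carriers: int
    n_control_carriers: int
    chi2_statistic: float
    permutation_p: float
    bonferroni_p: float
    degenerate: bool = False


def build_pseudomarkers(calls: pd.DataFrame) -> pd.DataFrame:
    """Distinct segment endpoints, sorted per chromosome."""
    pts = pd.concat(
        [
            calls[["chrom", "start"]].rename(columns={"start": "pos"}),
            calls[["chrom", "end"]].rename(columns={"end": "pos"}),
        ]
    )
    out = pts.drop_duplicates().sort_values(["chrom", "pos"], kind="stable")
    return out.reset_index(drop=True)


def status_matrix(
    calls: pd.DataFrame,
    markers: pd.DataFrame,
    cnv_type: str,
    sample_ids: list[str],
) -> np.ndarray:
    """Boolean carrier matrix, samples x markers.

    ``status[i, j]`` is True iff sample i has a call of ``cnv_type`` whose
    half-open interval contains marker j's position.
    """
    sidx = {s: i for i, s in enumerate(sample_ids)}
    status = np.zeros((len(sample_ids), len(markers)), dtype=bool)
    typed = calls[calls["cnv_type"] == cnv_type]
    for chrom, sub in typed.groupby("chrom", sort=False):
        mk = markers[markers["chrom"] == chrom]
        if mk.empty:
            continue
        mpos = mk["pos"].to_numpy()
        mcols = mk.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        rows = np.fromiter((sidx[s] for s in sub["sample_id"]), dtype=np.int64,
                           count=len(sub))
        for s, e, i in zip(starts, ends, rows):
            lo = np.searchsorted(mpos, s, side="left")
            hi = np.searchsorted(mpos, e, side="left")  # end excluded
            if hi > lo:
                status[i, mcols[lo:hi]] = True
    return status


def _chi2_from_counts(k1, k0, n1: int, n0: int) -> np.ndarray:
    """Pearson chi2 of 2x2 [[k1, n1-k1], [k0, n0-k0]] without correction.

    Degenerate margins (all or no carriers) yield 0.
    """
    k1 = np.asarray(k1, dtype=float)
    k0 = np.asarray(k0, dtype=float)
    n = n1 + n0
    tot = k1 + k0
    with np.errstate(divide="ignore", invalid="ignore"):
        num = n * (k1 * (n0 - k0) - k0 * (n1 - k1)) ** 2
        den = n1 * n0 * tot * (n - tot)
        chi2 = np.where(den > 0, num / den, 0.0)
    return chi2


def permutation_chi2(
    status: np.ndarray,
    is_case: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = 0,
    mode: str = "shared",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation chi-squared test for one or many markers.

    Parameters
    ----------
    status
        Boolean carrier matrix (samples x markers) or a single status vector.
    is_case
        Boolean group labels per sample.
    mode
        ``"shared"`` — one permutation set shared across markers;
        ``"independent"`` — a fresh permutation set per marker;
        ``"exhaustive"`` — enumerate all case/control relabelings (exact;
        feasible for small cohorts only).

    Returns ``(chi2_obs, p, degenerate)`` arrays over markers.
    """
    status = np.atleast_2d(np.asarray(status, dtype=bool))
    if status.shape[0] == 1 and status.shape[1] == np.asarray(is_case).size:
        status = status.T  # single vector passed row-wise
    is_case = np.asarray(is_case, dtype=bool)
    n = is_case.size
    n1 = int(is_case.sum())
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise RareCNVError("need at least 2 samples per group")
    k1_obs = is_case.astype(np.int64) @ status
    tot = status.sum(axis=0)
    k0_obs = tot - k1_obs
    chi2_obs = _chi2_from_counts(k1_obs, k0_obs, n1, n0)
    degenerate = (tot == 0) | (tot == n)

    if mode == "exhaustive":
        count = np.zeros(status.shape[1], dtype=np.int64)
        n_assign = 0
        for case_idx in combinations(range(n), n1):
            labels = np.zeros(n, dtype=np.int64)
            labels[list(case_idx)] = 1
            k1 = labels @ status
            chi2 = _chi2_from_counts(k1, tot - k1, n1, n0)
            count += chi2 >= chi2_obs - 1e-12
            n_assign += 1
        p = count / n_assign
    elif mode in ("shared", "independent"):
        rng = np.random.default_rng(seed)
        if mode == "shared":
            perms = np.empty((n_perm, n), dtype=np.int64)
            base = is_case.astype(np.int64)
            for i in range(n_perm):
                perms[i] = rng.permutation(base)
            k1 = perms @ status  # n_perm x markers
            chi2 = _chi2_from_counts(k1, tot[None, :] - k1, n1, n0)
            exceed = (chi2 >= chi2_obs[None, :] - 1e-12).sum(axis=0)
        else:
            exceed = np.zeros(status.shape[1], dtype=np.int64)
            base = is_case.astype(np.int64)
            for j in range(status.shape[1]):
                col = status[:, j].astype(np.int64)
                for _ in range(n_perm):
                    k1 = int(np.dot(rng.permutation(base), col))
                    chi2 = _chi2_from_counts(k1, int(tot[j]) - k1, n1, n0)
                    exceed[j] += chi2 >= chi2_obs[j] - 1e-12
        p = (1.0 + exceed) / (1.0 + n_perm)
    else:
        raise RareCNVError(f"unknown permutation mode {mode!r}")

    p = np.where(degenerate, 1.0, p)
    return chi2_obs, p, degenerate


def associate(
    case_calls: pd.DataFrame,
    control_calls: pd.DataFrame,
    cnv_types: tuple[str, ...] = ("gain", "loss"),
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "shared",
) -> pd.DataFrame:
    """Run the pseudomarker association across one or both CNV types.

    Bonferroni p-values are corrected for the total number of markers
    tested across all requested types.
    """
    pooled = pd.concat([case_calls, control_calls], ignore_index=True)
    markers = build_pseudomarkers(pooled)
    case_ids = sorted(set(case_calls["sample_id"]))
    control_ids = sorted(set(control_calls["sample_id"]))
    sample_ids = case_ids + control_ids
    is_case = np.array([True] * len(case_ids) + [False] * len(control_ids))
    frames = []
    for cnv_type in cnv_types:
        status = status_matrix(pooled, markers, cnv_type, sample_ids)
        chi2, p, degenerate = permutation_chi2(status, is_case, n_perm, seed, mode)
        k1 = is_case.astype(np.int64) @ status
        k0 = status.sum(axis=0) - k1
        frames.append(
            pd.DataFrame(
                {
                    "chrom": markers["chrom"],
                    "pos": markers["pos"],
                    "cnv_type": cnv_type,
                    "n_case_carriers": k1,
                    "n_control_carriers": k0,
                    "chi2": chi2,
                    "permutation_p": p,
                    "degenerate": degenerate,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["bonferroni_p"] = np.minimum(1.0, out["permutation_p"] * len(out))
    return out
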