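"""Independent brute-force oracles used to pin expected values in tests.

These are deliberately naive (enumeration, double loops, log-space sums)
and share no code with the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, exp, inf, lgamma, log

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration over the
    first cell at fixed margins.

    Tables whose probability is at most the observed table's (up to a
    1 + 1e-7 relative slack for floating-point ties) contribute.
    """
    n1, n0 = a + b, c + d
    m = a + c
    N = n1 + n0
    denom = comb(N, n1)
    lo, hi = max(0, m - n0), min(m, n1)
    probs = {x: comb(m, x) * comb(N - m, n1 - x) / denom for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-squared without continuity correction (plain formula)."""
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / den


def permutation_p_exhaustive(status, is_case) -> float:
    """Exact permutation p for one marker by enumerating every assignment
    of case labels to samples."""
    status = np.asarray(status, dtype=bool)
    is_case = np.asarray(is_case, dtype=bool)
    n = status.size
    n1 = int(is_case.sum())
    n0 = n - n1
    obs = chi2_2x2(
        int(status[is_case].sum()),
        int((~status[is_case]).sum()),
        int(status[~is_case].sum()),
        int((~status[~is_case]).sum()),
    )
    count = total = 0
    for idx in combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        stat = chi2_2x2(
            int(status[mask].sum()),
            int((~status[mask]).sum()),
            int(status[~mask].sum()),
            int((~status[~mask]).sum()),
        )
        count += stat >= obs - 1e-12
        total += 1
    return count / total


def binom_upper_tail_log_oracle(k: int, n: int, p: float) -> float:
    """P(X >= k) for Binomial(n, p) via log-space term summation."""
    if k <= 0:
        return 1.0
    logs = []
    lp, lq = log(p), log(1 - p)
    for x in range(k, n + 1):
        logs.append(
            lgamma(n + 1) - lgamma(x + 1) - lgamma(n - x + 1) + x * lp + (n - x) * lq
        )
    m = max(logs)
    if m == -inf:
        return 0.0
    return exp(m) * sum(exp(v - m) for v in logs)


def poisson_upper_tail_oracle(k: int, mu: float) -> float:
    """P(X >= k) for Poisson(mu) as 1 minus direct term summation."""
    if k <= 0:
        return 1.0
    term = exp(-mu)
    cdf = term
    for x in range(1, k):
        term *= mu / x
        cdf += term
    return 1.0 - cdf


def rank_sum_two_sided_oracle(x, y) -> float:
    """Two-sided rank-sum p by enumerating every assignment of the pooled
    ranks to the first group (ties not supported)."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle does not handle ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n = len(x), len(x) + len(y)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    mn = n1 * (len(y))
    count = total = 0
    for idx in combinations(range(n), n1):
        u = sum(i + 1 for i in idx) - n1 * (n1 + 1) / 2
        # symmetric two-sided: as or more extreme in either tail
        if min(u, mn - u) <= min(u_obs, mn - u_obs) + 1e-12:
            count += 1
        total += 1
    return count / total


def overlap_fraction_oracle(a, b) -> float:
    """Hand-rolled overlap fraction of interval a covered by b."""
    if a[0] != b[0]:
        return 0.0
    lo = max(a[1], b[1])
    hi = min(a[2], b[2])
    return max(0, hi - lo) / (a[2] - a[1])


def carrier_count_oracle(query, controls, fraction: float) -> int:
    """Quadratic double loop: distinct control samples with a same-type
    call overlapping more than ``fraction`` of the query."""
    carriers = set()
    for sample_id, chrom, start, end, cnv_type in controls:
        if cnv_type != query[4] or chrom != query[1]:
            continue
        ov = max(0, min(end, query[3]) - max(start, query[2]))
        if ov / (query[3] - query[2]) > fraction:
            carriers.add(sample_id)
    return len(carriers)
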