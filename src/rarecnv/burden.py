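"""Case-control CNV size-burden analysis.

Compares the size distribution of CNV calls between cases and controls via:

* exact 2x2 association (odds ratio + two-sided Fisher p);
* a size-threshold scan — for every threshold t, the 2x2 of calls larger
  than t versus at most t by group — selecting the minimal-p threshold; and
* a quintile analysis of the pooled size distribution with per-bin
  case/control fractions and Fisher tests.

The counting unit is the CNV call, not the individual; a per-sample mode
(samples carrying at least one call above t) is available via
``unit="sample"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RareCNVError


@dataclass
class ThresholdResult:
    threshold_kb: float
    a: int  # case calls > t
    b: int  # case calls <= t
    c: int  # control calls > t
    d: int  # control calls <= t
    odds_ratio: float
    p_value: float


@dataclass
class QuintileBin:
    lower_kb: float
    upper_kb: float
    case_fraction: float
    control_fraction: float
    p_value: float


@dataclass
class BurdenResult:
    """Output of the threshold scan and/or quintile analysis."""

    per_threshold: list[ThresholdResult] = field(default_factory=list)
    selected_threshold_kb: float | None = None
    selected_p: float | None = None
    significant: bool = False  # vs Bonferroni over the scanned grid
    quintiles: list[QuintileBin] = field(default_factory=list)
    quintile_borders_kb: list[float] = field(default_factory=list)

    def scan_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.threshold_kb, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value)
                for r in self.per_threshold
            ],
            columns=["threshold_kb", "a", "b", "c", "d", "odds_ratio", "p_value"],
        )

    def quintile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (q.lower_kb, q.upper_kb, q.case_fraction, q.control_fraction, q.p_value)
                for q in self.quintiles
            ],
            columns=["lower_kb", "upper_kb", "case_fraction", "control_fraction", "p_value"],
        )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for a 2x2 count table.

    The odds ratio is the sample odds ratio a*d / (b*c), reported as ``inf``
    when b*c = 0 (and ``nan`` for the degenerate 0/0 case); the p-value is
    the sum of hypergeometric probabilities of tables at most as probable as
    the observed one, at fixed margins.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise RareCNVError("contingency counts must be non-negative")
    if a + b + c + d == 0:
        raise RareCNVError("all-zero contingency table is undefined")
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return odds, float(min(p, 1.0))


def default_threshold_grid(
    lo_kb: float = 50.0, hi_kb: float = 1000.0, n: int = 200
) -> np.ndarray:
    """Log-spaced threshold grid (kb)."""
    return np.geomspace(lo_kb, hi_kb, n)


def _sizes(calls, unit: str) -> np.ndarray:
    if isinstance(calls, pd.DataFrame):
        if unit == "sample":
            # per-sample maximum call size: a sample exceeds t iff max > t
            return calls.groupby("sample_id")["size_kb"].max().to_numpy(float)
        return calls["size_kb"].to_numpy(float)
    return np.asarray(calls, dtype=float)


def threshold_scan(
    case_calls,
    control_calls,
    thresholds: np.ndarray | None = None,
    alpha: float = 0.05,
    unit: str = "call",
) -> BurdenResult:
    """Scan size thresholds and select the minimal-p threshold.

    ``case_calls``/``control_calls`` are call tables or plain size vectors
    (kb). Ties in p resolve to the smaller threshold; ``significant`` flags
    the selected p against ``alpha`` Bonferroni-corrected for the grid size.
    """
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise RareCNVError("threshold grid must be non-empty")
    case_sizes = np.sort(_sizes(case_calls, unit))
    control_sizes = np.sort(_sizes(control_calls, unit))
    if case_sizes.size == 0 or control_sizes.size == 0:
        raise RareCNVError("both groups must contain at least one call")

    n1, n0 = case_sizes.size, control_sizes.size
    a = n1 - np.searchsorted(case_sizes, thresholds, side="right")
    c = n0 - np.searchsorted(control_sizes, thresholds, side="right")
    result = BurdenResult()
    best = (2.0, math.inf)
    for t, ai, ci in zip(thresholds, a, c):
        odds, p = fisher_exact_2x2([[int(ai), n1 - int(ai)], [int(ci), n0 - int(ci)]])
        result.per_threshold.append(
            ThresholdResult(float(t), int(ai), n1 - int(ai), int(ci), n0 - int(ci), odds, p)
        )
        if (p, t) < best:
            best = (p, float(t))
    result.selected_p, result.selected_threshold_kb = best
    result.significant = result.selected_p < alpha / thresholds.size
    return result


def quintile_analysis(case_calls, control_calls, unit: str = "call") -> BurdenResult:
    """Quintile burden of the pooled case+control size distribution.

    Borders are the 20/40/60/80/100th percentiles of the pooled sizes under
    linear interpolation between order statistics; per-bin fractions are
    computed within each group and tested with Fisher's exact test of
    in-bin versus out-of-bin counts.
    """
    case_sizes = _sizes(case_calls, unit)
    control_sizes = _sizes(control_calls, unit)
    pooled = np.concatenate([case_sizes, control_sizes])
    if pooled.size < 5:
        raise RareCNVError("pooled size vector must have length >= 5")
    borders = np.percentile(pooled, [20, 40, 60, 80, 100], method="linear")
    result = BurdenResult(quintile_borders_kb=[float(b) for b in borders])
    edges = np.concatenate([[-np.inf], borders])
    # right-closed bins: (edge_{i-1}, edge_i]
    case_bins = np.searchsorted(borders, case_sizes, side="left")
    control_bins = np.searchsorted(borders, control_sizes, side="left")
    case_bins = np.minimum(case_bins, 4)
    control_bins = np.minimum(control_bins, 4)
    n1, n0 = case_sizes.size, control_sizes.size
    for k in range(5):
        a = int((case_bins == k).sum())
        c = int((control_bins == k).sum())
        _, p = fisher_exact_2x2([[a, n1 - a], [c, n0 - c]])
        result.quintiles.append(
            QuintileBin(
                lower_kb=float(edges[k]) if np.isfinite(edges[k]) else float(pooled.min()),
                upper_kb=float(borders[k]),
                case_fraction=a / n1,
                control_fraction=c / n0,
                p_value=p,
            )
        )
    return result
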