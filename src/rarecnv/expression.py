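"""Dosage-concordant differential expression of genes inside candidate CNVs.

Each gene inside a candidate CNV is tested for differential expression
between carrier and non-carrier samples with a one-way ANOVA (for two
groups the F statistic is the square of the equal-variance t). Fold changes
are computed on anti-logged group means with the signed-reciprocal
convention: positive ratios for up-regulation, negative reciprocals for
down-regulation, so a halving reads as -2.0.

A gene is dosage-concordant when its test is significant, the direction
matches the CNV (up in a gain, down in a loss) and the fold change passes
the direction-specific minimum (+1.25 / -1.33). The cohort-level excess of
concordant genes is assessed against Binomial(n, 0.025) — a two-sided
per-gene alpha of 0.05 halved because only one direction counts — by a
stable upper-tail summation. Per-gene p-values are deliberately left
uncorrected; the global binomial test carries the multiplicity burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GAIN, LOSS
from .errors import RareCNVError


@dataclass
class ExpressionConfig:
    alpha_per_gene: float = 0.05
    fc_up_min: float = 1.25
    fc_down_min: float = -1.33
    null_concordance_p: float = 0.025

    def validate(self) -> None:
        if not 0.0 < self.alpha_per_gene < 1.0:
            raise RareCNVError("alpha_per_gene must be in (0, 1)")
        if self.fc_up_min <= 1.0:
            raise RareCNVError("fc_up_min must exceed 1")
        if self.fc_down_min >= -1.0:
            raise RareCNVError("fc_down_min must be below -1")
        if not 0.0 < self.null_concordance_p < 1.0:
            raise RareCNVError("null_concordance_p must be in (0, 1)")


@dataclass
class GeneExpressionResult:
    gene_id: str
    carrier_mean: float
    control_mean: float
    fold_change: float
    statistic: float
    p_value: float
    concordant: bool = False


def signed_fold_change(carrier_mean_log2: float, control_mean_log2: float) -> float:
    """Signed-reciprocal fold change from log2 group means."""
    diff = carrier_mean_log2 - control_mean_log2
    ratio = 2.0 ** abs(diff)
    return ratio if diff >= 0 else -ratio


def de_test(values, carrier_ids, control_ids) -> tuple[float, float]:
    """One-way ANOVA between carrier and non-carrier samples.

    ``values`` is a pandas Series indexed by sample id (or a mapping).
    Zero variance in both groups with equal means returns (0, 1) by
    convention.
    """
    values = pd.Series(values)
    x = values.loc[list(carrier_ids)].to_numpy(float)
    y = values.loc[list(control_ids)].to_numpy(float)
    if len(x) < 2 or len(y) < 2:
        raise RareCNVError("need at least 2 samples per group")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise RareCNVError("expression values must be finite")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, 1.0
        return np.inf, 0.0
    f, p = stats.f_oneway(x, y)
    return float(f), float(p)


def concordance_call(
    result: GeneExpressionResult, cnv_type: str, config: ExpressionConfig
) -> bool:
    """Significant AND direction matches the CNV AND |fold| passes the
    direction-specific minimum."""
    if result.p_value >= config.alpha_per_gene:
        return False
    if cnv_type == GAIN:
        return result.fold_change >= config.fc_up_min
    if cnv_type == LOSS:
        return result.fold_change <= config.fc_down_min
    raise RareCNVError(f"unknown cnv_type {cnv_type!r}")


def concordance_binomial(k_concordant: int, n_genes: int, null_p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, null_p) via stable summation."""
    if not 0 <= k_concordant <= n_genes:
        raise RareCNVError("need 0 <= k <= n")
    if not 0.0 < null_p < 1.0:
        raise RareCNVError("null_p must be in (0, 1)")
    if k_concordant == 0:
        return 1.0
    return float(stats.binom.sf(k_concordant - 1, n_genes, null_p))


def analyze_expression(
    matrix: pd.DataFrame,
    gene_cnv_map: dict[str, tuple[str, set[str]]],
    config: ExpressionConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Test every mapped gene and summarize cohort-level concordance.

    ``gene_cnv_map`` maps gene id -> (cnv_type, carrier sample ids); all
    other columns of ``matrix`` act as the comparison group for that gene.

    Returns the per-gene table and a summary dict with ``k_concordant``,
    ``n_genes``, ``fraction`` and the upper-tail ``binomial_p``.
    """
    config = config or ExpressionConfig()
    config.validate()
    all_samples = list(matrix.columns)
    rows = []
    for gene_id, (cnv_type, carriers) in gene_cnv_map.items():
        if gene_id not in matrix.index:
            raise RareCNVError(f"gene {gene_id!r} missing from the matrix")
        carriers = [s for s in all_samples if s in carriers]
        others = [s for s in all_samples if s not in set(carriers)]
        if len(carriers) < 2 or len(others) < 2:
            # untestable with fewer than two samples per group
            rows.append(
                (gene_id, cnv_type, np.nan, np.nan, np.nan, np.nan, np.nan, False)
            )
            continue
        f, p = de_test(matrix.loc[gene_id], carriers, others)
        cm = float(matrix.loc[gene_id, carriers].mean())
        om = float(matrix.loc[gene_id, others].mean())
        res = GeneExpressionResult(
            gene_id=gene_id,
            carrier_mean=cm,
            control_mean=om,
            fold_change=signed_fold_change(cm, om),
            statistic=f,
            p_value=p,
        )
        res.concordant = concordance_call(res, cnv_type, config)
        rows.append(
            (
                gene_id,
                cnv_type,
                res.carrier_mean,
                res.control_mean,
                res.fold_change,
                res.statistic,
                res.p_value,
                res.concordant,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "cnv_type",
            "carrier_mean",
            "control_mean",
            "fold_change",
            "statistic",
            "p_value",
            "concordant",
        ],
    )
    k = int(table["concordant"].sum()) if len(table) else 0
    n_tested = int(table["p_value"].notna().sum()) if len(table) else 0
    summary = {
        "k_concordant": k,
        "n_genes": len(table),
        "n_tested": n_tested,
        "fraction": (k / n_tested) if n_tested else 0.0,
        "null_concordance_p": config.null_concordance_p,
        "binomial_p": concordance_binomial(k, n_tested, config.null_concordance_p)
        if n_tested
        else 1.0,
    }
    return table, summary
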