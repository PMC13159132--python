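"""Threshold-based marker-gene and differential-expression callers.

Both callers run a classic pooled-variance two-sided Student's t-test per
gene on the log2-normalized values and then apply fixed thresholds; no
multiple-testing correction beyond the hard p-value cutoff is applied.

Cell-type-specific genes (one type vs all others) must satisfy, in order:

1. detected (> 0) in at least ``min_pct_in`` (20%) of the type's cells;
2. detection-rate difference ``pct_in - pct_out`` of at least
   ``min_pct_diff`` (10 percentage points) — switchable to the alternative
   reading "detected in >= 10% of all cells" via ``pct_rule``;
3. p < 1e-10;
4. log2 fold change (difference of group means on the log2 scale)
   >= ``min_log2fc`` (2);
5. the gene's overall mean across all cells above the median of all
   genes' overall means.

Condition DEGs (within one cell type, condition A vs B) must satisfy
p < 1e-10, |log2FC| >= 1 and the same overall-mean criterion; the
direction (up/down in condition B) is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io_prep import NormalizedMatrix

logger = logging.getLogger("permtyper")

PCT_RULE_DIFFERENCE = "difference"   # pct_in - pct_out >= threshold
PCT_RULE_OVERALL = "overall"         # pct of all cells >= threshold


@dataclass
class MarkerParams:
    """Thresholds of the 5-criterion cell-type-specific gene caller."""

    min_pct_in: float = 0.20
    min_pct_diff: float = 0.10
    max_p: float = 1e-10
    min_log2fc: float = 2.0
    pct_rule: str = PCT_RULE_DIFFERENCE


@dataclass
class DEGParams:
    """Thresholds of the 3-criterion condition-DEG caller."""

    max_p: float = 1e-10
    min_abs_log2fc: float = 1.0


def two_sided_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample two-sided Student's t-test.

    Degenerate zero-pooled-variance inputs: equal means give p = 1,
    unequal means give the p = 0 sentinel (an infinitely confident
    difference between two constants).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    stat, p = _ttest_columns(a[:, None], b[:, None])
    return float(stat[0]), float(p[0])


def _ttest_columns(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise pooled-variance t-test with degenerate-case sentinels."""
    stat, p = scipy.stats.ttest_ind(A, B, axis=0, equal_var=True)
    stat = np.atleast_1d(np.asarray(stat, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        diff = A.mean(axis=0) - B.mean(axis=0)
        equal = np.abs(diff) == 0
        p[degenerate & equal] = 1.0
        stat[degenerate & equal] = 0.0
        p[degenerate & ~equal] = 0.0
        stat[degenerate & ~equal] = np.sign(diff[degenerate & ~equal]) * np.inf
    return stat, p


def _records(
    genes: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    mean_overall: np.ndarray,
) -> pd.DataFrame:
    stat, p = _ttest_columns(A, B)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "statistic": stat,
            "p_value": p,
            "log2fc": A.mean(axis=0) - B.mean(axis=0),
            "pct_in": (A > 0).mean(axis=0),
            "pct_out": (B > 0).mean(axis=0),
            "mean_in": A.mean(axis=0),
            "mean_out": B.mean(axis=0),
            "mean_overall": mean_overall,
        }
    )


def specific_genes(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    target_type: str,
    params: MarkerParams | None = None,
) -> pd.DataFrame:
    """Evaluate the 5 marker criteria for every gene, target type vs rest.

    Returns one record per gene with per-criterion boolean flags
    ``crit1_pct_in`` ... ``crit5_mean`` and ``passes`` (their AND).
    """
    params = params or MarkerParams()
    labels = np.asarray(labels, dtype=object)
    if len(labels) != norm.n_cells:
        raise ValueError("one label per cell required")
    in_mask = labels == target_type
    if in_mask.sum() == 0:
        raise ValueError(f"unknown or absent label {target_type!r}")
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError("both the target type and its complement need >= 2 cells")

    X = norm.values
    rec = _records(norm.genes, X[in_mask], X[~in_mask], X.mean(axis=0))
    rec["crit1_pct_in"] = rec["pct_in"] >= params.min_pct_in
    if params.pct_rule == PCT_RULE_DIFFERENCE:
        rec["crit2_pct_rule"] = (rec["pct_in"] - rec["pct_out"]) >= params.min_pct_diff
    elif params.pct_rule == PCT_RULE_OVERALL:
        pct_all = (X > 0).mean(axis=0)
        rec["crit2_pct_rule"] = pct_all >= params.min_pct_diff
    else:
        raise ValueError(f"unknown pct_rule {params.pct_rule!r}")
    rec["crit3_p"] = rec["p_value"] < params.max_p
    rec["crit4_log2fc"] = rec["log2fc"] >= params.min_log2fc
    rec["crit5_mean"] = rec["mean_overall"] > rec["mean_overall"].median()
    flags = ["crit1_pct_in", "crit2_pct_rule", "crit3_p", "crit4_log2fc", "crit5_mean"]
    rec["passes"] = rec[flags].all(axis=1)
    logger.info(
        "specific_genes(%s): %d/%d genes pass", target_type,
        int(rec["passes"].sum()), len(rec),
    )
    return rec


def condition_degs(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    cell_type: str,
    condition_a: str,
    condition_b: str,
    params: DEGParams | None = None,
) -> pd.DataFrame:
    """Condition DEGs within one cell type (3 criteria).

    ``log2fc`` is mean(B) - mean(A) on the log2 scale so that
    ``direction`` reads as up/down in ``condition_b``; the pass criterion
    uses |log2fc|.  The overall-mean criterion is evaluated over the cell
    type's cells (both conditions pooled).
    """
    params = params or DEGParams()
    labels = np.asarray(labels, dtype=object)
    cond = np.asarray(norm.condition, dtype=object)
    type_mask = labels == cell_type
    if type_mask.sum() == 0:
        raise ValueError(f"unknown or absent label {cell_type!r}")
    a_mask = type_mask & (cond == condition_a)
    b_mask = type_mask & (cond == condition_b)
    for name, mask in ((condition_a, a_mask), (condition_b, b_mask)):
        if mask.sum() < 2:
            raise ValueError(
                f"condition {name!r} has {int(mask.sum())} cells of type "
                f"{cell_type!r}; >= 2 required"
            )
    X = norm.values
    pooled_mean = X[type_mask].mean(axis=0)
    rec = _records(norm.genes, X[b_mask], X[a_mask], pooled_mean)
    rec = rec.rename(columns={"pct_in": "pct_b", "pct_out": "pct_a",
                              "mean_in": "mean_b", "mean_out": "mean_a"})
    rec["crit1_p"] = rec["p_value"] < params.max_p
    rec["crit2_log2fc"] = rec["log2fc"].abs() >= params.min_abs_log2fc
    rec["crit3_mean"] = rec["mean_overall"] > rec["mean_overall"].median()
    rec["passes"] = rec[["crit1_p", "crit2_log2fc", "crit3_mean"]].all(axis=1)
    rec["direction"] = np.where(rec["log2fc"] > 0, "up",
                                np.where(rec["log2fc"] < 0, "down", "none"))
    logger.info(
        "condition_degs(%s, %s vs %s): %d/%d genes pass", cell_type,
        condition_a, condition_b, int(rec["passes"].sum()), len(rec),
    )
    return rec
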