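"""Per-cell attributes: expression inequality, QC fractions and diversity.

The attributes summarize each cell's transcriptome shape:

* **Gini index** of the expressed genes' values — 0 when every expressed
  gene has the same level, approaching 1 when expression is concentrated
  in one gene.  Computed as
  ``G = (1/n) * (n + 1 - 2 * sum_i (n + 1 - i) y_i / sum_i y_i)``
  over the ascending-sorted positive values ``y_1 <= ... <= y_n``
  (algebraically identical to the mean-absolute-difference form
  ``sum_ij |y_i - y_j| / (2 n^2 ybar)``).
* **chrM% / chrX% / chrY%** — percentages of the cell's raw UMIs mapping
  to mitochondrial, X- and Y-class genes.
* **UMI(log10)** and **expressed-gene count**.
* **diversity** — 1 minus the mean Pearson correlation between the cell
  and every other cell of the same assigned type; 0 for a clone-like
  type, about 1 for unrelated profiles, up to 2 for anti-correlation.

Undefined quantities (no expressed genes, singleton types, zero-variance
profiles) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io_prep import CountMatrix, NormalizedMatrix

logger = logging.getLogger("permtyper")

ATTRIBUTE_NAMES = ("gini", "chrM_pct", "chrX_pct", "chrY_pct",
                   "umi_log10", "n_genes", "diversity")


def gini_index(expr: np.ndarray) -> float:
    """Gini index of a vector of non-negative expression values.

    Callers computing the per-cell attribute restrict the input to the
    expressed genes (> 0) first; the function itself tolerates zeros so
    that closed forms like the one-hot vector evaluate directly.  The
    ascending sort is applied internally.  Returns NaN for an empty or
    all-zero vector.  The result lies in ``[0, (n-1)/n]``.
    """
    y = np.sort(np.asarray(expr, dtype=float))
    n = len(y)
    if n == 0 or y.sum() == 0:
        return float("nan")
    if y[0] < 0:
        raise ValueError("gini_index expects non-negative values")
    i = np.arange(1, n + 1)
    return float((n + 1 - 2.0 * np.sum((n + 1 - i) * y) / y.sum()) / n)


def chrom_fractions(
    cell_counts: np.ndarray, chrom_class: np.ndarray
) -> tuple[float, float, float]:
    """(chrM%, chrX%, chrY%) of a cell's raw UMIs; NaN triple on zero total."""
    c = np.asarray(cell_counts, dtype=float)
    total = c.sum()
    if total <= 0:
        return (float("nan"),) * 3
    cls = np.asarray(chrom_class, dtype=object)
    return tuple(100.0 * c[cls == k].sum() / total for k in ("MT", "X", "Y"))


def diversity(cells_of_type: np.ndarray) -> np.ndarray:
    """Per-cell 1 - mean Pearson r against the other same-type cells.

    ``cells_of_type`` is a (m, n_genes) normalized-expression block for one
    assigned type.  Zero-variance cells yield undefined pairwise
    correlations; those pairs are excluded from the means (and the
    zero-variance cell itself gets NaN).  m = 1 returns NaN.
    """
    X = np.asarray(cells_of_type, dtype=float)
    m = X.shape[0]
    if m < 2:
        return np.full(m, np.nan)
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance cell(s): pairwise "
            "correlations undefined and excluded from diversity means",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    np.fill_diagonal(R, np.nan)
    R[degenerate, :] = np.nan
    R[:, degenerate] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return 1.0 - np.nanmean(R, axis=1)


def compute_attributes(
    raw: CountMatrix,
    norm: NormalizedMatrix,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Attribute table, one row per cell.

    ``raw`` supplies UMI totals and chromosome-class fractions, ``norm``
    the expression values for Gini and diversity.  ``labels`` (optional)
    enables the per-type diversity column; cells of reserved or singleton
    labels get NaN diversity.
    """
    if raw.n_cells != norm.n_cells or raw.n_genes != norm.n_genes:
        raise ValueError("raw and normalized matrices must be aligned")
    dense_raw = raw.counts.toarray().astype(float)
    totals = dense_raw.sum(axis=1)
    cls = raw.chrom_class
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = {
            k: np.where(totals > 0, 100.0 * dense_raw[:, cls == k].sum(axis=1) / totals, np.nan)
            for k in ("MT", "X", "Y")
        }
    X = norm.values
    gini = np.array([
        gini_index(row[row > 0]) if (row > 0).any() else np.nan for row in X
    ])
    out = pd.DataFrame(
        {
            "barcode": raw.barcodes,
            "gini": gini,
            "chrM_pct": pct["MT"],
            "chrX_pct": pct["X"],
            "chrY_pct": pct["Y"],
            "umi_log10": np.where(totals > 0, np.log10(np.where(totals > 0, totals, 1.0)), np.nan),
            "n_genes": (dense_raw > 0).sum(axis=1),
        }
    )
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        div = np.full(raw.n_cells, np.nan)
        for t in pd.unique(labels):
            idx = np.where(labels == t)[0]
            if len(idx) >= 2:
                div[idx] = diversity(X[idx])
        out["diversity"] = div
        out["label"] = labels
    return out


def attribute_gene_correlation(
    norm: NormalizedMatrix,
    attributes: pd.DataFrame,
    gene_id: str,
    attribute: str,
    labels: np.ndarray | None = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of a gene's expression with a per-cell attribute.

    Restricted to cells expressing the gene (> 0), reported pooled and,
    when ``labels`` is given, per cell-type stratum.  Strata with fewer
    than ``min_cells`` expressing cells are skipped with a warning; a
    constant attribute or constant expression yields NaN.

    Returns columns (gene_id, attribute, stratum, pcc, n_cells).
    """
    if attribute not in attributes.columns:
        raise KeyError(f"unknown attribute {attribute!r}")
    gcol = norm.gene_index([gene_id])[0]
    expr = norm.values[:, gcol]
    attr = attributes[attribute].to_numpy(dtype=float)

    def pcc(mask: np.ndarray) -> tuple[float, int]:
        x, y = expr[mask], attr[mask]
        ok = np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < min_cells:
            return float("nan"), len(x)
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), len(x)
        return float(np.corrcoef(x, y)[0, 1]), len(x)

    expressing = expr > 0
    rows = []
    r, n = pcc(expressing)
    rows.append({"gene_id": gene_id, "attribute": attribute,
                 "stratum": "pooled", "pcc": r, "n_cells": n})
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        for t in pd.unique(labels):
            mask = expressing & (labels == t)
            if mask.sum() < min_cells:
                warnings.warn(
                    f"stratum {t!r}: only {int(mask.sum())} expressing cells, skipped",
                    stacklevel=2,
                )
                continue
            r, n = pcc(mask)
            rows.append({"gene_id": gene_id, "attribute": attribute,
                         "stratum": t, "pcc": r, "n_cells": n})
    return pd.DataFrame(rows)
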