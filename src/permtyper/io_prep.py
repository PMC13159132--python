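"""Reading, filtering and normalizing 10x-style UMI count matrices.

The on-disk bundle is the familiar triplet of MatrixMarket matrix plus
``barcodes.tsv`` / ``features.tsv`` sidecars, extended with a gene-annotation
table that assigns every gene a chromosome class (mitochondrial, X, Y or
autosomal).  Filtering and normalization follow the droplet scRNA-seq
conventions used throughout this package:

* cells with at least ``min_genes_per_cell`` detected genes are retained
  (detected means UMI count > 0);
* genes detected in strictly more than ``min_cells_per_gene`` cells are
  retained, evaluated after the cell filter;
* expression is scaled per cell by ``total / median(total)`` (median-ratio
  scaling) and transformed with ``log2(x + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("permtyper")

CHROM_CLASSES = ("MT", "X", "Y", "AUTO")

RAW = "raw"
NORMALIZED = "normalized"


class FormatError(ValueError):
    """Malformed on-disk bundle (dimension mismatch, bad MTX, ...)."""


class ValidationError(ValueError):
    """Inconsistent matrix metadata (duplicates, missing annotation, ...)."""


@dataclass
class CountMatrix:
    """Sparse cells x genes UMI count matrix with per-cell / per-gene metadata.

    Parameters
    ----------
    counts
        ``(n_cells, n_genes)`` sparse CSR matrix of non-negative integers
        (UMI units) when ``layer == "raw"``.
    barcodes
        Unique cell identifiers, one per row.
    genes
        Unique gene identifiers, one per column.
    chrom_class
        Per-gene chromosome class, each in :data:`CHROM_CLASSES`.
    condition
        Per-cell condition label (e.g. ``"normoxia"`` / ``"hypoxia"``).
    gene_symbols
        Optional per-gene display symbols (non-unique allowed).
    layer
        ``"raw"`` or ``"normalized"``.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    genes: np.ndarray
    chrom_class: np.ndarray
    condition: np.ndarray
    gene_symbols: np.ndarray | None = None
    layer: str = RAW

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        self.chrom_class = np.asarray(self.chrom_class, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.gene_symbols is not None:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for a {n_cells}-row matrix"
            )
        if len(self.genes) != n_genes:
            raise FormatError(
                f"{len(self.genes)} gene ids for a {n_genes}-column matrix"
            )
        if len(self.chrom_class) != n_genes:
            raise FormatError("chrom_class length does not match gene count")
        if len(self.condition) != n_cells:
            raise FormatError("condition length does not match cell count")
        if len(set(self.barcodes)) != n_cells:
            raise ValidationError("duplicate cell barcodes")
        if len(set(self.genes)) != n_genes:
            raise ValidationError("duplicate gene identifiers")
        bad = sorted(set(self.chrom_class) - set(CHROM_CLASSES))
        if bad:
            raise ValidationError(f"unknown chromosome classes: {bad}")
        data = self.counts.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise ValidationError("counts must be finite and non-negative")
        if self.layer == RAW and data.size and np.any(data != np.round(data)):
            raise ValidationError("raw-layer matrix contains non-integers")

    # -- conveniences ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_ids) -> np.ndarray:
        """Column indices for ``gene_ids``; raises KeyError on misses."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        cm = np.arange(self.n_cells) if cell_mask is None else np.where(cell_mask)[0]
        gm = np.arange(self.n_genes) if gene_mask is None else np.where(gene_mask)[0]
        return CountMatrix(
            counts=self.counts[cm][:, gm],
            barcodes=self.barcodes[cm],
            genes=self.genes[gm],
            chrom_class=self.chrom_class[gm],
            condition=self.condition[cm],
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols[gm],
            layer=self.layer,
        )


@dataclass
class NormalizedMatrix:
    """log2-transformed median-ratio-scaled expression.

    ``values[c, g] = log2(counts[c, g] / scale_factors[c] + 1)`` with
    ``scale_factors[c] = total_c / median_total``, so that every cell's
    scaled (pre-log) total equals ``median_total``.
    """

    values: np.ndarray  # dense (n_cells, n_genes), float64
    scale_factors: np.ndarray
    median_total: float
    barcodes: np.ndarray
    genes: np.ndarray
    chrom_class: np.ndarray
    condition: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)


@dataclass
class FilterReport:
    """Bookkeeping emitted by :func:`filter_cells_genes`."""

    n_cells_in: int
    n_cells_kept: int
    n_genes_in: int
    n_genes_kept: int
    min_genes_per_cell: int
    min_cells_per_gene: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["cells", "genes"],
                "n_in": [self.n_cells_in, self.n_genes_in],
                "n_kept": [self.n_cells_kept, self.n_genes_kept],
                "n_removed": [
                    self.n_cells_in - self.n_cells_kept,
                    self.n_genes_in - self.n_genes_kept,
                ],
                "threshold": [self.min_genes_per_cell, self.min_cells_per_gene],
            }
        )


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def read_matrix(
    mtx_path,
    barcodes_path,
    features_path,
    annot_path,
    *,
    orientation: str = "genes_by_cells",
    condition_path=None,
    default_condition: str = "unknown",
) -> CountMatrix:
    """Read a 10x-style MTX bundle into a :class:`CountMatrix`.

    ``orientation`` names the on-disk layout: 10x writes genes as rows
    (``"genes_by_cells"``, the default); ``"cells_by_genes"`` accepts the
    transposed dialect.  The returned matrix is always cells x genes.

    ``features_path`` is a headerless TSV of 2-3 columns (id, symbol,
    [type]); joins against the annotation use column 1 (the id), because
    symbols are not unique.  ``annot_path`` is a TSV mapping gene id to
    chromosome class; a missing class for any gene is an error that names
    the offending genes.
    """
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    if orientation == "genes_by_cells":
        mat = sp.csr_matrix(mat.T)
    elif orientation != "cells_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")

    barcodes = _read_single_column(barcodes_path)
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    if features.shape[1] < 1:
        raise FormatError(f"empty features table {features_path}")
    gene_ids = features.iloc[:, 0].to_numpy(dtype=object)
    symbols = (
        features.iloc[:, 1].to_numpy(dtype=object)
        if features.shape[1] >= 2
        else None
    )

    n_cells, n_genes = mat.shape
    if len(barcodes) != n_cells:
        raise FormatError(
            f"barcodes file has {len(barcodes)} rows but the matrix has "
            f"{n_cells} cells (orientation={orientation})"
        )
    if len(gene_ids) != n_genes:
        raise FormatError(
            f"features file has {len(gene_ids)} rows but the matrix has "
            f"{n_genes} genes (orientation={orientation})"
        )

    annot = pd.read_csv(annot_path, sep="\t", header=None, dtype=str)
    if annot.shape[1] < 2:
        raise FormatError("gene-annotation table needs (gene_id, chrom_class)")
    # tolerate an optional header row
    if str(annot.iloc[0, 1]).upper() not in CHROM_CLASSES:
        annot = annot.iloc[1:]
    class_of = dict(zip(annot.iloc[:, 0], annot.iloc[:, 1].str.upper()))
    missing = [g for g in gene_ids if g not in class_of]
    if missing:
        raise ValidationError(
            f"{len(missing)} genes lack a chromosome class, e.g. {missing[:10]}"
        )
    chrom_class = np.array([class_of[g] for g in gene_ids], dtype=object)

    if condition_path is not None:
        condition = _read_single_column(condition_path)
        if len(condition) != n_cells:
            raise FormatError("condition file row count does not match cells")
    else:
        condition = np.full(n_cells, default_condition, dtype=object)

    return CountMatrix(
        counts=mat,
        barcodes=barcodes,
        genes=gene_ids,
        chrom_class=chrom_class,
        condition=condition,
        gene_symbols=symbols,
    )


def write_matrix(m: CountMatrix, out_dir, *, orientation: str = "genes_by_cells") -> dict:
    """Write the MTX/TSV bundle read back by :func:`read_matrix`.

    Returns the mapping of logical names to paths.  Triplets are written in
    coordinate integer format for a raw layer; the round trip preserves the
    triplet multiset exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = m.counts.T.tocoo() if orientation == "genes_by_cells" else m.counts.tocoo()
    field = "integer" if m.layer == RAW else "real"
    paths = {
        "mtx": out / "matrix.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "annot": out / "gene_annotation.tsv",
        "condition": out / "conditions.tsv",
    }
    scipy.io.mmwrite(str(paths["mtx"]), mat, field=field)
    pd.Series(m.barcodes).to_csv(paths["barcodes"], index=False, header=False)
    feats = pd.DataFrame({"id": m.genes})
    feats["symbol"] = m.genes if m.gene_symbols is None else m.gene_symbols
    feats.to_csv(paths["features"], sep="\t", index=False, header=False)
    pd.DataFrame({"gene_id": m.genes, "chrom_class": m.chrom_class}).to_csv(
        paths["annot"], sep="\t", index=False, header=False
    )
    pd.Series(m.condition).to_csv(paths["condition"], index=False, header=False)
    return paths


def _read_single_column(path) -> np.ndarray:
    values = pd.read_csv(path, sep="\t", header=None, dtype=str).iloc[:, 0]
    return values.to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def filter_cells_genes(
    m: CountMatrix,
    min_genes_per_cell: int = 500,
    min_cells_per_gene: int = 10,
) -> tuple[CountMatrix, FilterReport]:
    """Apply the cell filter, then the gene filter, one pass each.

    Cells need at least ``min_genes_per_cell`` genes with count > 0
    (inclusive), evaluated on the input matrix.  Genes need count > 0 in
    strictly more than ``min_cells_per_gene`` of the retained cells.
    """
    if m.layer != RAW:
        raise ValueError("filtering operates on the raw layer")
    binarized = m.counts.copy()
    binarized.data = (binarized.data > 0).astype(np.int64)
    genes_per_cell = np.asarray(binarized.sum(axis=1)).ravel()
    cell_mask = genes_per_cell >= min_genes_per_cell
    if not cell_mask.any():
        raise ValueError(
            "empty after filtering: no cell reaches "
            f"{min_genes_per_cell} detected genes"
        )
    cells_per_gene = np.asarray(binarized[np.where(cell_mask)[0]].sum(axis=0)).ravel()
    gene_mask = cells_per_gene > min_cells_per_gene
    if not gene_mask.any():
        raise ValueError(
            "empty after filtering: no gene detected in more than "
            f"{min_cells_per_gene} cells"
        )
    report = FilterReport(
        n_cells_in=m.n_cells,
        n_cells_kept=int(cell_mask.sum()),
        n_genes_in=m.n_genes,
        n_genes_kept=int(gene_mask.sum()),
        min_genes_per_cell=min_genes_per_cell,
        min_cells_per_gene=min_cells_per_gene,
    )
    logger.info(
        "filter: kept %d/%d cells, %d/%d genes",
        report.n_cells_kept, report.n_cells_in,
        report.n_genes_kept, report.n_genes_in,
    )
    return m.subset(cell_mask, gene_mask), report


def normalize(m: CountMatrix) -> NormalizedMatrix:
    """Median-ratio scale each cell, then transform with log2(x + 1).

    The per-cell scale factor is ``total_c / median(totals)`` (standard
    midpoint median), so after scaling every cell's pre-log total equals
    the median raw total.
    """
    if m.layer != RAW:
        raise ValueError("normalize expects a raw-layer matrix")
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    if np.any(totals <= 0):
        raise ValueError(
            "cells with zero total counts present; run filter_cells_genes first"
        )
    median_total = float(np.median(totals))
    scale = totals / median_total
    dense = m.counts.toarray().astype(float)
    values = np.log2(dense / scale[:, None] + 1.0)
    return NormalizedMatrix(
        values=values,
        scale_factors=scale,
        median_total=median_total,
        barcodes=m.barcodes,
        genes=m.genes,
        chrom_class=m.chrom_class,
        condition=m.condition,
    )
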