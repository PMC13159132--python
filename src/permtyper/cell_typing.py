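"""Permutation-based marker cell typing with enrichment score and empirical FDR.

For every cell and every candidate cell type, the mean normalized expression
of the type's marker genes (the observed signal) is compared against a
permutation background: the means of ``n_perm`` random gene sets of the same
size drawn without replacement from the cell's own expression vector.

* enrichment score  ES  = observed mean / mean of the background;
* empirical FDR         = fraction of background means strictly greater
  than the observed mean (so FDR is always a multiple of ``1 / n_perm``);
* a type is a candidate for a cell when more than ``min_marker_fraction``
  of its markers are detected, FDR < ``max_fdr`` and ES >= ``min_es``.

Among candidates the type with the highest ES wins, unless its ES falls
below the ES of a disjoint random negative-control gene set (default 500
genes, drawn once per run and shared by all cells), in which case the cell
is labelled ``random_others``.  A cell with no candidate is labelled
``no_type_match``.  A post-hoc consistency filter flags cells that sit away
from their type's main cluster in a 2-D embedding.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import NormalizedMatrix

logger = logging.getLogger("permtyper")

LABEL_RANDOM_OTHERS = "random_others"
LABEL_NO_MATCH = "no_type_match"
RESERVED_LABELS = (LABEL_RANDOM_OTHERS, LABEL_NO_MATCH)

#: Lineage-specific validation markers for the five major testis cell types
#: (spermatogenesis lineage plus Sertoli cells); bundled for illustration
#: and smoke tests, not as a production annotation panel.
VALIDATION_MARKERS: dict[str, tuple[str, ...]] = {
    "spermatogonia": ("Ina", "Jmjd1c", "Brd4", "Rest", "Ezh1", "Tet3", "Rad21"),
    "spermatocytes": ("Jdp2", "Fbxo43", "Dyx1c1", "Piwil1", "Tbpl1", "Prss44"),
    "round_spermatids": ("Mpzl3", "Svep1", "Slc4a4", "Wnt7a"),
    "elongating_spermatids": ("Prm2", "Dnmt3l"),
    "sertoli": ("Dancr", "Sox8", "Sox9"),
}


@dataclass
class TypingThresholds:
    """Assignment criteria: marker detection, empirical FDR and ES cutoffs."""

    min_marker_fraction: float = 0.20
    max_fdr: float = 0.001
    min_es: float = 5.0
    n_perm: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.min_marker_fraction < 1:
            raise ValueError("min_marker_fraction must be in (0, 1)")
        if not 0 < self.max_fdr <= 1:
            raise ValueError("max_fdr must be in (0, 1]")
        if self.min_es <= 0:
            raise ValueError("min_es must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class MarkerPanel:
    """Named cell types with marker gene lists and a negative-control set.

    ``negative_control`` must be disjoint from every marker list; it plays
    the role of a random pseudo-type whose ES flags cells that score high
    on any gene set (``random_others``).
    """

    types: list[str]
    markers: dict[str, list[str]]
    negative_control: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.markers) != list(self.types):
            self.types = list(self.markers)
        all_markers = set().union(*map(set, self.markers.values())) if self.markers else set()
        overlap = all_markers & set(self.negative_control)
        if overlap:
            raise ValueError(
                f"negative control overlaps marker lists: {sorted(overlap)[:10]}"
            )
        for t in self.types:
            if t in RESERVED_LABELS:
                raise ValueError(f"{t!r} is a reserved label")
            if not self.markers[t]:
                raise ValueError(f"cell type {t!r} has an empty marker list")

    @property
    def all_marker_genes(self) -> set[str]:
        return set().union(*map(set, self.markers.values()))

    def resolve(self, genes: np.ndarray) -> "MarkerPanel":
        """Drop gene ids absent from ``genes``, warning per type.

        A type whose entire marker list is unresolvable raises, naming the
        type.
        """
        present = set(genes)
        resolved: dict[str, list[str]] = {}
        for t in self.types:
            kept = [g for g in self.markers[t] if g in present]
            dropped = len(self.markers[t]) - len(kept)
            if dropped:
                warnings.warn(
                    f"type {t!r}: {dropped} marker gene(s) not in matrix, dropped",
                    stacklevel=2,
                )
            if not kept:
                raise ValueError(
                    f"no marker genes of type {t!r} resolvable against the matrix"
                )
            resolved[t] = kept
        control = [g for g in self.negative_control if g in present]
        if len(control) < len(self.negative_control):
            warnings.warn(
                f"{len(self.negative_control) - len(control)} negative-control "
                "gene(s) not in matrix, dropped",
                stacklevel=2,
            )
        return MarkerPanel(list(self.types), resolved, control)

    # -- serialization ---------------------------------------------------
    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        """Read a two-column (cell_type, gene_id) table; the reserved type
        name ``negative_control`` populates the control set."""
        df = pd.read_csv(path, sep="\t", header=None, names=["cell_type", "gene_id"],
                         dtype=str, comment="#")
        markers: dict[str, list[str]] = {}
        control: list[str] = []
        for t, sub in df.groupby("cell_type", sort=False):
            if t == "negative_control":
                control = sub["gene_id"].tolist()
            else:
                markers[t] = sub["gene_id"].tolist()
        return cls(list(markers), markers, control)

    @classmethod
    def from_json(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            obj = json.load(fh)
        markers = {t: list(g) for t, g in obj["markers"].items()}
        return cls(list(markers), markers, list(obj.get("negative_control", [])))

    def to_tsv(self, path) -> None:
        rows = [(t, g) for t in self.types for g in self.markers[t]]
        rows += [("negative_control", g) for g in self.negative_control]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def draw_negative_control(
    genes: np.ndarray,
    marker_genes: set[str],
    size: int = 500,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Draw ``size`` genes disjoint from all marker lists, once per run."""
    rng = np.random.default_rng(rng)
    pool = np.array([g for g in genes if g not in marker_genes], dtype=object)
    if len(pool) < size:
        raise ValueError(
            f"only {len(pool)} non-marker genes available for a "
            f"{size}-gene negative control"
        )
    return list(rng.choice(pool, size=size, replace=False))


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def marker_fraction(cell_expr: np.ndarray, marker_idx: np.ndarray) -> float:
    """Fraction of marker genes with expression > 0 in the cell."""
    if len(marker_idx) == 0:
        raise ValueError("empty resolved marker set")
    return float(np.mean(cell_expr[marker_idx] > 0))


def permutation_background(
    cell_expr: np.ndarray,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Means of ``n_perm`` k-subsets of the cell's expression values.

    Each subset is drawn uniformly without replacement from the full
    vector, emulating a shuffle of the expression values onto the marker
    positions.
    """
    n_genes = len(cell_expr)
    if k > n_genes:
        raise ValueError(f"marker set size {k} exceeds gene count {n_genes}")
    idx = _subset_indices(n_genes, k, n_perm, rng)
    return cell_expr[idx].mean(axis=1)


def _subset_indices(n_genes: int, k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, k) gene indices, each row sampled without replacement."""
    keys = rng.random((n_perm, n_genes))
    if k < n_genes:
        return np.argpartition(keys, k, axis=1)[:, :k]
    return np.tile(np.arange(n_genes), (n_perm, 1))


def enrichment_score(observed_mean: float, background: np.ndarray) -> float:
    """Observed marker mean over the background mean.

    Degenerate cases: a zero background with a positive signal yields
    ``+inf`` (criteria-passing); a zero signal yields 0.
    """
    bg = float(np.mean(background))
    if bg == 0.0:
        return float("inf") if observed_mean > 0 else 0.0
    return float(observed_mean) / bg


def empirical_fdr(observed_mean: float, background: np.ndarray) -> float:
    """Fraction of background values strictly greater than the signal."""
    return float(np.mean(background > observed_mean))


# ---------------------------------------------------------------------------
# Per-cell assignment
# ---------------------------------------------------------------------------

@dataclass
class TypingResult:
    """Typing output: one row per cell, per-type score columns.

    ``table`` columns: ``barcode``, per type ``es_<t>`` / ``fdr_<t>`` /
    ``frac_<t>`` / ``mean_<t>``, ``control_es``, ``label``,
    ``flagged_inconsistent``.
    """

    table: pd.DataFrame
    thresholds: TypingThresholds
    panel: MarkerPanel

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def assign_cell_type(
    cell_expr: np.ndarray,
    genes: np.ndarray,
    panel: MarkerPanel,
    thresholds: TypingThresholds | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Type a single cell; reference-path implementation of the full rule.

    Draws a fresh permutation background per marker-set size from ``rng``.
    The batch path (:func:`type_cells`) shares subset draws across cells
    for speed; per-cell statistics are identical in distribution.
    """
    thresholds = thresholds or TypingThresholds()
    rng = np.random.default_rng(rng)
    cell_expr = np.asarray(cell_expr, dtype=float)
    bg_cache: dict[int, np.ndarray] = {}

    def score(idx: np.ndarray) -> tuple[float, float, float, float]:
        k = len(idx)
        if k not in bg_cache:
            bg_cache[k] = permutation_background(cell_expr, k, thresholds.n_perm, rng)
        obs = float(cell_expr[idx].mean())
        bg = bg_cache[k]
        return obs, enrichment_score(obs, bg), empirical_fdr(obs, bg), float(
            np.mean(cell_expr[idx] > 0)
        )

    lookup = {g: i for i, g in enumerate(genes)}
    row: dict = {}
    candidates: list[tuple[float, str]] = []
    for t in panel.types:
        idx = np.array([lookup[g] for g in panel.markers[t]], dtype=int)
        obs, es, fdr, frac = score(idx)
        row[f"es_{t}"], row[f"fdr_{t}"], row[f"frac_{t}"], row[f"mean_{t}"] = es, fdr, frac, obs
        if (
            frac > thresholds.min_marker_fraction
            and fdr < thresholds.max_fdr
            and es >= thresholds.min_es
        ):
            candidates.append((es, t))

    if panel.negative_control:
        ctrl_idx = np.array([lookup[g] for g in panel.negative_control], dtype=int)
        _, control_es, _, _ = score(ctrl_idx)
    else:
        control_es = float("nan")
    row["control_es"] = control_es

    if not candidates:
        row["label"] = LABEL_NO_MATCH
    else:
        best_es, best_type = max(candidates)
        if np.isfinite(control_es) and best_es < control_es:
            row["label"] = LABEL_RANDOM_OTHERS
        else:
            row["label"] = best_type
    return row


def type_cells(
    norm: NormalizedMatrix,
    panel: MarkerPanel,
    thresholds: TypingThresholds | None = None,
    rng: np.random.Generator | int | None = None,
) -> TypingResult:
    """Type every cell of a normalized matrix (vectorized).

    One set of ``n_perm`` random gene subsets is drawn per distinct marker
    set size and applied to each cell's own expression vector, so the whole
    background computation is a dense matrix product.  Deterministic given
    ``rng``.
    """
    thresholds = thresholds or TypingThresholds()
    rng = np.random.default_rng(rng)
    panel = panel.resolve(norm.genes)
    X = np.asarray(norm.values, dtype=float)
    n_cells, n_genes = X.shape

    sizes = sorted({len(panel.markers[t]) for t in panel.types}
                   | ({len(panel.negative_control)} if panel.negative_control else set()))
    # Background means for all cells at once: X @ S where S[g, p] = 1/k for
    # the genes of permutation p.  (n_cells, n_perm) per distinct size k.
    backgrounds: dict[int, np.ndarray] = {}
    for k in sizes:
        idx = _subset_indices(n_genes, k, thresholds.n_perm, rng)
        S = np.zeros((n_genes, thresholds.n_perm))
        np.put_along_axis(S.T, idx, 1.0 / k, axis=1)
        backgrounds[k] = X @ S

    out = pd.DataFrame({"barcode": norm.barcodes})
    es_cols, frac_cols, fdr_cols = {}, {}, {}
    for t in panel.types:
        midx = norm.gene_index(panel.markers[t])
        k = len(midx)
        obs = X[:, midx].mean(axis=1)
        frac = (X[:, midx] > 0).mean(axis=1)
        bg = backgrounds[k]
        bg_mean = bg.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            es = np.where(bg_mean > 0, obs / bg_mean,
                          np.where(obs > 0, np.inf, 0.0))
        fdr = (bg > obs[:, None]).mean(axis=1)
        out[f"es_{t}"], out[f"fdr_{t}"] = es, fdr
        out[f"frac_{t}"], out[f"mean_{t}"] = frac, obs
        es_cols[t], frac_cols[t], fdr_cols[t] = es, frac, fdr

    if panel.negative_control:
        cidx = norm.gene_index(panel.negative_control)
        obs_c = X[:, cidx].mean(axis=1)
        bg = backgrounds[len(cidx)]
        bg_mean = bg.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            control_es = np.where(bg_mean > 0, obs_c / bg_mean,
                                  np.where(obs_c > 0, np.inf, 0.0))
    else:
        control_es = np.full(n_cells, np.nan)
    out["control_es"] = control_es

    labels = np.full(n_cells, LABEL_NO_MATCH, dtype=object)
    best_es = np.full(n_cells, -np.inf)
    best_type = np.full(n_cells, "", dtype=object)
    for t in panel.types:
        ok = (
            (frac_cols[t] > thresholds.min_marker_fraction)
            & (fdr_cols[t] < thresholds.max_fdr)
            & (es_cols[t] >= thresholds.min_es)
        )
        better = ok & (es_cols[t] > best_es)
        best_es[better] = es_cols[t][better]
        best_type[better] = t
    has_candidate = best_type != ""
    labels[has_candidate] = best_type[has_candidate]
    demoted = has_candidate & np.isfinite(control_es) & (best_es < control_es)
    labels[demoted] = LABEL_RANDOM_OTHERS
    out["label"] = labels
    out["flagged_inconsistent"] = False

    logger.info(
        "typing: %d cells, labels %s",
        n_cells, dict(pd.Series(labels).value_counts()),
    )
    return TypingResult(table=out, thresholds=thresholds, panel=panel)


# ---------------------------------------------------------------------------
# Post-hoc spatial consistency filter
# ---------------------------------------------------------------------------

def consistency_filter(
    labels: np.ndarray,
    embedding: np.ndarray,
    min_cluster_size: int = 100,
    n_neighbors_vote: int = 10,
) -> np.ndarray:
    """Flag cells that sit apart from their type's main embedding cluster.

    For each assigned type the type's cells are density-clustered in the
    2-D embedding (DBSCAN with an adaptive radius: 3x the median distance
    to the 10th nearest same-type neighbour, so the rule is invariant to
    the embedding's scale).  Cells in noise, in clusters smaller than
    ``min_cluster_size``, or outside the type's largest cluster are
    flagged, as are whole clusters in whose local neighbourhood (k-NN
    vote over all cells) the type is not the majority label.  Types with
    fewer cells than ``min_cluster_size`` are left unflagged
    (insufficient evidence) with a warning.  Reserved labels
    (``random_others`` / ``no_type_match``) are never flagged.

    Returns a boolean array; removal is the caller's decision.
    """
    from sklearn.cluster import DBSCAN
    from sklearn.neighbors import NearestNeighbors

    labels = np.asarray(labels, dtype=object)
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] != len(labels):
        raise ValueError("one embedding coordinate pair per labeled cell required")
    flags = np.zeros(len(labels), dtype=bool)

    nn = NearestNeighbors(n_neighbors=min(n_neighbors_vote + 1, len(labels))).fit(embedding)
    _, global_nbrs = nn.kneighbors(embedding)

    for t in pd.unique(labels):
        if t in RESERVED_LABELS:
            continue
        members = np.where(labels == t)[0]
        if len(members) < max(min_cluster_size, 2):
            warnings.warn(
                f"type {t!r} has only {len(members)} cells "
                f"(< min_cluster_size={min_cluster_size}); left unflagged",
                stacklevel=2,
            )
            continue
        pts = embedding[members]
        kth = min(10, len(members) - 1)
        knn_dist, _ = NearestNeighbors(n_neighbors=kth + 1).fit(pts).kneighbors(pts)
        eps = 3.0 * float(np.median(knn_dist[:, -1]))
        cl = DBSCAN(eps=max(eps, 1e-12), min_samples=min(5, kth)).fit_predict(pts)
        # clusters below the evidence threshold count as noise
        for cid, size in zip(*np.unique(cl[cl >= 0], return_counts=True)):
            if size < min_cluster_size:
                cl[cl == cid] = -1
        cluster_ids, counts = np.unique(cl[cl >= 0], return_counts=True)
        if len(cluster_ids) == 0:
            warnings.warn(
                f"type {t!r}: no density cluster of at least "
                f"{min_cluster_size} cells; left unflagged", stacklevel=2,
            )
            continue
        largest = cluster_ids[np.argmax(counts)]
        flags[members[cl != largest]] = True
        # majority-label vote around each retained cluster
        for cid in cluster_ids:
            cluster_members = members[cl == cid]
            nbrs = global_nbrs[cluster_members][:, 1:].ravel()
            votes = pd.Series(labels[nbrs]).value_counts()
            if votes.idxmax() != t:
                flags[cluster_members] = True
    return flags
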