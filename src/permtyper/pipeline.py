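"""Seeded end-to-end pipeline: simulate/read -> prep -> embed -> type ->
consistency -> attributes -> markers/DEGs -> subtypes.

The embedding and the density clustering are declared glue: published
algorithms (UMAP, HDBSCAN) behind thin, backend-configurable wrappers with
the defaults used throughout this package (UMAP: n_neighbors=100,
n_components=2, min_dist=0, random init, Euclidean metric, random_state
123, 1000 epochs; HDBSCAN: min_cluster_size=100).  ``run_pipeline``
orchestrates the stages, writes one TSV per stage plus a JSON manifest and
a log, and is byte-for-byte reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_attributes import attribute_gene_correlation, compute_attributes
from .cell_typing import (
    RESERVED_LABELS,
    MarkerPanel,
    TypingThresholds,
    consistency_filter,
    draw_negative_control,
    type_cells,
)
from .io_prep import CountMatrix, filter_cells_genes, normalize, read_matrix
from .marker_deg import DEGParams, MarkerParams, condition_degs, specific_genes
from .synthetic_data import SimulationConfig, default_config, generate

logger = logging.getLogger("permtyper")


@dataclass
class EmbeddingParams:
    backend: str = "umap"        # "umap" or "pca"
    n_neighbors: int = 100
    n_components: int = 2
    min_dist: float = 0.0
    init: str = "random"
    metric: str = "euclidean"
    random_state: int = 123
    n_epochs: int = 1000


@dataclass
class PipelineConfig:
    """All thresholds and stage toggles of one run, with printed defaults."""

    seed: int = 0
    out_dir: str = "permtyper_run"
    # stage toggles
    simulate: bool = True
    prep: bool = True
    embed: bool = True
    typing: bool = True
    consistency: bool = True
    attributes: bool = True
    markers: bool = True
    degs: bool = True
    subtypes: bool = True
    # stage parameters
    min_genes_per_cell: int = 500
    min_cells_per_gene: int = 10
    thresholds: TypingThresholds = field(default_factory=TypingThresholds)
    n_control_genes: int = 500
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    marker_params: MarkerParams = field(default_factory=MarkerParams)
    deg_params: DEGParams = field(default_factory=DEGParams)
    subtype_min_cluster_size: int = 100
    consistency_min_cluster_size: int = 100
    deg_conditions: tuple[str, str] = ("normoxia", "hypoxia")
    # inputs: either a simulation config or an on-disk bundle + panel
    sim: SimulationConfig | None = None
    mtx: str | None = None
    barcodes: str | None = None
    features: str | None = None
    annot: str | None = None
    conditions: str | None = None
    panel_path: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["deg_conditions"] = list(self.deg_conditions)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "thresholds" in kwargs and isinstance(kwargs["thresholds"], dict):
            kwargs["thresholds"] = TypingThresholds(**kwargs["thresholds"])
        if "embedding" in kwargs and isinstance(kwargs["embedding"], dict):
            kwargs["embedding"] = EmbeddingParams(**kwargs["embedding"])
        if "marker_params" in kwargs and isinstance(kwargs["marker_params"], dict):
            kwargs["marker_params"] = MarkerParams(**kwargs["marker_params"])
        if "deg_params" in kwargs and isinstance(kwargs["deg_params"], dict):
            kwargs["deg_params"] = DEGParams(**kwargs["deg_params"])
        if "deg_conditions" in kwargs:
            kwargs["deg_conditions"] = tuple(kwargs["deg_conditions"])
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            from .synthetic_data import AttributeCoupling, CellTypeSpec, ConditionEffect
            sim = dict(kwargs["sim"])
            sim["types"] = [CellTypeSpec(**t) for t in sim["types"]]
            sim["condition_effects"] = [
                ConditionEffect(**e) for e in sim.get("condition_effects", [])
            ]
            if sim.get("attribute_coupling"):
                sim["attribute_coupling"] = AttributeCoupling(**sim["attribute_coupling"])
            if isinstance(sim.get("base_expression"), list):
                sim["base_expression"] = tuple(sim["base_expression"])
            if isinstance(sim.get("marker_expression"), list):
                sim["marker_expression"] = tuple(sim["marker_expression"])
            kwargs["sim"] = SimulationConfig(**sim)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Glue stages
# ---------------------------------------------------------------------------

def embed(values: np.ndarray, params: EmbeddingParams | None = None) -> np.ndarray:
    """Nonlinear 2-D embedding of a cells x genes matrix (pluggable backend).

    ``backend="umap"`` delegates to umap-learn with the configured
    parameters; ``backend="pca"`` is a fast deterministic alternative
    (first ``n_components`` principal components).  Deterministic given
    ``random_state``.
    """
    params = params or EmbeddingParams()
    X = np.asarray(values, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot embed an empty matrix")
    if params.backend == "pca":
        from sklearn.decomposition import PCA
        return PCA(
            n_components=params.n_components, random_state=params.random_state
        ).fit_transform(X)
    if params.backend != "umap":
        raise ValueError(f"unknown embedding backend {params.backend!r}")
    try:
        import umap
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the 'umap' backend needs the optional dependency umap-learn; "
            "install it or set embedding.backend='pca'"
        ) from exc
    n_neighbors = min(params.n_neighbors, X.shape[0] - 1)
    reducer = umap.UMAP(
        n_neighbors=max(2, n_neighbors),
        n_components=params.n_components,
        min_dist=params.min_dist,
        init=params.init,
        metric=params.metric,
        random_state=params.random_state,
        n_epochs=params.n_epochs,
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)


def subtype_cluster(points: np.ndarray, min_cluster_size: int = 100) -> np.ndarray:
    """Density-based subtype labels; -1 marks noise.

    Fewer points than ``min_cluster_size`` yields all-noise with a
    warning.  Labels are invariant to point order up to relabeling.
    """
    import warnings as _warnings

    from sklearn.cluster import HDBSCAN

    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < min_cluster_size:
        _warnings.warn(
            f"{pts.shape[0]} points < min_cluster_size={min_cluster_size}: "
            "no cluster can form", stacklevel=2,
        )
        return np.full(pts.shape[0], -1, dtype=int)
    return HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(pts)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, run_id: str) -> str:
    with open(path, "w") as fh:
        fh.write(f"# permtyper {__version__} run {run_id}\n")
        df.to_csv(fh, sep="\t", index=False)
    return _sha256(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest.

    Writes per-stage TSVs, ``manifest.json`` (versions, seed, thresholds,
    per-stage row counts, output hashes) and ``run.log``.  The manifest
    contains no timestamps, so identical (config, seed) reproduce it
    byte-for-byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    cfg_dict = config.to_dict()
    run_id = hashlib.sha256(
        json.dumps({k: v for k, v in cfg_dict.items() if k != "out_dir"},
                   sort_keys=True, default=str).encode()
    ).hexdigest()[:12]

    manifest: dict = {
        "permtyper_version": __version__,
        "run_id": run_id,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }
    t_all = time.time()
    try:
        matrix: CountMatrix | None = None
        truth = None
        if config.simulate:
            t0 = time.time()
            sim = config.sim or default_config(seed=config.seed)
            sim = dataclasses.replace(sim, seed=config.seed)
            matrix, truth = generate(sim)
            manifest["stages"]["simulate"] = {"n_cells": matrix.n_cells,
                                              "n_genes": matrix.n_genes}
            logger.info("simulate: %d cells x %d genes (%.1fs)",
                        matrix.n_cells, matrix.n_genes, time.time() - t0)
        elif config.mtx:
            matrix = read_matrix(config.mtx, config.barcodes, config.features,
                                 config.annot, condition_path=config.conditions)
            manifest["stages"]["read"] = {"n_cells": matrix.n_cells,
                                          "n_genes": matrix.n_genes}

        norm = None
        if config.prep:
            if matrix is None:
                raise RuntimeError("stage prep: no input matrix (enable simulate "
                                   "or provide --mtx)")
            t0 = time.time()
            matrix, report = filter_cells_genes(
                matrix, config.min_genes_per_cell, config.min_cells_per_gene)
            norm = normalize(matrix)
            manifest["outputs"]["filter_report.tsv"] = _write_tsv(
                report.to_frame(), out / "filter_report.tsv", run_id)
            manifest["stages"]["prep"] = {
                "n_cells": matrix.n_cells, "n_genes": matrix.n_genes}
            logger.info("prep: %d cells x %d genes kept (%.1fs)",
                        matrix.n_cells, matrix.n_genes, time.time() - t0)

        coords = None
        if config.embed and norm is not None:
            t0 = time.time()
            coords = embed(norm.values, config.embedding)
            emb_df = pd.DataFrame(coords, columns=["dim1", "dim2"][: coords.shape[1]])
            emb_df.insert(0, "barcode", norm.barcodes)
            manifest["outputs"]["embedding.tsv"] = _write_tsv(
                emb_df, out / "embedding.tsv", run_id)
            manifest["stages"]["embed"] = {"n_cells": int(coords.shape[0])}
            logger.info("embed: %s backend (%.1fs)",
                        config.embedding.backend, time.time() - t0)

        typing = None
        if config.typing and norm is not None:
            t0 = time.time()
            rng = np.random.default_rng(config.seed)
            if config.panel_path:
                p = Path(config.panel_path)
                panel = (MarkerPanel.from_json(p) if p.suffix == ".json"
                         else MarkerPanel.from_tsv(p))
            elif truth is not None:
                panel = truth.panel
            else:
                raise RuntimeError("stage typing: no marker panel (provide "
                                   "panel_path or enable simulate)")
            if not panel.negative_control:
                control = draw_negative_control(
                    norm.genes, panel.all_marker_genes,
                    size=min(config.n_control_genes,
                             norm.n_genes - len(panel.all_marker_genes)),
                    rng=rng)
                panel = MarkerPanel(list(panel.types), dict(panel.markers), control)
            typing = type_cells(norm, panel, config.thresholds, rng)
            manifest["stages"]["typing"] = {
                "n_cells": int(len(typing.table)),
                "labels": {str(k): int(v) for k, v in
                           typing.table["label"].value_counts().items()},
            }
            logger.info("typing done (%.1fs)", time.time() - t0)

            if config.consistency and coords is not None:
                flags = consistency_filter(
                    typing.labels, coords,
                    min_cluster_size=config.consistency_min_cluster_size)
                typing.table["flagged_inconsistent"] = flags
                manifest["stages"]["consistency"] = {"n_flagged": int(flags.sum())}
            manifest["outputs"]["typing.tsv"] = _write_tsv(
                typing.table, out / "typing.tsv", run_id)

        if config.attributes and norm is not None:
            t0 = time.time()
            labels = typing.labels if typing is not None else None
            attrs = compute_attributes(matrix, norm, labels)
            manifest["outputs"]["attributes.tsv"] = _write_tsv(
                attrs, out / "attributes.tsv", run_id)
            manifest["stages"]["attributes"] = {"n_cells": int(len(attrs))}
            logger.info("attributes done (%.1fs)", time.time() - t0)

        if config.markers and typing is not None:
            t0 = time.time()
            labels = typing.labels
            for t in [t for t in pd.unique(labels) if t not in RESERVED_LABELS]:
                if (labels == t).sum() < 2 or (labels != t).sum() < 2:
                    continue
                rec = specific_genes(norm, labels, t, config.marker_params)
                name = f"markers_{t}.tsv"
                manifest["outputs"][name] = _write_tsv(rec, out / name, run_id)
            manifest["stages"]["markers"] = {"done": True}
            logger.info("markers done (%.1fs)", time.time() - t0)

        if config.degs and typing is not None:
            t0 = time.time()
            cond_a, cond_b = config.deg_conditions
            labels = typing.labels
            cond = np.asarray(norm.condition, dtype=object)
            for t in [t for t in pd.unique(labels) if t not in RESERVED_LABELS]:
                mask = labels == t
                if ((mask & (cond == cond_a)).sum() < 2
                        or (mask & (cond == cond_b)).sum() < 2):
                    continue
                rec = condition_degs(norm, labels, t, cond_a, cond_b,
                                     config.deg_params)
                name = f"degs_{t}.tsv"
                manifest["outputs"][name] = _write_tsv(rec, out / name, run_id)
            manifest["stages"]["degs"] = {"done": True}
            logger.info("degs done (%.1fs)", time.time() - t0)

        if config.subtypes and coords is not None:
            sub = subtype_cluster(coords, config.subtype_min_cluster_size)
            sub_df = pd.DataFrame({"barcode": norm.barcodes, "subtype": sub})
            manifest["outputs"]["subtypes.tsv"] = _write_tsv(
                sub_df, out / "subtypes.tsv", run_id)
            manifest["stages"]["subtypes"] = {
                "n_clusters": int(len(set(sub) - {-1}))}
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    # hash everything except the output location, so identical (config,
    # seed) runs agree regardless of where they write
    payload = json.loads(json.dumps(manifest, sort_keys=True, default=str))
    payload["config"].pop("out_dir", None)
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("pipeline complete in %.1fs", time.time() - t_all)
    return manifest
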