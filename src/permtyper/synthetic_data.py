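"""Synthetic testis-like scRNA-seq generator with known ground truth.

Counts follow a gamma-Poisson (negative binomial) model: every gene gets a
lognormal base weight, every cell a lognormal library size, and the
expected count of gene *g* in cell *c* is the library size times the
cell-specific normalized gene weight.  On top of this baseline the
generator plants the structure the analysis pipeline is meant to recover:

* **marker genes** — per cell type, ``n_markers`` dedicated genes whose
  mean is multiplied by ``2**marker_log2_fold`` in cells of that type;
* **condition effects** — programmed genes (e.g. an *Asxl2*-like gene
  down, a *Cep162*-like gene up) whose mean is scaled by
  ``2**log2_fold`` in the perturbed condition, within the affected types;
* **composition shift** — per-condition cell counts per type (the default
  configuration lowers the elongating-spermatid share and raises the
  round-spermatid share under hypoxia);
* **doublets** — optional droplet artifacts built by summing two singlet
  expectation profiles and rescaling the total to 1.4x the mean library
  size;
* **attribute coupling** — an optional "repressor" gene whose expression
  co-varies with a tempering of the cell's gene-weight distribution, so
  that high expression implies fewer detected genes (a planted negative
  expression-vs-n_genes correlation).

Every draw is controlled by a single seed; the emitted bundle is exactly
what :mod:`permtyper.io_prep` reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .cell_typing import VALIDATION_MARKERS, MarkerPanel
from .io_prep import CountMatrix, write_matrix


@dataclass
class CellTypeSpec:
    name: str
    n_cells: dict[str, int]          # condition -> cell count
    n_markers: int = 20
    marker_log2_fold: float = 3.0


@dataclass
class ConditionEffect:
    """A programmed gene whose mean shifts in one condition."""

    gene: str
    log2_fold: float
    condition: str = "hypoxia"
    cell_types: list[str] | None = None   # None = all types
    base_mean: float = 6.0                # expected counts at the median library


@dataclass
class AttributeCoupling:
    """Plant a negative dependence between one gene and detected-gene count."""

    gene: str = "Repressor1"
    strength: float = 0.6        # weight-tempering amplitude
    log2_amplitude: float = 2.0  # swing of the coupled gene itself
    base_mean: float = 6.0


@dataclass
class SimulationConfig:
    types: list[CellTypeSpec]
    n_genes: int = 3000
    base_expression: tuple[float, float] = (0.0, 1.0)    # lognormal (mu, sigma)
    marker_expression: tuple[float, float] = (2.2, 0.15)  # marker base weights
    library_median: float = 1200.0
    library_sigma_log: float = 0.35
    dispersion: float = 2.0                               # NB size parameter
    chrom_class_probs: dict[str, float] = field(
        default_factory=lambda: {"MT": 0.005, "X": 0.05, "Y": 0.005, "AUTO": 0.94}
    )
    condition_effects: list[ConditionEffect] = field(default_factory=list)
    doublet_rate: float = 0.05
    attribute_coupling: AttributeCoupling | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ValueError("at least 2 cell types required")
        names = [t.name for t in self.types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell-type names")
        if not 0 <= self.doublet_rate < 1:
            raise ValueError("doublet_rate must be in [0, 1)")
        if sum(t.n_markers for t in self.types) > self.n_genes // 2:
            raise ValueError("marker sets too large for n_genes")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for t in self.types:
            for c in t.n_cells:
                if c not in seen:
                    seen.append(c)
        return seen

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted truth aligned with the emitted matrix."""

    cells: pd.DataFrame   # barcode, true_type, condition, is_doublet, type_a, type_b
    genes: pd.DataFrame   # gene_id, chrom_class, marker_of, condition_effect, coupled
    panel: MarkerPanel    # planted marker panel (no negative control)


def default_config(
    n_cells_per_condition: int = 600,
    seed: int = 0,
    doublet_rate: float = 0.05,
) -> SimulationConfig:
    """The default testis emulation: 5 cell types, hypoxia composition shift.

    Normoxia composition follows the major-type proportions of an adult
    testis dominated by elongating spermatids; hypoxia lowers the
    elongating share and raises the round share, and programs an
    *Asxl2*-like gene down and a *Cep162*-like gene up in spermatids.
    """
    comp_norm = {
        "spermatogonia": 0.100, "spermatocytes": 0.250,
        "round_spermatids": 0.088, "elongating_spermatids": 0.504,
        "sertoli": 0.058,
    }
    comp_hyp = {
        "spermatogonia": 0.110, "spermatocytes": 0.270,
        "round_spermatids": 0.112, "elongating_spermatids": 0.424,
        "sertoli": 0.084,
    }
    types = [
        CellTypeSpec(
            name=name,
            n_cells={
                "normoxia": max(2, round(comp_norm[name] * n_cells_per_condition)),
                "hypoxia": max(2, round(comp_hyp[name] * n_cells_per_condition)),
            },
        )
        for name in comp_norm
    ]
    effects = [
        ConditionEffect(
            gene="Asxl2", log2_fold=-2.0,
            cell_types=["round_spermatids", "elongating_spermatids"],
        ),
        ConditionEffect(
            gene="Cep162", log2_fold=+2.0,
            cell_types=["round_spermatids", "elongating_spermatids"],
        ),
    ]
    return SimulationConfig(
        types=types, condition_effects=effects,
        doublet_rate=doublet_rate, seed=seed,
    )


def _marker_names(spec: CellTypeSpec) -> list[str]:
    """Marker gene ids for a type: known lineage markers first, then
    synthetic fill-ins."""
    known = list(VALIDATION_MARKERS.get(spec.name, ()))[: spec.n_markers]
    fill = [f"{spec.name}_m{j:02d}" for j in range(len(known), spec.n_markers)]
    return known + fill


def generate(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a dataset from the configured model; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes

    # --- gene layer -----------------------------------------------------
    mu0, sd0 = config.base_expression
    weights = rng.lognormal(mu0, sd0, size=n_genes)
    gene_ids = np.array([f"g{j:05d}" for j in range(n_genes)], dtype=object)
    marker_of = np.full(n_genes, "", dtype=object)
    effect_tag = np.full(n_genes, "", dtype=object)
    coupled = np.zeros(n_genes, dtype=bool)

    free = list(range(n_genes))
    rng.shuffle(free)
    panel_markers: dict[str, list[str]] = {}
    mmu, msd = config.marker_expression
    for spec in config.types:
        names = _marker_names(spec)
        cols = [free.pop() for _ in names]
        gene_ids[cols] = names
        marker_of[cols] = spec.name
        weights[cols] = rng.lognormal(mmu, msd, size=len(cols))
        panel_markers[spec.name] = names

    # expected counts per unit weight at the median library
    weight_sum = weights.sum()
    per_weight = config.library_median / weight_sum

    for eff in config.condition_effects:
        col = free.pop()
        gene_ids[col] = eff.gene
        effect_tag[col] = f"{eff.log2_fold:+g}@{eff.condition}"
        weights[col] = eff.base_mean / per_weight

    coupling = config.attribute_coupling
    temper = np.zeros(n_genes, dtype=bool)
    if coupling is not None:
        col = free.pop()
        gene_ids[col] = coupling.gene
        coupled[col] = True
        weights[col] = coupling.base_mean / per_weight
        temper = rng.random(n_genes) < 0.5
        temper[col] = False

    chrom_names = list(config.chrom_class_probs)
    probs = np.array([config.chrom_class_probs[k] for k in chrom_names], dtype=float)
    chrom_class = rng.choice(np.array(chrom_names, dtype=object),
                             size=n_genes, p=probs / probs.sum())

    # --- cell layer -----------------------------------------------------
    rows = []
    for spec in config.types:
        for cond, n in spec.n_cells.items():
            rows += [(spec.name, cond)] * n
    true_type = np.array([r[0] for r in rows], dtype=object)
    condition = np.array([r[1] for r in rows], dtype=object)
    n_singlets = len(rows)

    lib = rng.lognormal(np.log(config.library_median),
                        config.library_sigma_log, size=n_singlets)

    # expectation profile per singlet
    fold = np.ones((n_singlets, n_genes))
    for spec in config.types:
        mcols = np.isin(gene_ids, panel_markers[spec.name])
        fold[np.ix_(true_type == spec.name, mcols)] *= 2.0 ** spec.marker_log2_fold
    type_names = [t.name for t in config.types]
    for eff in config.condition_effects:
        col = int(np.where(gene_ids == eff.gene)[0][0])
        affected = np.isin(true_type, eff.cell_types or type_names) & (
            condition == eff.condition
        )
        fold[affected, col] *= 2.0 ** eff.log2_fold

    W = weights[None, :] * fold
    if coupling is not None:
        u = rng.random(n_singlets)
        col = int(np.where(coupled)[0][0])
        W = W.copy()
        # temper half the genes: high u concentrates mass -> fewer detected
        W[:, temper] **= (1.0 + coupling.strength * (u - 0.5))[:, None]
        W[:, col] *= 2.0 ** (coupling.log2_amplitude * 2.0 * (u - 0.5))
    mean = W / W.sum(axis=1, keepdims=True) * lib[:, None]

    # --- doublets -------------------------------------------------------
    is_doublet = np.zeros(n_singlets, dtype=bool)
    type_a = true_type.copy()
    type_b = np.full(n_singlets, "", dtype=object)
    if config.doublet_rate > 0:
        extra_mean, extra_rows = [], []
        for cond in config.conditions:
            pool = np.where(condition == cond)[0]
            n_dbl = int(round(config.doublet_rate * len(pool)))
            for _ in range(n_dbl):
                i, j = rng.choice(pool, size=2, replace=False)
                prof = mean[i] + mean[j]
                prof = prof / prof.sum() * (1.4 * lib.mean())
                extra_mean.append(prof)
                extra_rows.append((cond, true_type[i], true_type[j]))
        if extra_mean:
            mean = np.vstack([mean, np.array(extra_mean)])
            true_type = np.concatenate(
                [true_type, np.array(["doublet"] * len(extra_rows), dtype=object)])
            condition = np.concatenate(
                [condition, np.array([r[0] for r in extra_rows], dtype=object)])
            is_doublet = np.concatenate(
                [is_doublet, np.ones(len(extra_rows), dtype=bool)])
            type_a = np.concatenate(
                [type_a, np.array([r[1] for r in extra_rows], dtype=object)])
            type_b = np.concatenate(
                [type_b, np.array([r[2] for r in extra_rows], dtype=object)])

    # --- counts: gamma-Poisson == negative binomial ---------------------
    r = config.dispersion
    lam = rng.gamma(shape=r, scale=mean / r)
    counts = rng.poisson(lam)

    n_cells = counts.shape[0]
    barcodes = np.array([f"cell{c:05d}" for c in range(n_cells)], dtype=object)
    matrix = CountMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=barcodes,
        genes=gene_ids,
        chrom_class=chrom_class,
        condition=condition,
    )
    truth = GroundTruth(
        cells=pd.DataFrame({
            "barcode": barcodes, "true_type": true_type, "condition": condition,
            "is_doublet": is_doublet, "type_a": type_a, "type_b": type_b,
        }),
        genes=pd.DataFrame({
            "gene_id": gene_ids, "chrom_class": chrom_class,
            "marker_of": marker_of, "condition_effect": effect_tag,
            "coupled": coupled,
        }),
        panel=MarkerPanel(list(panel_markers), panel_markers, []),
    )
    return matrix, truth


def write_bundle(
    matrix: CountMatrix,
    truth: GroundTruth,
    config: SimulationConfig,
    out_dir,
) -> dict:
    """Emit the MTX/TSV bundle plus ground truth and the echoed config."""
    out = Path(out_dir)
    paths = write_matrix(matrix, out)
    paths["ground_truth_cells"] = out / "ground_truth_cells.tsv"
    truth.cells.to_csv(paths["ground_truth_cells"], sep="\t", index=False)
    paths["ground_truth_genes"] = out / "ground_truth_genes.tsv"
    truth.genes.to_csv(paths["ground_truth_genes"], sep="\t", index=False)
    paths["panel"] = out / "marker_panel.tsv"
    truth.panel.to_tsv(paths["panel"])
    paths["config"] = out / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return paths


# ---------------------------------------------------------------------------
# Hand-written micro fixture
# ---------------------------------------------------------------------------

def micro_fixture() -> tuple[CountMatrix, dict]:
    """A 6-cell x 12-gene matrix with exactly known intermediate values.

    Cell totals are (40, 20, 20, 20, 10, 8): the median is 20, so cell F1
    has scale factor 2 and its count of 6 normalizes to log2(6/2 + 1) = 2.
    Cell F2's block of genes g05..g08 is one-hot (0, 0, 0, 8), the
    maximal-inequality closed form of the Gini estimator (0.75).  The
    expected values returned alongside were derived by hand.
    """
    #          g01 g02 g03 g04 g05 g06 g07 g08 g09 g10 g11 g12
    counts = np.array([
        [6, 2, 2, 6, 6, 6, 6, 6, 0, 0, 0, 0],   # F1, total 40
        [4, 4, 2, 2, 0, 0, 0, 8, 0, 0, 0, 0],   # F2, total 20
        [2, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1],   # F3, total 20
        [5, 5, 0, 0, 5, 5, 0, 0, 0, 0, 0, 0],   # F4, total 20
        [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0],   # F5, total 10
        [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0],   # F6, total 8
    ])
    genes = [f"g{j:02d}" for j in range(1, 13)]
    chrom = ["MT", "X", "Y"] + ["AUTO"] * 9
    matrix = CountMatrix(
        counts=sp.csr_matrix(counts),
        barcodes=[f"F{i}" for i in range(1, 7)],
        genes=genes,
        chrom_class=chrom,
        condition=["normoxia"] * 6,
    )
    expected = {
        "median_total": 20.0,
        "scale_factors": [2.0, 1.0, 1.0, 1.0, 0.5, 0.4],
        # F1's count 6 at scale 2 -> log2(6/2 + 1)
        "f1_count6_normalized": 2.0,
        # Gini of F2's g05..g08 block (0, 0, 0, 8): one-hot closed form
        "f2_marker_block_gini": 0.75,
        "f1_chrM_pct": 100.0 * 6 / 40,
        "f1_chrX_pct": 100.0 * 2 / 40,
        "f1_chrY_pct": 100.0 * 2 / 40,
        # marker set for the exhaustive ES oracle tests
        "es_marker_genes": ["g05", "g06", "g07", "g08"],
    }
    return matrix, expected
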