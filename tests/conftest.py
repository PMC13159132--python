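import numpy as np
import pytest

import permtyper as pt


@pytest.fixture(scope="session")
def micro():
    """Hand-written 6x12 matrix with frozen expected intermediates."""
    return pt.micro_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """One default-configuration simulated dataset, filtered and normalized."""
    cfg = pt.default_config(seed=1)
    raw, truth = pt.generate(cfg)
    filtered, report = pt.filter_cells_genes(raw)
    norm = pt.normalize(filtered)
    truth_cells = truth.cells.set_index("barcode").loc[norm.barcodes]
    return {
        "config": cfg, "raw": raw, "truth": truth, "filtered": filtered,
        "report": report, "norm": norm, "truth_cells": truth_cells,
    }


@pytest.fixture(scope="session")
def typed(small_dataset):
    """Typing result on the small dataset with a seeded 500-gene control."""
    norm = small_dataset["norm"]
    truth = small_dataset["truth"]
    rng = np.random.default_rng(1)
    control = pt.draw_negative_control(
        norm.genes, truth.panel.all_marker_genes, 500, rng)
    panel = pt.MarkerPanel(list(truth.panel.types), dict(truth.panel.markers),
                           control)
    return pt.type_cells(norm, panel, rng=rng), panel


def make_norm(values, conditions=None, genes=None):
    """Wrap a dense array as a NormalizedMatrix with synthetic metadata."""
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    if genes is None:
        genes = np.array([f"g{j}" for j in range(n_genes)], dtype=object)
    return pt.NormalizedMatrix(
        values=values,
        scale_factors=np.ones(n_cells),
        median_total=1.0,
        barcodes=np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        genes=np.asarray(genes, dtype=object),
        chrom_class=np.array(["AUTO"] * n_genes, dtype=object),
        condition=np.array(
            ["a"] * n_cells if conditions is None else conditions, dtype=object),
    )
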