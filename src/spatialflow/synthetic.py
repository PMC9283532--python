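"""Synthetic ground-truth tissues for testing the full pipeline.

Two generators emulate the statistical structure the method assumes, so every
stage can be exercised without downloading data:

* :func:`simulate_layered_tissue` — cells on a jittered grid partitioned into
  horizontal bands (cortical-layer-like domains). Counts are negative
  binomial; each layer owns a disjoint set of marker genes whose mean is
  ``fold_change`` times the baseline inside that layer.
* :func:`simulate_gradient_tissue` — cells on a jittered strip; a block of
  "program" genes interpolates log-linearly between two expression programs
  along x, giving a smooth ground-truth spatiotemporal coordinate.

Counts are NB(mean mu, dispersion alpha) with variance mu + alpha * mu^2
(the standard overdispersed model for UMI counts). All randomness flows from
the single ``seed`` argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .preprocess import STDataset

logger = logging.getLogger("spatialflow")

__all__ = ["SyntheticTissue", "simulate_layered_tissue", "simulate_gradient_tissue"]


@dataclass
class SyntheticTissue:
    """A generated dataset with its ground truth attached."""

    dataset: STDataset
    layer_labels: np.ndarray  # ground-truth domain per cell
    gradient: np.ndarray  # ground-truth pseudo-spatiotemporal coordinate
    planted_markers: dict  # layer -> gene indices (empty for gradient tissue)
    params: dict


def _nb_counts(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """NB draws with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def _jittered_grid(n_cols: int, n_rows: int, jitter: float,
                   rng: np.random.Generator) -> np.ndarray:
    xx, yy = np.meshgrid(np.arange(n_cols, dtype=float),
                         np.arange(n_rows, dtype=float))
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return pts + rng.uniform(-jitter, jitter, size=pts.shape)


def simulate_layered_tissue(
    n_layers: int = 3,
    cells_per_layer: int = 200,
    n_genes: int = 300,
    n_markers_per_layer: int = 20,
    baseline_mean: float = 1.0,
    fold_change: float = 5.0,
    nb_dispersion: float = 0.5,
    grid_jitter: float = 0.1,
    seed: int = 0,
    min_genes_expressed: int = 100,
) -> SyntheticTissue:
    """Layered tissue: horizontal spatial bands with layer-specific markers.

    Every gene has NB mean ``baseline_mean``; the ``n_markers_per_layer``
    genes planted for layer L have mean ``fold_change * baseline_mean`` in the
    cells of layer L. The ground-truth gradient is the band index. If a draw
    leaves some cell expressing fewer than ``min_genes_expressed`` genes
    (so that it would not survive default preprocessing), the baseline mean
    is bumped by 50% and the tissue redrawn (at most 3 times, logged).
    """
    if min(n_layers, cells_per_layer, n_genes, n_markers_per_layer) <= 0:
        raise ValueError("all size parameters must be positive")
    if n_markers_per_layer * n_layers > n_genes:
        raise ValueError(
            f"{n_markers_per_layer} markers x {n_layers} layers exceeds "
            f"{n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    n_cells = n_layers * cells_per_layer

    # geometry: one band of jittered grid rows per layer
    n_cols = int(np.ceil(np.sqrt(cells_per_layer)))
    n_rows = int(np.ceil(cells_per_layer / n_cols))
    coords_list, labels = [], []
    for layer in range(n_layers):
        pts = _jittered_grid(n_cols, n_rows, grid_jitter, rng)[:cells_per_layer]
        pts[:, 1] += layer * n_rows  # stack bands vertically
        coords_list.append(pts)
        labels += [layer] * cells_per_layer
    coords = np.vstack(coords_list)
    labels = np.asarray(labels)

    markers = {
        layer: np.arange(layer * n_markers_per_layer,
                         (layer + 1) * n_markers_per_layer)
        for layer in range(n_layers)
    }

    base = baseline_mean
    for attempt in range(3):
        mean = np.full((n_cells, n_genes), base)
        for layer, genes in markers.items():
            mean[np.ix_(labels == layer, genes)] = fold_change * base
        counts = _nb_counts(mean, nb_dispersion, rng)
        expressed = (counts > 0).sum(axis=1)
        # coverage guarantee only meaningful at full panel size; small test
        # panels are expected to be used with a lower cell filter threshold
        if n_genes < 3 * min_genes_expressed \
                or expressed.min() >= min_genes_expressed:
            break
        logger.warning(
            "cell with only %d expressed genes; bumping baseline_mean "
            "%g -> %g and redrawing", expressed.min(), base, base * 1.5
        )
        base *= 1.5

    width = max(len(str(n_cells)), len(str(n_genes)))
    dataset = STDataset(
        counts=sp.csr_matrix(counts),
        coords=coords,
        cell_ids=np.asarray([f"cell_{i:0{width}d}" for i in range(n_cells)],
                            dtype=object),
        gene_ids=np.asarray([f"gene_{j:0{width}d}" for j in range(n_genes)],
                            dtype=object),
    )
    return SyntheticTissue(
        dataset=dataset,
        layer_labels=labels,
        gradient=labels.astype(float),
        planted_markers=markers,
        params=dict(
            kind="layered", n_layers=n_layers, cells_per_layer=cells_per_layer,
            n_genes=n_genes, n_markers_per_layer=n_markers_per_layer,
            baseline_mean=base, fold_change=fold_change,
            nb_dispersion=nb_dispersion, grid_jitter=grid_jitter, seed=seed,
        ),
    )


def simulate_gradient_tissue(
    n_cells: int = 600,
    n_genes: int = 300,
    n_program_genes: int = 50,
    nb_dispersion: float = 0.5,
    seed: int = 0,
    baseline_mean: float = 1.0,
    program_high: float = 5.0,
    program_low: float = 0.5,
    n_rows: int = 10,
    grid_jitter: float = 0.1,
) -> SyntheticTissue:
    """Gradient tissue: program-gene means interpolate log-linearly along x.

    Half the program genes follow program A (mean ``program_high`` at the left
    edge decaying to ``program_low`` at the right), the other half the mirror
    program B. The ground-truth gradient is the normalized x position.
    """
    if min(n_cells, n_genes, n_program_genes) <= 0:
        raise ValueError("all size parameters must be positive")
    if n_program_genes > n_genes:
        raise ValueError("n_program_genes exceeds n_genes")
    rng = np.random.default_rng(seed)

    n_cols = int(np.ceil(n_cells / n_rows))
    coords = _jittered_grid(n_cols, n_rows, grid_jitter, rng)[:n_cells]
    t = coords[:, 0] / coords[:, 0].max()  # normalized position along the strip

    half = n_program_genes // 2
    mean = np.full((n_cells, n_genes), baseline_mean)
    log_hi, log_lo = np.log(program_high), np.log(program_low)
    mean_a = np.exp((1.0 - t) * log_hi + t * log_lo)  # high -> low
    mean_b = np.exp(t * log_hi + (1.0 - t) * log_lo)  # low -> high
    mean[:, :half] = mean_a[:, None]
    mean[:, half:n_program_genes] = mean_b[:, None]
    counts = _nb_counts(mean, nb_dispersion, rng)

    width = max(len(str(n_cells)), len(str(n_genes)))
    dataset = STDataset(
        counts=sp.csr_matrix(counts),
        coords=coords,
        cell_ids=np.asarray([f"cell_{i:0{width}d}" for i in range(n_cells)],
                            dtype=object),
        gene_ids=np.asarray([f"gene_{j:0{width}d}" for j in range(n_genes)],
                            dtype=object),
    )
    return SyntheticTissue(
        dataset=dataset,
        layer_labels=np.zeros(n_cells, dtype=int),
        gradient=t,
        planted_markers={},
        params=dict(
            kind="gradient", n_cells=n_cells, n_genes=n_genes,
            n_program_genes=n_program_genes, nb_dispersion=nb_dispersion,
            baseline_mean=baseline_mean, program_high=program_high,
            program_low=program_low, seed=seed,
        ),
    )
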