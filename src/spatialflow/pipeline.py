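"""End-to-end pipeline: preprocess -> spatial graph -> train -> downstream.

A :class:`RunConfig` holds every knob of every stage plus the input paths and
round-trips to YAML. :func:`run_pipeline` executes the stages in order and
writes the standard artifacts (embeddings, domain labels, pSM, per-epoch loss
log, resolved config) into the output directory; each artifact carries the
SHA-256 hash of the resolved configuration so outputs are traceable to the
exact run that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import dgi, downstream, preprocess, spatial_graph

logger = logging.getLogger("spatialflow")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_dataset"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    # input paths (counts+genes+barcodes for MTX, or matrix for dense CSV/TSV)
    counts: str | None = None
    genes: str | None = None
    barcodes: str | None = None
    matrix: str | None = None
    coords: str | None = None
    outdir: str = "spatialflow_out"

    # preprocess
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 100
    scale_factor: float = 10000.0
    n_top_hvg: int = 3000
    hvg_bins: int = 20

    # spatial graph
    graph_method: str = "alpha"  # "alpha" | "knn"
    knn_k: int = 15
    delta: float | None = None  # estimated from data when None

    # training
    gamma: float = 0.1
    lr: float = 0.001
    max_epochs: int = 1000
    min_epochs: int = 100
    patience: int = 50
    latent_dim: int = 50
    pair_subsample_threshold: int = 10000
    n_pairs: int | None = None
    device: str = "cpu"

    # downstream
    n_neighbors: int = 50
    resolution: float = 1.0
    target_k: int | None = None
    n_dcs: int = 10
    marker_alpha: float = 0.01

    seed: int = 0
    log_level: str = "INFO"

    # ----- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def hash(self) -> str:
        """Digest of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def train_config(self) -> dgi.TrainConfig:
        return dgi.TrainConfig(
            gamma=self.gamma, lr=self.lr, max_epochs=self.max_epochs,
            min_epochs=self.min_epochs, patience=self.patience,
            latent_dim=self.latent_dim, seed=self.seed,
            pair_subsample_threshold=self.pair_subsample_threshold,
            n_pairs=self.n_pairs, device=self.device,
        )


# ---------------------------------------------------------------------------
# input handling
# ---------------------------------------------------------------------------

def load_dataset(cfg: RunConfig) -> preprocess.STDataset:
    """Read the dataset the config points at (MTX triplet or dense matrix)."""
    for name in ("coords",):
        if cfg.coords is None or not os.path.exists(cfg.coords):
            raise FileNotFoundError(f"coordinates file not found: {cfg.coords}")
    if cfg.matrix is not None:
        if not os.path.exists(cfg.matrix):
            raise FileNotFoundError(f"matrix file not found: {cfg.matrix}")
        return preprocess.read_dense(cfg.matrix, cfg.coords)
    for attr in ("counts", "genes", "barcodes"):
        path = getattr(cfg, attr)
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"{attr} file not found: {path}")
    return preprocess.read_mtx(cfg.counts, cfg.genes, cfg.barcodes, cfg.coords)


def validate_inputs(counts: str, genes: str, barcodes: str, coords: str) -> dict:
    """Machine-readable validity report for an on-disk MTX dataset.

    Checks that ids are unique, counts are non-negative integers, and every
    barcode has a coordinate row. Failures are collected, never raised.
    """
    report: dict = {"failures": [], "n_cells": None, "n_genes": None}
    try:
        from scipy.io import mmread

        mat = sp.coo_matrix(mmread(counts))
        gene_ids = preprocess._read_lines(genes)
        cell_ids = preprocess._read_lines(barcodes)
        coord_df = preprocess.read_coordinates(coords)
    except Exception as exc:  # pragma: no cover - parse failure path
        report["failures"].append({"check": "parse", "detail": str(exc)})
        return report

    if mat.shape == (len(gene_ids), len(cell_ids)) and mat.shape[0] != mat.shape[1]:
        mat = mat.T
    report["n_cells"], report["n_genes"] = mat.shape
    if mat.shape != (len(cell_ids), len(gene_ids)):
        report["failures"].append({
            "check": "shape",
            "detail": f"matrix {mat.shape} vs {len(cell_ids)} barcodes "
                      f"x {len(gene_ids)} genes",
        })
    for name, ids in (("genes", gene_ids), ("barcodes", cell_ids)):
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            report["failures"].append({
                "check": f"duplicate_{name}",
                "detail": str(dup[dup > 1].index.tolist()[:5]),
            })
    neg = np.where(mat.data < 0)[0]
    if len(neg):
        k = neg[0]
        report["failures"].append({
            "check": "negative_count",
            "detail": f"(row={int(mat.row[k])}, col={int(mat.col[k])})",
        })
    nonint = np.where(mat.data != np.round(mat.data))[0]
    if len(nonint):
        k = nonint[0]
        report["failures"].append({
            "check": "non_integer_count",
            "detail": f"(row={int(mat.row[k])}, col={int(mat.col[k])})",
        })
    missing = [c for c in cell_ids if c not in coord_df.index]
    if missing:
        report["failures"].append({
            "check": "missing_coordinates", "detail": str(missing[:5]),
        })
    return report


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _write_csv(path: str, df: pd.DataFrame, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig, data: preprocess.STDataset | None = None
                 ) -> downstream.DownstreamResult:
    """Execute preprocess -> SEG -> train -> segment + pSM and write artifacts.

    ``data`` may be passed directly (e.g. a synthetic tissue's dataset) to
    bypass file input. Artifacts written to ``cfg.outdir``: embeddings.csv,
    domains.csv, psm.csv, loss_log.tsv, config.yaml.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stage = "input"
    try:
        if data is None:
            data = load_dataset(cfg)

        stage = "preprocess"
        features, filtered = preprocess.preprocess(
            data,
            min_cells_per_gene=cfg.min_cells_per_gene,
            min_genes_per_cell=cfg.min_genes_per_cell,
            scale_factor=cfg.scale_factor,
            n_top_hvg=cfg.n_top_hvg,
            n_bins=cfg.hvg_bins,
        )
        logger.info("preprocess: %d cells x %d HVGs", *features.X.shape)

        stage = "spatial_graph"
        seg = spatial_graph.build_graph(
            features, filtered.coords, method=cfg.graph_method,
            k=cfg.knn_k, delta=cfg.delta,
        )
        logger.info("SEG (%s): %d nodes, %d edges",
                    seg.method, seg.n_nodes, len(seg.edge_list))

        stage = "train"
        result = dgi.train(seg, cfg.train_config())
        H = result.embeddings.H

        stage = "downstream"
        labels = downstream.segment_domains(
            H, n_neighbors=cfg.n_neighbors, resolution=cfg.resolution,
            target_k=cfg.target_k, seed=cfg.seed,
        )
        root = downstream.select_root(H)
        psm = downstream.compute_psm(H, root, n_neighbors=cfg.n_neighbors,
                                     n_dcs=cfg.n_dcs)

        stage = "write"
        os.makedirs(cfg.outdir, exist_ok=True)
        h = cfg.hash
        ids = filtered.cell_ids
        dgi.write_embeddings(os.path.join(cfg.outdir, "embeddings.csv"),
                             H, ids, header=f"config={h}")
        _write_csv(os.path.join(cfg.outdir, "domains.csv"),
                   pd.DataFrame({"cell_id": ids, "domain": labels}), h)
        _write_csv(os.path.join(cfg.outdir, "psm.csv"),
                   pd.DataFrame({"cell_id": ids, "psm": psm}), h)
        with open(os.path.join(cfg.outdir, "loss_log.tsv"), "w") as fh:
            fh.write(f"# config={h}\n")
            result.loss_log.to_csv(fh, sep="\t", index=False)
        cfg.save(os.path.join(cfg.outdir, "config.yaml"))

        return downstream.DownstreamResult(
            labels=labels, psm=psm, root_index=root, n_neighbors=cfg.n_neighbors
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
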