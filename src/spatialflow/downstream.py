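"""Downstream analysis of the trained embeddings.

* **Domain segmentation** — Leiden community detection on a k-nearest-neighbor
  graph built in embedding space (neighborhood size 50 by default for smooth
  segmentations), optionally bisection-searching the resolution to hit a
  target number of domains, as done when benchmarking against an annotation.
* **pseudo-Spatiotemporal Map (pSM)** — diffusion pseudotime (DPT) on the
  embedding kNN graph, rooted at the cell with the largest summed embedding
  distance to all others; shifted to 0 at the root and max-normalized to 1.
* **Marker genes** — per-domain one-vs-rest Wilcoxon rank-sum tests
  (normal approximation with tie correction) with Benjamini-Hochberg
  correction across genes within each domain.
* **Evaluation** — the Hubert-Arabie adjusted Rand index against a reference
  partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from sklearn.neighbors import kneighbors_graph
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("spatialflow")

__all__ = [
    "DownstreamResult",
    "segment_domains",
    "select_root",
    "compute_psm",
    "rank_markers",
    "adjusted_rand_index",
]


@dataclass
class DownstreamResult:
    """Domain labels and pSM values derived from one embedding."""

    labels: np.ndarray  # int per cell, 0..K-1 by decreasing cluster size
    psm: np.ndarray  # in [0, 1]; 0 at the root
    root_index: int
    n_neighbors: int = 50


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _embedding_knn(H: np.ndarray, n_neighbors: int) -> sp.csr_matrix:
    a = kneighbors_graph(H, n_neighbors, mode="connectivity", include_self=False)
    a = a.maximum(a.T)
    return sp.csr_matrix(a)


def _leiden(adj: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    coo = sp.triu(adj, k=1).tocoo()
    g = ig.Graph(
        n=adj.shape[0], edges=list(zip(coo.row.tolist(), coo.col.tolist()))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 by decreasing size (stable on ties)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    mapping = {int(old): new for new, old in enumerate(order)}
    return np.asarray([mapping[int(l)] for l in labels])


def segment_domains(
    H: np.ndarray,
    n_neighbors: int = 50,
    resolution: float = 1.0,
    target_k: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Leiden clustering of the embedding kNN graph.

    When ``target_k`` is given, the resolution is bisection-searched in
    [1e-3, 10] (at most 40 iterations) until the number of communities equals
    ``target_k``; unreachable targets raise with the bracketing resolutions.
    Labels are renumbered 0..K-1 by decreasing cluster size.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[0] <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} cells, got {H.shape[0]}"
        )
    adj = _embedding_knn(H, n_neighbors)

    if target_k is None:
        return _relabel_by_size(_leiden(adj, resolution, seed))

    lo, hi = 1e-3, 10.0
    k_lo = len(np.unique(_leiden(adj, lo, seed)))
    k_hi = len(np.unique(_leiden(adj, hi, seed)))
    for k, res in ((k_lo, lo), (k_hi, hi)):
        if k == target_k:
            return _relabel_by_size(_leiden(adj, res, seed))
    if not (k_lo < target_k < k_hi):
        raise ValueError(
            f"target_k={target_k} unreachable: resolution {lo} gives {k_lo} "
            f"clusters, {hi} gives {k_hi}"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        labels = _leiden(adj, mid, seed)
        k_mid = len(np.unique(labels))
        if k_mid == target_k:
            return _relabel_by_size(labels)
        if k_mid < target_k:
            lo, k_lo = mid, k_mid
        else:
            hi, k_hi = mid, k_mid
    raise ValueError(
        f"target_k={target_k} unreachable after bisection: resolution {lo} "
        f"gives {k_lo} clusters, {hi} gives {k_hi}"
    )


# ---------------------------------------------------------------------------
# pseudo-spatiotemporal map
# ---------------------------------------------------------------------------

def select_root(H: np.ndarray) -> int:
    """Root cell: argmax of summed embedding distance to all other cells.

    Ties are broken by the lowest index.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    n = H.shape[0]
    if n == 1:
        return 0
    if n <= 4096:
        sums = cdist(H, H).sum(axis=1)
    else:
        sums = np.empty(n)
        for start in range(0, n, 2048):
            stop = min(start + 2048, n)
            sums[start:stop] = cdist(H[start:stop], H).sum(axis=1)
    return int(np.argmax(sums))


def compute_psm(H: np.ndarray, root: int, n_neighbors: int = 50,
                n_dcs: int = 10) -> np.ndarray:
    """Diffusion pseudotime from ``root`` on the embedding kNN graph.

    Uses the adaptive Gaussian-kernel diffusion operator and diffusion-
    distance pseudotime of scanpy (Haghverdi-style DPT) with ``n_dcs``
    diffusion components. The result is shifted so that the root is 0 and
    max-normalized to 1; cells unreachable from the root get 1. Constant
    embeddings yield an all-zero map.
    """
    import anndata
    import scanpy as sc

    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    if not 0 <= root < n:
        raise IndexError(f"root {root} out of range for {n} cells")
    if n <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} cells, got {n}"
        )
    if np.allclose(H, H[0]):
        return np.zeros(n)

    ad = anndata.AnnData(X=H.copy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(ad, n_neighbors=n_neighbors, use_rep="X", method="gauss")
        sc.tl.diffmap(ad, n_comps=min(n_dcs, n - 1))
        ad.uns["iroot"] = int(root)
        sc.tl.dpt(ad, n_dcs=min(n_dcs, n - 1))
    pt = ad.obs["dpt_pseudotime"].to_numpy(dtype=float)

    unreachable = ~np.isfinite(pt)
    if unreachable.any():
        logger.warning(
            "kNN graph disconnected: %d cells unreachable from root; "
            "their pSM is set to 1", int(unreachable.sum())
        )
    finite = pt[~unreachable]
    finite = finite - finite.min()
    mx = finite.max()
    if mx > 0:
        finite = finite / mx
    psm = np.ones(n)
    psm[~unreachable] = finite
    psm[root] = 0.0
    return psm


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------

def rank_markers(expr, labels, alpha: float = 0.01,
                 gene_ids=None) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker test per domain.

    For every domain with at least 2 cells, each gene is tested two-sided
    (normal approximation with tie correction) against all remaining cells;
    p-values are Benjamini-Hochberg adjusted across genes within the domain.
    Rows are sorted by adjusted p within each domain; ``significant`` flags
    adjusted p < ``alpha``.
    """
    X = np.asarray(expr.todense() if sp.issparse(expr) else expr, dtype=float)
    labels = np.asarray(labels)
    n, g = X.shape
    if len(labels) != n:
        raise ValueError("labels length must match expression rows")
    domains = np.unique(labels)
    if len(domains) < 2:
        raise ValueError("need at least 2 domains")
    gene_ids = (np.asarray(gene_ids, dtype=object) if gene_ids is not None
                else np.asarray([f"g{i}" for i in range(g)], dtype=object))

    frames = []
    for dom in domains:
        mask = labels == dom
        if mask.sum() < 2 or (~mask).sum() < 2:
            warnings.warn(f"domain {dom} has < 2 cells on one side; skipped")
            continue
        a, b = X[mask], X[~mask]
        with np.errstate(all="ignore"):
            res = mannwhitneyu(a, b, axis=0, alternative="two-sided",
                               method="asymptotic")
        pvals = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
        direction = np.sign(a.mean(axis=0) - b.mean(axis=0)).astype(int)
        adj = multipletests(pvals, method="fdr_bh")[1]
        df = pd.DataFrame({
            "domain": dom,
            "gene": gene_ids,
            "gene_index": np.arange(g),
            "direction": direction,
            "p": pvals,
            "adj_p": adj,
        })
        df["significant"] = df["adj_p"] < alpha
        frames.append(df.sort_values(["adj_p", "gene_index"], kind="stable"))
    if not frames:
        raise ValueError("no domain had enough cells to test")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    1 for identical partitions (up to relabeling); expectation 0 for
    independent labelings.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(ct, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    total = comb2(len(a))
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0  # both partitions trivial (all-singletons or single cluster)
    return float((sum_ij - expected) / (max_index - expected))
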