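"""Spatially regularized deep graph infomax (DGI).

The encoder is a two-layer graph convolutional network with PReLU activations
operating on the spatial expression graph (SEG). Training is contrastive: a
bilinear discriminator D(h, s) = sigmoid(h' Theta s) is asked to tell apart
embeddings of the true graph (paired with the global summary vector s, the
sigmoid of the mean embedding) from embeddings of the expression-permuted
graph (EPG). The minimized objective is

    L_total = L_DGI + gamma * R,

where L_DGI is the binary cross-entropy form of the infomax objective

    L_DGI = -(1/2N) [ sum_i log D(h_i, s) + sum_j log(1 - D(h~_j, s)) ],

and R is the spatial regularizer: with spatial distances d^(s) and embedding
distances d^(z), each max-normalized over the evaluated pair set,

    R = mean over pairs of  d^(s) * (1 - d^(z)).

R penalizes placing spatially distant cells close together in latent space.
For populations above ``pair_subsample_threshold`` the regularizer is
evaluated on a fixed-size random subset of ordered cell pairs each step,
making its cost constant in N.

The whole model is plain NumPy/SciPy: forward pass, analytically derived
backward pass (verified against finite differences in the test suite), and an
Adam optimizer. All randomness flows from the seed in :class:`TrainConfig`.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .spatial_graph import SpatialExpressionGraph, permute_features

logger = logging.getLogger("spatialflow")

__all__ = [
    "ModelState",
    "TrainConfig",
    "EmbeddingMatrix",
    "normalize_adjacency",
    "gcn_encode",
    "summary",
    "discriminate",
    "dgi_loss",
    "spatial_regularization",
    "sample_pairs",
    "train",
    "write_embeddings",
    "read_embeddings",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Trainable parameters of the encoder + discriminator."""

    W1: np.ndarray  # (n_features, latent_dim)
    W2: np.ndarray  # (latent_dim, latent_dim)
    prelu1_slope: float
    prelu2_slope: float
    Theta: np.ndarray  # (latent_dim, latent_dim) bilinear discriminator weight
    latent_dim: int = 50

    @classmethod
    def init(cls, n_features: int, latent_dim: int, rng: np.random.Generator,
             prelu_slope: float = 0.25) -> "ModelState":
        """Glorot-uniform weights, shared initial PReLU slope."""

        def glorot(fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_in, fan_out))

        return cls(
            W1=glorot(n_features, latent_dim),
            W2=glorot(latent_dim, latent_dim),
            prelu1_slope=prelu_slope,
            prelu2_slope=prelu_slope,
            Theta=glorot(latent_dim, latent_dim),
            latent_dim=latent_dim,
        )

    def copy(self) -> "ModelState":
        return copy.deepcopy(self)


@dataclass
class EmbeddingMatrix:
    """Latent embeddings H (one row per cell) with the summary vector s."""

    H: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.H)):
            raise ValueError("non-finite embedding entries")


@dataclass
class TrainConfig:
    """Training hyper-parameters; every random draw derives from ``seed``."""

    gamma: float = 0.1
    lr: float = 0.001
    max_epochs: int = 1000
    min_epochs: int = 100
    patience: int = 50
    latent_dim: int = 50
    seed: int = 0
    pair_subsample_threshold: int = 10000
    n_pairs: int | None = None  # default min(N^2, 1e6) when subsampling
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must be <= max_epochs")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def normalize_adjacency(A: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric propagation matrix D~^{-1/2} (A + I) D~^{-1/2}."""
    n = A.shape[0]
    a_tilde = sp.csr_matrix(A, dtype=float) + sp.identity(n, format="csr")
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return sp.csr_matrix(d_inv_sqrt @ a_tilde @ d_inv_sqrt)


def _prelu(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # stable for large |x|


def _forward(X: np.ndarray, A_hat: sp.csr_matrix, state: ModelState):
    """Two-layer GCN forward pass; returns H plus the caches backprop needs."""
    T1 = A_hat @ (X @ state.W1)
    H1 = _prelu(T1, state.prelu1_slope)
    T2 = A_hat @ (H1 @ state.W2)
    H = _prelu(T2, state.prelu2_slope)
    return H, (T1, H1, T2)


def gcn_encode(X: np.ndarray, A: sp.spmatrix, state: ModelState) -> np.ndarray:
    """Encode node features: H = PReLU2(A^ PReLU1(A^ X W1) W2)."""
    H, _ = _forward(np.asarray(X, dtype=float), normalize_adjacency(A), state)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite values in GCN output")
    return H


def summary(H: np.ndarray) -> np.ndarray:
    """Global readout: componentwise sigmoid of the mean embedding."""
    return _sigmoid(np.asarray(H, dtype=float).mean(axis=0))


def discriminate(h: np.ndarray, s: np.ndarray, Theta: np.ndarray) -> float:
    """Probability that embedding h belongs to the true graph: sigmoid(h' Theta s)."""
    return float(_sigmoid(np.asarray(h) @ Theta @ np.asarray(s)))


_CLAMP = 1e-7


def dgi_loss(H: np.ndarray, H_tilde: np.ndarray, s: np.ndarray,
             Theta: np.ndarray) -> float:
    """Binary cross-entropy form of the graph-infomax objective (minimized).

    L = -(1/2N)[sum_i log D(h_i,s) + sum_j log(1 - D(h~_j,s))]; probabilities
    are clamped to [1e-7, 1 - 1e-7] before the logs.
    """
    n = H.shape[0]
    ts = Theta @ s
    p_pos = np.clip(_sigmoid(H @ ts), _CLAMP, 1.0 - _CLAMP)
    p_neg = np.clip(_sigmoid(H_tilde @ ts), _CLAMP, 1.0 - _CLAMP)
    return float(-(np.log(p_pos).sum() + np.log1p(-p_neg).sum()) / (2.0 * n))


def spatial_regularization(coords: np.ndarray, H: np.ndarray,
                           pairs: tuple[np.ndarray, np.ndarray]) -> float:
    """Mean over pairs of d^(s) * (1 - d^(z)) with max-normalized distances.

    ``pairs`` is a tuple of index arrays (i, j). Over all N^2 ordered pairs
    this equals the double sum with the N*N normalizer (diagonal terms are 0).
    If the maximum of either distance set is 0 that normalized set is all-zero.
    """
    i, j = pairs
    if len(i) == 0:
        raise ValueError("pair set must be nonempty")
    ds = np.linalg.norm(coords[i] - coords[j], axis=1)
    dz = np.linalg.norm(H[i] - H[j], axis=1)
    ms, mz = ds.max(), dz.max()
    ds_hat = ds / ms if ms > 0 else np.zeros_like(ds)
    dz_hat = dz / mz if mz > 0 else np.zeros_like(dz)
    return float(np.mean(ds_hat * (1.0 - dz_hat)))


def all_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """All N^2 ordered pairs (i, j), diagonal included (it contributes 0)."""
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return i.ravel(), j.ravel()


def sample_pairs(n: int, n_pairs: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniform ordered pairs (i, j), i != j, drawn with replacement."""
    if n < 2:
        raise ValueError("need at least 2 cells")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)
    return i, j


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _reg_loss_and_grad(coords_d: np.ndarray, H: np.ndarray,
                       pairs: tuple[np.ndarray, np.ndarray] | None):
    """Regularizer value and its gradient with respect to H.

    ``coords_d`` are the precomputed spatial distances: an (m,) vector for an
    explicit pair set, or the full (N, N) distance matrix when ``pairs`` is
    None (all ordered pairs). The gradient is exact, including the path
    through the max-normalizer of the embedding distances (a single argmax
    element, as reverse-mode autodiff of a max would give).
    """
    if pairs is None:
        return _reg_all_pairs(coords_d, H)

    i, j = pairs
    m = len(i)
    ds = coords_d
    ms = ds.max()
    ds_hat = ds / ms if ms > 0 else np.zeros_like(ds)

    diff = H[i] - H[j]
    dz = np.linalg.norm(diff, axis=1)
    mz = dz.max()
    if mz == 0:
        return float(ds_hat.mean()), np.zeros_like(H)
    dz_hat = dz / mz
    loss = float(np.mean(ds_hat * (1.0 - dz_hat)))

    # dL/d dz_k = -ds_hat_k / (m * mz)  plus the argmax term:
    # dL/d mz = sum_k ds_hat_k * dz_k / (m * mz^2), routed to the argmax pair.
    g_dz = -ds_hat / (m * mz)
    kmax = int(np.argmax(dz))
    g_dz[kmax] += float(np.sum(ds_hat * dz)) / (m * mz * mz)

    safe = np.where(dz > 0, dz, 1.0)
    contrib = (g_dz / safe)[:, None] * diff  # d dz_k / dH_i = diff/dz
    n_latent = H.shape[1]
    grad = np.zeros_like(H)
    for d in range(n_latent):
        grad[:, d] = (
            np.bincount(i, weights=contrib[:, d], minlength=H.shape[0])
            - np.bincount(j, weights=contrib[:, d], minlength=H.shape[0])
        )
    return loss, grad


def _reg_all_pairs(ds_mat: np.ndarray, H: np.ndarray):
    """All-ordered-pairs regularizer in dense matrix form (cost O(N^2))."""
    n = H.shape[0]
    ms = ds_mat.max()
    ds_hat = ds_mat / ms if ms > 0 else np.zeros_like(ds_mat)

    dz = cdist(H, H)
    mz = dz.max()
    if mz == 0:
        return float(ds_hat.mean()), np.zeros_like(H)
    loss = float(np.mean(ds_hat * (1.0 - dz / mz)))

    m = n * n
    g_dz = -ds_hat / (m * mz)  # symmetric
    kmax = np.unravel_index(int(np.argmax(dz)), dz.shape)
    g_max = float(np.sum(ds_hat * dz)) / (m * mz * mz)

    # grad_H[k] = sum_l (g_dz[k,l] + g_dz[l,k]) * (h_k - h_l) / dz[k,l]
    safe = np.where(dz > 0, dz, 1.0)
    C = 2.0 * g_dz / safe
    C[kmax] += g_max / safe[kmax]
    C[kmax[::-1]] += g_max / safe[kmax]
    np.fill_diagonal(C, 0.0)
    grad = C.sum(axis=1)[:, None] * H - C @ H
    return loss, grad


def _losses_and_grads(X, Xp, A_hat, state: ModelState, gamma: float,
                      coords_d, pairs):
    """Total loss and gradients for one training step.

    Returns (dgi, reg, grads dict) where reg is None when gamma == 0.
    """
    n = X.shape[0]
    H, (T1, H1, T2) = _forward(X, A_hat, state)
    Hp, (T1p, H1p, T2p) = _forward(Xp, A_hat, state)

    m_vec = H.mean(axis=0)
    s = _sigmoid(m_vec)
    ts = state.Theta @ s
    u = H @ ts
    v = Hp @ ts
    p_pos = np.clip(_sigmoid(u), _CLAMP, 1.0 - _CLAMP)
    p_neg = np.clip(_sigmoid(v), _CLAMP, 1.0 - _CLAMP)
    loss_dgi = float(-(np.log(p_pos).sum() + np.log1p(-p_neg).sum()) / (2.0 * n))

    du = (_sigmoid(u) - 1.0) / (2.0 * n)
    dv = _sigmoid(v) / (2.0 * n)

    gH = du[:, None] * ts[None, :]
    gHp = dv[:, None] * ts[None, :]

    w = H.T @ du + Hp.T @ dv  # (latent,)
    gTheta = np.outer(w, s)
    gs = state.Theta.T @ w
    gm = gs * s * (1.0 - s)
    gH = gH + gm[None, :] / n

    loss_reg = None
    if gamma > 0:
        loss_reg, g_reg = _reg_loss_and_grad(coords_d, H, pairs)
        gH = gH + gamma * g_reg

    def back_layer(gOut, T, slope, W, upstream_T):
        """Backprop through PReLU(A^ upstream @ W); returns (dW, dslope, dUpstream)."""
        dT = gOut * np.where(T > 0, 1.0, slope)
        dslope = float(np.sum(gOut * np.where(T > 0, 0.0, T)))
        pre = A_hat @ dT  # A_hat symmetric
        dW = upstream_T.T @ pre
        dUp = pre @ W.T
        return dW, dslope, dUp

    # layer 2 (both branches share weights)
    dW2_a, da2_a, dH1 = back_layer(gH, T2, state.prelu2_slope, state.W2, H1)
    dW2_b, da2_b, dH1p = back_layer(gHp, T2p, state.prelu2_slope, state.W2, H1p)
    # layer 1
    dW1_a, da1_a, _ = back_layer(dH1, T1, state.prelu1_slope, state.W1, X)
    dW1_b, da1_b, _ = back_layer(dH1p, T1p, state.prelu1_slope, state.W1, Xp)

    grads = {
        "W1": dW1_a + dW1_b,
        "W2": dW2_a + dW2_b,
        "prelu1_slope": da1_a + da1_b,
        "prelu2_slope": da2_a + da2_b,
        "Theta": gTheta,
    }
    return loss_dgi, loss_reg, grads


class _Adam:
    """Adam optimizer over the named parameters of a ModelState."""

    def __init__(self, state: ModelState, lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(getattr(state, k), dtype=float))
                  for k in ("W1", "W2", "prelu1_slope", "prelu2_slope", "Theta")}
        self.v = {k: np.zeros_like(v) for k, v in self.m.items()}

    def step(self, state: ModelState, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            g = np.asarray(g, dtype=float)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            cur = getattr(state, k)
            if np.isscalar(cur):
                setattr(state, k, float(cur - update))
            else:
                setattr(state, k, cur - update)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    embeddings: EmbeddingMatrix
    state: ModelState
    loss_log: pd.DataFrame  # epoch, dgi, reg, total
    best_epoch: int


def train(seg: SpatialExpressionGraph, cfg: TrainConfig) -> TrainResult:
    """Train the spatially regularized DGI model on a SEG.

    Each epoch draws a fresh expression permutation (the EPG), runs both
    branches through the shared encoder, evaluates L_DGI + gamma * R, and
    takes one Adam step. Early stopping: after ``min_epochs``, stop when the
    best total loss has not improved for ``patience`` consecutive epochs. The
    returned embeddings come from the best-loss parameter snapshot.
    """
    rng = np.random.default_rng(cfg.seed)
    X = np.asarray(seg.X, dtype=float)
    n = X.shape[0]
    A_hat = normalize_adjacency(seg.A)
    state = ModelState.init(X.shape[1], cfg.latent_dim, rng)
    opt = _Adam(state, cfg.lr)

    subsample = n > cfg.pair_subsample_threshold
    if cfg.gamma > 0 and not subsample:
        pairs = None  # all ordered pairs, evaluated in matrix form
        coords_d = cdist(seg.coords, seg.coords)
    n_pairs = cfg.n_pairs if cfg.n_pairs is not None else min(n * n, 10 ** 6)

    best_loss = np.inf
    best_state = state.copy()
    best_epoch = 0
    stall = 0
    rows = []

    for epoch in range(1, cfg.max_epochs + 1):
        perm_seed = int(rng.integers(0, 2 ** 31 - 1))
        epg = permute_features(seg, seed=perm_seed)
        if cfg.gamma > 0 and subsample:
            pairs = sample_pairs(n, n_pairs, rng)
            coords_d = np.linalg.norm(
                seg.coords[pairs[0]] - seg.coords[pairs[1]], axis=1
            )
        elif cfg.gamma == 0:
            pairs, coords_d = None, None

        loss_dgi, loss_reg, grads = _losses_and_grads(
            X, epg.X_tilde, A_hat, state, cfg.gamma, coords_d, pairs
        )
        total = loss_dgi + (cfg.gamma * loss_reg if loss_reg is not None else 0.0)
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: dgi={loss_dgi}, reg={loss_reg}"
            )
        rows.append((epoch, loss_dgi, loss_reg if loss_reg is not None else np.nan,
                     total))

        if total < best_loss:
            best_loss, best_epoch, stall = total, epoch, 0
            best_state = state.copy()
        else:
            stall += 1
        if epoch >= cfg.min_epochs and stall >= cfg.patience:
            logger.info("early stopping at epoch %d (best %d)", epoch, best_epoch)
            break

        opt.step(state, grads)

    H, _ = _forward(X, A_hat, best_state)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite embeddings after training")
    log = pd.DataFrame(rows, columns=["epoch", "dgi_loss", "reg_loss", "total_loss"])
    return TrainResult(
        embeddings=EmbeddingMatrix(H=H, s=summary(H)),
        state=best_state,
        loss_log=log,
        best_epoch=best_epoch,
    )


# ---------------------------------------------------------------------------
# embedding I/O
# ---------------------------------------------------------------------------

def write_embeddings(path: str, H: np.ndarray, cell_ids, header: str | None = None
                     ) -> None:
    """CSV with cell_id + one column per latent dimension."""
    df = pd.DataFrame(H, columns=[f"z{c}" for c in range(H.shape[1])])
    df.insert(0, "cell_id", list(cell_ids))
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)


def read_embeddings(path: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    ids = df["cell_id"].to_numpy(dtype=object)
    return df.drop(columns="cell_id").to_numpy(dtype=float), ids
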