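"""Cross-modal contrastive alignment of Hi-C and epigenomic representations.

Two small MLP encoders — a structural encoder over LINE Hi-C embeddings and a
functional encoder over the binned epigenomic feature vector — are trained
jointly so that the embeddings of the same genomic bin agree. The objective
is a bidirectional InfoNCE loss over cosine similarities: within a batch,
bin i's structural embedding must identify bin i's functional embedding
among all batch members (row direction) and vice versa (column direction).

Everything here is plain NumPy with hand-written backpropagation and Adam,
which keeps the package dependency-light and makes the analytic gradients
directly testable against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EncoderConfig",
    "PairedEmbeddings",
    "cosine_similarity_matrix",
    "info_nce_bidirectional",
    "info_nce_gradients",
    "init_encoder",
    "encoder_forward",
    "train_contrastive",
]


@dataclass
class EncoderConfig:
    """Architecture and optimization settings shared by both encoders.

    ``out_dim`` (d) is identical for the structural and functional encoder by
    construction; ``temperature`` is the fixed InfoNCE temperature tau. A soft temperature
    (default 1.0) keeps the alignment task from over-discriminating individual
    bins, which would erase domain-level structure.
    """

    hidden_dims: tuple[int, ...] = (256, 256)
    out_dim: int = 64
    activation: str = "relu"
    temperature: float = 1.0
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class PairedEmbeddings:
    """Row-aligned structural (S) and functional (F) embeddings.

    Row i of both matrices refers to the same genomic bin (masked-in bins in
    genome order).
    """

    S: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.S.shape != self.F.shape:
            raise ValueError(
                f"S and F must have the same shape, got {self.S.shape} vs {self.F.shape}"
            )

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def d(self) -> int:
        return self.S.shape[1]


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-norm row encountered in cosine similarity")
    return X / norms[:, None], norms


def cosine_similarity_matrix(S: np.ndarray, F: np.ndarray) -> np.ndarray:
    """All-pairs cosine similarities; entry (i, j) = cos(s_i, f_j)."""
    S = np.asarray(S, dtype=float)
    F = np.asarray(F, dtype=float)
    if S.shape[1] != F.shape[1]:
        raise ValueError("S and F must have the same embedding dimension")
    S_hat, _ = _normalize_rows(S)
    F_hat, _ = _normalize_rows(F)
    return S_hat @ F_hat.T


def _softmax(X: np.ndarray, axis: int) -> np.ndarray:
    Z = X - X.max(axis=axis, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=axis, keepdims=True)


def info_nce_bidirectional(S: np.ndarray, F: np.ndarray, tau: float) -> float:
    """Bidirectional InfoNCE loss over cosine similarities.

    With C the cosine-similarity matrix scaled by 1/tau, returns the mean of
    the row-wise and column-wise cross-entropies of the diagonal (matched
    pairs as positives, all in-batch mismatches as negatives):

        1/2 [ mean_i(-log softmax_row(C)_ii) + mean_j(-log softmax_col(C)_jj) ]

    Nonnegative; exactly 0 for n = 1.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    C = cosine_similarity_matrix(S, F) / tau
    n = C.shape[0]
    # -log softmax, stably: logsumexp - diagonal
    row_lse = np.logaddexp.reduce(C, axis=1)
    col_lse = np.logaddexp.reduce(C, axis=0)
    d = np.diagonal(C)
    return float(0.5 * ((row_lse - d).mean() + (col_lse - d).mean()))


def info_nce_gradients(
    S: np.ndarray, F: np.ndarray, tau: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss and its analytic gradients with respect to S and F."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    S = np.asarray(S, dtype=float)
    F = np.asarray(F, dtype=float)
    S_hat, s_norm = _normalize_rows(S)
    F_hat, f_norm = _normalize_rows(F)
    C = (S_hat @ F_hat.T) / tau
    n = C.shape[0]
    P = _softmax(C, axis=1)
    Q = _softmax(C, axis=0)
    I = np.eye(n)
    dC = (P + Q - 2.0 * I) / (2.0 * n)
    dS_hat = (dC @ F_hat) / tau
    dF_hat = (dC.T @ S_hat) / tau
    # backprop through row normalization x_hat = x / ||x||
    dS = (dS_hat - (dS_hat * S_hat).sum(axis=1, keepdims=True) * S_hat) / s_norm[:, None]
    dF = (dF_hat - (dF_hat * F_hat).sum(axis=1, keepdims=True) * F_hat) / f_norm[:, None]
    row_lse = np.logaddexp.reduce(C, axis=1)
    col_lse = np.logaddexp.reduce(C, axis=0)
    diag = np.diagonal(C)
    loss = float(0.5 * ((row_lse - diag).mean() + (col_lse - diag).mean()))
    return loss, dS, dF


# ---------------------------------------------------------------------------
# MLP encoder: list of (W, b) layers, affine -> activation per hidden layer,
# final affine to out_dim.
# ---------------------------------------------------------------------------

def init_encoder(
    rng: np.random.Generator, in_dim: int, config: EncoderConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """He-initialized MLP parameters for one encoder."""
    dims = [in_dim, *config.hidden_dims, config.out_dim]
    params = []
    for a, b in zip(dims[:-1], dims[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
        params.append((W, np.zeros(b)))
    return params


def _activate(X: np.ndarray, activation: str) -> np.ndarray:
    return np.maximum(X, 0.0) if activation == "relu" else np.tanh(X)


def encoder_forward(
    config: EncoderConfig,
    params: list[tuple[np.ndarray, np.ndarray]],
    X: np.ndarray,
    return_cache: bool = False,
):
    """Deterministic MLP forward pass; optionally keeps the backprop cache."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params[0][0].shape[0]:
        raise ValueError(
            f"input has shape {X.shape}, encoder expects {params[0][0].shape[0]} columns"
        )
    cache = []
    H = X
    for li, (W, b) in enumerate(params):
        Z = H @ W + b
        if li < len(params) - 1:
            A = _activate(Z, config.activation)
        else:
            A = Z
        cache.append((H, Z))
        H = A
    if return_cache:
        return H, cache
    return H


def _encoder_backward(
    config: EncoderConfig,
    params: list[tuple[np.ndarray, np.ndarray]],
    cache: list[tuple[np.ndarray, np.ndarray]],
    grad_out: np.ndarray,
) -> list[tuple[np.ndarray, np.ndarray]]:
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(params)  # type: ignore
    G = grad_out
    for li in range(len(params) - 1, -1, -1):
        H, Z = cache[li]
        if li < len(params) - 1:
            if config.activation == "relu":
                G = G * (Z > 0)
            else:
                G = G * (1.0 - np.tanh(Z) ** 2)
        W, _ = params[li]
        grads[li] = (H.T @ G, G.sum(axis=0))
        G = G @ W.T
    return grads


def train_contrastive(
    hic_features: np.ndarray,
    signal_features: np.ndarray,
    config: EncoderConfig,
) -> tuple[PairedEmbeddings, np.ndarray]:
    """Jointly train the structural and functional encoders.

    Parameters
    ----------
    hic_features
        n x p matrix of LINE Hi-C embeddings for masked-in bins, genome order.
    signal_features
        n x t matrix of normalized epigenomic signals, same rows.
    config
        Shared architecture/optimization settings.

    Returns
    -------
    (PairedEmbeddings, loss_history)
        Final structural/functional embeddings for all input rows and the
        per-epoch mean InfoNCE loss. Fully reproducible for a fixed seed.
    """
    Xs = np.asarray(hic_features, dtype=float)
    Xf = np.asarray(signal_features, dtype=float)
    if Xs.shape[0] != Xf.shape[0]:
        raise ValueError("structural and functional inputs must have equal row counts")
    n = Xs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 usable bins to form contrastive negatives")

    rng = np.random.default_rng(config.seed)
    p_s = init_encoder(rng, Xs.shape[1], config)
    p_f = init_encoder(rng, Xf.shape[1], config)
    opt_s = _AdamSimple(p_s, config.lr)
    opt_f = _AdamSimple(p_f, config.lr)

    history = []
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        batch_losses = []
        bs = config.batch_size if config.batch_size and config.batch_size >= 2 else n
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            if len(idx) < 2:
                continue  # a singleton batch has no negatives
            S, cache_s = encoder_forward(config, p_s, Xs[idx], return_cache=True)
            F, cache_f = encoder_forward(config, p_f, Xf[idx], return_cache=True)
            loss, dS, dF = info_nce_gradients(S, F, config.temperature)
            g_s = _encoder_backward(config, p_s, cache_s, dS)
            g_f = _encoder_backward(config, p_f, cache_f, dF)
            p_s = opt_s.step(p_s, g_s)
            p_f = opt_f.step(p_f, g_f)
            batch_losses.append(loss)
        history.append(float(np.mean(batch_losses)))

    S = encoder_forward(config, p_s, Xs)
    F = encoder_forward(config, p_f, Xf)
    return PairedEmbeddings(S=S, F=F), np.asarray(history)


class _AdamSimple:
    """Adam with bias correction over (W, b) parameter lists."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.mW = [np.zeros_like(W) for W, _ in params]
        self.mb = [np.zeros_like(b) for _, b in params]
        self.vW = [np.zeros_like(W) for W, _ in params]
        self.vb = [np.zeros_like(b) for _, b in params]

    def step(self, params, grads):
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        out = []
        for k, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
            self.mW[k] = self.b1 * self.mW[k] + (1 - self.b1) * gW
            self.mb[k] = self.b1 * self.mb[k] + (1 - self.b1) * gb
            self.vW[k] = self.b2 * self.vW[k] + (1 - self.b2) * gW**2
            self.vb[k] = self.b2 * self.vb[k] + (1 - self.b2) * gb**2
            W = W - self.lr * (self.mW[k] / c1) / (np.sqrt(self.vW[k] / c2) + self.eps)
            b = b - self.lr * (self.mb[k] / c1) / (np.sqrt(self.vb[k] / c2) + self.eps)
            out.append((W, b))
        return out
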