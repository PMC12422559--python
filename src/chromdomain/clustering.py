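"""Domain-type assignment: concatenate aligned embeddings, run K-means.

The structural and functional embeddings of each bin are concatenated into a
2d-dimensional vector and partitioned into K groups by K-means (default
K = 6). Cluster labels are then reordered by transcriptional activity so
that C1 is the most active domain type and CK the least, mirroring the usual
active-to-inactive presentation of chromatin domain catalogs.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .core import NA_LABEL, BinTable, DomainAnnotation
from .contrastive import PairedEmbeddings

__all__ = [
    "concat_embeddings",
    "kmeans_cluster",
    "annotate",
    "order_labels_by_activity",
]


def concat_embeddings(pe: PairedEmbeddings, l2_normalize_halves: bool = False) -> np.ndarray:
    """Row-wise concatenation [s_i ; f_i] -> n x 2d feature matrix.

    With ``l2_normalize_halves`` each half is L2-normalized first, so that
    K-means distances weight the two modalities equally regardless of their
    embedding scales.
    """
    S, F = pe.S, pe.F
    if l2_normalize_halves:
        def _norm(X):
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            return X / norms

        S, F = _norm(S), _norm(F)
    return np.concatenate([S, F], axis=1)


def kmeans_cluster(X: np.ndarray, K: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Best-of-``n_init`` K-means++; returns labels in 1..K.

    Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < K:
        raise ValueError(f"cannot form {K} clusters from {X.shape[0]} points")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=int(seed) % (2**31))
    return km.fit_predict(X).astype(np.int64) + 1


def annotate(bins: BinTable, labels: np.ndarray, mask: np.ndarray) -> DomainAnnotation:
    """Place cluster labels of masked-in bins into genome order, NA elsewhere."""
    labels = np.asarray(labels, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    if labels.shape[0] != int(mask.sum()):
        raise ValueError(
            f"{labels.shape[0]} labels for {int(mask.sum())} masked-in bins"
        )
    full = np.full(bins.n_bins, NA_LABEL, dtype=np.int64)
    full[mask] = labels
    K = int(labels.max()) if labels.size else 0
    return DomainAnnotation(labels=full, K=max(K, 1), bins=bins)


def order_labels_by_activity(
    ann: DomainAnnotation, activity: np.ndarray
) -> DomainAnnotation:
    """Relabel clusters so C1 has the highest mean activity, CK the lowest.

    ``activity`` is a per-bin vector (e.g. a z-scored H3K27ac track or gene
    expression); only labeled bins contribute. Ties are broken by cluster
    size, larger first. Cluster memberships are unchanged — this is a pure
    relabeling.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.shape[0] != ann.bins.n_bins:
        raise ValueError("activity vector length must equal number of bins")
    lab = ann.labels
    stats = []
    for k in range(1, ann.K + 1):
        members = lab == k
        size = int(members.sum())
        vals = activity[members]
        vals = vals[np.isfinite(vals)]
        mean = float(vals.mean()) if vals.size else -np.inf
        stats.append((k, mean, size))
    # highest mean first; ties by size descending, then stable by old label
    order = sorted(stats, key=lambda t: (-t[1], -t[2], t[0]))
    remap = {old: new for new, (old, _, _) in enumerate(order, start=1)}
    new_labels = lab.copy()
    for old, new in remap.items():
        new_labels[lab == old] = new
    return DomainAnnotation(labels=new_labels, K=ann.K, bins=ann.bins)
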