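"""LINE graph embedding of Hi-C contact maps.

The contact matrix is read as a weighted undirected graph over usable bins
and embedded with LINE: edges are drawn with probability proportional to
weight via an O(1) alias sampler, negatives with probability proportional to
(weighted) degree^0.75, and vertex/context vectors are updated by SGD on the
negative-sampling objective with a linearly decaying learning rate. The
second-order variant (separate context vectors) is the default; first-order
proximity is available via ``order="first"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightedGraph",
    "AliasTable",
    "EmbeddingMatrix",
    "build_graph",
    "build_alias_table",
    "line_edge_loss",
    "train_line",
]


@dataclass
class WeightedGraph:
    """Undirected weighted graph; each edge stored once with i < j."""

    n_nodes: int
    i: np.ndarray
    j: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.w)):
            raise ValueError("edge arrays must have equal length")
        if (self.i == self.j).any():
            raise ValueError("self-loops are not allowed")
        if (self.w <= 0).any():
            raise ValueError("edge weights must be positive")

    @property
    def n_edges(self) -> int:
        return len(self.w)

    def degrees(self) -> np.ndarray:
        """Weighted degree per node."""
        deg = np.zeros(self.n_nodes)
        np.add.at(deg, self.i, self.w)
        np.add.at(deg, self.j, self.w)
        return deg


@dataclass
class EmbeddingMatrix:
    """Bin-by-dimension real embedding; row order matches the BinTable."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("embedding must be 2-D")
        if not np.isfinite(v).all():
            raise ValueError("embedding has non-finite entries")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def build_graph(contacts, mask: np.ndarray | None = None, top_k: int | None = None) -> WeightedGraph:
    """Weighted graph over masked-in bins from a contact matrix.

    Every unordered pair of masked-in bins with positive contact weight
    becomes an edge; the diagonal is ignored. With ``top_k``, each node keeps
    only its ``top_k`` heaviest incident edges and the retained edge set is
    the union over endpoints (an edge survives if either endpoint ranks it).
    """
    v = contacts.values
    n = v.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    keep = (v[iu, ju] > 0) & mask[iu] & mask[ju]
    i, j, w = iu[keep], ju[keep], v[iu, ju][keep]
    if len(w) == 0:
        raise ValueError("empty graph: no positive off-diagonal contacts among usable bins")
    if top_k is not None:
        if top_k <= 0:
            raise ValueError("top_k must be positive")
        selected = np.zeros(len(w), dtype=bool)
        incident: dict[int, list[int]] = {}
        for e, (a, b) in enumerate(zip(i, j)):
            incident.setdefault(int(a), []).append(e)
            incident.setdefault(int(b), []).append(e)
        for edges in incident.values():
            ew = w[edges]
            order = np.argsort(-ew, kind="stable")[:top_k]
            selected[np.asarray(edges)[order]] = True
        i, j, w = i[selected], j[selected], w[selected]
    return WeightedGraph(n_nodes=n, i=i, j=j, w=w)


@dataclass
class AliasTable:
    """Walker alias table for O(1) sampling from a discrete distribution."""

    prob: np.ndarray
    alias: np.ndarray

    def sample(self, rng: np.random.Generator, size: int | tuple[int, ...]) -> np.ndarray:
        n = len(self.prob)
        idx = rng.integers(0, n, size=size)
        accept = rng.random(size=size) < self.prob[idx]
        return np.where(accept, idx, self.alias[idx])


def build_alias_table(weights: np.ndarray) -> AliasTable:
    """Construct an alias table; sampling frequency is weight / sum(weights)."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight vector")
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")
    n = len(w)
    p = w * n / w.sum()
    prob = np.zeros(n)
    alias = np.zeros(n, dtype=np.int64)
    small = [i for i in range(n) if p[i] < 1.0]
    large = [i for i in range(n) if p[i] >= 1.0]
    p = p.copy()
    while small and large:
        s = small.pop()
        l = large.pop()
        prob[s] = p[s]
        alias[s] = l
        p[l] = p[l] - (1.0 - p[s])
        (small if p[l] < 1.0 else large).append(l)
    for rest in (large, small):
        for i in rest:
            prob[i] = 1.0
            alias[i] = i
    return AliasTable(prob=prob, alias=alias)


def _log1pexp(x: np.ndarray) -> np.ndarray:
    # -log sigmoid(x) = log(1 + e^{-x}), computed stably
    return np.logaddexp(0.0, -x)


def line_edge_loss(u_i: np.ndarray, v_j: np.ndarray, neg_ctx: list[np.ndarray] | np.ndarray = ()) -> float:
    """Negative-sampling objective for one edge.

    ``-log sigma(u_i . v_j) - sum_k log sigma(-u_i . v_k)`` with ``sigma``
    the logistic function.
    """
    u = np.asarray(u_i, dtype=float)
    v = np.asarray(v_j, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u_i and v_j must have the same dimension")
    loss = float(_log1pexp(np.array(u @ v)))
    for vk in neg_ctx:
        vk = np.asarray(vk, dtype=float)
        if vk.shape != u.shape:
            raise ValueError("negative context dimension mismatch")
        loss += float(_log1pexp(np.array(-(u @ vk))))
    return loss


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_line(
    graph: WeightedGraph,
    dim: int = 8,
    order: str = "second",
    n_samples: int = 1_000_000,
    n_negatives: int = 5,
    lr: float = 0.025,
    seed: int = 0,
    batch_size: int = 1024,
    return_loss: bool = False,
):
    """Train LINE embeddings by edge-sampled SGD.

    Edges are drawn from an alias table with probability proportional to
    weight, each draw oriented uniformly at random (an undirected edge acts
    as two directed ones); negatives are drawn proportional to weighted
    degree^0.75. The learning rate decays linearly from ``lr`` to
    ``lr / 100`` over the sample budget. Updates are applied in mini-batches
    with scatter-add, an in-memory stand-in for LINE's asynchronous SGD.

    Returns an :class:`EmbeddingMatrix` whose rows follow graph node order;
    nodes with no incident edge (masked-out bins) get zero rows. Bitwise
    reproducible for a fixed seed.
    """
    if order not in ("first", "second"):
        raise ValueError(f"unknown LINE order {order!r}")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")

    # canonical edge order so embeddings do not depend on input edge ordering
    edge_order = np.lexsort((graph.j, graph.i))
    ei, ej, ew = graph.i[edge_order], graph.j[edge_order], graph.w[edge_order]

    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    emb = (rng.random((n, dim)) - 0.5) / dim
    ctx = np.zeros((n, dim)) if order == "second" else emb

    edge_table = build_alias_table(ew)
    deg = np.zeros(n)
    np.add.at(deg, ei, ew)
    np.add.at(deg, ej, ew)
    active = np.flatnonzero(deg > 0)
    noise_table = build_alias_table(deg[active] ** 0.75)

    # scatter-add applies a whole batch as one step, so cap the batch at the
    # edge count: on tiny graphs the same few nodes would otherwise absorb
    # hundreds of summed gradients at once and diverge
    batch_size = max(1, min(batch_size, graph.n_edges))

    losses = []
    done = 0
    while done < n_samples:
        b = min(batch_size, n_samples - done)
        e = edge_table.sample(rng, b)
        src, dst = ei[e].copy(), ej[e].copy()
        flip = rng.random(b) < 0.5
        src[flip], dst[flip] = dst[flip], src[flip]
        neg = active[noise_table.sample(rng, (b, n_negatives))]

        cur_lr = lr * (1.0 - 0.99 * (done / n_samples))
        u = emb[src]                      # (b, d)
        vpos = ctx[dst]                   # (b, d)
        vneg = ctx[neg]                   # (b, K, d)

        s_pos = np.einsum("bd,bd->b", u, vpos)
        s_neg = np.einsum("bd,bkd->bk", u, vneg)
        g_pos = _sigmoid(s_pos) - 1.0     # d loss / d s_pos
        g_neg = _sigmoid(s_neg)           # d loss / d s_neg

        grad_u = g_pos[:, None] * vpos + np.einsum("bk,bkd->bd", g_neg, vneg)
        grad_vpos = g_pos[:, None] * u
        grad_vneg = g_neg[:, :, None] * u[:, None, :]

        np.add.at(emb, src, -cur_lr * grad_u)
        target = ctx if order == "second" else emb
        np.add.at(target, dst, -cur_lr * grad_vpos)
        np.add.at(target, neg.ravel(), -cur_lr * grad_vneg.reshape(-1, dim))

        losses.append(float(np.mean(_log1pexp(s_pos) + _log1pexp(-s_neg).sum(axis=1))))
        done += b

    emb = emb.copy()
    emb[deg == 0] = 0.0
    result = EmbeddingMatrix(values=emb)
    if return_loss:
        return result, np.asarray(losses)
    return result
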