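"""Quantitative evaluation of chromatin-domain annotations.

Implements the battery used to judge domain catalogs against continuous
genomic readouts and against each other:

* variance explained (VE) — one-way ANOVA R² of a continuous track
  (gene expression, replication timing, individual input signals) given the
  categorical annotation;
* observed/expected (O/E) ratio for chromatin loops — how much more often
  loop anchors share a domain type than under a label-permutation null;
* fold enrichment — median signal within a domain type over the global
  median;
* adjusted Rand index and overlap matrices between two annotations;
* domain coverage and mean contiguous-segment lengths.

Bins without a label (NA) are excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NA_LABEL, DomainAnnotation, LoopSet, SignalMatrix

__all__ = [
    "OverlapMatrix",
    "variance_explained",
    "per_signal_ve",
    "normalize_ve_across_annotations",
    "loop_oe_ratio",
    "fold_enrichment",
    "adjusted_rand_index",
    "overlap_matrix",
    "domain_coverage",
    "mean_segment_length",
]


def variance_explained(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA R²: between-class sum of squares over total sum of squares.

    ``values`` may contain NaN and ``labels`` NA; such positions are dropped
    pairwise. Returns 0.0 when the total variance is zero. Invariant to
    positive affine transforms of ``values`` and to renaming of labels.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    ok = np.isfinite(values) & (labels != NA_LABEL)
    if not ok.any():
        raise ValueError("no usable (value, label) pairs")
    x = values[ok]
    g = labels[ok]
    if x.size < 2:
        raise ValueError("need at least 2 usable (value, label) pairs")
    grand = x.mean()
    sst = float(((x - grand) ** 2).sum())
    if sst == 0.0:
        return 0.0
    ssb = 0.0
    for k in np.unique(g):
        xk = x[g == k]
        ssb += xk.size * (xk.mean() - grand) ** 2
    return float(min(max(ssb / sst, 0.0), 1.0))


def per_signal_ve(signals, ann: DomainAnnotation) -> np.ndarray:
    """VE of each track (or embedding component) given the annotation.

    ``signals`` may be a :class:`SignalMatrix` (its mask is respected) or a
    plain bin-by-column matrix such as a LINE embedding.
    """
    if isinstance(signals, SignalMatrix):
        values = signals.values
        usable = signals.mask
    else:
        values = np.asarray(getattr(signals, "values", signals), dtype=float)
        usable = np.ones(values.shape[0], dtype=bool)
    if values.shape[0] != ann.bins.n_bins:
        raise ValueError("signals and annotation refer to different bin tables")
    labels = np.where(usable, ann.labels, NA_LABEL)
    return np.array(
        [variance_explained(values[:, t], labels) for t in range(values.shape[1])]
    )


def normalize_ve_across_annotations(ve_table: np.ndarray) -> np.ndarray:
    """Divide each column (signal) by its maximum across annotations (rows).

    Used to compare how strongly different annotation methods capture each
    signal on a common [0, 1] scale; all-zero columns stay zero.
    """
    ve = np.asarray(ve_table, dtype=float)
    if (ve < 0).any():
        raise ValueError("VE values must be nonnegative")
    out = ve.copy()
    colmax = ve.max(axis=0)
    nz = colmax > 0
    out[:, nz] = ve[:, nz] / colmax[nz]
    return out


def loop_oe_ratio(
    loops: LoopSet,
    ann: DomainAnnotation,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> float:
    """Observed/expected ratio of same-domain loops.

    Observed: number of loops whose two anchor bins carry the same domain
    label. Expected: the mean of that count over ``n_perm`` uniform random
    permutations of the per-bin labels (anchors keep their genomic
    positions). ``method="closed_form"`` instead uses the analytic
    permutation expectation ``L * sum_k c_k^2`` with ``c_k`` the label
    fractions. Loops with an unlabeled anchor or with both anchors in the
    same bin are dropped (and counted). Returns NaN when the expectation is
    zero.
    """
    if loops.resolved is None:
        raise ValueError("loops must be resolved to bin pairs first")
    if method not in ("permutation", "closed_form"):
        raise ValueError(f"unknown O/E method {method!r}")
    lab = ann.labels
    pairs = loops.resolved
    valid = (
        (lab[pairs[:, 0]] != NA_LABEL)
        & (lab[pairs[:, 1]] != NA_LABEL)
        & (pairs[:, 0] != pairs[:, 1])
    )
    pairs = pairs[valid]
    if len(pairs) == 0:
        raise ValueError("no loops with both anchors on distinct labeled bins")
    observed = int((lab[pairs[:, 0]] == lab[pairs[:, 1]]).sum())

    labeled_pos = np.flatnonzero(lab != NA_LABEL)
    labeled = lab[labeled_pos]
    rank = np.full(len(lab), -1, dtype=np.int64)
    rank[labeled_pos] = np.arange(len(labeled_pos))
    ai, aj = rank[pairs[:, 0]], rank[pairs[:, 1]]

    if method == "closed_form":
        c = np.bincount(labeled)[1:] / len(labeled)
        expected = len(pairs) * float((c**2).sum())
    else:
        rng = np.random.default_rng(seed)
        m = len(labeled)
        total = 0
        for _ in range(n_perm):
            perm = labeled[rng.permutation(m)]
            total += int((perm[ai] == perm[aj]).sum())
        expected = total / n_perm
    if expected == 0:
        return float("nan")
    return observed / expected


def fold_enrichment(signals: SignalMatrix, ann: DomainAnnotation) -> np.ndarray:
    """K x n_tracks fold enrichment of median signal per domain type.

    Entry (k, t) is the median of track t over bins labeled k divided by the
    median of track t over all labeled bins. A zero global median yields a
    NaN column; an empty domain type yields a NaN row. Invariant to positive
    rescaling of a track.
    """
    if signals.n_bins != ann.bins.n_bins:
        raise ValueError("signals and annotation refer to different bin tables")
    usable = signals.mask & ann.assigned
    out = np.full((ann.K, signals.n_tracks), np.nan)
    if not usable.any():
        return out
    global_med = np.median(signals.values[usable], axis=0)
    for k in range(1, ann.K + 1):
        members = usable & (ann.labels == k)
        if not members.any():
            continue
        med = np.median(signals.values[members], axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            row = np.where(global_med != 0, med / global_med, np.nan)
        out[k - 1] = row
    return out


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected pair-counting similarity between two labelings.

    Computed from the contingency table:
        ARI = (index - expected) / (max_index - expected)
    with index = sum_ij C(n_ij, 2). Positions where either labeling is NA
    (or NaN) are dropped pairwise. 1.0 for identical partitions, about 0 for
    independent ones.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")

    def _ok(x):
        if x.dtype.kind == "f":
            return np.isfinite(x) & (x != NA_LABEL)
        return x != NA_LABEL

    ok = _ok(a) & _ok(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 jointly labeled positions")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    index = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((index - expected) / (max_index - expected))


@dataclass
class OverlapMatrix:
    """Co-occupancy of domain types between two annotations.

    ``raw[p, q]`` counts bins labeled p in annotation A and q in annotation
    B; ``values`` carries the row- or column-normalized rates (or the raw
    counts for ``normalization="none"``).
    """

    values: np.ndarray
    raw: np.ndarray
    normalization: str


def overlap_matrix(
    a: DomainAnnotation, b: DomainAnnotation, normalization: str = "row"
) -> OverlapMatrix:
    """Count co-labeled bins between two annotations on the same bin table."""
    if normalization not in ("row", "column", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if a.bins != b.bins:
        raise ValueError("annotations refer to different bin tables")
    ok = a.assigned & b.assigned
    raw = np.zeros((a.K, b.K), dtype=np.int64)
    np.add.at(raw, (a.labels[ok] - 1, b.labels[ok] - 1), 1)
    vals = raw.astype(float)
    if normalization == "row":
        tot = vals.sum(axis=1, keepdims=True)
        np.divide(vals, tot, out=vals, where=tot > 0)
    elif normalization == "column":
        tot = vals.sum(axis=0, keepdims=True)
        np.divide(vals, tot, out=vals, where=tot > 0)
    return OverlapMatrix(values=vals, raw=raw, normalization=normalization)


def domain_coverage(ann: DomainAnnotation) -> np.ndarray:
    """Number of bins per domain type (NA excluded)."""
    counts = np.zeros(ann.K, dtype=np.int64)
    lab = ann.labels[ann.assigned]
    if lab.size:
        bc = np.bincount(lab, minlength=ann.K + 1)
        counts = bc[1 : ann.K + 1]
    return counts


def mean_segment_length(ann: DomainAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """Mean length of maximal same-label runs, per domain type.

    Runs are broken at chromosome boundaries and at NA bins. Returns two
    K-vectors: mean run length in bins and in base pairs (bins × bin_size).
    Types with no run are NaN.
    """
    lab = ann.labels
    chrom = ann.bins.chrom_index
    runs: dict[int, list[int]] = {k: [] for k in range(1, ann.K + 1)}
    cur_label, cur_len, cur_chrom = None, 0, None
    for i in range(len(lab)):
        li, ci = int(lab[i]), int(chrom[i])
        if li == cur_label and ci == cur_chrom and li != NA_LABEL:
            cur_len += 1
        else:
            if cur_label is not None and cur_label != NA_LABEL:
                runs[cur_label].append(cur_len)
            cur_label, cur_len, cur_chrom = li, 1, ci
    if cur_label is not None and cur_label != NA_LABEL:
        runs[cur_label].append(cur_len)
    mean_bins = np.array(
        [np.mean(runs[k]) if runs[k] else np.nan for k in range(1, ann.K + 1)]
    )
    return mean_bins, mean_bins * ann.bins.bin_size
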