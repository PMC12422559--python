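"""Core data containers and preprocessing for binned chromatin data.

The genome is partitioned into fixed-width bins (100 kb by default); every
other object in the package — contact matrices, signal tracks, embeddings and
domain annotations — is indexed by the resulting :class:`BinTable`.
Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NA_LABEL",
    "BinTable",
    "ContactMatrix",
    "SignalMatrix",
    "DomainAnnotation",
    "LoopSet",
    "bin_genome",
    "compute_bin_mask",
    "normalize_signals",
    "oe_transform",
]

#: Sentinel for bins excluded from annotation (masked-out / unassignable).
NA_LABEL = -1


@dataclass(frozen=True)
class BinTable:
    """Ordered genomic bins at fixed resolution.

    Bins are non-overlapping, sorted by (chromosome order, start), with
    ``end - start == bin_size`` everywhere except possibly the terminal bin
    of each chromosome, which is truncated at the chromosome end.
    """

    chroms: tuple[str, ...]
    chrom_index: np.ndarray  # per-bin index into ``chroms``
    start: np.ndarray
    end: np.ndarray
    bin_size: int

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def chrom_names(self) -> np.ndarray:
        """Per-bin chromosome name array."""
        return np.asarray(self.chroms, dtype=object)[self.chrom_index]

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous bin-index slice covering one chromosome."""
        ci = self.chroms.index(chrom)
        idx = np.flatnonzero(self.chrom_index == ci)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def bin_at(self, chrom: str, pos: int) -> int | None:
        """Index of the bin containing ``pos`` on ``chrom``, or None."""
        if chrom not in self.chroms:
            return None
        sl = self.chrom_slice(chrom)
        if pos < 0 or pos >= self.end[sl.stop - 1]:
            return None
        return sl.start + int(pos // self.bin_size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom_names, "start": self.start, "end": self.end}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinTable):
            return NotImplemented
        return (
            self.chroms == other.chroms
            and self.bin_size == other.bin_size
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
            and np.array_equal(self.chrom_index, other.chrom_index)
        )

    __hash__ = None  # type: ignore[assignment]


def bin_genome(chrom_sizes: list[tuple[str, int]], bin_size: int) -> BinTable:
    """Partition chromosomes into fixed-width bins.

    Parameters
    ----------
    chrom_sizes
        Ordered ``(name, length)`` pairs, lengths in base pairs.
    bin_size
        Bin width in base pairs (the method's native resolution is 100 kb).

    Returns
    -------
    BinTable
        ``ceil(length / bin_size)`` bins per chromosome; the final bin of
        each chromosome is truncated at the chromosome end.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    names = [n for n, _ in chrom_sizes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate chromosome name(s): {dupes}")
    chrom_index, starts, ends = [], [], []
    for ci, (name, length) in enumerate(chrom_sizes):
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        s = np.arange(0, length, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, length)
        starts.append(s)
        ends.append(e)
        chrom_index.append(np.full(len(s), ci, dtype=np.int64))
    return BinTable(
        chroms=tuple(names),
        chrom_index=np.concatenate(chrom_index),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
        bin_size=int(bin_size),
    )


@dataclass
class ContactMatrix:
    """Symmetric nonnegative bin-by-bin Hi-C contact weights."""

    values: np.ndarray
    bins: BinTable

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact matrix must be square, got shape {v.shape}")
        if v.shape[0] != self.bins.n_bins:
            raise ValueError(
                f"contact matrix has {v.shape[0]} rows for {self.bins.n_bins} bins"
            )
        if not np.isfinite(v).all():
            raise ValueError("contact matrix has non-finite entries")
        if (v < 0).any():
            raise ValueError("contact matrix has negative entries")
        if not np.allclose(v, v.T, atol=1e-8, rtol=1e-8):
            raise ValueError("contact matrix is not symmetric")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class SignalMatrix:
    """Bin-by-track real-valued signals with a usable-bin mask.

    ``mask[i]`` is True when bin ``i`` participates in training, clustering
    and statistics; masked-out rows are excluded everywhere and reported as
    NA downstream.
    """

    values: np.ndarray
    track_names: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("signal matrix must be 2-D (bins x tracks)")
        if v.shape[1] != len(self.track_names):
            raise ValueError(
                f"{v.shape[1]} columns for {len(self.track_names)} track names"
            )
        if len(set(self.track_names)) != len(self.track_names):
            raise ValueError("track names must be unique")
        if self.mask is None:
            self.mask = np.ones(v.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (v.shape[0],):
            raise ValueError("mask length must equal number of bins")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.values.shape[1]


@dataclass
class DomainAnnotation:
    """Per-bin chromatin-domain labels in ``{1..K}``, with NA for excluded bins."""

    labels: np.ndarray
    K: int
    bins: BinTable

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.shape != (self.bins.n_bins,):
            raise ValueError("label vector length must equal number of bins")
        assigned = lab != NA_LABEL
        if assigned.any() and ((lab[assigned] < 1) | (lab[assigned] > self.K)).any():
            raise ValueError(f"labels must lie in 1..{self.K} or NA")
        self.labels = lab

    @property
    def assigned(self) -> np.ndarray:
        """Boolean mask of bins that carry a domain label."""
        return self.labels != NA_LABEL


@dataclass
class LoopSet:
    """Chromatin loops as anchor-interval pairs, optionally resolved to bins.

    ``anchors`` holds ``(chrom1, start1, end1, chrom2, start2, end2)`` rows;
    ``resolved`` the corresponding ``(bin_i, bin_j)`` pairs (anchor midpoint
    mapped to its containing bin). ``n_skipped`` counts input records that
    could not be resolved.
    """

    anchors: list[tuple[str, int, int, str, int, int]]
    resolved: np.ndarray | None = None
    n_skipped: int = 0

    def __post_init__(self) -> None:
        for a in self.anchors:
            if a[1] >= a[2] or a[4] >= a[5]:
                raise ValueError(f"invalid anchor interval in {a}")
        if self.resolved is not None:
            self.resolved = np.asarray(self.resolved, dtype=np.int64).reshape(-1, 2)

    @property
    def n_loops(self) -> int:
        if self.resolved is not None:
            return len(self.resolved)
        return len(self.anchors)

    def resolve(self, bins: BinTable) -> "LoopSet":
        """Map anchor midpoints to bin indices; unresolvable loops are dropped."""
        kept, pairs = [], []
        skipped = self.n_skipped
        for a in self.anchors:
            c1, s1, e1, c2, s2, e2 = a
            i = bins.bin_at(c1, (s1 + e1) // 2)
            j = bins.bin_at(c2, (s2 + e2) // 2)
            if i is None or j is None:
                skipped += 1
                continue
            kept.append(a)
            pairs.append((i, j))
        return LoopSet(
            anchors=kept,
            resolved=np.asarray(pairs, dtype=np.int64).reshape(-1, 2),
            n_skipped=skipped,
        )


def compute_bin_mask(contacts: ContactMatrix, signals: SignalMatrix) -> np.ndarray:
    """Usable-bin mask: positive contact row-sum AND all signal values finite.

    Bins failing either test are excluded from graph construction, encoder
    training, clustering and every downstream statistic.
    """
    if contacts.n_bins != signals.n_bins:
        raise ValueError(
            f"contacts have {contacts.n_bins} bins, signals {signals.n_bins}"
        )
    rowsum = contacts.values.sum(axis=1)
    finite = np.isfinite(signals.values).all(axis=1)
    return (rowsum > 0) & finite


def normalize_signals(signals: SignalMatrix, method: str = "log1p_zscore") -> SignalMatrix:
    """Per-track signal normalization over masked-in bins.

    ``"log1p_zscore"``
        x -> log(1+x), then per-track z-score (population std) computed over
        masked-in bins. The standard choice for nonnegative ChIP-seq-like
        fold-change tracks; raises on negative input.
    ``"zscore"``
        Per-track z-score only (use for tracks that may be negative).
    ``"none"``
        Identity.

    Zero-variance tracks map to all-zeros rather than dividing by zero.
    """
    if method not in ("log1p_zscore", "zscore", "none"):
        raise ValueError(f"unknown normalization method {method!r}")
    if method == "none":
        return replace(signals, values=signals.values.copy())
    v = signals.values.copy()
    m = signals.mask
    if method == "log1p_zscore":
        if (v[m] < 0).any():
            raise ValueError(
                "negative signal values are incompatible with log1p; "
                "use method='zscore'"
            )
        v = np.log1p(v)
    mu = v[m].mean(axis=0)
    sd = v[m].std(axis=0)  # population std
    out = np.zeros_like(v)
    nz = sd > 0
    out[:, nz] = (v[:, nz] - mu[nz]) / sd[nz]
    return replace(signals, values=out)


def oe_transform(contacts: ContactMatrix) -> ContactMatrix:
    """Observed-over-expected normalization removing the distance-decay trend.

    Each intra-chromosomal off-diagonal entry is divided by the mean of its
    diagonal (same genomic distance, same chromosome); the main diagonal is
    left untouched (a single-bin chromosome passes through unchanged).
    Inter-chromosomal entries are divided by the mean over all
    inter-chromosomal entries. Diagonals (or an inter block) with zero mean
    are left at zero.
    """
    v = contacts.values.copy()
    bins = contacts.bins
    intra = np.zeros_like(v, dtype=bool)
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        intra[sl, sl] = True
        block = v[sl, sl]
        m = block.shape[0]
        for off in range(1, m):
            d = np.diagonal(block, offset=off)
            mean = d.mean()
            if mean > 0:
                idx = np.arange(m - off)
                block[idx, idx + off] = d / mean
                if off > 0:
                    block[idx + off, idx] = block[idx, idx + off]
        v[sl, sl] = block
    inter = ~intra
    if inter.any():
        mean = v[inter].mean()
        if mean > 0:
            v[inter] = v[inter] / mean
    return ContactMatrix(values=v, bins=bins)
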