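"""Readers and writers for the on-disk formats.

Text formats only: dense or triplet contact TSV, bin-by-track signal TSV,
bedGraph, BEDPE loops, BED annotations, chrom.sizes, embedding TSV, YAML
config and JSON metrics. Coordinates are 0-based half-open throughout (UCSC
BED convention). Every writer/reader pair round-trips valid data exactly;
skipped or malformed records are counted and logged.
"""

from __future__ import annotations

import json
import logging
import os
import re
import tempfile
from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd
import yaml

from .core import (
    NA_LABEL,
    BinTable,
    ContactMatrix,
    DomainAnnotation,
    LoopSet,
    SignalMatrix,
)
from .line import EmbeddingMatrix

logger = logging.getLogger("chromdomain")

__all__ = [
    "PipelineConfig",
    "read_chrom_sizes",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_signal_tsv",
    "write_signal_tsv",
    "read_signal_bedgraph",
    "read_bin_values",
    "write_bin_values",
    "read_loops_bedpe",
    "write_loops_bedpe",
    "read_annotation_bed",
    "write_annotation_bed",
    "read_embeddings_tsv",
    "write_embeddings_tsv",
    "write_metrics_json",
    "atomic_write_text",
]


def atomic_write_text(path: str, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved run configuration; YAML keys mirror field names 1:1."""

    bin_size: int = 100_000
    normalization: str = "log1p_zscore"
    oe: bool = True
    top_k: int | None = None
    # LINE
    dim: int = 8
    order: str = "second"
    samples: int = 1_000_000
    negatives: int = 5
    line_lr: float = 0.025
    # encoders
    hidden: tuple[int, ...] = (256, 256)
    out_dim: int = 64
    temperature: float = 1.0
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 256
    # clustering
    k: int = 6
    n_init: int = 10
    l2_normalize_halves: bool = True
    order_by_track: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "hidden" in data and data["hidden"] is not None:
            data["hidden"] = tuple(data["hidden"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["hidden"] = list(d["hidden"])
        atomic_write_text(path, yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# chrom sizes / bins
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str) -> list[tuple[str, int]]:
    """Two-column whitespace-separated (name, length) text."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'name length'")
            out.append((parts[0], int(parts[1])))
    if not out:
        raise ValueError(f"{path}: no chromosomes found")
    return out


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def read_contact_matrix(path: str, bins: BinTable, dialect: str = "triplet_tsv") -> ContactMatrix:
    """Read a contact matrix in the given text dialect.

    ``dense_tsv``: an n x n numeric matrix (no header). Asymmetry beyond
    1e-6 is an error.
    ``triplet_tsv``: rows ``bin_i  bin_j  count``; entries are mirrored.
    ``cooler``: requires the optional ``cooler`` dependency.
    """
    n = bins.n_bins
    if dialect == "dense_tsv":
        v = np.loadtxt(path, ndmin=2)
        if v.shape != (n, n):
            raise ValueError(f"{path}: matrix is {v.shape}, expected ({n}, {n})")
        if np.abs(v - v.T).max() > 1e-6:
            raise ValueError(f"{path}: dense matrix is asymmetric beyond 1e-6")
        v = (v + v.T) / 2.0
    elif dialect == "triplet_tsv":
        t = np.loadtxt(path, ndmin=2)
        if t.shape[1] != 3:
            raise ValueError(f"{path}: triplet file must have 3 columns")
        i = t[:, 0].astype(np.int64)
        j = t[:, 1].astype(np.int64)
        if (i < 0).any() or (i >= n).any() or (j < 0).any() or (j >= n).any():
            raise ValueError(f"{path}: bin index out of range for {n} bins")
        v = np.zeros((n, n))
        v[i, j] = t[:, 2]
        v[j, i] = t[:, 2]
    elif dialect == "cooler":
        raise ImportError(
            "the 'cooler' dialect needs the optional cooler dependency; "
            "use dense_tsv or triplet_tsv"
        )
    else:
        raise ValueError(f"unknown contact dialect {dialect!r}")
    return ContactMatrix(values=v, bins=bins)


def write_contact_matrix(cm: ContactMatrix, path: str, dialect: str = "triplet_tsv") -> None:
    if dialect == "dense_tsv":
        lines = "\n".join("\t".join(f"{x:.10g}" for x in row) for row in cm.values)
        atomic_write_text(path, lines + "\n")
    elif dialect == "triplet_tsv":
        i, j = np.nonzero(np.triu(cm.values))
        rows = [f"{a}\t{b}\t{cm.values[a, b]:.10g}" for a, b in zip(i, j)]
        atomic_write_text(path, "\n".join(rows) + "\n")
    else:
        raise ValueError(f"unknown contact dialect {dialect!r}")


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def write_signal_tsv(signals: SignalMatrix, bins: BinTable, path: str) -> None:
    """Bin-by-track TSV with chrom/start/end columns and a header row."""
    df = bins.to_dataframe()
    for t, name in enumerate(signals.track_names):
        df[name] = signals.values[:, t]
    atomic_write_text(path, df.to_csv(sep="\t", index=False, na_rep="nan"))


def read_signal_tsv(path: str, bins: BinTable) -> SignalMatrix:
    df = pd.read_csv(path, sep="\t")
    expected = {"chrom", "start", "end"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: signal TSV needs chrom/start/end columns")
    if len(df) != bins.n_bins:
        raise ValueError(f"{path}: {len(df)} rows for {bins.n_bins} bins")
    tracks = [c for c in df.columns if c not in expected]
    return SignalMatrix(
        values=df[tracks].to_numpy(dtype=float), track_names=list(tracks)
    )


def read_signal_bedgraph(
    paths: list[str], bins: BinTable, aggregation: str = "mean"
) -> SignalMatrix:
    """One track per bedGraph file, aggregated into bins.

    ``mean`` is the coverage-weighted mean of overlapping interval values;
    ``sum`` accumulates value x overlap-length. Bins with no coverage are
    NaN (and will be masked out). Intervals on unknown chromosomes are
    skipped with a warning and counted.
    """
    if aggregation not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    n = bins.n_bins
    values = np.full((n, len(paths)), np.nan)
    names = []
    for t, path in enumerate(paths):
        name = os.path.splitext(os.path.basename(path))[0]
        names.append(name)
        wsum = np.zeros(n)
        cov = np.zeros(n)
        skipped = 0
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    logger.warning("%s:%d: malformed bedGraph row, skipped", path, ln)
                    skipped += 1
                    continue
                chrom, s, e, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if chrom not in bins.chroms:
                    skipped += 1
                    continue
                sl = bins.chrom_slice(chrom)
                chrom_len = int(bins.end[sl.stop - 1])
                s, e = max(s, 0), min(e, chrom_len)
                if s >= e:
                    continue
                b0 = sl.start + s // bins.bin_size
                b1 = sl.start + (e - 1) // bins.bin_size
                for b in range(b0, b1 + 1):
                    ov = min(e, int(bins.end[b])) - max(s, int(bins.start[b]))
                    if ov > 0:
                        wsum[b] += val * ov
                        cov[b] += ov
        if skipped:
            logger.warning("%s: skipped %d record(s)", path, skipped)
        with np.errstate(invalid="ignore"):
            col = wsum / cov if aggregation == "mean" else wsum
        if aggregation == "mean":
            col = np.where(cov > 0, col, np.nan)
        else:
            col = np.where(cov > 0, wsum, np.nan)
        values[:, t] = col
    return SignalMatrix(values=values, track_names=names)


def read_bin_values(path: str, bins: BinTable) -> np.ndarray:
    """Two-column (bin_index, value) TSV -> full-length vector (NaN gaps)."""
    t = np.loadtxt(path, ndmin=2)
    if t.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (bin_index, value)")
    out = np.full(bins.n_bins, np.nan)
    idx = t[:, 0].astype(np.int64)
    if (idx < 0).any() or (idx >= bins.n_bins).any():
        raise ValueError(f"{path}: bin index out of range")
    out[idx] = t[:, 1]
    return out


def write_bin_values(values: np.ndarray, path: str) -> None:
    rows = [f"{i}\t{v:.10g}" for i, v in enumerate(values) if np.isfinite(v)]
    atomic_write_text(path, "\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# loops
# ---------------------------------------------------------------------------

def read_loops_bedpe(path: str, bins: BinTable) -> LoopSet:
    """BEDPE (>= 6 columns); anchors resolved to their midpoint bins.

    Malformed or unresolvable rows are skipped with a warning and counted in
    ``LoopSet.n_skipped``.
    """
    anchors = []
    skipped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                parts = line.split()
            if len(parts) < 6:
                logger.warning("%s:%d: fewer than 6 BEDPE columns, skipped", path, ln)
                skipped += 1
                continue
            try:
                rec = (
                    parts[0], int(parts[1]), int(parts[2]),
                    parts[3], int(parts[4]), int(parts[5]),
                )
                if rec[1] >= rec[2] or rec[4] >= rec[5]:
                    raise ValueError("empty anchor interval")
            except ValueError:
                logger.warning("%s:%d: malformed BEDPE row, skipped", path, ln)
                skipped += 1
                continue
            anchors.append(rec)
    loops = LoopSet(anchors=anchors, n_skipped=skipped).resolve(bins)
    if loops.n_skipped:
        logger.warning("%s: %d loop record(s) skipped/unresolvable", path, loops.n_skipped)
    return loops


def write_loops_bedpe(loops: LoopSet, path: str) -> None:
    rows = [
        f"{c1}\t{s1}\t{e1}\t{c2}\t{s2}\t{e2}"
        for c1, s1, e1, c2, s2, e2 in loops.anchors
    ]
    atomic_write_text(path, "\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# annotations (BED)
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^C(\d+)$|^NA$")


def write_annotation_bed(
    ann: DomainAnnotation, path: str, na_policy: str = "emit", merge: bool = False
) -> None:
    """BED4 output: chrom, start, end, C<label> (or NA).

    ``na_policy="omit"`` drops NA bins; ``merge=True`` merges runs of
    adjacent same-label bins into single records (within a chromosome).
    """
    if na_policy not in ("emit", "omit"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    bins = ann.bins
    names = np.where(ann.assigned, [f"C{l}" for l in ann.labels], "NA")
    rows = []
    i = 0
    n = bins.n_bins
    while i < n:
        j = i
        if merge:
            while (
                j + 1 < n
                and ann.labels[j + 1] == ann.labels[i]
                and bins.chrom_index[j + 1] == bins.chrom_index[i]
            ):
                j += 1
        name = names[i]
        if not (name == "NA" and na_policy == "omit"):
            rows.append(
                f"{bins.chroms[bins.chrom_index[i]]}\t{bins.start[i]}\t{bins.end[j]}\t{name}"
            )
        i = j + 1
    atomic_write_text(path, "\n".join(rows) + "\n")


def read_annotation_bed(path: str, bins: BinTable, K: int | None = None) -> DomainAnnotation:
    """Read a BED4 annotation back onto a bin table (expanding merged runs)."""
    labels = np.full(bins.n_bins, NA_LABEL, dtype=np.int64)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected BED4")
            chrom, s, e, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            m = _LABEL_RE.match(name)
            if not m:
                raise ValueError(f"{path}:{ln}: label {name!r} not C<k> or NA")
            if name == "NA":
                continue
            lab = int(m.group(1))
            b0 = bins.bin_at(chrom, s)
            b1 = bins.bin_at(chrom, e - 1)
            if b0 is None or b1 is None:
                raise ValueError(f"{path}:{ln}: interval outside bin table")
            labels[b0 : b1 + 1] = lab
    kmax = int(labels.max())
    if K is None:
        K = max(kmax, 1)
    return DomainAnnotation(labels=labels, K=K, bins=bins)


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def write_embeddings_tsv(emb: EmbeddingMatrix, bins: BinTable, path: str) -> None:
    """TSV dialect: bin_index, chrom, start, end, e1..e_dim (header row)."""
    df = bins.to_dataframe()
    df.insert(0, "bin_index", np.arange(bins.n_bins))
    for d in range(emb.dim):
        df[f"e{d + 1}"] = emb.values[:, d]
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format="%.10g"))


def read_embeddings_tsv(path: str, bins: BinTable) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if re.match(r"^e\d+$", c)]
    if not cols or len(df) != bins.n_bins:
        raise ValueError(f"{path}: not a valid embedding TSV for {bins.n_bins} bins")
    cols = sorted(cols, key=lambda c: int(c[1:]))
    return EmbeddingMatrix(values=df[cols].to_numpy(dtype=float))


def write_metrics_json(metrics: dict, path: str) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    atomic_write_text(path, json.dumps(metrics, indent=2, default=_default) + "\n")
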