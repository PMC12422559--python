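"""High-level modelling interface.

:class:`ChromatinDomainModel` bundles the full annotation procedure — bin
masking, signal normalization, O/E contact normalization, LINE graph
embedding, contrastive encoder training, K-means clustering and
activity-based label ordering — behind a statsmodels-like ``Model.fit() ->
Results`` surface. :class:`DomainResults` carries the annotation together
with its diagnostics (loss histories, K-means inertia, per-signal VE) and
knows how to evaluate itself against loops, expression and other continuous
tracks.

Example
-------
>>> from chromdomain import simulate, ChromatinDomainModel
>>> g = simulate.generate_planted_genome(simulate.default_paper_like_params(seed=1))
>>> res = ChromatinDomainModel(g.contacts, g.signals, normalization="zscore").fit(seed=1)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import clustering, evaluation
from .contrastive import EncoderConfig, PairedEmbeddings, train_contrastive
from .core import (
    ContactMatrix,
    DomainAnnotation,
    SignalMatrix,
    compute_bin_mask,
    normalize_signals,
    oe_transform,
)
from .line import EmbeddingMatrix, build_graph, train_line


def _subseeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(int(seed)).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass
class ChromatinDomainModel:
    """Chromatin domain annotation from a contact matrix and signal tracks.

    Parameters
    ----------
    contacts
        Symmetric bin-by-bin Hi-C contact matrix.
    signals
        Bin-by-track epigenomic signals on the same bin table.
    k
        Number of domain types (default 6).
    normalization
        Signal preprocessing: ``"log1p_zscore"`` (default, for nonnegative
        tracks), ``"zscore"`` or ``"none"``.
    oe
        Apply observed/expected distance normalization to contacts before
        graph construction.
    top_k
        Optional per-node edge sparsification of the contact graph.
    line_dim, line_order, line_samples, line_negatives, line_lr
        LINE embedding hyperparameters (dim 8 matches the usual Hi-C
        embedding dimensionality).
    encoder
        :class:`EncoderConfig` for the contrastive stage; ``None`` uses
        defaults (two 256-unit hidden layers, d=64, tau=1.0).
    n_init
        K-means restarts.
    l2_normalize_halves
        L2-normalize each embedding half before concatenation (default
        True: the contrastive embeddings live on a cosine geometry).
    order_by_track
        Track name whose mean orders the final labels (C1 = most active);
        default: first track.
    """

    contacts: ContactMatrix
    signals: SignalMatrix
    k: int = 6
    normalization: str = "log1p_zscore"
    oe: bool = True
    top_k: int | None = None
    line_dim: int = 8
    line_order: str = "second"
    line_samples: int = 1_000_000
    line_negatives: int = 5
    line_lr: float = 0.025
    encoder: EncoderConfig | None = None
    n_init: int = 10
    l2_normalize_halves: bool = True
    order_by_track: str | None = None

    def __post_init__(self) -> None:
        if self.contacts.n_bins != self.signals.n_bins:
            raise ValueError("contacts and signals disagree on the number of bins")
        if not 2 <= self.k:
            raise ValueError("k must be >= 2")

    def fit(self, seed: int = 0) -> "DomainResults":
        """Run the full pipeline; deterministic for a fixed seed."""
        s_line, s_enc, s_km = _subseeds(seed, 3)

        mask = compute_bin_mask(self.contacts, self.signals)
        signals = SignalMatrix(
            values=self.signals.values,
            track_names=self.signals.track_names,
            mask=mask,
        )
        norm = normalize_signals(signals, self.normalization)

        contacts = oe_transform(self.contacts) if self.oe else self.contacts
        graph = build_graph(contacts, mask=mask, top_k=self.top_k)
        hic_emb, line_loss = train_line(
            graph,
            dim=self.line_dim,
            order=self.line_order,
            n_samples=self.line_samples,
            n_negatives=self.line_negatives,
            lr=self.line_lr,
            seed=s_line,
            return_loss=True,
        )

        enc = self.encoder or EncoderConfig()
        enc = EncoderConfig(
            hidden_dims=enc.hidden_dims,
            out_dim=enc.out_dim,
            activation=enc.activation,
            temperature=enc.temperature,
            lr=enc.lr,
            epochs=enc.epochs,
            batch_size=enc.batch_size,
            seed=s_enc,
        )
        paired, contrastive_loss = train_contrastive(
            hic_emb.values[mask], norm.values[mask], enc
        )

        X = clustering.concat_embeddings(paired, self.l2_normalize_halves)
        labels = clustering.kmeans_cluster(X, self.k, seed=s_km, n_init=self.n_init)
        ann = clustering.annotate(self.contacts.bins, labels, mask)

        track = self.order_by_track or norm.track_names[0]
        if track not in norm.track_names:
            raise ValueError(f"unknown ordering track {track!r}")
        activity = np.where(
            mask, norm.values[:, norm.track_names.index(track)], np.nan
        )
        ann = clustering.order_labels_by_activity(ann, activity)

        return DomainResults(
            model=self,
            seed=seed,
            mask=mask,
            normalized_signals=norm,
            hic_embedding=hic_emb,
            paired=paired,
            features=X,
            annotation=ann,
            line_loss=line_loss,
            contrastive_loss=contrastive_loss,
        )


@dataclass
class DomainResults:
    """Fitted domain annotation with diagnostics."""

    model: ChromatinDomainModel
    seed: int
    mask: np.ndarray
    normalized_signals: SignalMatrix
    hic_embedding: EmbeddingMatrix
    paired: PairedEmbeddings
    features: np.ndarray
    annotation: DomainAnnotation
    line_loss: np.ndarray
    contrastive_loss: np.ndarray

    # -- diagnostics -------------------------------------------------------

    def per_signal_ve(self) -> dict[str, float]:
        """VE of each input track given the fitted annotation."""
        ve = evaluation.per_signal_ve(self.normalized_signals, self.annotation)
        return dict(zip(self.normalized_signals.track_names, ve))

    def per_component_ve(self) -> np.ndarray:
        """VE of each raw Hi-C embedding component given the annotation."""
        return evaluation.per_signal_ve(self.hic_embedding, self.annotation)

    def coverage(self) -> np.ndarray:
        return evaluation.domain_coverage(self.annotation)

    def segment_lengths(self) -> tuple[np.ndarray, np.ndarray]:
        return evaluation.mean_segment_length(self.annotation)

    def evaluate(
        self,
        loops=None,
        expression: np.ndarray | None = None,
        tracks: dict[str, np.ndarray] | None = None,
        n_perm: int = 1000,
        log_expression: bool = True,
    ) -> dict:
        """Metric report against external evaluation data.

        ``loops`` is a resolved :class:`LoopSet` (O/E ratio); ``expression``
        a per-bin RPKM-like vector (VE, log1p by default); ``tracks`` extra
        named continuous tracks (e.g. replication timing), each scored by VE.
        """
        out: dict = {
            "n_bins": int(self.annotation.bins.n_bins),
            "n_usable_bins": int(self.mask.sum()),
            "k": int(self.annotation.K),
            "coverage": self.coverage(),
            "mean_segment_bins": self.segment_lengths()[0],
            "per_signal_ve": self.per_signal_ve(),
        }
        lab = self.annotation.labels
        if expression is not None:
            x = np.log1p(expression) if log_expression else expression
            out["expression_ve"] = evaluation.variance_explained(x, lab)
        if tracks:
            out["track_ve"] = {
                name: evaluation.variance_explained(v, lab)
                for name, v in tracks.items()
            }
        if loops is not None:
            oe_seed = _subseeds(self.seed, 4)[3]
            out["loop_oe"] = evaluation.loop_oe_ratio(
                loops, self.annotation, n_perm=n_perm, seed=oe_seed
            )
        return out

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text table)."""
        cov = self.coverage()
        seg_bins, seg_bp = self.segment_lengths()
        ve = self.per_signal_ve()
        lines = [
            "Chromatin Domain Annotation Results",
            "=" * 55,
            f"bins               {self.annotation.bins.n_bins:>8d}",
            f"usable bins        {int(self.mask.sum()):>8d}",
            f"domain types (K)   {self.annotation.K:>8d}",
            f"seed               {self.seed:>8d}",
            f"final InfoNCE loss {self.contrastive_loss[-1]:>8.4f}",
            "-" * 55,
            f"{'type':<6}{'bins':>8}{'mean seg (bins)':>18}{'mean seg (bp)':>18}",
        ]
        for k in range(self.annotation.K):
            sb = f"{seg_bins[k]:.2f}" if np.isfinite(seg_bins[k]) else "NA"
            sp = f"{seg_bp[k]:.0f}" if np.isfinite(seg_bp[k]) else "NA"
            lines.append(f"C{k + 1:<5}{cov[k]:>8d}{sb:>18}{sp:>18}")
        lines.append("-" * 55)
        lines.append("per-track variance explained:")
        for name, v in ve.items():
            lines.append(f"  {name:<20} {v:6.3f}")
        lines.append("=" * 55)
        return "\n".join(lines)
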