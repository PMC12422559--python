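"""Planted-domain genome simulator.

Generates a binned genome whose ground-truth domain types drive both the
Hi-C contact structure and the epigenomic signals, so that the whole
pipeline — graph embedding, contrastive alignment, clustering, evaluation —
can be exercised end to end with a known answer.

The generative model:

* true labels form contiguous segments (geometric segment lengths) over one
  to three pseudo-chromosomes, mimicking the megabase-scale block structure
  of real subcompartment maps;
* contacts are Poisson counts with rate ``lambda_within`` for same-type bin
  pairs and ``lambda_between`` otherwise, attenuated by the power-law
  distance decay ``1 / (1 + |i - j|)^alpha`` within chromosomes;
* each signal track is a type-specific mean plus Gaussian noise;
* gene expression is lognormal with a high location for "active" types;
* a configurable fraction of loops joins two bins of the same type, the
  remainder joins uniform random bins.

What this deliberately does not model: TAD hierarchy, compartment
eigen-structure, mappability artifacts, or read-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    BinTable,
    ContactMatrix,
    LoopSet,
    SignalMatrix,
    bin_genome,
)

__all__ = [
    "PlantedGenomeParams",
    "PlantedGenome",
    "default_paper_like_params",
    "null_params",
    "generate_planted_genome",
]


@dataclass(frozen=True)
class PlantedGenomeParams:
    """Generator settings; defaults describe a strongly structured genome."""

    K: int = 6
    n_bins: int = 600
    bin_size: int = 100_000
    n_chroms: int = 2
    n_tracks: int = 12
    mean_segment_bins: float = 20.0
    lambda_within: float = 10.0
    lambda_between: float = 1.0
    decay_exponent: float = 1.0
    signal_means: np.ndarray | None = None  # K x n_tracks; None -> built-in layout
    noise_sd: float = 0.5
    n_loops: int = 300
    within_loop_frac: float = 0.8
    active_types: tuple[int, ...] = (1, 2)
    expression_active_logmean: float = 2.0
    expression_logsd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.n_bins < 10 * self.K:
            raise ValueError("n_bins must be >= 10 * K")
        if not 1 <= self.n_chroms <= 3:
            raise ValueError("n_chroms must be in 1..3")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.mean_segment_bins < 1:
            raise ValueError("mean_segment_bins must be >= 1")
        if self.lambda_within < 0 or self.lambda_between < 0:
            raise ValueError("lambda_within / lambda_between must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.within_loop_frac <= 1:
            raise ValueError("within_loop_frac must be in [0, 1]")
        if self.n_loops < 0:
            raise ValueError("n_loops must be nonnegative")
        if self.signal_means is not None:
            sm = np.asarray(self.signal_means, dtype=float)
            if sm.shape != (self.K, self.n_tracks):
                raise ValueError("signal_means must have shape (K, n_tracks)")
        for t in self.active_types:
            if not 1 <= t <= self.K:
                raise ValueError("active_types must name labels in 1..K")


@dataclass
class PlantedGenome:
    """A complete synthetic dataset with ground truth."""

    bins: BinTable
    true_labels: np.ndarray
    contacts: ContactMatrix
    signals: SignalMatrix
    loops: LoopSet
    expression: np.ndarray
    params: PlantedGenomeParams


def _default_signal_means(K: int, n_tracks: int) -> np.ndarray:
    """Built-in type-by-track mean layout.

    The first half of the tracks behaves like activating marks, the second
    half like repressive ones. Two "active" types are high on activating
    tracks with distinct profiles, one type is neutral, and the remaining
    types are high on disjoint subsets of repressive tracks or uniformly
    low, echoing the active/neutral/inactive ordering of real domain
    catalogs.
    """
    mu = np.full((K, n_tracks), 0.5)
    act = np.arange(0, n_tracks // 2)      # activating marks
    rep = np.arange(n_tracks // 2, n_tracks)  # repressive marks
    mu[0, act] = 3.0                                   # broadly active
    if K >= 2:
        mu[1, act[: max(1, len(act) // 2)]] = 3.0      # active, narrower profile
        mu[1, act[max(1, len(act) // 2):]] = 1.5
    if K >= 3:
        mu[2, :] = 1.0                                 # neutral
    if K >= 4 and len(rep):
        half = max(1, len(rep) // 2)
        mu[3, rep[:half]] = 3.0                        # repressive set A
    if K >= 5 and len(rep):
        half = max(1, len(rep) // 2)
        mu[4, rep[half:]] = 3.0                        # repressive set B
    # remaining types (including K=6 default) stay uniformly low at 0.5
    for k in range(5, K):
        mu[k, :] = 0.5 - 0.2 * (k - 4) / max(1, K - 5)
    return mu


def default_paper_like_params(seed: int = 0) -> PlantedGenomeParams:
    """Default study conditions: K=6 domain types, 600 bins of 100 kb over two
    pseudo-chromosomes, 12 signal tracks, strong planted structure."""
    return PlantedGenomeParams(seed=seed)


def null_params(seed: int = 0) -> PlantedGenomeParams:
    """A structureless control: contact rates identical within and between
    types and signal noise overwhelming the type means, so no method should
    recover the planted labels."""
    return replace(
        default_paper_like_params(seed=seed),
        lambda_within=3.0,
        lambda_between=3.0,
        noise_sd=50.0,
    )


def _plant_labels(rng: np.random.Generator, params: PlantedGenomeParams,
                  bins: BinTable) -> np.ndarray:
    labels = np.empty(bins.n_bins, dtype=np.int64)
    p_geom = 1.0 / params.mean_segment_bins
    for chrom in bins.chroms:
        sl = bins.chrom_slice(chrom)
        pos = sl.start
        prev = 0
        while pos < sl.stop:
            seg = int(rng.geometric(p_geom))
            # avoid repeating the previous type so segments stay maximal
            k = int(rng.integers(1, params.K + 1))
            while k == prev:
                k = int(rng.integers(1, params.K + 1))
            end = min(pos + seg, sl.stop)
            labels[pos:end] = k
            prev = k
            pos = end
    return labels


def generate_planted_genome(params: PlantedGenomeParams) -> PlantedGenome:
    """Draw one synthetic genome; bitwise reproducible for a fixed seed."""
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    rng_labels, rng_contacts, rng_signals, rng_loops, rng_expr = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    per = params.n_bins // params.n_chroms
    sizes = []
    for c in range(params.n_chroms):
        nb = per + (1 if c < params.n_bins % params.n_chroms else 0)
        sizes.append((f"chrS{c + 1}", nb * params.bin_size))
    bins = bin_genome(sizes, params.bin_size)
    assert bins.n_bins == params.n_bins

    labels = _plant_labels(rng_labels, params, bins)

    # contact rates: block structure from labels, distance decay within chroms
    same = labels[:, None] == labels[None, :]
    rate = np.where(same, params.lambda_within, params.lambda_between).astype(float)
    ci = bins.chrom_index
    intra = ci[:, None] == ci[None, :]
    d = np.abs(np.arange(params.n_bins)[:, None] - np.arange(params.n_bins)[None, :])
    decay = 1.0 / (1.0 + d) ** params.decay_exponent
    rate = np.where(intra, rate * decay, rate)
    upper = np.triu(rng_contacts.poisson(rate)).astype(float)
    contacts_values = upper + np.triu(upper, k=1).T
    contacts = ContactMatrix(values=contacts_values, bins=bins)

    mu = (
        np.asarray(params.signal_means, dtype=float)
        if params.signal_means is not None
        else _default_signal_means(params.K, params.n_tracks)
    )
    values = mu[labels - 1] + rng_signals.normal(
        0.0, params.noise_sd, size=(params.n_bins, params.n_tracks)
    )
    signals = SignalMatrix(
        values=values,
        track_names=[f"track{t + 1}" for t in range(params.n_tracks)],
    )

    # expression: lognormal, elevated location for active types
    logmean = np.where(
        np.isin(labels, params.active_types), params.expression_active_logmean, 0.0
    )
    expression = np.exp(rng_expr.normal(logmean, params.expression_logsd))

    loops = _plant_loops(rng_loops, params, bins, labels)

    return PlantedGenome(
        bins=bins,
        true_labels=labels,
        contacts=contacts,
        signals=signals,
        loops=loops,
        expression=expression,
        params=params,
    )


def _plant_loops(
    rng: np.random.Generator,
    params: PlantedGenomeParams,
    bins: BinTable,
    labels: np.ndarray,
) -> LoopSet:
    n = bins.n_bins
    pairs = []
    by_type = {k: np.flatnonzero(labels == k) for k in range(1, params.K + 1)}
    present = [k for k, idx in by_type.items() if len(idx) >= 2]
    for _ in range(params.n_loops):
        if present and rng.random() < params.within_loop_frac:
            k = present[int(rng.integers(len(present)))]
            i, j = rng.choice(by_type[k], size=2, replace=False)
        else:
            i, j = rng.choice(n, size=2, replace=False)
        pairs.append((int(i), int(j)))
    anchors = []
    for i, j in pairs:
        anchors.append(
            (
                bins.chroms[bins.chrom_index[i]],
                int(bins.start[i]) + bins.bin_size // 4,
                int(bins.start[i]) + bins.bin_size // 2,
                bins.chroms[bins.chrom_index[j]],
                int(bins.start[j]) + bins.bin_size // 4,
                int(bins.start[j]) + bins.bin_size // 2,
            )
        )
    return LoopSet(
        anchors=anchors,
        resolved=np.asarray(pairs, dtype=np.int64).reshape(-1, 2),
    )
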