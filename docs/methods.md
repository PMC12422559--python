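# Methods

This note documents the model implemented by `chromdomain`, the parameter
defaults and why they were chosen, what the synthetic benchmark does and
does not establish, and the numerical conventions.

## Model

### Binning and preprocessing

The genome is divided into fixed-width bins (`bin_size`, default 100 kb,
0-based half-open coordinates; truncated terminal bins are kept). A bin is
*usable* when its Hi-C contact row-sum is positive and all its signal
values are finite; unusable bins are excluded from graph construction,
training, clustering and every statistic, and appear as `NA` in output BED.

Signals are normalized per track over usable bins. The default,
`log1p_zscore` (log(1+x) then population z-score), suits nonnegative
ChIP-seq-like fold-change tracks and refuses negative input; `zscore` is
provided for signed tracks (and is what the synthetic benchmark uses, since
its tracks are Gaussian around type means). Zero-variance tracks map to
zeros rather than dividing by zero.

Contacts are normalized observed/expected before graph construction: each
intra-chromosomal off-diagonal entry is divided by the mean of its diagonal
(same chromosome, same genomic distance), inter-chromosomal entries by the
global inter-chromosomal mean. The main diagonal is left untouched (it is
ignored by graph construction anyway), so a single-bin chromosome passes
through unchanged. O/E removes the dominant distance-decay trend so that
edge weights reflect relative, not absolute, contact propensity.

### LINE embedding of the contact graph

Every unordered pair of usable bins with positive (O/E) contact weight is
an edge; `top_k` optionally keeps each node's heaviest edges (union over
endpoints). LINE is trained by edge-sampling SGD: edges are drawn from a
Walker alias table with probability proportional to weight, oriented
uniformly at random (an undirected edge acts as two directed ones);
negatives are drawn with probability proportional to weighted
degree^0.75; the objective per draw is
−log σ(u_i·v_j) − Σ_k log σ(−u_i·v_k). Defaults: dimension 8 (the usual
size for Hi-C bin embeddings at 100 kb), second-order proximity with
separate context vectors (first-order available), 5 negatives, learning
rate 0.025 decaying linearly to 1/100 of its start over the sample budget
(10^6 edge draws by default), vertex vectors initialized uniform in
[−0.5, 0.5]/dim and context vectors at zero.

Mini-batches of edge draws are applied with scatter-add — an in-memory
stand-in for asynchronous SGD. The batch is capped at the number of edges:
on very small graphs the same node would otherwise absorb hundreds of
summed gradients in a single step and diverge, while on realistic graphs
(thousands of edges) the cap is inactive and recurrences within a batch
are rare. Edges are canonically sorted internally, so the embedding does
not depend on input edge order; all sampling flows from one seeded
generator, making training bitwise reproducible.

### Contrastive alignment

A structural encoder (input: LINE vectors) and a functional encoder
(input: normalized signals) — MLPs with two 256-unit ReLU hidden layers and
a linear map to d = 64 — are trained jointly with the bidirectional InfoNCE
loss over cosine similarities: with C_ij = cos(s_i, f_j)/τ,

    L = ½ [ mean_i CE(row_i(C), i) + mean_j CE(col_j(C), j) ],

positives are the matched bin on the diagonal, negatives all in-batch
mismatches. Optimization is Adam (lr 10⁻³), shuffled mini-batches of 256
bins, 50 epochs. The loss, its analytic gradients and the entire backward
pass are hand-written NumPy and verified against finite differences in the
test suite.

**Temperature.** τ defaults to 1.0, not the sharp values common in
instance-discrimination settings. With many near-duplicate bins per domain
type, a sharp temperature forces the encoders to tell same-type bins apart,
which they can only do by amplifying per-bin noise — and that demonstrably
erases domain-level structure downstream (on the planted benchmark,
recovery ARI drops from ≈0.95 to as low as 0.17 at τ = 0.1 with long
training). A soft temperature keeps the alignment pressure at the level of
modality correspondence rather than bin identity. Epochs default to 50,
the middle of a plateau (30–100 epochs behave equivalently at τ = 1.0).
Both are configuration-exposed.

### Clustering and label order

Per-bin embeddings are concatenated, [s_i ; f_i] ∈ R^{2d}, and clustered
with K-means (K = 6 by default, matching the common six-type domain and
subcompartment catalogs; K ∈ 2..10 supported; best of `n_init` = 10
k-means++ starts, seeded). Each half is L2-normalized before concatenation
by default: the contrastive training objective only constrains directions
(cosines), so embedding norms are uninformative nuisance scale that would
otherwise dominate Euclidean K-means; a flag restores raw concatenation.
Cluster labels are then reordered so C1 has the highest mean activity and
CK the lowest (ties broken by cluster size), where activity is the first
normalized track unless the user names one (e.g. H3K27ac) — a pure
relabeling that never changes memberships.

## Evaluation statistics

* **Variance explained (VE)** of a continuous track by the annotation is
  one-way ANOVA R² — between-class over total sum of squares — the natural
  formalization of "variance explained" by a categorical labeling. It is
  invariant to positive affine transforms of the track and to label
  renaming; zero total variance returns 0. Gene expression is log1p'd
  before VE by default (flag to disable).
* **Loop O/E**: observed number of loops whose two anchor bins share a
  label, divided by the mean of that count over `n_perm` = 1000 seeded
  uniform permutations of the per-bin labels. The permutation null keeps
  anchor positions fixed; a closed-form alternative (L·Σ_k c_k², the exact
  permutation expectation for distinct anchors under label exchangeability)
  is provided for speed and agrees with the permutation estimate within
  Monte-Carlo error in the tests. Anchors map to the bin containing their
  midpoint; loops with an unlabeled anchor or both anchors in one bin are
  dropped and counted.
* **Fold enrichment**: median signal within a type over the median across
  all labeled bins; scale-invariant; empty types give NaN rows, zero global
  medians NaN columns.
* **ARI** is computed from the pair-counting contingency formula in-package
  (scikit-learn's implementation serves as an independent cross-check in
  the tests only); NA positions are dropped pairwise.
* **Overlap matrices** count co-labeled bins between two annotations, row-
  or column-normalized. **Coverage** counts bins per type; **mean segment
  length** averages maximal same-label runs, broken at chromosome
  boundaries and NA gaps, reported in bins and base pairs.

A VE table over several annotations can be column-normalized by its maximum
to compare methods signal-by-signal on a common scale.

## Synthetic benchmark

`generate_planted_genome` draws ground-truth domain labels as contiguous
segments (geometric lengths, mean 20 bins) over two pseudo-chromosomes of
300 bins each (600 bins of 100 kb, K = 6, 12 tracks — the scale of one
large chromosome pair rather than a whole genome, which keeps the default
test and acceptance runs in seconds while leaving every pathway exercised).
Contacts are Poisson with rate λ_within = 10 for same-type pairs and
λ_between = 1 otherwise — a 10:1 contrast comparable to the strong
block structure of deeply sequenced subcompartment maps — attenuated by
1/(1+d) distance decay within chromosomes (the simplest monotone kernel;
exponent configurable). Tracks are type-specific means plus Gaussian noise
(σ = 0.5 against mean contrasts of ~2.5, i.e. clearly informative but far
from noiseless); the built-in mean layout gives two "active" types high on
the activating half of the tracks with distinct profiles, one neutral
type, two types high on disjoint repressive track subsets and one
uniformly low type. Expression is lognormal with elevated location in the
active types; 300 loops are planted, 80% with both anchors in one type.
A structureless control (`null_params`) sets λ_within = λ_between and
σ = 50 so that no method should beat chance.

All randomness flows from one seed through per-component spawned
generators; regeneration is bitwise identical. The simulator writes every
component in the same text formats the pipeline reads, so fixtures double
as format round-trip tests.

**What passing shows — and does not.** Recovering planted types with
ARI ≥ 0.9 and staying at |ARI| < 0.1 on the control shows the pipeline
extracts exactly the joint structure-plus-signal information it is designed
for, with correctly seeded determinism. It does not show performance on
real Hi-C: the simulator has no TAD hierarchy, no compartment
eigen-structure, no mappability artifacts, no inter-replicate noise, and
its inter-chromosomal contacts carry undamped type signal. Real-data claims
require real evaluation tracks.

## Numerical conventions and degenerate inputs

* InfoNCE is computed via log-sum-exp; cosine similarity refuses zero-norm
  rows; a single-pair batch has loss exactly 0 and singleton batches are
  skipped during training (no negatives exist).
* The alias sampler is Vose's method; its empirical law matches the target
  within TV 0.01 at 10^5 draws for distributions up to a few dozen
  categories (near 100 equiprobable categories the expected TV of an exact
  sampler already reaches ~0.01 at that sample size, so tests probe below
  that regime).
* K-means ties (duplicate rows) land in the same cluster; empty clusters
  are re-seeded at far points by the underlying scikit-learn
  implementation.
* Masked-out bins carry zero rows in every embedding file and `NA` in BED;
  readers and writers are exact inverses on valid data, and malformed or
  unresolvable records are skipped, counted and logged, never silently
  dropped.
* Per-stage seeds (LINE, encoders, K-means, permutation nulls) are spawned
  deterministically from the single user-facing seed.

## Known limitations

* No `.hic`/cooler binary input in the core path (the cooler dialect is an
  optional dependency hook); no KR/ICE balancing — input is assumed raw or
  pre-balanced, only O/E is offered.
* No HMM smoothing of labels along the genome; segment statistics reflect
  raw K-means output.
* Single CPU; the NumPy encoders are ample for 100 kb genome-wide bin
  counts (~30k bins) but not intended for 5 kb resolutions.
* The activity-based label ordering is a presentation convention; domain
  *identities* across runs match only up to this ordering.
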