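# chromdomain

Chromatin domain annotation from Hi-C contact maps and binned epigenomic
tracks, by contrastive alignment of the two modalities in a shared latent
space.

## The problem

Genome segmentation methods assign each fixed-width genomic bin (100 kb by
default) a domain type — active chromatin, facultative heterochromatin,
quiescent chromatin, and so on. Epigenome-only segmentations ignore 3D
architecture; Hi-C-only subcompartment calls ignore the rich 1D signal.
Simply concatenating the two feature sets treats them as independent and
loses the correspondence between structure and function at each bin.

`chromdomain` instead learns the correspondence explicitly:

1. **Structural features.** The Hi-C contact matrix is normalized
   observed/expected (removing distance decay), read as a weighted graph
   over usable bins, and embedded with **LINE** (edge-sampling SGD with
   negative sampling, second-order proximity, 8 dimensions by default).
2. **Contrastive alignment.** Two MLP encoders — a structural encoder on
   the LINE vectors and a functional encoder on the z-scored epigenomic
   tracks — map each bin *i* to embeddings *s_i, f_i ∈ R^d* and are trained
   with a **bidirectional InfoNCE** loss over cosine similarities: within a
   batch, *s_i* must identify *f_i* among all batch members and vice versa,

   L = ½·[ mean_i −log softmax_j(cos(s_i, f_j)/τ)_{j=i}
         + mean_j −log softmax_i(cos(s_i, f_j)/τ)_{i=j} ].

3. **Clustering.** The per-bin embeddings are concatenated, [s_i ; f_i],
   and partitioned into *K* = 6 domain types with K-means (best of 10
   k-means++ starts); labels are reordered so C1 is the most active type.
4. **Evaluation.** Variance explained (one-way ANOVA R²) of continuous
   readouts (gene expression, replication timing, individual tracks),
   observed/expected same-domain loop ratios against a label-permutation
   null, per-type fold enrichment of signal medians, adjusted Rand index
   and overlap matrices between annotations, domain coverage and mean
   contiguous-segment lengths.

A planted-domain genome simulator with known ground truth exercises every
stage end to end without any downloads.

## Worked example

```python
import chromdomain as cd
from chromdomain.evaluation import adjusted_rand_index

genome = cd.generate_planted_genome(cd.default_paper_like_params(seed=1))
model = cd.ChromatinDomainModel(genome.contacts, genome.signals,
                                normalization="zscore")
res = model.fit(seed=1)
print(res.summary())
print("recovery ARI:",
      adjusted_rand_index(genome.true_labels, res.annotation.labels))
```

which prints (abridged):

```
Chromatin Domain Annotation Results
=======================================================
bins                    600
usable bins             600
domain types (K)          6
seed                      1
final InfoNCE loss   4.4865
-------------------------------------------------------
type      bins   mean seg (bins)     mean seg (bp)
C1         269             33.62           3362500
C2          28              2.55            254545
C3          23              1.64            164286
C4          57              4.38            438462
C5         154             25.67           2566667
C6          69              4.60            460000
-------------------------------------------------------
per-track variance explained:
  track1                0.854
  ...
=======================================================
recovery ARI: 0.9639696680264237
```

The annotation recovers the six planted domain types almost perfectly
(adjusted Rand index 0.96); the uneven type sizes mirror the planted
segmental truth for this seed, and C1 is the type with the highest mean on
the first (activating) track. `res.evaluate(loops=genome.loops,
expression=genome.expression)` adds the loop O/E ratio (2.38 here: loop
anchors share a domain type ~2.4× more often than under the permutation
null) and the expression VE (0.785).

The same pipeline is available from the shell:

```bash
chromdomain simulate --out data/ --seed 1
chromdomain run-all --dir data/ --out-dir out/        # BED + metrics JSON
# or stage by stage:
chromdomain embed-hic --contacts data/contacts.tsv --chrom-sizes data/chrom.sizes \
    --signals data/signals.tsv --out out/emb.tsv
chromdomain train --hic-emb out/emb.tsv --signals data/signals.tsv \
    --chrom-sizes data/chrom.sizes --normalization zscore --out-dir out/
chromdomain cluster --s out/S.tsv --f out/F.tsv --chrom-sizes data/chrom.sizes \
    --signals data/signals.tsv --out out/annotation.bed
chromdomain evaluate --annotation out/annotation.bed --chrom-sizes data/chrom.sizes \
    --signals data/signals.tsv --loops data/loops.bedpe --out out/metrics.json
```

Accepted input formats: dense or triplet contact TSV, bin×track signal TSV
or per-track bedGraph, BEDPE loops, two-column chrom.sizes, BED annotations
(0-based half-open throughout).

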