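# Methods

## Problem and model

The package co-embeds two per-protein data modalities — for the motivating
application, a protein–protein-interaction network view and an
immunofluorescence-image view of the same cohort of proteins — into one latent
space, so that the two views of a protein land close together and the fused
representation can be clustered, classified and organized into a hierarchy of
subcellular assemblies.

Each modality enters as a feature matrix over a shared identifier set:
`V (n×f)` from a network encoder (random-walk embedding of an interaction
edge list) and `X (n×k)` from a pre-trained image encoder. Two projection
heads map them into a common `l`-dimensional space:

```
z_v = W2_v · relu(W1_v · v)        z_x = W2_x · relu(W1_x · x)
```

Training minimizes a symmetric InfoNCE objective in which the denominator for
every anchor contains both cross-modal similarities to all batch members and
intra-modal similarities to the other members:

```
L_v2x = − Σ_i log [ exp(τ·sim(z_v,i , z_x,i)) /
         ( Σ_j exp(τ·sim(z_v,i , z_x,j)) + Σ_{j≠i} exp(τ·sim(z_v,i , z_v,j)) ) ]
```

plus the mirrored `L_x2v` term; `sim` is cosine similarity and `τ` a learnable
scale (inverse temperature) multiplying the similarities. The intra-modal
negatives are the distinguishing feature versus a vanilla CLIP loss (available
as `loss="clip"` for ablations): with a cohort of only ~10³ proteins the batch
cannot supply many negatives, so each modality's other members are recruited
as additional negatives. After training, per-protein representations are fused
by concatenation, `Z = [z_v | z_x]`.

### Closed forms used for verification

At `τ = 0` every exponential equals 1, so each anchor contributes
`log(2B−1)` and the total loss is exactly `2B·log(2B−1)` for batch size `B`
(0 for `B=1`). The test suite and acceptance script hold the vectorized
implementation to this identity at 1e-9 and to an independent scalar
double-loop evaluation at 1e-6 relative error; all analytic gradients are
checked against central finite differences.

## Training configuration

| parameter | default | notes |
|---|---|---|
| batch size | 128 | mini-batches of matched pairs, reshuffled per epoch |
| epochs | 100 | trailing batches of <2 pairs are dropped |
| hidden / latent dim | 512 / 128 | one rectified hidden layer, no biases |
| optimizer | Adam, lr 1e-5 | see "Step size and memorization" below |
| τ | learnable, init 14.3, clamp ≤100 | log-parameterized; `tau_learnable=False` fixes it |
| input standardization | on | per-feature z-score, fitted on training rows, stored with the model |

The objective optimized is the mean per-anchor loss (the printed sum divided
by `2B`) for step-size stability; loss traces report that mean. Runs are
bit-reproducible for a fixed seed on one thread. Projected rows that are
exactly zero (possible with dead rectifier units) are nudged by 1e-12 on
their first coordinate, with a warning, before cosine normalization.

### Step size and memorization

On a small fixed cohort the contrastive objective has a failure mode that
large-data contrastive setups rarely meet: with enough optimization pressure
the heads memorize the individual training pairs, the loss approaches zero,
and the uniformity pressure of the softmax then separates *same-module*
proteins as vigorously as different-module ones, erasing the cluster geometry
the embedding exists to expose. At lr 1e-3, 100 epochs on the default
n=876 synthetic cohort reach near-zero loss and the fused embedding scores
*worse* on module detection than either raw input modality. At lr 1e-5 the
same 100 epochs align the modalities (matched cross-modal pairs collapse
together; zero-shot transfer works) while within-module structure survives.
The zero-shot behaviour in this regime — top-1 accuracy close to
1/(module size) rather than near-perfect instance identification — is also
the behaviour reported for the real network+image cohort, which is why the
default sits deliberately on the gentle side. The learning rate, like every
other training knob, is configurable.

## Synthetic data generator

The generator emulates the statistical structure the model assumes: a shared
latent space with `K` planted clusters, observed through two fixed linear
views with independent noise.

- Cluster centers are drawn so the expected inter-center distance equals
  `cluster_sep` (default 4) in a `latent_dim=16` space; each protein is its
  center plus isotropic noise (`noise_sd=0.3`), and both modality views
  derive from the *same* perturbed latent point, so individual-level matching
  signal exists in principle.
- **Views**: random orthonormal maps into `dim_v = dim_x = 64` output
  coordinates plus independent per-view noise. The per-view noise defaults to
  `noise_sd · sqrt(latent_dim/dim)` per coordinate so the total view-noise
  energy matches the latent-noise energy instead of growing with the view
  dimension; encoder embeddings of co-localized proteins are coherent, not
  noise-dominated.
- **Complementarity** `c` models assays carrying partly disjoint information:
  `m = round(c·latent_dim/2)` latent coordinates are visible only to V and a
  disjoint `m` only to X, and on its exclusive block a modality sees only
  coarse group-level center values (groups pair clusters two different ways
  for the two modalities). At `c = 1` neither modality alone can resolve the
  full K-cluster structure, while the two together identify every cluster —
  the regime in which integration must pay off.
- **Scale asymmetry**: modality X is emitted on a 10× coarser unit scale
  (`scale_x=10`), mimicking heterogeneous encoders (random-walk embeddings vs
  CNN feature activations live on very different scales). Cosine-based
  methods are unaffected; naive feature concatenation is dominated by the
  larger-scale modality — which is what makes the layman Concat baseline a
  meaningful comparator rather than a lossless ceiling.
- `nested=True` splits each cluster into two sub-clusters (offset
  `cluster_sep/2`) for hierarchy tests; `truth` is then the fine partition.

What the generator does **not** emulate: realistic degree distributions or
walk statistics of interaction networks, image-level variability behind the
per-protein embeddings, non-linear view distortions, and missing proteins per
modality. Passing tests therefore certify the method's behaviour under its
own structural assumptions, not performance on any real cohort.

## Evaluation protocols

- **Module detection**: cosine kNN graph (k=10; edge weight `(1+sim)/2`,
  ties broken by identifier), Louvain clustering swept over resolutions
  {0.1, 0.25, 0.5, 1, 2, 4}, best adjusted mutual information per standard
  reported together with the winning resolution. Overlapping standards are
  flattened to partitions by assigning each protein its lexicographically
  first set; AMI uses the permutation-model chance correction.
- **Function prediction**: stratified 5-fold cross-validation of a one-vs-rest
  L2-regularized logistic classifier; classes smaller than the fold count are
  dropped with a warning; score is the class-size-weighted F1 averaged over
  folds.
- **Zero-shot matching**: 10-fold protocol; the model is retrained without the
  held-out fold, held-out image rows are ranked against the held-out fold's
  projected network rows by cosine similarity (similarity ties broken by
  identifier; `candidates="all"` ranks against the full cohort instead).
  The analytic random baseline for top-K with an m-candidate pool is
  `min(K/m, 1)`; confidence intervals use the t-distribution across folds.
- **Alignment diagnostic**: 2-D UMAP of the stacked `2n` latent rows with
  seeded *random* initialization — spectral initialization can imprint
  correlated internal layouts onto the two disconnected modality clouds of an
  unaligned embedding (their kNN graphs are near-isomorphic through the
  shared proteins) and thereby fake a matched-pair advantage. Matched
  cross-modal distances are compared with one random mismatched pair per
  protein by a one-sided Mann-Whitney U test.
- **Hierarchy**: Louvain partitions at resolutions {0.2, 0.5, 1, 2, 5}
  (coarse→fine), clusters under `min_size=2` dropped, duplicate member sets
  keep their coarsest occurrence, a child attaches to the smallest coarser
  node containing ≥75% of its members (root otherwise). Enrichment per node
  and term is the upper-tail hypergeometric probability against the embedded
  cohort as background (not the genome — the question is concentration within
  the analysed set), with Benjamini-Hochberg control across all node×term
  tests; assemblies with ≥10 proteins are the reported summary, smaller ones
  are retained in the output tables.

## Numerical and degenerate-input choices

- Cosine similarity of an exactly zero vector is an error in the public API;
  inside training the 1e-12 nudge applies (see above).
- Louvain determinism is obtained by seeding the RNG the graph library draws
  from; identical seeds give identical partitions.
- Modality intersection returns ids in lexicographic order so downstream
  results cannot depend on input file ordering; identifier matching is exact
  and case-sensitive, with an opt-in normalization flag.
- `k ≥ n` kNN graphs, empty intersections, sub-2-pair batches, classes
  smaller than the fold count and τ < 0 all fail fast with descriptive errors.

## Problem sizes

The default study conditions are n=876 proteins, 8 clusters, 64-dimensional
views; training takes seconds on one CPU thread, the full zero-shot protocol
(10 retrainings) about a minute, and a UMAP diagnostic a few seconds. The
test suite and the acceptance script use these sizes (or smaller for
structural tests).

## Known limitations

- The network encoder is a compact random-walk + skip-gram implementation
  intended for cohort-scale graphs (10³–10⁴ nodes); it is not tuned for
  million-edge networks.
- The hierarchy builder is a deliberately simple nested-Louvain/containment
  procedure; it does not implement community persistence analysis across
  resolutions.
- Zero-shot accuracy in the default regime reflects module-level matching
  (top-1 ≈ 1/module-size within the candidate pool), not instance-level
  identification; this mirrors the intended operating point of the model, not
  a ceiling of the protocol.
- AMI comparisons require flattening overlapping standards to partitions; the
  lexicographic-first rule is deterministic but arbitrary where sets overlap
  heavily.
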