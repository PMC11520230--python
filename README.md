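# dice-embed

Contrastive co-embedding of paired protein data modalities, with the full
downstream evaluation stack: module detection, function prediction, zero-shot
cross-modal matching, alignment diagnostics, and hierarchical assembly maps.

## The problem

Different assays describe the same protein in incompatible vocabularies: an
interaction screen yields a network neighbourhood, imaging yields a
subcellular appearance. Integrating such *modalities* requires a joint space
in which the two views of a protein are directly comparable. This package
learns that space with a CLIP-style contrastive model: two small projection
heads (one rectified hidden layer each) map the modality features `V (n×f)`
and `X (n×k)` into a shared `l`-dimensional space, trained so that the two
views of the same protein are mutually nearest while all other pairs are
pushed apart. For anchor `i` in the v→x direction the loss term is

```
−log  exp(τ·sim(zv_i, zx_i)) / ( Σ_j exp(τ·sim(zv_i, zx_j)) + Σ_{j≠i} exp(τ·sim(zv_i, zv_j)) )
```

with the mirrored x→v term added; `sim` is cosine similarity and `τ` a
learnable scale. Unlike vanilla CLIP, the denominator also contains
**intra-modal negatives** — essential when the cohort (~10³ proteins) is too
small for large in-batch negative sets. Fused per-protein vectors are the
concatenation `Z = [zv | zx]`.

Everything runs on one CPU in seconds-to-minutes; no GPU, no downloads. A
synthetic-data module generates paired modalities with planted cluster
structure, modality-specific noise/scale, and tunable complementarity, so the
whole pipeline is testable end-to-end. See `docs/methods.md` for the model,
the generator, and every protocol choice.

## Worked example

```bash
dice simulate --n 876 --clusters 8 --seed 1 --out sim/
dice train --modality-v sim/modality_v.tsv --modality-x sim/modality_x.tsv --seed 1 --out run/
dice eval-modules  --embedding run/fused.tsv --standards sim/truth.gmt --seed 1 --out modules.json
dice eval-function --embedding run/fused.tsv --labels sim/truth_coarse.gmt --seed 1
dice zero-shot --modality-v sim/modality_v.tsv --modality-x sim/modality_x.tsv --folds 10 --seed 1 --out zs.json
dice hierarchy --embedding run/fused.tsv --terms sim/truth.gmt --seed 1 --out hier/
dice diagnose --zv run/zv.tsv --zx run/zx.tsv --seed 1 --out diag/
```

Output of that exact session:

```
wrote 876 paired proteins to sim
trained 100 epochs on 876 pairs; loss 12.8305 -> 4.1850 (tau=14.25)
truth: AMI=0.9853 at resolution 2.0
weighted F1 = 1.0000 (5-fold CV)
top-1: 0.148 (random 0.011, ±0.018)
top-3: 0.369 (random 0.034, ±0.038)
top-5: 0.535 (random 0.057, ±0.037)
top-10: 0.831 (random 0.114, ±0.019)
30 assemblies (30 with >= 10 proteins, 30 of those enriched at FDR < 5%)
matched mean 6.787 vs mismatched 12.951 (Mann-Whitney p=3.22e-89)
```

Reading the numbers: training cuts the mean per-anchor contrastive loss to a
third; Louvain clustering of the fused embedding recovers the 8 planted
modules almost perfectly (AMI 0.985); the coarse function labels are linearly
separable in the embedding (weighted F1 1.0). In the 10-fold zero-shot
protocol, held-out image-modality rows are matched to held-out proteins 13×
better than chance at top-1 — roughly one over the module size, i.e. the
model transfers module-level identity to unseen proteins. The hierarchy step
organizes the embedding into 30 assemblies, all significantly enriched (FDR
< 5%) for a planted module, and the alignment diagnostic confirms matched
cross-modal pairs sit far closer in the 2-D map than mismatched ones.

Real data enters through the same doors: `dice embed-network` produces a
random-walk embedding from any `source<TAB>target` interaction edge list, and
any per-protein feature table (e.g. image-encoder embeddings, aggregated per
protein with `aggregate_per_protein`) serves as the second modality. Module
standards and annotation terms are ordinary GMT files.

## Library use

```python
from dice import (SyntheticConfig, generate, TrainConfig, train, embed,
                  module_detection_eval, truth_collections)

res = generate(SyntheticConfig(seed=1))
model, trace = train(res.dataset, TrainConfig(seed=1))
emb = embed(model, res.dataset)              # emb.Zv, emb.Zx, emb.Z
modules, labels = truth_collections(res)
report = module_detection_eval(emb.Z, emb.ids, {"truth": modules}, seed=1)
```

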