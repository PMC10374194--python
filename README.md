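# phenosynth

Quantitative fruit phenotyping and zero-annotation orchard dataset
construction.

Training a fruit detector for a new species normally means collecting and
hand-labeling thousands of orchard photographs. `phenosynth` implements
the non-neural computational core of an automatic-labeling workflow that
removes that cost in three steps:

1. **Optimal source-domain selection.** Transparent-background fruit
   sprites are described in three phenotype dimensions — boundary shape
   via normalized Fourier descriptors, color via CIELAB interval
   histograms, texture via rotation-invariant uniform LBP histograms.
   The three pairwise distance matrices are scale-normalized, embedded
   in 2-D by classical multidimensional scaling, fused by PCA into one
   plane (x = shape, y = color ⊕ texture), and clustered with DBSCAN.
   Each cluster's **medoid** — the species with the smallest mean
   distance to its co-members — is the recommended source domain: one
   dataset that can be translated into every species in its cluster.
2. **Rule-governed scene synthesis.** Sprites are composited onto
   orchard backgrounds under a small rule hierarchy: backgrounds are
   segmented into sky/tree/ground and fruits are confined to the tree
   canopy; sprites are jittered in rotation, scale, saturation, and
   brightness; leaves are scattered with a downward-biased rotation
   prior; and a graded-shading rule rejects any placement that would
   push a fruit's occlusion ratio above 0.5. Because every transform is
   known, each instance's visible mask, polygon, tight bounding box, and
   occlusion ratio are **exact** — labels come for free.
3. **Pseudo-label self-training.** A pluggable detector trained on the
   synthetic scenes labels real images; the confidence threshold
   separating high- from low-quality pseudo-labels is chosen each round
   by maximizing the between-class variance of the score distribution
   (Otsu's criterion), σ²(t) = w₀w₁(μ₀ − μ₁)², and the retained labels
   retrain the detector. A PR/AP evaluator (greedy IoU matching,
   all-points precision-envelope AP, balance-point P/R) scores label
   quality.

A fixtures module generates the whole input universe procedurally —
multi-species sprite collections with planted shape/color/texture
parameters, leaf sprites, and layered orchard backgrounds — so every
stage is testable without downloads. Neural components (image
translation, the detector itself) are out of scope; the detector is an
interface with a calibrated mock implementation.

## Worked example

```python
from phenosynth import commonality as cm
from phenosynth import fixtures as fx

specs = fx.demo_species(3, seed=0)
sprites = fx.generate_species_collection(specs, n_per_species=8)
selection = cm.select_optimal_sources(sprites, level="image",
                                      min_samples=4, seed=0)
for cid, ranked in sorted(selection.recommendations.items()):
    print(f"cluster {cid}: optimal source = {ranked[0]}")
```

prints

```
cluster 0: optimal source = species_0#6
cluster 1: optimal source = species_1#0
cluster 2: optimal source = species_2#1
```

— the three planted species are recovered as three clusters, and within
each, the sprite with the smallest mean fused-space distance to its
cluster mates is nominated as the source domain. Scene synthesis then
reports, per scene, the exact instance count and the largest occlusion
ratio (always ≤ 0.5):

```
scene 0: 12 fruits, max occlusion 0.493
scene 1:  8 fruits, max occlusion 0.148
```

The `examples/` directory holds one short narrative script per
capability (fixtures, descriptors, source selection, synthesis,
pseudo-labeling). A thin CLI mirrors the same stages:

```bash
phenosynth fixtures --out fx --species 3 --per-species 8 --seed 0
phenosynth select-source --images fx/fruits --out selection.json
phenosynth synthesize --fruits fx/fruits --leaves fx/leaves \
    --backgrounds fx/backgrounds --n 100 --out scenes --seed 0
phenosynth evaluate --gt gt.json --pred pred.json
```

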