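# Methods

This note documents the models implemented by `phenosynth`, the
parameter defaults and why they were chosen, what the synthetic fixtures
do and do not emulate, and the numerical conventions that make the
package deterministic.

## Phenotype descriptors

**Shape.** The fruit boundary is the sub-pixel marching-squares contour
of the sprite's alpha channel at level 0.5 (largest component if there
are several), oriented counterclockwise in the complex plane
s = x + j·y and arc-length resampled to a fixed N_b = 128 points.
Fixing N_b is required because the downstream dissimilarity (Pearson
correlation) needs equal-length descriptor vectors; 128 points resolve
harmonics far beyond the 16 kept. The Fourier coefficients are

    a(u) = (1/N_b) Σ_k s(k) · exp(−j·2π·k·u/N_b).

Two normalizations are exposed:

* `standard` (default): d(u) = |a(u)|/|a(1)| for u = 2…17. Dropping
  a(0) (the centroid) gives translation invariance, taking the modulus
  gives rotation and start-point invariance, and dividing by the
  fundamental gives scale invariance. These invariances are exact for
  point-set transforms (≪ 1e−6 numerically) and hold to raster accuracy
  when the sprite itself is transformed.
* `paper`: d(u) = |a(u)/a(0)|, a literal centroid-normalized variant.
  It is *not* translation invariant (a(0) encodes position), which is
  why it is not the default; it is kept for comparability.

Note the descriptor uses positive-frequency bins only. An ellipse's
axis ratio lives mostly in the negative-frequency fundamental a(−1), so
the standard descriptor sees an ellipse through the odd harmonics its
radial modulation induces (u = 3, 5, …) rather than through u = 2.
For the superellipse-family fixtures this is ample signal; for shape
families that differ only by an affine stretch it would be weak.

**Color.** Foreground pixels (alpha ≥ 128) are converted sRGB → CIELAB
under D65/2°. Each channel's range (L: 0–100; a, b: −128…127) is split
into fixed 20-unit intervals; the descriptor stores the per-interval
pixel fractions Rate_i = N_i/N_all and interval means Mean_i, and
summarizes each channel as Σ_i Rate_i·Mean_i with the interval-weighted
variance Σ_i Rate_i·(Mean_i − mean)². The weighted sum is algebraically
the plain channel mean; the histogram form is kept because it is the
quantity of record and exposes the distribution. The color distance is
the Euclidean (ΔE76-style) distance between the weighted Lab means;
variances are stored but deliberately excluded from the distance.
8-bit sRGB quantization bounds round-trip error at roughly ΔE 1, hence
the ΔE 2.0 tolerance used in recovery tests.

**Texture.** Square grayscale patches (default 16 patches of 32 px) are
sampled uniformly among all positions whose footprint is ≥ 95% inside
the foreground, enumerated exhaustively via an integral image. Each
patch yields a rotation-invariant uniform LBP histogram (8 neighbors,
radius 1 → 10 code bins, L1-normalized); the one-pixel border ring of
each LBP map is dropped because its neighborhoods are clipped. The
descriptor aggregate is the mean histogram. Patch count and size trade
off coverage against foreground size; 16×32 px covers a 256² sprite's
interior several times over.

**Dissimilarities.** Shape and texture use 1 − Pearson correlation
(range [0, 2]; affine-invariant). Zero-variance descriptors are
defined to have distance 0 if exactly equal, else 2. Color uses the L2
distance above. Dataset-level matrices average all image-level cross
pairs between two species (mean-of-pairs); a descriptor-averaging
variant is available behind `dataset_aggregate="descriptor-mean"`.

## Commonality model and source selection

The three matrices are scale-normalized by multiplying each with
max_range / own_range (ranges over off-diagonal entries — with a zero
diagonal the off-diagonal minimum coincides with the all-entries
convention), making the three distance ranges equal exactly. Each is
embedded by classical (Torgerson) MDS: double-centered Gram matrix,
top-2 eigenpairs, coordinates scaled by √eigenvalue. Classical MDS was
chosen over iterative stress minimization because it is deterministic,
and the embedding is only consumed through distances and PCA scores.
Axis signs (inherently arbitrary) are fixed by making each axis's
largest-magnitude coordinate positive, so outputs are byte-reproducible
across platforms. Fusion takes the first principal-component score of
the shape embedding as x and of the concatenated color⊕texture block
as y (columns centered first, same sign rule).

DBSCAN clusters the fused plane. When `eps` is not given it is
estimated from the sorted 4-NN distance curve: if the curve contains a
dominant jump (consecutive ratio > 2, the signature of a gap between
cluster-interior and cross-cluster scales), eps is placed inside the
gap; otherwise eps is set just above the curve maximum so that every
point is a core point. `min_samples` defaults to 4. Each cluster's
recommendation is its medoid — the member minimizing mean Euclidean
distance to co-members, ties broken by label order — with remaining
members ranked by the same criterion.

## Synthetic fixtures

The fixture generator defines the study conditions for every test:

* **Fruits**: a superellipse outline (exponent n, aspect ratio) with
  additive radial wobble on harmonics 2–6 (relative amplitude ≈ 0.02).
  The family was chosen because its harmonic content is analytically
  controllable — the disc limit (n=2, aspect 1, wobble 0) is a
  single-harmonic boundary, giving the Fourier pipeline a closed-form
  test case. Color is synthesized CIELAB-first (center + smooth
  per-channel spread, default σ ≈ 2–3) and converted to sRGB last, so
  descriptor recovery has a planted ground truth; texture is
  multiplicative multi-octave value noise on lightness. Canvas 256²,
  matching common transparent-background fruit collections. The demo
  palette keeps aspect ratios away from 1 and CIELAB centers pairwise
  ΔE > 30 so that planted species are separable in every dimension.
* **Leaves**: a lanceolate profile (half-width ∝ sin(πt)^0.8 along the
  axis, slight midrib bend), green CIELAB centers (a < 0), drawn tip
  down so rotation 0 means hanging. Ten leaves per run by default.
* **Backgrounds**: three horizontal bands — blue-gradient sky,
  green-dominant textured canopy, brown ground — with smooth-noise
  boundaries (tree fraction ≈ 0.55) and a ground-truth region mask.

One RNG stream per (seed, index) pair is derived by `SeedSequence`
splitting, so collections are order-independent and every raster is
byte-identical under a fixed seed.

What the fixtures do **not** emulate: photo-realistic lighting,
inter-reflections, depth-of-field, real leaf/branch geometry,
within-species cultivar structure, or background clutter that resembles
fruit. Passing tests therefore demonstrate the correctness of the
descriptors, the selection machinery, the compositing rules, and the
label geometry — not detector transfer to real orchards.

## Scene synthesis

Backgrounds are segmented by fixed HSV/position thresholds: the
per-column top run of blue-dominant or bright/unsaturated pixels is
sky, the bottom run of non-green pixels is ground, the remainder is
tree; the largest connected tree component is the placement region.
Fruit centers are sampled uniformly over tree pixels; each sprite is
cropped to its alpha box, photometrically jittered in HSV (saturation
and value multipliers from [0.85, 1.15]), scaled to a target fraction
of image height (default 0.10–0.18), and rotated (uniform over ±180°
for fruits; Normal(0°, 25°) for leaves — a downward-growth prior
standing in for branch geometry). Geometric interpolation runs on
alpha-premultiplied channels to avoid dark edge fringes.

Occlusion is handled by rejection-resampling rather than post-hoc
cropping: a candidate placement is rejected whenever compositing it on
top would push any already-placed fruit's occlusion ratio — occluded
pixels over total footprint pixels, counting only later-composited
(higher z-order) sprites — above `max_occlusion` (default 0.5). The
bound therefore holds per fruit by construction, and is verified
independently in tests by brute-force raster recounts. Default leaf
density is 1 leaf per fruit; fruit count per scene defaults to 10–30.
200 consecutive rejections abort the scene with an audit record.
Emitted labels: visible mask, its outline polygon (vertices decimated
2:1), the exact tight bounding box of the visible mask, visible area,
and occlusion ratio. COCO boxes are 0-based [x, y, w, h]; VOC corners
are 1-based inclusive; the conversions are exact inverses.

## Pseudo-label loop and evaluation

Threshold selection scans candidates t ∈ {0.01, 0.02, …, 0.99}
(grid step 0.01), splits scores into low (< t) and high (≥ t) groups,
and maximizes the between-class variance w₀w₁(μ₀ − μ₁)²; ties break
toward the lower threshold, and an all-identical score set is flagged
degenerate (grid midpoint returned). The per-candidate high-group
counts are logged alongside the variance curve for inspection. The
loop re-selects the threshold each round from the pooled score
distribution rather than freezing it after round 0, so it adapts as the
detector sharpens; the round count is a parameter (default 3) since no
principled stopping rule exists at this abstraction level — once false
positives are exhausted the pooled scores turn unimodal and further
rounds trade recall for purity.

Matching is greedy in descending score at IoU ≥ 0.5 (each truth box
used at most once), the common detection convention. AP is the area
under the precision envelope over recall (all-points interpolation, not
11-point sampling); with a single foreground class, mAP = AP. The
balance point is the curve point minimizing |P − R|, ties toward higher
recall.

The mock detector emits jittered truth boxes scored near a high center
and Poisson-sampled false boxes near a low center (normal score noise,
clipped to [0, 1]); retraining on pseudo-labels multiplies its
false-positive rate by the label impurity, emulating the benefit a real
detector draws from cleaner supervision. It is a calibration instrument
for the loop's logic, not a model of any detector architecture.

## Determinism and problem sizes

Every stochastic operation takes a seed or Generator; pipelines split
one global seed per stage and per item. Reported study sizes — 100
scenes of 10–30 fruits for the occlusion analyses, 3 species × 20
sprites × 20 replicate runs for partition recovery, 50 random score
sets for threshold verification — were chosen so each analysis runs in
minutes on one CPU while leaving the measured properties comfortably
away from their sampling noise floors.

## Known limitations

* The positive-frequency-only shape descriptor under-weights pure
  affine stretches (see above).
* Background segmentation is a fixed heuristic tuned to layered
  orchard scenes; cluttered or backlit real photographs would need a
  learned segmenter behind the same interface.
* The occlusion bound counts only same-scene sprite occluders; truncation
  by the image border is not counted as occlusion (the footprint is
  clipped to the canvas before the ratio is computed).
* DBSCAN's automatic eps is a heuristic; pathological cluster shapes
  (nested rings, strongly varying densities) should override it.
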