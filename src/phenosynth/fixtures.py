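"""Procedural fruit/leaf sprites, orchard backgrounds, and a mock detector.

Real multi-species transparent-background fruit collections are expensive
to assemble, so this module generates them. A species is parameterized by

* shape: a superellipse (exponent n, aspect ratio) with low-harmonic
  radial wobble — the disc limit (n=2, aspect 1, wobble 0) has a
  single-harmonic boundary, giving the Fourier shape descriptors an
  analytic ground truth;
* color: a CIELAB center plus per-channel spread — synthesis happens in
  CIELAB and converts to sRGB last, so color-descriptor recovery has a
  planted ground truth;
* texture: multiplicative multi-octave value noise on lightness.

Backgrounds are layered sky/tree/ground bands with noisy boundaries and a
ground-truth region mask, emulating orchard photographs at the level the
compositing rules need. The mock detector stands in for a trained
neural detector in the pseudo-label loop: it jitters ground-truth boxes
at high confidence and plants Poisson-sampled false boxes at low
confidence.

Everything is bit-deterministic in (seed, index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import color as skcolor
from skimage import measure, transform

from phenosynth._rng import as_generator, stream
from phenosynth.pseudolabel import ScoredBox, box_iou

__all__ = [
    "SpeciesSpec",
    "Sprite",
    "generate_fruit_sprite",
    "generate_leaf_sprite",
    "generate_background",
    "generate_species_collection",
    "mock_detector",
    "MockDetector",
    "demo_species",
    "fractal_noise",
]

DEFAULT_CANVAS = 256
MIN_FOREGROUND_AREA = 500


@dataclass
class SpeciesSpec:
    """Parameters controlling one synthetic fruit species."""

    species_id: str
    #: superellipse exponent n (> 0); n=2 is an ellipse, larger -> boxier
    shape_exponent: float = 2.0
    #: height/width ratio of the un-wobbled outline
    aspect: float = 1.0
    #: relative amplitude of low-harmonic radial wobble (dimensionless)
    wobble: float = 0.03
    #: CIELAB color center; L in [0, 100], a/b in [-128, 127]
    lab_center: Tuple[float, float, float] = (65.0, 45.0, 40.0)
    #: per-channel CIELAB standard deviation of the base color field
    lab_spread: Tuple[float, float, float] = (3.0, 2.0, 2.0)
    #: octaves of multiplicative value noise on lightness
    texture_octaves: int = 3
    #: relative contrast of the texture noise (0 disables)
    texture_contrast: float = 0.06
    seed: int = 0

    def validate(self) -> None:
        if self.shape_exponent <= 0:
            raise ValueError(f"shape_exponent must be > 0, got {self.shape_exponent}")
        if self.aspect <= 0:
            raise ValueError("aspect must be > 0")
        if self.wobble < 0:
            raise ValueError("wobble must be >= 0")
        L, a, b = self.lab_center
        if not (0 <= L <= 100 and -128 <= a <= 127 and -128 <= b <= 127):
            raise ValueError(f"lab_center outside CIELAB gamut box: {self.lab_center}")
        if self.texture_octaves < 1:
            raise ValueError("texture_octaves must be >= 1")


@dataclass
class Sprite:
    """An RGBA raster of a single fruit or leaf on transparent background."""

    pixels: np.ndarray  # (H, W, 4) uint8
    species_id: str
    source: str = "generated"  # generated | loaded | translated

    @property
    def alpha(self) -> np.ndarray:
        return self.pixels[..., 3]

    @property
    def mask(self) -> np.ndarray:
        """Binary foreground mask (alpha >= 128)."""
        return self.pixels[..., 3] >= 128

    def validate(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 4:
            raise ValueError("sprite pixels must be (H, W, 4)")
        mask = self.mask
        if mask.sum() < MIN_FOREGROUND_AREA:
            raise ValueError(
                f"foreground area {mask.sum()} < {MIN_FOREGROUND_AREA} px"
            )
        labels = measure.label(mask, connectivity=2)
        if labels.max() != 1:
            raise ValueError(f"foreground has {labels.max()} connected components")
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        h, w = mask.shape
        if rows[0] == 0 or rows[-1] == h - 1 or cols[0] == 0 or cols[-1] == w - 1:
            raise ValueError("foreground touches the image border")


def fractal_noise(
    shape: Tuple[int, int], octaves: int, rng: np.random.Generator
) -> np.ndarray:
    """Multi-octave value noise, roughly zero-mean / unit-ish scale."""
    out = np.zeros(shape, dtype=float)
    amplitude, total = 1.0, 0.0
    for octave in range(octaves):
        cells = 4 * 2**octave
        grid = rng.standard_normal((cells + 1, cells + 1))
        out += amplitude * transform.resize(
            grid, shape, order=3, mode="reflect", anti_aliasing=False
        )
        total += amplitude
        amplitude *= 0.5
    return out / total


def _superellipse_radius(
    theta: np.ndarray, exponent: float, aspect: float
) -> np.ndarray:
    """Polar radius of the unit superellipse |x|^n + |y/aspect|^n = 1."""
    c = np.abs(np.cos(theta)) ** exponent
    s = np.abs(np.sin(theta) / aspect) ** exponent
    return (c + s) ** (-1.0 / exponent)


def _paint_lab(
    mask_alpha: np.ndarray,
    lab_center: Sequence[float],
    lab_spread: Sequence[float],
    texture_octaves: int,
    texture_contrast: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill an alpha footprint with CIELAB-centered color + texture noise."""
    h, w = mask_alpha.shape
    lab = np.empty((h, w, 3), dtype=float)
    for ch in range(3):
        spread = lab_spread[ch]
        if spread > 0:
            lab[..., ch] = lab_center[ch] + spread * fractal_noise(
                (h, w), 2, rng
            )
        else:
            lab[..., ch] = lab_center[ch]
    if texture_contrast > 0:
        noise = fractal_noise((h, w), texture_octaves, rng)
        lab[..., 0] = lab[..., 0] * (1.0 + texture_contrast * noise)
    lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)
    lab[..., 1:] = np.clip(lab[..., 1:], -100.0, 100.0)
    rgb = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0)
    rgba = np.zeros((h, w, 4), dtype=np.uint8)
    fg = mask_alpha > 0
    rgba[..., :3] = np.where(
        fg[..., None], np.round(rgb * 255.0).astype(np.uint8), 0
    )
    rgba[..., 3] = np.round(np.clip(mask_alpha, 0.0, 1.0) * 255.0).astype(np.uint8)
    return rgba


def generate_fruit_sprite(
    spec: SpeciesSpec, index: int, size: int = DEFAULT_CANVAS
) -> Sprite:
    """Generate one fruit sprite, deterministic in (spec.seed, index).

    The outline is a superellipse with additive low-harmonic radial
    wobble; the fill is the species CIELAB center plus smooth per-channel
    spread and multiplicative lightness texture. The alpha edge is
    anti-aliased (soft 1-px ramp) so extracted contours are sub-pixel
    smooth.
    """
    spec.validate()
    if index < 0:
        raise ValueError("index must be >= 0")
    rng = stream(spec.seed, 0, index)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = cy = (size - 1) / 2.0
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    base_r = 0.33 * size
    boundary = base_r * _superellipse_radius(theta, spec.shape_exponent, spec.aspect)
    if spec.wobble > 0:
        harmonics = np.arange(2, 7)
        amps = rng.normal(0.0, 1.0, size=harmonics.size)
        amps *= spec.wobble / max(np.abs(amps).sum(), 1e-12)
        phases = rng.uniform(0.0, 2 * np.pi, size=harmonics.size)
        wob = np.zeros_like(theta)
        for h, a, p in zip(harmonics, amps, phases):
            wob += a * np.cos(h * theta + p)
        boundary = boundary * (1.0 + wob)
    else:
        # keep the RNG stream aligned whether or not wobble is used
        rng.normal(0.0, 1.0, size=5)
        rng.uniform(0.0, 2 * np.pi, size=5)

    alpha = np.clip(boundary - r + 0.5, 0.0, 1.0)
    rgba = _paint_lab(
        alpha,
        spec.lab_center,
        spec.lab_spread,
        spec.texture_octaves,
        spec.texture_contrast,
        rng,
    )
    sprite = Sprite(pixels=rgba, species_id=spec.species_id, source="generated")
    sprite.validate()
    return sprite


def generate_leaf_sprite(
    seed: int, index: int, size: int = DEFAULT_CANVAS
) -> Sprite:
    """Generate one lanceolate, green leaf sprite (tip pointing down).

    The outline is a symmetric lanceolate profile: along the axis
    t in [0, 1], half-width w(t) = W * sin(pi * t)^0.8, tapering to both
    ends. Color is a green CIELAB center (a < 0) with small per-leaf
    variation. Rotation 0 in the compositor means "hanging downward".
    """
    rng = stream(seed, 1, index)
    length = 0.80 * size
    halfwidth = 0.14 * size * rng.uniform(0.8, 1.2)
    y0 = (size - length) / 2.0
    cx = (size - 1) / 2.0

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    t = (yy - y0) / length
    inside = (t > 0) & (t < 1)
    w_t = np.zeros_like(t)
    w_t[inside] = halfwidth * np.sin(np.pi * t[inside]) ** 0.8
    # slight asymmetric bend of the midrib
    bend = 0.08 * size * rng.uniform(-1.0, 1.0)
    mid = cx + bend * np.sin(np.pi * np.clip(t, 0, 1))
    alpha = np.clip(w_t - np.abs(xx - mid) + 0.5, 0.0, 1.0)
    alpha[~inside] = 0.0

    lab_center = (
        42.0 + rng.uniform(-4.0, 4.0),
        -38.0 + rng.uniform(-5.0, 5.0),
        32.0 + rng.uniform(-4.0, 4.0),
    )
    rgba = _paint_lab(alpha, lab_center, (4.0, 3.0, 3.0), 3, 0.08, rng)
    sprite = Sprite(pixels=rgba, species_id="leaf", source="generated")
    sprite.validate()
    return sprite


def generate_background(
    width: int, height: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Layered orchard background: sky band, tree band, ground band.

    Returns (RGB uint8 image, region mask) where the mask labels each
    pixel 0=sky, 1=tree, 2=ground. Band boundaries are smooth 1-D noise
    curves; the tree band occupies roughly half the image.
    """
    if width < 128 or height < 128:
        raise ValueError("background must be at least 128x128")
    rng = stream(seed, 2)

    def boundary_curve(mean_frac: float) -> np.ndarray:
        knots = rng.standard_normal(9)
        curve = transform.resize(
            knots[None, :], (1, width), order=3, mode="reflect",
            anti_aliasing=False,
        )[0]
        return mean_frac * height + 0.04 * height * curve

    sky_bottom = boundary_curve(0.22)
    tree_bottom = boundary_curve(0.78)
    tree_bottom = np.maximum(tree_bottom, sky_bottom + 0.15 * height)

    yy = np.arange(height, dtype=float)[:, None]
    region = np.full((height, width), 1, dtype=np.uint8)
    region[yy < sky_bottom[None, :]] = 0
    region[yy >= tree_bottom[None, :]] = 2

    img = np.empty((height, width, 3), dtype=float)
    noise = fractal_noise((height, width), 4, rng)
    # sky: blue, brighter near the horizon
    grad = (yy / max(height - 1, 1)) * np.ones((1, width))
    sky = np.stack(
        [
            140 + 40 * grad + 6 * noise,
            180 + 30 * grad + 6 * noise,
            230 + 10 * grad + 6 * noise,
        ],
        axis=-1,
    )
    # tree canopy: green-dominant with strong texture
    tree = np.stack(
        [
            60 + 22 * noise,
            100 + 30 * noise,
            45 + 16 * noise,
        ],
        axis=-1,
    )
    # ground: brown, R > G > B
    ground = np.stack(
        [
            130 + 18 * noise,
            95 + 14 * noise,
            60 + 10 * noise,
        ],
        axis=-1,
    )
    img = np.where(
        (region == 0)[..., None], sky, np.where((region == 1)[..., None], tree, ground)
    )
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, region


def generate_species_collection(
    specs: Sequence[SpeciesSpec], n_per_species: int, size: int = DEFAULT_CANVAS
) -> List[Sprite]:
    """Generate n_per_species sprites for each spec, species-tagged."""
    if len(specs) < 2:
        raise ValueError("need at least 2 species specs")
    if n_per_species < 2:
        raise ValueError("need at least 2 sprites per species")
    sprites: List[Sprite] = []
    for spec in specs:
        for i in range(n_per_species):
            sprites.append(generate_fruit_sprite(spec, i, size=size))
    return sprites


def demo_species(
    n_species: int = 3, seed: int = 0, separated: bool = True
) -> List[SpeciesSpec]:
    """A palette of well-separated demo species (distinct shape exponents
    and CIELAB centers with pairwise deltaE > 30)."""
    # aspect kept away from 1 so each species has a deterministic
    # low-harmonic shape signature (a pure disc's normalized descriptor
    # is all-zero and correlates as noise)
    shapes = [(2.0, 0.82), (3.5, 0.70), (1.4, 1.30), (5.0, 0.88), (2.5, 0.60)]
    colors = [
        (70.0, 45.0, 45.0),   # orange-red
        (75.0, -35.0, 55.0),  # green-yellow
        (45.0, 55.0, 10.0),   # dark red
        (85.0, 0.0, 70.0),    # yellow
        (55.0, -45.0, 20.0),  # green
    ]
    if n_species > len(shapes):
        raise ValueError(f"at most {len(shapes)} demo species available")
    specs = []
    for k in range(n_species):
        exponent, aspect = shapes[k]
        specs.append(
            SpeciesSpec(
                species_id=f"species_{k}",
                shape_exponent=exponent,
                aspect=aspect,
                wobble=0.02 if separated else 0.05,
                lab_center=colors[k],
                lab_spread=(3.0, 2.0, 2.0),
                texture_octaves=3,
                texture_contrast=0.05 + 0.03 * k,
                seed=seed + k,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Mock detector
# ---------------------------------------------------------------------------


def mock_detector(
    truth: Sequence[ScoredBox],
    score_high: float,
    score_low: float,
    fp_rate: float,
    miss_rate: float,
    seed: int,
    jitter: float = 0.0,
    score_spread: float = 0.0,
    image_size: Tuple[int, int] = (512, 512),
) -> List[ScoredBox]:
    """Simulate detector output from ground truth.

    Each truth box is emitted with probability 1 - miss_rate, jittered by
    a fraction ``jitter`` of its own size, and scored near ``score_high``.
    Per image, ``Poisson(fp_rate * n_truth_in_image)`` false boxes with
    random geometry are added, scored near ``score_low``. Scores are
    normal with sd ``score_spread``, clipped to [0, 1]. Emitted boxes
    carry ``origin`` = "truth" or "false" for test bookkeeping.
    """
    if not (0.0 <= fp_rate and 0.0 <= miss_rate <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if score_low >= score_high:
        raise ValueError("score_low must be < score_high")
    rng = as_generator(seed)
    width, height = image_size
    by_image: Dict[str, List[ScoredBox]] = {}
    for g in truth:
        by_image.setdefault(g.image_ref, []).append(g)
    out: List[ScoredBox] = []
    for image_ref in sorted(by_image):
        boxes = by_image[image_ref]
        for g in boxes:
            if rng.random() < miss_rate:
                continue
            x, y, w, h = g.bbox
            if jitter > 0:
                x += rng.normal(0.0, jitter * w)
                y += rng.normal(0.0, jitter * h)
                w = max(1.0, w * (1.0 + rng.normal(0.0, jitter)))
                h = max(1.0, h * (1.0 + rng.normal(0.0, jitter)))
            score = score_high
            if score_spread > 0:
                score = rng.normal(score_high, score_spread)
            out.append(
                ScoredBox(
                    image_ref=image_ref,
                    bbox=(x, y, w, h),
                    score=float(np.clip(score, 0.0, 1.0)),
                    origin="truth",
                )
            )
        n_fp = rng.poisson(fp_rate * len(boxes))
        for _ in range(n_fp):
            w = rng.uniform(0.04, 0.15) * width
            h = rng.uniform(0.04, 0.15) * height
            x = rng.uniform(0, width - w)
            y = rng.uniform(0, height - h)
            score = score_low
            if score_spread > 0:
                score = rng.normal(score_low, score_spread)
            out.append(
                ScoredBox(
                    image_ref=image_ref,
                    bbox=(float(x), float(y), float(w), float(h)),
                    score=float(np.clip(score, 0.0, 1.0)),
                    origin="false",
                )
            )
    return out


class MockDetector:
    """A :class:`~phenosynth.pseudolabel.DetectorContract` stand-in.

    Holds the ground truth internally (it is a mock); ``infer`` calls
    :func:`mock_detector` with a false-positive rate that shrinks as the
    detector is retrained on purer pseudo-label sets, emulating the
    improvement a real detector gains from cleaner supervision. ``train``
    measures label purity against the truth at IoU 0.5 and multiplies the
    false-positive scale by the impurity.
    """

    def __init__(
        self,
        truth: Sequence[ScoredBox],
        score_high: float = 0.8,
        score_low: float = 0.5,
        fp_rate: float = 0.3,
        miss_rate: float = 0.0,
        jitter: float = 0.0,
        score_spread: float = 0.12,
        image_size: Tuple[int, int] = (512, 512),
    ):
        self.truth = list(truth)
        self.score_high = score_high
        self.score_low = score_low
        self.fp_rate = fp_rate
        self.miss_rate = miss_rate
        self.jitter = jitter
        self.score_spread = score_spread
        self.image_size = image_size

    def train(self, images, labels, state):
        if state is None:
            return {"fp_scale": 1.0, "rounds_trained": 0}
        labels = list(labels)
        if labels:
            tp = 0
            matched = set()
            for b in labels:
                for j, g in enumerate(self.truth):
                    if j in matched or g.image_ref != b.image_ref:
                        continue
                    if box_iou(b.bbox, g.bbox) >= 0.5:
                        tp += 1
                        matched.add(j)
                        break
            impurity = 1.0 - tp / len(labels)
        else:
            impurity = 1.0
        return {
            "fp_scale": state["fp_scale"] * max(impurity, 0.01),
            "rounds_trained": state["rounds_trained"] + 1,
        }

    def infer(self, images, state, seed: int) -> List[ScoredBox]:
        image_set = set(images)
        truth = [g for g in self.truth if g.image_ref in image_set]
        fp_scale = 1.0 if state is None else state["fp_scale"]
        return mock_detector(
            truth,
            score_high=self.score_high,
            score_low=self.score_low,
            fp_rate=self.fp_rate * fp_scale,
            miss_rate=self.miss_rate,
            seed=seed,
            jitter=self.jitter,
            score_spread=self.score_spread,
            image_size=self.image_size,
        )
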