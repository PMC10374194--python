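"""Shape, color, and texture descriptors and pairwise distance matrices.

Shape: the closed fruit boundary is traversed counterclockwise, arc-
length resampled to a fixed number of points N_b, encoded as a complex
sequence s(k) = x(k) + j*y(k), and Fourier-transformed:

    a(u) = (1/N_b) * sum_k s(k) * exp(-j*2*pi*k*u/N_b)

Two normalizations are provided. ``mode="paper"`` stores |a(u)/a(0)|,
which divides by the centroid term and is therefore *not* translation
invariant; ``mode="standard"`` (default) stores |a(u)|/|a(1)| for
u = 2..U+1, which is invariant to translation, rotation, uniform scaling
and start-point shift. Shape dissimilarity between two descriptor
vectors is 1 - Pearson correlation.

Color: foreground pixels are converted sRGB -> CIELAB (D65, 2 degrees);
each channel's value range is divided into fixed 20-unit intervals, and
the descriptor keeps the per-interval pixel fractions Rate_i = N_i/N_all
and interval means Mean_i. The channel summary is the weighted sum
sum_i Rate_i * Mean_i (algebraically the plain channel mean, but kept in
histogram form to expose the distribution). Color distance is the
Euclidean (L2) distance between the weighted Lab means.

Texture: square patches are sampled uniformly among positions lying
(almost) entirely inside the fruit foreground; each patch is summarized
by a rotation-invariant uniform LBP histogram (8 neighbors, radius 1,
10 bins), and a descriptor aggregates the per-patch histograms by their
mean. Texture dissimilarity is again 1 - Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import color as skcolor
from skimage import feature, measure

from phenosynth._rng import as_generator, substream_seed
from phenosynth.fixtures import Sprite

__all__ = [
    "ContourSequence",
    "ShapeDescriptor",
    "ColorDescriptor",
    "TextureDescriptor",
    "DistanceMatrix",
    "extract_contour",
    "resample_closed_contour",
    "shape_descriptor",
    "shape_distance",
    "color_descriptor",
    "color_distance",
    "sample_texture_patches",
    "valid_patch_positions",
    "texture_descriptor",
    "texture_distance",
    "pearson_distance",
    "build_distance_matrix",
    "LBP_N_BINS",
]

DEFAULT_N_POINTS = 128
DEFAULT_N_TERMS = 16
LBP_NEIGHBORS = 8
LBP_RADIUS = 1
LBP_N_BINS = LBP_NEIGHBORS + 2  # rotation-invariant uniform codes

#: CIELAB channel value ranges used for interval binning
_LAB_RANGES = ((0.0, 100.0), (-128.0, 127.0), (-128.0, 127.0))


@dataclass
class ContourSequence:
    """Closed boundary as ordered (x, y) points, counterclockwise.

    Coordinates are 0-based with origin at the top-left and y increasing
    downward. "Counterclockwise" means positive shoelace area in the
    complex plane s = x + j*y used by the Fourier descriptor, so the
    boundary's fundamental harmonic lands at u = 1.
    """

    points: np.ndarray  # (N, 2) float, columns x, y
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be (N, 2)")
        if len(self.points) < 8:
            raise ValueError("contour needs at least 8 points")

    def __len__(self) -> int:
        return len(self.points)


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


def resample_closed_contour(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polyline to n_points equally spaced by arc length."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    targets = total * np.arange(n_points) / n_points
    x = np.interp(targets, arclen, closed[:, 0])
    y = np.interp(targets, arclen, closed[:, 1])
    return np.column_stack([x, y])


def extract_contour(sprite: Sprite, n_points: int = DEFAULT_N_POINTS) -> ContourSequence:
    """Outer boundary of the sprite's largest foreground component.

    Uses sub-pixel marching squares on the alpha channel at level 0.5,
    orients the boundary counterclockwise (visually, y-down frame), and
    arc-length resamples to ``n_points``.
    """
    alpha = sprite.pixels[..., 3].astype(float) / 255.0
    mask = alpha >= 0.5
    if not mask.any():
        raise ValueError("sprite has an empty foreground")
    labels = measure.label(mask, connectivity=2)
    if labels.max() > 1:
        warnings.warn(
            f"foreground has {labels.max()} components; using the largest",
            stacklevel=2,
        )
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        alpha = np.where(labels == largest, alpha, 0.0)
    contours = measure.find_contours(alpha, 0.5)
    if not contours:
        raise ValueError("no contour found at alpha level 0.5")
    boundary = max(contours, key=len)  # rows, cols
    pts = boundary[:, ::-1]  # -> x, y
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if _signed_area(pts) < 0:  # enforce CCW in the x + j*y plane
        pts = pts[::-1]
    return ContourSequence(points=resample_closed_contour(pts, n_points))


@dataclass
class ShapeDescriptor:
    """Fourier boundary descriptor of a closed contour."""

    coefficients: np.ndarray  # complex a(u), u = 0..N_b-1
    normalized: np.ndarray  # real d-values, length n_terms
    mode: str  # "paper" | "standard"
    n_terms: int


def fourier_coefficients(contour: ContourSequence) -> np.ndarray:
    """a(u) = (1/N) sum_k s(k) exp(-j 2 pi k u / N), s(k) = x(k) + j y(k)."""
    s = contour.points[:, 0] + 1j * contour.points[:, 1]
    return np.fft.fft(s) / len(s)


def shape_descriptor(
    contour: ContourSequence,
    n_terms: int = DEFAULT_N_TERMS,
    mode: str = "standard",
) -> ShapeDescriptor:
    """Normalized Fourier descriptor of a closed contour.

    mode="standard": d(u) = |a(u)| / |a(1)| for u = 2..n_terms+1
    (translation/rotation/scale/start-shift invariant).
    mode="paper": d(u) = |a(u) / a(0)| for u = 0..n_terms-1 (divides by
    the centroid term; kept for literal reproduction).
    """
    if not contour.closed:
        raise ValueError("contour must be closed")
    a = fourier_coefficients(contour)
    n = len(a)
    if mode == "paper":
        if n_terms > n:
            raise ValueError("n_terms exceeds contour length")
        if abs(a[0]) < 1e-9:
            raise ValueError(
                "paper-mode normalization undefined: centroid at the origin (|a(0)| ~ 0)"
            )
        d = np.abs(a[:n_terms] / a[0])
    elif mode == "standard":
        if n_terms + 2 > n:
            raise ValueError("n_terms + 2 exceeds contour length")
        if abs(a[1]) < 1e-12:
            raise ValueError("degenerate contour: |a(1)| ~ 0")
        d = np.abs(a[2 : n_terms + 2]) / np.abs(a[1])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ShapeDescriptor(coefficients=a, normalized=d, mode=mode, n_terms=n_terms)


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation, in [0, 2].

    Convention for zero-variance inputs: 0 if the sequences are exactly
    equal, else 2 (maximal dissimilarity).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("descriptor vectors must have equal length")
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0 if np.array_equal(x, y) else 2.0
    rho = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return 1.0 - rho


def shape_distance(d1: ShapeDescriptor, d2: ShapeDescriptor) -> float:
    """Shape dissimilarity: 1 - Pearson correlation of the d-sequences."""
    if d1.mode != d2.mode:
        raise ValueError("cannot compare descriptors of different modes")
    return pearson_distance(d1.normalized, d2.normalized)


@dataclass
class ColorDescriptor:
    """CIELAB interval-histogram color summary of a sprite's foreground."""

    lab_means: np.ndarray  # (3,) weighted means, one per L/a/b channel
    lab_vars: np.ndarray  # (3,) interval-weighted variances
    bin_width: float
    rates: List[np.ndarray]  # per channel, per-interval pixel fractions
    interval_means: List[np.ndarray]  # per channel, per-interval means


def _channel_bins(channel: int, bin_width: float) -> np.ndarray:
    lo, hi = _LAB_RANGES[channel]
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    return edges


def color_descriptor(sprite: Sprite, bin_width: float = 20.0) -> ColorDescriptor:
    """CIELAB interval rates, means, weighted means and variances.

    Foreground pixels (alpha >= 128) are converted sRGB -> CIELAB under
    D65/2 degrees. Per channel, values are divided into fixed
    ``bin_width``-unit intervals; Rate_i = N_i / N_all, Mean_i is the
    mean value inside interval i, and the channel summary is
    sum_i Rate_i * Mean_i with variance sum_i Rate_i * (Mean_i - mean)^2.
    """
    mask = sprite.mask
    if not mask.any():
        raise ValueError("sprite has an empty foreground")
    rgb = sprite.pixels[..., :3].astype(float) / 255.0
    lab = skcolor.rgb2lab(rgb[mask][None, :, :])[0]  # (N_all, 3)
    n_all = lab.shape[0]

    means = np.zeros(3)
    variances = np.zeros(3)
    rates: List[np.ndarray] = []
    interval_means: List[np.ndarray] = []
    for ch in range(3):
        values = lab[:, ch]
        edges = _channel_bins(ch, bin_width)
        idx = np.clip(np.digitize(values, edges) - 1, 0, len(edges) - 2)
        n_bins = len(edges) - 1
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        sums = np.bincount(idx, weights=values, minlength=n_bins)
        rate = counts / n_all
        mean_i = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
        weighted_mean = float(np.sum(rate * mean_i))
        weighted_var = float(np.sum(rate * (mean_i - weighted_mean) ** 2))
        means[ch] = weighted_mean
        variances[ch] = weighted_var
        rates.append(rate)
        interval_means.append(mean_i)
    return ColorDescriptor(
        lab_means=means,
        lab_vars=variances,
        bin_width=bin_width,
        rates=rates,
        interval_means=interval_means,
    )


def color_distance(c1: ColorDescriptor, c2: ColorDescriptor) -> float:
    """L2 distance between the weighted CIELAB means (deltaE-76 form)."""
    if c1.bin_width != c2.bin_width:
        raise ValueError("descriptors use different bin widths")
    return float(np.linalg.norm(c1.lab_means - c2.lab_means))


def valid_patch_positions(sprite: Sprite, patch_size: int, min_coverage: float = 0.95) -> np.ndarray:
    """All (row, col) top-left positions whose patch footprint is
    >= min_coverage inside the foreground mask."""
    mask = sprite.mask.astype(np.int64)
    h, w = mask.shape
    if patch_size > min(h, w):
        return np.empty((0, 2), dtype=int)
    integral = np.pad(mask.cumsum(axis=0).cumsum(axis=1), ((1, 0), (1, 0)))
    p = patch_size
    window = (
        integral[p:, p:]
        - integral[:-p, p:]
        - integral[p:, :-p]
        + integral[:-p, :-p]
    )
    valid = window >= min_coverage * p * p
    return np.argwhere(valid)


def sample_texture_patches(
    sprite: Sprite,
    n_patches: int = 16,
    patch_size: int = 32,
    seed: int = 0,
) -> List[np.ndarray]:
    """Sample grayscale patches uniformly among near-interior positions.

    Positions whose footprint is at least 95% foreground are enumerated
    exhaustively and sampled with replacement; sampling is seeded.
    """
    positions = valid_patch_positions(sprite, patch_size)
    if len(positions) == 0:
        raise ValueError(
            f"no valid {patch_size}px patch position inside the foreground; "
            "try a smaller patch_size"
        )
    rng = as_generator(seed)
    chosen = positions[rng.integers(0, len(positions), size=n_patches)]
    gray = np.round(
        skcolor.rgb2gray(sprite.pixels[..., :3].astype(float) / 255.0) * 255.0
    ).astype(np.uint8)
    return [
        gray[r : r + patch_size, c : c + patch_size].copy() for r, c in chosen
    ]


@dataclass
class TextureDescriptor:
    """Rotation-invariant uniform LBP histogram summary over patches."""

    patch_histograms: np.ndarray  # (n_patches, LBP_N_BINS)
    n_patches: int
    patch_size: int
    aggregate: np.ndarray  # (LBP_N_BINS,) mean histogram


def texture_descriptor(patches: Sequence[np.ndarray]) -> TextureDescriptor:
    """LBP (8 neighbors, radius 1, rotation-invariant uniform) histograms.

    Each patch yields a 10-bin L1-normalized code histogram; the
    aggregate is the mean histogram over patches.
    """
    if len(patches) == 0:
        raise ValueError("need at least one patch")
    hists = np.empty((len(patches), LBP_N_BINS))
    for i, patch in enumerate(patches):
        codes = feature.local_binary_pattern(
            patch, LBP_NEIGHBORS, LBP_RADIUS, method="uniform"
        )
        r = LBP_RADIUS  # drop the border ring: its neighborhoods are clipped
        codes = codes[r:-r, r:-r]
        hist = np.bincount(
            codes.astype(int).ravel(), minlength=LBP_N_BINS
        ).astype(float)
        hists[i] = hist / hist.sum()
    return TextureDescriptor(
        patch_histograms=hists,
        n_patches=len(patches),
        patch_size=patches[0].shape[0],
        aggregate=hists.mean(axis=0),
    )


def texture_distance(t1: TextureDescriptor, t2: TextureDescriptor) -> float:
    """1 - Pearson correlation of the aggregate LBP histograms."""
    if t1.aggregate.shape != t2.aggregate.shape:
        raise ValueError("descriptors use different LBP configurations")
    return pearson_distance(t1.aggregate, t2.aggregate)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix for one feature dimension."""

    labels: List[str]
    values: np.ndarray
    feature: str  # shape | color | texture
    level: str  # image | dataset

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def validate(self) -> None:
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("distance matrix has negative entries")


def _image_descriptors(
    sprites: Sequence[Sprite],
    feature_name: str,
    *,
    n_points: int,
    n_terms: int,
    mode: str,
    bin_width: float,
    n_patches: int,
    patch_size: int,
    seed: int,
):
    if feature_name == "shape":
        return [
            shape_descriptor(extract_contour(s, n_points), n_terms, mode)
            for s in sprites
        ]
    if feature_name == "color":
        return [color_descriptor(s, bin_width) for s in sprites]
    if feature_name == "texture":
        return [
            texture_descriptor(
                sample_texture_patches(
                    s, n_patches, patch_size, seed=substream_seed(seed, 3, i)
                )
            )
            for i, s in enumerate(sprites)
        ]
    raise ValueError(f"unknown feature {feature_name!r}")


_DISTANCE_FN = {
    "shape": shape_distance,
    "color": color_distance,
    "texture": texture_distance,
}


def build_distance_matrix(
    sprites: Sequence[Sprite],
    feature: str,
    level: str = "image",
    *,
    n_points: int = DEFAULT_N_POINTS,
    n_terms: int = DEFAULT_N_TERMS,
    mode: str = "standard",
    bin_width: float = 20.0,
    n_patches: int = 16,
    patch_size: int = 32,
    seed: int = 0,
    dataset_aggregate: str = "pairs",
) -> DistanceMatrix:
    """Pairwise feature-distance matrix at image or dataset level.

    Image level: one row per sprite, labeled ``species#index``. Dataset
    level: one row per species tag; with ``dataset_aggregate="pairs"``
    (default) entry (A, B) is the mean of all image-level cross-pair
    distances between A's and B's sprites; ``"descriptor-mean"`` instead
    averages descriptors within each species first.
    """
    if len(sprites) < 2:
        raise ValueError("need at least 2 sprites")
    dist_fn = _DISTANCE_FN[feature]
    descriptors = _image_descriptors(
        sprites,
        feature,
        n_points=n_points,
        n_terms=n_terms,
        mode=mode,
        bin_width=bin_width,
        n_patches=n_patches,
        patch_size=patch_size,
        seed=seed,
    )
    if level == "image":
        n = len(sprites)
        counts: Dict[str, int] = {}
        labels = []
        for s in sprites:
            k = counts.get(s.species_id, 0)
            labels.append(f"{s.species_id}#{k}")
            counts[s.species_id] = k + 1
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = dist_fn(descriptors[i], descriptors[j])
                values[i, j] = values[j, i] = d
        return DistanceMatrix(labels=labels, values=values, feature=feature, level="image")

    if level != "dataset":
        raise ValueError(f"unknown level {level!r}")
    for s in sprites:
        if not s.species_id:
            raise ValueError("dataset-level matrix requires species tags")
    species: List[str] = []
    for s in sprites:
        if s.species_id not in species:
            species.append(s.species_id)
    if len(species) < 2:
        raise ValueError("dataset level needs at least 2 species")
    groups = {sp: [i for i, s in enumerate(sprites) if s.species_id == sp] for sp in species}
    m = len(species)
    values = np.zeros((m, m))
    if dataset_aggregate == "pairs":
        for a in range(m):
            for b in range(a + 1, m):
                pairs = [
                    dist_fn(descriptors[i], descriptors[j])
                    for i in groups[species[a]]
                    for j in groups[species[b]]
                ]
                values[a, b] = values[b, a] = float(np.mean(pairs))
    elif dataset_aggregate == "descriptor-mean":
        mean_desc = {}
        for sp in species:
            idx = groups[sp]
            if feature == "shape":
                stacked = np.mean([descriptors[i].normalized for i in idx], axis=0)
                proto = descriptors[idx[0]]
                mean_desc[sp] = ShapeDescriptor(
                    coefficients=proto.coefficients,
                    normalized=stacked,
                    mode=proto.mode,
                    n_terms=proto.n_terms,
                )
            elif feature == "color":
                proto = descriptors[idx[0]]
                mean_desc[sp] = ColorDescriptor(
                    lab_means=np.mean([descriptors[i].lab_means for i in idx], axis=0),
                    lab_vars=np.mean([descriptors[i].lab_vars for i in idx], axis=0),
                    bin_width=proto.bin_width,
                    rates=proto.rates,
                    interval_means=proto.interval_means,
                )
            else:
                proto = descriptors[idx[0]]
                agg = np.mean([descriptors[i].aggregate for i in idx], axis=0)
                mean_desc[sp] = TextureDescriptor(
                    patch_histograms=proto.patch_histograms,
                    n_patches=proto.n_patches,
                    patch_size=proto.patch_size,
                    aggregate=agg,
                )
        for a in range(m):
            for b in range(a + 1, m):
                d = dist_fn(mean_desc[species[a]], mean_desc[species[b]])
                values[a, b] = values[b, a] = d
    else:
        raise ValueError(f"unknown dataset_aggregate {dataset_aggregate!r}")
    return DistanceMatrix(labels=species, values=values, feature=feature, level="dataset")
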