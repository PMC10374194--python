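"""Cross-species commonality model: fused 2-D feature space and medoids.

The three feature distance matrices (shape, color, texture) live on
different numeric scales, so each is first multiplied by

    scale_feature = max_range / range_feature

where range_feature is the max-min spread of that matrix's off-diagonal
distances and max_range is the largest of the three spreads; after
scaling, all three matrices span the same range exactly. Each scaled
matrix is embedded in 2-D by classical (Torgerson) MDS — double-centered
Gram matrix, top-2 eigenpairs — which is deterministic up to axis signs;
signs are fixed by making each axis's largest-magnitude coordinate
positive. The three 2-D embeddings are fused into one plane by PCA:
the x coordinate is the first principal-component score of the shape
embedding, the y coordinate the first PC score of the concatenated
color+texture block. DBSCAN then partitions the fused plane, and each
cluster's representative — the optimal source-domain dataset — is its
medoid, the member with the smallest mean distance to its co-members.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import DBSCAN

from phenosynth.phenotype import DistanceMatrix, build_distance_matrix

__all__ = [
    "FeatureSpaceEmbedding",
    "ClusterResult",
    "SourceSelection",
    "normalize_scales",
    "mds_embed",
    "pca_first_component",
    "fuse_features",
    "build_embedding",
    "estimate_eps",
    "cluster_embedding",
    "select_optimal_sources",
]


@dataclass
class FeatureSpaceEmbedding:
    labels: List[str]
    shape_xy: np.ndarray
    color_xy: np.ndarray
    texture_xy: np.ndarray
    fused_xy: np.ndarray
    scales: Dict[str, float]


@dataclass
class ClusterResult:
    labels: List[str]
    cluster_ids: np.ndarray  # -1 = noise
    medoids: Dict[int, str]  # cluster id -> entity label
    eps: float
    min_samples: int


@dataclass
class SourceSelection:
    embedding: FeatureSpaceEmbedding
    clusters: ClusterResult
    #: cluster id -> entity labels ranked by mean intra-cluster distance
    recommendations: Dict[int, List[str]]


def _offdiag_range(values: np.ndarray) -> float:
    off = values[~np.eye(len(values), dtype=bool)]
    return float(off.max() - off.min())


def normalize_scales(
    d_shape: DistanceMatrix, d_color: DistanceMatrix, d_texture: DistanceMatrix
) -> Tuple[Tuple[DistanceMatrix, DistanceMatrix, DistanceMatrix], Dict[str, float]]:
    """Rescale the three matrices so their distance ranges coincide.

    Each matrix is multiplied by max_range / own_range, computed over
    off-diagonal entries. Raises if any matrix has zero range.
    """
    mats = {"shape": d_shape, "color": d_color, "texture": d_texture}
    labels = d_shape.labels
    for name, m in mats.items():
        if m.labels != labels:
            raise ValueError(f"{name} matrix labels differ from shape matrix labels")
    ranges = {name: _offdiag_range(m.values) for name, m in mats.items()}
    for name, r in ranges.items():
        if r <= 0:
            raise ValueError(f"zero distance range in {name} matrix; cannot normalize")
    max_range = max(ranges.values())
    scales = {name: max_range / r for name, r in ranges.items()}
    scaled = tuple(
        DistanceMatrix(
            labels=list(m.labels),
            values=m.values * scales[name],
            feature=m.feature,
            level=m.level,
        )
        for name, m in mats.items()
    )
    return scaled, scales


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Make each axis's largest-magnitude coordinate positive (reproducible)."""
    out = coords.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, k] = -col
    return out


def mds_embed(d: DistanceMatrix, dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix.

    B = -1/2 * J D^2 J with J the centering matrix; coordinates are the
    top-``dim`` eigenvectors scaled by sqrt(eigenvalue). Deterministic;
    axis signs fixed by the largest-magnitude rule. If fewer than ``dim``
    eigenvalues are positive the missing axes are zero-padded with a
    warning.
    """
    d.validate()
    D = d.values
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, dim))
    n_pos = int(np.sum(eigvals[:dim] > 1e-12))
    if n_pos < dim:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; padding {dim - n_pos} zero axes",
            stacklevel=2,
        )
    for k in range(min(dim, n_pos)):
        coords[:, k] = eigvecs[:, k] * np.sqrt(eigvals[k])
    return _fix_signs(coords)


def pca_first_component(block: np.ndarray) -> np.ndarray:
    """First principal-component score of a (centered) column block.

    Returns zeros with a warning if the block has no variance.
    """
    X = np.asarray(block, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0.0):
        warnings.warn("rank-0 block; axis set to zeros", stacklevel=2)
        return np.zeros(len(X))
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    scores = X @ vt[0]
    return _fix_signs(scores[:, None])[:, 0]


def fuse_features(
    shape_xy: np.ndarray, color_xy: np.ndarray, texture_xy: np.ndarray
) -> np.ndarray:
    """Fuse per-feature 2-D embeddings into one plane.

    x = first PC score of the shape embedding; y = first PC score of the
    concatenated color (+) texture 4-column block.
    """
    if not (len(shape_xy) == len(color_xy) == len(texture_xy)):
        raise ValueError("embeddings must cover identical entities")
    x = pca_first_component(shape_xy)
    y = pca_first_component(np.hstack([color_xy, texture_xy]))
    return np.column_stack([x, y])


def build_embedding(
    d_shape: DistanceMatrix, d_color: DistanceMatrix, d_texture: DistanceMatrix
) -> FeatureSpaceEmbedding:
    """Scale-normalize, MDS-embed, and fuse the three distance matrices."""
    (s_shape, s_color, s_texture), scales = normalize_scales(d_shape, d_color, d_texture)
    shape_xy = mds_embed(s_shape)
    color_xy = mds_embed(s_color)
    texture_xy = mds_embed(s_texture)
    fused = fuse_features(shape_xy, color_xy, texture_xy)
    return FeatureSpaceEmbedding(
        labels=list(d_shape.labels),
        shape_xy=shape_xy,
        color_xy=color_xy,
        texture_xy=texture_xy,
        fused_xy=fused,
        scales=scales,
    )


def estimate_eps(points: np.ndarray, k: int = 4) -> float:
    """Radius estimate from the sorted k-NN distance curve.

    If the curve shows a dominant jump (a consecutive ratio > 2 — the
    signature of a cluster/outlier gap), eps is placed inside that gap;
    otherwise every point should be reachable and eps is set just above
    the largest k-NN distance.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points to estimate eps")
    k = min(k, n - 1)  # small collections: fall back to the nearest rank
    diffs = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diffs, axis=-1)
    kth = np.sort(dist, axis=1)[:, k]  # column 0 is self-distance 0
    curve = np.sort(kth)
    if curve[-1] <= 0:
        raise ValueError("all points identical; eps undefined")
    positive = curve[curve > 0]
    lo = positive[:-1]
    hi = positive[1:]
    ratios = hi / lo
    if ratios.size and ratios.max() > 2.0:
        j = int(np.argmax(ratios))
        return float(0.5 * (lo[j] + hi[j]))
    return float(1.1 * curve[-1])


def cluster_embedding(
    fused_xy: np.ndarray,
    labels: Sequence[str],
    eps: Optional[float] = None,
    min_samples: int = 4,
) -> ClusterResult:
    """DBSCAN on the fused plane plus per-cluster medoid selection.

    ``eps=None`` uses the 4-NN knee heuristic. The medoid of a cluster is
    the member with the smallest mean Euclidean distance to its
    co-members; ties break toward the earlier label.
    """
    pts = np.asarray(fused_xy, dtype=float)
    if len(pts) < min_samples:
        raise ValueError("fewer points than min_samples")
    if eps is None:
        eps = estimate_eps(pts, k=min_samples)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    ids = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)
    medoids: Dict[int, str] = {}
    for cid in sorted(set(ids)):
        if cid == -1:
            continue
        members = np.flatnonzero(ids == cid)
        sub = pts[members]
        dists = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
        mean_d = dists.mean(axis=1)
        medoids[int(cid)] = labels[members[int(np.argmin(mean_d))]]
    return ClusterResult(
        labels=list(labels),
        cluster_ids=ids,
        medoids=medoids,
        eps=float(eps),
        min_samples=min_samples,
    )


def select_optimal_sources(
    sprites,
    *,
    eps: Optional[float] = None,
    min_samples: int = 4,
    level: str = "dataset",
    seed: int = 0,
    out_json: Optional[str] = None,
    plot_path: Optional[str] = None,
    **feature_params,
) -> SourceSelection:
    """End-to-end optimal source-domain selection from sprites.

    Builds the three distance matrices at the requested level, fuses them
    into the 2-D feature space, clusters, and ranks each cluster's
    members by mean intra-cluster distance (the medoid first). Optionally
    writes a JSON summary and a scatter plot.
    """
    matrices = {
        f: build_distance_matrix(sprites, f, level=level, seed=seed, **feature_params)
        for f in ("shape", "color", "texture")
    }
    if len(matrices["shape"].labels) < 2:
        raise ValueError("need at least 2 entities")
    embedding = build_embedding(
        matrices["shape"], matrices["color"], matrices["texture"]
    )
    clusters = cluster_embedding(
        embedding.fused_xy, embedding.labels, eps=eps, min_samples=min_samples
    )
    recommendations: Dict[int, List[str]] = {}
    pts = embedding.fused_xy
    for cid in sorted(medoid_cid for medoid_cid in clusters.medoids):
        members = np.flatnonzero(clusters.cluster_ids == cid)
        sub = pts[members]
        dists = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
        order = np.argsort(dists.mean(axis=1), kind="stable")
        recommendations[cid] = [embedding.labels[members[i]] for i in order]
    selection = SourceSelection(
        embedding=embedding, clusters=clusters, recommendations=recommendations
    )
    if out_json is not None:
        _write_selection_json(selection, out_json)
    if plot_path is not None:
        plot_selection(selection, plot_path)
    return selection


def _write_selection_json(selection: SourceSelection, path: str) -> None:
    payload = {
        "labels": selection.embedding.labels,
        "fused_xy": selection.embedding.fused_xy.tolist(),
        "scales": selection.embedding.scales,
        "cluster_ids": selection.clusters.cluster_ids.tolist(),
        "medoids": {str(k): v for k, v in selection.clusters.medoids.items()},
        "recommendations": {
            str(k): v for k, v in selection.recommendations.items()
        },
        "eps": selection.clusters.eps,
        "min_samples": selection.clusters.min_samples,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def plot_selection(selection: SourceSelection, path: str) -> None:
    """Scatter plot of the fused feature space with clusters and medoids."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = selection.embedding.fused_xy
    ids = selection.clusters.cluster_ids
    fig, ax = plt.subplots(figsize=(6, 5))
    for cid in sorted(set(ids)):
        sel = ids == cid
        label = f"cluster {cid}" if cid >= 0 else "noise"
        ax.scatter(pts[sel, 0], pts[sel, 1], label=label, s=40)
    for cid, name in selection.clusters.medoids.items():
        i = selection.embedding.labels.index(name)
        ax.scatter(
            pts[i, 0], pts[i, 1], marker="s", s=160, facecolors="none",
            edgecolors="red", linewidths=2,
        )
        ax.annotate(name, (pts[i, 0], pts[i, 1]), fontsize=8)
    ax.set_xlabel("shape (PC1 of MDS)")
    ax.set_ylabel("color + texture (PC1 of MDS)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
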