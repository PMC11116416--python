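"""Dominant-color extraction and sample-level yellowness for pellet photos.

Photographs of curated pellet sets arrive with the background already
removed (transparent alpha, or a uniform reference color).  Foreground
pixels are clustered into the ten most prevalent colors with seeded
k-means in raw 8-bit RGB, each cluster centroid is converted to CIE XYZ,
and the sample %YI is the pixel-fraction-weighted mean of the per-cluster
yellowness indices.  For an image with fewer distinct colors than
requested clusters the distinct colors themselves are the clusters, so a
solid-color image reproduces the closed-form YI of that color exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.cluster import KMeans

from .colorimetry import (
    DEFAULT_ILLUMINANT_OBSERVER,
    IlluminantObserver,
    RGB8Color,
    XYZTristimulus,
    linearize_rgb,
    xyz_from_linear_rgb,
    yellowness_index,
)

__all__ = [
    "MaskedImage",
    "ColorCluster",
    "YellownessResult",
    "load_masked_image",
    "extract_dominant_colors",
    "sample_yellowness",
    "analyze_images",
]


class EmptyForegroundError(ValueError):
    """Raised when background removal leaves no foreground pixels."""


@dataclass
class MaskedImage:
    """Foreground pixels of a background-removed pellet photograph."""

    pixels: np.ndarray  # (n_foreground, 3) uint8
    source_path: str
    n_foreground: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_foreground < 1:
            raise EmptyForegroundError(
                f"{self.source_path}: no foreground pixels after masking"
            )
        if self.n_foreground > self.n_total:
            raise ValueError("n_foreground exceeds n_total")


@dataclass(frozen=True)
class ColorCluster:
    """One dominant color: rounded centroid, XYZ, pixel fraction and YI."""

    centroid_rgb: RGB8Color
    centroid_xyz: XYZTristimulus
    weight: float
    yi: float


@dataclass
class YellownessResult:
    sample_id: str
    clusters: list[ColorCluster]
    sample_yi: float
    k_requested: int
    k_effective: int
    seed: int


def load_masked_image(
    path: str | os.PathLike,
    background_policy: str = "alpha",
    reference_color: tuple[int, int, int] = (255, 255, 255),
    tol: int = 0,
) -> MaskedImage:
    """Read a PNG/JPEG and drop background pixels.

    Parameters
    ----------
    background_policy
        ``"alpha"`` — drop pixels with alpha exactly 0 (fully opaque
        images are retained whole); ``"reference"`` — drop pixels whose
        maximum per-channel distance from ``reference_color`` is <= ``tol``.
    """
    with Image.open(path) as im:
        has_alpha = im.mode in ("RGBA", "LA", "PA") or "transparency" in im.info
        rgba = im.convert("RGBA")
        arr = np.asarray(rgba, dtype=np.uint8).reshape(-1, 4)

    n_total = arr.shape[0]
    if background_policy == "alpha":
        mask = arr[:, 3] > 0 if has_alpha else np.ones(n_total, dtype=bool)
    elif background_policy == "reference":
        ref = np.asarray(reference_color, dtype=int)
        dist = np.max(np.abs(arr[:, :3].astype(int) - ref), axis=1)
        mask = dist > tol
    else:
        raise ValueError(
            f"unknown background_policy {background_policy!r}; "
            "expected 'alpha' or 'reference'"
        )

    pixels = arr[mask, :3]
    return MaskedImage(
        pixels=pixels,
        source_path=str(path),
        n_foreground=int(pixels.shape[0]),
        n_total=n_total,
    )


def _clusters_from_centroids(
    centroids: np.ndarray,
    weights: np.ndarray,
    io: IlluminantObserver,
) -> list[ColorCluster]:
    """Build ColorCluster records ordered by descending weight.

    XYZ/YI are computed from the unrounded centroid; the rounded RGB is
    reported for display.  Ties in weight break on the rounded RGB triple
    so output order is fully deterministic.
    """
    order = sorted(
        range(len(weights)),
        key=lambda i: (-weights[i], tuple(np.rint(centroids[i]).astype(int))),
    )
    out = []
    for i in order:
        c = centroids[i]
        xyz = xyz_from_linear_rgb(linearize_rgb(c), io)
        xyz_t = XYZTristimulus(*np.maximum(np.where(np.abs(xyz) < 1e-12, 0, xyz), 0))
        yi = yellowness_index(xyz_t, io) if xyz_t.Y > 0 else 0.0
        rgb = np.clip(np.rint(c), 0, 255).astype(int)
        out.append(
            ColorCluster(
                centroid_rgb=RGB8Color(*(int(v) for v in rgb)),
                centroid_xyz=xyz_t,
                weight=float(weights[i]),
                yi=float(yi),
            )
        )
    return out


def extract_dominant_colors(
    img: MaskedImage,
    k: int = 10,
    seed: int = 0,
    io: IlluminantObserver = DEFAULT_ILLUMINANT_OBSERVER,
    max_pixels: int | None = None,
) -> list[ColorCluster]:
    """Cluster foreground pixels into at most ``k`` dominant colors.

    Pixels are deduplicated into (color, count) pairs and the counts used
    as k-means sample weights, which is exactly equivalent to clustering
    the full pixel list.  With fewer than ``k`` distinct colors the
    distinct colors are returned directly (zero within-cluster spread).
    An optional ``max_pixels`` cap subsamples deterministically by seed
    before deduplication.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    pixels = img.pixels
    if max_pixels is not None and pixels.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        idx = rng.choice(pixels.shape[0], size=max_pixels, replace=False)
        pixels = pixels[np.sort(idx)]

    colors, counts = np.unique(pixels, axis=0, return_counts=True)
    n = counts.sum()
    if colors.shape[0] <= k:
        centroids = colors.astype(float)
        weights = counts / n
    else:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=10,
            tol=1e-4,
            random_state=seed % (2**32),
        )
        labels = km.fit_predict(colors.astype(float), sample_weight=counts.astype(float))
        weights = np.bincount(labels, weights=counts, minlength=k) / n
        keep = weights > 0  # k-means can leave a cluster empty
        centroids = km.cluster_centers_[keep]
        weights = weights[keep]
    return _clusters_from_centroids(centroids, weights, io)


def sample_yellowness(
    img: MaskedImage,
    k: int = 10,
    seed: int = 0,
    io: IlluminantObserver = DEFAULT_ILLUMINANT_OBSERVER,
    sample_id: str = "",
    aggregation: str = "weighted_mean",
    max_pixels: int | None = None,
) -> YellownessResult:
    """Sample-level %YI from the dominant-color decomposition.

    ``aggregation="weighted_mean"`` (default) averages per-cluster YIs by
    pixel fraction; ``"dominant"`` reports the YI of the single heaviest
    cluster.  The weighted mean reduces to the exact closed-form YI for a
    solid-color image.
    """
    clusters = extract_dominant_colors(img, k=k, seed=seed, io=io, max_pixels=max_pixels)
    if aggregation == "weighted_mean":
        yi = float(sum(c.weight * c.yi for c in clusters))
    elif aggregation == "dominant":
        yi = clusters[0].yi
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return YellownessResult(
        sample_id=sample_id,
        clusters=clusters,
        sample_yi=yi,
        k_requested=k,
        k_effective=len(clusters),
        seed=seed,
    )


def analyze_images(
    manifest: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    io: IlluminantObserver = DEFAULT_ILLUMINANT_OBSERVER,
    background_policy: str = "alpha",
    aggregation: str = "weighted_mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch %YI over a manifest with columns ``sample_id, path``.

    Returns an image-level table (sample_id, path, n_foreground,
    k_effective, sample_yi, seed) and a long cluster table (sample_id,
    path, rank, r, g, b, weight, yi).
    """
    required = {"sample_id", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rows, cluster_rows = [], []
    for rec in manifest.itertuples(index=False):
        img = load_masked_image(rec.path, background_policy=background_policy)
        res = sample_yellowness(
            img, k=k, seed=seed, io=io, sample_id=str(rec.sample_id),
            aggregation=aggregation,
        )
        rows.append(
            dict(
                sample_id=res.sample_id,
                path=str(rec.path),
                n_foreground=img.n_foreground,
                k_effective=res.k_effective,
                sample_yi=res.sample_yi,
                seed=seed,
            )
        )
        for rank, c in enumerate(res.clusters, start=1):
            cluster_rows.append(
                dict(
                    sample_id=res.sample_id,
                    path=str(rec.path),
                    rank=rank,
                    r=c.centroid_rgb.r,
                    g=c.centroid_rgb.g,
                    b=c.centroid_rgb.b,
                    weight=c.weight,
                    yi=c.yi,
                )
            )
    return pd.DataFrame(rows), pd.DataFrame(cluster_rows)
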