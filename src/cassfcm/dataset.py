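"""Mapping images into the spatio-tonal universe, and its metrics.

Every pixel of an M×N CIELab image becomes one instance
``(x, y, t1, ..., tk)``: two normalized spatial coordinates followed
by its tonal values.  Distances in this joint universe are convex
combinations of a spatial and a tonal metric,

    d_psi(a, b) = alpha * d_tau(a_tonal, b_tonal)
                + (1 - alpha) * d_omega(a_spatial, b_spatial),

with ``alpha`` in [0, 1] weighting tonal against spatial information.
Spatial coordinates are divided by a single scale (by default
``max(M, N)``) so the aspect ratio is preserved and both coordinates
land in [0, 1); tonal values stay in native CIELab units, so a tonal
distance of 1 is one CIELab unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

from .image import CIELAB, RasterImage

SpatialScaling = str  # "max-dim" | "per-axis" | "none"


def _euclidean_pair(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


#: Registered point-to-point metrics, by name.  ``cdist`` handles the
#: vectorized pairwise case for anything scipy knows about.
METRICS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "euclidean": _euclidean_pair,
}


@dataclass(frozen=True)
class MetricSpec:
    """Choice of spatial metric, tonal metric and spatio-tonal weight."""

    spatial: str = "euclidean"
    tonal: str = "euclidean"
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        for name in (self.spatial, self.tonal):
            if name not in METRICS:
                raise ValueError(f"unregistered metric {name!r}")


@dataclass(frozen=True)
class SpatioTonalDataset:
    """One row per pixel: (x, y, t1, ..., tk) in row-major pixel order.

    Row ``i * N + j`` holds pixel (row=i, col=j); spatial columns store
    ``(x, y) = (j, i) / scale``.  The mapping back to the grid is a
    bijection, so tonal round trips are exact.
    """

    X: np.ndarray                      # (M*N, 2 + k) float64
    grid_shape: tuple[int, int]        # (M, N)
    spatial_scale: tuple[float, float]  # divisor applied to (col, row)
    scaling: SpatialScaling = "max-dim"

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_tonal(self) -> int:
        return self.X.shape[1] - 2

    @property
    def spatial(self) -> np.ndarray:
        return self.X[:, :2]

    @property
    def tonal(self) -> np.ndarray:
        return self.X[:, 2:]


def image_to_dataset(img: RasterImage,
                     scaling: SpatialScaling = "max-dim") -> SpatioTonalDataset:
    """Map a CIELab image into its spatio-tonal dataset.

    ``scaling`` selects the spatial divisor: ``"max-dim"`` divides both
    axes by max(M, N) (aspect preserved), ``"per-axis"`` divides each
    axis by its own extent, ``"none"`` keeps raw pixel indices.
    """
    if img.colorspace != CIELAB:
        raise ValueError("image_to_dataset expects a cielab image")
    M, N = img.shape
    if M == 0 or N == 0:
        raise ValueError("empty image")
    if scaling == "max-dim":
        s = float(max(M, N))
        scale = (s, s)
    elif scaling == "per-axis":
        scale = (float(N), float(M))
    elif scaling == "none":
        scale = (1.0, 1.0)
    else:
        raise ValueError(f"unknown spatial scaling {scaling!r}")
    jj, ii = np.meshgrid(np.arange(N), np.arange(M))
    k = img.channels
    X = np.empty((M * N, 2 + k))
    X[:, 0] = jj.ravel() / scale[0]
    X[:, 1] = ii.ravel() / scale[1]
    X[:, 2:] = img.values.reshape(M * N, k)
    return SpatioTonalDataset(X, (M, N), scale, scaling)


def dataset_to_image(ds: SpatioTonalDataset) -> RasterImage:
    """Rebuild the CIELab image from the tonal columns (exact inverse)."""
    M, N = ds.grid_shape
    return RasterImage(ds.tonal.reshape(M, N, ds.n_tonal), CIELAB)


def export_dataset(ds: SpatioTonalDataset, path: str | Path) -> None:
    """Dump the instance matrix as a delimited text table for inspection."""
    names = ["x", "y"] + (["L", "a", "b"] if ds.n_tonal == 3 else
                          [f"t{i + 1}" for i in range(ds.n_tonal)])
    np.savetxt(Path(path), ds.X, delimiter="\t", header="\t".join(names),
               comments="")


# ---------------------------------------------------------------------------
# metrics

def spatial_distance(a, b, spec: MetricSpec = MetricSpec()) -> float:
    """Distance between two spatial coordinate pairs."""
    return METRICS[spec.spatial](a, b)


def tonal_distance(a, b, spec: MetricSpec = MetricSpec()) -> float:
    """Distance between two tonal vectors (CIELab units)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"tonal dimension mismatch: {a.shape} vs {b.shape}")
    return METRICS[spec.tonal](a, b)


def spatio_tonal_distance(a, b, spec: MetricSpec) -> float:
    """Convex combination of tonal and spatial distance between instances.

    ``a`` and ``b`` are full (2+k)-vectors from the same universe.
    With alpha=1 this is the tonal distance; with alpha=0, the spatial
    one.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    return (spec.alpha * tonal_distance(a[2:], b[2:], spec)
            + (1.0 - spec.alpha) * spatial_distance(a[:2], b[:2], spec))


def pairwise_distances(X: np.ndarray, C: np.ndarray,
                       spec: MetricSpec) -> np.ndarray:
    """Spatio-tonal distances between all instance/centroid pairs.

    ``X`` is (n, 2+k), ``C`` is (r, 2+k); the result is (n, r).  The
    two component metrics are evaluated separately and fused, which is
    not the same as a Euclidean distance on rescaled columns.
    """
    d_tau = cdist(X[:, 2:], C[:, 2:], metric=spec.tonal)
    if spec.alpha == 1.0:
        return d_tau
    d_omega = cdist(X[:, :2], C[:, :2], metric=spec.spatial)
    if spec.alpha == 0.0:
        return d_omega
    return spec.alpha * d_tau + (1.0 - spec.alpha) * d_omega
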