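"""Local homogeneity maps and region/edge-band summary statistics.

Local homogeneity of a [0, 1]-valued channel is

    H(x, y) = 1 - max_window I + min_window I

over the (2n+1) x (2n+1) neighborhood of each pixel, with positions
outside the grid excluded from both extrema (no padding).  H is 1 on
flat patches and 0 across full-contrast edges.  For k-channel images
the per-channel maps are averaged.

These maps are descriptive: they let one check that smoothing raises
homogeneity inside regions while boundary bands keep their contrast.
They are not a standalone quality score for comparing smoothers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import UNIT, RasterImage


@dataclass(frozen=True)
class HomogeneityMap:
    """Per-pixel local homogeneity in [0, 1] at window radius ``n``."""

    values: np.ndarray  # (M, N)
    n: int
    mode: str  # "single" | "multichannel-average"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RegionPartition:
    """Integer region labels on the pixel grid (e.g. background/deposit)."""

    labels: np.ndarray  # (M, N) int
    names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 2-D integer array")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def name(self, rid: int) -> str:
        if self.names and rid in self.names:
            return self.names[rid]
        return f"region_{rid}"


def _windowed_extrema(channel: np.ndarray, n: int):
    # 'nearest' replication is equivalent to restricting the extrema to
    # the in-grid part of the window: each padded value duplicates an
    # in-grid pixel that the same window already covers.
    size = 2 * n + 1
    mx = ndimage.maximum_filter(channel, size=size, mode="nearest")
    mn = ndimage.minimum_filter(channel, size=size, mode="nearest")
    return mx, mn


def local_homogeneity(img: RasterImage, n: int = 2) -> HomogeneityMap:
    """Single-channel local homogeneity map at window radius ``n``."""
    if img.colorspace != UNIT:
        raise ValueError("local homogeneity requires a unit-normalized image; "
                         "apply normalize_unit first")
    if img.channels != 1:
        raise ValueError("local_homogeneity is single-channel; use "
                         "multichannel_homogeneity for k > 1")
    if n < 0:
        raise ValueError("window radius n must be >= 0")
    ch = img.values[:, :, 0]
    mx, mn = _windowed_extrema(ch, n)
    return HomogeneityMap(1.0 - mx + mn, n, "single")


def multichannel_homogeneity(img: RasterImage, n: int = 2) -> HomogeneityMap:
    """Mean of the per-channel homogeneity maps of a k-channel image."""
    if img.colorspace != UNIT:
        raise ValueError("homogeneity requires a unit-normalized image")
    if n < 0:
        raise ValueError("window radius n must be >= 0")
    acc = np.zeros(img.shape)
    for c in range(img.channels):
        mx, mn = _windowed_extrema(img.values[:, :, c], n)
        acc += 1.0 - mx + mn
    return HomogeneityMap(acc / img.channels, n, "multichannel-average")


def edge_band(partition: RegionPartition, w: int = 7,
              geometry: str = "chebyshev") -> np.ndarray:
    """Boolean mask of the w-pixel-wide band centered on region boundaries.

    Boundary seeds are the pixels whose label differs from their right
    or lower neighbor (one seed per boundary interface); the band is
    every pixel within distance floor(w/2) of a seed, so an odd ``w``
    yields a band exactly ``w`` pixels wide across a straight boundary.
    ``geometry`` selects Chebyshev (square, default) or Euclidean
    (disc) distance.
    """
    if w < 0:
        raise ValueError("band width must be >= 0")
    lab = partition.labels
    band = np.zeros(lab.shape, dtype=bool)
    if w == 0:
        return band
    seeds = np.zeros(lab.shape, dtype=bool)
    seeds[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    seeds[:-1, :] |= lab[:-1, :] != lab[1:, :]
    if not seeds.any():
        return band
    radius = w // 2
    if radius == 0:
        return seeds
    if geometry == "chebyshev":
        return ndimage.maximum_filter(seeds, size=2 * radius + 1,
                                      mode="constant", cval=False)
    if geometry == "euclidean":
        dist = ndimage.distance_transform_edt(~seeds)
        return dist <= radius
    raise ValueError(f"unknown band geometry {geometry!r}")


def region_mean_homogeneity(H: HomogeneityMap, partition: RegionPartition,
                            band: np.ndarray) -> pd.DataFrame:
    """Mean homogeneity per region (band excluded) and over the band.

    Returns a table with columns ``region``, ``mean_homogeneity`` and
    ``n_pixels``; a region left empty after band exclusion is reported
    with NaN mean and zero pixels.
    """
    if H.shape != partition.shape or band.shape != partition.shape:
        raise ValueError("homogeneity map, partition and band shapes differ")
    rows = []
    for rid in partition.region_ids():
        mask = (partition.labels == rid) & ~band
        count = int(mask.sum())
        mean = float(H.values[mask].mean()) if count else float("nan")
        rows.append((partition.name(int(rid)), mean, count))
    count = int(band.sum())
    mean = float(H.values[band].mean()) if count else float("nan")
    rows.append(("band", mean, count))
    return pd.DataFrame(rows,
                        columns=["region", "mean_homogeneity", "n_pixels"])
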