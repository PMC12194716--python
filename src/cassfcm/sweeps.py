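"""Experiment drivers: cluster-count and alpha sweeps, output analysis.

These reproduce the two qualitative studies one runs when configuring
the smoother: how the number of clusters r shapes the converged image
(underestimating r merges tone families, overestimating it splits
regions into sub-regions), and how the spatio-tonal weight alpha
trades spatial against tonal coherence on images whose regions are
spatially compact, partially compact, or scattered.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .engine import SmoothingConfig, SmoothingTrace, run_cas_sfcm
from .image import RasterImage


def distinct_tone_count(img: RasterImage, precision: float = 0.5) -> int:
    """Number of distinct tones after rounding channels to ``precision``."""
    if precision <= 0:
        raise ValueError("precision must be positive")
    tones = np.round(img.values.reshape(-1, img.channels) / precision)
    return int(np.unique(tones, axis=0).shape[0])


def partition_agreement(pred: np.ndarray, truth: np.ndarray) -> float:
    """Best-matched fraction of pixels on which two labelings agree.

    Cluster indices are arbitrary, so predicted labels are matched to
    ground-truth labels by maximum-overlap assignment before scoring.
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("label arrays must have the same size")
    p_ids, p_inv = np.unique(pred, return_inverse=True)
    t_ids, t_inv = np.unique(truth, return_inverse=True)
    conf = np.zeros((p_ids.size, t_ids.size))
    np.add.at(conf, (p_inv, t_inv), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / pred.size)


def sweep_clusters(img: RasterImage, r_list: list[int],
                   iters_list: list[int],
                   config: SmoothingConfig) -> tuple[dict, pd.DataFrame]:
    """Run one trace per r and snapshot the listed iterations.

    Returns ``(snapshots, table)`` where ``snapshots[r][t]`` is the
    image after t iterations (the run is extended to ``max(iters_list)``
    iterations regardless of the tolerance) and ``table`` holds the
    distinct-tone count of every snapshot.
    """
    if any(r < 1 for r in r_list):
        raise ValueError("all cluster counts must be >= 1")
    horizon = max(iters_list)
    snapshots: dict[int, dict[int, RasterImage]] = {}
    rows = []
    for r in r_list:
        cfg = replace(config, r=r, max_iter=horizon, delta=1e-12)
        trace = run_cas_sfcm(img, cfg)
        per_r = {}
        for t in iters_list:
            # a run that converged numerically before t stays at its
            # final image
            snap = trace.images[min(t, trace.n_iterations)]
            per_r[t] = snap
            rows.append((r, t, distinct_tone_count(snap)))
        snapshots[r] = per_r
    table = pd.DataFrame(rows, columns=["r", "iteration", "distinct_tones"])
    return snapshots, table


def sweep_alpha(img: RasterImage, alpha_list: list[float],
                config: SmoothingConfig) -> dict[float, SmoothingTrace]:
    """One converged-or-capped run per alpha with a fixed seed."""
    for a in alpha_list:
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {a}")
    return {a: run_cas_sfcm(img, replace(config, alpha=a))
            for a in alpha_list}


def tile_images(images: list[RasterImage], n_cols: int,
                pad: int = 2, pad_value: float = 100.0) -> RasterImage:
    """Tile same-shape images into one grid image (CIELab, white gaps)."""
    if not images:
        raise ValueError("nothing to tile")
    M, N = images[0].shape
    k = images[0].channels
    n_rows = -(-len(images) // n_cols)
    grid = np.full((n_rows * (M + pad) - pad, n_cols * (N + pad) - pad, k),
                   0.0)
    grid[:, :, 0] = pad_value
    for idx, im in enumerate(images):
        i, j = divmod(idx, n_cols)
        grid[i * (M + pad):i * (M + pad) + M,
             j * (N + pad):j * (N + pad) + N] = im.values
    return RasterImage(grid, images[0].colorspace)
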