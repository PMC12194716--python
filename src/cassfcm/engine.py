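"""The fuzzy-clustering core of the smoother.

The smoother is a spatial fuzzy c-means iteration driven by the
spatio-tonal metric d_psi.  Cluster membership and centroid updates
are the standard fuzzy c-means ones with d_psi substituted for the
distance:

    mu_i(p) = [ sum_j ( d_psi(p, C_i) / d_psi(p, C_j) )^(2/(m-1)) ]^-1
    C_i     = sum_p mu_i(p)^m * p  /  sum_p mu_i(p)^m

where ``m > 1`` is the fuzzifier and centroids live in the full
(2+k)-dimensional spatio-tonal universe.  Memberships always form a
Ruspini partition (they sum to 1 at every pixel), so the reconstructed
image is a per-pixel convex combination of centroid tones.

One smoothing run proceeds as: map the image to a dataset, pick r
initial centroids by Forgy initialization (r random instances),
compute memberships and the initial image I_0, then iterate —
centroid update, membership update, image reconstruction — until the
mean per-pixel tonal difference between consecutive images,

    Phi(A, B) = (1/|Omega|) * sum_(x,y) d_tau(A(x,y), B(x,y)),

drops to the tolerance delta, or an iteration cap is reached.  Because
the centroids converge to a fixed point of the fuzzy c-means updates
rather than collapsing to a single tone, the sequence ends in a
non-trivial (non-flat) state: smoothing regularizes tones within
regions while region contrasts survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import (MetricSpec, SpatioTonalDataset, image_to_dataset,
                      pairwise_distances)
from .image import CIELAB, RasterImage, to_cielab
from .reconstruction import reconstruct_image

logger = logging.getLogger(__name__)

#: Membership mass below which a cluster counts as empty and is re-seeded.
_EMPTY_MASS = 1e-12


@dataclass(frozen=True)
class CentroidSet:
    """r centroids in the spatio-tonal universe at iteration ``t``."""

    points: np.ndarray  # (r, 2 + k) float64
    t: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.points, float)
        if p.ndim != 2 or p.shape[0] < 1:
            raise ValueError("centroids must form a non-empty (r, 2+k) array")
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite centroid component")
        object.__setattr__(self, "points", p)

    @property
    def r(self) -> int:
        return self.points.shape[0]

    @property
    def spatial(self) -> np.ndarray:
        return self.points[:, :2]

    @property
    def tonal(self) -> np.ndarray:
        """The tonal parts C_hat used to paint reconstructed images."""
        return self.points[:, 2:]


@dataclass(frozen=True)
class MembershipField:
    """r membership maps on the pixel grid forming a Ruspini partition."""

    values: np.ndarray  # (M, N, r), rows of the flattened view sum to 1
    t: int = 0

    @property
    def r(self) -> int:
        return self.values.shape[2]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def flat(self) -> np.ndarray:
        """(M*N, r) row-major view of the membership maps."""
        M, N, r = self.values.shape
        return self.values.reshape(M * N, r)

    def ruspini_deviation(self) -> float:
        """Largest per-pixel deviation of the membership sum from 1."""
        return float(np.abs(self.flat.sum(axis=1) - 1.0).max())

    def hard_labels(self) -> np.ndarray:
        """Nearest-centroid hardening: per-pixel argmax membership (M, N)."""
        return np.argmax(self.values, axis=2)


@dataclass(frozen=True)
class SmoothingConfig:
    """Parameters of one smoothing run.

    ``r`` is the number of clusters and should reflect the number of
    distinct regions in the image; ``alpha`` weights tonal against
    spatial information in the metric; ``delta`` is the convergence
    tolerance on the mean inter-iteration tonal difference (CIELab
    units); ``m`` is the fuzzifier.
    """

    r: int
    alpha: float = 0.5
    delta: float = 0.05
    m: float = 2.0
    max_iter: int = 200
    seed: int = 0
    spatial_metric: str = "euclidean"
    tonal_metric: str = "euclidean"
    spatial_scaling: str = "max-dim"
    keep_memberships: bool = False

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError(f"r must be >= 1, got {self.r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.m <= 1.0:
            raise ValueError(f"fuzzifier m must be > 1, got {self.m}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def metric(self) -> MetricSpec:
        return MetricSpec(self.spatial_metric, self.tonal_metric, self.alpha)


@dataclass
class SmoothingTrace:
    """Everything one run produced, in iteration order.

    ``images[t]`` is I_t; ``diffs[t-1]`` is v_t = Phi(I_t, I_{t-1})
    for t >= 1.  ``ruspini_deviations[t]`` records the worst per-pixel
    membership-sum error at iteration t (a numerical health check).
    """

    images: list[RasterImage]
    diffs: list[float]
    centroids: list[CentroidSet]
    ruspini_deviations: list[float]
    termination: str  # "converged" | "cap-reached"
    config: SmoothingConfig
    final_membership: MembershipField
    memberships: list[MembershipField] | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.images) - 1

    @property
    def final_image(self) -> RasterImage:
        return self.images[-1]

    def log_table(self) -> pd.DataFrame:
        """Per-iteration convergence log (iteration, v)."""
        return pd.DataFrame(
            {"iteration": np.arange(1, len(self.diffs) + 1), "v": self.diffs}
        )


# ---------------------------------------------------------------------------
# elementary steps

def forgy_init(data: SpatioTonalDataset, r: int,
               seed: int | np.random.Generator) -> CentroidSet:
    """Pick r distinct instances uniformly at random as initial centroids."""
    n = data.n_instances
    if not 1 <= r <= n:
        raise ValueError(f"r must be in [1, {n}], got {r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rows = rng.choice(n, size=r, replace=False)
    return CentroidSet(data.X[rows].copy(), t=0)


def membership_matrix(X: np.ndarray, C: np.ndarray, spec: MetricSpec,
                      m: float) -> np.ndarray:
    """Fuzzy c-means memberships under the spatio-tonal metric.

    Returns the (n, r) matrix with rows summing to 1.  A pixel at zero
    distance from one or more centroids splits its membership equally
    over the zero-distance centroids (and holds 0 elsewhere), which
    keeps the partition well defined when centroids coincide with
    instances.
    """
    D = pairwise_distances(X, C, spec)
    p = 2.0 / (m - 1.0)
    U = np.empty_like(D)
    zero = D <= 0.0
    with np.errstate(divide="ignore", over="ignore"):
        inv = D ** (-p)
    np.copyto(inv, np.inf, where=zero)
    denom = inv.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        U = inv / denom
    rows_zero = zero.any(axis=1)
    if rows_zero.any():
        z = zero[rows_zero]
        U[rows_zero] = z / z.sum(axis=1, keepdims=True)
    return U


def update_memberships(data: SpatioTonalDataset, C: CentroidSet,
                       spec: MetricSpec, m: float = 2.0) -> MembershipField:
    """Membership update step, returned on the pixel grid."""
    U = membership_matrix(data.X, C.points, spec, m)
    M, N = data.grid_shape
    return MembershipField(U.reshape(M, N, C.r), t=C.t)


def centroid_matrix(X: np.ndarray, U: np.ndarray, m: float,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Fuzzy c-means centroid update over the full spatio-tonal columns.

    A cluster whose total membership mass underflows is re-seeded from
    a uniformly random instance so the declared region count r stays
    fixed throughout the run.
    """
    W = U ** m
    mass = W.sum(axis=0)
    C = np.empty((U.shape[1], X.shape[1]))
    ok = mass > _EMPTY_MASS
    C[ok] = (W[:, ok].T @ X) / mass[ok, None]
    if not ok.all():
        rng = rng if rng is not None else np.random.default_rng()
        idx = rng.choice(X.shape[0], size=(~ok).sum(), replace=False)
        logger.warning("re-seeding %d empty cluster(s)", (~ok).sum())
        C[~ok] = X[idx]
    return C


def update_centroids(data: SpatioTonalDataset, U: MembershipField,
                     m: float = 2.0,
                     rng: np.random.Generator | None = None) -> CentroidSet:
    """Centroid update step (membership-weighted means of instances)."""
    C = centroid_matrix(data.X, U.flat, m, rng)
    return CentroidSet(C, t=U.t + 1)


def image_difference(A: RasterImage, B: RasterImage,
                     spec: MetricSpec = MetricSpec()) -> float:
    """Phi: mean per-pixel tonal distance between two same-shape images."""
    if A.values.shape != B.values.shape:
        raise ValueError(
            f"image shape mismatch: {A.values.shape} vs {B.values.shape}")
    if A.colorspace != B.colorspace:
        raise ValueError("images must share a colorspace")
    diff = A.values - B.values
    if spec.tonal != "euclidean":  # pragma: no cover - registry hook
        raise NotImplementedError("Phi is defined for the registered "
                                  "Euclidean tonal metric")
    return float(np.sqrt((diff ** 2).sum(axis=2)).mean())


# ---------------------------------------------------------------------------
# the full loop

def run_cas_sfcm(img: RasterImage, config: SmoothingConfig) -> SmoothingTrace:
    """Run the full smoothing loop and record the image sequence.

    The loop order is: initial centroids C_0 -> memberships M_0 ->
    image I_0, then per iteration a centroid update *before* the
    membership update, a reconstruction, and the convergence check
    v = Phi(I_t, I_{t-1}) <= delta.  Hitting the iteration cap without
    convergence is reported in ``termination``, not raised.
    """
    if img.colorspace != CIELAB:
        img = to_cielab(img)
    data = image_to_dataset(img, config.spatial_scaling)
    spec = config.metric
    rng = np.random.default_rng(config.seed)

    C = forgy_init(data, config.r, rng)
    U = update_memberships(data, C, spec, config.m)
    I_prev = reconstruct_image(U.flat, C.tonal, data.grid_shape)

    images = [I_prev]
    centroids = [C]
    ruspini = [U.ruspini_deviation()]
    memberships = [U] if config.keep_memberships else None
    diffs: list[float] = []

    termination = "cap-reached"
    v = np.inf
    for _ in range(config.max_iter):
        C = update_centroids(data, U, config.m, rng)
        U = update_memberships(data, C, spec, config.m)
        I_t = reconstruct_image(U.flat, C.tonal, data.grid_shape)
        v = image_difference(I_t, I_prev, spec)

        images.append(I_t)
        centroids.append(C)
        ruspini.append(U.ruspini_deviation())
        diffs.append(v)
        if memberships is not None:
            memberships.append(U)
        I_prev = I_t
        if v <= config.delta:
            termination = "converged"
            break
    if termination == "cap-reached":
        logger.info("iteration cap %d reached with v=%.4g > delta=%.4g",
                    config.max_iter, v, config.delta)
    return SmoothingTrace(images, diffs, centroids, ruspini, termination,
                          config, U, memberships)


def init_sensitivity_experiment(img: RasterImage, config: SmoothingConfig,
                                n_seeds: int,
                                n_iters: int) -> pd.DataFrame:
    """Initialization-sensitivity study: n_seeds runs compared pairwise.

    The smoother is run ``n_seeds`` times (seeds ``config.seed + 0 ...
    + n_seeds - 1``) for exactly ``n_iters`` iterations each, in
    lockstep; at every iteration Phi is evaluated for all unordered
    pairs of current images.  Returns a table with columns
    ``iteration`` (0 = the initial reconstruction), ``max_phi`` and
    ``mean_phi``.
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds to compare")
    if img.colorspace != CIELAB:
        img = to_cielab(img)
    data = image_to_dataset(img, config.spatial_scaling)
    spec = config.metric

    rngs = [np.random.default_rng(config.seed + s) for s in range(n_seeds)]
    Cs = [forgy_init(data, config.r, rng) for rng in rngs]
    Us = [update_memberships(data, C, spec, config.m) for C in Cs]
    imgs = [reconstruct_image(U.flat, C.tonal, data.grid_shape)
            for U, C in zip(Us, Cs)]

    def pair_stats(current):
        phis = [image_difference(current[i], current[j], spec)
                for i in range(n_seeds) for j in range(i + 1, n_seeds)]
        return max(phis), float(np.mean(phis))

    rows = [(0, *pair_stats(imgs))]
    for t in range(1, n_iters + 1):
        for s in range(n_seeds):
            Cs[s] = update_centroids(data, Us[s], config.m, rngs[s])
            Us[s] = update_memberships(data, Cs[s], spec, config.m)
            imgs[s] = reconstruct_image(Us[s].flat, Cs[s].tonal,
                                        data.grid_shape)
        rows.append((t, *pair_stats(imgs)))
    return pd.DataFrame(rows, columns=["iteration", "max_phi", "mean_phi"])
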