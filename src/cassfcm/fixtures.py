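"""Synthetic test imagery with exact ground-truth partitions.

Three families of fixtures cover the situations the smoother is
designed for, so every experiment runs without downloading anything:

* ``cube`` — a clean isometric cube on a split background: five
  regions (three cube faces in an orange palette family, two
  background areas in a blueish family), for cluster-count studies.
* ``coherence-A/B/C`` — two-region pink/green images with decreasing
  spatial coherence: A is a compact pink disc with a color-blended
  rim, B a compact pink disc over a scattered two-tone green
  background, C pink pixels scattered uniformly with no spatial
  structure.  These probe the spatio-tonal weight alpha.
* ``blob-deposit`` — brownish blobs with blurred boundaries and
  speckle texture on a light-bluish textured background, emulating
  the look of immunohistochemical tau-protein deposits on neural
  tissue.

Palettes are stated directly in CIELab so metric-space contrasts are
controlled.  All randomness flows from the spec's seed, so a fixture
is reproducible bit-exactly from its spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import disk, polygon

from .image import CIELAB, LAB_OFFSETS, LAB_SCALES, RasterImage
from .homogeneity import RegionPartition

KINDS = ("cube", "coherence-A", "coherence-B", "coherence-C", "blob-deposit")

# blueish background pair + orange face triple; min pairwise tonal
# distance ~22.9 CIELab units
CUBE_PALETTE = [
    (70.0, -10.0, -30.0),   # background, upper
    (40.0, -5.0, -35.0),    # background, lower
    (75.0, 25.0, 55.0),     # cube face, top
    (55.0, 35.0, 50.0),     # cube face, left
    (35.0, 30.0, 40.0),     # cube face, right
]
PINK = (75.0, 40.0, 0.0)
GREEN = (65.0, -45.0, 35.0)
DARK_GREEN = (45.0, -35.0, 25.0)
BLOB_BACKGROUND = (75.0, -5.0, -12.0)
# unit direction from background toward a brownish tone (darker,
# redder, yellower); scaled by the contrast parameter
_BLOB_DIRECTION = np.array([-0.8, 0.35, 0.45])
_BLOB_DIRECTION = _BLOB_DIRECTION / np.linalg.norm(_BLOB_DIRECTION)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic fixture.

    ``noise`` is the per-channel additive Gaussian std in CIELab
    units; the quarter-unit default keeps pixel tones distinct (exact
    tonal duplicates are a degeneracy real imagery does not exhibit)
    while staying below both perceptual relevance and the half-unit
    tone rounding used by the experiments.  ``softness`` is the
    Gaussian blur radius applied to region masks for gradual
    transitions; ``pink_fraction`` the target pink area fraction of
    the coherence fixtures; ``contrast`` the CIELab distance between
    blob and background mean tones; ``texture`` the std of the
    background/speckle texture of the blob fixture.
    """

    kind: str
    size: int | tuple[int, int] = 128
    palette: list[tuple[float, float, float]] | None = None
    noise: float = 0.25
    softness: float | None = None  # None -> per-kind default; 0 -> crisp
    seed: int = 0
    pink_fraction: float = 0.3
    n_blobs: int = 2
    contrast: float = 30.0
    texture: float = 2.0
    blob_radius_frac: float = 0.16

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        M, N = self.grid_shape
        if M < 8 or N < 8:
            raise ValueError("fixture size must be at least 8x8")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.palette is not None:
            for tone in self.palette:
                L, a, b = tone
                if not (0 <= L <= 100 and -128 <= a <= 127
                        and -128 <= b <= 127):
                    raise ValueError(f"palette tone {tone} outside CIELab "
                                     "ranges")

    @property
    def grid_shape(self) -> tuple[int, int]:
        if isinstance(self.size, int):
            return (self.size, self.size)
        return tuple(self.size)  # type: ignore[return-value]


def make_fixture(spec: FixtureSpec) -> tuple[RasterImage, RegionPartition]:
    """Dispatch on the fixture kind."""
    if spec.kind == "cube":
        return make_cube_fixture(spec)
    if spec.kind.startswith("coherence"):
        return make_coherence_fixture(spec)
    return make_blob_fixture(spec)


def _finalize(tones: np.ndarray, spec: FixtureSpec,
              rng: np.random.Generator) -> RasterImage:
    if spec.noise > 0:
        tones = tones + rng.normal(0.0, spec.noise, size=tones.shape)
    tones = np.clip(tones, -LAB_OFFSETS, LAB_SCALES - LAB_OFFSETS)
    return RasterImage(tones, CIELAB)


def make_cube_fixture(spec: FixtureSpec) -> tuple[RasterImage, RegionPartition]:
    """Isometric cube over a two-part background; five labelled regions."""
    if spec.kind != "cube":
        raise ValueError("spec.kind must be 'cube'")
    palette = spec.palette if spec.palette is not None else CUBE_PALETTE
    if len(palette) < 5:
        raise ValueError("cube fixture needs a palette of at least 5 tones")
    M, N = spec.grid_shape
    rng = np.random.default_rng(spec.seed)

    labels = np.zeros((M, N), dtype=np.int64)
    labels[M // 2:, :] = 1  # lower background area

    # isometric cube centered on the grid
    cy, cx = M * 0.48, N * 0.5
    hw, hh = N * 0.26, M * 0.30  # half-width / half-height of the hexagon
    top = np.array([[cy - hh, cx], [cy - hh * 0.45, cx + hw],
                    [cy + 0.1 * hh, cx], [cy - hh * 0.45, cx - hw]])
    left = np.array([[cy - hh * 0.45, cx - hw], [cy + 0.1 * hh, cx],
                     [cy + hh, cx], [cy + hh * 0.45, cx - hw]])
    right = np.array([[cy - hh * 0.45, cx + hw], [cy + 0.1 * hh, cx],
                      [cy + hh, cx], [cy + hh * 0.45, cx + hw]])
    for lab_id, poly in ((2, top), (3, left), (4, right)):
        rr, cc = polygon(poly[:, 0], poly[:, 1], shape=(M, N))
        labels[rr, cc] = lab_id

    tones = np.asarray(palette, float)[labels]
    img = _finalize(tones, spec, rng)
    names = {0: "background-upper", 1: "background-lower",
             2: "face-top", 3: "face-left", 4: "face-right"}
    return img, RegionPartition(labels, names)


def make_coherence_fixture(spec: FixtureSpec) -> tuple[RasterImage,
                                                       RegionPartition]:
    """Two-region pink/green fixtures with graded spatial coherence."""
    if not spec.kind.startswith("coherence"):
        raise ValueError("spec.kind must be one of the coherence variants")
    M, N = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    pink = np.array(spec.palette[0] if spec.palette else PINK)
    green = np.array(spec.palette[1] if spec.palette else GREEN)
    names = {0: "background", 1: "pink"}

    if spec.kind == "coherence-C":
        # no spatial structure: exactly the target number of pink
        # pixels, placed uniformly at random
        n_pink = int(round(spec.pink_fraction * M * N))
        idx = rng.choice(M * N, size=n_pink, replace=False)
        mask = np.zeros(M * N, dtype=bool)
        mask[idx] = True
        mask = mask.reshape(M, N)
        tones = np.where(mask[:, :, None], pink, green)
        return (_finalize(tones, spec, rng),
                RegionPartition(mask.astype(np.int64), names))

    radius = float(np.sqrt(spec.pink_fraction * M * N / np.pi))
    mask = np.zeros((M, N), dtype=bool)
    rr, cc = disk((M / 2, N / 2), radius, shape=(M, N))
    mask[rr, cc] = True

    if spec.kind == "coherence-A":
        # compact disc with a color-blended rim
        softness = 3.0 if spec.softness is None else spec.softness
        w = mask.astype(float)
        if softness > 0:
            w = ndimage.gaussian_filter(w, sigma=softness)
        tones = w[:, :, None] * pink + (1.0 - w[:, :, None]) * green
    else:  # coherence-B: crisp disc over a scattered two-tone background
        tones = np.where(mask[:, :, None], pink, green)
        scatter = rng.random((M, N)) < 0.5
        tones[scatter & ~mask] = DARK_GREEN
    return (_finalize(tones, spec, rng),
            RegionPartition(mask.astype(np.int64), names))


def make_blob_fixture(spec: FixtureSpec) -> tuple[RasterImage,
                                                  RegionPartition]:
    """Brownish deposits on textured light-blue tissue background.

    Blob boundaries are Gaussian-blurred (gradual transitions) and
    blob interiors carry speckle; the returned partition uses the
    crisp pre-blur geometry.
    """
    if spec.kind != "blob-deposit":
        raise ValueError("spec.kind must be 'blob-deposit'")
    if not 1 <= spec.n_blobs <= 3:
        raise ValueError("n_blobs must be between 1 and 3")
    M, N = spec.grid_shape
    rng = np.random.default_rng(spec.seed)
    bg = np.array(spec.palette[0] if spec.palette else BLOB_BACKGROUND)
    blob_tone = bg + spec.contrast * _BLOB_DIRECTION

    radius = spec.blob_radius_frac * min(M, N)
    if spec.n_blobs * np.pi * radius ** 2 >= M * N:
        raise ValueError("total blob area exceeds the image")
    mask = np.zeros((M, N), dtype=bool)
    lo, hi = 0.22, 0.78  # keep blob centers away from the border
    for _ in range(spec.n_blobs):
        cy = rng.uniform(lo * M, hi * M)
        cx = rng.uniform(lo * N, hi * N)
        r = radius * rng.uniform(0.8, 1.2)
        rr, cc = disk((cy, cx), r, shape=(M, N))
        mask[rr, cc] = True

    softness = 1.5 if spec.softness is None else spec.softness
    w = mask.astype(float)
    if softness > 0:
        w = ndimage.gaussian_filter(w, sigma=softness)
    tones = w[:, :, None] * blob_tone + (1.0 - w[:, :, None]) * bg
    if spec.texture > 0:
        # low-frequency unstructured background texture ...
        rough = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=(M, N, 3)), sigma=(1.5, 1.5, 0))
        tones = tones + spec.texture * rough / np.std(rough)
        # ... plus fine speckle inside the deposits
        speckle = rng.normal(0.0, spec.texture, size=(M, N, 3))
        tones = tones + speckle * mask[:, :, None]
    img = _finalize(tones, spec, rng)
    return img, RegionPartition(mask.astype(np.int64),
                                {0: "background", 1: "deposit"})
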