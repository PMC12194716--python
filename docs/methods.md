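# Methods

## Model

The smoother treats an image I : Ω → T as a dataset: pixel (x, y) with
tone t = (t₁, …, t_k) becomes the instance (x, y, t₁, …, t_k) in the
spatio-tonal universe Ω×T.  Fuzzy c-means is run on this dataset with
the metric

    d_ψ(a, b) = α·d_τ(â, b̂) + (1 − α)·d_ω(ã, b̃),

a convex combination of a tonal and a spatial Euclidean distance.
This is the *metric-generalized* spatial variant of fuzzy c-means: the
spatial information enters only through d_ψ, not through any
neighborhood-averaging of memberships.  The membership and centroid
updates are the standard fuzzy c-means ones with d_ψ substituted for
the distance; centroids live in the full (2+k)-dimensional universe,
and only their tonal parts are used when reconstructing images.

One run executes, in order: map to dataset → Forgy initialization C₀
(r distinct instances drawn uniformly without replacement) → initial
memberships M₀ → initial image I₀ → loop { centroid update, membership
update, reconstruction I_t, v ← Φ(I_t, I_{t−1}) } until v ≤ δ or an
iteration cap.  Note the centroid update precedes the membership
update inside an iteration; M₀ is computed once before the loop.  The
convergence statistic Φ is the mean per-pixel tonal (CIELab Euclidean)
distance between consecutive images.

Assumptions: distinct visual regions are separable in the spatio-tonal
universe; Euclidean distance in CIELab approximates perceived color
difference well enough for clustering; the user can state the number
of distinct regions r.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| r | — (required) | clusters | equals the number of distinct regions the user perceives |
| α | 0.5 | — | balanced spatial/tonal weight; 1 = color only, 0 = position only |
| δ | 0.05 | CIELab units | mean per-pixel change small against the ~2.3 just-noticeable difference |
| m | 2.0 | — | the near-universal fuzzy c-means fuzzifier default |
| max_iter | 200 | iterations | the qualitative studies use up to 100; 2× headroom |
| spatial scaling | 1/max(M, N) | — | one divisor for both axes preserves aspect ratio; coordinates land in [0, 1) |
| homogeneity n | 2 | pixels | 5×5 window: large enough to see texture, small enough to localize edges |
| band width w | 7 | pixels | band centered on region boundaries for edge-preservation statistics |

Tonal values are kept in native CIELab units inside the metric (L up
to 100), so α trades "CIELab units of tone" against "image diagonals
of displacement"; the fixed [0, 1] embedding of CIELab channels
(L/100, (a+128)/255, (b+128)/255) is used only by the homogeneity
operator, and uses fixed nominal ranges — not per-image min/max — so
homogeneity values are comparable across the iteration sequence.
Conversions assume sRGB with the D65/2° standard observer; grayscale
images are lifted to (L, 0, 0) with L = 100·gray so a single metric
and reconstruction path serves k = 1 and k = 3.

## Numerical choices

* **Zero-distance ties.**  A pixel at d_ψ = 0 from one or more
  centroids splits its membership equally over the zero-distance
  centroids and holds 0 elsewhere, preserving the Ruspini property
  symmetrically.
* **Empty clusters.**  A cluster whose membership mass underflows
  (< 1e-12) is re-seeded from a uniformly random instance, keeping r
  fixed at the user's declared region count.
* **Homogeneity borders.**  Windowed extrema are taken over the
  in-grid part of the window only (no padding); this is implemented
  with replicate-padding max/min filters, which is exactly equivalent
  because each padded value duplicates an in-grid pixel already
  covered by the same window.
* **Band geometry.**  Boundary seeds are pixels whose label differs
  from their right or lower neighbor; the band is all pixels within
  Chebyshev distance ⌊w/2⌋ of a seed, so odd w gives a band exactly w
  pixels wide across a straight boundary.  Euclidean geometry is
  available as an option.
* **Degenerate inputs.**  A constant image is a fixed point for any r
  (every centroid's tonal part equals the constant tone, so the
  reconstruction is exact and v = 0 at the first check).  r = 1
  converges to the flat tonal-mean image.
* **Determinism.**  One seeded generator per run drives both the
  Forgy draw and any re-seeding; the initialization-sensitivity
  experiment uses seeds seed+0 … seed+n−1 and compares all unordered
  pairs of images per iteration, run in lockstep to bound memory.

## Synthetic fixtures

The generator produces the three image families the studies need,
with exact ground-truth partitions: a five-region isometric cube
(blueish background pair + orange face triple, minimum pairwise tonal
separation ≈ 22.9 CIELab units) for cluster-count studies; three
two-region pink/green images with graded spatial coherence (compact
disc with blended rim / compact disc on scattered background /
uniformly scattered pixels) for the α studies; and a deposit fixture
(brownish blobs with Gaussian-blurred rims and speckle on a textured
light-bluish background, default contrast 30 CIELab units) emulating
the statistical character of tau-stained tissue patches.  Default
size is 128×128.

Fixtures carry 0.25 CIELab units of additive Gaussian noise by
default.  This keeps pixel tones distinct: with exactly duplicated
tones, two initial centroids drawn from the same region are identical
in the tonal subspace under α = 1 and receive identical updates
forever — a degeneracy real imagery does not exhibit.  A quarter unit
is far below perceptual relevance and below the half-unit tone
rounding used by the experiments.

What the fixtures do **not** emulate: optical blur and chromatic
aberration, stain-intensity gradients across a slide, JPEG artifacts,
and 1D structures (vessels, membranes).  Passing tests therefore show
correct behavior for blob-like regions on textured backgrounds, not
for curvilinear structure preservation.

## Known limitations

* **Initialization local minima.**  Fuzzy c-means can settle in local
  optima in which two centroids nearly coincide inside one tonal
  cluster while two true regions share a centroid.  On the cube
  fixture with r = 5 and α = 1 this happens for roughly a third of
  Forgy seeds; the affected runs still converge (v → 0) but recover
  only ~75 % of the ground-truth partition.  The pairwise-difference
  experiment quantifies exactly this spread; increasing iterations
  does not escape such a state.
* **Residual blending for under-specified r.**  With m = 2,
  memberships are never crisp: when r is smaller than the number of
  distinct regions, each merged region keeps a residual membership
  ~ (d_intra/d_inter)² to the far centroid, so the tones inside a
  merged family stay a few CIELab units apart rather than collapsing
  to a single value.  Visually the family is homogenized; numerically
  the distinct-tone count (at half-unit rounding) can exceed r.
* **1D structures.**  The spatial term favors compact 2D regions;
  lines and thin curvilinear structures are better served by raising
  α or by local-information smoothers.
* Homogeneity statistics are descriptive, for inspecting one method's
  behavior over iterations; they are not a standalone quality score
  for ranking different smoothing algorithms.

## Problem sizes

The test suite and the acceptance script run on 128×128 fixtures
(16 384 instances) with r ≤ 7 and up to 200 iterations, and on 8×8
images for the brute-force oracle comparisons; the full suite
completes in well under a minute on one CPU.  The implementation is
fully vectorized (pairwise distances via `scipy.spatial.distance.cdist`),
so desk-scale images (≈ 0.3 MPixel) remain practical.
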