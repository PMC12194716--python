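# cassfcm — content-aware image smoothing via spatial fuzzy c-means

`cassfcm` smooths raster images while preserving region boundaries.  It
is aimed at preprocessing for biological image analysis — the motivating
case is immunohistochemistry, where stained structures (e.g. brownish
tau-protein deposits on light neural tissue) sit on rugged, textured
backgrounds with gradual color transitions, and one wants to homogenize
tones *within* each structure without blending the structures together.
Unlike Gaussian blurring (content-unaware) or diffusion-style smoothers
that eventually flatten the whole image, this smoother converges to a
non-trivial state in which region contrasts survive.

## The method

Each pixel of an M×N image becomes an instance (x, y, t₁, …, t_k) in
the joint *spatio-tonal* universe Ω×T: two normalized spatial
coordinates plus its CIELab tone.  Distances there are a convex
combination of a spatial and a tonal metric (both Euclidean by
default):

    d_ψ(a, b) = α·d_τ(â, b̂) + (1 − α)·d_ω(ã, b̃),    α ∈ [0, 1]

The instances are soft-clustered by fuzzy c-means driven by d_ψ, with
r clusters (set by the user to the number of distinct regions) and
Forgy initialization (r random pixels).  Memberships μ_i and centroids
C_i follow the standard updates with fuzzifier m:

    μ_i(p) = [ Σ_j (d_ψ(p, C_i) / d_ψ(p, C_j))^(2/(m−1)) ]⁻¹
    C_i    = Σ_p μ_i(p)^m · p / Σ_p μ_i(p)^m

and form a Ruspini partition (Σ_i μ_i(p) = 1 at every pixel).  At each
iteration t an image is reconstructed by painting every pixel with the
membership-weighted combination of the centroid *tones*,
I_t(x, y) = Σ_i μ_{t,i}(x, y)·Ĉ_{t,i}, and the loop stops when the mean
per-pixel tonal difference between consecutive images,
Φ(I_t, I_{t−1}) = (1/|Ω|) Σ d_τ, drops below a tolerance δ.

The weight α tunes content-awareness: α = 1 clusters by color alone
(spatially scattered regions are still grouped), α = 0 is tonally blind
(pure spatial partition), intermediate values trade the two off.

For evaluation the package computes *local homogeneity* maps,
H(x, y) = 1 − max_W I + min_W I over (2n+1)×(2n+1) windows of
[0, 1]-normalized channels (averaged over channels), plus per-region
and boundary-band summaries: successful content-aware smoothing raises
H inside regions while the boundary band keeps its contrast.

## Worked example

Everything runs on synthetic fixtures the package generates itself;
the `blob-deposit` fixture emulates stained tissue patches (textured
light-bluish background, brownish deposits with blurred rims, exact
ground-truth labels):

```python
from cassfcm import (FixtureSpec, SmoothingConfig, make_blob_fixture,
                     run_cas_sfcm, normalize_unit, multichannel_homogeneity,
                     edge_band, region_mean_homogeneity)

img, regions = make_blob_fixture(FixtureSpec("blob-deposit", seed=7))
trace = run_cas_sfcm(img, SmoothingConfig(r=2, alpha=0.5, delta=0.05, seed=7))
print(f"{trace.termination} after {trace.n_iterations} iterations; "
      f"final v = {trace.diffs[-1]:.4f}")

band = edge_band(regions, w=7)
H = multichannel_homogeneity(normalize_unit(trace.final_image), n=2)
print(region_mean_homogeneity(H, regions, band).to_string(index=False))
```

prints

```
converged after 6 iterations; final v = 0.0090
    region  mean_homogeneity  n_pixels
background          0.996137     11699
   deposit          0.991690      2197
      band          0.935987      2488
```

The run converged (the mean inter-iteration tonal change fell below
δ = 0.05 CIELab units).  Mean local homogeneity inside background and
deposits rose from 0.971 / 0.942 on the textured original to 0.996 /
0.992 — the interiors were regularized — while the 7-pixel boundary
band stays clearly lower (0.936): the deposit edges were preserved, not
blurred away.

The same machinery is available from the shell:

```
cas-sfcm fixtures blob-deposit --seed 7 -o fx/
cas-sfcm smooth fx/blob-deposit.png -r 2 --alpha 0.5 --seed 7 -o run/
cas-sfcm evaluate run/smoothed.png --mask fx/blob-deposit_labels.png \
         --band-width 7 -n 2 -o report.csv
```

plus `sweep-clusters`, `sweep-alpha` and `init-sensitivity` for the
parameter studies.  Every run writes a `manifest.yaml` sufficient to
reproduce it bit-identically.

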