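"""Rebuilding an image from memberships and centroid tones.

At every iteration each pixel is painted with the membership-weighted
convex combination of the centroid *tonal* parts:

    I_t(x, y) = sum_i mu_{t,i}(x, y) * C_hat_{t,i}.

Because memberships form a Ruspini partition, every output tone lies
in the convex hull of the centroid tones; a pixel with full membership
in one cluster takes that centroid's color exactly.
"""

from __future__ import annotations

import numpy as np

from .image import CIELAB, RasterImage


def reconstruct_image(U: np.ndarray, C_tonal: np.ndarray,
                      grid_shape: tuple[int, int]) -> RasterImage:
    """Membership-weighted reconstruction of the iteration image.

    Parameters
    ----------
    U : (n_pixels, r) membership matrix in row-major pixel order,
        rows summing to 1.
    C_tonal : (r, k) tonal parts of the centroids, CIELab units.
    grid_shape : (M, N) of the target image.
    """
    U = np.asarray(U, float)
    C_tonal = np.asarray(C_tonal, float)
    if U.ndim != 2 or C_tonal.ndim != 2 or U.shape[1] != C_tonal.shape[0]:
        raise ValueError(
            f"cluster count mismatch: memberships have r={U.shape[1]}, "
            f"centroids have r={C_tonal.shape[0]}"
        )
    M, N = grid_shape
    if U.shape[0] != M * N:
        raise ValueError("membership rows do not cover the pixel grid")
    tones = U @ C_tonal
    return RasterImage(tones.reshape(M, N, C_tonal.shape[1]), CIELAB)
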