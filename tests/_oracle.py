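"""Independent brute-force reference for the fuzzy clustering steps.

Everything here is written as explicit double loops straight from the
defining formulas, deliberately sharing no code with the package, so
it can serve as an oracle for the vectorized implementation.
"""

import math

import numpy as np


def spatio_tonal_dist(a, b, alpha):
    ds = math.sqrt((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2)
    dt = math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a[2:], b[2:])))
    return alpha * dt + (1.0 - alpha) * ds


def memberships(X, C, alpha, m):
    n, r = len(X), len(C)
    U = np.zeros((n, r))
    for p in range(n):
        d = [spatio_tonal_dist(X[p], C[i], alpha) for i in range(r)]
        zeros = [i for i in range(r) if d[i] == 0.0]
        if zeros:
            for i in zeros:
                U[p, i] = 1.0 / len(zeros)
            continue
        for i in range(r):
            s = 0.0
            for j in range(r):
                s += (d[i] / d[j]) ** (2.0 / (m - 1.0))
            U[p, i] = 1.0 / s
    return U


def centroids(X, U, m):
    n, dim = X.shape
    r = U.shape[1]
    C = np.zeros((r, dim))
    for i in range(r):
        num = np.zeros(dim)
        den = 0.0
        for p in range(n):
            w = U[p, i] ** m
            num = num + w * X[p]
            den += w
        C[i] = num / den
    return C


def reconstruct(U, C, grid_shape, k):
    M, N = grid_shape
    out = np.zeros((M, N, k))
    r = U.shape[1]
    for i in range(M):
        for j in range(N):
            p = i * N + j
            for c in range(r):
                out[i, j] += U[p, c] * C[c, 2:]
    return out


def one_iteration(X, U_prev, alpha, m, grid_shape, k):
    """Centroid step, membership step, reconstruction — in loop form."""
    C = centroids(X, U_prev, m)
    U = memberships(X, C, alpha, m)
    I = reconstruct(U, C, grid_shape, k)
    return C, U, I
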