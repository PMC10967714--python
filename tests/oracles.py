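"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain Python loops evaluating the defining
formulas directly, sharing no code with the package, so that agreement
between the two routes is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math


def fcm_reference(x, T0, m=2.0, eps=1e-3, max_iter=200):
    """Plain fuzzy c-means by direct formula evaluation.

    Schedule: membership from current centroids -> centroid update ->
    stop when the largest elementwise membership change is <= eps.
    Returns (centroids, membership[c][n], iterations).
    """
    x = [float(v) for v in x]
    T = [float(v) for v in T0]
    n, c = len(x), len(T)

    def membership(T):
        U = [[0.0] * n for _ in range(c)]
        for l in range(n):
            ds = [abs(x[l] - T[k]) for k in range(c)]
            if any(d == 0.0 for d in ds):
                hits = [1.0 if d == 0.0 else 0.0 for d in ds]
                tot = sum(hits)
                for k in range(c):
                    U[k][l] = hits[k] / tot
            else:
                for k in range(c):
                    U[k][l] = 1.0 / sum(
                        (ds[k] / ds[j]) ** (2.0 / (m - 1.0)) for j in range(c)
                    )
        return U

    U = membership(T)
    iterations = 0
    for v in range(1, max_iter + 1):
        T = [
            sum((U[k][l] ** m) * x[l] for l in range(n))
            / sum(U[k][l] ** m for l in range(n))
            for k in range(c)
        ]
        U_new = membership(T)
        delta = max(
            abs(U_new[k][l] - U[k][l]) for k in range(c) for l in range(n)
        )
        U = U_new
        iterations = v
        if delta <= eps:
            break
    return T, U, iterations


def lloyd_reference(x, centers0, max_iter=100):
    """Hard K-means (Lloyd) on scalars by direct evaluation."""
    x = [float(v) for v in x]
    centers = [float(v) for v in centers0]
    for _ in range(max_iter):
        assign = [
            min(range(len(centers)), key=lambda k: abs(v - centers[k])) for v in x
        ]
        new = []
        for k in range(len(centers)):
            pts = [x[i] for i in range(len(x)) if assign[i] == k]
            new.append(sum(pts) / len(pts) if pts else centers[k])
        if new == centers:
            break
        centers = new
    return centers, assign


def glcm_reference(levels, W, offsets, symmetric=True, normalize=True):
    """Co-occurrence by exhaustive pair enumeration; averaged over offsets."""
    rows = len(levels)
    cols = len(levels[0])
    mats = []
    for dr, dc in offsets:
        P = [[0.0] * W for _ in range(W)]
        total = 0
        for i in range(rows):
            for j in range(cols):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < rows and 0 <= j2 < cols:
                    a, b = levels[i][j], levels[i2][j2]
                    P[a][b] += 1.0
                    total += 1
                    if symmetric:
                        P[b][a] += 1.0
        if symmetric:
            total *= 2
        if normalize and total:
            P = [[v / total for v in row] for row in P]
        mats.append(P)
    return [
        [sum(m[i][j] for m in mats) / len(mats) for j in range(W)] for i in range(W)
    ]


def glcm_features_reference(P):
    """Contrast/correlation/homogeneity/energy by double summation."""
    W = len(P)
    total = sum(sum(row) for row in P)
    pk = [sum(P[k][l] for l in range(W)) / total for k in range(W)]
    M = sum(k * pk[k] for k in range(W))
    S4 = math.sqrt(sum((k - M) ** 2 * pk[k] for k in range(W)))
    contrast = sum(P[k][l] * (k - l) ** 2 for k in range(W) for l in range(W))
    homog = sum(P[k][l] / (1 + (k - l) ** 2) for k in range(W) for l in range(W))
    energy = sum(P[k][l] ** 2 for k in range(W) for l in range(W))
    if S4 > 0:
        corr = (
            sum(P[k][l] * (k - M) * (l - M) for k in range(W) for l in range(W))
            / S4**2
        )
    else:
        corr = 0.0
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_homogeneity": homog,
        "glcm_energy": energy,
    }


def ngtdm_reference(levels, W, window=3):
    """NGTDM busyness/strength by exhaustive window scanning."""
    rows = len(levels)
    cols = len(levels[0])
    half = window // 2
    s = [0.0] * W
    counts = [0] * W
    for i in range(rows):
        for j in range(cols):
            nb = []
            for di in range(-half, half + 1):
                for dj in range(-half, half + 1):
                    if di == 0 and dj == 0:
                        continue
                    i2, j2 = i + di, j + dj
                    if 0 <= i2 < rows and 0 <= j2 < cols:
                        nb.append(levels[i2][j2])
            if not nb:
                continue
            lvl = levels[i][j]
            s[lvl] += abs(lvl - sum(nb) / len(nb))
            counts[lvl] += 1
    n = sum(counts)
    present = [k for k in range(W) if counts[k] > 0]
    p = [counts[k] / n for k in range(W)]
    if len(present) <= 1:
        return {"ngtdm_busyness": 0.0, "ngtdm_strength": 0.0}, s, p
    busy_den = sum(
        abs(i * p[i] - j * p[j]) for i in present for j in present
    )
    busyness = (
        sum(p[i] * s[i] for i in present) / busy_den if busy_den > 0 else 0.0
    )
    s_total = sum(s[i] for i in present)
    strength = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_total
        if s_total > 0
        else 0.0
    )
    return {"ngtdm_busyness": busyness, "ngtdm_strength": strength}, s, p


def histogram_entropy_reference(values, bins):
    """Equal-width binning entropy (bits) of a min-max normalized column."""
    lo, hi = min(values), max(values)
    if hi == lo:
        return 0.0
    counts = [0] * bins
    for v in values:
        u = (v - lo) / (hi - lo)
        k = min(int(u * bins), bins - 1)
        counts[k] += 1
    n = len(values)
    ent = 0.0
    for c in counts:
        if c:
            ent -= (c / n) * math.log2(c / n)
    return ent
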