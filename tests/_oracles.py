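"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over definitions, deliberately
sharing no code path with the package.
"""

import math

import numpy as np


def glcm_counts_oracle(levels, offsets, symmetric=True):
    """Exhaustive voxel-pair enumeration into a raw co-occurrence count matrix."""
    levels = np.asarray(levels)
    G = int(levels.max())
    counts = np.zeros((G, G), dtype=float)
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = levels[z, y, x]
                if a == 0:
                    continue
                for dz, dy, dx in offsets:
                    z2, y2, x2 = z + dz, y + dy, x + dx
                    if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                        continue
                    b = levels[z2, y2, x2]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    if symmetric:
                        counts[b - 1, a - 1] += 1
    return counts


def glcm_features_oracle(P):
    """Direct double-loop evaluation of the four texture sums."""
    G = P.shape[0]
    contrast = energy = homogeneity = 0.0
    for i in range(G):
        for j in range(G):
            contrast += (i - j) ** 2 * P[i, j]
            energy += P[i, j] ** 2
            homogeneity += P[i, j] / (1 + abs(i - j))
    p_i = [sum(P[i, j] for j in range(G)) for i in range(G)]
    p_j = [sum(P[i, j] for i in range(G)) for j in range(G)]
    mu_i = sum((i + 1) * p_i[i] for i in range(G))
    mu_j = sum((j + 1) * p_j[j] for j in range(G))
    sd_i = math.sqrt(sum((i + 1 - mu_i) ** 2 * p_i[i] for i in range(G)))
    sd_j = math.sqrt(sum((j + 1 - mu_j) ** 2 * p_j[j] for j in range(G)))
    correlation = float("nan")
    if sd_i > 0 and sd_j > 0:
        correlation = sum(
            (i + 1 - mu_i) * (j + 1 - mu_j) * P[i, j]
            for i in range(G)
            for j in range(G)
        ) / (sd_i * sd_j)
    return contrast, correlation, energy, homogeneity


def skewness_oracle(x):
    x = list(map(float, x))
    n = len(x)
    m = sum(x) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))
    return n / ((n - 1) * (n - 2)) * sum((v - m) ** 3 for v in x) / sd**3


def kurtosis_oracle(x):
    x = list(map(float, x))
    n = len(x)
    m = sum(x) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))
    t1 = n * (n + 1) / ((n - 1) * (n - 2) * (n - 3))
    t2 = 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return t1 * sum((v - m) ** 4 for v in x) / sd**4 - t2


def entropy_oracle(x, n_bins, value_range=None):
    x = list(map(float, x))
    if value_range is None:
        value_range = (min(x), max(x))
    lo, hi = value_range
    counts = [0] * n_bins
    for v in x:
        if hi > lo:
            k = int((v - lo) / (hi - lo) * n_bins)
        else:
            k = 0
        counts[min(max(k, 0), n_bins - 1)] += 1
    total = len(x)
    e = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            e -= p * math.log2(p)
    return e


def spearman_rho_oracle(x, y):
    """Average-rank Spearman via explicit rank arithmetic."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
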