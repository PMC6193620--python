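"""Independent brute-force reference for the co-occurrence features.

Everything here is written as explicit double loops over gray levels and
pixel positions, with no shared code with the package implementation, so it
can serve as the oracle in equivalence tests.
"""

import math

import numpy as np


def brute_glcm(image, mask, offset, levels):
    """Ordered pair counts by explicit pixel iteration; returns normalized P."""
    h, w = image.shape
    dr, dc = offset
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i = (int(image[r, c]) * levels) // 256
                j = (int(image[r2, c2]) * levels) // 256
                counts[i, j] += 1
    total = counts.sum()
    assert total > 0
    return counts / total


def _xlogx(p):
    return p * math.log(p) if p > 0 else 0.0


def brute_features(P):
    """All 22 features from a normalized GLCM, by explicit summation."""
    L = P.shape[0]
    p_x = [sum(P[i, j] for j in range(L)) for i in range(L)]
    p_y = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * p_x[i] for i in range(L))
    mu_y = sum(j * p_y[j] for j in range(L))
    sigma_x = math.sqrt(sum((i - mu_x) ** 2 * p_x[i] for i in range(L)))
    sigma_y = math.sqrt(sum((j - mu_y) ** 2 * p_y[j] for j in range(L)))
    mu = (mu_x + mu_y) / 2.0

    s = [0.0] * (2 * L - 1)
    d = [0.0] * L
    for i in range(L):
        for j in range(L):
            s[i + j] += P[i, j]
            d[abs(i - j)] += P[i, j]

    f = {}
    f["H"] = -sum(_xlogx(P[i, j]) for i in range(L) for j in range(L))
    f["INV"] = sum(P[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L))
    f["HO"] = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    f["D"] = sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L))
    f["CS"] = sum((i + j - mu_x - mu_y) ** 3 * P[i, j]
                  for i in range(L) for j in range(L))
    f["CP"] = sum((i + j - mu_x - mu_y) ** 4 * P[i, j]
                  for i in range(L) for j in range(L))
    f["AC"] = sum(i * j * P[i, j] for i in range(L) for j in range(L))
    f["CO1"] = sum(n * n * d[n] for n in range(L))
    f["CO2"] = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    f["A"] = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    f["V"] = sum((i - mu) ** 2 * P[i, j] for i in range(L) for j in range(L))
    f["SA"] = sum(n * s[n] for n in range(2 * L - 1))
    f["SH"] = -sum(_xlogx(sn) for sn in s)
    f["DH"] = -sum(_xlogx(dn) for dn in d)
    f["SV"] = sum((n - f["SH"]) ** 2 * s[n] for n in range(2 * L - 1))
    d_mean = sum(n * d[n] for n in range(L))
    f["DV"] = sum((n - d_mean) ** 2 * d[n] for n in range(L))
    f["M"] = max(P[i, j] for i in range(L) for j in range(L))

    if sigma_x > 0 and sigma_y > 0:
        f["C1"] = sum((i - mu_x) * (j - mu_y) * P[i, j]
                      for i in range(L) for j in range(L)) / (sigma_x * sigma_y)
        f["C2"] = (f["AC"] - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        f["C1"] = f["C2"] = 0.0

    # maximal correlation coefficient: second eigenvalue of Q by modulus
    live_x = [i for i in range(L) if p_x[i] > 0]
    live_y = [k for k in range(L) if p_y[k] > 0]
    n = len(live_x)
    if n < 2:
        f["MCC"] = 0.0
    else:
        Q = np.zeros((n, n))
        for a, i in enumerate(live_x):
            for b, j in enumerate(live_x):
                Q[a, b] = sum(P[i, k] * P[j, k] / (p_x[i] * p_y[k]) for k in live_y)
        eig = sorted(np.linalg.eigvals(Q), key=lambda z: -abs(z))
        f["MCC"] = float(np.real(eig[1]))

    HX = -sum(_xlogx(p) for p in p_x)
    HY = -sum(_xlogx(p) for p in p_y)
    H1XY = -sum(P[i, j] * math.log(p_x[i] * p_y[j])
                for i in range(L) for j in range(L) if P[i, j] > 0)
    H2XY = -sum(_xlogx(p_x[i] * p_y[j]) for i in range(L) for j in range(L))
    hmax = max(HX, HY)
    f["IC1"] = (f["H"] - H1XY) / hmax if hmax > 0 else 0.0
    f["IC2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (H2XY - f["H"]))))
    return f
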