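"""Gray-level co-occurrence matrix and the 22 textural features.

The GLCM for offset (dr, dc) is the normalized joint distribution P_ij of
ordered gray-level pairs (pixel, pixel + offset) with both members inside the
ROI. The reference protocol uses a 2-pixel spacing along the horizontal
(0, +2) and vertical (+2, 0) directions, yielding 22 features per direction
and a 44-dimensional per-frame vector.

The 22 features fall into three groups:

* group 1 — ten classical descriptors computed directly on P_ij:
  entropy H, homogeneity HO, dissimilarity D, cluster shade CS, cluster
  prominence CP, autocorrelation AC, contrast CO2, energy A, variance V,
  maximum probability M;
* group 2 — seven descriptors of the sum (i+j) and difference |i-j|
  distributions: inverse difference INV, contrast CO1, sum average SA,
  sum entropy SH, difference entropy DH, sum variance SV, difference
  variance DV;
* group 3 — five correlation-based descriptors: C1, C2, the maximal
  correlation coefficient MCC, and the information measures IC1, IC2.

Conventions (all chosen so every feature is finite on every valid GLCM):
natural logarithm with 0*log 0 = 0; gray levels are 0-based, so CO1 and CO2
are algebraically identical, as are C1 and C2; zero marginal variance maps
C1 = C2 = 0; a negative radicand in IC2 clamps to 0; MCC is the real part of
the second-largest-modulus eigenvalue of Q (0 when Q is 1x1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateGLCMError, ValidationError
from .io import Frame
from .roi import ROIMask

HORIZONTAL = (0, 2)
VERTICAL = (2, 0)

#: the unique partition consistent with the printed group sizes 10/7/5
FEATURE_GROUPS = {
    1: ("H", "HO", "D", "CS", "CP", "AC", "CO2", "A", "V", "M"),
    2: ("INV", "CO1", "SA", "SH", "DH", "SV", "DV"),
    3: ("C1", "C2", "MCC", "IC1", "IC2"),
}
FEATURE_ORDER = FEATURE_GROUPS[1] + FEATURE_GROUPS[2] + FEATURE_GROUPS[3]
DIRECTIONS = {"h": HORIZONTAL, "v": VERTICAL}


@dataclass
class GLCM:
    """Normalized co-occurrence distribution P with its raw pair counts."""

    P: np.ndarray
    raw_counts: np.ndarray
    levels: int
    offset: tuple[int, int]


@dataclass
class MarginalStats:
    """Marginals, sum/difference distributions and entropies derived from P."""

    p_x: np.ndarray          # row marginal
    p_y: np.ndarray          # column marginal
    sum_dist: np.ndarray     # distribution of n = i + j, n in 0..2(L-1)
    diff_dist: np.ndarray    # distribution of n = |i - j|, n in 0..L-1
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    mu: float                # mean gray level under P, (mu_x + mu_y)/2
    HX: float
    HY: float
    H1XY: float
    H2XY: float


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*log 0 = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit grays onto ``levels`` bins: level = floor(gray * L / 256)."""
    if 256 % levels != 0:
        raise ValidationError(f"levels must divide 256, got {levels}")
    return (pixels.astype(np.int64) * levels) // 256


def compute_glcm(frame: Frame | np.ndarray, mask: ROIMask | np.ndarray | None,
                 offset: tuple[int, int] = HORIZONTAL, levels: int = 256) -> GLCM:
    """Count ordered gray-level pairs (p, p + offset) with both pixels in the mask.

    ``mask=None`` uses the full frame. Raises :class:`DegenerateGLCMError`
    when no valid pair exists.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if mask is None:
        m = np.ones(pixels.shape, dtype=bool)
    else:
        m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if m.shape != pixels.shape:
        raise ValidationError("mask shape must match frame shape")

    q = quantize(pixels, levels)
    dr, dc = offset
    h, w = q.shape
    # source window such that (r+dr, c+dc) stays in bounds
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise DegenerateGLCMError(f"offset {offset} larger than frame")
    src = q[r0:r1, c0:c1]
    dst = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = m[r0:r1, c0:c1] & m[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    i, j = src[valid], dst[valid]
    if i.size == 0:
        raise DegenerateGLCMError(f"no valid pixel pair for offset {offset}")
    counts = np.bincount(i * levels + j, minlength=levels * levels)
    counts = counts.reshape(levels, levels)
    P = counts / counts.sum()
    return GLCM(P=P, raw_counts=counts, levels=levels, offset=offset)


def marginal_statistics(glcm: GLCM) -> MarginalStats:
    """Marginals, sum/difference distributions, their moments and entropies."""
    P = glcm.P
    L = glcm.levels
    idx = np.arange(L, dtype=float)
    p_x = P.sum(axis=1)
    p_y = P.sum(axis=0)
    mu_x = float(idx @ p_x)
    mu_y = float(idx @ p_y)
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ p_x))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ p_y))

    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    sum_dist = np.bincount((ii + jj).ravel(), weights=P.ravel(), minlength=2 * L - 1)
    diff_dist = np.bincount(np.abs(ii - jj).ravel(), weights=P.ravel(), minlength=L)

    HX = _entropy(p_x)
    HY = _entropy(p_y)
    prod = np.outer(p_x, p_y)
    nz = P > 0  # P_ij > 0 implies both marginals > 0
    H1XY = float(-(P[nz] * np.log(prod[nz])).sum())
    H2XY = _entropy(prod.ravel())

    return MarginalStats(p_x=p_x, p_y=p_y, sum_dist=sum_dist, diff_dist=diff_dist,
                         mu_x=mu_x, mu_y=mu_y, sigma_x=sigma_x, sigma_y=sigma_y,
                         mu=(mu_x + mu_y) / 2.0, HX=HX, HY=HY, H1XY=H1XY, H2XY=H2XY)


def classical_features(glcm: GLCM, marg: MarginalStats) -> dict[str, float]:
    """The ten classical descriptors computed directly on P_ij."""
    P = glcm.P
    L = glcm.levels
    ii, jj = np.meshgrid(np.arange(L, dtype=float), np.arange(L, dtype=float),
                         indexing="ij")
    dev = ii + jj - marg.mu_x - marg.mu_y
    return {
        "H": _entropy(P.ravel()),
        "HO": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "D": float((np.abs(ii - jj) * P).sum()),
        "CS": float((dev ** 3 * P).sum()),
        "CP": float((dev ** 4 * P).sum()),
        "AC": float((ii * jj * P).sum()),
        "CO2": float(((ii - jj) ** 2 * P).sum()),
        "A": float((P ** 2).sum()),
        "V": float(((ii - marg.mu) ** 2 * P).sum()),
        "M": float(P.max()),
    }


def sum_difference_features(glcm: GLCM, marg: MarginalStats) -> dict[str, float]:
    """The seven descriptors of the sum and difference distributions."""
    P = glcm.P
    L = glcm.levels
    ii, jj = np.meshgrid(np.arange(L, dtype=float), np.arange(L, dtype=float),
                         indexing="ij")
    s, d = marg.sum_dist, marg.diff_dist
    ns = np.arange(len(s), dtype=float)
    nd = np.arange(len(d), dtype=float)
    SH = _entropy(s)
    d_mean = float(nd @ d)
    return {
        "INV": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "CO1": float((nd ** 2) @ d),
        "SA": float(ns @ s),
        "SH": SH,
        "DH": _entropy(d),
        "SV": float(((ns - SH) ** 2) @ s),  # sum entropy inside the square
        "DV": float(((nd - d_mean) ** 2) @ d),
    }


def _mcc(glcm: GLCM, marg: MarginalStats) -> float:
    """Second-largest-modulus eigenvalue (real part) of the Q matrix."""
    P = glcm.P
    rows = marg.p_x > 0
    cols = marg.p_y > 0
    Psub = P[np.ix_(rows, cols)]
    # Q_ij = sum_k P_ik P_jk / (p_x(i) p_y(k)), zero-marginal terms skipped
    W = Psub / marg.p_y[cols][None, :]
    Q = (Psub / marg.p_x[rows][:, None]) @ W.T
    if Q.shape[0] < 2:
        return 0.0
    eig = np.linalg.eigvals(Q)
    order = np.argsort(-np.abs(eig))
    return float(np.real(eig[order[1]]))


def correlation_features(glcm: GLCM, marg: MarginalStats) -> dict[str, float]:
    """The five correlation-based descriptors (zero-variance cases map to 0)."""
    P = glcm.P
    L = glcm.levels
    ii, jj = np.meshgrid(np.arange(L, dtype=float), np.arange(L, dtype=float),
                         indexing="ij")
    denom = marg.sigma_x * marg.sigma_y
    if denom > 0:
        c1 = float((((ii - marg.mu_x) * (jj - marg.mu_y)) * P).sum() / denom)
        c2 = float(((ii * jj * P).sum() - marg.mu_x * marg.mu_y) / denom)
    else:
        c1 = c2 = 0.0
    H = _entropy(P.ravel())
    hmax = max(marg.HX, marg.HY)
    ic1 = (H - marg.H1XY) / hmax if hmax > 0 else 0.0
    ic2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (marg.H2XY - H)))))
    return {"C1": c1, "C2": c2, "MCC": _mcc(glcm, marg), "IC1": ic1, "IC2": ic2}


def all_features(glcm: GLCM) -> dict[str, float]:
    """All 22 named features of one GLCM."""
    marg = marginal_statistics(glcm)
    out = classical_features(glcm, marg)
    out.update(sum_difference_features(glcm, marg))
    out.update(correlation_features(glcm, marg))
    return out


def feature_names(directions: tuple[str, ...] = ("h", "v")) -> list[str]:
    """Names of the 44-vector entries, e.g. ``H_h ... IC2_h H_v ... IC2_v``."""
    return [f"{name}_{d}" for d in directions for name in FEATURE_ORDER]


def group_columns(group: int | str, directions: tuple[str, ...] = ("h", "v")) -> list[int]:
    """Column indices of one feature group (both directions) in the 44-vector."""
    if group in ("all", "ALL"):
        return list(range(len(FEATURE_ORDER) * len(directions)))
    group = int(group)
    if group not in FEATURE_GROUPS:
        raise ValidationError(f"unknown feature group {group!r}; use 1, 2, 3 or 'all'")
    names = feature_names(directions)
    wanted = set(FEATURE_GROUPS[group])
    return [k for k, n in enumerate(names) if n.rsplit("_", 1)[0] in wanted]


def feature_vector(frame: Frame | np.ndarray, mask: ROIMask | np.ndarray | None,
                   distance: int = 2, levels: int = 256) -> np.ndarray:
    """44-dimensional per-frame texture vector.

    Computes the GLCM at (0, +distance) and (+distance, 0) and concatenates
    the 22 features per direction, horizontal first, in the fixed order
    group 1, group 2, group 3 (see :data:`FEATURE_ORDER`).
    """
    values = []
    for dname in ("h", "v"):
        dr, dc = DIRECTIONS[dname]
        offset = (np.sign(dr) * distance, np.sign(dc) * distance)
        g = compute_glcm(frame, mask, offset=(int(offset[0]), int(offset[1])),
                         levels=levels)
        feats = all_features(g)
        values.extend(feats[name] for name in FEATURE_ORDER)
    return np.asarray(values, dtype=float)
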