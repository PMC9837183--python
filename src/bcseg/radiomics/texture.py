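"""High-order texture features over discretized gray levels (75 features).

All five families operate on a :class:`~bcseg.radiomics.discretize.DiscretizedROI`
in full 3D with unit (Chebyshev distance 1) neighborhoods:

* GLCM — symmetric co-occurrence matrices over the 13 unique 3D directions,
  normalized per direction; features averaged over directions (24 features).
* GLRLM — run-length matrices per direction, direction-averaged (16).
* GLSZM — 26-connected same-level zones, orientation-free (16).
* NGTDM — neighborhood gray-tone differences over the 26-neighborhood (5).
* GLDM — gray-level dependence counts, distance 1, dependence threshold
  α = 0 (14).  A voxel's dependence is its number of in-mask neighbors with
  |Δlevel| ≤ α; the reference formulas weight dependence size as count + 1
  (the center voxel counts itself).

Degenerate conventions, frozen here and exercised in the tests: a
single-gray-level ROI has GLCM Correlation = MCC = 1 and Imc1 = Imc2 = 0;
NGTDM Contrast and Busyness are 0 when only one gray tone is present;
direction averaging skips directions with no voxel pairs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI
from .manifest import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
)

__all__ = [
    "ANGLES_13",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "glcm_matrix",
    "run_length_matrix",
    "size_zone_matrix",
    "ngtdm_table",
    "dependence_matrix",
]

#: the 13 unique (lexicographically positive) 3D direction offsets
ANGLES_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(ANGLES_13) == 13

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _pair_slices(shape, off):
    src = tuple(slice(max(0, -o), s - max(0, o)) for o, s in zip(off, shape))
    dst = tuple(slice(max(0, o), s - max(0, -o)) for o, s in zip(off, shape))
    return src, dst


def _plog2(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with 0·log(0) = 0."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# --------------------------------------------------------------------------- GLCM
def glcm_matrix(d: DiscretizedROI, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric (unnormalized) co-occurrence counts P(i, j) for one offset."""
    src, dst = _pair_slices(d.levels.shape, offset)
    valid = d.mask[src] & d.mask[dst]
    a = d.levels[src][valid] - 1
    b = d.levels[dst][valid] - 1
    c = np.bincount(a * d.ng + b, minlength=d.ng * d.ng).reshape(d.ng, d.ng)
    return (c + c.T).astype(np.float64)


def _glcm_one(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng, dtype=np.float64)
    idx = np.abs(np.arange(ng)[:, None] - np.arange(ng)[None, :])
    p_diff = np.bincount(idx.ravel(), weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    sdx = np.arange(ng)[:, None] + np.arange(ng)[None, :]
    p_sum = np.bincount(sdx.ravel(), weights=p.ravel(), minlength=2 * ng - 1)

    hxy = float(-_plog2(p).sum())
    hx = float(-_plog2(px).sum())
    hy = float(-_plog2(py).sum())
    pxy = np.outer(px, py)
    nzj = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nzj] * np.log2(pxy[nzj])).sum())
    hxy2 = float(-_plog2(pxy[pxy > 0]).sum()) if ng > 1 else 0.0

    da = float((k_diff * p_diff).sum())
    autoc = float((ii * jj * p).sum())

    if sigx * sigy > 0:
        corr = (autoc - mux * muy) / (sigx * sigy)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if ng > 1 else 0.0

    if ng > 1:
        # for a symmetric matrix (px == py) the MCC matrix Q factors as
        # (D^-1 P)^2 with D = diag(px); its eigenvalues are the squared
        # eigenvalues of the symmetric D^-1/2 P D^-1/2
        keep = px > 0
        sqrt_px = np.sqrt(px[keep])
        s_mat = p[keep][:, keep] / np.outer(sqrt_px, sqrt_px)
        lam2 = np.sort(np.linalg.eigvalsh(s_mat) ** 2)
        mcc = float(np.sqrt(max(0.0, lam2[-2]))) if lam2.size > 1 else 1.0
    else:
        mcc = 1.0

    kd_pos = k_diff > 0
    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float(((ii + jj - mux - muy) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - mux - muy) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - mux - muy) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_plog2(p_diff).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p_diff[kd_pos] / k_diff[kd_pos] ** 2).sum()),
        "JointAverage": mux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-_plog2(p_sum).sum()),
        "SumSquares": float(((i - mux) ** 2 * px).sum()),
    }


def glcm_features(d: DiscretizedROI, distance: int = 1) -> dict[str, float]:
    """24 co-occurrence features, averaged over the 13 unique directions."""
    if distance != 1:
        raise ValueError("only distance-1 co-occurrence is supported")
    per_angle = []
    for off in ANGLES_13:
        c = glcm_matrix(d, off)
        tot = c.sum()
        if tot == 0:
            continue
        per_angle.append(_glcm_one(c / tot, d.ng))
    if not per_angle:  # single voxel: degenerate self-pair convention
        per_angle = [_glcm_one(np.ones((1, 1)), 1)]
    out = {k: float(np.mean([f[k] for f in per_angle])) for k in per_angle[0]}
    assert tuple(out) == GLCM_FEATURES
    return out


# -------------------------------------------------------------------------- GLRLM
def run_length_matrix(d: DiscretizedROI, offset: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts P(i, r): maximal same-level runs along one direction."""
    shape = d.levels.shape
    src, dst = _pair_slices(shape, offset)
    eq = np.zeros(shape, dtype=bool)  # eq[v]: run continues from v to v+offset
    eq[src] = d.mask[src] & d.mask[dst] & (d.levels[src] == d.levels[dst])

    run = np.ones(shape, dtype=np.int64)
    run[~d.mask] = 0
    for _ in range(max(shape)):
        ahead = np.zeros(shape, dtype=np.int64)
        ahead[src] = run[dst]
        new = np.where(d.mask, 1 + np.where(eq, ahead, 0), 0)
        if (new == run).all():
            break
        run = new

    prev = np.zeros(shape, dtype=bool)  # prev[v]: run continues from v-offset into v
    prev[dst] = eq[src]
    starts = d.mask & ~prev
    lev = d.levels[starts] - 1
    rl = run[starts] - 1
    max_r = int(run.max())
    return (
        np.bincount(lev * max_r + rl, minlength=d.ng * max_r)
        .reshape(d.ng, max_r)
        .astype(np.float64)
    )


def _gl_size_features(p: np.ndarray, n_voxels: int, names: dict[str, str]) -> dict[str, float]:
    """Shared feature formulas for the (gray level × size) matrix families.

    GLRLM, GLSZM and GLDM all reduce to a matrix P(i, s) of counts by gray
    level i and a size-like index s (run length, zone size, dependence
    size); `names` maps the generic feature keys to family-specific names.
    """
    ns = p.sum()
    i = np.arange(1, p.shape[0] + 1, dtype=np.float64)
    s = np.arange(1, p.shape[1] + 1, dtype=np.float64)
    pn = p / ns
    pg = p.sum(axis=1)  # per gray level
    ps = p.sum(axis=0)  # per size
    mu_i = float((i * pn.sum(axis=1)).sum())
    mu_s = float((s * pn.sum(axis=0)).sum())
    ii = i[:, None]
    ss = s[None, :]
    out_generic = {
        "SmallEmphasis": float((p / ss**2).sum() / ns),
        "LargeEmphasis": float((p * ss**2).sum() / ns),
        "GrayLevelNonUniformity": float((pg**2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / ns**2),
        "SizeNonUniformity": float((ps**2).sum() / ns),
        "SizeNonUniformityNormalized": float((ps**2).sum() / ns**2),
        "Percentage": float(ns / n_voxels),
        "GrayLevelVariance": float((pn * (ii - mu_i) ** 2).sum()),
        "SizeVariance": float((pn * (ss - mu_s) ** 2).sum()),
        "Entropy": float(-_plog2(pn).sum()),
        "LowGrayLevelEmphasis": float((p / ii**2).sum() / ns),
        "HighGrayLevelEmphasis": float((p * ii**2).sum() / ns),
        "SmallLowGrayLevelEmphasis": float((p / (ii**2 * ss**2)).sum() / ns),
        "SmallHighGrayLevelEmphasis": float((p * ii**2 / ss**2).sum() / ns),
        "LargeLowGrayLevelEmphasis": float((p * ss**2 / ii**2).sum() / ns),
        "LargeHighGrayLevelEmphasis": float((p * ii**2 * ss**2).sum() / ns),
    }
    return {fam_name: out_generic[generic] for generic, fam_name in names.items()}


_GLRLM_NAMES = {
    "SmallEmphasis": "ShortRunEmphasis",
    "LargeEmphasis": "LongRunEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "Percentage": "RunPercentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "SizeVariance": "RunVariance",
    "Entropy": "RunEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
    "SmallLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "ShortRunHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LongRunLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "SmallEmphasis": "SmallAreaEmphasis",
    "LargeEmphasis": "LargeAreaEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "Percentage": "ZonePercentage",
    "GrayLevelVariance": "GrayLevelVariance",
    "SizeVariance": "ZoneVariance",
    "Entropy": "ZoneEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
    "SmallLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(d: DiscretizedROI) -> dict[str, float]:
    """16 run-length features, averaged over the 13 unique directions."""
    per_angle = []
    n = d.n_voxels
    for off in ANGLES_13:
        p = run_length_matrix(d, off)
        per_angle.append(_gl_size_features(p, n, _GLRLM_NAMES))
    out = {k: float(np.mean([f[k] for f in per_angle])) for k in GLRLM_FEATURES}
    return out


# -------------------------------------------------------------------------- GLSZM
def size_zone_matrix(d: DiscretizedROI) -> np.ndarray:
    """Zone counts P(i, s): 26-connected same-level zones by size."""
    zones: list[tuple[int, int]] = []
    for lvl in np.unique(d.levels[d.mask]):
        lab, nlab = ndimage.label(d.levels == lvl, structure=_CONN26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(lvl), int(sz)) for sz in sizes)
    max_s = max(sz for _, sz in zones)
    p = np.zeros((d.ng, max_s), dtype=np.float64)
    for lvl, sz in zones:
        p[lvl - 1, sz - 1] += 1
    return p


def glszm_features(d: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features (orientation-free; each zone counted once)."""
    p = size_zone_matrix(d)
    out = _gl_size_features(p, d.n_voxels, _GLSZM_NAMES)
    return {k: out[k] for k in GLSZM_FEATURES}


# -------------------------------------------------------------------------- NGTDM
def ngtdm_table(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) from 26-neighborhood gray-tone differences.

    Returns ``(n, s, n_valid)`` where ``n[i-1]`` counts ROI voxels of level i
    that have at least one in-mask neighbor, ``s[i-1]`` sums |i - mean
    neighbor level| over those voxels, and ``n_valid`` is their total.
    """
    shape = d.levels.shape
    nb_sum = np.zeros(shape, dtype=np.float64)
    nb_cnt = np.zeros(shape, dtype=np.float64)
    lv = d.levels.astype(np.float64) * d.mask
    for off in ANGLES_13:
        src, dst = _pair_slices(shape, off)
        nb_sum[src] += lv[dst]
        nb_cnt[src] += d.mask[dst]
        nb_sum[dst] += lv[src]
        nb_cnt[dst] += d.mask[src]
    valid = d.mask & (nb_cnt > 0)
    abar = np.zeros(shape, dtype=np.float64)
    abar[valid] = nb_sum[valid] / nb_cnt[valid]
    n = np.zeros(d.ng, dtype=np.float64)
    s = np.zeros(d.ng, dtype=np.float64)
    for i in range(1, d.ng + 1):
        sel = valid & (d.levels == i)
        n[i - 1] = sel.sum()
        s[i - 1] = np.abs(i - abar[sel]).sum()
    return n, s, int(valid.sum())


def ngtdm_features(d: DiscretizedROI) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength (5 features)."""
    n, s, nvp = ngtdm_table(d)
    if nvp == 0:
        # isolated voxels only: no gray-tone differences anywhere
        out = {k: 0.0 for k in NGTDM_FEATURES}
        out["Coarseness"] = 1e6
        return out
    p = n / nvp
    i = np.arange(1, d.ng + 1, dtype=np.float64)
    present = p > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p[present], s[present]

    denom_coarse = float((p * s).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else 1e6

    if ngp > 1:
        dif2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float((pp[:, None] * pp[None, :] * dif2).sum()) / (ngp * (ngp - 1)) * (
            s.sum() / nvp
        )
        busy_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
        absdif = np.abs(ip[:, None] - ip[None, :])
        complexity = float(
            (absdif * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
             / (pp[:, None] + pp[None, :])).sum()
        ) / nvp
        s_tot = float(s.sum())
        strength = (
            float(((pp[:, None] + pp[None, :]) * dif2).sum()) / s_tot if s_tot > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    out = {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
    assert tuple(out) == NGTDM_FEATURES
    return out


# --------------------------------------------------------------------------- GLDM
def dependence_matrix(d: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence counts P(i, j): column j is the number of dependent neighbors.

    A 26-neighbor is dependent when |Δlevel| ≤ `alpha`.  Column index 0 means
    no dependent neighbors; the feature formulas use dependence size j + 1.
    """
    shape = d.levels.shape
    dep = np.zeros(shape, dtype=np.int64)
    for off in ANGLES_13:
        src, dst = _pair_slices(shape, off)
        ok = d.mask[src] & d.mask[dst] & (
            np.abs(d.levels[src] - d.levels[dst]) <= alpha
        )
        dep[src] += ok
        dep[dst] += ok
    lev = d.levels[d.mask] - 1
    dp = dep[d.mask]
    ncol = int(dp.max()) + 1
    return (
        np.bincount(lev * ncol + dp, minlength=d.ng * ncol)
        .reshape(d.ng, ncol)
        .astype(np.float64)
    )


def gldm_features(d: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    """14 gray-level dependence features (every ROI voxel contributes once)."""
    p = dependence_matrix(d, alpha=alpha)
    generic = _gl_size_features(p, d.n_voxels, {
        "SmallEmphasis": "SmallDependenceEmphasis",
        "LargeEmphasis": "LargeDependenceEmphasis",
        "GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "SizeNonUniformity": "DependenceNonUniformity",
        "SizeNonUniformityNormalized": "DependenceNonUniformityNormalized",
        "GrayLevelVariance": "GrayLevelVariance",
        "SizeVariance": "DependenceVariance",
        "Entropy": "DependenceEntropy",
        "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
        "SmallLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
        "SmallHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
        "LargeLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
        "LargeHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
    })
    return {k: generic[k] for k in GLDM_FEATURES}
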