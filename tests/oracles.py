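"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain nested loops straight from the published
definitions, deliberately sharing no code with the package's vectorized
implementations.  They are only feasible on tiny inputs.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS_13 = [
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]

OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _in(shape, v):
    return all(0 <= c < s for c, s in zip(v, shape))


def naive_glcm(levels, mask, offset, ng):
    """Symmetric co-occurrence counts by voxel-pair enumeration."""
    p = np.zeros((ng, ng))
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for x in range(mask.shape[2]):
                if not mask[z, y, x]:
                    continue
                for sign in (1, -1):
                    w = (z + sign * offset[0], y + sign * offset[1], x + sign * offset[2])
                    if _in(mask.shape, w) and mask[w]:
                        p[levels[z, y, x] - 1, levels[w] - 1] += 1
    return p


def naive_glrlm(levels, mask, offset, ng):
    """Run-length counts by explicit line walking."""
    runs = []
    visited = set()
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for x in range(mask.shape[2]):
                v = (z, y, x)
                if not mask[v] or v in visited:
                    continue
                back = (z - offset[0], y - offset[1], x - offset[2])
                if _in(mask.shape, back) and mask[back] and levels[back] == levels[v]:
                    continue  # not a run start
                length = 0
                cur = v
                while _in(mask.shape, cur) and mask[cur] and levels[cur] == levels[v]:
                    visited.add(cur)
                    length += 1
                    cur = (cur[0] + offset[0], cur[1] + offset[1], cur[2] + offset[2])
                runs.append((levels[v], length))
    max_r = max(r for _, r in runs)
    p = np.zeros((ng, max_r))
    for lvl, r in runs:
        p[lvl - 1, r - 1] += 1
    return p


def naive_glszm(levels, mask, ng):
    """Zone counts by flood fill with 26-connectivity."""
    zones = []
    seen = np.zeros_like(mask, dtype=bool)
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for x in range(mask.shape[2]):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                lvl = levels[z, y, x]
                stack, size = [(z, y, x)], 0
                seen[z, y, x] = True
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in OFFSETS_26:
                        w = (cz + dz, cy + dy, cx + dx)
                        if _in(mask.shape, w) and mask[w] and not seen[w] and levels[w] == lvl:
                            seen[w] = True
                            stack.append(w)
                zones.append((lvl, size))
    max_s = max(s for _, s in zones)
    p = np.zeros((ng, max_s))
    for lvl, s in zones:
        p[lvl - 1, s - 1] += 1
    return p


def naive_ngtdm(levels, mask, ng):
    """Per-level (n_i, s_i) and the count of voxels with >= 1 neighbor."""
    n = np.zeros(ng)
    s = np.zeros(ng)
    nvp = 0
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for x in range(mask.shape[2]):
                if not mask[z, y, x]:
                    continue
                nb = [
                    levels[z + dz, y + dy, x + dx]
                    for dz, dy, dx in OFFSETS_26
                    if _in(mask.shape, (z + dz, y + dy, x + dx)) and mask[z + dz, y + dy, x + dx]
                ]
                if not nb:
                    continue
                nvp += 1
                i = levels[z, y, x]
                n[i - 1] += 1
                s[i - 1] += abs(i - sum(nb) / len(nb))
    return n, s, nvp


def naive_gldm(levels, mask, ng, alpha=0):
    """Dependence counts: column j = number of dependent 26-neighbors."""
    entries = []
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for x in range(mask.shape[2]):
                if not mask[z, y, x]:
                    continue
                dep = 0
                for dz, dy, dx in OFFSETS_26:
                    w = (z + dz, y + dy, x + dx)
                    if _in(mask.shape, w) and mask[w] and abs(int(levels[w]) - int(levels[z, y, x])) <= alpha:
                        dep += 1
                entries.append((levels[z, y, x], dep))
    ncol = max(d for _, d in entries) + 1
    p = np.zeros((ng, ncol))
    for lvl, d in entries:
        p[lvl - 1, d] += 1
    return p


def naive_first_order(values, shift=1.0, bin_width=0.005, voxel_volume=1.0):
    """The 18 first-order statistics computed with literal formulas."""
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n

    def pct(q):
        return float(np.percentile(np.array(x), q))

    energy = sum((v + shift) ** 2 for v in x)
    p10, p90 = pct(10), pct(90)
    sub = [v for v in x if p10 <= v <= p90]
    submean = sum(sub) / len(sub)
    counts: dict[int, int] = {}
    for v in x:
        b = math.floor((v - x[0]) / bin_width)
        counts[b] = counts.get(b, 0) + 1
    probs = [c / n for c in counts.values()]
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": -sum(p * math.log2(p + 2.2e-16) for p in probs),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": pct(50),
        "InterquartileRange": pct(75) - pct(25),
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - submean) for v in sub) / len(sub),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": sum(p**2 for p in probs),
    }


def naive_majority_vote(member_masks, min_votes):
    """Per-voxel counting with explicit loops."""
    shape = member_masks[0].shape
    out = np.zeros(shape, dtype=np.uint8)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                votes = sum(int(m[z, y, x]) for m in member_masks)
                out[z, y, x] = 1 if votes >= min_votes else 0
    return out


def naive_dice(t, p):
    """Dice coefficient by voxel enumeration."""
    tp = st = sp = 0
    for a, b in zip(t.ravel().tolist(), p.ravel().tolist()):
        st += a
        sp += b
        tp += a * b
    if st + sp == 0:
        return 1.0
    return 2.0 * tp / (st + sp)


def naive_icc_2_1(x):
    """ICC(2,1) from first-principles two-way ANOVA sums of squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (row.mean() - grand) ** 2 for row in x)
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((v - grand) ** 2 for v in x.ravel())
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# --------------------------------------------------------------------------
# literal-formula feature computations (loops over matrix entries)
# --------------------------------------------------------------------------

def naive_glcm_features(p, ng):
    """All 24 co-occurrence features from one normalized matrix, by loops."""
    lv = list(range(1, ng + 1))
    px = [sum(p[i - 1][j - 1] for j in lv) for i in lv]
    py = [sum(p[i - 1][j - 1] for i in lv) for j in lv]
    mux = sum(i * px[i - 1] for i in lv)
    muy = sum(j * py[j - 1] for j in lv)
    sigx = math.sqrt(sum((i - mux) ** 2 * px[i - 1] for i in lv))
    sigy = math.sqrt(sum((j - muy) ** 2 * py[j - 1] for j in lv))
    p_diff = [sum(p[i - 1][j - 1] for i in lv for j in lv if abs(i - j) == k)
              for k in range(ng)]
    p_sum = [sum(p[i - 1][j - 1] for i in lv for j in lv if i + j == k)
             for k in range(2, 2 * ng + 1)]

    def log2z(v):
        return math.log2(v) if v > 0 else 0.0

    hxy = -sum(p[i - 1][j - 1] * log2z(p[i - 1][j - 1]) for i in lv for j in lv)
    hx = -sum(px[i - 1] * log2z(px[i - 1]) for i in lv)
    hy = -sum(py[j - 1] * log2z(py[j - 1]) for j in lv)
    hxy1 = -sum(p[i - 1][j - 1] * log2z(px[i - 1] * py[j - 1])
                for i in lv for j in lv if p[i - 1][j - 1] > 0)
    hxy2 = -sum(px[i - 1] * py[j - 1] * log2z(px[i - 1] * py[j - 1])
                for i in lv for j in lv) if ng > 1 else 0.0
    da = sum(k * p_diff[k] for k in range(ng))
    autoc = sum(i * j * p[i - 1][j - 1] for i in lv for j in lv)
    corr = (autoc - mux * muy) / (sigx * sigy) if sigx * sigy > 0 else 1.0
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))) if ng > 1 else 0.0

    if ng > 1:
        keep = [i for i in lv if px[i - 1] > 0]
        q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                q[a, b] = sum(
                    p[i - 1][k - 1] * p[j - 1][k - 1] / (px[i - 1] * py[k - 1])
                    for k in keep if py[k - 1] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, eig[-2])) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autoc,
        "ClusterProminence": sum((i + j - mux - muy) ** 4 * p[i - 1][j - 1]
                                 for i in lv for j in lv),
        "ClusterShade": sum((i + j - mux - muy) ** 3 * p[i - 1][j - 1]
                            for i in lv for j in lv),
        "ClusterTendency": sum((i + j - mux - muy) ** 2 * p[i - 1][j - 1]
                               for i in lv for j in lv),
        "Contrast": sum((i - j) ** 2 * p[i - 1][j - 1] for i in lv for j in lv),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * log2z(v) for v in p_diff),
        "DifferenceVariance": sum((k - da) ** 2 * p_diff[k] for k in range(ng)),
        "Id": sum(p_diff[k] / (1.0 + k) for k in range(ng)),
        "Idm": sum(p_diff[k] / (1.0 + k * k) for k in range(ng)),
        "Idmn": sum(p_diff[k] / (1.0 + (k / ng) ** 2) for k in range(ng)),
        "Idn": sum(p_diff[k] / (1.0 + k / ng) for k in range(ng)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(p_diff[k] / k**2 for k in range(1, ng)),
        "JointAverage": mux,
        "JointEnergy": sum(v * v for row in p for v in row),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(v for row in p for v in row),
        "SumAverage": sum(k * p_sum[k - 2] for k in range(2, 2 * ng + 1)),
        "SumEntropy": -sum(v * log2z(v) for v in p_sum),
        "SumSquares": sum((i - mux) ** 2 * px[i - 1] for i in lv),
    }


def naive_glcm_features_averaged(levels, mask, ng):
    per = []
    for off in OFFSETS_13:
        c = naive_glcm(levels, mask, off, ng)
        tot = c.sum()
        if tot > 0:
            per.append(naive_glcm_features((c / tot).tolist(), ng))
    return {k: sum(f[k] for f in per) / len(per) for k in per[0]}


def naive_size_family(p, n_voxels):
    """Generic gray-level × size-index features by explicit loops."""
    ng, ns_cols = p.shape
    ns = p.sum()
    pg = [sum(p[i, s] for s in range(ns_cols)) for i in range(ng)]
    psz = [sum(p[i, s] for i in range(ng)) for s in range(ns_cols)]
    mu_i = sum((i + 1) * pg[i] for i in range(ng)) / ns
    mu_s = sum((s + 1) * psz[s] for s in range(ns_cols)) / ns

    def log2z(v):
        return math.log2(v) if v > 0 else 0.0

    return {
        "SmallEmphasis": sum(p[i, s] / (s + 1) ** 2 for i in range(ng)
                             for s in range(ns_cols)) / ns,
        "LargeEmphasis": sum(p[i, s] * (s + 1) ** 2 for i in range(ng)
                             for s in range(ns_cols)) / ns,
        "GrayLevelNonUniformity": sum(g * g for g in pg) / ns,
        "GrayLevelNonUniformityNormalized": sum(g * g for g in pg) / ns**2,
        "SizeNonUniformity": sum(z * z for z in psz) / ns,
        "SizeNonUniformityNormalized": sum(z * z for z in psz) / ns**2,
        "Percentage": ns / n_voxels,
        "GrayLevelVariance": sum(p[i, s] / ns * (i + 1 - mu_i) ** 2
                                 for i in range(ng) for s in range(ns_cols)),
        "SizeVariance": sum(p[i, s] / ns * (s + 1 - mu_s) ** 2
                            for i in range(ng) for s in range(ns_cols)),
        "Entropy": -sum((p[i, s] / ns) * log2z(p[i, s] / ns)
                        for i in range(ng) for s in range(ns_cols)),
        "LowGrayLevelEmphasis": sum(p[i, s] / (i + 1) ** 2 for i in range(ng)
                                    for s in range(ns_cols)) / ns,
        "HighGrayLevelEmphasis": sum(p[i, s] * (i + 1) ** 2 for i in range(ng)
                                     for s in range(ns_cols)) / ns,
        "SmallLowGrayLevelEmphasis": sum(p[i, s] / ((i + 1) ** 2 * (s + 1) ** 2)
                                         for i in range(ng) for s in range(ns_cols)) / ns,
        "SmallHighGrayLevelEmphasis": sum(p[i, s] * (i + 1) ** 2 / (s + 1) ** 2
                                          for i in range(ng) for s in range(ns_cols)) / ns,
        "LargeLowGrayLevelEmphasis": sum(p[i, s] * (s + 1) ** 2 / (i + 1) ** 2
                                         for i in range(ng) for s in range(ns_cols)) / ns,
        "LargeHighGrayLevelEmphasis": sum(p[i, s] * (i + 1) ** 2 * (s + 1) ** 2
                                          for i in range(ng) for s in range(ns_cols)) / ns,
    }


def naive_ngtdm_features(levels, mask, ng):
    n, s, nvp = naive_ngtdm(levels, mask, ng)
    p = [v / nvp for v in n]
    present = [i for i in range(1, ng + 1) if p[i - 1] > 0]
    ngp = len(present)
    denom = sum(p[i - 1] * s[i - 1] for i in present)
    coarse = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[i - 1] * p[j - 1] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (sum(s) / nvp)
        busy_den = sum(abs(i * p[i - 1] - j * p[j - 1]) for i in present for j in present)
        busy = denom / busy_den if busy_den > 0 else 0.0
        cplx = sum(
            abs(i - j) * (p[i - 1] * s[i - 1] + p[j - 1] * s[j - 1]) / (p[i - 1] + p[j - 1])
            for i in present for j in present
        ) / nvp
        stot = sum(s)
        strength = (
            sum((p[i - 1] + p[j - 1]) * (i - j) ** 2 for i in present for j in present) / stot
            if stot > 0 else 0.0
        )
    else:
        contrast = busy = cplx = strength = 0.0
    return {"Busyness": busy, "Coarseness": coarse, "Complexity": cplx,
            "Contrast": contrast, "Strength": strength}


_GLRLM_MAP = {
    "SmallEmphasis": "ShortRunEmphasis", "LargeEmphasis": "LongRunEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "Percentage": "RunPercentage", "GrayLevelVariance": "GrayLevelVariance",
    "SizeVariance": "RunVariance", "Entropy": "RunEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
    "SmallLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "ShortRunHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LongRunLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_MAP = {
    "SmallEmphasis": "SmallAreaEmphasis", "LargeEmphasis": "LargeAreaEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "Percentage": "ZonePercentage", "GrayLevelVariance": "GrayLevelVariance",
    "SizeVariance": "ZoneVariance", "Entropy": "ZoneEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
    "SmallLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
}

_GLDM_MAP = {
    "SmallEmphasis": "SmallDependenceEmphasis", "LargeEmphasis": "LargeDependenceEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "SizeNonUniformity": "DependenceNonUniformity",
    "SizeNonUniformityNormalized": "DependenceNonUniformityNormalized",
    "GrayLevelVariance": "GrayLevelVariance", "SizeVariance": "DependenceVariance",
    "Entropy": "DependenceEntropy",
    "LowGrayLevelEmphasis": "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis": "HighGrayLevelEmphasis",
    "SmallLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
    "SmallHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
    "LargeLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
    "LargeHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
}


def naive_shape_subset(mask, spacing):
    """Voxel-count and covariance-eigenvalue shape features by loops."""
    coords = [
        (z * spacing[0], y * spacing[1], x * spacing[2])
        for z in range(mask.shape[0])
        for y in range(mask.shape[1])
        for x in range(mask.shape[2])
        if mask[z, y, x]
    ]
    n = len(coords)
    out = {"VoxelVolume": n * spacing[0] * spacing[1] * spacing[2]}
    if n > 1:
        means = [sum(c[a] for c in coords) / n for a in range(3)]
        cov = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                cov[a, b] = sum((c[a] - means[a]) * (c[b] - means[b]) for c in coords) / (n - 1)
        eig = sorted(np.linalg.eigvalsh(cov), reverse=True)
        eig = [max(e, 0.0) for e in eig]
    else:
        eig = [0.0, 0.0, 0.0]
    out["MajorAxisLength"] = 4.0 * math.sqrt(eig[0])
    out["MinorAxisLength"] = 4.0 * math.sqrt(eig[1])
    out["LeastAxisLength"] = 4.0 * math.sqrt(eig[2])
    out["Elongation"] = math.sqrt(eig[1] / eig[0]) if eig[0] > 0 else 0.0
    out["Flatness"] = math.sqrt(eig[2] / eig[0]) if eig[0] > 0 else 0.0
    return out


def reference_features(vol, mask, d):
    """Independent loop-based values for every feature that has a closed,
    mesh-free definition: 18 first-order + 6 shape + all 75 texture features.
    Keys use the package's full names; mesh-based shape features are omitted
    (they are validated against analytic solids instead)."""
    out = {}
    vals = vol[mask.astype(bool)]
    for k, v in naive_first_order(vals, shift=1.0, bin_width=0.005, voxel_volume=1.0).items():
        out[f"firstorder_{k}"] = v
    for k, v in naive_shape_subset(mask.astype(bool), (1.0, 1.0, 1.0)).items():
        out[f"shape_{k}"] = v
    for k, v in naive_glcm_features_averaged(d.levels, d.mask, d.ng).items():
        out[f"glcm_{k}"] = v
    rl = []
    for off in OFFSETS_13:
        p = naive_glrlm(d.levels, d.mask, off, d.ng)
        rl.append(naive_size_family(p, int(d.mask.sum())))
    for gk, fk in _GLRLM_MAP.items():
        out[f"glrlm_{fk}"] = sum(f[gk] for f in rl) / len(rl)
    sz = naive_size_family(naive_glszm(d.levels, d.mask, d.ng), int(d.mask.sum()))
    for gk, fk in _GLSZM_MAP.items():
        out[f"glszm_{fk}"] = sz[gk]
    for k, v in naive_ngtdm_features(d.levels, d.mask, d.ng).items():
        out[f"ngtdm_{k}"] = v
    dm = naive_size_family(naive_gldm(d.levels, d.mask, d.ng), int(d.mask.sum()))
    for gk, fk in _GLDM_MAP.items():
        out[f"gldm_{fk}"] = dm[gk]
    return out
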