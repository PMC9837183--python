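"""First-order (intensity-histogram) features of an ROI: 18 statistics.

The voxel-array shift c (default 1) is added to intensities only where the
reference definitions apply it: Energy, TotalEnergy and RootMeanSquared.
Entropy and Uniformity use the same fixed-bin-width discretization as the
texture families.
"""

from __future__ import annotations

import numpy as np

from .manifest import FIRSTORDER_FEATURES

__all__ = ["first_order_features"]

_LOG_EPS = 2.2e-16


def first_order_features(
    roi_values: np.ndarray,
    shift: float = 1.0,
    bin_width: float = 0.005,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """The 18 first-order statistics of the ROI intensity distribution.

    Parameters
    ----------
    roi_values : 1D array of in-mask intensities (>= 1 voxel).
    shift : voxel-array shift c applied to energy-type features.
    bin_width : histogram bin width for Entropy/Uniformity.
    voxel_volume : physical voxel volume in mm³ (for TotalEnergy).
    """
    x = np.asarray(roi_values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    p10, p25, p50, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))

    energy = float(((x + shift) ** 2).sum())
    sub = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0

    # discretized probabilities for Entropy / Uniformity
    lev = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(lev).astype(np.float64)
    p = p[p > 0] / n

    out = {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-(p * np.log2(p + _LOG_EPS)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": float((p**2).sum()),
    }
    assert tuple(out) == FIRSTORDER_FEATURES
    return out
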