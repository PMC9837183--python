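"""Fixed-bin-width gray-level discretization of an ROI.

Continuous ADC values are mapped to integer gray levels with bins of width W
anchored at the ROI minimum:

    level(v) = floor((v - min) / W) + 1,        1 <= level <= Ng.

With ADC stored in 10^-3 mm²/s and the default bin width 0.005, a typical
tumor ROI spans on the order of a hundred gray levels.  Anchoring at the
minimum makes all texture features invariant to adding a constant to the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizedROI", "discretize"]


@dataclass
class DiscretizedROI:
    """Gray-level grid over the ROI bounding box.

    ``levels`` is an integer array over the bounding box with 0 outside the
    ROI and levels 1..Ng inside; ``roi_values`` are the original intensities
    of the in-mask voxels (flattened in C order).
    """

    levels: np.ndarray
    mask: np.ndarray
    roi_values: np.ndarray
    ng: int
    spacing: tuple[float, float, float]
    bin_width: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def discretize(adc_volume: np.ndarray, mask: np.ndarray, bin_width: float = 0.005,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> DiscretizedROI:
    """Discretize the masked voxels of a volume into fixed-width gray levels.

    The volume and mask are cropped to the mask's bounding box.  Raises on an
    empty mask or non-positive bin width.
    """
    adc_volume = np.asarray(adc_volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if adc_volume.shape != mask.shape:
        raise ValueError(f"volume {adc_volume.shape} and mask {mask.shape} shapes differ")
    if not mask.any():
        raise ValueError("empty mask: nothing to discretize")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    nz = np.nonzero(mask)
    bbox = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    sub = adc_volume[bbox]
    msk = mask[bbox]
    vals = sub[msk]
    levels = np.zeros(sub.shape, dtype=np.int32)
    # tiny offset guards against quotients like 0.005/0.005 landing just
    # below an integer in binary floating point
    levels[msk] = np.floor((sub[msk] - vals.min()) / bin_width + 1e-9).astype(np.int64) + 1
    ng = int(levels.max())
    return DiscretizedROI(
        levels=levels,
        mask=msk,
        roi_values=vals,
        ng=ng,
        spacing=tuple(float(s) for s in spacing),
        bin_width=float(bin_width),
    )
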