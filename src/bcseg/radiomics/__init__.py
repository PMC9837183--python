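"""From-scratch radiomics feature extraction on ADC maps (107 features).

The extractor mirrors the widely used reference taxonomy: 18 first-order
statistics, 14 shape descriptors, and 75 high-order texture features (GLCM 24,
GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14), computed in 3D with direction
averaging, gray levels discretized at a fixed bin width of 0.005 (ADC in
10^-3 mm²/s) anchored at the ROI minimum, and a voxel-array shift of 1
applied to the energy-type first-order features.

>>> from bcseg.radiomics import extract_all, RadiomicsConfig
>>> fv = extract_all(adc, mask, spacing=(3.0, 1.5, 1.5))
>>> len(fv)
107
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discretize import DiscretizedROI, discretize
from .firstorder import first_order_features
from .manifest import ALL_FEATURE_NAMES, FAMILIES, FAMILY_SIZES, N_FEATURES, family_of
from .shape import shape_features
from .texture import (
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "RadiomicsConfig",
    "FeatureVector",
    "DiscretizedROI",
    "discretize",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "extract_all",
    "ALL_FEATURE_NAMES",
    "FAMILIES",
    "FAMILY_SIZES",
    "N_FEATURES",
]


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction settings (reference defaults except bin width and shift)."""

    bin_width: float = 0.005
    voxel_array_shift: float = 1.0
    glcm_distance: int = 1
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.glcm_distance != 1:
            raise ValueError("only distance-1 texture matrices are supported")


@dataclass
class FeatureVector:
    """The 107 named features of one ROI on one ADC map."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [n for n in ALL_FEATURE_NAMES if n not in self.values]
        extra = [n for n in self.values if n not in ALL_FEATURE_NAMES]
        if missing or extra:
            raise ValueError(f"feature set mismatch: missing={missing[:3]} extra={extra[:3]}")
        self.values = {n: float(self.values[n]) for n in ALL_FEATURE_NAMES}

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def by_family(self, family: str) -> dict[str, float]:
        return {f"{family}_{n}": self.values[f"{family}_{n}"] for n in FAMILIES[family]}


def extract_all(
    adc_volume: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    config: RadiomicsConfig | None = None,
) -> FeatureVector:
    """Extract all 107 features of one ROI.

    `mask` may be a binary array or a :class:`~bcseg.phantom.SegmentationMask`.
    Deterministic; raises on an empty mask.  Degenerate ROIs (constant
    intensity, single voxel) follow the conventions documented in the
    submodules and still yield 107 finite values.
    """
    config = config or RadiomicsConfig()
    mask_arr = getattr(mask, "voxels", mask)
    d = discretize(adc_volume, mask_arr, bin_width=config.bin_width, spacing=spacing)
    voxel_volume = float(np.prod(spacing))

    values: dict[str, float] = {}
    fo = first_order_features(
        d.roi_values, shift=config.voxel_array_shift,
        bin_width=config.bin_width, voxel_volume=voxel_volume,
    )
    values.update({f"firstorder_{k}": v for k, v in fo.items()})
    values.update({f"shape_{k}": v for k, v in shape_features(mask_arr, spacing).items()})
    values.update({f"glcm_{k}": v for k, v in glcm_features(d, config.glcm_distance).items()})
    values.update({f"glrlm_{k}": v for k, v in glrlm_features(d).items()})
    values.update({f"glszm_{k}": v for k, v in glszm_features(d).items()})
    values.update({f"ngtdm_{k}": v for k, v in ngtdm_features(d).items()})
    values.update({f"gldm_{k}": v for k, v in gldm_features(d, config.gldm_alpha).items()})
    return FeatureVector(values=values)
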