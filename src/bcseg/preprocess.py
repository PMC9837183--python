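"""Raw volumes -> normalized fixed-grid model inputs.

Axial slices are resized to a square model grid (128×128 by default; clinical
DWI matrices run 110-192 × 80-128) and signal intensities are normalized per
sequence and per patient volume as

    normalized_SI = (SI - mean_SI) / (12 * SD_SI)

where mean_SI and SD_SI are the mean and standard deviation of the volume.
The network consumes three channels: either one sequence replicated three
times (single-sequence modes ``b0``, ``b1000``, ``adc``) or the three
sequences stacked in the order (b0, b1000, adc) (``multi`` mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .phantom import PatientCase

__all__ = [
    "NormalizationStats",
    "ChannelStack",
    "CHANNEL_MODES",
    "resize_to_model_grid",
    "normalize_intensity",
    "denormalize_intensity",
    "assemble_channels",
]

CHANNEL_MODES = ("b0", "b1000", "adc", "multi")


@dataclass(frozen=True)
class NormalizationStats:
    """Volume statistics needed to invert the intensity normalization."""

    mean_si: float
    sd_si: float
    divisor_factor: float = 12.0

    def __post_init__(self) -> None:
        if self.sd_si <= 0:
            raise ValueError("SD_SI must be positive")
        if self.divisor_factor <= 0:
            raise ValueError("divisor_factor must be positive")


@dataclass
class ChannelStack:
    """Per-slice model input of shape (n_slices, H, W, 3)."""

    slices: np.ndarray
    channel_mode: str
    case_id: str

    def __post_init__(self) -> None:
        if self.slices.ndim != 4 or self.slices.shape[-1] != 3:
            raise ValueError(f"expected (n, H, W, 3) array, got {self.slices.shape}")
        if self.channel_mode not in CHANNEL_MODES:
            raise ValueError(f"channel_mode must be one of {CHANNEL_MODES}")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def grid_size(self) -> int:
        return self.slices.shape[1]


def resize_to_model_grid(image: np.ndarray, is_mask: bool = False, size: int = 128) -> np.ndarray:
    """Resize one axial slice to `size`×`size`.

    Intensity slices are interpolated bilinearly (with anti-aliasing when
    shrinking); masks use nearest-neighbor so the output stays binary.
    Non-square inputs are stretched anisotropically — no padding.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {image.shape}")
    if min(image.shape) < 8:
        raise ValueError(f"degenerate input slice of shape {image.shape}")
    if image.shape == (size, size):
        return image.astype(np.float32) if not is_mask else image
    if is_mask:
        out = _sk_resize(
            image.astype(np.float32), (size, size), order=0, preserve_range=True,
            anti_aliasing=False,
        )
        return (out > 0.5).astype(image.dtype)
    shrinking = image.shape[0] > size or image.shape[1] > size
    return _sk_resize(
        image.astype(np.float32), (size, size), order=1, preserve_range=True,
        anti_aliasing=shrinking,
    ).astype(np.float32)


def normalize_intensity(
    volume: np.ndarray, divisor_factor: float = 12.0
) -> tuple[np.ndarray, NormalizationStats]:
    """Normalize a signal-intensity volume to (SI - mean) / (12·SD).

    The statistics are taken over the whole per-patient, per-sequence volume,
    so inter-slice contrast is preserved.  Raises on a constant volume (zero
    SD) instead of emitting NaNs.
    """
    volume = np.asarray(volume, dtype=np.float64)
    mean = float(volume.mean())
    sd = float(volume.std())
    if sd == 0.0:
        raise ZeroDivisionError(
            "cannot normalize a constant volume: SD of the signal intensity is zero"
        )
    stats = NormalizationStats(mean_si=mean, sd_si=sd, divisor_factor=divisor_factor)
    return ((volume - mean) / (divisor_factor * sd)), stats


def denormalize_intensity(volume: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Invert :func:`normalize_intensity` given its statistics."""
    return np.asarray(volume, dtype=np.float64) * (stats.divisor_factor * stats.sd_si) + stats.mean_si


def assemble_channels(case: PatientCase, channel_mode: str, size: int = 128) -> ChannelStack:
    """Build the per-slice three-channel model input for one case.

    ``multi`` stacks the independently-normalized (b0, b1000, adc) volumes in
    that order; a single-sequence mode replicates the chosen normalized
    sequence into all three channels.
    """
    if channel_mode not in CHANNEL_MODES:
        raise ValueError(f"channel_mode must be one of {CHANNEL_MODES}, got {channel_mode!r}")

    sequences = {"b0": case.b0, "b1000": case.b1000, "adc": case.adc}
    for name, vol in sequences.items():
        if vol is None:
            raise ValueError(f"case {case.case_id} is missing the {name} sequence")

    def norm_resized(vol: np.ndarray) -> np.ndarray:
        normed, _ = normalize_intensity(vol)
        return np.stack(
            [resize_to_model_grid(sl, size=size) for sl in normed.astype(np.float32)]
        )

    if channel_mode == "multi":
        chans = [norm_resized(sequences[k]) for k in ("b0", "b1000", "adc")]
    else:
        one = norm_resized(sequences[channel_mode])
        chans = [one, one, one]
    return ChannelStack(
        slices=np.stack(chans, axis=-1).astype(np.float32),
        channel_mode=channel_mode,
        case_id=case.case_id,
    )
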