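"""Synthetic bladder DWI phantoms with known ground truth.

Each case emulates a clinical bladder-MRI study: aligned b=0 and b=1000 s/mm²
diffusion-weighted volumes plus an apparent-diffusion-coefficient (ADC) map,
all generated from a mono-exponential decay model

    S(b) = S0 * exp(-b * ADC),

with a urine-filled bladder lumen (high S0, high ADC), a muscular bladder wall,
and one or more tumors growing from the wall into the lumen (high b1000 signal,
restricted diffusion / low ADC).  ADC values are stored in units of
10^-3 mm²/s (clinical scale, roughly 0.5-3.0), so at b = 1000 the decay
exponent is simply ``-adc``.

The module also provides controlled mask perturbations used to emulate the
disagreement between manual and automatic tumor delineations in the
radiomics-reproducibility experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "TissueParams",
    "PhantomTissues",
    "SegmentationMask",
    "PatientCase",
    "DEFAULT_TISSUES",
    "synthesize_case",
    "generate_cohort",
    "perturb_mask",
    "calibrate_perturbation",
]

#: structuring element for 26-connectivity in 3D
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class TissueParams:
    """Signal model of one tissue compartment.

    Parameters
    ----------
    s0_mean : float
        Mean b=0 signal intensity (arbitrary units), must be positive.
    adc_mean : float
        Mean ADC in 10^-3 mm²/s, must be positive.
    s0_sd, adc_sd : float
        Within-tissue voxelwise variability (Gaussian).
    """

    s0_mean: float
    adc_mean: float
    s0_sd: float = 0.0
    adc_sd: float = 0.0
    #: correlation length (voxels) of the within-tissue variability field;
    #: 0 = white noise.  Real lesions differ in texture scale, not just level.
    texture_corr_vox: float = 0.0

    def __post_init__(self) -> None:
        if self.s0_mean <= 0 or self.adc_mean <= 0:
            raise ValueError(
                f"tissue parameters must be positive, got s0_mean={self.s0_mean}, "
                f"adc_mean={self.adc_mean}"
            )
        if self.s0_sd < 0 or self.adc_sd < 0:
            raise ValueError("tissue variability (sd) must be non-negative")

    @property
    def b1000_mean(self) -> float:
        """Noiseless mean signal at b = 1000 s/mm² (ADC in 10^-3 mm²/s)."""
        return self.s0_mean * float(np.exp(-self.adc_mean))


@dataclass(frozen=True)
class PhantomTissues:
    """The four phantom compartments (plus optional intraluminal decoys)."""

    background: TissueParams = TissueParams(30.0, 2.0, 5.0, 0.10)
    wall: TissueParams = TissueParams(200.0, 1.6, 15.0, 0.12)
    urine: TissueParams = TissueParams(1000.0, 3.0, 30.0, 0.08)
    # tumor ADC heterogeneity ~0.18e-3 mm²/s: an ROI spans a few hundred
    # gray levels at the 0.005 bin width, as intended for that setting
    tumor: TissueParams = TissueParams(450.0, 0.9, 25.0, 0.18)

    def __post_init__(self) -> None:
        if not self.tumor.adc_mean < self.urine.adc_mean:
            raise ValueError("tumor ADC must be below urine ADC (restricted diffusion)")
        if not self.tumor.b1000_mean > self.urine.b1000_mean:
            raise ValueError("tumor must be brighter than urine at b=1000 in the noiseless limit")


DEFAULT_TISSUES = PhantomTissues()


@dataclass
class SegmentationMask:
    """Binary 3D voxel labeling; may hold several disconnected tumors."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        vals = np.unique(self.voxels)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(f"mask must be binary, found values {vals}")
        self.voxels = self.voxels.astype(np.uint8)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing))

    def n_components(self) -> int:
        """Number of 26-connected components."""
        _, n = ndimage.label(self.voxels, structure=_CONN26)
        return int(n)

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())


@dataclass
class PatientCase:
    """Aligned b0/b1000/ADC volumes, reference tumor mask and metadata."""

    case_id: str
    b0: np.ndarray
    b1000: np.ndarray
    adc: np.ndarray
    spacing: tuple[float, float, float]
    reference_mask: SegmentationMask
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.b0.shape, self.b1000.shape, self.adc.shape, self.reference_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"volumes and mask must share one shape, got {shapes}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if np.any(self.adc < 0):
            raise ValueError("ADC values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.b0.shape

    @property
    def n_slices(self) -> int:
        return self.b0.shape[0]


def _ellipsoid(shape, center, semiaxes, spacing) -> np.ndarray:
    """Boolean ellipsoid in physical (mm) coordinates."""
    zz, yy, xx = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    return (
        ((zz - center[0]) / semiaxes[0]) ** 2
        + ((yy - center[1]) / semiaxes[1]) ** 2
        + ((xx - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _rician(clean: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI (Rician) noise on a noiseless signal."""
    if sigma == 0:
        return clean.copy()
    re = clean + rng.normal(0.0, sigma, clean.shape)
    im = rng.normal(0.0, sigma, clean.shape)
    return np.sqrt(re**2 + im**2)


def _jitter_field(shape, sd, corr_vox, rng):
    """Zero-mean variability field with the requested SD and correlation length."""
    if sd == 0:
        return None
    f = rng.standard_normal(shape)
    if corr_vox > 0:
        f = ndimage.gaussian_filter(f, sigma=corr_vox)
        f /= f.std()
    return sd * f


def _tissue_fields(labels, tissue_list, rng):
    """Voxelwise S0 and ADC fields from per-compartment Gaussian variability."""
    s0 = np.zeros(labels.shape, dtype=np.float64)
    adc = np.zeros(labels.shape, dtype=np.float64)
    for lab, t in enumerate(tissue_list):
        m = labels == lab
        if not m.any():
            continue
        s0[m] = t.s0_mean
        adc[m] = t.adc_mean
        fs = _jitter_field(labels.shape, t.s0_sd, t.texture_corr_vox, rng)
        if fs is not None:
            s0[m] += fs[m]
        fa = _jitter_field(labels.shape, t.adc_sd, t.texture_corr_vox, rng)
        if fa is not None:
            adc[m] += fa[m]
    np.clip(s0, 1e-3, None, out=s0)
    np.clip(adc, 1e-6, None, out=adc)
    return s0, adc


def _decoy_tissues(tissues: PhantomTissues) -> list[TissueParams]:
    """Intraluminal decoy lesions, each matching the tumor in exactly one channel.

    Decoy 0 matches the tumor's b1000 signal (but high ADC), decoy 1 its b0
    signal, decoy 2 its ADC.  A segmenter fed a single channel cannot separate
    the tumor from the corresponding decoy; the joint (b0, b1000, ADC) profile
    is unique to the tumor.
    """
    t = tissues.tumor
    adc_hi = 0.5 * (tissues.urine.adc_mean + t.adc_mean) + 0.6  # clearly non-restricted
    return [
        TissueParams(t.s0_mean * float(np.exp(adc_hi - t.adc_mean)), adc_hi, t.s0_sd, t.adc_sd),
        TissueParams(t.s0_mean, adc_hi, t.s0_sd, t.adc_sd),
        TissueParams(t.s0_mean * 0.28, t.adc_mean, t.s0_sd, t.adc_sd),
    ]


#: physical field of view in mm (slab, rows, cols); spacing defaults derive from it
FOV_MM = (48.0, 192.0, 192.0)


def synthesize_case(
    shape: tuple[int, int, int] = (16, 128, 128),
    tissues: PhantomTissues = DEFAULT_TISSUES,
    noise_sigma: float = 25.0,
    n_tumors: int = 1,
    seed: int = 0,
    spacing: tuple[float, float, float] | None = None,
    tumor_radius_frac: float = 0.45,
    noise_model: str = "rician",
    decoys: bool = False,
    psf_sigma_mm: float = 0.0,
    case_id: str | None = None,
    metadata: dict | None = None,
) -> PatientCase:
    """Generate one synthetic patient case.

    Parameters
    ----------
    shape : (n_slices, n_rows, n_cols)
        In-plane dimensions must lie in 64..192.
    tissues : PhantomTissues
        Signal parameters per compartment.
    noise_sigma : float
        Acquisition noise level (signal units) applied to b0 and b1000.  The
        default gives a tumor/urine contrast-to-noise ratio of about 5 at
        b = 1000.
    n_tumors : int
        Number of disconnected tumors attached to the bladder wall.
    spacing : (dz, dy, dx) in mm, or None
        Defaults to ``FOV_MM / shape`` so any grid size samples the same
        physical anatomy.
    tumor_radius_frac : float
        Tumor semi-axes as a fraction of the lumen semi-axes; must be < 1
        (a tumor cannot exceed the lumen).
    noise_model : {"rician", "gaussian"}
        Magnitude-MRI Rician noise by default.
    decoys : bool
        Add three intraluminal decoy lesions, each matching the tumor signal
        in exactly one of the three channels (see :func:`_decoy_tissues`).
    psf_sigma_mm : float
        Gaussian point-spread blur (standard deviation, mm) applied to the
        clean S0/ADC fields, emulating the effective resolution of
        echo-planar DWI (partial-volume averaging at tissue boundaries).
        Converted to voxels per axis via the spacing, so the physical blur
        is grid-independent.  Zero (default) keeps the decay law exact.

    Notes
    -----
    The ADC map is recomputed from the *noiseless* signals as
    ``ln(b0/b1000) / b`` with b = 1000 s/mm² (stored in 10^-3 mm²/s), so for
    every voxel it equals the simulated tissue ADC exactly.
    """
    if len(shape) != 3:
        raise ValueError("shape must be 3D (slices, rows, cols)")
    if not all(64 <= n <= 192 for n in shape[1:]):
        raise ValueError(f"in-plane dimensions must be within 64..192, got {shape[1:]}")
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if not 0 < tumor_radius_frac < 1.0:
        raise ValueError(
            f"tumor_radius_frac={tumor_radius_frac}: tumor must be strictly smaller "
            "than the bladder lumen"
        )
    if noise_model not in ("rician", "gaussian"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    if spacing is None:
        spacing = tuple(f / n for f, n in zip(FOV_MM, shape))

    rng = np.random.default_rng(seed)
    extent = np.array(shape) * np.array(spacing)  # physical mm extent
    center = extent / 2.0 + rng.uniform(-0.04, 0.04, 3) * extent

    # bladder: single outer ellipsoid; lumen = inner ellipsoid; wall = shell
    outer_ax = extent * rng.uniform(0.27, 0.33, 3)
    wall_mm = rng.uniform(2.5, 4.0)
    inner_ax = np.maximum(outer_ax - wall_mm, outer_ax * 0.5)
    outer = _ellipsoid(shape, center, outer_ax, spacing)
    lumen = _ellipsoid(shape, center, inner_ax, spacing)

    # tumors grow from the wall into the lumen at well-separated angles
    n_sites = n_tumors + (3 if decoys else 0)
    base = rng.uniform(0, 2 * np.pi)
    angles = base + np.arange(n_sites) * (2 * np.pi / n_sites)
    rng.shuffle(angles)
    tumor_mask = np.zeros(shape, dtype=bool)
    decoy_masks = []
    for i, ang in enumerate(angles):
        # site on the lumen boundary in the central slice plane
        site = center + np.array(
            [
                rng.uniform(-0.3, 0.3) * inner_ax[0],
                0.85 * inner_ax[1] * np.sin(ang),
                0.85 * inner_ax[2] * np.cos(ang),
            ]
        )
        ax = tumor_radius_frac * inner_ax * rng.uniform(0.8, 1.2, 3)
        blob = _ellipsoid(shape, site, ax, spacing) & lumen
        if i < n_tumors:
            tumor_mask |= blob
        else:
            decoy_masks.append(blob & ~tumor_mask)

    n_found = ndimage.label(tumor_mask, structure=_CONN26)[1]
    if n_found != n_tumors:
        raise ValueError(
            f"could not place {n_tumors} disconnected tumors of relative radius "
            f"{tumor_radius_frac} in the lumen (got {n_found} components); "
            "reduce the tumor size or count"
        )

    # compartment labels: 0 background, 1 wall, 2 urine, 3 tumor, 4.. decoys
    labels = np.zeros(shape, dtype=np.int8)
    labels[outer] = 1
    labels[lumen] = 2
    for k, dm in enumerate(decoy_masks):
        labels[dm] = 4 + k
    labels[tumor_mask] = 3

    tissue_list = [tissues.background, tissues.wall, tissues.urine, tissues.tumor]
    if decoys:
        tissue_list += _decoy_tissues(tissues)
    s0_field, adc_field = _tissue_fields(labels, tissue_list, rng)
    if psf_sigma_mm > 0:
        sig_vox = [psf_sigma_mm / s for s in spacing]
        s0_field = ndimage.gaussian_filter(s0_field, sigma=sig_vox)
        adc_field = ndimage.gaussian_filter(adc_field, sigma=sig_vox)

    b0_clean = s0_field
    b1000_clean = s0_field * np.exp(-adc_field)  # b=1000, ADC in 1e-3 mm²/s
    if noise_model == "rician":
        b0 = _rician(b0_clean, noise_sigma, rng)
        b1000 = _rician(b1000_clean, noise_sigma, rng)
    else:
        b0 = b0_clean + rng.normal(0.0, noise_sigma, shape)
        b1000 = b1000_clean + rng.normal(0.0, noise_sigma, shape)
    # scanner-style ADC: mono-exponential fit on the noiseless decay
    adc_map = np.log(b0_clean / b1000_clean)

    meta = {"adc_units": "1e-3 mm^2/s"}
    if metadata:
        meta.update(metadata)
    return PatientCase(
        case_id=case_id or f"phantom-{seed:08d}",
        b0=b0.astype(np.float32),
        b1000=b1000.astype(np.float32),
        adc=np.clip(adc_map, 0, None).astype(np.float32),
        spacing=tuple(spacing),
        reference_mask=SegmentationMask(tumor_mask.astype(np.uint8), tuple(spacing)),
        metadata=meta,
    )


def generate_cohort(
    n_patients: int,
    seed: int = 0,
    shape: tuple[int, int, int] = (16, 128, 128),
    tissues: PhantomTissues = DEFAULT_TISSUES,
    noise_sigma: float = 25.0,
    spacing: tuple[float, float, float] | None = None,
    decoys: bool = False,
    multi_tumor_prob: float = 0.2,
    psf_sigma_mm: float = 2.25,
    patient_variability: float = 1.0,
) -> list[PatientCase]:
    """Generate a cohort of unique cases with per-case seeds derived from `seed`.

    Tumor count is 1 or (with probability `multi_tumor_prob`) 2; tumor size is
    drawn per case.  Ages emulate the study population (mean ≈ 73.6 y, range
    47-94); about 36% of cases are flagged muscle-invasive.

    Patients differ from one another: per-case tissue parameters are drawn
    around the cohort-level means (tumor ADC spread ~0.13·`patient_variability`
    in 10^-3 mm²/s, S0 scales ±10-15%, intra-lesion heterogeneity varies),
    matching the between-patient heterogeneity that agreement statistics such
    as the ICC are defined against.  Acquisitions differ too, emulating a
    multi-vendor, multi-field-strength population: the point-spread blur is
    drawn per case around `psf_sigma_mm` (default 2.25 mm, ~5 mm FWHM
    effective DWI resolution) and the noise level around `noise_sigma`.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    master = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(n_patients)]
    meta_rng = np.random.default_rng(master.spawn(1)[0])
    cases = []
    for i, cs in enumerate(case_seeds):
        n_tum = 2 if meta_rng.random() < multi_tumor_prob else 1
        frac = float(np.clip(meta_rng.normal(0.45, 0.08), 0.30, 0.65))
        if n_tum > 1:
            frac = min(frac, 0.45)
        age = int(np.clip(round(meta_rng.normal(73.6, 9.2)), 47, 94))
        mibc = bool(meta_rng.random() < 0.36)
        pv = patient_variability
        sp = spacing if spacing is not None else tuple(f / n for f, n in zip(FOV_MM, shape))
        # lesions differ in texture scale: correlation length drawn in mm
        tex_vox = float(meta_rng.uniform(0.5, 5.0)) / sp[1] if pv > 0 else \
            tissues.tumor.texture_corr_vox
        case_tissues = replace(
            tissues,
            tumor=replace(
                tissues.tumor,
                adc_mean=float(np.clip(
                    tissues.tumor.adc_mean + pv * meta_rng.normal(0.0, 0.13), 0.6, 1.4)),
                s0_mean=tissues.tumor.s0_mean * float(1 + pv * meta_rng.uniform(-0.15, 0.15)),
                # tumors also differ in intra-lesion heterogeneity
                adc_sd=tissues.tumor.adc_sd * float(np.exp(pv * meta_rng.uniform(-0.7, 0.7))),
                s0_sd=tissues.tumor.s0_sd * float(np.exp(pv * meta_rng.uniform(-0.5, 0.5))),
                texture_corr_vox=tex_vox,
            ),
            wall=replace(
                tissues.wall,
                adc_mean=tissues.wall.adc_mean * float(1 + pv * meta_rng.uniform(-0.06, 0.06)),
                s0_mean=tissues.wall.s0_mean * float(1 + pv * meta_rng.uniform(-0.10, 0.10)),
            ),
            urine=replace(
                tissues.urine,
                adc_mean=tissues.urine.adc_mean * float(1 + pv * meta_rng.uniform(-0.05, 0.05)),
                s0_mean=tissues.urine.s0_mean * float(1 + pv * meta_rng.uniform(-0.10, 0.10)),
            ),
        )
        case_psf = psf_sigma_mm * float(1 + pv * meta_rng.uniform(-0.4, 0.4))
        case_noise = noise_sigma * float(1 + pv * meta_rng.uniform(-0.3, 0.4))
        for attempt in range(20):
            try:
                case = synthesize_case(
                    shape=shape,
                    tissues=case_tissues,
                    noise_sigma=case_noise,
                    n_tumors=n_tum,
                    seed=cs + attempt,
                    spacing=spacing,
                    tumor_radius_frac=frac,
                    decoys=decoys,
                    psf_sigma_mm=case_psf,
                    case_id=f"case-{i:04d}",
                    metadata={"age": age, "muscle_invasion": mibc},
                )
                break
            except ValueError:
                frac *= 0.85
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"failed to synthesize case {i}")
        cases.append(case)
    return cases


def perturb_mask(mask: SegmentationMask, magnitude: float, seed: int = 0) -> SegmentationMask:
    """Randomly deform a tumor mask, emulating auto-vs-manual ROI disagreement.

    The boundary is moved by adding a smooth Gaussian random field (unit
    variance, correlation length ~2 voxels) scaled by `magnitude` (voxels) to
    the signed Euclidean distance map, after a random sub-voxel-scale
    translation.  Expected overlap with the original decreases monotonically
    as `magnitude` grows; `magnitude = 0` returns an identical copy.
    """
    if mask.is_empty():
        raise ValueError("cannot perturb an empty mask: no boundary to move")
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return SegmentationMask(mask.voxels.copy(), mask.spacing)

    rng = np.random.default_rng(seed)
    m = mask.voxels.astype(bool)
    for _ in range(5):
        shift = np.round(rng.normal(0.0, magnitude / 2.0, 3) * [0.3, 1.0, 1.0]).astype(int)
        shifted = np.roll(m, shift, axis=(0, 1, 2))
        sdist = ndimage.distance_transform_edt(shifted) - ndimage.distance_transform_edt(~shifted)
        f = ndimage.gaussian_filter(rng.standard_normal(m.shape), sigma=2.0)
        f /= f.std()
        out = (sdist + magnitude * f) > 0
        if out.any():
            return SegmentationMask(out.astype(np.uint8), mask.spacing)
    return SegmentationMask(mask.voxels.copy(), mask.spacing)  # pragma: no cover


def calibrate_perturbation(
    masks: list[SegmentationMask],
    target_dsc: float = 0.85,
    seed: int = 0,
    tol: float = 0.01,
    max_iter: int = 20,
) -> float:
    """Find the perturbation magnitude whose mean Dice overlap hits `target_dsc`.

    Bisection on `magnitude`, using the mean Dice similarity between each mask
    and its perturbation over the supplied masks.
    """
    from .ensemble_eval import dice_coefficient

    def mean_dsc(mag: float) -> float:
        vals = [
            dice_coefficient(m, perturb_mask(m, mag, seed=seed + i))
            for i, m in enumerate(masks)
        ]
        return float(np.mean(vals))

    lo, hi = 0.0, 1.0
    while mean_dsc(hi) > target_dsc and hi < 64:
        hi *= 2
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d = mean_dsc(mid)
        if abs(d - target_dsc) < tol:
            return mid
        if d > target_dsc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
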