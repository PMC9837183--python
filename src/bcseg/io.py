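"""NIfTI and CSV input/output for cases, cohorts, models and feature tables.

Per-case layout on disk: ``<dir>/<case_id>/{b0,b1000,adc,mask}.nii.gz`` with
voxel spacing in the header (array axis 0 is the slice axis) plus a cohort
manifest CSV (case_id, path, age, muscle_invasion).  Feature tables are tidy
CSVs with one row per (case, mask source, feature).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PatientCase, SegmentationMask
from .radiomics import FeatureVector
from .radiomics.manifest import family_of
from .unet import ModelConfig, TrainedModel, build_unet

__all__ = [
    "write_case",
    "read_case",
    "write_cohort",
    "read_cohort",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
]

_SEQUENCES = ("b0", "b1000", "adc")


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def _save_nii(arr: np.ndarray, spacing, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(arr), _affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def write_case(case: PatientCase, out_dir: str | Path) -> Path:
    """Write one case as four NIfTI volumes plus a JSON metadata sidecar."""
    case_dir = Path(out_dir) / case.case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    for name in _SEQUENCES:
        _save_nii(getattr(case, name).astype(np.float32), case.spacing, case_dir / f"{name}.nii.gz")
    _save_nii(case.reference_mask.voxels, case.spacing, case_dir / "mask.nii.gz")
    (case_dir / "meta.json").write_text(json.dumps({"case_id": case.case_id, **case.metadata}))
    return case_dir


def read_case(case_dir: str | Path, case_id: str | None = None) -> PatientCase:
    """Load a case, validating that all sequences are aligned and the mask binary."""
    case_dir = Path(case_dir)
    vols, spacings = {}, {}
    for name in _SEQUENCES + ("mask",):
        path = case_dir / f"{name}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing {name} volume for case at {case_dir}")
        img = nib.load(str(path))
        vols[name] = np.asarray(img.dataobj)
        spacings[name] = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    shapes = {name: v.shape for name, v in vols.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"sequence shapes disagree: {shapes}")
    if len(set(spacings.values())) != 1:
        raise ValueError(f"sequence spacings disagree: {spacings}")
    mask_vals = np.unique(vols["mask"])
    if not np.isin(mask_vals, [0, 1]).all():
        raise ValueError(f"mask is not binary: found values {mask_vals}")
    spacing = spacings["mask"]
    meta_path = case_dir / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    cid = case_id or meta.pop("case_id", case_dir.name)
    meta.pop("case_id", None)
    return PatientCase(
        case_id=cid,
        b0=vols["b0"].astype(np.float32),
        b1000=vols["b1000"].astype(np.float32),
        adc=vols["adc"].astype(np.float32),
        spacing=spacing,
        reference_mask=SegmentationMask(vols["mask"].astype(np.uint8), spacing),
        metadata=meta,
    )


def write_cohort(cases: list[PatientCase], out_dir: str | Path) -> Path:
    """Write every case plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for case in cases:
        case_dir = write_case(case, out_dir)
        rows.append(
            {
                "case_id": case.case_id,
                "path": str(case_dir.relative_to(out_dir)),
                "age": case.metadata.get("age", ""),
                "muscle_invasion": case.metadata.get("muscle_invasion", ""),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | Path) -> list[PatientCase]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    return [read_case(manifest.parent / row.path, case_id=row.case_id) for row in df.itertuples()]


def write_feature_table(
    vectors: list[FeatureVector],
    case_ids: list[str],
    mask_sources: list[str],
    path: str | Path,
) -> Path:
    """Write feature vectors as a tidy CSV (case_id, mask_source, feature, family, value)."""
    if not (len(vectors) == len(case_ids) == len(mask_sources)):
        raise ValueError("vectors, case_ids and mask_sources must have equal length")
    rows = [
        {
            "case_id": cid,
            "mask_source": src,
            "feature_name": name,
            "family": family_of(name),
            "value": value,
        }
        for fv, cid, src in zip(vectors, case_ids, mask_sources)
        for name, value in fv.values.items()
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"case_id", "mask_source", "feature_name", "family", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"feature table missing columns {required - set(df.columns)}")
    return df


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Persist a trained model (weights + config + history) as an .npz checkpoint."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = {f"config_{k}": v for k, v in vars(model.config).items()}
    np.savez_compressed(
        path,
        __history=json.dumps(model.history),
        __config=json.dumps(cfg),
        **model.net.state_dict(),
    )
    return path


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg_raw = json.loads(str(data["__config"]))
        config = ModelConfig(**{k.removeprefix("config_"): v for k, v in cfg_raw.items()})
        model = build_unet(config)
        state = {k: data[k] for k in data.files if not k.startswith("__")}
        model.net.load_state_dict(state)
        model.history = json.loads(str(data["__history"]))
    return model
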