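"""End-to-end study pipeline on synthetic cohorts.

Stages, mirroring the clinical workflow: simulate a cohort → patient-level
train/test split → five-fold cross-validated U-Net training on the training
set → majority-vote ensemble segmentation of the held-out test set → Dice
evaluation → radiomics extraction from the ADC maps under both the reference
("manual") and ensemble ("auto") masks → per-feature ICC(2,1) and per-family
summaries.  Every stage is seeded from the single master seed, so a rerun
with the same config reproduces all reports exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble_eval, repro_stats
from .phantom import generate_cohort
from .preprocess import assemble_channels
from .radiomics import RadiomicsConfig, extract_all
from .unet import ModelConfig, cross_validate

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full run."""

    n_patients: int = 50
    test_fraction: float = 0.18  # emulates the 140/30 train-test design
    shape: tuple[int, int, int] = (8, 64, 64)
    noise_sigma: float = 25.0
    decoys: bool = False
    input_mode: str = "multi"
    model: ModelConfig = field(
        default_factory=lambda: ModelConfig(base_filters=8, epochs=10, batch_size=8, grid_size=64)
    )
    vote_threshold: int = 3
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.shape[1] != self.model.grid_size or self.shape[2] != self.model.grid_size:
            raise ValueError(
                "phantom in-plane shape must equal the model grid so ensemble masks "
                f"align with the native voxel grid; got {self.shape[1:]} vs "
                f"{self.model.grid_size}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "model" in raw:
            raw["model"] = ModelConfig(**raw["model"])
        if "radiomics" in raw:
            raw["radiomics"] = RadiomicsConfig(**raw["radiomics"])
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d


def _split_cohort(cases, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(cases))))
    order = rng.permutation(len(cases))
    test_idx = set(order[:n_test].tolist())
    train = [c for i, c in enumerate(cases) if i not in test_idx]
    test = [c for i, c in enumerate(cases) if i in test_idx]
    return train, test


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and optionally writes) the report bundle.

    The bundle holds the cross-validation DSC summary, per-test-case ensemble
    DSC with median/IQR, the tidy manual/auto feature table, per-feature ICC
    results, and per-family ICC summaries, plus a reproducibility log of
    seeds and stage timings.
    """
    log: list[dict] = []

    def stage(name):
        t0 = time.time()
        log.append({"stage": name, "t_start": t0})
        return t0

    def done(t0):
        log[-1]["seconds"] = round(time.time() - t0, 2)

    t0 = stage("simulate")
    cohort = generate_cohort(
        config.n_patients,
        seed=config.seed,
        shape=config.shape,
        noise_sigma=config.noise_sigma,
        decoys=config.decoys,
    )
    train_cases, test_cases = _split_cohort(cohort, config.test_fraction, config.seed + 17)
    done(t0)

    t0 = stage("cross_validate")
    try:
        cv = cross_validate(train_cases, config.model, channel_mode=config.input_mode)
    except Exception as err:
        raise RuntimeError(f"pipeline stage cross_validate failed: {err}") from err
    cv_summary = {
        "train": ensemble_eval.summarize_cv(cv.train_dsc),
        "val": ensemble_eval.summarize_cv(cv.val_dsc),
    }
    done(t0)

    t0 = stage("ensemble_predict")
    per_case_dsc: dict[str, float] = {}
    auto_masks: dict[str, object] = {}
    for case in test_cases:
        try:
            stack = assemble_channels(case, config.input_mode, size=config.model.grid_size)
            pred = ensemble_eval.ensemble_predict(
                cv.models, stack, min_votes=config.vote_threshold, spacing=case.spacing
            )
        except Exception as err:
            raise RuntimeError(
                f"pipeline stage ensemble_predict failed on case {case.case_id}: {err}"
            ) from err
        auto_masks[case.case_id] = pred
        per_case_dsc[case.case_id] = ensemble_eval.dice_coefficient(case.reference_mask, pred)
    test_summary = ensemble_eval.summarize_test(list(per_case_dsc.values()))
    done(t0)

    t0 = stage("radiomics")
    rows = []
    for case in test_cases:
        manual = extract_all(case.adc, case.reference_mask, case.spacing, config.radiomics)
        rows.append((case.case_id, "manual", manual))
        auto = auto_masks[case.case_id]
        if auto.is_empty():
            continue  # no automatic ROI: case drops out of the agreement analysis
        rows.append((case.case_id, "auto", extract_all(case.adc, auto, case.spacing, config.radiomics)))
    feature_df = pd.DataFrame(
        [
            {"case_id": cid, "mask_source": src, "feature_name": name,
             "family": name.split("_", 1)[0], "value": val}
            for cid, src, fv in rows
            for name, val in fv.values.items()
        ]
    )
    done(t0)

    t0 = stage("icc")
    wide = feature_df.pivot_table(
        index=["case_id", "feature_name"], columns="mask_source", values="value"
    ).dropna()
    n_paired = wide.index.get_level_values("case_id").nunique() if "auto" in wide.columns else 0
    if n_paired < 2:
        raise RuntimeError(
            "pipeline stage icc failed: fewer than 2 test cases have a non-empty "
            "automatic segmentation"
        )
    icc_rows = []
    for feat in feature_df["feature_name"].unique():
        sub = wide.xs(feat, level="feature_name")[["manual", "auto"]]
        res = repro_stats.icc_2_1(sub.to_numpy())
        icc_rows.append(
            {"feature_name": feat, "family": feat.split("_", 1)[0], "icc": res.icc,
             "p_value": res.p_value, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
             "category": res.category}
        )
    icc_df = pd.DataFrame(icc_rows)
    families = repro_stats.feature_group_summary(
        dict(zip(icc_df["feature_name"], icc_df["icc"]))
    )
    family_df = pd.DataFrame(
        [
            {"family": f.family, "n_features": f.n_features, "median_icc": f.median_icc,
             "iqr_low": f.iqr[0], "iqr_high": f.iqr[1]}
            for f in families
        ]
    )
    done(t0)

    bundle = {
        "config": config.to_dict(),
        "n_train": len(train_cases),
        "n_test": len(test_cases),
        "cv_summary": cv_summary,
        "per_case_dsc": per_case_dsc,
        "test_summary": test_summary,
        "features": feature_df,
        "icc": icc_df,
        "family_summary": family_df,
        "log": log,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        pd.DataFrame(
            [{"fold": i, "train_dsc": tr, "val_dsc": va}
             for i, (tr, va) in enumerate(zip(cv.train_dsc, cv.val_dsc))]
        ).to_csv(out / "dsc_cv.csv", index=False)
        pd.DataFrame(
            [{"case_id": cid, "dsc": d} for cid, d in per_case_dsc.items()]
        ).to_csv(out / "dsc_test.csv", index=False)
        feature_df.to_csv(out / "features.csv", index=False)
        icc_df.to_csv(out / "icc.csv", index=False)
        family_df.to_csv(out / "family_summary.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(
            {"seed": config.seed, "stages": log,
             "cv_summary": cv_summary, "test_summary": test_summary}, indent=2))
    return bundle
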