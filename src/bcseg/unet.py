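"""Five-level U-Net segmentation model and its cross-validated training.

The network is a conventional U-Net deepened to five resolution levels (the
original design has four): per level two Conv–BatchNorm–ReLU blocks, 2×2 max
pooling on the way down, 2×2 transposed convolutions and skip concatenations
on the way up, and a sigmoid head.  Training minimizes the soft-Dice loss
with Adam.  The defaults mirror the full-scale protocol (30 epochs, batch 56,
learning rate 0.001, base width 32 on a 128×128 grid); `TEST_SCALE` is a
reduced profile for CPU-scale experiments.

Cross-validation is always at the patient level: all slices of a patient stay
on one side of every fold split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .phantom import PatientCase
from .preprocess import CHANNEL_MODES, ChannelStack, assemble_channels, resize_to_model_grid

__all__ = [
    "ModelConfig",
    "TEST_SCALE",
    "FoldSplit",
    "TrainedModel",
    "CVResult",
    "build_unet",
    "dice_loss",
    "make_folds",
    "train_fold",
    "cross_validate",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyper-parameters."""

    depth: int = 5
    base_filters: int = 32
    epochs: int = 30
    batch_size: int = 56
    learning_rate: float = 0.001
    seed: int = 0
    loss: str = "dice"
    grid_size: int = 128
    smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.grid_size % 2 ** (self.depth - 1):
            raise ValueError(
                f"grid size {self.grid_size} not divisible by 2^(depth-1)={2**(self.depth-1)}"
            )
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss != "dice":
            raise ValueError("only the Dice loss is supported")


#: reduced profile for CPU-scale runs (smaller net, coarser grid, short schedule)
TEST_SCALE = ModelConfig(base_filters=8, epochs=10, batch_size=8, grid_size=64)


@dataclass(frozen=True)
class FoldSplit:
    """Patient-level fold assignment: patient_id -> fold index in 0..k-1."""

    assignments: dict
    k: int

    def val_ids(self, fold: int) -> list:
        return [p for p, f in self.assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list:
        return [p for p, f in self.assignments.items() if f != fold]


@dataclass
class TrainedModel:
    """A (possibly trained) network plus its config and training history."""

    net: nn.UNet2D
    config: ModelConfig
    history: list = field(default_factory=list)

    def predict(self, stack: ChannelStack, batch_size: int = 16) -> np.ndarray:
        """Per-pixel tumor probabilities for every slice: (n_slices, H, W) in [0,1]."""
        x = np.ascontiguousarray(stack.slices.transpose(0, 3, 1, 2))
        out = [
            self.net.forward(x[i : i + batch_size], train=False)
            for i in range(0, x.shape[0], batch_size)
        ]
        probs = np.concatenate(out, axis=0)
        if not np.isfinite(probs).all():  # pragma: no cover - defensive
            raise RuntimeError("model produced non-finite probabilities")
        return probs

    def param_checksum(self) -> float:
        return self.net.param_checksum()


@dataclass
class CVResult:
    """Five trained models with per-fold mean train/validation Dice scores."""

    models: list
    fold_split: FoldSplit
    train_dsc: list
    val_dsc: list
    channel_mode: str


def build_unet(config: ModelConfig) -> TrainedModel:
    """Construct an untrained model; initialization is deterministic in the seed."""
    net = nn.UNet2D(
        in_channels=3, base_filters=config.base_filters, depth=config.depth, seed=config.seed
    )
    return TrainedModel(net=net, config=config)


def dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """Soft-Dice loss ``1 - (2Σpt+s)/(Σp+Σt+s)``; see :func:`bcseg.nn.soft_dice_loss`."""
    target = np.asarray(target)
    uniq = np.unique(target)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("target must be binary")
    pred = np.asarray(pred)
    if pred.min() < 0 or pred.max() > 1:
        raise ValueError("pred must lie in [0, 1]")
    return nn.soft_dice_loss(pred, target, smooth=smooth)


def make_folds(patient_ids: list, k: int = 5, seed: int = 0) -> FoldSplit:
    """Random patient-level partition into k folds of near-equal size (±1)."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients for {k}-fold cross-validation")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {}
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            assignments[ids[idx]] = fold
    return FoldSplit(assignments=assignments, k=k)


def _case_arrays(cases: list[PatientCase], channel_mode: str, grid: int):
    """Stack all slices of the given cases into model inputs and binary targets."""
    xs, ys, slice_counts = [], [], []
    for case in cases:
        stack = assemble_channels(case, channel_mode, size=grid)
        xs.append(stack.slices)
        ys.append(
            np.stack(
                [resize_to_model_grid(sl, is_mask=True, size=grid)
                 for sl in case.reference_mask.voxels]
            )
        )
        slice_counts.append(stack.n_slices)
    x = np.concatenate(xs).transpose(0, 3, 1, 2).astype(np.float32)
    y = np.concatenate(ys).astype(np.float32)
    return np.ascontiguousarray(x), y, slice_counts


def _mean_case_dsc(model: TrainedModel, cases: list[PatientCase], channel_mode: str,
                  threshold: float = 0.5) -> float:
    """Volumetric per-patient Dice against the (grid-resampled) reference."""
    from .ensemble_eval import dice_coefficient, predict_mask

    grid = model.config.grid_size
    vals = []
    for case in cases:
        stack = assemble_channels(case, channel_mode, size=grid)
        pred = predict_mask(model, stack, prob_threshold=threshold, spacing=case.spacing)
        ref = np.stack(
            [resize_to_model_grid(sl, is_mask=True, size=grid)
             for sl in case.reference_mask.voxels]
        )
        from .phantom import SegmentationMask

        vals.append(dice_coefficient(SegmentationMask(ref, case.spacing), pred))
    return float(np.mean(vals))


def train_fold(
    model: TrainedModel,
    train_cases: list[PatientCase],
    val_cases: list[PatientCase],
    config: ModelConfig | None = None,
    channel_mode: str = "multi",
) -> TrainedModel:
    """Train `model` on the training cases' 2D slices; track per-epoch losses.

    Patient sets must be disjoint.  With ``epochs = 0`` the initialized model
    is returned unchanged.  A non-finite loss aborts with a diagnostic.
    """
    config = config or model.config
    if not train_cases:
        raise ValueError("empty training set")
    overlap = {c.case_id for c in train_cases} & {c.case_id for c in val_cases}
    if overlap:
        raise ValueError(f"patients in both train and validation sets: {sorted(overlap)}")
    if channel_mode not in CHANNEL_MODES:
        raise ValueError(f"unknown channel mode {channel_mode!r}")

    x, y, _ = _case_arrays(train_cases, channel_mode, config.grid_size)
    xv = yv = None
    if val_cases:
        xv, yv, _ = _case_arrays(val_cases, channel_mode, config.grid_size)

    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.net, lr=config.learning_rate)
    n = x.shape[0]
    for epoch in range(config.epochs):
        # cosine decay from the initial learning rate
        opt.lr = config.learning_rate * 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs = model.net.forward(x[idx], train=True)
            loss, grad = nn.soft_dice_loss(probs, y[idx], smooth=config.smooth, with_grad=True)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            model.net.zero_grad()
            model.net.backward(grad)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if xv is not None:
            vp = np.concatenate(
                [model.net.forward(xv[i : i + 16], train=False) for i in range(0, xv.shape[0], 16)]
            )
            entry["val_loss"] = nn.soft_dice_loss(vp, yv, smooth=config.smooth)
        model.history.append(entry)
    return model


def cross_validate(
    cohort: list[PatientCase],
    config: ModelConfig,
    channel_mode: str = "multi",
    k: int = 5,
) -> CVResult:
    """K-fold patient-level cross-validation; one trained model per fold.

    Per fold, reports the mean volumetric Dice on the training and validation
    patients (probabilities binarized at 0.5).
    """
    if len(cohort) < k:
        raise ValueError(f"cohort of {len(cohort)} patients cannot support {k} folds")
    by_id = {c.case_id: c for c in cohort}
    split = make_folds(list(by_id), k=k, seed=config.seed)
    models, train_dsc, val_dsc = [], [], []
    for fold in range(k):
        train_cases = [by_id[i] for i in split.train_ids(fold)]
        val_cases = [by_id[i] for i in split.val_ids(fold)]
        model = build_unet(replace(config, seed=config.seed + 1000 * (fold + 1)))
        try:
            train_fold(model, train_cases, val_cases, config=model.config,
                       channel_mode=channel_mode)
        except Exception as err:
            raise RuntimeError(f"cross-validation failed in fold {fold}") from err
        models.append(model)
        train_dsc.append(_mean_case_dsc(model, train_cases, channel_mode))
        val_dsc.append(_mean_case_dsc(model, val_cases, channel_mode))
    return CVResult(models=models, fold_split=split, train_dsc=train_dsc,
                    val_dsc=val_dsc, channel_mode=channel_mode)
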