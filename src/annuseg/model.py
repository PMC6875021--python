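"""Segmentation model: configuration, training loop, inference, checkpoints.

One encoder-decoder residual network is trained per plane resolution
(1.0 mm and 0.5 mm).  Inputs are Hounsfield-unit rasters standardised by a
fixed affine transform (clamp to [-1024, 1500] HU, rescale to [-1, 1]);
training minimises an equal-weight soft-Dice + binary-cross-entropy loss
with on-the-fly geometric and intensity augmentation, and the returned
model carries the weights of the epoch with the best validation Dice.

Everything is seeded: two training runs with the same data, config and seed
produce identical weights and history.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .core import AnnularPlane, BinaryMask, ProbabilityMap, ValidationError

__all__ = [
    "AugmentationConfig",
    "ModelConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
    "standardize_hu",
    "HU_CLAMP",
]

#: HU clamp window applied before rescaling network inputs to [-1, 1].
HU_CLAMP = (-1024.0, 1500.0)

_LOSSES = ("dice", "bce", "dice+bce")


def standardize_hu(values: np.ndarray) -> np.ndarray:
    """Clamp HU to [-1024, 1500] and rescale linearly to [-1, 1]."""
    lo, hi = HU_CLAMP
    v = np.clip(values, lo, hi)
    return ((v - lo) / (hi - lo) * 2.0 - 1.0).astype(np.float32)


@dataclass(frozen=True)
class AugmentationConfig:
    """On-the-fly training augmentation: generic CT plane perturbations."""

    rotation_max: float = 30.0  # degrees
    flip_horizontal: bool = True
    flip_vertical: bool = True
    intensity_shift_sd: float = 25.0  # HU
    translation_max: int = 5  # pixels

    def validate(self) -> None:
        if self.rotation_max < 0 or self.intensity_shift_sd < 0 or self.translation_max < 0:
            raise ValidationError("augmentation magnitudes must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are sized for single-core CPU training on phantom cohorts; the
    task saturates at this capacity and every field is overridable.
    """

    depth: int = 3
    base_channels: int = 4
    residual_blocks_per_level: int = 1
    input_size: int = 128
    loss: str = "dice+bce"
    learning_rate: float = 3e-3
    epochs: int = 10
    batch_size: int = 8
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValidationError(f"depth must be >= 1, got {self.depth}")
        if self.input_size % 2**self.depth != 0:
            raise ValidationError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )
        if self.epochs < 1:
            raise ValidationError(f"epochs must be >= 1, got {self.epochs}")
        if self.loss not in _LOSSES:
            raise ValidationError(f"loss must be one of {_LOSSES}, got {self.loss!r}")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        self.augmentation.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        aug = d.pop("augmentation", {})
        return cls(augmentation=AugmentationConfig(**aug), **d)


@dataclass
class TrainedModel:
    """A trained network plus its config, resolution tag and history."""

    net: nn.SegmentationUNet
    config: ModelConfig
    resolution: float  # mm/pixel the model was trained at
    history: pd.DataFrame  # epoch, train_loss, val_loss, val_dice


def build_model(config: ModelConfig) -> nn.SegmentationUNet:
    """Instantiate an untrained network; weight init is seeded by the config."""
    config.validate()
    return nn.SegmentationUNet(
        depth=config.depth,
        base_channels=config.base_channels,
        blocks_per_level=config.residual_blocks_per_level,
        seed=config.seed,
    )


def _loss_grad(logits: np.ndarray, targets: np.ndarray, kind: str):
    if kind == "dice+bce":
        return nn.dice_bce_loss_grad(logits, targets)
    p = nn.sigmoid(logits)
    t = targets.astype(np.float32, copy=False)
    if kind == "bce":
        n = logits.size
        z = logits
        loss = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * t))
        return loss, ((p - t) / n).astype(np.float32)
    # soft dice only
    eps = 1.0
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + eps
    dice = (2.0 * inter + eps) / denom
    ddice_dp = (2.0 * t * denom - (2.0 * inter + eps)) / denom**2
    return 1.0 - dice, (-ddice_dp * p * (1.0 - p)).astype(np.float32)


def _augment_pair(
    img: np.ndarray, mask: np.ndarray, aug: AugmentationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly rotate/flip/translate/intensity-shift one (HU image, mask) pair."""
    out_img, out_mask = img, mask
    if aug.rotation_max > 0:
        angle = rng.uniform(-aug.rotation_max, aug.rotation_max)
        out_img = ndimage.rotate(
            out_img, angle, reshape=False, order=1, mode="constant", cval=HU_CLAMP[0]
        )
        out_mask = ndimage.rotate(
            out_mask.astype(np.float32), angle, reshape=False, order=0, mode="constant", cval=0.0
        )
    if aug.flip_horizontal and rng.random() < 0.5:
        out_img, out_mask = out_img[:, ::-1], out_mask[:, ::-1]
    if aug.flip_vertical and rng.random() < 0.5:
        out_img, out_mask = out_img[::-1, :], out_mask[::-1, :]
    if aug.translation_max > 0:
        ty, tx = rng.integers(-aug.translation_max, aug.translation_max + 1, size=2)
        shifted = np.full_like(out_img, HU_CLAMP[0])
        smask = np.zeros_like(out_mask)
        h, w = out_img.shape
        ys = slice(max(ty, 0), min(h + ty, h))
        xs = slice(max(tx, 0), min(w + tx, w))
        ys_src = slice(max(-ty, 0), min(h - ty, h))
        xs_src = slice(max(-tx, 0), min(w - tx, w))
        shifted[ys, xs] = out_img[ys_src, xs_src]
        smask[ys, xs] = out_mask[ys_src, xs_src]
        out_img, out_mask = shifted, smask
    if aug.intensity_shift_sd > 0:
        out_img = out_img + rng.normal(0.0, aug.intensity_shift_sd)
    return np.ascontiguousarray(out_img), np.ascontiguousarray(out_mask)


def _hard_dice(prob: np.ndarray, target: np.ndarray, threshold: float = 0.5) -> float:
    a = prob >= threshold
    b = target >= 0.5
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def _check_resolution(samples, resolution: float | None, what: str) -> float:
    for plane, mask in samples:
        if not plane.is_isotropic:
            raise ValidationError(f"{what} plane is not isotropic: {plane.spacing}")
        s = plane.spacing[0]
        if resolution is None:
            resolution = s
        elif abs(s - resolution) > 1e-9:
            raise ValidationError(
                f"{what} resolution mismatch: plane at {s} mm, model at {resolution} mm"
            )
        if mask is not None and mask.shape != plane.shape:
            raise ValidationError(f"{what} mask/plane shape mismatch")
    return resolution


def train(
    model: nn.SegmentationUNet,
    samples: list[tuple[AnnularPlane, BinaryMask]],
    val_samples: list[tuple[AnnularPlane, BinaryMask]],
    config: ModelConfig,
) -> TrainedModel:
    """Train a segmentation network and return the best-validation-Dice weights.

    Augmentation is applied on the fly to training samples only; validation
    metrics are computed in inference mode each epoch.  Raises on an empty
    training or validation set, on mixed resolutions, and on NaN loss.
    """
    config.validate()
    if len(samples) < 1 or len(val_samples) < 1:
        raise ValidationError("need at least 1 training and 1 validation sample")
    resolution = _check_resolution(samples, None, "training")
    resolution = _check_resolution(val_samples, resolution, "validation")
    if not any(np.isclose(resolution, r) for r in (1.0, 0.5)):
        raise ValidationError(f"resolution must be 1.0 or 0.5 mm, got {resolution}")

    raw = [np.asarray(p.values, dtype=np.float32) for p, _ in samples]
    masks = [m.values.astype(np.float32) for _, m in samples]
    x_val = np.stack([standardize_hu(p.values) for p, _ in val_samples])[..., None]
    y_val = np.stack([m.values.astype(np.float32) for _, m in val_samples])[..., None]

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters, lr=config.learning_rate)
    history = []
    best_dice = -1.0
    best_state = [a.copy() for a in model.state_arrays()]

    n = len(samples)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = [], []
            for i in idx:
                img, msk = _augment_pair(raw[i], masks[i], config.augmentation, rng)
                xb.append(standardize_hu(img))
                yb.append(msk)
            x = np.stack(xb)[..., None]
            y = np.stack(yb)[..., None]
            logits = model.forward(x, train=True)
            loss, dlogits = _loss_grad(logits, y, config.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, step {start // config.batch_size}: "
                    f"loss={loss}, logits range [{logits.min()}, {logits.max()}]"
                )
            model.backward(dlogits)
            opt.step(model.gradients)
            losses.append(loss)

        val_logits = model.forward(x_val, train=False)
        val_loss, _ = _loss_grad(val_logits, y_val, config.loss)
        val_prob = nn.sigmoid(val_logits)
        val_dice = float(
            np.mean([_hard_dice(val_prob[i], y_val[i]) for i in range(len(val_samples))])
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": float(val_loss),
                "val_dice": val_dice,
            }
        )
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = [a.copy() for a in model.state_arrays()]

    model.set_state(best_state)
    return TrainedModel(
        net=model,
        config=config,
        resolution=float(resolution),
        history=pd.DataFrame(history),
    )


def predict(model: TrainedModel, plane: AnnularPlane) -> ProbabilityMap:
    """Run inference on one prepared plane; deterministic, no augmentation."""
    size = model.config.input_size
    if plane.shape != (size, size):
        raise ValidationError(f"plane shape {plane.shape} != expected ({size}, {size})")
    if not plane.is_isotropic or abs(plane.spacing[0] - model.resolution) > 1e-9:
        raise ValidationError(
            f"plane spacing {plane.spacing} does not match model resolution "
            f"{model.resolution} mm"
        )
    x = standardize_hu(plane.values)[None, ..., None]
    prob = model.net.predict_proba(x)[0, ..., 0].astype(np.float64)
    return ProbabilityMap(values=prob, spacing=plane.spacing, origin=plane.origin)


def save_checkpoint(model: TrainedModel, path) -> None:
    """Serialise weights + config + resolution + history to an .npz file."""
    arrays = {f"arr_{i}": a for i, a in enumerate(model.net.state_arrays())}
    meta = json.dumps(
        {
            "config": model.config.to_dict(),
            "resolution": model.resolution,
            "n_arrays": len(arrays),
        }
    )
    hist_csv = model.history.to_csv(index=False)
    np.savez(
        path,
        __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
        __history__=np.frombuffer(hist_csv.encode(), dtype=np.uint8),
        **arrays,
    )


def load_checkpoint(path) -> TrainedModel:
    """Restore a checkpoint written by :func:`save_checkpoint`, bit-exact."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        history = pd.read_csv(io.StringIO(bytes(data["__history__"]).decode()))
        config = ModelConfig.from_dict(meta["config"])
        net = build_model(config)
        net.set_state([data[f"arr_{i}"] for i in range(meta["n_arrays"])])
    return TrainedModel(
        net=net, config=config, resolution=float(meta["resolution"]), history=history
    )
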