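"""Training pipeline: ROI-masked soft Dice loss, random large-patch
sampling with rigid augmentation, and the optimization protocol.

The loss is the soft Dice restricted to the lung region-of-interest
N_L::

    L = 1 - 2 * sum_{x in N_L} p(x) g(x)
          / (sum_{x in N_L} p(x) + sum_{x in N_L} g(x) + eps)

so voxels outside the lungs contribute neither to the value nor to the
gradient; the ground truth is masked to the lungs beforehand, which
removes the trachea and part of the main bronchi and focuses training
on the smaller branches.

Per epoch, a fixed number of random patches is drawn per scan (corner
uniform over the valid range), each optionally augmented by random
per-axis flips, small 3D rotations (up to 10 degrees) and isotropic
scaling in (0.75, 1.25); ground truth and ROI are resampled with
nearest-neighbour interpolation in a single composed transform.
Optimization uses Adam with batches of one patch; convergence monitors
the moving average of the validation loss, and the returned model is
the snapshot at the overall minimum validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import DEFAULT_INTENSITY_WINDOW, VolumeGrid, normalize_intensity
from .nn import Adam
from .unet import UNet3D, is_admissible_input

__all__ = [
    "Sample",
    "PatchPair",
    "AugmentConfig",
    "TrainConfig",
    "TrainingHistory",
    "crop_to_roi_bbox",
    "sample_random_patch",
    "augment",
    "masked_soft_dice_loss",
    "convergence_check",
    "train",
]

DICE_EPS = 1e-6  # defines the empty-ROI / empty-truth limit of the loss


@dataclass
class Sample:
    """One scan with ground truth and lung ROI, on a shared grid."""

    image: VolumeGrid
    labels: VolumeGrid
    roi_mask: VolumeGrid
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (
            self.image.shape == self.labels.shape == self.roi_mask.shape
        ):
            raise ValueError("image, labels and roi_mask must share one grid")


@dataclass
class PatchPair:
    """An aligned (image, labels, roi) crop and its corner in the source."""

    image_patch: np.ndarray
    label_patch: np.ndarray
    roi_patch: np.ndarray
    corner: Tuple[int, int, int]


@dataclass(frozen=True)
class AugmentConfig:
    """Rigid augmentation parameters (applied flips -> rotation -> scaling)."""

    enabled: bool = True
    flip_axes: Tuple[bool, bool, bool] = (True, True, True)
    max_rotation_deg: float = 10.0
    scale_range: Tuple[float, float] = (0.75, 1.25)

    def __post_init__(self) -> None:
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid scale_range {self.scale_range}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol parameters.

    The defaults follow the reference protocol: Adam at learning rate
    1e-4, 8 random patches per scan per epoch in batches of one, an
    80/20 train/validation split, and a stopping rule on the 50-epoch
    moving average of the validation loss (stop when it rises > 5% or
    fails to fall by > 0.1% across 20 epochs).
    """

    learning_rate: float = 1e-4
    patches_per_scan_per_epoch: int = 8
    batch_size: int = 1
    val_fraction: float = 0.2
    ma_window_epochs: int = 50
    stop_rise_fraction: float = 0.05
    stop_stall_fraction: float = 0.001
    stop_patience_epochs: int = 20
    max_epochs: int = 1000
    patch_size: Tuple[int, int, int] = (252, 252, 252)
    intensity_window: Tuple[float, float] = DEFAULT_INTENSITY_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        for name in ("ma_window_epochs", "stop_patience_epochs", "max_epochs",
                     "patches_per_scan_per_epoch"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """Epoch index (0-based) of the overall minimum validation loss."""
        if not self.val_loss:
            raise ValueError("empty history")
        return int(np.argmin(self.val_loss))


# ---------------------------------------------------------------------------
# preprocessing and patch extraction
# ---------------------------------------------------------------------------

def crop_to_roi_bbox(sample: Sample, buffer_voxels: int = 30) -> Sample:
    """Crop all grids to the ROI bounding box + buffer, and mask labels.

    The buffer (default 30 voxels in every direction, clamped at the
    volume bounds) keeps boundary effects of the zero-padded network
    levels away from peripheral airways. Label voxels outside the ROI
    are zeroed, removing the trachea/main-bronchi part of the truth.
    """
    roi = sample.roi_mask.values.astype(bool)
    if not roi.any():
        raise ValueError("roi_mask is empty; cannot crop to its bounding box")
    coords = np.argwhere(roi)
    lo = np.maximum(coords.min(axis=0) - buffer_voxels, 0)
    hi = np.minimum(coords.max(axis=0) + 1 + buffer_voxels, roi.shape)
    window = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    labels = sample.labels.values * sample.roi_mask.values.astype(
        sample.labels.values.dtype
    )
    sp = sample.image.spacing
    return Sample(
        image=VolumeGrid(sample.image.values[window], sp),
        labels=VolumeGrid(labels[window], sp),
        roi_mask=VolumeGrid(sample.roi_mask.values[window], sp),
        sample_id=sample.sample_id,
    )


def _pad_to(arr: np.ndarray, target: Sequence[int], mode: str, **kw) -> np.ndarray:
    pads = []
    for s, t in zip(arr.shape, target):
        extra = max(0, t - s)
        pads.append((extra // 2, extra - extra // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, mode=mode, **kw)
    return arr


def pad_sample_to_patch(sample: Sample, patch_size: Sequence[int]) -> Sample:
    """Symmetrically zero-pad grids smaller than the patch size."""
    sp = sample.image.spacing
    return Sample(
        image=VolumeGrid(_pad_to(sample.image.values, patch_size, "constant"), sp),
        labels=VolumeGrid(_pad_to(sample.labels.values, patch_size, "constant"), sp),
        roi_mask=VolumeGrid(_pad_to(sample.roi_mask.values, patch_size, "constant"), sp),
        sample_id=sample.sample_id,
    )


def sample_random_patch(
    sample: Sample, patch_size: Sequence[int], rng: np.random.Generator
) -> PatchPair:
    """Draw one patch with its first corner uniform over the valid range.

    With (D, W, H) the volume size and (d, w, h) the patch size, the
    corner is uniform on [0, D-d] x [0, W-w] x [0, H-h] and the patch is
    the half-open window from the corner, applied identically to image,
    labels and ROI.
    """
    shape = sample.image.shape
    patch_size = tuple(int(p) for p in patch_size)
    if any(p > s for p, s in zip(patch_size, shape)):
        raise ValueError(f"patch {patch_size} larger than volume {shape}")
    corner = tuple(int(rng.integers(0, s - p + 1)) for s, p in zip(shape, patch_size))
    window = tuple(slice(c, c + p) for c, p in zip(corner, patch_size))
    return PatchPair(
        image_patch=sample.image.values[window],
        label_patch=sample.labels.values[window],
        roi_patch=sample.roi_mask.values[window],
        corner=corner,
    )


def _euler_matrix(angles_rad: Sequence[float]) -> np.ndarray:
    az, ay, ax = angles_rad
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment(
    pair: PatchPair, config: AugmentConfig, rng: np.random.Generator
) -> PatchPair:
    """Apply random flips, a small 3D rotation and isotropic scaling.

    All three operations are composed into a single affine resampling:
    the image is interpolated linearly (constant fill at the patch
    minimum, i.e. air), labels and ROI with nearest neighbour, so they
    stay strictly binary. Output shape equals input shape.
    """
    if not config.enabled:
        return pair
    flips = np.array(
        [
            -1.0 if (config.flip_axes[i] and rng.random() < 0.5) else 1.0
            for i in range(3)
        ]
    )
    angles = np.deg2rad(
        rng.uniform(-config.max_rotation_deg, config.max_rotation_deg, size=3)
    )
    scale = rng.uniform(*config.scale_range)
    # content transform A = Scale @ Rot @ Flip; resampler needs A^-1
    rot = _euler_matrix(angles)
    a_inv = (np.diag(flips) @ rot.T) / scale
    shape = np.asarray(pair.image_patch.shape, dtype=float)
    center = (shape - 1.0) / 2.0
    offset = center - a_inv @ center

    def warp(arr: np.ndarray, order: int, cval: float) -> np.ndarray:
        return ndimage.affine_transform(
            arr.astype(np.float32) if order else arr,
            a_inv,
            offset=offset,
            order=order,
            mode="constant",
            cval=cval,
            output_shape=arr.shape,
        )

    image = warp(pair.image_patch, 1, float(pair.image_patch.min()))
    labels = warp(pair.label_patch, 0, 0)
    roi = warp(pair.roi_patch, 0, 0)
    return PatchPair(image, labels, roi, pair.corner)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def masked_soft_dice_loss(
    pred: np.ndarray,
    truth: np.ndarray,
    roi: np.ndarray,
    eps: float = DICE_EPS,
    return_grad: bool = False,
):
    """ROI-masked soft Dice loss; optionally its gradient w.r.t. ``pred``.

    Only voxels with ``roi != 0`` enter the sums, so predictions and
    truth outside the ROI influence neither the value nor the gradient.
    ``eps`` resolves the 0/0 case of an empty ROI or empty truth+pred.
    """
    if pred.shape != truth.shape or pred.shape != roi.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, truth {truth.shape}, roi {roi.shape}"
        )
    m = roi.astype(np.float64)
    p = pred.astype(np.float64) * m
    g = truth.astype(np.float64) * m
    num = float((p * g).sum())
    den = float(p.sum() + g.sum()) + eps
    loss = 1.0 - 2.0 * num / den
    if not return_grad:
        return loss
    grad = ((-2.0 * g * den + 2.0 * num) / den ** 2) * m
    return loss, grad


# ---------------------------------------------------------------------------
# convergence rule
# ---------------------------------------------------------------------------

def convergence_check(history: TrainingHistory, config: TrainConfig) -> Tuple[bool, str]:
    """Stopping rule on the moving average of the validation loss.

    Let ``ma(t)`` be the mean of the last ``ma_window_epochs`` validation
    losses ending at epoch ``t``. Training stops when, relative to its
    value ``stop_patience_epochs`` earlier, the moving average has
    (1) risen by more than ``stop_rise_fraction``, or (2) failed to fall
    by more than ``stop_stall_fraction``. No stop is signalled before
    ``ma_window_epochs + stop_patience_epochs`` epochs exist.
    """
    losses = np.asarray(history.val_loss, dtype=float)
    w, pat = config.ma_window_epochs, config.stop_patience_epochs
    if len(losses) < w + pat:
        return False, "insufficient history"
    current = losses[-w:].mean()
    past = losses[-w - pat : -pat].mean()
    if past <= 0:
        return True, "stall (non-positive reference)"
    rel = (current - past) / past
    if rel > config.stop_rise_fraction:
        return True, f"rise ({100 * rel:.2f}% > {100 * config.stop_rise_fraction}%)"
    if -rel <= config.stop_stall_fraction:
        return True, (
            f"stall (decrease {100 * max(-rel, 0):.3f}% <= "
            f"{100 * config.stop_stall_fraction}%)"
        )
    return False, "improving"


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _split_samples(
    samples: Sequence[Sample], val_fraction: float, rng: np.random.Generator
) -> Tuple[List[Sample], List[Sample]]:
    """Deterministic split: sort by id, seeded shuffle, last fraction = val."""
    order = sorted(range(len(samples)), key=lambda i: (samples[i].sample_id, i))
    order = list(np.asarray(order)[rng.permutation(len(order))])
    n_val = max(1, int(round(val_fraction * len(samples))))
    n_val = min(n_val, len(samples) - 1)
    val_idx = set(order[:n_val])
    train = [samples[i] for i in order if i not in val_idx]
    val = [samples[i] for i in sorted(val_idx)]
    return train, val


def _prepare(sample: Sample, config: TrainConfig) -> Sample:
    """Normalize intensities and pad to patch size if needed."""
    sp = sample.image.spacing
    norm = VolumeGrid(
        normalize_intensity(sample.image.values, config.intensity_window), sp
    )
    out = Sample(norm, sample.labels, sample.roi_mask, sample.sample_id)
    return pad_sample_to_patch(out, config.patch_size)


def _patch_loss(
    model: UNet3D,
    pair: PatchPair,
    margin: Tuple[int, int, int],
    train_mode: bool,
) -> float:
    """Forward pass + loss on the centered crop of truth/ROI; optionally
    backpropagates through the model."""
    pred = model.forward(pair.image_patch, train=train_mode)
    crop = tuple(
        slice(m, m + o) for m, o in zip(margin, pred.shape)
    )
    truth = pair.label_patch[crop]
    roi = pair.roi_patch[crop]
    if train_mode:
        loss, grad = masked_soft_dice_loss(pred, truth, roi, return_grad=True)
        model.backward(grad.astype(np.float32))
    else:
        loss = masked_soft_dice_loss(pred, truth, roi)
    return loss


def train(
    model: UNet3D,
    samples: Sequence[Sample],
    config: TrainConfig,
    augment_config: Optional[AugmentConfig] = None,
) -> Tuple[UNet3D, TrainingHistory]:
    """Train to convergence; return the min-validation-loss snapshot.

    Per epoch, ``patches_per_scan_per_epoch`` augmented random patches
    are drawn from every training scan and optimized one at a time with
    Adam. Validation loss is evaluated on deterministic (seeded, fixed
    across epochs) patches from the validation scans without
    augmentation. Training stops per :func:`convergence_check` or at
    ``max_epochs``; the weights at the overall minimum validation loss
    are restored into the returned model.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples (1 train + 1 validation)")
    if not is_admissible_input(model.config, config.patch_size):
        raise ValueError(
            f"patch size {config.patch_size} is not admissible for the model; "
            "pick an admissible size (see find_admissible_size)"
        )
    augment_config = augment_config if augment_config is not None else AugmentConfig()
    margin = model.output_margin(config.patch_size)

    split_rng = np.random.default_rng([config.seed, 11])
    train_samples, val_samples = _split_samples(samples, config.val_fraction, split_rng)
    train_samples = [_prepare(s, config) for s in train_samples]
    val_samples = [_prepare(s, config) for s in val_samples]

    val_rng = np.random.default_rng([config.seed, 13])
    val_patches = [
        sample_random_patch(s, config.patch_size, val_rng)
        for s in val_samples
        for _ in range(config.patches_per_scan_per_epoch)
    ]

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    epoch_rng = np.random.default_rng([config.seed, 17])
    history = TrainingHistory()
    best_loss = np.inf
    best_state = model.state_dict()

    for _epoch in range(config.max_epochs):
        order = epoch_rng.permutation(len(train_samples))
        epoch_losses = []
        for i in order:
            sample = train_samples[i]
            for _ in range(config.patches_per_scan_per_epoch):
                pair = sample_random_patch(sample, config.patch_size, epoch_rng)
                pair = augment(pair, augment_config, epoch_rng)
                optimizer.zero_grad()
                loss = _patch_loss(model, pair, margin, train_mode=True)
                if config.learning_rate > 0:
                    optimizer.step()
                epoch_losses.append(loss)
        val_losses = [
            _patch_loss(model, pair, margin, train_mode=False) for pair in val_patches
        ]
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(float(np.mean(val_losses)))
        if history.val_loss[-1] < best_loss:
            best_loss = history.val_loss[-1]
            best_state = model.state_dict()
        stop, _reason = convergence_check(history, config)
        if stop:
            break

    model.load_state_dict(best_state)
    return model, history
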