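"""Airway extraction from a trained model: sliding-window prediction
with overlap averaging, lung masking, thresholding, central-airway
merge and largest-connected-component post-processing.

Full volumes are tiled into overlapping patches (50% overlap by
default). Each patch passes through the network; because the first
levels use valid convolutions the predicted patch is smaller than its
input window, and it is placed at the centered sub-window of the input
window. Aggregated probabilities are divided voxelwise by the number
of contributing patches. To guarantee that every original voxel is
covered by some output footprint, the volume is reflect-padded by the
network margin before planning.

The binary airway tree is then obtained by (1) masking the probability
map to the lung fields, (2) thresholding (0.5 by default; 0.1 in EXACT
mode), (3) merging with a trachea + main-bronchi mask, and (4) keeping
the largest connected component (26-connectivity by default; 6 in
EXACT mode).

The lung-field and central-airway masks can come from ground truth or
from the simplified intensity-based region-growing segmenters included
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid, normalize_intensity

__all__ = [
    "PatchWindow",
    "SlidingWindowPlan",
    "AggregationState",
    "plan_sliding_windows",
    "predict_volume",
    "predict_probability",
    "segment_lungs",
    "segment_central_airways",
    "extract_airway_tree",
]

EXACT_MODE_THRESHOLD = 0.1
EXACT_MODE_CONNECTIVITY = 6
DEFAULT_THRESHOLD = 0.5
DEFAULT_CONNECTIVITY = 26


@dataclass(frozen=True)
class PatchWindow:
    """Axis-aligned half-open 3D crop: [corner, corner + size)."""

    corner: Tuple[int, int, int]
    size: Tuple[int, int, int]

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(c, c + s) for c, s in zip(self.corner, self.size))


@dataclass
class SlidingWindowPlan:
    """The tiling of one volume into overlapping patch windows."""

    volume_shape: Tuple[int, int, int]
    patch_size: Tuple[int, int, int]
    overlap: float
    windows: List[PatchWindow]
    padded: bool = False  # patch exceeded the volume; caller must pad


def plan_sliding_windows(
    volume_shape: Sequence[int], patch_size: Sequence[int], overlap: float = 0.5
) -> SlidingWindowPlan:
    """Tile a volume with windows at stride ``floor(patch * (1-overlap))``.

    Corners advance from 0 at the regular stride; when the last regular
    window would overrun, a final corner clamped to ``volume - patch``
    is appended, so the plan covers every voxel. If the patch exceeds
    the volume along any axis, a single window is returned with the
    ``padded`` flag set and the caller is expected to pad.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must lie in [0, 1), got {overlap}")
    volume_shape = tuple(int(s) for s in volume_shape)
    patch_size = tuple(int(p) for p in patch_size)
    if any(p > s for p, s in zip(patch_size, volume_shape)):
        return SlidingWindowPlan(
            volume_shape,
            patch_size,
            overlap,
            [PatchWindow((0, 0, 0), patch_size)],
            padded=True,
        )
    per_axis: List[List[int]] = []
    for s, p in zip(volume_shape, patch_size):
        stride = max(1, int(np.floor(p * (1.0 - overlap))))
        corners = list(range(0, s - p + 1, stride))
        if corners[-1] != s - p:
            corners.append(s - p)
        per_axis.append(corners)
    windows = [
        PatchWindow((cz, cy, cx), patch_size)
        for cz in per_axis[0]
        for cy in per_axis[1]
        for cx in per_axis[2]
    ]
    return SlidingWindowPlan(volume_shape, patch_size, overlap, windows)


@dataclass
class AggregationState:
    """Voxelwise probability accumulator and patch-count grid."""

    accumulator: np.ndarray
    counts: np.ndarray

    @classmethod
    def for_shape(cls, shape: Sequence[int]) -> "AggregationState":
        return cls(
            np.zeros(tuple(shape), dtype=np.float32),
            np.zeros(tuple(shape), dtype=np.int32),
        )

    def add(self, corner: Sequence[int], patch: np.ndarray) -> None:
        window = tuple(slice(c, c + s) for c, s in zip(corner, patch.shape))
        self.accumulator[window] += patch
        self.counts[window] += 1

    def finalize(self) -> np.ndarray:
        """Divide by counts on covered voxels (counts >= 1 there)."""
        covered = self.counts > 0
        out = np.zeros_like(self.accumulator)
        out[covered] = self.accumulator[covered] / self.counts[covered]
        return out


def predict_volume(
    model,
    image: VolumeGrid,
    plan: Optional[SlidingWindowPlan] = None,
    overlap: float = 0.5,
    patch_size: Optional[Sequence[int]] = None,
) -> VolumeGrid:
    """Sliding-window prediction with count-normalized overlap averaging.

    ``model`` needs two methods: ``predict_patch(patch) -> prob_patch``
    and ``output_margin(input_shape) -> (mz, my, mx)`` giving the
    one-sided offset of the output inside the input window (zero for a
    size-preserving model). The image is reflect-padded by the margin
    so every original voxel falls in some output footprint; ``plan``,
    when given, must tile the padded shape.
    """
    if plan is not None:
        patch_size = plan.patch_size
    elif patch_size is None:
        patch_size = _default_patch_size(model, image)
    patch_size = tuple(int(p) for p in patch_size)
    margin = tuple(model.output_margin(patch_size))
    values = image.values.astype(np.float32)
    padded = np.pad(values, [(m, m) for m in margin], mode="reflect")
    if plan is None:
        plan = plan_sliding_windows(padded.shape, patch_size, overlap)
    elif tuple(plan.volume_shape) != padded.shape:
        raise ValueError(
            f"plan tiles {plan.volume_shape} but the padded volume is {padded.shape}"
        )
    if plan.padded:
        target = tuple(max(p, s) for p, s in zip(patch_size, padded.shape))
        pads = [( (t - s) // 2, (t - s) - (t - s) // 2) for t, s in zip(target, padded.shape)]
        padded = np.pad(padded, pads, mode="reflect")
        inner = tuple(slice(p[0], p[0] + s) for p, s in zip(pads, plan.volume_shape))
        plan = plan_sliding_windows(padded.shape, patch_size, overlap)
    else:
        inner = None

    out_size = tuple(p - 2 * m for p, m in zip(patch_size, margin))
    for s, o in zip(
        [max(1, int(np.floor(p * (1.0 - plan.overlap)))) for p in patch_size], out_size
    ):
        if s > o:
            raise ValueError(
                "sliding-window stride exceeds the network output size; "
                "increase the overlap or the patch size"
            )
    state = AggregationState.for_shape(padded.shape)
    for window in plan.windows:
        patch = padded[window.slices]
        pred = model.predict_patch(patch)
        out_corner = tuple(c + m for c, m in zip(window.corner, margin))
        state.add(out_corner, pred)
    prob = state.finalize()
    if inner is not None:
        prob = prob[inner]
    crop = tuple(slice(m, m + s) for m, s in zip(margin, values.shape))
    return VolumeGrid(np.clip(prob[crop], 0.0, 1.0), image.spacing)


def _default_patch_size(model, image: VolumeGrid) -> Tuple[int, int, int]:
    size = getattr(model, "patch_size", None)
    if size is None:
        raise ValueError("no plan given and the model declares no patch_size")
    return tuple(size)


def predict_probability(
    model,
    image: VolumeGrid,
    patch_size: Sequence[int],
    overlap: float = 0.5,
    intensity_window=None,
) -> VolumeGrid:
    """Normalize intensities, then run :func:`predict_volume`."""
    from .grid import DEFAULT_INTENSITY_WINDOW

    window = intensity_window or DEFAULT_INTENSITY_WINDOW
    norm = VolumeGrid(normalize_intensity(image.values, window), image.spacing)
    _size = tuple(int(p) for p in patch_size)

    class _Wrapper:
        patch_size = _size

        @staticmethod
        def predict_patch(patch):
            return model.predict_patch(patch)

        @staticmethod
        def output_margin(shape):
            return model.output_margin(shape)

    return predict_volume(_Wrapper, norm, overlap=overlap)


# ---------------------------------------------------------------------------
# simplified region-growing segmenters (lungs, central airways)
# ---------------------------------------------------------------------------

def segment_lungs(
    image: VolumeGrid,
    air_threshold: float = -700.0,
    min_component_fraction: float = 5e-4,
    closing_radius: int = 2,
) -> VolumeGrid:
    """Threshold-based lung-field segmentation.

    Voxels below ``air_threshold`` are grouped into connected
    components; components touching a lateral (y or x) image border and
    components smaller than ``min_component_fraction`` of the volume
    are discarded; the rest are morphologically closed and hole-filled.
    """
    values = image.values
    mask = values < air_threshold
    if not mask.any():
        warnings.warn("segment_lungs: no voxels below the air threshold")
        return image.with_values(np.zeros_like(values, dtype=np.uint8))
    labels, n = ndimage.label(mask)
    if n == 0:
        warnings.warn("segment_lungs: no air-like component found")
        return image.with_values(np.zeros_like(values, dtype=np.uint8))
    border_labels = set()
    for lbl_slice in (
        labels[:, 0, :], labels[:, -1, :], labels[:, :, 0], labels[:, :, -1]
    ):
        border_labels |= set(np.unique(lbl_slice))
    border_labels.discard(0)
    sizes = np.bincount(labels.ravel())
    min_size = min_component_fraction * values.size
    keep = np.zeros(n + 1, dtype=bool)
    for lbl in range(1, n + 1):
        keep[lbl] = lbl not in border_labels and sizes[lbl] >= min_size
    lungs = keep[labels]
    if not lungs.any():
        warnings.warn("segment_lungs: all air components rejected")
        return image.with_values(lungs.astype(np.uint8))
    if closing_radius > 0:
        ball = _ball(closing_radius)
        lungs = ndimage.binary_closing(lungs, structure=ball)
    lungs = ndimage.binary_fill_holes(lungs)
    return image.with_values(lungs.astype(np.uint8))


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return (zz ** 2 + yy ** 2 + xx ** 2) <= r ** 2


class SeedNotFoundError(ValueError):
    """No suitable dark tubular cross-section found near the top slices."""


def _find_trachea_seed(values: np.ndarray, air_threshold: float):
    """Most superior dark, roughly circular cross-section."""
    depth = values.shape[0]
    slice_area = values.shape[1] * values.shape[2]
    for z in range(0, max(1, depth // 3)):
        dark = values[z] < air_threshold
        labels, n = ndimage.label(dark)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())
        for lbl in range(1, n + 1):
            size = sizes[lbl]
            if not (3 <= size <= 0.05 * slice_area):
                continue
            ys, xs = np.nonzero(labels == lbl)
            dy, dx = np.ptp(ys) + 1, np.ptp(xs) + 1
            bbox_area = dy * dx
            extent_ratio = dy / dx
            if size / bbox_area >= 0.5 and 0.33 <= extent_ratio <= 3.0:
                return (z, int(round(ys.mean())), int(round(xs.mean())))
    return None


def segment_central_airways(
    image: VolumeGrid,
    seed_point: Optional[Tuple[int, int, int]] = None,
    air_threshold: float = -925.0,
    max_volume_fraction: float = 0.05,
    threshold_step: float = 25.0,
    max_backtracks: int = 8,
) -> VolumeGrid:
    """Region-grow the trachea + main bronchi from a superior seed.

    26-connected growing over voxels below an intensity threshold,
    started from the most superior dark circular cross-section (or the
    given seed). If the grown region explodes beyond
    ``max_volume_fraction`` of the volume, the threshold is backtracked
    (lowered) and growing restarts.
    """
    values = image.values
    if seed_point is None:
        seed_point = _find_trachea_seed(values, air_threshold)
        if seed_point is None:
            raise SeedNotFoundError(
                "no trachea-like dark cross-section found near the top slices; "
                "pass seed_point explicitly"
            )
    seed_point = tuple(int(c) for c in seed_point)
    if values[seed_point] >= air_threshold:
        raise ValueError(
            f"seed {seed_point} has intensity {values[seed_point]:.0f}, not below "
            f"the air threshold {air_threshold:.0f} (seed must be in the lumen)"
        )
    structure = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    threshold = air_threshold
    best = None
    for _ in range(max_backtracks + 1):
        mask = values < threshold
        labels, _n = ndimage.label(mask, structure=structure)
        lbl = labels[seed_point]
        if lbl == 0:
            break
        region = labels == lbl
        if region.sum() <= max_volume_fraction * values.size:
            best = region
            break
        threshold -= threshold_step
        best = None
    if best is None:
        warnings.warn(
            "segment_central_airways: volume-explosion guard exhausted; "
            "returning the seed voxel only"
        )
        best = np.zeros_like(values, dtype=bool)
        best[seed_point] = True
    return image.with_values(best.astype(np.uint8))


# ---------------------------------------------------------------------------
# post-processing into a single airway tree
# ---------------------------------------------------------------------------

def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def extract_airway_tree(
    prob: VolumeGrid,
    lung_mask: VolumeGrid,
    central_mask: VolumeGrid,
    threshold: float = DEFAULT_THRESHOLD,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> VolumeGrid:
    """Probability map -> single connected binary airway tree.

    Steps: mask probabilities to the lung fields; binarize at
    ``threshold``; merge with the central-airway (trachea + main
    bronchi) mask in full; keep the largest connected component at the
    requested connectivity. Ties between equal-size largest components
    prefer the one containing a central-mask voxel, then the lowest
    lexicographic corner.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    structure = _connectivity_structure(connectivity)
    masked = prob.values * (lung_mask.values > 0)
    binary = (masked >= threshold) | (central_mask.values > 0)
    if not binary.any():
        warnings.warn("extract_airway_tree: empty segmentation")
        return prob.with_values(binary.astype(np.uint8))
    labels, n = ndimage.label(binary, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    max_size = sizes.max()
    candidates = np.flatnonzero(sizes == max_size)
    if len(candidates) > 1:
        central = central_mask.values > 0
        with_central = [c for c in candidates if (labels[central] == c).any()]
        if with_central:
            candidates = with_central
        else:
            flat = labels.ravel()
            candidates = sorted(
                candidates, key=lambda c: int(np.argmax(flat == c))
            )
    tree = labels == candidates[0]
    return prob.with_values(tree.astype(np.uint8))
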