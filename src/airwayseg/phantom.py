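"""Synthetic branching-tube CT phantoms with exact ground truth.

Emulates the image content the airway-segmentation method relies on: a
binary tree of tubes with per-generation decreasing radii, a dark lumen
(air) enclosed by a brighter wall, dark noisy parenchyma inside the
lung fields, brighter soft tissue outside them, optional bright
vessel-like tubes, and a lung-field mask that excludes the tree root
(the trachea analogue). Every phantom carries its exact lumen mask and
generative centerline, so training, inference and evaluation can all be
exercised without any external data.

Intensities are abstract HU-like numbers chosen to match the
qualitative CT contrast (air around -1000, parenchyma around -850,
airway wall and soft tissue much brighter); no scanner physics is
simulated. Geometry is likewise schematic: capsules (cylinders with
spherical caps) rasterized by a per-voxel distance-to-segment test,
which keeps bifurcation junctions gap-free.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .grid import VolumeGrid, read_volume, write_volume

__all__ = [
    "BranchSegment",
    "PhantomConfig",
    "AirwayPhantom",
    "PhantomConfigError",
    "generate_tree_skeleton",
    "rasterize_phantom",
    "generate_phantom",
    "save_phantom",
    "load_phantom",
]


class PhantomConfigError(ValueError):
    """Configuration cannot produce a valid phantom (e.g. volume too small)."""


@dataclass
class BranchSegment:
    """One straight tube of the airway tree, in voxel coordinates (z, y, x)."""

    start_point: np.ndarray
    end_point: np.ndarray
    radius: float
    wall_thickness: float
    parent_index: Optional[int]
    generation: int

    def __post_init__(self) -> None:
        self.start_point = np.asarray(self.start_point, dtype=float)
        self.end_point = np.asarray(self.end_point, dtype=float)
        if self.radius <= 0:
            raise ValueError("segment radius must be > 0")
        if self.wall_thickness < 0:
            raise ValueError("wall_thickness must be >= 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end_point - self.start_point))


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters; identical (config, seed) gives a bit-identical phantom.

    ``root_length`` is the trachea-analogue length in voxels; when None
    it defaults to 22% of the volume's z extent. ``intensity_body`` is
    the soft-tissue value painted outside the lung fields, which gives
    the intensity-based lung segmentation something to separate.
    """

    volume_shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_generations: int = 4
    root_radius: float = 4.0
    radius_ratio: float = 0.75
    length_ratio: float = 0.7
    root_length: Optional[float] = None
    branch_angle_deg: float = 35.0
    wall_thickness: float = 1.5
    intensity_lumen: float = -1000.0
    intensity_wall: float = -200.0
    intensity_parenchyma: float = -850.0
    intensity_vessel: float = 50.0
    intensity_body: float = 0.0
    noise_sigma: float = 25.0
    n_vessels: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise PhantomConfigError(f"volume_shape too small: {self.volume_shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomConfigError("spacing must be positive")
        if self.n_generations < 1:
            raise PhantomConfigError("n_generations must be >= 1")
        if self.root_radius <= 0:
            raise PhantomConfigError("root_radius must be > 0")
        if not 0 < self.radius_ratio < 1:
            raise PhantomConfigError("radius_ratio must be in (0, 1)")
        if not 0 < self.length_ratio < 1:
            raise PhantomConfigError("length_ratio must be in (0, 1)")
        if self.intensity_lumen >= self.intensity_wall:
            raise PhantomConfigError("lumen must be darker than wall")
        if self.noise_sigma < 0 or self.n_vessels < 0:
            raise PhantomConfigError("noise_sigma and n_vessels must be >= 0")

    @property
    def effective_root_length(self) -> float:
        if self.root_length is not None:
            return float(self.root_length)
        return 0.22 * self.volume_shape[0]


@dataclass
class AirwayPhantom:
    """Paired image + exact ground truth, all on one grid."""

    image: VolumeGrid
    lumen_mask: VolumeGrid
    centerline_mask: VolumeGrid
    lung_mask: VolumeGrid
    root_mask: VolumeGrid
    segments: List[BranchSegment] = field(default_factory=list)

    def grids(self):
        return (
            self.image,
            self.lumen_mask,
            self.centerline_mask,
            self.lung_mask,
            self.root_mask,
        )


# ---------------------------------------------------------------------------
# skeleton generation
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _perpendicular(d: np.ndarray, azimuth: float) -> np.ndarray:
    """Unit vector perpendicular to d, at the given azimuth around it."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, ref))
    w = np.cross(d, u)
    return np.cos(azimuth) * u + np.sin(azimuth) * w


def generate_tree_skeleton(config: PhantomConfig) -> List[BranchSegment]:
    """Grow a full binary tree of segments, root along the z (superior-
    inferior) axis, bifurcation directions jittered by the seeded rng.

    Per-generation radii follow ``root_radius * radius_ratio**g`` and
    lengths ``root_length * length_ratio**g``. Segment endpoints are
    kept inside the volume with a margin of radius + wall + 1.
    """
    rng = np.random.default_rng([config.seed, 101])
    shape = np.asarray(config.volume_shape, dtype=float)
    root_len = config.effective_root_length
    margin0 = config.root_radius + config.wall_thickness + 1.0
    start = np.array([2.0 + margin0 * 0.5, shape[1] / 2.0, shape[2] / 2.0])
    if start[0] + root_len + margin0 >= shape[0] or 2 * margin0 >= min(shape[1:]):
        raise PhantomConfigError(
            f"volume {config.volume_shape} too small for root segment "
            f"(length {root_len:.1f}, radius {config.root_radius})"
        )
    root = BranchSegment(
        start_point=start,
        end_point=start + np.array([root_len, 0.0, 0.0]),
        radius=config.root_radius,
        wall_thickness=config.wall_thickness,
        parent_index=None,
        generation=0,
    )
    segments = [root]
    frontier = [(0, np.array([1.0, 0.0, 0.0]))]  # (segment index, direction)
    theta0 = np.deg2rad(config.branch_angle_deg)
    for gen in range(1, config.n_generations):
        new_frontier = []
        for parent_idx, d in frontier:
            parent = segments[parent_idx]
            radius = config.root_radius * config.radius_ratio ** gen
            length = root_len * config.length_ratio ** gen
            margin = radius + config.wall_thickness + 1.0
            if gen == 1:
                # main bronchi split laterally (x axis) so the two lungs separate
                azimuths = [0.0, np.pi]
                perp_base = np.array([0.0, 0.0, 1.0])
            else:
                phi = rng.uniform(0, 2 * np.pi)
                azimuths = [phi, phi + np.pi]
                perp_base = None
            for az in azimuths:
                theta = theta0 * (1.0 + rng.uniform(-0.25, 0.25))
                if perp_base is not None:
                    perp = np.cos(az) * perp_base + np.sin(az) * _unit(
                        np.cross(d, perp_base)
                    )
                else:
                    perp = _perpendicular(d, az)
                child_dir = _unit(np.cos(theta) * d + np.sin(theta) * perp)
                end = parent.end_point + length * child_dir
                end = np.clip(end, margin, shape - 1.0 - margin)
                seg = BranchSegment(
                    start_point=parent.end_point.copy(),
                    end_point=end,
                    radius=radius,
                    wall_thickness=config.wall_thickness,
                    parent_index=parent_idx,
                    generation=gen,
                )
                segments.append(seg)
                new_frontier.append((len(segments) - 1, _unit(end - parent.end_point)))
        frontier = new_frontier
    return segments


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _segment_distance_field(
    seg_start: np.ndarray, seg_end: np.ndarray, radius: float, shape: Sequence[int]
):
    """Distance from voxel centers to the segment axis, inside a local bbox.

    Returns (slices, dist) where ``dist`` covers the bbox given by
    ``slices``; voxels outside the bbox are farther than ``radius``.
    """
    lo = np.floor(np.minimum(seg_start, seg_end) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(seg_start, seg_end) + radius + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape))
    if np.any(hi <= lo):
        return None, None
    axes = [np.arange(lo[i], hi[i], dtype=float) for i in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    ab = seg_end - seg_start
    denom = float(ab @ ab)
    if denom == 0.0:
        dist = np.linalg.norm(pts - seg_start, axis=-1)
    else:
        t = np.clip(((pts - seg_start) @ ab) / denom, 0.0, 1.0)
        proj = seg_start + t[..., None] * ab
        dist = np.linalg.norm(pts - proj, axis=-1)
    slc = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    return slc, dist


def _paint_capsules(
    segments: List[BranchSegment], shape, radius_fn
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for seg in segments:
        r = radius_fn(seg)
        slc, dist = _segment_distance_field(seg.start_point, seg.end_point, r, shape)
        if slc is None:
            continue
        mask[slc] |= dist <= r
    return mask


def _rasterize_centerline(segments: List[BranchSegment], shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for seg in segments:
        n = max(2, int(np.ceil(seg.length / 0.25)) + 1)
        t = np.linspace(0.0, 1.0, n)
        pts = seg.start_point[None] + t[:, None] * (seg.end_point - seg.start_point)[None]
        idx = np.round(pts).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return mask


def _ellipsoid_mask(center, semi_axes, shape) -> np.ndarray:
    axes = [np.arange(shape[i], dtype=float) for i in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    q = (
        ((zz - center[0]) / semi_axes[0]) ** 2
        + ((yy - center[1]) / semi_axes[1]) ** 2
        + ((xx - center[2]) / semi_axes[2]) ** 2
    )
    return q <= 1.0


def _covering_ellipsoid(points: np.ndarray, shape) -> np.ndarray:
    """Ellipsoid containing all given points, clipped to the volume grid."""
    center = (points.min(axis=0) + points.max(axis=0)) / 2.0
    half = np.maximum((points.max(axis=0) - points.min(axis=0)) / 2.0, 2.0)
    # scale semi-axes until every point satisfies the ellipsoid inequality
    q = np.sqrt((((points - center) / half) ** 2).sum(axis=1)).max()
    semi = half * max(q, 1.0) * 1.1 + 1.0
    return _ellipsoid_mask(center, semi, shape)


def _capsule_extreme_points(segments: List[BranchSegment]) -> np.ndarray:
    """Endpoint +- (radius+wall+1) offsets along each axis, per segment."""
    pts = []
    eye = np.eye(3)
    for seg in segments:
        m = seg.radius + seg.wall_thickness + 1.0
        for p in (seg.start_point, seg.end_point):
            for ax in range(3):
                pts.append(p + m * eye[ax])
                pts.append(p - m * eye[ax])
    return np.asarray(pts)


def rasterize_phantom(
    segments: List[BranchSegment], config: PhantomConfig
) -> AirwayPhantom:
    """Paint the tree into intensity and ground-truth volumes.

    The lung field is built from two ellipsoids (one per lateral half;
    a single ellipsoid when the tree does not split) grown to contain
    every non-root segment capsule, with the root capsule carved out so
    the ROI excludes the trachea analogue.
    """
    if not segments:
        raise ValueError("segments must be non-empty")
    shape = tuple(config.volume_shape)
    rng = np.random.default_rng([config.seed, 202])

    lumen = _paint_capsules(segments, shape, lambda s: s.radius)
    outer = _paint_capsules(
        segments, shape, lambda s: s.radius + s.wall_thickness
    )
    wall = outer & ~lumen
    centerline = _rasterize_centerline(segments, shape) & lumen

    root = segments[0]
    root_capsule = _paint_capsules([root], shape, lambda s: s.radius + s.wall_thickness)

    # lung fields: covering ellipsoids over the non-root capsules
    non_root = [s for s in segments if s.parent_index is not None]
    lung = np.zeros(shape, dtype=bool)
    if non_root:
        pts = _capsule_extreme_points(non_root)
        x_mid = shape[2] / 2.0
        left = pts[pts[:, 2] <= x_mid + 1]
        right = pts[pts[:, 2] >= x_mid - 1]
        if min(shape) >= 48 and len(left) and len(right):
            lung = _covering_ellipsoid(left, shape) | _covering_ellipsoid(right, shape)
        else:
            lung = _covering_ellipsoid(pts, shape)
    else:  # single-segment tree: a lung field around (but excluding) the root
        pad = root.radius + root.wall_thickness + 6.0
        pts = np.array([root.start_point - pad, root.end_point + pad])
        lung = _covering_ellipsoid(pts, shape)
    lung &= ~root_capsule
    # the trachea + main-bronchi analogue is the extrapulmonary lumen:
    # everything of the airway lumen that the lung field does not cover
    # (the root tube plus the carved-out start of the main bronchi).
    # Defined this way it is voxel-adjacent to the in-lung lumen, so
    # merging it with an in-lung prediction yields a connected tree.
    root_mask = lumen & ~lung

    image = np.full(shape, config.intensity_body, dtype=np.float32)
    image[lung] = config.intensity_parenchyma

    # bright vessel-like tubes inside the lung, never overlapping the airways
    airway = outer
    for _ in range(config.n_vessels):
        lung_idx = np.argwhere(lung)
        if not len(lung_idx):
            break
        start = lung_idx[rng.integers(len(lung_idx))].astype(float)
        direction = _unit(rng.normal(size=3))
        length = 0.4 * shape[0] * rng.uniform(0.5, 1.0)
        end = np.clip(start + length * direction, 1, np.asarray(shape, float) - 2)
        r = rng.uniform(1.0, 2.2)
        slc, dist = _segment_distance_field(start, end, r, shape)
        if slc is None:
            continue
        vessel = (dist <= r) & ~airway[slc]
        image[slc][vessel] = config.intensity_vessel

    image[wall] = config.intensity_wall
    image[lumen] = config.intensity_lumen
    if config.noise_sigma > 0:
        image += rng.normal(0.0, config.noise_sigma, size=shape).astype(np.float32)

    sp = config.spacing
    as_grid = lambda arr, dt: VolumeGrid(arr.astype(dt), sp)
    return AirwayPhantom(
        image=as_grid(image, np.float32),
        lumen_mask=as_grid(lumen, np.uint8),
        centerline_mask=as_grid(centerline, np.uint8),
        lung_mask=as_grid(lung, np.uint8),
        root_mask=as_grid(root_mask, np.uint8),
        segments=segments,
    )


def generate_phantom(config: PhantomConfig) -> AirwayPhantom:
    """Skeleton + rasterization in one call (fully determined by config)."""
    return rasterize_phantom(generate_tree_skeleton(config), config)


# ---------------------------------------------------------------------------
# on-disk layout: five NIfTI volumes + a YAML manifest
# ---------------------------------------------------------------------------

_GRID_NAMES = ("image", "lumen", "centerline", "lungs", "root")


def save_phantom(phantom: AirwayPhantom, out_dir, name: str, config: PhantomConfig) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for grid, suffix in zip(phantom.grids(), _GRID_NAMES):
        write_volume(grid, out_dir / f"{name}_{suffix}.nii.gz")
    manifest = {"name": name, "config": dataclasses.asdict(config)}
    with open(out_dir / f"{name}_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def load_phantom(out_dir, name: str) -> AirwayPhantom:
    out_dir = Path(out_dir)
    grids = [read_volume(out_dir / f"{name}_{suffix}.nii.gz") for suffix in _GRID_NAMES]
    return AirwayPhantom(*grids)
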