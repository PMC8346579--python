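"""Volumetric grids and file I/O.

The internal convention throughout the package is: 3D arrays indexed
``(z, y, x)`` (superior-inferior first), 0-based, with half-open crop
windows, and voxel spacing stored as a millimetre triple in the same
``(z, y, x)`` order. SimpleITK uses ``(x, y, z)`` for spacing, so the
readers/writers reverse it at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeGrid",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "normalize_intensity",
]

#: Default intensity window (HU-like) used to rescale images to [0, 1]
#: before they enter the network.
DEFAULT_INTENSITY_WINDOW: Tuple[float, float] = (-1000.0, 500.0)

_KNOWN_EXTENSIONS = (".nii", ".nii.gz", ".mhd", ".mha")


class VolumeIOError(ValueError):
    """Raised for unreadable paths, unknown formats or non-3D images."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing.

    Parameters
    ----------
    values:
        3D array, axes ordered ``(z, y, x)``. Depending on role the
        values are intensities, probabilities in [0, 1], or binary {0, 1}.
    spacing:
        Voxel spacing in mm, ``(z, y, x)`` order, all entries > 0.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeIOError(
                f"VolumeGrid requires a 3D array, got shape {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def astype(self, dtype) -> "VolumeGrid":
        return VolumeGrid(self.values.astype(dtype), self.spacing)

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """Same grid geometry, new voxel values."""
        return VolumeGrid(values, self.spacing)

    def same_grid_as(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _KNOWN_EXTENSIONS):
        raise VolumeIOError(
            f"unknown volume format for '{path}': expected one of {_KNOWN_EXTENSIONS}"
        )


def read_volume(path) -> VolumeGrid:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) volume.

    Values and spacing round-trip bit-exactly for integer masks. The
    array is returned in the internal (z, y, x) axis order.
    """
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise VolumeIOError(f"volume file not found: {path}")
    try:
        image = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # corrupt header etc.
        raise VolumeIOError(f"could not read '{path}': {exc}") from exc
    if image.GetDimension() != 3:
        raise VolumeIOError(
            f"'{path}' is {image.GetDimension()}D with size {image.GetSize()}; "
            "only 3D volumes are supported"
        )
    values = sitk.GetArrayFromImage(image)  # (z, y, x)
    spacing = tuple(reversed(image.GetSpacing()))  # sitk is (x, y, z)
    return VolumeGrid(values, spacing)


def write_volume(grid: VolumeGrid, path) -> None:
    """Write a volume as NIfTI or MetaImage, recording spacing in the header."""
    path = Path(path)
    _check_extension(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    image = sitk.GetImageFromArray(np.ascontiguousarray(grid.values))
    image.SetSpacing(tuple(reversed(grid.spacing)))
    sitk.WriteImage(image, str(path))


def normalize_intensity(
    values: np.ndarray,
    window: Tuple[float, float] = DEFAULT_INTENSITY_WINDOW,
) -> np.ndarray:
    """Clip intensities to ``window`` and rescale linearly to [0, 1].

    Applied to every image before it enters the network, both during
    training and inference, so the model sees a fixed input range.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"invalid intensity window {window}")
    out = np.clip(values.astype(np.float32), lo, hi)
    out -= lo
    out /= hi - lo
    return out
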