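"""Core in-memory containers for EM volumes.

All volumetric arrays use (z, y, x) axis order with 0-based indices; the slice
index is z.  Physical voxel spacing is carried alongside the array as
(sz, sy, sx) in nanometres.  The default spacing corresponds to serial-section
SEM acquisition at 6 nm per pixel in-plane and 30 nm section thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: (sz, sy, sx) in nanometres, used when a volume carries no metadata.
DEFAULT_SPACING: tuple[float, float, float] = (30.0, 6.0, 6.0)


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive numbers, got {spacing!r}")
    return spacing


@dataclass
class ImageStack:
    """A grayscale or RGB intensity volume.

    ``voxels`` has shape (z, y, x) for single-channel data or (z, y, x, 3)
    for RGB, with an 8-bit or 16-bit unsigned dtype.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = field(default=DEFAULT_SPACING)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError("ImageStack.voxels must be (z,y,x) or (z,y,x,3)")
        if self.voxels.ndim == 4 and self.voxels.shape[-1] != 3:
            raise ValueError("multi-channel stacks must have exactly 3 channels")
        if self.voxels.dtype not in (np.uint8, np.uint16):
            raise ValueError(
                f"ImageStack dtype must be uint8 or uint16, got {self.voxels.dtype}"
            )
        self.spacing = _check_spacing(self.spacing)

    @property
    def channels(self) -> int:
        return 1 if self.voxels.ndim == 3 else 3

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass
class LabelVolume:
    """A volume of nonnegative integer object ids; 0 is background.

    Ids need not be contiguous.  Stored as int32 (ids below 2^24 survive an
    RGB-packed PNG round trip; larger ids require TIFF or HDF5).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = field(default=DEFAULT_SPACING)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("LabelVolume.labels must be 3-D (z,y,x)")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("LabelVolume.labels must be integral")
        if labels.size and labels.min() < 0:
            raise ValueError("label ids must be nonnegative")
        self.labels = labels.astype(np.int32, copy=False)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ids(self) -> np.ndarray:
        """Sorted nonzero ids present in the volume."""
        u = np.unique(self.labels)
        return u[u != 0]


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities in [0, 1].

    ``values`` has shape (z, y, x) for a single class or (z, y, x, c).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = field(default=DEFAULT_SPACING)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float32)
        if values.ndim not in (3, 4):
            raise ValueError("ProbabilityMap.values must be (z,y,x[,c])")
        if values.size and (values.min() < -1e-6 or values.max() > 1 + 1e-6):
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = np.clip(values, 0.0, 1.0)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


@dataclass
class BinaryVolume:
    """A boolean foreground mask with the shape of its source volume."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = field(default=DEFAULT_SPACING)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError("BinaryVolume.mask must be 3-D (z,y,x)")
        self.mask = mask.astype(bool, copy=False)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape
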