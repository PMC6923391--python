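"""Read/write image stacks and label volumes (PNG, TIFF, HDF5).

Conventions
-----------
* A "stack path" is a directory of numbered slice files, a multipage TIFF, or
  an HDF5 file with a dataset named ``stack`` in (z, y, x) order.
* Slices in a directory are stacked in ascending order of the numeric part of
  their filenames (``slice0000.png`` .. ``slice0099.png``).
* Label images stored as 24-bit RGB pack the id little-endian in the channel
  order:  ``id = R + 256*G + 65536*B``.  Grayscale label images are taken
  verbatim (an 8-bit binary ground-truth mask therefore reads back with ids
  {0, 255}; use :func:`emseg.postprocess.binarize` to treat any value > 0 as
  foreground).
"""

from __future__ import annotations

import re
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .core import DEFAULT_SPACING, ImageStack, LabelVolume

_SLICE_EXTS = {".png", ".tif", ".tiff"}
_HDF5_EXTS = {".h5", ".hdf5"}

RGB_ID_LIMIT = 1 << 24


class FormatError(ValueError):
    """Unknown or unsupported file format."""


class DimensionMismatchError(ValueError):
    """Slices in a stack do not share height/width."""


def pack_rgb(ids: np.ndarray) -> np.ndarray:
    """Pack integer ids in [0, 2^24) into (..., 3) uint8 RGB, R least significant."""
    ids = np.asarray(ids)
    if ids.size and (ids.min() < 0 or ids.max() >= RGB_ID_LIMIT):
        raise ValueError(f"ids must lie in [0, {RGB_ID_LIMIT}) for RGB packing")
    ids = ids.astype(np.uint32)
    rgb = np.empty(ids.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = ids & 0xFF
    rgb[..., 1] = (ids >> 8) & 0xFF
    rgb[..., 2] = (ids >> 16) & 0xFF
    return rgb


def unpack_rgb(rgb: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_rgb`: (..., 3) uint8 → int32 ids."""
    rgb = np.asarray(rgb)
    if rgb.shape[-1] != 3:
        raise ValueError("expected trailing RGB axis of length 3")
    r = rgb[..., 0].astype(np.int32)
    g = rgb[..., 1].astype(np.int32)
    b = rgb[..., 2].astype(np.int32)
    return r + 256 * g + 65536 * b


def _numeric_key(p: Path):
    m = re.findall(r"\d+", p.stem)
    if not m:
        raise FormatError(f"slice filename {p.name!r} has no numeric index")
    return (int(m[-1]), p.name)


def _read_slice(path: Path) -> np.ndarray:
    ext = path.suffix.lower()
    if ext == ".png":
        arr = iio.imread(path)
    elif ext in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        raise FormatError(f"unsupported slice extension {ext!r}")
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr


def read_stack(
    path,
    kind: str = "image",
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
):
    """Read a stack from a directory, a (multipage) TIFF, or an HDF5 file.

    Parameters
    ----------
    path : str or Path
        Directory of slice files, multipage TIFF, or HDF5 file.
    kind : {"image", "label"}
        ``image`` returns :class:`ImageStack`; ``label`` returns
        :class:`LabelVolume` (RGB slices are decoded via the id packing).
    spacing : (sz, sy, sx), nm
    """
    if kind not in ("image", "label"):
        raise ValueError("kind must be 'image' or 'label'")
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTS),
            key=_numeric_key,
        )
        if not files:
            raise FormatError(f"no slice files found in {path}")
        slices = [_read_slice(p) for p in files]
        shapes = {s.shape[:2] for s in slices}
        if len(shapes) != 1:
            raise DimensionMismatchError(f"mixed slice dimensions: {sorted(shapes)}")
        arr = np.stack(slices, axis=0)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            arr = arr[None]
    elif path.suffix.lower() in _HDF5_EXTS:
        with h5py.File(path, "r") as f:
            if "stack" not in f:
                raise FormatError(f"{path} has no dataset named 'stack'")
            arr = f["stack"][()]
    elif not path.exists():
        raise FileNotFoundError(path)
    else:
        raise FormatError(f"unknown stack format {path.suffix!r}")

    if kind == "label":
        if arr.ndim == 4:
            arr = unpack_rgb(arr)
        return LabelVolume(arr.astype(np.int32), spacing)
    return ImageStack(arr, spacing)


def write_stack(volume, path, format: str = "png") -> list[str]:
    """Write a volume as numbered slices (png/tiff) or one HDF5 file.

    Returns the list of written file names.  ``read_stack`` on the output
    reproduces the volume bit-exactly.  Label ids above 255 are written as
    RGB-packed PNG or 32-bit TIFF; ids ≥ 2^24 cannot be PNG-packed.
    """
    if format not in ("png", "tiff", "hdf5"):
        raise FormatError(f"unknown output format {format!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    is_label = isinstance(volume, LabelVolume)
    arr = volume.labels if is_label else volume.voxels

    if format == "hdf5":
        fname = "stack.h5"
        with h5py.File(path / fname, "w") as f:
            f.create_dataset("stack", data=arr)
            f.attrs["spacing_nm"] = volume.spacing
        return [fname]

    if is_label:
        max_id = int(arr.max()) if arr.size else 0
        if format == "png":
            if max_id >= RGB_ID_LIMIT:
                raise ValueError(
                    f"label id {max_id} ≥ 2^24 cannot be packed into RGB PNG"
                )
            slices = pack_rgb(arr) if max_id > 255 else arr.astype(np.uint8)
        else:
            slices = arr.astype(np.int32)
    else:
        slices = arr

    ext = "png" if format == "png" else "tif"
    names = []
    for z in range(slices.shape[0]):
        name = f"slice{z:04d}.{ext}"
        sl = slices[z]
        if format == "png":
            iio.imwrite(path / name, sl, extension=".png")
        else:
            tifffile.imwrite(str(path / name), sl)
        names.append(name)
    return names
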