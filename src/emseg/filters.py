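"""Classic 2D/3D preprocessing filters, chainable in a single execution.

The catalog holds the filters an EM preprocessing pipeline typically needs
before CNN segmentation: ``gaussian``, ``median``, ``clahe``, ``invert`` and
``threshold``.  Filters operate slice-wise by default; a
:class:`FilterSpec` with ``dimensionality="3d"`` switches gaussian/median to a
true volumetric kernel.  Chains are applied left-to-right and are bit-identical
to applying each filter separately.

CLAHE
-----
Contrast-limited adaptive histogram equalization is implemented natively so
that its contract is explicit:

* the image is divided into a grid of ``block_size``-sized tiles;
* each tile's ``bins``-bin histogram is clipped at
  ``max_slope / bins`` of the tile's pixel mass (the "max slope" bounds the
  slope of the tile's transfer function, i.e. of the normalized CDF) and the
  excess is redistributed uniformly;
* per-tile equalization LUTs are bilinearly interpolated between tile centers
  (Zuiderveld's scheme), with reflect handling implicit in the equal-partition
  tiling;
* a single-valued tile has no contrast to redistribute and maps through the
  identity, so a constant slice is a fixed point of the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ImageStack


class CatalogError(ValueError):
    """Unknown filter name."""


class FilterParameterError(ValueError):
    """Invalid parameter for a registered filter."""


@dataclass
class FilterSpec:
    """One step of a filter chain."""

    name: str
    params: dict = field(default_factory=dict)
    dimensionality: str = "2d"

    def __post_init__(self) -> None:
        if self.dimensionality not in ("2d", "3d"):
            raise FilterParameterError("dimensionality must be '2d' or '3d'")


def _dtype_max(dtype) -> int:
    return int(np.iinfo(dtype).max)


# ---------------------------------------------------------------------------
# CLAHE


def _clahe_luts(img: np.ndarray, block_size: int, bins: int, max_slope: float):
    """Per-tile LUTs (ny, nx, bins) plus identity flags and tile centers."""
    h, w = img.shape
    vmax = _dtype_max(img.dtype)
    ny = max(1, int(np.ceil(h / block_size)))
    nx = max(1, int(np.ceil(w / block_size)))
    ye = np.linspace(0, h, ny + 1).astype(int)
    xe = np.linspace(0, w, nx + 1).astype(int)
    cy = (ye[:-1] + ye[1:] - 1) / 2.0
    cx = (xe[:-1] + xe[1:] - 1) / 2.0

    bin_idx = (img.astype(np.int64) * bins) // (vmax + 1)
    luts = np.empty((ny, nx, bins), dtype=np.float64)
    ident = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            tile = bin_idx[ye[i] : ye[i + 1], xe[j] : xe[j + 1]]
            area = tile.size
            hist = np.bincount(tile.ravel(), minlength=bins).astype(np.float64)
            if np.count_nonzero(hist) <= 1:
                ident[i, j] = True
                continue
            clip = max(1.0, max_slope * area / bins)
            excess = np.clip(hist - clip, 0, None).sum()
            hist = np.minimum(hist, clip) + excess / bins
            cdf = np.cumsum(hist)
            cdfmin = cdf[np.argmax(hist > 0)]
            denom = area - cdfmin
            if denom <= 0:
                ident[i, j] = True
                continue
            luts[i, j] = np.clip((cdf - cdfmin) / denom * vmax, 0, vmax)
    return luts, ident, cy, cx, bin_idx


def _interp_axis(coords: np.ndarray, centers: np.ndarray):
    """Lower/upper tile index and fractional weight per coordinate."""
    hi = np.clip(np.searchsorted(centers, coords), 0, len(centers) - 1)
    lo = np.clip(hi - 1, 0, len(centers) - 1)
    span = centers[hi] - centers[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(span > 0, (coords - centers[lo]) / np.where(span > 0, span, 1), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return lo, hi, frac


def clahe2d(img: np.ndarray, block_size: int, bins: int, max_slope: float) -> np.ndarray:
    """CLAHE on a single 2-D slice, preserving shape and dtype."""
    h, w = img.shape
    if block_size % 2 == 0 or block_size >= min(h, w):
        raise FilterParameterError(
            f"block_size must be odd and smaller than the image side, got "
            f"{block_size} for a {h}x{w} slice"
        )
    if bins < 2:
        raise FilterParameterError("bins must be ≥ 2")
    if max_slope < 1:
        raise FilterParameterError("max_slope must be ≥ 1")

    luts, ident, cy, cx, bin_idx = _clahe_luts(img, block_size, bins, max_slope)
    i0, i1, wy = _interp_axis(np.arange(h, dtype=float), cy)
    j0, j1, wx = _interp_axis(np.arange(w, dtype=float), cx)

    vals = img.astype(np.float64)
    out = np.zeros((h, w), dtype=np.float64)
    for ii, wi in ((i0, 1.0 - wy), (i1, wy)):
        for jj, wj in ((j0, 1.0 - wx), (j1, wx)):
            mapped = luts[ii[:, None], jj[None, :], bin_idx]
            idm = ident[ii[:, None], jj[None, :]]
            corner = np.where(idm, vals, mapped)
            out += wi[:, None] * wj[None, :] * corner
    return np.rint(out).clip(0, _dtype_max(img.dtype)).astype(img.dtype)


def apply_clahe(
    stack: ImageStack, block_size: int = 127, bins: int = 256, max_slope: float = 1.5
) -> ImageStack:
    """Slice-wise CLAHE with the standard EM preprocessing defaults
    (block size 127, 256 histogram bins, max slope 1.50)."""
    if stack.channels != 1:
        raise FilterParameterError("CLAHE requires a single-channel stack")
    out = np.stack(
        [clahe2d(sl, block_size, bins, max_slope) for sl in stack.voxels]
    )
    return ImageStack(out, stack.spacing)


# ---------------------------------------------------------------------------
# Catalog


def _f_gaussian(vol: np.ndarray, params: dict, dim: str) -> np.ndarray:
    sigma = float(params.get("sigma", 1.0))
    if sigma < 0:
        raise FilterParameterError("sigma must be ≥ 0")
    full_sigma = (0, sigma, sigma) if dim == "2d" else sigma
    out = ndimage.gaussian_filter(vol.astype(np.float64), full_sigma, mode="reflect")
    return np.rint(out).clip(0, _dtype_max(vol.dtype)).astype(vol.dtype)


def _f_median(vol: np.ndarray, params: dict, dim: str) -> np.ndarray:
    size = int(params.get("size", 3))
    if size < 1:
        raise FilterParameterError("size must be ≥ 1")
    full_size = (1, size, size) if dim == "2d" else size
    return ndimage.median_filter(vol, size=full_size, mode="reflect")


def _f_clahe(vol: np.ndarray, params: dict, dim: str) -> np.ndarray:
    block_size = int(params.get("block_size", 127))
    bins = int(params.get("bins", 256))
    max_slope = float(params.get("max_slope", 1.5))
    return np.stack([clahe2d(sl, block_size, bins, max_slope) for sl in vol])


def _f_invert(vol: np.ndarray, params: dict, dim: str) -> np.ndarray:
    return (_dtype_max(vol.dtype) - vol.astype(np.int64)).astype(vol.dtype)


def _f_threshold(vol: np.ndarray, params: dict, dim: str) -> np.ndarray:
    t = params.get("threshold", 128)
    vmax = _dtype_max(vol.dtype)
    return np.where(vol >= t, vmax, 0).astype(vol.dtype)


CATALOG = {
    "gaussian": _f_gaussian,
    "median": _f_median,
    "clahe": _f_clahe,
    "invert": _f_invert,
    "threshold": _f_threshold,
}


def apply_filter(stack: ImageStack, spec: FilterSpec) -> ImageStack:
    """Apply one registered filter to a stack."""
    if spec.name not in CATALOG:
        raise CatalogError(
            f"unknown filter {spec.name!r}; valid filters: {sorted(CATALOG)}"
        )
    if stack.channels != 1:
        raise FilterParameterError("filters operate on single-channel stacks")
    out = CATALOG[spec.name](stack.voxels, spec.params, spec.dimensionality)
    return ImageStack(out, stack.spacing)


def apply_filter_chain(stack: ImageStack, chain: list[FilterSpec]) -> ImageStack:
    """Apply an ordered filter chain left-to-right in one pass.

    Equivalent (bit-exactly) to applying each filter separately; an empty
    chain returns the input stack unchanged.
    """
    for spec in chain:
        stack = apply_filter(stack, spec)
    return stack
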