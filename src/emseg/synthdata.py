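"""Synthetic EM-like fixture volumes with aligned ground truth.

Two generators emulate the two canonical serial-section SEM segmentation
targets at desk scale:

* ``mitochondria`` — dark oval organelles (random 3-D ellipsoids, flattened in
  z to mimic anisotropic sectioning, with faint internal cristae-like
  stripes) scattered in a brighter textured cytosol;
* ``mosaic`` — a membrane-bounded cell tessellation: columnar cells from a
  seeded nearest-neighbour partition with mild per-slice drift, separated by
  thin dark membranes.

The intensity model (dark organelles/membranes on brighter cytosol plus
Gaussian noise) mimics SEM contrast qualitatively; no imaging physics,
section artifacts or alignment jitter are simulated.  Both generators are
bit-exactly reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DEFAULT_SPACING, ImageStack, LabelVolume


class PlacementError(RuntimeError):
    """Could not place all requested objects without overlap."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"placed only {achieved} of {requested} objects without overlap"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class SynthSpec:
    shape: tuple[int, int, int] = (20, 256, 256)
    mode: str = "mitochondria"
    n_objects: int = 15
    intensity_fg: float = 90.0
    intensity_bg: float = 170.0
    noise_sd: float = 8.0
    membrane_width: float = 2.0
    seed: int = 0
    spacing: tuple[float, float, float] = field(default=DEFAULT_SPACING)

    def __post_init__(self) -> None:
        if self.mode not in ("mitochondria", "mosaic"):
            raise ValueError("mode must be 'mitochondria' or 'mosaic'")
        if self.n_objects < 0:
            raise ValueError("n_objects must be ≥ 0")
        for v in (self.intensity_fg, self.intensity_bg):
            if not 0 <= v <= 255:
                raise ValueError("gray levels must lie in the 8-bit range")


def _ellipsoid_mask(shape, center, semiaxes, angle):
    """Boolean mask of a z-aligned ellipsoid rotated by ``angle`` in-plane."""
    az, ay, ax = semiaxes
    cz, cy, cx = center
    # bounding box with margin
    r = int(np.ceil(max(ay, ax))) + 2
    rzi = int(np.ceil(az)) + 2
    z0, z1 = max(0, int(cz) - rzi), min(shape[0], int(cz) + rzi + 1)
    y0, y1 = max(0, int(cy) - r), min(shape[1], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(shape[2], int(cx) + r + 1)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1) - cz,
        np.arange(y0, y1) - cy,
        np.arange(x0, x1) - cx,
        indexing="ij",
    )
    c, s = np.cos(angle), np.sin(angle)
    u = c * xx + s * yy
    v = -s * xx + c * yy
    q = (zz / az) ** 2 + (v / ay) ** 2 + (u / ax) ** 2
    box = q <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[z0:z1, y0:y1, x0:x1] = box
    return mask, (u, v, (z0, z1, y0, y1, x0, x1))


def gen_mitochondria(spec: SynthSpec) -> tuple[ImageStack, LabelVolume]:
    """Non-overlapping dark ellipsoids in textured cytosol, with ids 1..n."""
    if spec.mode != "mitochondria":
        raise ValueError("spec.mode must be 'mitochondria'")
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int32)
    occupied = np.zeros(spec.shape, dtype=bool)

    # textured cytosol: low-pass filtered noise around the background level
    texture = ndimage.gaussian_filter(
        rng.normal(0.0, 3.0 * spec.noise_sd + 1e-6, spec.shape), (0, 3, 3)
    )
    image = spec.intensity_bg + texture

    placed = 0
    for oid in range(1, spec.n_objects + 1):
        for _attempt in range(100):
            # flattened in z for thin stacks; fits inside the volume
            if nz >= 10:
                az = rng.uniform(2.0, min(max(2.5, nz / 5), (nz - 2) / 2))
            else:
                az = rng.uniform(0.6, max(0.7, min(2.0, (nz - 1) / 2)))
            ay = rng.uniform(5.0, max(6.0, ny / 18))
            ax = rng.uniform(5.0, max(6.0, nx / 18))
            cz = (nz - 1) / 2 if az >= nz - 1 - az else rng.uniform(az, nz - 1 - az)
            center = (
                cz,
                rng.uniform(ay + 2, ny - 3 - ay),
                rng.uniform(ax + 2, nx - 3 - ax),
            )
            angle = rng.uniform(0, np.pi)
            mask, (u, v, bbox) = _ellipsoid_mask(spec.shape, center, (az, ay, ax), angle)
            if not mask.any():
                continue
            # 2-voxel clearance so objects stay separate components
            grown = ndimage.binary_dilation(mask, iterations=2)
            if (grown & occupied).any():
                continue
            labels[mask] = oid
            occupied |= grown
            z0, z1, y0, y1, x0, x1 = bbox
            box = mask[z0:z1, y0:y1, x0:x1]
            # cristae-like stripes across the minor axis
            period = rng.uniform(3.0, 5.0)
            stripes = 10.0 * np.sin(2 * np.pi * v / period)
            region = image[z0:z1, y0:y1, x0:x1]
            region[box] = spec.intensity_fg + stripes[box]
            placed += 1
            break
        else:
            raise PlacementError(spec.n_objects, placed)

    image = image + rng.normal(0.0, spec.noise_sd, spec.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return ImageStack(image, spec.spacing), LabelVolume(labels, spec.spacing)


def gen_mosaic(spec: SynthSpec) -> tuple[ImageStack, LabelVolume]:
    """Columnar nearest-neighbour cell tessellation with dark membranes.

    Labels are cell ids 1..n with membrane voxels set to 0; each voxel's label
    is the id of the nearest generator point of its slice (membranes are the
    loci where the two nearest points are nearly equidistant).
    """
    if spec.mode != "mosaic":
        raise ValueError("spec.mode must be 'mosaic'")
    if spec.n_objects < 2:
        raise ValueError("mosaic needs n_objects ≥ 2")
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    pts = rng.uniform(0, 1, (spec.n_objects, 2)) * (ny, nx)
    drift = rng.normal(0.0, 0.5, (nz, spec.n_objects, 2)).cumsum(axis=0)

    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    labels = np.zeros(spec.shape, dtype=np.int32)
    membrane = np.zeros(spec.shape, dtype=bool)
    for z in range(nz):
        p = pts + drift[z]
        d2 = (yy[None] - p[:, 0, None, None]) ** 2 + (xx[None] - p[:, 1, None, None]) ** 2
        d = np.sqrt(d2)
        order = np.argsort(d, axis=0)
        d.sort(axis=0)
        labels[z] = order[0] + 1
        membrane[z] = (d[1] - d[0]) < spec.membrane_width
    labels[membrane] = 0

    cell_gain = rng.uniform(-10, 10, spec.n_objects + 1)
    cell_gain[0] = 0.0
    image = np.where(
        membrane,
        spec.intensity_fg,
        spec.intensity_bg + cell_gain[labels],
    )
    image = image + rng.normal(0.0, spec.noise_sd, spec.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return ImageStack(image, spec.spacing), LabelVolume(labels, spec.spacing)


def generate(spec: SynthSpec) -> tuple[ImageStack, LabelVolume]:
    """Dispatch on ``spec.mode``."""
    if spec.mode == "mitochondria":
        return gen_mitochondria(spec)
    return gen_mosaic(spec)
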