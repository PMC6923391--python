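"""Desk-scale flood-filling 3-D instance segmentation.

A flood-filling network (FFN) is a 3-D CNN that, given a field of view (FOV)
of image intensity plus the current soft object mask, re-predicts per-voxel
membership of the object centred in the FOV.  Inference grows one object at a
time: starting from a seed, the FOV repeatedly moves by ``delta`` toward faces
whose predicted membership exceeds ``move_threshold``, writing refreshed mask
probabilities into a canvas, until no moves remain; voxels at probability
≥ ``segment_threshold`` become the object.  Objects are grown in seed-policy
order with first-come priority on claimed voxels and no agglomeration
afterwards.

The pipeline has four stages mirroring a preprocessing/training/inference/
postprocessing workflow: :func:`partition_examples` (balanced training
coordinates), :func:`train_ffn`, :func:`flood_fill_segment`, and
:func:`ffn_postprocess` (id compaction plus a colored preview stack).

During training the predicted mask is fed back as the mask input channel for
a fixed number of refinement iterations; gradients are not propagated through
the feedback (each refinement is its own training example), which keeps the
memory footprint flat.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from . import nnet
from .core import ImageStack, LabelVolume
from .nnet import F32, sigmoid


@dataclass
class FfnConfig:
    fov: tuple[int, int, int] = (17, 17, 17)
    depth: int = 3
    channels: int = 12
    delta: tuple[int, int, int] = (4, 4, 4)
    seed_prob: float = 0.95
    move_threshold: float = 0.9
    segment_threshold: float = 0.6
    min_segment_size: int = 27
    steps: int = 500
    refine_iters: int = 2
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        self.fov = tuple(int(v) for v in self.fov)
        self.delta = tuple(int(v) for v in self.delta)
        if any(v % 2 == 0 or v < 3 for v in self.fov):
            raise ValueError("fov components must be odd and ≥ 3")
        if any(d >= f // 2 or d < 1 for d, f in zip(self.delta, self.fov)):
            raise ValueError("delta components must lie in [1, fov radius)")
        if not 0.5 < self.move_threshold < 1:
            raise ValueError("move_threshold must lie in (0.5, 1)")
        if not 0 < self.segment_threshold < 1:
            raise ValueError("segment_threshold must lie in (0, 1)")

    @property
    def radius(self) -> tuple[int, int, int]:
        return tuple(f // 2 for f in self.fov)


@dataclass
class TrainingCoordinate:
    center: tuple[int, int, int]
    object_id: int
    partition_class: int


@dataclass
class SegmentationCanvas:
    labels: np.ndarray
    probability: np.ndarray
    visited: np.ndarray

    @classmethod
    def allocate(cls, shape) -> "SegmentationCanvas":
        return cls(
            labels=np.zeros(shape, dtype=np.int32),
            probability=np.zeros(shape, dtype=F32),
            visited=np.zeros(shape, dtype=bool),
        )


# ---------------------------------------------------------------------------
# Stage 1: training-example partitioning


def _box_counts(binary: np.ndarray, fov) -> np.ndarray:
    """Exact count of true voxels in the centered fov box, via integral image."""
    ii = binary.astype(np.int64)
    for ax in range(3):
        ii = np.cumsum(ii, axis=ax)
    ii = np.pad(ii, [(1, 0)] * 3)
    out = np.zeros(binary.shape, dtype=np.int64)
    rz, ry, rx = (f // 2 for f in fov)
    nz, ny, nx = binary.shape
    z1, y1, x1 = nz - 2 * rz, ny - 2 * ry, nx - 2 * rx
    fz, fy, fx = 2 * rz + 1, 2 * ry + 1, 2 * rx + 1
    s = (
        ii[fz : fz + z1, fy : fy + y1, fx : fx + x1]
        - ii[0:z1, fy : fy + y1, fx : fx + x1]
        - ii[fz : fz + z1, 0:y1, fx : fx + x1]
        - ii[fz : fz + z1, fy : fy + y1, 0:x1]
        + ii[0:z1, 0:y1, fx : fx + x1]
        + ii[0:z1, fy : fy + y1, 0:x1]
        + ii[fz : fz + z1, 0:y1, 0:x1]
        - ii[0:z1, 0:y1, 0:x1]
    )
    out[rz : nz - rz, ry : ny - ry, rx : nx - rx] = s
    return out


def partition_examples(
    labels: LabelVolume,
    fov: tuple[int, int, int],
    n_classes: int = 8,
    seed: int = 0,
) -> list[TrainingCoordinate]:
    """Balanced training coordinates bucketed by local object fill fraction.

    For every voxel of a foreground object whose centered FOV fits inside the
    volume, the fraction of the FOV occupied by that object is bucketed into
    ``n_classes`` equal-width classes; an equal number of coordinates is then
    sampled per nonempty class (capped by availability) and shuffled.
    """
    arr = labels.labels
    if not (arr > 0).any():
        warnings.warn("label volume has no foreground; no coordinates", stacklevel=2)
        return []
    fov_vol = int(np.prod(fov))
    rz, ry, rx = (f // 2 for f in fov)
    nz, ny, nx = arr.shape
    if nz <= 2 * rz or ny <= 2 * ry or nx <= 2 * rx:
        warnings.warn("volume smaller than FOV; no coordinates", stacklevel=2)
        return []

    by_class: dict[int, list[tuple[tuple[int, int, int], int]]] = {}
    for oid in np.unique(arr[arr > 0]):
        counts = _box_counts(arr == oid, fov)
        valid = np.zeros(arr.shape, dtype=bool)
        valid[rz : nz - rz, ry : ny - ry, rx : nx - rx] = True
        centers = np.argwhere((arr == oid) & valid)
        for z, y, x in centers:
            frac = counts[z, y, x] / fov_vol
            cls = min(int(frac * n_classes), n_classes - 1)
            by_class.setdefault(cls, []).append(((int(z), int(y), int(x)), int(oid)))

    rng = np.random.default_rng(seed)
    n_per = min(len(v) for v in by_class.values())
    coords: list[TrainingCoordinate] = []
    for cls in sorted(by_class):
        pool = by_class[cls]
        idx = rng.choice(len(pool), size=n_per, replace=False)
        for i in idx:
            center, oid = pool[i]
            coords.append(TrainingCoordinate(center, oid, cls))
    rng.shuffle(coords)
    return coords


def save_coordinates(coords: list[TrainingCoordinate], path) -> None:
    """Write the coordinate table as HDF5 (datasets: centers Nx3, ids N, classes N)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("centers", data=np.array([c.center for c in coords], dtype=np.int32).reshape(-1, 3))
        f.create_dataset("ids", data=np.array([c.object_id for c in coords], dtype=np.int32))
        f.create_dataset("classes", data=np.array([c.partition_class for c in coords], dtype=np.int32))


def load_coordinates(path) -> list[TrainingCoordinate]:
    with h5py.File(path, "r") as f:
        centers = f["centers"][()]
        ids = f["ids"][()]
        classes = f["classes"][()]
    return [
        TrainingCoordinate(tuple(int(v) for v in c), int(i), int(k))
        for c, i, k in zip(centers, ids, classes)
    ]


# ---------------------------------------------------------------------------
# Model


class FfnModel:
    """3-D residual CNN mapping (intensity, mask) FOVs to membership logits."""

    def __init__(self, config: FfnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.channels
        layers = [nnet.Conv3d(2, c, 3, rng), nnet.ReLU()]
        for _ in range(config.depth):
            conv = nnet.Conv3d(c, c, 3, rng)
            conv.W.data *= 1.0 / np.sqrt(config.depth)
            layers.append(
                nnet.Residual(nnet.Sequential([nnet.ReLU(), conv]))
            )
        head = nnet.Conv3d(c, 1, 1, rng)
        head.W.data[...] = 0.0  # start at membership probability 0.5
        layers += [nnet.ReLU(), head]
        self.net = nnet.Sequential(layers)
        self.loss_history: list[tuple[int, float]] = []
        self.norm_stats: tuple[float, float] = (0.0, 1.0)

    def _input(self, intensity: np.ndarray, mask: np.ndarray) -> np.ndarray:
        return np.stack([intensity, 2.0 * mask - 1.0]).astype(F32)[None]

    def forward_scores(self, intensity, mask):
        return self.net.forward(self._input(intensity, mask))[0, 0]

    def predict(self, intensity: np.ndarray, mask: np.ndarray, center=None) -> np.ndarray:
        """Membership probability over the FOV given the current soft mask."""
        return sigmoid(self.forward_scores(intensity, mask))


class GroundTruthOracle:
    """Membership oracle backed by a reference segmentation.

    Stands in for a trained FFN in tests and degenerate pipelines: predicts
    probability 1 exactly on the voxels of the object under the current seed.
    """

    def __init__(self, labels: LabelVolume):
        self.labels = labels.labels
        self.radius = None
        self._oid = 0

    def begin(self, seed: tuple[int, int, int]) -> None:
        self._oid = int(self.labels[seed])

    def predict(self, intensity, mask, center) -> np.ndarray:
        rz, ry, rx = (s // 2 for s in intensity.shape)
        z, y, x = center
        fov = self.labels[z - rz : z + rz + 1, y - ry : y + ry + 1, x - rx : x + rx + 1]
        if self._oid == 0:
            return np.zeros_like(fov, dtype=F32)
        return (fov == self._oid).astype(F32)


def _normalize_volume(voxels: np.ndarray) -> tuple[np.ndarray, float, float]:
    x = voxels.astype(F32)
    mu, sd = float(x.mean()), float(x.std())
    sd = sd if sd > 0 else 1.0
    return (x - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# Stage 2: training


def train_ffn(
    images: ImageStack,
    labels: LabelVolume,
    coords: list[TrainingCoordinate],
    config: FfnConfig,
) -> FfnModel:
    """Train the FFN on FOV examples cut at the given coordinates.

    Input channels are the normalized intensity and the soft mask initialised
    to ``seed_prob`` at the centre and background elsewhere; the target is the
    binary mask of the centre object within the FOV; the loss is voxelwise
    logistic.  Deterministic for a fixed ``config.seed``.
    """
    if images.shape != labels.shape:
        raise ValueError("images and labels must be aligned")
    x, _, _ = _normalize_volume(images.voxels)
    arr = labels.labels
    rz, ry, rx = config.radius
    nz, ny, nx = arr.shape

    good = []
    for c in coords:
        z, y, xx = c.center
        if rz <= z < nz - rz and ry <= y < ny - ry and rx <= xx < nx - rx:
            good.append(c)
    if len(good) < len(coords):
        warnings.warn(
            f"filtered {len(coords) - len(good)} out-of-bounds coordinates",
            stacklevel=2,
        )
    if not good:
        raise ValueError("no valid training coordinates")

    model = FfnModel(config)
    opt = nnet.Adam(model.net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    bce = lambda s, t: (
        float(np.mean(np.maximum(s, 0) - s * t + np.log1p(np.exp(-np.abs(s))))),
        (sigmoid(s) - t) / s.size,
    )

    init_mask = np.full(config.fov, 1.0 - config.seed_prob, dtype=F32)
    init_mask[rz, ry, rx] = config.seed_prob

    for step in range(config.steps):
        c = good[int(rng.integers(len(good)))]
        z, y, xx = c.center
        sl = (
            slice(z - rz, z + rz + 1),
            slice(y - ry, y + ry + 1),
            slice(xx - rx, xx + rx + 1),
        )
        intensity = x[sl]
        target = (arr[sl] == c.object_id).astype(F32)
        mask = init_mask
        losses = []
        for _ in range(config.refine_iters):
            scores = model.forward_scores(intensity, mask)
            loss, dsc = bce(scores, target)
            opt.zero_grad()
            model.net.backward(dsc.astype(F32)[None, None])
            opt.step()
            losses.append(loss)
            mask = sigmoid(scores)  # feedback, no gradient through it
        model.loss_history.append((step, float(np.mean(losses))))
    return model


# ---------------------------------------------------------------------------
# Stage 3: seeds and flood-fill inference


def seed_policy(
    canvas: SegmentationCanvas, images: ImageStack, min_distance: int = 2
) -> list[tuple[int, int, int]]:
    """Ordered seed candidates: distance-transform peaks of the foreground.

    The intensity volume is split by Otsu's threshold and the minority side is
    taken as foreground (objects are the rarer phase on either polarity of EM
    contrast); voxels already visited on the canvas are excluded.  Peaks of
    the Euclidean distance transform are returned ranked by distance
    descending, ties broken by (z, y, x) ascending.
    """
    vox = images.voxels
    if vox.min() == vox.max():
        return []
    thr = threshold_otsu(vox)
    dark = vox <= thr
    fg = dark if dark.sum() <= dark.size / 2 else ~dark
    fg &= ~canvas.visited
    if not fg.any():
        return []
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=min_distance, labels=fg, exclude_border=False
    )
    if len(peaks) == 0:
        return []
    vals = dist[tuple(peaks.T)]
    order = np.lexsort((peaks[:, 2], peaks[:, 1], peaks[:, 0], -vals))
    return [tuple(int(v) for v in p) for p in peaks[order]]


def _clamp_center(c, radius, shape):
    return tuple(
        int(np.clip(v, r, s - r - 1)) for v, r, s in zip(c, radius, shape)
    )


def flood_fill_segment(
    model, images: ImageStack, config: FfnConfig
) -> LabelVolume:
    """Grow one object per seed by iterative FOV movement; first-come priority.

    ``model`` must expose ``predict(intensity_fov, mask_fov, center) ->
    probability_fov`` (and optionally ``begin(seed)``); both a trained
    :class:`FfnModel` and a :class:`GroundTruthOracle` qualify.
    """
    x, _, _ = _normalize_volume(images.voxels)
    shape = x.shape
    radius = config.radius
    rz, ry, rx = radius
    if any(s <= 2 * r for s, r in zip(shape, radius)):
        raise ValueError("volume smaller than the FOV")
    canvas = SegmentationCanvas.allocate(shape)
    next_id = 1

    for seed in seed_policy(canvas, images):
        seed = _clamp_center(seed, radius, shape)
        if canvas.visited[seed] or canvas.labels[seed] != 0:
            continue
        if hasattr(model, "begin"):
            model.begin(seed)
        obj_prob = np.full(shape, 1.0 - config.seed_prob, dtype=F32)
        obj_prob[seed] = config.seed_prob
        queue = deque([seed])
        moved = {seed}
        while queue:
            cz, cy, cx = queue.popleft()
            sl = (
                slice(cz - rz, cz + rz + 1),
                slice(cy - ry, cy + ry + 1),
                slice(cx - rx, cx + rx + 1),
            )
            probs = model.predict(x[sl], obj_prob[sl], (cz, cy, cx))
            obj_prob[sl] = probs
            for axis in range(3):
                for sign in (-1, 1):
                    off = [rz, ry, rx]
                    off[axis] += sign * config.delta[axis]
                    if probs[tuple(off)] < config.move_threshold:
                        continue
                    nc = [cz, cy, cx]
                    nc[axis] += sign * config.delta[axis]
                    nc = _clamp_center(nc, radius, shape)
                    if nc not in moved:
                        moved.add(nc)
                        queue.append(nc)
        obj_mask = (obj_prob >= config.segment_threshold) & (canvas.labels == 0)
        canvas.visited[seed] = True
        if int(obj_mask.sum()) < config.min_segment_size:
            continue
        canvas.labels[obj_mask] = next_id
        canvas.probability[obj_mask] = np.maximum(
            canvas.probability[obj_mask], obj_prob[obj_mask]
        )
        canvas.visited |= obj_mask
        next_id += 1

    return LabelVolume(canvas.labels, images.spacing)


# ---------------------------------------------------------------------------
# Stage 4: postprocessing


def _palette(n: int) -> np.ndarray:
    """Deterministic distinct colors via golden-ratio hue stepping."""
    import colorsys

    cols = np.zeros((n + 1, 3), dtype=np.uint8)
    h = 0.0
    for i in range(1, n + 1):
        h = (h + 0.61803398875) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.75, 0.95)
        cols[i] = (int(r * 255), int(g * 255), int(b * 255))
    return cols


def ffn_postprocess(canvas_output: LabelVolume) -> tuple[LabelVolume, ImageStack]:
    """Compact ids to 1..K (order of first appearance) and color a preview."""
    arr = canvas_output.labels
    flat = arr.ravel()
    nz = np.flatnonzero(flat)
    if nz.size:
        ids = flat[nz]
        _, first = np.unique(ids, return_index=True)
        order = ids[np.sort(first)]
        remap = np.zeros(int(arr.max()) + 1, dtype=np.int32)
        remap[order] = np.arange(1, len(order) + 1, dtype=np.int32)
        compact = remap[arr]
        k = len(order)
    else:
        compact = arr.copy()
        k = 0
    preview = _palette(k)[compact]
    return (
        LabelVolume(compact, canvas_output.spacing),
        ImageStack(preview, canvas_output.spacing),
    )
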