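"""2-D CNN segmentation engine: topologies, losses, training, tiled inference.

Four network topologies are available — ``unet`` (contracting/expansive paths
with skip connections), and full-resolution ``resnet`` / ``highway`` /
``dense`` stacks of depth ``n_layers`` — combined freely with five loss
functions (``square``, ``softmax``, ``entropy``, ``dice``, ``logistic``).

"Epochs" count gradient steps on randomly sampled, optionally augmented
patches: with only a handful of annotated slices (one suffices for oval
organelles like mitochondria), a pass over "the dataset" is not a meaningful
unit.  The canonical configuration for organelle segmentation is a 9-layer
resnet with the square loss trained for 2000 steps; a 16-layer resnet is the
heavier variant.

Inference tiles each slice with an overlap margin and keeps only the central
region of every tile (a degenerate weighted-average blend).  When the margin
is at least the network's receptive-field radius, tiled output is identical
to a whole-slice forward pass away from the image border.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nnet
from .core import ImageStack, LabelVolume, ProbabilityMap
from .nnet import F32, sigmoid, softmax

TOPOLOGIES = ("unet", "resnet", "highway", "dense")
LOSSES = ("square", "softmax", "entropy", "dice", "logistic")
AUGMENTATIONS = ("fliplr", "flipud", "rot90", "transpose")


class ConfigError(ValueError):
    pass


@dataclass
class Cnn2dConfig:
    topology: str = "resnet"
    n_layers: int = 9
    loss: str = "square"
    epochs: int = 2000
    patch_size: int = 128
    base_filters: int = 32
    augmentations: tuple[str, ...] = ("fliplr", "flipud", "rot90", "transpose")
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 4
    class_balance: bool = False
    growth: int = 8  # dense topology growth rate

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ConfigError(f"topology must be one of {TOPOLOGIES}")
        if self.loss not in LOSSES:
            raise ConfigError(f"loss must be one of {LOSSES}")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be ≥ 1")
        if self.epochs < 1:
            raise ConfigError("epochs must be ≥ 1")
        bad = set(self.augmentations) - set(AUGMENTATIONS)
        if bad:
            raise ConfigError(f"unknown augmentations {sorted(bad)}")
        self.augmentations = tuple(self.augmentations)
        if self.patch_size % self.downsampling_factor:
            raise ConfigError(
                f"patch_size {self.patch_size} must be divisible by the "
                f"topology downsampling factor {self.downsampling_factor}"
            )

    @property
    def downsampling_factor(self) -> int:
        # unet halves the resolution n_layers times; the other topologies
        # work at full resolution throughout
        return 2**self.n_layers if self.topology == "unet" else 1


def build_model(config: Cnn2dConfig, in_channels: int = 1, out_channels: int = 1):
    """Instantiate an untrained model mapping (N, in, H, W) → (N, out, H, W) scores."""
    rng = np.random.default_rng(config.seed)
    f = config.base_filters
    if config.topology == "unet":
        if config.n_layers > 5:
            raise ConfigError("unet supports at most 5 resolution levels")
        net = nnet.UNet2d(in_channels, out_channels, f, config.n_layers, rng)
        net.head.W.data[...] = 0.0
        return net
    stem = [nnet.Conv2d(in_channels, f, 3, rng), nnet.ReLU()]
    if config.topology == "resnet":
        trunk = []
        for _ in range(config.n_layers):
            conv = nnet.Conv2d(f, f, 3, rng)
            # scale the residual branch so activation variance stays flat
            # across depth (otherwise scores saturate the link at init)
            conv.W.data *= 1.0 / np.sqrt(config.n_layers)
            trunk.append(nnet.Residual(nnet.Sequential([nnet.ReLU(), conv])))
        head_in = f
    elif config.topology == "highway":
        trunk = [nnet.Highway2d(f, rng) for _ in range(config.n_layers)]
        head_in = f
    else:  # dense
        dense = nnet.DenseTrunk2d(f, config.n_layers, config.growth, rng)
        trunk = [dense]
        head_in = dense.out_channels
    head_conv = nnet.Conv2d(head_in, out_channels, 1, rng)
    head_conv.W.data[...] = 0.0  # start at the link midpoint (p = 0.5)
    head = [nnet.ReLU(), head_conv]
    return nnet.Sequential(stem + trunk + head)


# ---------------------------------------------------------------------------
# Losses: each returns (scalar loss, gradient w.r.t. raw scores)


def _loss_square(scores, targets):
    p = sigmoid(scores)
    d = p - targets
    loss = float(np.mean(d**2))
    return loss, (2.0 / d.size) * d * p * (1.0 - p)


def _loss_softmax(scores, targets):
    if scores.shape[1] < 2:
        raise ConfigError("softmax loss requires out_channels ≥ 2")
    p = softmax(scores, axis=1)
    npix = scores.size // scores.shape[1]
    loss = float(-(targets * np.log(p + 1e-12)).sum() / npix)
    return loss, (p - targets) / npix


def _bce(scores, targets):
    # numerically stable sigmoid cross-entropy with logits
    loss = float(
        np.mean(np.maximum(scores, 0) - scores * targets + np.log1p(np.exp(-np.abs(scores))))
    )
    return loss, (sigmoid(scores) - targets) / scores.size


def _loss_entropy(scores, targets):
    return _bce(scores, targets)


def _loss_logistic(scores, targets):
    if scores.shape[1] != 1:
        raise ConfigError("logistic loss is single-channel")
    return _bce(scores, targets)


def _loss_dice(scores, targets, eps=1e-6):
    p = sigmoid(scores)
    inter = float((p * targets).sum())
    denom = float(p.sum() + targets.sum())
    dice = (2.0 * inter + eps) / (denom + eps)
    loss = 1.0 - dice
    gp = -(2.0 * targets * (denom + eps) - (2.0 * inter + eps)) / (denom + eps) ** 2
    return loss, (gp * p * (1.0 - p)).astype(F32)


_LOSS_TABLE = {
    "square": _loss_square,
    "softmax": _loss_softmax,
    "entropy": _loss_entropy,
    "dice": _loss_dice,
    "logistic": _loss_logistic,
}


def make_loss(name: str):
    """Return ``loss_fn(scores, targets) -> (value, dvalue/dscores)``."""
    if name not in _LOSS_TABLE:
        raise ConfigError(f"unknown loss {name!r}; valid: {sorted(_LOSS_TABLE)}")
    return _LOSS_TABLE[name]


# ---------------------------------------------------------------------------
# Augmentation

TRANSFORMS = {
    "identity": lambda a: a,
    "fliplr": lambda a: a[..., :, ::-1],
    "flipud": lambda a: a[..., ::-1, :],
    "rot90": lambda a: np.rot90(a, axes=(-2, -1)),
    "transpose": lambda a: np.swapaxes(a, -2, -1),
}


def augment(patch_pair, config: Cnn2dConfig, rng: np.random.Generator):
    """Apply one transform, drawn from the configured set (or identity), to both
    members of an (image, label) patch pair."""
    img, lab = patch_pair
    if img.shape[-2:] != lab.shape[-2:]:
        raise ValueError("image and label patches must share spatial shape")
    choices = ("identity",) + config.augmentations
    name = choices[rng.integers(len(choices))]
    t = TRANSFORMS[name]
    return np.ascontiguousarray(t(img)), np.ascontiguousarray(t(lab))


# ---------------------------------------------------------------------------
# Training / inference


@dataclass
class TrainedModel2d:
    weights: list
    config: Cnn2dConfig
    loss_history: list = field(default_factory=list)
    in_channels: int = 1
    out_channels: int = 1

    def build(self):
        model = build_model(self.config, self.in_channels, self.out_channels)
        nnet.set_weights(model, self.weights)
        return model

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "config": asdict(self.config),
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "loss_history": self.loss_history,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel2d":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            weights = [z[f"w{i}"] for i in range(len(z.files) - 1)]
        cfg = Cnn2dConfig(**{**meta["config"], "augmentations": tuple(meta["config"]["augmentations"])})
        return cls(
            weights=weights,
            config=cfg,
            loss_history=[tuple(t) for t in meta["loss_history"]],
            in_channels=meta["in_channels"],
            out_channels=meta["out_channels"],
        )


def _normalize(voxels: np.ndarray) -> np.ndarray:
    x = voxels.astype(F32)
    sd = float(x.std())
    return (x - float(x.mean())) / (sd if sd > 0 else 1.0)


def _targets_from_labels(labels: LabelVolume, out_channels: int) -> np.ndarray:
    fg = (labels.labels > 0).astype(F32)
    if out_channels == 1:
        return fg[:, None]  # (z, 1, y, x)
    if out_channels == 2:
        return np.stack([1.0 - fg, fg], axis=1)
    raise ConfigError("binary training supports out_channels 1 or 2")


def train2d(
    images: ImageStack,
    labels: LabelVolume,
    config: Cnn2dConfig,
    out_channels: int | None = None,
) -> TrainedModel2d:
    """Train a 2-D CNN on random augmented patches of the annotated slices.

    ``labels`` is interpreted as a foreground mask (any nonzero id).  Runs
    ``config.epochs`` gradient steps of Adam and records the loss at each
    step; fully reproducible from ``config.seed``.
    """
    if images.shape != labels.shape:
        raise ValueError("images and labels must be aligned")
    if out_channels is None:
        out_channels = 2 if config.loss == "softmax" else 1
    if not (labels.labels > 0).any():
        import warnings

        warnings.warn("training labels contain no foreground", stacklevel=2)

    x = _normalize(images.voxels)
    if images.channels == 3:
        x = np.moveaxis(x, -1, 1)  # (z, 3, y, x)
    else:
        x = x[:, None]
    y = _targets_from_labels(labels, out_channels)

    model = build_model(config, x.shape[1], out_channels)
    # start the head at the foreground-prior logit: with rare foreground the
    # saturating losses otherwise collapse to the all-background constant
    prior = float(np.clip(y[:, -1].mean(), 1e-4, 1 - 1e-4))
    head = model.head if isinstance(model, nnet.UNet2d) else model.layers[-1]
    if config.loss == "softmax":
        head.b.data[...] = np.log([1.0 - prior, prior])
    else:
        head.b.data[...] = np.log(prior / (1.0 - prior))
    loss_fn = make_loss(config.loss)
    opt = nnet.Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    nz, _, h, w = x.shape
    ps = min(config.patch_size, h, w)
    ps -= ps % config.downsampling_factor
    if ps < config.downsampling_factor:
        raise ConfigError("slices smaller than the topology downsampling factor")

    history = []
    for step in range(config.epochs):
        xb, yb = [], []
        for _ in range(config.batch_size):
            for _attempt in range(10):
                z = int(rng.integers(nz))
                y0 = int(rng.integers(h - ps + 1))
                x0 = int(rng.integers(w - ps + 1))
                xi = x[z, :, y0 : y0 + ps, x0 : x0 + ps]
                yi = y[z, :, y0 : y0 + ps, x0 : x0 + ps]
                if not config.class_balance or yi[-1].any():
                    break
            xi, yi = augment((xi, yi), config, rng)
            xb.append(xi)
            yb.append(yi)
        xb = np.stack(xb)
        yb = np.stack(yb)
        scores = model.forward(xb)
        loss, dscores = loss_fn(scores, yb)
        opt.zero_grad()
        model.backward(dscores.astype(F32))
        opt.step()
        history.append((step, loss))

    return TrainedModel2d(
        weights=nnet.get_weights(model),
        config=config,
        loss_history=history,
        in_channels=x.shape[1],
        out_channels=out_channels,
    )


def _reflect_pad_yx(x: np.ndarray, pads: tuple[int, int, int, int]) -> np.ndarray:
    """Reflect-pad the trailing two axes, in passes when a pad exceeds the
    axis length (small images under a large tile)."""
    top, bot, left, right = pads
    while top or bot or left or right:
        h, w = x.shape[-2], x.shape[-1]
        t, b = min(top, h - 1), min(bot, h - 1)
        l, r = min(left, w - 1), min(right, w - 1)
        x = np.pad(x, ((0, 0), (0, 0), (t, b), (l, r)), mode="reflect")
        top, bot, left, right = top - t, bot - b, left - l, right - r
    return x


def _link(scores: np.ndarray, loss_name: str) -> np.ndarray:
    if loss_name == "softmax":
        return softmax(scores, axis=1)
    return sigmoid(scores)


def infer2d(
    trained: TrainedModel2d,
    images: ImageStack,
    tile: int = 128,
    overlap: int = 16,
) -> ProbabilityMap:
    """Tiled slice-wise inference producing per-voxel probabilities in [0, 1].

    Each slice is reflect-padded by ``overlap`` and covered with tiles of side
    ``tile`` advancing by ``tile − 2·overlap``; only the central region of
    each tile is kept.  Choose ``overlap`` at least the receptive-field radius
    (one pixel per 3×3 convolution) for output independent of the tiling; for
    a unet, ``tile`` and ``tile − 2·overlap`` must be divisible by the
    downsampling factor.
    """
    cfg = trained.config
    if overlap < 0 or 2 * overlap >= tile:
        raise ValueError("need 0 ≤ overlap < tile/2")
    stride = tile - 2 * overlap
    ds = cfg.downsampling_factor
    if tile % ds or stride % ds:
        raise ValueError(f"tile and tile−2·overlap must be divisible by {ds}")

    model = trained.build()
    x = _normalize(images.voxels)
    x = np.moveaxis(x, -1, 1) if images.channels == 3 else x[:, None]
    nz, cin, h, w = x.shape
    if cin != trained.in_channels:
        raise ValueError("channel count differs from the training images")

    ny = int(np.ceil(h / stride))
    nx = int(np.ceil(w / stride))
    pad_y = ny * stride - h
    pad_x = nx * stride - w
    xp = _reflect_pad_yx(x, (overlap, overlap + pad_y, overlap, overlap + pad_x))
    out = np.empty((nz, trained.out_channels, h, w), dtype=F32)
    for z in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                y0, x0 = iy * stride, ix * stride
                patch = xp[z : z + 1, :, y0 : y0 + tile, x0 : x0 + tile]
                probs = _link(model.forward(patch), cfg.loss)[0]
                core = probs[:, overlap : overlap + stride, overlap : overlap + stride]
                ye = min(y0 + stride, h)
                xe = min(x0 + stride, w)
                out[z, :, y0:ye, x0:xe] = core[:, : ye - y0, : xe - x0]

    values = out[:, 0] if trained.out_channels == 1 else np.moveaxis(out, 1, -1)
    return ProbabilityMap(values, images.spacing)
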