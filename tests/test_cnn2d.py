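import numpy as np
import pytest

from emseg.cnn2d import (
    AUGMENTATIONS,
    TRANSFORMS,
    Cnn2dConfig,
    ConfigError,
    TrainedModel2d,
    augment,
    build_model,
    infer2d,
    make_loss,
    train2d,
)
from emseg.core import ImageStack, LabelVolume
from emseg.synthdata import SynthSpec, gen_mitochondria


def small_cfg(**kw):
    base = dict(
        topology="resnet", n_layers=3, loss="square", epochs=2,
        patch_size=32, base_filters=8, seed=0,
    )
    base.update(kw)
    return Cnn2dConfig(**base)


# ---------------------------------------------------------------------------
# build_model


@pytest.mark.parametrize("n_layers", [9, 16])
def test_resnet_depths_output_shape(n_layers):
    cfg = small_cfg(n_layers=n_layers)
    model = build_model(cfg, 1, 1)
    out = model.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))
    assert out.shape == (1, 1, 32, 32)
    assert np.isfinite(out).all()


@pytest.mark.parametrize("topology", ["unet", "resnet", "highway", "dense"])
def test_all_topologies_forward_finite(topology):
    cfg = small_cfg(topology=topology, n_layers=2 if topology == "unet" else 3,
                    patch_size=64)
    model = build_model(cfg, 1, 2)
    out = model.forward(np.zeros((1, 1, 64, 64), dtype=np.float32))
    assert out.shape == (1, 2, 64, 64)
    assert np.isfinite(out).all()


def test_unet_rejects_excess_depth():
    with pytest.raises(ConfigError):
        build_model(small_cfg(topology="unet", n_layers=6, patch_size=64), 1, 1)


def test_unet_patch_divisibility_enforced():
    with pytest.raises(ConfigError):
        small_cfg(topology="unet", n_layers=4, patch_size=40)


# ---------------------------------------------------------------------------
# losses


def test_square_loss_zero_at_perfect_fit():
    loss = make_loss("square")
    scores = np.full((1, 1, 4, 4), 80.0, dtype=np.float32)  # sigmoid ≈ 1
    targets = np.ones_like(scores)
    val, _ = loss(scores, targets)
    assert val < 1e-10


def test_square_loss_half_ones_at_zero_scores():
    # sigmoid(0) = 0.5 against a half-ones target: mean (0.5)^2 = 0.25
    loss = make_loss("square")
    scores = np.zeros((1, 1, 2, 2), dtype=np.float32)
    targets = np.array([[[[1.0, 1.0], [0.0, 0.0]]]], dtype=np.float32)
    val, grad = loss(scores, targets)
    assert val == pytest.approx(0.25)
    assert grad.shape == scores.shape


def test_dice_loss_bounded_by_smoothing_at_perfect_overlap():
    loss = make_loss("dice")
    targets = np.zeros((1, 1, 8, 8), dtype=np.float32)
    targets[0, 0, 2:6, 2:6] = 1.0
    scores = np.where(targets > 0, 80.0, -80.0).astype(np.float32)
    val, _ = loss(scores, targets)
    assert 0 <= val < 1e-5


def test_softmax_loss_needs_two_channels():
    loss = make_loss("softmax")
    with pytest.raises(ConfigError):
        loss(np.zeros((1, 1, 2, 2), dtype=np.float32), np.zeros((1, 1, 2, 2)))


def test_logistic_loss_single_channel_only():
    loss = make_loss("logistic")
    with pytest.raises(ConfigError):
        loss(np.zeros((1, 2, 2, 2), dtype=np.float32), np.zeros((1, 2, 2, 2)))


@pytest.mark.parametrize("name", ["square", "entropy", "dice", "logistic"])
def test_losses_nonnegative_on_random_input(name):
    rng = np.random.default_rng(0)
    loss = make_loss(name)
    scores = rng.normal(0, 2, (2, 1, 8, 8)).astype(np.float32)
    targets = (rng.uniform(0, 1, scores.shape) > 0.5).astype(np.float32)
    val, grad = loss(scores, targets)
    assert val >= 0
    assert grad.shape == scores.shape


# ---------------------------------------------------------------------------
# augmentation


def test_empty_augmentation_set_is_identity():
    cfg = small_cfg(augmentations=())
    rng = np.random.default_rng(0)
    img = np.arange(16, dtype=np.float32).reshape(1, 4, 4)
    out_img, out_lab = augment((img, img.copy()), cfg, rng)
    np.testing.assert_array_equal(out_img, img)
    np.testing.assert_array_equal(out_lab, img)


def test_fliplr_is_an_involution():
    t = TRANSFORMS["fliplr"]
    img = np.arange(16, dtype=np.float32).reshape(4, 4)
    np.testing.assert_array_equal(t(t(img)), img)


def test_dihedral_group_closure():
    """rot90 composed four times is the identity, and the 8 transforms
    generated by rot90/fliplr close over the dihedral group of the square."""
    img = np.arange(16, dtype=np.float32).reshape(4, 4)
    r = TRANSFORMS["rot90"]
    out = img
    for _ in range(4):
        out = r(out)
    np.testing.assert_array_equal(out, img)

    group = set()
    for flips in range(2):
        cur = TRANSFORMS["fliplr"](img) if flips else img
        for _ in range(4):
            cur = r(cur)
            group.add(cur.tobytes())
    assert len(group) == 8


def test_augment_applies_same_transform_to_both():
    cfg = small_cfg(augmentations=("rot90",))
    rng = np.random.default_rng(1)
    img = np.arange(16, dtype=np.float32).reshape(1, 4, 4)
    for _ in range(10):
        a, b = augment((img, img.copy()), cfg, rng)
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# training / inference


@pytest.fixture(scope="module")
def tiny_fixture():
    spec = SynthSpec(shape=(4, 64, 64), n_objects=2, seed=3)
    return gen_mitochondria(spec)


def test_single_training_image_suffices(tiny_fixture):
    img, lab = tiny_fixture
    cfg = small_cfg(epochs=3)
    z = int(np.argmax((lab.labels > 0).sum(axis=(1, 2))))
    model = train2d(
        ImageStack(img.voxels[z : z + 1]), LabelVolume(lab.labels[z : z + 1]), cfg
    )
    assert len(model.loss_history) == 3


def test_loss_decreases_on_fixture(tiny_fixture):
    img, lab = tiny_fixture
    cfg = small_cfg(epochs=120, seed=7)
    model = train2d(img, lab, cfg)
    losses = [v for _, v in model.loss_history]
    assert np.mean(losses[-30:]) < np.mean(losses[:30])


def test_training_reproducible_from_seed(tiny_fixture):
    img, lab = tiny_fixture
    cfg = small_cfg(epochs=5, seed=11)
    a = train2d(img, lab, cfg)
    b = train2d(img, lab, cfg)
    assert a.loss_history == b.loss_history
    for wa, wb in zip(a.weights, b.weights):
        np.testing.assert_array_equal(wa, wb)


def test_no_foreground_warns(tiny_fixture):
    img, _ = tiny_fixture
    empty = LabelVolume(np.zeros(img.shape, dtype=np.int32))
    with pytest.warns(UserWarning, match="no foreground"):
        train2d(img, empty, small_cfg(epochs=1))


def test_checkpoint_round_trip(tmp_path, tiny_fixture):
    img, lab = tiny_fixture
    model = train2d(img, lab, small_cfg(epochs=2))
    path = tmp_path / "model.npz"
    model.save(path)
    back = TrainedModel2d.load(path)
    assert back.config == model.config
    probs_a = infer2d(model, img, tile=32, overlap=8)
    probs_b = infer2d(back, img, tile=32, overlap=8)
    np.testing.assert_array_equal(probs_a.values, probs_b.values)


def test_inference_bounds_and_shape(tiny_fixture):
    img, lab = tiny_fixture
    model = train2d(img, lab, small_cfg(epochs=2))
    probs = infer2d(model, img, tile=32, overlap=8)
    assert probs.values.shape == img.shape
    assert probs.values.min() >= 0 and probs.values.max() <= 1


def test_constant_model_blending_identity(tiny_fixture):
    """A head emitting one fixed score must give a uniform sigmoid(s) map:
    the tile blending cannot change a constant field."""
    img, _ = tiny_fixture
    cfg = small_cfg(epochs=1)
    model = build_model(cfg, 1, 1)
    for p in model.params():
        p.data[...] = 0.0
    model.layers[-1].b.data[...] = 1.25
    trained = TrainedModel2d(
        weights=[p.data.copy() for p in model.params()], config=cfg
    )
    probs = infer2d(trained, img, tile=32, overlap=8)
    expect = 1.0 / (1.0 + np.exp(-1.25))
    np.testing.assert_allclose(probs.values, expect, atol=1e-6)


def test_tiled_equals_whole_image_in_interior():
    spec = SynthSpec(shape=(1, 128, 128), n_objects=3, seed=5)
    img, _ = gen_mitochondria(spec)
    cfg = Cnn2dConfig(topology="resnet", n_layers=9, loss="square", epochs=1,
                      patch_size=64, base_filters=8, seed=2)
    rng = np.random.default_rng(9)
    model = build_model(cfg, 1, 1)
    # randomize the (zero-initialised) head so the output is nontrivial
    head = model.layers[-1]
    head.W.data[...] = rng.normal(0, 0.5, head.W.data.shape)
    trained = TrainedModel2d(
        weights=[p.data.copy() for p in model.params()], config=cfg
    )
    whole = infer2d(trained, img, tile=128, overlap=0).values
    tiled = infer2d(trained, img, tile=64, overlap=16).values
    inner = (slice(None), slice(16, -16), slice(16, -16))
    assert np.abs(whole[inner] - tiled[inner]).max() < 1e-5


def test_small_image_reflect_padded(tiny_fixture):
    img, lab = tiny_fixture
    model = train2d(img, lab, small_cfg(epochs=1))
    small = ImageStack(img.voxels[:, :20, :20])
    probs = infer2d(model, small, tile=32, overlap=8)
    assert probs.values.shape == (4, 20, 20)
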