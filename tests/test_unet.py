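import numpy as np
import pytest

from cardiopcct import TrainingConfig, UNet3D, predict_unet, split_dataset, train_unet
from cardiopcct.unet import _softmax_ce


def make_toy(seed=0, size=16, contrast=2.0):
    """Volume with a bright LV-like blob (class 1) inside a mid shell (class 2)."""
    rng = np.random.default_rng(seed)
    z, y, x = np.mgrid[:size, :size, :size]
    c = size / 2
    r2 = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2
    labels = np.zeros((size, size, size), dtype=np.int64)
    labels[r2 <= (size / 3) ** 2] = 2
    labels[r2 <= (size / 5) ** 2] = 1
    vol = np.where(labels == 1, contrast, np.where(labels == 2, 1.0, 0.0))
    vol = vol + rng.normal(0.0, 0.05, vol.shape)
    return vol.astype(np.float32), labels


def test_gradient_check_backprop(rng):
    model = UNet3D(n_classes=3, base=2, depth=2, seed=0)
    x = rng.standard_normal((1, 8, 8, 8))
    y = rng.integers(0, 3, (8, 8, 8))
    logits, caches = model.forward(x)
    loss, dlogits, _ = _softmax_ce(logits, y)
    grads = model.backward(dlogits, caches)
    eps = 1e-5
    for key in ("enc0_W", "dec0_W", "head_W", "enc1_b"):
        p = model.params[key]
        idx = tuple(np.unravel_index(np.argmax(np.abs(grads[key])), p.shape))
        orig = p[idx]
        p[idx] = orig + eps
        lp, _, _ = _softmax_ce(model.forward(x)[0], y)
        p[idx] = orig - eps
        lm, _, _ = _softmax_ce(model.forward(x)[0], y)
        p[idx] = orig
        numeric = (lp - lm) / (2 * eps)
        assert numeric == pytest.approx(float(grads[key][idx]), rel=1e-3, abs=1e-8)


def test_untrained_posterior_near_uniform():
    model = UNet3D(n_classes=4, base=4, depth=2, seed=1)
    x = np.random.default_rng(2).standard_normal((1, 8, 8, 8))
    p = model.predict_proba(x)
    assert p.shape == (4, 8, 8, 8)
    assert np.allclose(p.sum(axis=0), 1.0)
    assert np.abs(p - 0.25).max() < 0.05  # small head init


def test_zero_epochs_returns_untrained_model():
    vol, lab = make_toy()
    cfg = TrainingConfig(crop_size=16, epochs=0, base_channels=2, depth=2, seed=0)
    model, log = train_unet([vol, vol], [lab, lab], cfg, n_classes=3)
    assert log == []
    p = model.predict_proba(vol[None].astype(np.float64))
    assert np.abs(p - 1.0 / 3.0).max() < 0.05


def test_training_is_deterministic():
    vol, lab = make_toy()
    cfg = TrainingConfig(crop_size=16, epochs=3, base_channels=2, depth=2, seed=0)
    m1, log1 = train_unet([vol, vol], [lab, lab], cfg, n_classes=3)
    m2, log2 = train_unet([vol, vol], [lab, lab], cfg, n_classes=3)
    assert log1 == log2
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])


def test_overfits_toy_segmentation():
    vol, lab = make_toy(seed=0)
    vol2, lab2 = make_toy(seed=5)
    cfg = TrainingConfig(crop_size=16, epochs=120, base_channels=4, depth=2,
                         seed=0, augmentations=("random_crop",),
                         learning_rate=0.003)
    model, log = train_unet([vol, vol2], [lab, lab2], cfg, n_classes=3)
    assert log[-1] < log[0]  # loss decreased
    pred = predict_unet(model, vol, crop_size=16)
    dice = []
    for cls in (1, 2):
        p, t = pred == cls, lab == cls
        dice.append(2 * np.sum(p & t) / (p.sum() + t.sum()))
    assert min(dice) > 0.85


def test_training_input_validation():
    vol, lab = make_toy()
    cfg = TrainingConfig(crop_size=16, epochs=1, base_channels=2, depth=2)
    with pytest.raises(ValueError, match="at least 2"):
        train_unet([vol], [lab], cfg)
    with pytest.raises(ValueError, match="differ in length"):
        train_unet([vol, vol], [lab], cfg)


def test_training_config_validation():
    with pytest.raises(ValueError, match="learning_rate"):
        TrainingConfig(learning_rate=0.0)
    with pytest.raises(ValueError, match="adam"):
        TrainingConfig(optimizer="sgd")
    with pytest.raises(ValueError, match="cross_entropy"):
        TrainingConfig(loss="dice")
    with pytest.raises(ValueError, match="depth"):
        TrainingConfig(depth=1)


def test_split_dataset_partitions():
    train, val, test = split_dataset(46, (36, 5, 5), seed=3)
    assert len(train) == 36 and len(val) == 5 and len(test) == 5
    assert sorted(train + val + test) == list(range(46))
    with pytest.raises(ValueError, match="does not sum"):
        split_dataset(40, (36, 5, 5), seed=0)


def test_predict_pads_small_volume():
    vol, lab = make_toy(size=12)
    model = UNet3D(n_classes=3, base=2, depth=2, seed=0)
    with pytest.warns(UserWarning, match="padding"):
        pred = predict_unet(model, vol, crop_size=16)
    assert pred.shape == vol.shape
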