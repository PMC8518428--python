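import numpy as np
import pytest

from livernav import nn


def _rand_net(ndim, seed=0, cin=2):
    net = nn.UNet(in_channels=cin, ndim=ndim, levels=2, base_filters=2,
                  dropout_rate=0.0, seed=seed, dtype=np.float64)
    # nudge biases off zero so no preactivation sits exactly on the ReLU kink
    rng = np.random.default_rng(seed + 99)
    for p, _ in net.parameters():
        if p.ndim == 1:
            p += rng.normal(0, 0.1, size=p.shape)
    return net


@pytest.mark.parametrize("ndim", [2, 3])
def test_gradients_match_finite_differences(ndim):
    rng = np.random.default_rng(5)
    net = _rand_net(ndim)
    sp = (4,) * ndim
    x = rng.normal(size=(2, 2, *sp))
    y = (rng.random((2, *sp)) > 0.6).astype(float)
    w = nn.class_weights(y)

    def loss():
        logits = net.forward(x, train=True)
        return nn.weighted_bce_with_logits(logits[:, 0], y, w)

    net.zero_grad()
    _, dl = loss()
    net.backward(dl[:, None])
    eps = 1e-6
    for p, g in net.parameters():
        flat, gf = p.reshape(-1), g.reshape(-1)
        for i in range(0, flat.size, max(1, flat.size // 5)):
            old = flat[i]
            flat[i] = old + eps
            lp, _ = loss()
            flat[i] = old - eps
            lm, _ = loss()
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            assert gf[i] == pytest.approx(num, rel=1e-4, abs=1e-9)


def test_weighted_bce_closed_forms():
    # uniform p = 0.5, weights (1, 1) -> ln 2
    logits = np.zeros((2, 3, 3))
    y = (np.arange(18).reshape(2, 3, 3) % 2).astype(float)
    loss, _ = nn.weighted_bce_with_logits(logits, y, (1.0, 1.0))
    assert loss == pytest.approx(np.log(2.0), abs=1e-12)
    # perfect confident prediction -> loss ~ 0
    big = 50.0 * (2 * y - 1)
    loss, _ = nn.weighted_bce_with_logits(big, y, (1.0, 1.0))
    assert loss < 1e-6
    # hand-computed asymmetric case: one voxel, y=1, p=sigmoid(0)=0.5, w1=1.8
    loss, dl = nn.weighted_bce_with_logits(np.zeros(1), np.ones(1), (0.2, 1.8))
    assert loss == pytest.approx(1.8 * np.log(2.0))
    assert dl[0] == pytest.approx(1.8 * (0.5 - 1.0))


def test_class_weights_inverse_frequency():
    y = np.zeros(100)
    y[:10] = 1  # frequencies (0.9, 0.1)
    w_bg, w_fg = nn.class_weights(y)
    assert (w_bg, w_fg) == pytest.approx((0.2, 1.8))
    assert w_bg + w_fg == pytest.approx(2.0)
    with pytest.raises(ValueError):
        nn.class_weights(np.zeros(10))


def test_sigmoid_stable_extremes():
    z = np.array([-1000.0, 0.0, 1000.0])
    p = nn.sigmoid(z)
    assert np.all(np.isfinite(p))
    np.testing.assert_allclose(p, [0.0, 0.5, 1.0], atol=1e-12)


def test_adam_matches_reference_update():
    p = np.array([1.0, -2.0])
    g = np.array([0.5, -0.25])
    opt = nn.Adam([(p, g)], lr=0.1)
    opt.step()
    # first step: m_hat = g, v_hat = g^2 -> update = lr * sign(g) approx
    expected = np.array([1.0, -2.0]) - 0.1 * g / (np.abs(g) + 1e-8)
    np.testing.assert_allclose(p, expected, atol=1e-7)


def test_maxpool_and_upsample_are_inverse_shapes():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 3, 4, 6)).astype(np.float32)
    pool = nn.MaxPool(2)
    up = nn.Upsample(2)
    y = pool.forward(x, train=True)
    assert y.shape == (2, 3, 2, 3)
    z = up.forward(y)
    assert z.shape == x.shape
    # pooled values are the window maxima
    assert y[0, 0, 0, 0] == x[0, 0, :2, :2].max()


def test_maxpool_rejects_odd_sizes():
    with pytest.raises(ValueError, match="even"):
        nn.MaxPool(2).forward(np.zeros((1, 1, 3, 4)))


def test_dropout_inverted_and_eval_identity():
    rng = np.random.default_rng(0)
    d = nn.Dropout(0.5, np.random.default_rng(1))
    x = np.ones((4, 2, 16, 16))
    out_eval = d.forward(x, train=False)
    np.testing.assert_array_equal(out_eval, x)
    out_train = d.forward(x, train=True)
    kept = out_train != 0
    assert 0.3 < kept.mean() < 0.7
    np.testing.assert_allclose(out_train[kept], 2.0)  # inverted scaling


def test_unet_output_shape_and_determinism():
    x = np.random.default_rng(0).normal(size=(2, 5, 32, 32, 32)).astype(np.float32)
    a = nn.UNet(in_channels=5, ndim=3, levels=5, base_filters=4, seed=7)
    b = nn.UNet(in_channels=5, ndim=3, levels=5, base_filters=4, seed=7)
    pa, pb = a.predict_proba(x), b.predict_proba(x)
    assert pa.shape == (2, 32, 32, 32)
    np.testing.assert_array_equal(pa, pb)
    assert pa.min() >= 0.0 and pa.max() <= 1.0


def test_unet_rejects_bad_spatial_size():
    net = nn.UNet(in_channels=1, ndim=2, levels=3, base_filters=2)
    with pytest.raises(ValueError, match="divisible"):
        net.forward(np.zeros((1, 1, 10, 12)))


def test_training_reduces_loss_and_is_deterministic():
    # learnable toy task: segment the bright half of each tile
    rng = np.random.default_rng(0)
    n = 16
    x = rng.normal(0, 0.1, size=(n, 1, 8, 8)).astype(np.float32)
    y = np.zeros((n, 8, 8), np.float32)
    y[:, :, 4:] = 1
    x[:, 0, :, 4:] += 1.0

    def run():
        net = nn.UNet(in_channels=1, ndim=2, levels=2, base_filters=4,
                      dropout_rate=0.0, seed=3)
        hist = nn.train_network(net, x, y, nn.TrainConfig(epochs=5, batch_size=4,
                                                          learning_rate=0.01, seed=3))
        return net, hist

    net1, h1 = run()
    net2, h2 = run()
    assert h1.epoch_losses == h2.epoch_losses
    assert h1.epoch_losses[-1] < h1.epoch_losses[0]
    p = net1.predict_proba(x[:4])
    assert p[:, :, 6:].mean() > 0.7
    assert p[:, :, :2].mean() < 0.3
    np.testing.assert_array_equal(p, net2.predict_proba(x[:4]))


def test_divergence_raises():
    x = np.zeros((4, 1, 4, 4), np.float32)
    x[0, 0, 0, 0] = np.nan  # a poisoned input must abort, not train through
    y = np.ones((4, 4, 4), np.float32)
    y[0] = 0
    net = nn.UNet(in_channels=1, ndim=2, levels=2, base_filters=2, seed=0)
    with pytest.raises(nn.DivergenceError):
        nn.train_network(net, x, y, nn.TrainConfig(epochs=1, batch_size=4,
                                                   learning_rate=0.01, seed=0))
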