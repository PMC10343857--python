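"""Neural-network engine: conv arithmetic, gradients, residual contracts."""

import numpy as np
import pytest

from ir2dcos import nn


class TestConvOutputSize:
    @pytest.mark.parametrize(
        "n_in,p,f,s,expected",
        [
            (224, 3, 7, 2, 112),
            (5, 0, 3, 1, 3),
            (32, 1, 3, 1, 32),
            (10, 0, 1, 1, 10),   # 1x1 identity convolution
        ],
    )
    def test_formula(self, n_in, p, f, s, expected):
        assert nn.conv_output_size(nn.ConvSpec(n_in, p, f, s)) == expected

    def test_nonpositive_output_rejected(self):
        with pytest.raises(ValueError):
            nn.ConvSpec(2, 0, 5, 1)


class TestLayers:
    def test_conv_matches_direct_convolution(self, rng):
        """im2col convolution equals an explicit nested-loop oracle."""
        conv = nn.Conv2d(2, 3, 3, stride=2, padding=1, rng=rng)
        x = rng.normal(size=(2, 2, 7, 7)).astype(np.float32)
        out = conv.forward(x)
        w = conv.weight.data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        ho = wo = nn.conv_output_size(nn.ConvSpec(7, 1, 3, 2))
        ref = np.zeros((2, 3, ho, wo), dtype=np.float32)
        for n in range(2):
            for co in range(3):
                for i in range(ho):
                    for j in range(wo):
                        patch = xp[n, :, 2 * i:2 * i + 3, 2 * j:2 * j + 3]
                        ref[n, co, i, j] = (patch * w[co]).sum()
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_full_backward_directional_derivative(self, rng):
        """Analytic gradient matches finite differences along itself."""
        model = nn.ResNet(n_classes=3, channels=(4, 4), identity_plan=(1, 0),
                          stem_filter=3, stem_stride=1, seed=0)
        x = rng.normal(size=(4, 3, 8, 8)).astype(np.float32)
        y = np.array([0, 1, 2, 0])
        model.set_training(True)
        params = model.parameters()
        for p in params:
            p.grad[...] = 0.0
        _, dl = nn.cross_entropy(model.forward(x), y)
        model.backward(dl)
        g = [p.grad.copy() for p in params]
        gnorm2 = float(sum((gi ** 2).sum() for gi in g))
        eps = 1e-3 / np.sqrt(gnorm2)
        for p, gi in zip(params, g):
            p.data += eps * gi
        l1, _ = nn.cross_entropy(model.forward(x), y)
        for p, gi in zip(params, g):
            p.data -= 2 * eps * gi
        l2, _ = nn.cross_entropy(model.forward(x), y)
        assert (l1 - l2) / (2 * eps) == pytest.approx(gnorm2, rel=5e-3)

    def test_batchnorm_normalizes_in_training_mode(self, rng):
        bn = nn.BatchNorm2d(4)
        x = rng.normal(2.0, 3.0, size=(8, 4, 5, 5)).astype(np.float32)
        out = bn.forward(x)
        assert np.abs(out.mean(axis=(0, 2, 3))).max() < 1e-5
        np.testing.assert_allclose(out.std(axis=(0, 2, 3)), 1.0, atol=1e-3)

    def test_global_avg_pool(self, rng):
        pool = nn.GlobalAvgPool()
        x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(pool.forward(x), x.mean(axis=(2, 3)))

    def test_softmax_probabilities(self, rng):
        p = nn.softmax(rng.normal(size=(5, 7)).astype(np.float32))
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestResidualBlocks:
    def test_identity_block_preserves_shape(self, rng):
        block = nn.IdentityBlock(6, rng)
        x = rng.normal(size=(2, 6, 9, 9)).astype(np.float32)
        assert block.forward(x).shape == x.shape

    def test_zeroed_residual_branch_gives_identity(self, rng):
        """With F's final BN scale/shift zeroed, the block passes x through."""
        block = nn.IdentityBlock(5, rng)
        final_bn = block.f.layers[-1]
        final_bn.gamma.data[...] = 0.0
        final_bn.beta.data[...] = 0.0
        x = np.abs(rng.normal(size=(3, 5, 6, 6))).astype(np.float32)  # post-ReLU
        np.testing.assert_array_equal(block.forward(x), x)

    def test_conv_block_changes_dimensions(self, rng):
        block = nn.ConvBlock(4, 8, stride=2, rng=rng)
        x = rng.normal(size=(2, 4, 10, 10)).astype(np.float32)
        assert block.forward(x).shape == (2, 8, 5, 5)


class TestResNetModel:
    def test_default_plan_has_4_conv_6_identity_blocks(self):
        model = nn.ResNet(n_classes=7)
        assert model.block_counts() == {"convolution": 4, "identity": 6}

    def test_logit_width_follows_n_classes(self):
        model = nn.ResNet(n_classes=2, channels=(4, 4), identity_plan=(1, 0),
                          stem_filter=3, stem_stride=1)
        x = np.zeros((1, 3, 16, 16), dtype=np.float32)
        assert model.forward(x).shape == (1, 2)

    def test_shape_audit_default_model(self):
        model = nn.ResNet(n_classes=7, channels=(8, 16, 32, 64),
                          stem_filter=3, stem_stride=1)
        report = nn.shape_audit(model, 32)
        assert all(r["n_out_realized"] == r["n_out_predicted"] for r in report)
        # stem + 10 blocks x 2 main convs + 4 shortcut 1x1 convs
        assert len(report) == 1 + 10 * 2 + 4

    def test_sgd_zero_lr_keeps_parameters(self, rng):
        model = nn.ResNet(n_classes=2, channels=(4,), identity_plan=(1,),
                          stem_filter=3, stem_stride=1, seed=1)
        before = [p.data.copy() for p in model.parameters()]
        opt = nn.SGD(model.parameters(), lr=0.0)
        x = rng.normal(size=(4, 3, 8, 8)).astype(np.float32)
        y = np.array([0, 1, 0, 1])
        for _ in range(3):
            opt.zero_grad()
            loss, dl = nn.cross_entropy(model.forward(x), y)
            model.backward(dl)
            opt.step()
        for b, p in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_capacity_overfits_8_images(self):
        """Training loss drops below 0.01 on 8 images within 200 epochs."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 3, 16, 16)).astype(np.float32)
        y = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        model = nn.ResNet(n_classes=4, channels=(8, 16), identity_plan=(1, 1),
                          stem_filter=3, stem_stride=1, seed=3)
        opt = nn.SGD(model.parameters(), lr=0.01, momentum=0.9,
                     weight_decay=1e-4)
        model.set_training(True)
        loss = np.inf
        for _ in range(200):
            opt.zero_grad()
            loss, dl = nn.cross_entropy(model.forward(X), y)
            if loss < 0.01:
                break
            model.backward(dl)
            opt.step()
        assert loss < 0.01
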