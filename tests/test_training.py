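"""Optimiser, scheduler, loss, and augmentation behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmhkit import nn, phantom, segnet, training
from tmhkit.errors import DataError, InvalidArgumentError


class TestCosineLR:
    def test_endpoints_and_midpoint(self):
        assert training.cosine_lr(0, 100, 0.0, 1e-4) == pytest.approx(1e-4)
        assert training.cosine_lr(100, 100, 0.0, 1e-4) == pytest.approx(0.0)
        assert training.cosine_lr(50, 100, 0.0, 1e-4) == pytest.approx(5e-5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        n_max=st.integers(1, 10**6),
        lr_min=st.floats(0, 1e-3),
        span=st.floats(0, 1e-2),
    )
    def test_endpoints_for_any_config(self, n_max, lr_min, span):
        lr_max = lr_min + span
        assert training.cosine_lr(0, n_max, lr_min, lr_max) == pytest.approx(lr_max)
        assert training.cosine_lr(n_max, n_max, lr_min, lr_max) == pytest.approx(lr_min)

    def test_monotone_nonincreasing(self):
        lrs = [training.cosine_lr(i, 200, 1e-6, 1e-4) for i in range(201)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_out_of_range_step(self):
        with pytest.raises(InvalidArgumentError):
            training.cosine_lr(101, 100, 0, 1e-4)


class TestSGDStep:
    def test_plain_gradient_step(self):
        theta, _ = training.sgd_step(np.array(1.0), np.array(0.5), lr=0.1)
        assert theta == pytest.approx(0.95)

    def test_zero_gradient_fixed_point(self):
        theta, _ = training.sgd_step(np.array(2.5), np.array(0.0), lr=0.1)
        assert theta == pytest.approx(2.5)

    def test_matches_scalar_recurrence_oracle(self):
        m, wd, lr = 0.9, 1e-4, 0.01
        theta, v = 1.0, None
        # independent scalar recurrence
        ref_theta, ref_v = 1.0, 0.0
        rng = np.random.default_rng(0)
        for _ in range(12):
            g = float(rng.normal())
            ref_v = m * ref_v + (g + wd * ref_theta)
            ref_theta = ref_theta - lr * ref_v
            theta, v = training.sgd_step(theta, g, lr, momentum=m,
                                         weight_decay=wd, velocity=v)
        assert float(theta) == pytest.approx(ref_theta, abs=1e-8)

    def test_optimizer_class_matches_functional_rule(self):
        rng = np.random.default_rng(1)
        p = nn.Parameter(rng.normal(size=(3, 3)))
        opt = training.SGD([p], momentum=0.9, weight_decay=1e-4)
        ref, v = p.data.astype(np.float64).copy(), None
        for _ in range(10):
            g = rng.normal(size=(3, 3)).astype(np.float32)
            p.grad[...] = g
            opt.step(0.01)
            ref, v = training.sgd_step(ref, g, 0.01, momentum=0.9,
                                       weight_decay=1e-4, velocity=v)
        assert np.allclose(p.data, ref, atol=1e-5)


class TestLoss:
    def _output(self, scores, aux=None):
        return segnet.SegmentationOutput(main_scores=scores, aux_scores=aux)

    def test_perfect_one_hot_scores(self):
        labels = np.array([[[0, 1], [1, 0]]])
        scores = np.zeros((1, 2, 2, 2), dtype=np.float32)
        scores[0, 1][labels[0] == 1] = 50.0
        scores[0, 0][labels[0] == 0] = 50.0
        assert training.loss(self._output(scores), labels) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_scores_give_ln2(self):
        scores = np.zeros((1, 2, 4, 4), dtype=np.float32)
        labels = np.zeros((1, 4, 4), dtype=np.int64)
        assert training.loss(self._output(scores), labels) == pytest.approx(np.log(2))

    def test_random_scores_match_per_pixel_oracle(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        labels = (rng.random((1, 4, 4)) > 0.5).astype(np.int64)
        # brute-force per-pixel cross-entropy
        total = 0.0
        for i in range(4):
            for j in range(4):
                z = scores[0, :, i, j].astype(np.float64)
                p = np.exp(z) / np.exp(z).sum()
                total += -np.log(p[labels[0, i, j]])
        assert training.loss(self._output(scores), labels) == pytest.approx(
            total / 16, abs=1e-6
        )

    def test_aux_term_weighted(self):
        rng = np.random.default_rng(6)
        main = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        aux = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        labels = (rng.random((1, 4, 4)) > 0.5).astype(np.int64)
        lm = training.loss(self._output(main), labels)
        la = training.loss(self._output(aux), labels)
        both = training.loss(self._output(main, aux), labels, aux_weight=0.4)
        assert both == pytest.approx(lm + 0.4 * la, abs=1e-6)


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(7)
        img = rng.random((64, 64, 3))
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[40:50, :] = 1
        return img, mask

    def test_identity_policy_is_identity(self):
        img, mask = self._pair()
        out_img, out_mask = training.augment(
            img, mask, training.AugmentationPolicy.identity(),
            np.random.default_rng(0),
        )
        assert np.allclose(out_img, img)
        assert np.array_equal(out_mask, mask)

    def test_horizontal_flip_is_involution(self):
        img, mask = self._pair()
        policy = training.AugmentationPolicy(
            hue_delta=0, sat_range=(1, 1), val_range=(1, 1),
            rotation_deg=(0, 0), translation_frac=(0, 0), flip_prob=1.0,
        )
        i1, m1 = training.augment(img, mask, policy, np.random.default_rng(0))
        i2, m2 = training.augment(i1, m1, policy, np.random.default_rng(0))
        assert np.allclose(i2, img)
        assert np.array_equal(m2, mask)

    def test_rotation_roughly_preserves_mask_area(self):
        img = np.random.default_rng(8).random((400, 400, 3))
        mask = np.zeros((400, 400), dtype=np.uint8)
        mask[100:300, :] = 1  # centred band, 200 px tall
        policy = training.AugmentationPolicy(
            hue_delta=0, sat_range=(1, 1), val_range=(1, 1),
            rotation_deg=(10, 10), translation_frac=(0, 0), flip_prob=0.0,
        )
        _, rotated = training.augment(img, mask, policy, np.random.default_rng(0))
        before, after = mask.sum(), rotated.sum()
        assert abs(after - before) / before < 0.05

    def test_outputs_stay_in_range(self):
        img, mask = self._pair()
        rng = np.random.default_rng(9)
        for _ in range(5):
            img2, mask2 = training.augment(
                img, mask, training.AugmentationPolicy(), rng
            )
            assert img2.min() >= 0.0 and img2.max() <= 1.0
            assert set(np.unique(mask2)) <= {0, 1}


@pytest.fixture(scope="module")
def tiny_setup():
    spec = phantom.scaled_spec(size_px=64)
    samples, _ = phantom.generate_dataset(4, spec, seed=0, n_train=4)
    dataset = [(s.image, s.meniscus_mask) for s in samples]
    cfg = segnet.NetworkConfig(base_channels=4, aspp_channels=8,
                               aspp_rates=(1, 2, 3))
    return dataset, cfg


class TestTrainLoop:
    def test_lr_trace_matches_scheduler(self, tiny_setup):
        dataset, net_cfg = tiny_setup
        tc = training.TrainConfig(batch_size=2, max_epochs=3, crop_size=64, seed=0)
        net = segnet.build_network(net_cfg, seed=0)
        _, hist = training.train(net, dataset, tc)
        n_max = 3 * 2
        expected = [training.cosine_lr(i, n_max, tc.lr_min, tc.lr_max)
                    for i in range(len(hist))]
        assert np.allclose(hist["lr"], expected)

    def test_loss_trace_reproducible(self, tiny_setup):
        dataset, net_cfg = tiny_setup
        tc = training.TrainConfig(batch_size=2, max_epochs=2, crop_size=64, seed=3)
        traces = []
        for _ in range(2):
            net = segnet.build_network(net_cfg, seed=1)
            _, hist = training.train(
                net, dataset, tc, policy=training.AugmentationPolicy()
            )
            traces.append(hist["loss"].to_numpy())
        assert np.array_equal(traces[0], traces[1])

    def test_empty_dataset_rejected(self, tiny_setup):
        _, net_cfg = tiny_setup
        net = segnet.build_network(net_cfg, seed=0)
        with pytest.raises(DataError):
            training.train(net, [], training.TrainConfig(max_epochs=1, crop_size=8))
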