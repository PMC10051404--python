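import math

import numpy as np
import pytest

from patchrefine.grid import make_grid
from patchrefine.models import TinySegModel
from patchrefine.synthetic import SyntheticConfig, generate_dataset
from patchrefine.training import (
    AugmentConfig,
    TrainConfig,
    augment,
    focal_loss,
    focal_loss_grad,
    init_stage2_from_stage1,
    train_stage1,
    train_stage2,
)

IDENTITY_AUG = AugmentConfig(hflip_prob=0.0, jitter_brightness=0.0,
                             jitter_contrast=0.0, translate_frac=0.0)


def _bce_oracle(p, y, eps=1e-7):
    pc = np.clip(p, eps, 1 - eps)
    return float(np.mean(-(y * np.log(pc) + (1 - y) * np.log(1 - pc))))


class TestFocalLoss:
    def test_gamma_zero_reduces_to_bce(self, rng):
        p = rng.random((8, 8))
        y = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        assert focal_loss(p, y, gamma=0.0, alpha=1.0) == pytest.approx(_bce_oracle(p, y), abs=1e-10)

    def test_confident_correct_predictions_cost_nothing(self):
        y = np.array([[1, 0]], dtype=np.uint8)
        p = np.array([[1.0, 0.0]])
        assert focal_loss(p, y) == pytest.approx(0.0, abs=1e-12)

    def test_single_pixel_hand_value(self):
        # (1 - 0.5)^2 * (-ln 0.5) = 0.25 * ln 2
        loss = focal_loss(np.array([[0.5]]), np.array([[1]]), gamma=2.0, alpha=1.0)
        assert loss == pytest.approx(0.25 * math.log(2), abs=1e-10)

    def test_brute_force_pixel_oracle(self, rng):
        p = rng.random((8, 8))
        y = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        gamma, alpha = 2.0, 0.7
        acc = []
        for pij, yij in zip(p.ravel(), y.ravel()):
            pt = pij if yij == 1 else 1.0 - pij
            at = alpha if yij == 1 else 1.0 - alpha
            acc.append(-at * (1.0 - pt) ** gamma * math.log(max(pt, 1e-7)))
        assert focal_loss(p, y, gamma, alpha) == pytest.approx(float(np.mean(acc)), abs=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            focal_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    @pytest.mark.parametrize("gamma,alpha", [(2.0, 1.0), (0.0, 1.0), (1.5, 0.25)])
    def test_gradient_matches_numerical(self, gamma, alpha, rng):
        logits = rng.normal(size=(3, 4))
        y = (rng.random((3, 4)) > 0.5).astype(np.uint8)
        _, grad = focal_loss_grad(logits, y, gamma, alpha)
        eps = 1e-6
        for (i, j) in [(0, 0), (1, 2), (2, 3)]:
            zp, zm = logits.copy(), logits.copy()
            zp[i, j] += eps
            zm[i, j] -= eps
            num = (focal_loss_grad(zp, y, gamma, alpha)[0] - focal_loss_grad(zm, y, gamma, alpha)[0]) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestModelGradients:
    def test_backward_matches_numerical(self, rng):
        m = TinySegModel((8, 8), seed=0)
        xb = rng.random((2, 3, 8, 8))
        yb = (rng.random((2, 8, 8)) > 0.5).astype(np.uint8)

        def loss_of_params():
            logits, _ = m.forward_batch(xb)
            return focal_loss_grad(logits, yb, 2.0, 1.0)[0]

        logits, _, cache = m.forward_batch(xb, need_cache=True)
        _, dlogits = focal_loss_grad(logits, yb, 2.0, 1.0)
        grads = m.backward_batch(cache, dlogits)
        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for name in ("w1", "w3", "w5", "b2", "b5"):
            flat_idx = int(check_rng.integers(m.params[name].size))
            orig = m.params[name].ravel()[flat_idx]
            m.params[name].ravel()[flat_idx] = orig + eps
            lp = loss_of_params()
            m.params[name].ravel()[flat_idx] = orig - eps
            lm = loss_of_params()
            m.params[name].ravel()[flat_idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name].ravel()[flat_idx] == pytest.approx(num, rel=2e-3, abs=1e-8)


class TestAugment:
    def test_identity_configuration(self, rng):
        x = rng.random((20, 20, 3))
        y = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        x2, y2 = augment(x, y, IDENTITY_AUG, np.random.default_rng(0))
        np.testing.assert_array_equal(x2, x)
        np.testing.assert_array_equal(y2, y)

    def test_double_hflip_is_involution(self, rng):
        cfg = AugmentConfig(hflip_prob=1.0, jitter_brightness=0.0,
                            jitter_contrast=0.0, translate_frac=0.0)
        x = rng.random((10, 12, 3))
        y = (rng.random((10, 12)) > 0.5).astype(np.uint8)
        r = np.random.default_rng(0)
        x1, y1 = augment(x, y, cfg, r)
        x2, y2 = augment(x1, y1, cfg, r)
        np.testing.assert_array_equal(x2, x)
        np.testing.assert_array_equal(y2, y)

    def test_translation_bounded_by_ten_percent(self):
        cfg = AugmentConfig(hflip_prob=0.0, jitter_brightness=0.0,
                            jitter_contrast=0.0, translate_frac=0.1)
        x = np.zeros((100, 100, 3))
        y = np.zeros((100, 100), dtype=np.uint8)
        y[50, 50] = 1
        x[50, 50] = 1.0
        for s in range(10):
            _, y2 = augment(x, y, cfg, np.random.default_rng(s))
            rows, cols = np.nonzero(y2)
            assert rows.size >= 1
            assert np.abs(rows - 50).max() <= 10 and np.abs(cols - 50).max() <= 10

    def test_preserves_binarity_and_range(self, rng):
        cfg = AugmentConfig()
        x = rng.random((32, 32, 3))
        y = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        for s in range(10):
            x2, y2 = augment(x, y, cfg, np.random.default_rng(s))
            assert x2.shape == x.shape and y2.shape == y.shape
            assert set(np.unique(y2)) <= {0, 1}
            assert x2.min() >= 0.0 and x2.max() <= 1.0


def _pairs(n=12, seed=0, size=(64, 64)):
    cfg = SyntheticConfig(image_size=size, seed=seed)
    return [(x, y) for x, y, _ in generate_dataset(cfg, n)]


class TestTrainStage1:
    def test_loss_decreases_across_seeds(self):
        for seed in range(3):
            data = _pairs(20, seed=seed)
            m = TinySegModel((16, 16), seed=seed)
            cfg = TrainConfig(learning_rate=2e-3, epochs=8, batch_size=4,
                              image_size=(64, 64), seed=seed)
            res = train_stage1(m, data, cfg)
            assert res.loss_history[-1] < res.loss_history[0]

    def test_zero_lr_leaves_weights_unchanged(self):
        data = _pairs(4)
        m = TinySegModel((16, 16), seed=0)
        before = {k: v.copy() for k, v in m.params.items()}
        train_stage1(m, data, TrainConfig(learning_rate=0.0, epochs=2, image_size=(64, 64)))
        for k in before:
            np.testing.assert_array_equal(m.params[k], before[k])

    def test_loss_history_length_is_epochs(self):
        res = train_stage1(TinySegModel((16, 16)), _pairs(4),
                           TrainConfig(epochs=3, image_size=(64, 64)))
        assert len(res.loss_history) == 3

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_stage1(TinySegModel((16, 16)), [], TrainConfig())

    def test_reproducible_from_seed(self):
        histories = []
        for _ in range(2):
            m = TinySegModel((16, 16), seed=4)
            res = train_stage1(m, _pairs(6), TrainConfig(learning_rate=1e-3, epochs=2,
                                                         image_size=(64, 64), seed=4))
            histories.append(res.loss_history)
        assert histories[0] == histories[1]


class TestInitStage2:
    def test_forward_equality_after_init(self, rng):
        m1 = TinySegModel((24, 24), seed=1)
        m2 = init_stage2_from_stage1(m1)
        x = rng.random((24, 24, 3))
        np.testing.assert_array_equal(m1.forward(x)[0], m2.forward(x)[0])

    def test_deep_copy_semantics(self):
        m1 = TinySegModel((24, 24), seed=1)
        m2 = init_stage2_from_stage1(m1)
        m2.params["w1"][:] += 1.0
        assert not np.array_equal(m1.params["w1"], m2.params["w1"])

    def test_exhaustive_parameter_equality(self):
        m1 = TinySegModel((24, 24), seed=2)
        m2 = init_stage2_from_stage1(m1)
        assert m1.param_shapes() == m2.param_shapes()
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])


class TestTrainStage2:
    def _setup(self, seed=0, n=6):
        data = _pairs(n, seed=seed, size=(64, 64))
        grid = make_grid(64, 64, 16)
        m1 = TinySegModel((16, 16), seed=seed)
        train_stage1(m1, data, TrainConfig(learning_rate=2e-3, epochs=3,
                                           image_size=(64, 64), seed=seed))
        return data, grid, m1

    def test_stage1_frozen(self):
        data, grid, m1 = self._setup()
        h = m1.state_hash()
        m2 = init_stage2_from_stage1(m1)
        train_stage2(m1, m2, data, grid, "weighted",
                     TrainConfig(learning_rate=1e-3, epochs=2, image_size=(64, 64)))
        assert m1.state_hash() == h

    def test_highest_strategy_deterministic_patch_per_image(self):
        data, grid, m1 = self._setup(n=1)
        m2 = init_stage2_from_stage1(m1)
        cfg = TrainConfig(learning_rate=1e-4, epochs=5, image_size=(64, 64),
                          augment=AugmentConfig(0.0, 0.0, 0.0, 0.0))
        res = train_stage2(m1, m2, data, grid, "highest", cfg)
        # frozen scores on the un-augmented image: the same patch every epoch
        assert len(res.sampled_patches) == 1
        assert sum(res.sampled_patches.values()) == 5

    def test_invalid_strategy(self):
        data, grid, m1 = self._setup()
        with pytest.raises(ValueError):
            train_stage2(m1, init_stage2_from_stage1(m1), data, grid, "rl", TrainConfig())

    def test_loss_history_and_histogram(self):
        data, grid, m1 = self._setup()
        m2 = init_stage2_from_stage1(m1)
        res = train_stage2(m1, m2, data, grid, "random",
                           TrainConfig(epochs=2, image_size=(64, 64)))
        assert len(res.loss_history) == 2
        assert sum(res.sampled_patches.values()) == 2 * len(data)
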