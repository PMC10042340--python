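"""Network contract tests: shapes, softmax, augmentation, training."""

import numpy as np
import pytest

from octamb.errors import TrainingError, ValidationError
from octamb.phantom import FovealPit, PhantomConfig, generate_bscan
from octamb.segnet import (
    AugmentConfig,
    BoundaryNet,
    ModelConfig,
    ProbabilityVolume,
    TrainConfig,
    apply_augment,
    build_model,
    extract_boundaries,
    flip_lr,
    predict_probabilities,
    quarter_split,
    train_model,
)

TINY_MODEL = ModelConfig(input_depth=64, input_width=16, base_channels=4, seed=3)


def tiny_phantoms(n, seed0=100, **cfg_kw):
    cfg_kw.setdefault("width_ascans", 64)
    cfg_kw.setdefault("depth_pixels", 64)
    cfg_kw.setdefault("boundary_waviness_amplitude", 1.0)
    cfg_kw.setdefault("foveal_pit", FovealPit(depth_px=5.0, halfwidth_px=10.0))
    cfg = PhantomConfig(**cfg_kw)
    return [generate_bscan(cfg, (), seed=seed0 + i) for i in range(n)]


class TestBuildAndForward:
    def test_output_shape_and_normalization(self, rng):
        model = build_model(TINY_MODEL)
        img = rng.uniform(0, 1, size=(64, 32))
        pv = predict_probabilities(model, img)
        assert pv.p.shape == (32, 64, 6)
        sums = pv.p.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) <= 1e-5
        assert pv.p.min() >= 0.0

    def test_indivisible_dims_rejected_with_padding_hint(self):
        with pytest.raises(ValidationError, match="pad"):
            ModelConfig(input_depth=65, input_width=16).validate()

    def test_forward_deterministic(self):
        model = build_model(TINY_MODEL)
        img = np.zeros((64, 16))
        a = predict_probabilities(model, img)
        b = predict_probabilities(model, img)
        assert a.p.tobytes() == b.p.tobytes()

    def test_same_seed_same_init(self):
        a = build_model(TINY_MODEL)
        b = build_model(TINY_MODEL)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name].data, b.params[name].data)

    def test_width_mismatch_rejected(self, rng):
        model = build_model(TINY_MODEL)
        with pytest.raises(ValidationError, match="width"):
            predict_probabilities(model, rng.uniform(0, 1, (64, 18)))

    def test_depth_mismatch_rejected(self, rng):
        model = build_model(TINY_MODEL)
        with pytest.raises(ValidationError, match="depth"):
            predict_probabilities(model, rng.uniform(0, 1, (32, 16)))


class TestAugment:
    def test_flip_involution(self):
        s = tiny_phantoms(1)[0]
        back = flip_lr(flip_lr(s))
        np.testing.assert_array_equal(back.image, s.image)
        np.testing.assert_array_equal(back.truth_boundaries, s.truth_boundaries)

    def test_identity_augment(self):
        s = tiny_phantoms(1)[0]
        out = apply_augment(s, flip=False, scale=1.0, rotation_deg=0.0)
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.truth_boundaries, s.truth_boundaries)

    def test_flip_reverses_truth_index_oracle(self):
        s = tiny_phantoms(1)[0]
        out = apply_augment(s, flip=True, scale=1.0, rotation_deg=0.0)
        np.testing.assert_array_equal(
            out.truth_boundaries, s.truth_boundaries[:, ::-1]
        )

    def test_rotation_moves_boundaries_consistently(self):
        # truth should track the image content: after a small rotation
        # the brightest vertical step (ILM edge) follows the new truth
        s = tiny_phantoms(1, speckle_noise_sd=0.0)[0]
        out = apply_augment(s, flip=False, scale=1.0, rotation_deg=10.0)
        for x in (10, 32, 50):
            truth = out.truth_boundaries[0, x]
            lo = max(0, int(truth) - 5)
            grad = np.gradient(out.image[:, x])
            est = lo + int(np.argmax(grad[lo : int(truth) + 6]))
            assert abs(est - truth) <= 2.0

    def test_all_out_of_frame_rejected(self):
        cfg = PhantomConfig(
            width_ascans=64,
            depth_pixels=128,
            layer_mean_depths=(100, 104, 108, 112, 116, 120),
            boundary_waviness_amplitude=0.0,
            speckle_noise_sd=0.0,
            foveal_pit=FovealPit(depth_px=0.0),
        )
        s = generate_bscan(cfg, (), seed=0)
        with pytest.raises(ValidationError, match="out of frame"):
            apply_augment(s, flip=False, scale=3.0, rotation_deg=0.0)

    def test_labels_preserved(self):
        from octamb.phantom import LesionSpec

        cfg = PhantomConfig(width_ascans=64, depth_pixels=64,
                            foveal_pit=FovealPit(depth_px=4.0, halfwidth_px=8.0),
                            boundary_waviness_amplitude=0.5)
        s = generate_bscan(
            cfg, [LesionSpec("EZ_LOSS", 32, 8, blur_sd=2.0)], seed=1
        )
        out = apply_augment(s, flip=True, scale=1.05, rotation_deg=5.0)
        np.testing.assert_array_equal(out.layer_labels, s.layer_labels)


class TestQuarterSplit:
    def test_four_tiles_of_quarter_width(self):
        s = tiny_phantoms(1)[0]
        tiles = quarter_split(s)
        assert len(tiles) == 4
        assert all(t.image.shape == (64, 16) for t in tiles)

    def test_concatenation_reproduces_original(self):
        s = tiny_phantoms(1)[0]
        tiles = quarter_split(s)
        np.testing.assert_array_equal(
            np.concatenate([t.image for t in tiles], axis=1), s.image
        )

    def test_truth_slicing_contract(self):
        s = tiny_phantoms(1)[0]
        tiles = quarter_split(s)
        for k, t in enumerate(tiles):
            for x in (0, 7, 15):
                assert (
                    t.truth_boundaries[2, x]
                    == s.truth_boundaries[2, x + k * 16]
                )

    def test_indivisible_width_rejected(self):
        s = tiny_phantoms(1)[0]
        trimmed = type(s)(
            image=s.image[:, :63],
            truth_boundaries=s.truth_boundaries[:, :63],
            layer_labels=s.layer_labels,
        )
        with pytest.raises(ValidationError, match="divisible"):
            quarter_split(trimmed)


class TestTraining:
    def _quick_cfg(self, epochs, seed=0):
        return TrainConfig(
            epochs=epochs,
            seed=seed,
            augmentation=AugmentConfig(
                lr_flip=True,
                scale_range=(1.0, 1.0),
                rotation_deg=0.0,
                quarter_split=True,
            ),
        )

    def test_loss_decreases_20_phantoms_10_epochs(self):
        samples = tiny_phantoms(20)
        model = build_model(TINY_MODEL)
        model, hist = train_model(model, samples, self._quick_cfg(10))
        assert len(hist) == 10
        assert hist[-1] < hist[0]

    def test_training_deterministic(self):
        samples = tiny_phantoms(6)
        m1, h1 = train_model(build_model(TINY_MODEL), samples, self._quick_cfg(2))
        m2, h2 = train_model(build_model(TINY_MODEL), samples, self._quick_cfg(2))
        assert h1 == h2
        for name in m1.params:
            np.testing.assert_array_equal(m1.params[name].data, m2.params[name].data)

    def test_tiny_scale_boundary_recovery(self):
        train = tiny_phantoms(30)
        held = tiny_phantoms(8, seed0=9_000)
        model = build_model(
            ModelConfig(input_depth=64, input_width=16, base_channels=8, seed=3)
        )
        model, _ = train_model(model, train, self._quick_cfg(10))
        maes = []
        for s in held:
            tr = extract_boundaries(predict_probabilities(model, s.image))
            maes.append(np.abs(tr.depth - s.truth_boundaries).mean())
        assert float(np.mean(maes)) <= 2.0

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValidationError, match="at least one"):
            train_model(build_model(TINY_MODEL), [], self._quick_cfg(1))

    def test_nan_loss_aborts(self):
        samples = tiny_phantoms(5)
        model = build_model(TINY_MODEL)
        model.params["head.w"].data[:] = np.inf
        with pytest.raises(TrainingError, match="non-finite"):
            train_model(model, samples, self._quick_cfg(1))

    def test_checkpoint_roundtrip(self, tmp_path):
        samples = tiny_phantoms(5)
        model, _ = train_model(
            build_model(TINY_MODEL), samples, self._quick_cfg(1)
        )
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = BoundaryNet.load(path)
        assert loaded.trained
        assert loaded.config == model.config
        img = samples[0].image
        np.testing.assert_array_equal(
            predict_probabilities(model, img).p,
            predict_probabilities(loaded, img).p,
        )


class TestExtractBoundaries:
    def _pv(self, p):
        return ProbabilityVolume(p=p)

    def test_delta_case(self):
        p = np.zeros((3, 64, 6))
        p[:, 40, :] = 1.0
        tr = extract_boundaries(self._pv(p))
        assert np.all(tr.depth == 40)

    def test_tie_breaks_to_smallest_depth(self):
        p = np.zeros((1, 32, 6))
        p[:, 10, :] = 0.5
        p[:, 20, :] = 0.5
        tr = extract_boundaries(self._pv(p))
        assert np.all(tr.depth == 10)

    def test_linear_scan_oracle(self, rng):
        raw = rng.uniform(0, 1, size=(4, 16, 6))
        p = raw / raw.sum(axis=1, keepdims=True)
        tr = extract_boundaries(self._pv(p))
        for x in range(4):
            for l in range(6):
                best, best_z = -1.0, -1
                for z in range(16):
                    if p[x, z, l] > best:
                        best, best_z = p[x, z, l], z
                assert tr.depth[l, x] == best_z
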