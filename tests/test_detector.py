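"""Losses, targets, decoding, augmentation, and the training schedule."""

import math

import numpy as np
import pytest

from hipmetrics.detector import (
    BoxParams,
    DetectorConfig,
    TrainConfig,
    augment,
    build_detector,
    crossval_train,
    decode_keypoints,
    focal_keypoint_loss,
    load_detector,
    make_keypoint_target,
    save_detector,
    smooth_l1_box_loss,
    total_loss,
    train_detector,
)
from hipmetrics.geometry import measure_hips
from hipmetrics.phantom import RaterModel, generate_dataset

SMALL = DetectorConfig(mask_resolution=56)


class TestFocalLoss:
    def test_quarter_log_two_closed_form(self):
        # p = 0.5 on a single foreground pixel, gamma 2, N = 1
        loss = focal_keypoint_loss(np.array([[[0.5]]]), np.array([[[1.0]]]), 2.0, 1.0)
        assert loss == pytest.approx(0.25 * math.log(2), abs=1e-12)

    def test_gamma_zero_equals_binary_cross_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0.01, 0.99, size=(4, 6, 6))
            y = (rng.uniform(size=(4, 6, 6)) < 0.05).astype(float)
            n = max(y.sum(), 1.0)
            bce = -(np.sum(np.log(p[y == 1])) + np.sum(np.log(1 - p[y == 0]))) / n
            assert focal_keypoint_loss(p, y, 0.0) == pytest.approx(bce, abs=1e-10)

    def test_confident_correct_prediction_vanishes(self):
        y = np.zeros((1, 4, 4))
        y[0, 1, 2] = 1.0
        p = np.full((1, 4, 4), 1e-9)
        p[0, 1, 2] = 1 - 1e-9
        assert focal_keypoint_loss(p, y, 2.0) < 1e-12

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            focal_keypoint_loss(np.ones((1, 2, 2)) * 0.5, np.zeros((1, 3, 3)))

    def test_focusing_downweights_easy_background(self):
        y = np.zeros((1, 8, 8))
        y[0, 0, 0] = 1.0
        p = np.full((1, 8, 8), 0.1)
        p[0, 0, 0] = 0.9
        assert focal_keypoint_loss(p, y, 2.0) < focal_keypoint_loss(p, y, 0.0)


class TestSmoothL1:
    @pytest.mark.parametrize(
        "delta,expected", [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5), (-2.0, 1.5), (1.0, 0.5)]
    )
    def test_closed_forms_single_coordinate(self, delta, expected):
        t = BoxParams(10, 20, 100, 80)
        t_hat = BoxParams(10 + delta, 20, 100, 80)
        assert smooth_l1_box_loss(t_hat, t) == pytest.approx(expected, abs=1e-12)

    def test_sums_over_all_four_parameters(self):
        t = BoxParams(0, 0, 1, 1)
        t_hat = BoxParams(0.5, 0.5, 1.5, 3.0)
        assert smooth_l1_box_loss(t_hat, t) == pytest.approx(0.125 * 3 + 1.5)

    def test_total_loss_is_plain_sum(self):
        assert total_loss(0.0, 0.0) == 0.0
        assert total_loss(0.2, 0.3) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            total_loss(float("nan"), 0.0)


class TestKeypointTargets:
    def test_one_hot_channel_sums(self, clean_dataset):
        ann = clean_dataset.ground_truth[0]
        target = make_keypoint_target(ann, ann.bbox, SMALL)
        assert target.shape == (8, 56, 56)
        assert np.all(target.sum(axis=(1, 2)) == 1.0)

    def test_center_keypoint_maps_to_center_cell(self, clean_dataset):
        ann = clean_dataset.ground_truth[0]
        roi = BoxParams.from_any(ann.bbox)
        from hipmetrics.geometry import Keypoint, PelvisAnnotation

        # place one synthetic keypoint exactly at the RoI center
        coords = ann.coords().copy()
        coords[0] = [roi.x + roi.w / 2, roi.y + roi.h / 2]
        ann2 = PelvisAnnotation.from_coords(coords, ann.bbox)
        target = make_keypoint_target(ann2, roi, SMALL)
        assert target[0, 28, 28] == 1.0

    def test_keypoint_outside_roi_raises(self, clean_dataset):
        ann = clean_dataset.ground_truth[0]
        tiny = (ann.bbox[0], ann.bbox[1], 5.0, 5.0)
        with pytest.raises(ValueError):
            make_keypoint_target(ann, tiny, SMALL)

    def test_target_decode_round_trip_within_one_cell(self):
        rng = np.random.default_rng(1)
        from conftest import sample_feasible_config

        for _ in range(100):
            _, ann = sample_feasible_config(rng)
            roi = BoxParams.from_any(ann.bbox)
            target = make_keypoint_target(ann, roi, SMALL)
            decoded = decode_keypoints(target, roi)
            cell = np.array([roi.w / 56, roi.h / 56])
            err = np.abs(decoded.coords() - ann.coords())
            assert np.all(err[:, 0] <= cell[0]) and np.all(err[:, 1] <= cell[1])

    def test_heatmap_peak_at_keypoint_cell(self, clean_dataset):
        ann = clean_dataset.ground_truth[0]
        cfg = DetectorConfig(mask_resolution=56, target_mask_kind="heatmap")
        onehot = make_keypoint_target(ann, ann.bbox, SMALL)
        heat = make_keypoint_target(ann, ann.bbox, cfg)
        for k in range(8):
            assert np.argmax(heat[k]) == np.argmax(onehot[k])
            assert heat[k].max() == 1.0


class TestDecode:
    def test_uniform_map_tie_breaks_to_first_cell(self):
        probs = np.full((8, 10, 10), 0.3)
        ann = decode_keypoints(probs, BoxParams(0, 0, 100, 100))
        assert np.allclose(ann.coords(), [[5.0, 5.0]] * 8)

    def test_point_mass_decodes_to_cell_center(self):
        probs = np.zeros((8, 10, 10))
        probs[:, 4, 7] = 1.0
        ann = decode_keypoints(probs, BoxParams(10, 20, 100, 50))
        assert np.allclose(ann.coords(), [[10 + 75.0, 20 + 22.5]] * 8)

    def test_non_finite_maps_rejected(self):
        probs = np.zeros((8, 5, 5))
        probs[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            decode_keypoints(probs, BoxParams(0, 0, 10, 10))


class TestBuildDetector:
    def test_forward_contract_on_blank_image(self):
        model = build_detector(SMALL, seed=0)
        out = model.forward(np.zeros((256, 256), dtype=np.uint8))
        probs = out["keypoint_probs"]
        assert probs.shape == (8, 56, 56)
        assert np.all(np.isfinite(probs)) and np.all((probs > 0) & (probs < 1))
        assert np.all(np.isfinite(out["roi"].as_array()))
        assert out["roi"].w > 0 and out["roi"].h > 0

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(backbone="resnet101")

    @pytest.mark.parametrize("backbone", ["wide", "deep"])
    def test_sensitivity_variants_build_and_run(self, backbone):
        cfg = DetectorConfig(backbone=backbone, mask_resolution=28)
        model = build_detector(cfg, seed=0)
        out = model.forward(np.zeros((256, 256), dtype=np.uint8))
        assert out["keypoint_probs"].shape == (8, 28, 28)

    def test_checkpoint_round_trip(self, tmp_path, clean_dataset):
        model = build_detector(SMALL, seed=3)
        img = clean_dataset.images[0]
        before = model.forward(img)["keypoint_probs"]
        save_detector(model, tmp_path / "det.npz")
        loaded = load_detector(tmp_path / "det.npz")
        after = loaded.forward(img)["keypoint_probs"]
        assert np.allclose(before, after)
        assert loaded.config == model.config


class TestAugment:
    def test_zero_rotation_zero_noise_is_identity(self, clean_dataset):
        rng = np.random.default_rng(0)
        img, ann = clean_dataset.images[0], clean_dataset.ground_truth[0]
        img2, ann2 = augment(img, ann, rng, rotation_range_deg=0.0, noise_sigma=0.0)
        assert np.array_equal(img, img2)
        assert np.allclose(ann.coords(), ann2.coords())

    def test_rotation_preserves_measured_angles(self, clean_dataset):
        rng = np.random.default_rng(1)
        img, ann = clean_dataset.images[0], clean_dataset.ground_truth[0]
        base = measure_hips(ann)
        for _ in range(5):
            _, ann2 = augment(img, ann, rng, rotation_range_deg=6.0, noise_sigma=0.0)
            rotated = measure_hips(ann2)
            for side in ("right", "left"):
                assert rotated[side].as_tuple() == pytest.approx(
                    base[side].as_tuple(), abs=1e-6
                )

    def test_rotated_keypoints_track_image_content(self, clean_dataset):
        rng = np.random.default_rng(2)
        img, ann = clean_dataset.images[0], clean_dataset.ground_truth[0]
        img2, ann2 = augment(img, ann, rng, rotation_range_deg=8.0, noise_sigma=0.0)
        for side in ("right", "left"):
            b = ann2.get(side, "B")
            r = 4
            patch = img2[int(b.y) - r : int(b.y) + r + 1, int(b.x) - r : int(b.x) + r + 1]
            iy, ix = np.unravel_index(np.argmax(patch), patch.shape)
            peak = np.array([int(b.x) - r + ix, int(b.y) - r + iy])
            assert np.hypot(*(peak - [b.x, b.y])) <= 2.0


class TestTrainingSchedule:
    def test_plateau_divides_learning_rate_by_factor(self):
        """A simulated 3-epoch validation plateau drops the lr from 0.005 to 0.001."""
        ds = generate_dataset(8, rater_model=RaterModel.zero(), seed=31, noise_sigma=0.0)
        tc = TrainConfig(
            epochs=5, batch_size=4, learning_rate=0.005, plateau_patience=3, seed=0,
            rotation_range_deg=0.0, noise_sigma=0.0,
        )
        cfg = DetectorConfig(mask_resolution=28)
        # freeze learning entirely so the validation loss cannot improve
        frozen = TrainConfig(**{**tc.__dict__, "learning_rate": 1e-12})
        _, hist = train_detector(ds, frozen, cfg)
        assert len(hist["train_loss"]) == 5
        assert hist["lr"][-1] == pytest.approx(1e-12 / 5)

    def test_smoke_training_reduces_loss(self):
        ds = generate_dataset(16, seed=33)
        tc = TrainConfig(epochs=2, seed=0)
        model, hist = train_detector(ds, tc, DetectorConfig(mask_resolution=28))
        assert len(hist["train_loss"]) == 2
        assert hist["train_loss"][1] < hist["train_loss"][0]
        assert all(np.isfinite(hist["val_loss"]))

    def test_empty_split_rejected(self):
        ds = generate_dataset(4, seed=34)
        with pytest.raises(ValueError):
            train_detector(ds, TrainConfig(epochs=1), DetectorConfig(mask_resolution=28),
                           train_indices=[], val_indices=[0])


class TestCrossval:
    def test_fold_structure(self):
        ds = generate_dataset(8, seed=35)
        tc = TrainConfig(epochs=1, seed=0)
        models, folds = crossval_train(ds, k=2, train_config=tc,
                                       config=DetectorConfig(mask_resolution=28))
        assert len(models) == 2
        all_val = np.concatenate(folds)
        assert sorted(all_val.tolist()) == list(range(8))
        assert len(set(folds[0]) & set(folds[1])) == 0
        assert abs(len(folds[0]) - len(folds[1])) <= 1

    def test_k_less_than_two_rejected(self):
        ds = generate_dataset(4, seed=36)
        with pytest.raises(ValueError):
            crossval_train(ds, k=1)
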