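"""OKS detection metrics and agreement statistics against independent oracles."""

import math

import numpy as np
import pytest

from hipmetrics.evalmetrics import (
    OKS_THRESHOLDS,
    OKSConfig,
    bland_altman,
    icc,
    mann_whitney,
    map_mar,
    oks,
    pr_at_threshold,
)
from hipmetrics.geometry import PelvisAnnotation
from hipmetrics.phantom import RaterModel

from conftest import sample_feasible_config


def displaced(ann, index, dx, dy):
    coords = ann.coords().copy()
    coords[index] += [dx, dy]
    return PelvisAnnotation.from_coords(coords, ann.bbox, ann.image_id)


class TestOKS:
    def test_perfect_prediction_scores_one(self, clean_dataset):
        ann = clean_dataset.ground_truth[0]
        sims, mean = oks(ann, ann)
        assert np.allclose(sims, 1.0) and mean == 1.0

    def test_exp_minus_one_at_characteristic_distance(self, clean_dataset):
        """Displacing one keypoint by s*k*sqrt(2) gives similarity e^-1."""
        truth = clean_dataset.ground_truth[0]
        cfg = OKSConfig()
        s = math.sqrt(truth.bbox[2] * truth.bbox[3])
        k = cfg.k_vector()[0]
        d = s * k * math.sqrt(2)
        pred = displaced(truth, 0, d, 0.0)
        sims, _ = oks(pred, truth, cfg)
        assert sims[0] == pytest.approx(math.exp(-1), abs=1e-12)
        assert np.allclose(sims[1:], 1.0)

    def test_similarity_vanishes_at_large_distance(self, clean_dataset):
        truth = clean_dataset.ground_truth[0]
        pred = displaced(truth, 3, 1e5, 1e5)
        sims, _ = oks(pred, truth)
        assert sims[3] < 1e-12

    def test_monotone_decrease_in_displacement(self, clean_dataset):
        truth = clean_dataset.ground_truth[0]
        prev = 1.1
        for d in (1, 3, 7, 15, 40):
            sims, _ = oks(displaced(truth, 2, d, 0), truth)
            assert sims[2] < prev
            prev = sims[2]

    def test_invariant_under_joint_translation(self, clean_dataset):
        truth = clean_dataset.ground_truth[0]
        pred = displaced(truth, 5, 4.0, -3.0)
        base, _ = oks(pred, truth)
        shift = lambda pts: pts + [17.0, -6.0]
        moved, _ = oks(pred.transformed(shift), truth.transformed(shift))
        # bbox recomputation keeps w*h identical under pure translation
        assert np.allclose(base, moved)

    def test_zero_area_box_rejected(self, clean_dataset):
        # a zero-area box cannot even be represented as a valid annotation
        ann = clean_dataset.ground_truth[0]
        with pytest.raises(ValueError):
            PelvisAnnotation.from_coords(ann.coords(), (0, 0, 0.0, 10.0))


class TestDetectionPR:
    def test_perfect_predictions(self, clean_dataset):
        truths = clean_dataset.ground_truth
        pr = map_mar(truths, truths)
        assert pr.map == 1.0 and pr.mar == 1.0
        assert len(pr.thresholds) == 10

    def test_one_poor_keypoint_count_rule(self, clean_dataset):
        truth = clean_dataset.ground_truth[0]
        cfg = OKSConfig()
        s = math.sqrt(truth.bbox[2] * truth.bbox[3])
        # push keypoint 7 to similarity ~0.4: d = s k sqrt(2 ln(1/0.4))
        k = cfg.k_vector()[7]
        d = s * k * math.sqrt(2 * math.log(1 / 0.4))
        pred = displaced(truth, 7, d, 0)
        p, r = pr_at_threshold([pred], [truth], 0.5, cfg)
        assert r == pytest.approx(7 / 8)
        assert p == 1.0

    def test_missing_detection_contributes_eight_false_negatives(self, clean_dataset):
        truths = clean_dataset.ground_truth[:3]
        preds = [truths[0], None, truths[2]]
        p, r = pr_at_threshold(preds, truths, 0.9)
        assert r == pytest.approx(16 / 24)
        assert p == 1.0

    def test_constant_similarity_thresholds_strictly(self, clean_dataset):
        """Similarity 0.70 everywhere -> TP only at the 4 grid points below it
        (the 0.70 threshold itself is excluded by the strict inequality)."""
        truth = clean_dataset.ground_truth[0]
        cfg = OKSConfig.uniform(0.05)
        s = math.sqrt(truth.bbox[2] * truth.bbox[3])
        # nudge infinitesimally past the characteristic distance so float
        # rounding cannot place the similarity above the 0.70 grid point
        d = s * 0.05 * math.sqrt(2 * math.log(1 / 0.70)) * (1 + 1e-9)
        coords = truth.coords() + np.array([d, 0.0])
        pred = PelvisAnnotation.from_coords(coords, truth.bbox)
        sims, _ = oks(pred, truth, cfg)
        assert np.allclose(sims, 0.70, atol=1e-6)
        pr = map_mar([pred], [truth], cfg)
        assert pr.mar == pytest.approx(0.4)

    def test_brute_force_recount_oracle(self):
        rng = np.random.default_rng(6)
        cfg = OKSConfig()
        preds, truths = [], []
        for _ in range(100):
            _, ann = sample_feasible_config(rng)
            noisy = PelvisAnnotation.from_coords(
                ann.coords() + rng.normal(0, 4.0, size=(8, 2)), ann.bbox
            )
            truths.append(ann)
            preds.append(noisy)
        pr = map_mar(preds, truths, cfg)
        # independent recount: pool all similarities and recount per threshold
        sims = np.concatenate([oks(p, t, cfg)[0] for p, t in zip(preds, truths)])
        for i, thr in enumerate(OKS_THRESHOLDS):
            tp = int(np.sum(sims > thr))
            assert pr.recall[i] == pytest.approx(tp / sims.size)
        assert pr.mar == pytest.approx(np.mean(pr.recall))

    def test_length_mismatch_raises(self, clean_dataset):
        with pytest.raises(ValueError):
            pr_at_threshold(clean_dataset.ground_truth[:2], clean_dataset.ground_truth[:3], 0.5)


def icc2_oracle(x):
    """Direct two-way ANOVA mean-squares computation of ICC(2,1)."""
    n, k = x.shape
    grand = x.mean()
    ms_r = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum(
        (x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand) ** 2
    )
    ms_e = sse / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


class TestICC:
    def test_agrees_with_anova_mean_squares_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            m = int(rng.integers(2, 5))
            subject = rng.normal(0, 2, size=(n, 1))
            x = subject + rng.normal(0, 1, size=(n, m)) + rng.normal(0, 0.3, size=(1, m))
            coef, _ = icc(x)
            assert coef == pytest.approx(icc2_oracle(x), abs=1e-8)

    def test_duplicated_rater_columns_give_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 1))
        coef, _ = icc(np.repeat(base, 3, axis=1))
        assert coef == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        coef, _ = icc(rng.normal(size=(50, 2)))
        assert abs(coef) < 0.2

    def test_six_by_two_worked_matrix(self):
        x = np.array([[1.0, 2.0], [3.0, 3.5], [5.0, 4.0], [7.0, 8.0], [9.0, 8.5], [11.0, 12.0]])
        coef, ci = icc(x)
        assert coef == pytest.approx(icc2_oracle(x), abs=1e-8)
        assert ci[0] <= coef <= ci[1]
        assert -1 <= coef <= 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((5, 2)))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, 2.0], [3.0, 4.0]]))  # too few subjects
        bad = np.random.default_rng(0).normal(size=(5, 3))
        bad[2, 1] = np.nan
        with pytest.raises(ValueError):
            icc(bad)


class TestBlandAltman:
    def test_identical_measurements(self):
        a = np.arange(10.0)
        res = bland_altman(a, a)
        assert res["bias"] == 0.0
        assert res["loa_lower"] == 0.0 and res["loa_upper"] == 0.0

    def test_antisymmetry_of_bias(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert bland_altman(a, b)["bias"] == pytest.approx(-bland_altman(b, a)["bias"])

    def test_monte_carlo_limits_for_unit_normal_differences(self):
        rng = np.random.default_rng(4)
        b = rng.normal(0, 1, 10000)
        a = b + rng.normal(1.0, 1.0, 10000)
        res = bland_altman(a, b)
        assert res["bias"] == pytest.approx(1.0, abs=0.05)
        assert res["loa_upper"] == pytest.approx(1.0 + 1.96, abs=0.05)
        d = a - b
        inside = np.mean((d >= res["loa_lower"]) & (d <= res["loa_upper"]))
        assert 0.93 <= inside <= 0.97

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestMannWhitney:
    def test_identical_samples_high_p(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(x, x)
        assert p > 0.99

    def test_fully_separated_exact_enumeration(self):
        """x all greater than y at n=m=5: U = 25 and exact p = 2/252."""
        u, p = mann_whitney([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert u == 25.0
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_invariance_under_joint_monotone_transform(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(0.7, 1, size=25)
        u1, p1 = mann_whitney(x, y)
        u2, p2 = mann_whitney(np.exp(x), np.exp(y))
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestOKSConfigDefaults:
    def test_derived_from_rater_variability(self):
        """Default falloffs mirror the rater model: k = 2 sigma / scale, so D
        is the most forgiving landmark and B the strictest."""
        cfg = OKSConfig()
        assert cfg.per_label["D"] > cfg.per_label["C"] > cfg.per_label["B"]
        rater = RaterModel()
        scale = math.sqrt(215.0 * 110.0)  # typical phantom box area at 256 px
        derived = OKSConfig.from_rater_model(rater, scale)
        for lab in "ABCD":
            assert derived.per_label[lab] == pytest.approx(2 * rater.sigma(lab) / scale)

    def test_uniform_fallback(self):
        cfg = OKSConfig.uniform(0.05)
        assert np.allclose(cfg.k_vector(), 0.05)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            OKSConfig({"A": 0.1, "B": 0.1, "C": 0.1, "D": 0.0})
        with pytest.raises(ValueError):
            OKSConfig({"A": 0.1})
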