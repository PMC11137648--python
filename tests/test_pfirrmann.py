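"""Feature extractors (HPI/LBP/PHOG), disc crops, and the grading MLP."""

import numpy as np
import pytest

from spinedss import pfirrmann as pf
from spinedss import phantom as ph
from spinedss.exceptions import NotTrainedError, TrainingError, ValidationError


class TestHpi:
    def test_constant_zero_patch_all_mass_in_first_bin(self):
        h = pf.extract_hpi(np.zeros((10, 10)))
        assert h[0] == 1.0
        assert h[1:].sum() == 0.0

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        h = pf.extract_hpi(rng.integers(0, 256, (30, 30)))
        assert h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_grade1_first_moment_exceeds_grade5(self):
        cfg = ph.PhantomConfig(seed=60)
        specs = [
            ph.DiscGroundTruth(level_index=i + 1, herniated=False, pfirrmann=g)
            for i, g in enumerate([1, 5, 1, 5, 1])
        ]
        p = ph.generate_sagittal(cfg, specs)
        pts = p.vertebra_centers
        centers = np.arange(64) * 4 + 2  # bin centers on the 0..255 scale
        moments = []
        for p0, p1 in zip(pts[:-1], pts[1:]):
            patch = pf.crop_pfirrmann_roi(p.image, p0, p1)
            moments.append(float(pf.extract_hpi(patch) @ centers))
        assert min(moments[0], moments[2], moments[4]) > max(moments[1], moments[3])


class TestLbp:
    def test_constant_patch_all_ones_code(self):
        h = pf.extract_lbp(np.full((8, 8), 77.0))
        assert h[255] == 1.0

    def test_sums_to_one(self):
        rng = np.random.default_rng(1)
        h = pf.extract_lbp(rng.integers(0, 256, (20, 20)))
        assert h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_patch_too_small(self):
        with pytest.raises(ValidationError):
            pf.extract_lbp(np.zeros((2, 5)))

    def test_180_rotation_permutes_codes_by_bit_rotation(self):
        """Rotating the patch 180 deg rotates each 8-bit code by 4 positions."""
        rng = np.random.default_rng(2)
        patch = rng.integers(0, 256, (9, 9)).astype(float)
        h = pf.extract_lbp(patch)
        h_rot = pf.extract_lbp(np.rot90(patch, 2))
        perm = [((c << 4) | (c >> 4)) & 0xFF for c in range(256)]
        assert np.allclose(h_rot[perm], h)


class TestPhog:
    def test_constant_patch_uniform_fallback(self):
        v = pf.extract_phog(np.full((16, 16), 40.0))
        assert np.allclose(v, 1.0 / 252)

    def test_vertical_step_edge_concentrates_in_horizontal_gradient_bin(self):
        patch = np.zeros((32, 32))
        patch[:, 16:] = 200.0
        v = pf.extract_phog(patch)
        per_cell = v.reshape(21, 12)
        occupied = per_cell[per_cell.sum(axis=1) > 0]
        # gradient points along +x: orientation 0, first bin at every level
        assert (occupied.argmax(axis=1) == 0).all()

    def test_sums_to_one(self):
        rng = np.random.default_rng(3)
        v = pf.extract_phog(rng.integers(0, 256, (24, 24)))
        assert v.sum() == pytest.approx(1.0, abs=1e-9)

    def test_length_is_252(self):
        assert pf.extract_phog(np.eye(16) * 100).shape == (252,)


class TestFeatureVector:
    def test_length_exactly_572_with_fixed_block_order(self, disc_cohort):
        fv = pf.FeatureVector572(values=disc_cohort["features"][0])
        assert fv.values.shape == (572,)
        assert fv.hpi.shape == (64,)
        assert fv.lbp.shape == (256,)
        assert fv.phog.shape == (252,)

    def test_blocks_each_sum_to_one(self):
        rng = np.random.default_rng(4)
        patch = rng.integers(0, 256, (48, 96)).astype(float)
        fv = pf.build_feature_vector(patch)
        assert fv.hpi.sum() == pytest.approx(1.0, abs=1e-9)
        assert fv.lbp.sum() == pytest.approx(1.0, abs=1e-9)
        assert fv.phog.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_patches_identical_vectors(self):
        rng = np.random.default_rng(5)
        patch = rng.integers(0, 256, (48, 96)).astype(float)
        a = pf.build_feature_vector(patch)
        b = pf.build_feature_vector(patch.copy())
        assert np.array_equal(a.values, b.values)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            pf.FeatureVector572(values=np.zeros(571))


class TestCrop:
    def test_vertical_centers_crop_geometry(self):
        image = np.zeros((300, 300))
        patch = pf.crop_pfirrmann_roi(image, (150, 100), (150, 160))
        assert patch.shape == (48, 96)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(6)
        base = np.zeros((300, 300))
        base[:200, :200] = rng.integers(0, 255, (200, 200))
        shifted = np.zeros((300, 300))
        shifted[40:240, 30:230] = base[:200, :200]
        a = pf.crop_pfirrmann_roi(base, (90, 60), (94, 120))
        b = pf.crop_pfirrmann_roi(shifted, (120, 100), (124, 160))
        assert np.allclose(a, b)

    def test_phantom_patch_intensity_tracks_grade(self):
        """Crop means decrease monotonically with grade under fixed geometry."""
        cfg = ph.PhantomConfig(seed=61, noise_sigma=0.0)
        p = ph.generate_sagittal(
            cfg,
            [
                ph.DiscGroundTruth(level_index=i + 1, herniated=False, pfirrmann=i + 1)
                for i in range(5)
            ],
        )
        pts = p.vertebra_centers
        means = [
            float(pf.crop_pfirrmann_roi(p.image, p0, p1).mean())
            for p0, p1 in zip(pts[:-1], pts[1:])
        ]
        assert all(a > b for a, b in zip(means, means[1:]))


class TestMlp:
    def test_config_locks_architecture(self):
        with pytest.raises(ValidationError):
            pf.MlpConfig(layer_sizes=(572, 100, 5))

    def test_missing_grade_rejected(self, disc_cohort):
        x = disc_cohort["features"][:50]
        y = np.where(disc_cohort["grades"][:50] == 5, 4, disc_cohort["grades"][:50])
        with pytest.raises(TrainingError, match="5"):
            pf.train_pfirrmann(x, y, pf.MlpConfig(epochs=1))

    def test_training_is_deterministic(self, disc_cohort):
        x = disc_cohort["features"][:100]
        y = disc_cohort["grades"][:100]
        cfg = pf.MlpConfig(epochs=5, seed=3)
        m1 = pf.train_pfirrmann(x, y, cfg)
        m2 = pf.train_pfirrmann(x, y, cfg)
        for w1, w2 in zip(m1.mlp.coefs_, m2.mlp.coefs_):
            assert np.array_equal(w1, w2)

    def test_loss_decreases_over_training(self, pfirrmann_model):
        curve = pfirrmann_model.loss_curve
        assert curve[-1] < curve[0]

    def test_probabilities_sum_to_one(self, disc_cohort, pfirrmann_model):
        _, proba = pf.predict_pfirrmann(pfirrmann_model, disc_cohort["features"][7])
        assert proba.sum() == pytest.approx(1.0, abs=1e-9)
        assert proba.shape == (5,)

    def test_untrained_model_rejected(self, disc_cohort):
        with pytest.raises(NotTrainedError):
            pf.predict_pfirrmann(
                pf.PfirrmannModel(config=pf.MlpConfig()), disc_cohort["features"][0]
            )

    def test_holdout_accuracy_at_least_090(self, disc_cohort, holdout_mask, pfirrmann_model):
        preds = [
            pf.predict_pfirrmann(pfirrmann_model, f)[0]
            for f in disc_cohort["features"][~holdout_mask]
        ]
        truth = disc_cohort["grades"][~holdout_mask]
        assert np.mean(np.asarray(preds) == truth) >= 0.90

    def test_errors_concentrate_on_adjacent_grades(
        self, disc_cohort, holdout_mask, pfirrmann_model
    ):
        preds = np.asarray(
            [
                pf.predict_pfirrmann(pfirrmann_model, f)[0]
                for f in disc_cohort["features"][~holdout_mask]
            ]
        )
        truth = disc_cohort["grades"][~holdout_mask]
        errors = np.abs(preds - truth)[preds != truth]
        if errors.size:
            assert np.mean(errors == 1) >= 0.80

    def test_permuted_labels_give_chance_accuracy(self, disc_cohort, holdout_mask):
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(disc_cohort["grades"][holdout_mask])
        model = pf.train_pfirrmann(
            disc_cohort["features"][holdout_mask], y_perm, pf.MlpConfig(seed=0)
        )
        preds = [
            pf.predict_pfirrmann(model, f)[0]
            for f in disc_cohort["features"][~holdout_mask]
        ]
        acc = np.mean(np.asarray(preds) == disc_cohort["grades"][~holdout_mask])
        assert 0.14 <= acc <= 0.26

    def test_accuracy_monotone_in_class_separation(self):
        """Wider grade-to-intensity gaps can only help a fixed-size model."""
        rng = np.random.default_rng(9)
        accs = []
        for gap_scale in (0.25, 0.6, 1.0):
            feats, grades = [], []
            for i in range(30):
                cfg = ph.PhantomConfig(seed=5000 + i, noise_sigma=12.0)
                perm = rng.permutation(5) + 1
                specs = [
                    ph.DiscGroundTruth(level_index=j + 1, herniated=False, pfirrmann=int(g))
                    for j, g in enumerate(perm)
                ]
                p = ph.generate_sagittal(cfg, specs)
                pts = np.asarray(p.vertebra_centers)
                for (p0, p1), spec, mask in zip(
                    zip(pts[:-1], pts[1:]), specs, p.disc_masks
                ):
                    # shrink the apparent separation by pulling disc pixels
                    # toward the grade-3 level before feature extraction
                    grades.append(spec.pfirrmann)
                    target = ph.disc_intensity_for_grade(3)
                    img = p.image.astype(float)
                    blend = img + (1 - gap_scale) * (target - img) * mask
                    patch = pf.crop_pfirrmann_roi(blend, p0, p1)
                    feats.append(pf.build_feature_vector(patch).values)
            feats = np.asarray(feats)
            grades_arr = np.asarray(grades)
            tr = np.arange(len(grades_arr)) % 3 != 2
            model = pf.train_pfirrmann(feats[tr], grades_arr[tr], pf.MlpConfig(epochs=80, seed=1))
            preds = [pf.predict_pfirrmann(model, f)[0] for f in feats[~tr]]
            accs.append(float(np.mean(np.asarray(preds) == grades_arr[~tr])))
        assert accs[0] <= accs[1] + 0.05
        assert accs[1] <= accs[2] + 0.05
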