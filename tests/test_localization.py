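"""Chain geometry, anatomical constraints, repair, and detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinedss import localization as loc
from spinedss import phantom as ph
from spinedss.exceptions import (
    ChainTooShortError,
    DegenerateGeometryError,
    UnrepairableChainError,
    ValidationError,
)


def straight_chain(n=6, step=60.0, spacing=0.2646):
    return loc.PointChain(
        points=[(100.0, 50.0 + step * i) for i in range(n)], pixel_spacing_mm=spacing
    )


class TestSegmentLength:
    def test_pythagorean_triple(self):
        c = loc.PointChain(points=[(0, 0), (3, 4), (10, 10)])
        assert loc.segment_length(c, 1) == 5.0

    def test_coincident_points_zero(self):
        c = loc.PointChain(points=[(2, 2), (2, 2), (5, 5)])
        assert loc.segment_length(c, 1) == 0.0

    def test_translation_invariance(self):
        c = loc.PointChain(points=[(1, 1), (4, 5), (9, 9)])
        assert loc.segment_length(c, 1) == 5.0

    def test_index_out_of_range(self):
        c = loc.PointChain(points=[(0, 0), (1, 1), (2, 2)])
        with pytest.raises(IndexError):
            loc.segment_length(c, 3)


class TestDistanceConstraint:
    def test_equally_spaced_ok(self):
        assert loc.distance_ok(straight_chain(), 3)

    def test_ratio_half_violates_lower_bound(self):
        c = loc.PointChain(points=[(0, 0), (0, 10), (0, 15), (0, 30)])
        assert not loc.distance_ok(c, 2)  # ratio 0.5 < lambda1 = 0.6

    def test_upper_bound_is_strict(self):
        c = loc.PointChain(points=[(0, 0), (0, 8), (0, 18), (0, 30)])
        assert not loc.distance_ok(c, 2)  # ratio exactly 1.25

    def test_zero_previous_segment_degenerate(self):
        c = loc.PointChain(points=[(0, 0), (0, 0), (0, 5), (0, 10)])
        with pytest.raises(DegenerateGeometryError):
            loc.distance_ok(c, 2)


class TestAngle:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            ([(0, 0), (1, 0), (2, 0)], 180.0),
            ([(0, 0), (1, 1), (2, 0)], 90.0),
            ([(0, 0), (1, 0), (1, 1)], 90.0),
        ],
    )
    def test_hand_computed_angles(self, pts, expected):
        assert loc.angle_at(loc.PointChain(points=pts), 2) == pytest.approx(expected)

    def test_zero_segment_degenerate(self):
        c = loc.PointChain(points=[(0, 0), (0, 0), (1, 1)])
        with pytest.raises(DegenerateGeometryError):
            loc.angle_at(c, 2)

    @given(
        angle=st.floats(0.1, 2 * math.pi - 0.1),
        scale=st.floats(0.1, 10.0),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_similarity_invariance(self, angle, scale, tx, ty):
        """Angles and distance ratios are preserved by similarity transforms."""
        pts = np.array([(0.0, 0.0), (13.0, 7.0), (25.0, 3.0), (40.0, 11.0)])
        rot = np.array(
            [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
        )
        moved = scale * pts @ rot.T + np.array([tx, ty])
        c0 = loc.PointChain(points=pts.tolist())
        c1 = loc.PointChain(points=moved.tolist())
        for i in (2, 3):
            assert loc.angle_at(c1, i) == pytest.approx(loc.angle_at(c0, i), abs=1e-6)
            assert loc.distance_ok(c1, i) == loc.distance_ok(c0, i)


class TestRepair:
    def test_clean_chain_is_fixed_point(self):
        c = straight_chain()
        res = loc.repair_chain(c)
        assert res.chain.points == c.points
        assert res.repaired_indices == ()
        assert res.converged

    def test_displaced_interior_point_restored(self):
        c = straight_chain(n=6, step=78.0)
        pts = list(c.points)
        original = pts[2]
        pts[2] = (pts[2][0] + 30.0, pts[2][1])  # 30 px lateral displacement
        res = loc.repair_chain(loc.PointChain(points=pts, pixel_spacing_mm=0.2646))
        assert 3 in res.repaired_indices
        restored = res.chain.points[2]
        err_mm = math.dist(restored, original) * 0.2646
        assert err_mm < 4.0
        for i in (0, 1, 3, 4, 5):
            assert res.chain.points[i] == pts[i]

    def test_repair_is_idempotent(self):
        pts = list(straight_chain(n=6, step=70.0).points)
        pts[3] = (pts[3][0] - 45.0, pts[3][1] + 20.0)
        once = loc.repair_chain(loc.PointChain(points=pts))
        twice = loc.repair_chain(once.chain)
        assert twice.chain.points == once.chain.points
        assert twice.repaired_indices == ()

    def test_all_points_deviant_unrepairable(self):
        # geometric spacing: every ratio is 2.0, no clean reference remains
        pts = [(0.0, 0.0), (0.0, 5.0), (0.0, 15.0), (0.0, 35.0), (0.0, 75.0)]
        with pytest.raises(UnrepairableChainError):
            loc.repair_chain(loc.PointChain(points=pts))

    def test_too_short_for_repair(self):
        with pytest.raises(ChainTooShortError):
            loc.repair_chain(loc.PointChain(points=[(0, 0), (0, 1), (0, 2)]))

    def test_flagged_set_matches_brute_force_oracle(self):
        """Deviance flags equal a direct re-evaluation of both constraints."""
        rng = np.random.default_rng(0)
        cfg = loc.ConstraintConfig()
        for trial in range(50):
            n = int(rng.integers(5, 9))
            pts = [(100.0 + rng.uniform(-2, 2), 60.0 * i + rng.uniform(-2, 2)) for i in range(n)]
            k = int(rng.integers(1, n - 1))
            pts[k] = (pts[k][0] + rng.uniform(35, 60), pts[k][1])
            chain = loc.PointChain(points=pts)
            # independent brute force over the definitions
            expected = set()
            for i in range(2, n):
                v_prev = math.dist(pts[i - 2], pts[i - 1])
                v = math.dist(pts[i - 1], pts[i])
                ratio = v / v_prev
                u = np.subtract(pts[i - 2], pts[i - 1])
                w = np.subtract(pts[i], pts[i - 1])
                ang = math.degrees(
                    math.acos(
                        np.clip(np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w)), -1, 1)
                    )
                )
                if not (cfg.lambda1 < ratio < cfg.lambda2) or not (
                    cfg.theta1_deg < ang <= cfg.theta2_deg
                ):
                    expected.add(i)
            lengths = [math.dist(pts[i], pts[i + 1]) for i in range(n - 1)]
            med = float(np.median(lengths))
            if not cfg.lambda1 < lengths[0] / med < cfg.lambda2:
                expected.add(1)
            if not cfg.lambda1 < lengths[-1] / med < cfg.lambda2:
                expected.add(n)
            assert loc.find_deviant_points(chain, cfg) == expected


class TestDetection:
    def test_phantom_centers_detected_within_4mm(self):
        cfg = ph.PhantomConfig(seed=20, noise_sigma=0.0)
        specs = [
            ph.DiscGroundTruth(level_index=i + 1, herniated=False, pfirrmann=(i % 5) + 1)
            for i in range(5)
        ]
        p = ph.generate_sagittal(cfg, specs)
        det = loc.detect_vertebrae(p.image)
        assert len(det.points) == cfg.n_vertebrae
        truth = np.asarray(p.vertebra_centers)
        pred = np.asarray(det.points)
        err_mm = np.linalg.norm(pred - truth, axis=1) * cfg.pixel_spacing_mm
        assert (err_mm < 4.0).all()

    def test_blank_image_chain_too_short(self):
        with pytest.raises(ChainTooShortError):
            loc.detect_vertebrae(np.zeros((128, 128), dtype=np.uint8))

    def test_occluded_vertebra_restored_by_repair(self):
        cfg = ph.PhantomConfig(seed=21)
        specs = [
            ph.DiscGroundTruth(level_index=i + 1, herniated=False, pfirrmann=1)
            for i in range(5)
        ]
        p = ph.generate_sagittal(cfg, specs)
        image = p.image.copy()
        x, y = p.vertebra_centers[2]
        image[int(y) - 30 : int(y) + 30, int(x) - 35 : int(x) + 35] = 30  # occlude
        det = loc.detect_vertebrae(image)
        assert len(det.points) == cfg.n_vertebrae - 1
        # insert a deliberately bad placeholder where the vertebra was lost,
        # as a detector emitting a spurious low-quality box would
        pts = list(det.points)
        pts.insert(2, (x + 60.0, y - 25.0))
        res = loc.repair_chain(loc.PointChain(points=pts, pixel_spacing_mm=cfg.pixel_spacing_mm))
        truth = loc.PointChain(points=p.vertebra_centers, pixel_spacing_mm=cfg.pixel_spacing_mm)
        match = loc.localization_sensitivity(res.chain, truth, threshold_mm=4.0)
        assert match.sensitivity == 1.0


class TestSensitivity:
    def test_identical_chains(self):
        c = straight_chain()
        res = loc.localization_sensitivity(c, c, threshold_mm=4.0)
        assert res.sensitivity == 1.0
        assert res.mean_distance_mm == 0.0

    def test_uniform_5mm_displacement_misses_at_4mm(self):
        truth = straight_chain()
        shift = 5.0 / 0.2646
        pred = loc.PointChain(
            points=[(x + shift, y) for x, y in truth.points], pixel_spacing_mm=0.2646
        )
        assert loc.localization_sensitivity(pred, truth, 4.0).sensitivity == 0.0

    def test_one_missing_point_gives_fraction(self):
        truth = straight_chain(n=5)
        pred = loc.PointChain(points=truth.points[:-1], pixel_spacing_mm=0.2646)
        assert loc.localization_sensitivity(pred, truth, 4.0).sensitivity == 0.8

    def test_empty_chain_rejected(self):
        with pytest.raises(ValidationError):
            loc.localization_sensitivity(
                loc.PointChain(points=[]), straight_chain(), 4.0
            )
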