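"""Gaussian eye trackers: density, assignment, updates, corrections."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from blinktrack.pairing import BlinkDetection
from blinktrack.tracking import (
    ACTIVE,
    FaceTrack,
    GaussianTracker,
    assign_event,
    box_center,
    correct_single_eye,
    correct_with_blink,
    event_score,
    face_box,
    init_face,
    update_tracker,
)


def tracker_with_sigma(mu, sxx, sxy, syy):
    tr = GaussianTracker(*mu)
    tr.set_sigma(sxx, sxy, syy, min_eig=1e-6, max_eig=1e9)
    return tr


def random_spd(rng, lo=2.0, hi=80.0):
    a = rng.uniform(-1, 1, (2, 2))
    s = a @ a.T + np.eye(2) * 0.5
    s *= rng.uniform(lo, hi) / np.trace(s)
    return s


def detection(left, right, t=0):
    return BlinkDetection(
        t=t, left_eye=left, right_eye=right,
        eye_distance=math.dist(left, right),
    )


class TestDensity:
    def test_at_mean_with_identity_sigma(self):
        tr = tracker_with_sigma((10.0, 20.0), 1.0, 0.0, 1.0)
        assert event_score(tr, (10.0, 20.0)) == pytest.approx(1 / (2 * math.pi), rel=1e-12)

    def test_one_sigma_offset_with_identity(self):
        tr = tracker_with_sigma((0.0, 0.0), 1.0, 0.0, 1.0)
        expected = math.exp(-0.5) / (2 * math.pi)
        assert event_score(tr, (1.0, 0.0)) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scipy_density(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(0, 300, 2)
        s = random_spd(rng)
        tr = tracker_with_sigma(mu, s[0, 0], s[0, 1], s[1, 1])
        for _ in range(20):
            u = mu + rng.normal(0, 10, 2)
            expected = multivariate_normal(mu, s).pdf(u)
            assert event_score(tr, tuple(u)) == pytest.approx(expected, rel=1e-9)


class TestAssignment:
    def make_face(self, face_id, left_mu, right_mu):
        return FaceTrack(
            face_id=face_id,
            left=GaussianTracker(*left_mu),
            right=GaussianTracker(*right_mu),
            scale=1.0,
        )

    def test_event_at_mean_is_assigned(self):
        face = self.make_face(0, (66, 97), (161, 97))
        assert assign_event([face], 66, 97) == (0, "left")

    def test_event_far_from_all_trackers_is_background(self):
        face = self.make_face(0, (66, 97), (161, 97))
        assert assign_event([face], 66, 97 + 10 * 19) is None

    def test_equidistant_event_breaks_tie_to_first_side(self):
        face = self.make_face(0, (60, 100), (160, 100))
        assert assign_event([face], 110, 100) == (0, "left")

    def test_lost_faces_do_not_compete(self):
        face = self.make_face(0, (66, 97), (161, 97))
        face.status = "lost"
        assert assign_event([face], 66, 97) is None


class TestUpdate:
    def test_unit_rate_jumps_to_event(self):
        tr = GaussianTracker(0.0, 0.0)
        update_tracker(tr, (30.0, 40.0), 5, eta_mu=1.0)
        assert (tr.mu_x, tr.mu_y) == (30.0, 40.0)

    def test_zero_rate_leaves_mean_unchanged(self):
        tr = GaussianTracker(3.0, 4.0)
        update_tracker(tr, (30.0, 40.0), 5, eta_mu=0.0)
        assert (tr.mu_x, tr.mu_y) == (3.0, 4.0)

    def test_mean_tracks_a_drifting_event_cloud(self):
        """5,000 events around a linearly drifting center: the blended mean
        ends within 2 px of the final true center."""
        rng = np.random.default_rng(42)
        tr = GaussianTracker(100.0, 100.0)
        n = 5000
        for i in range(n):
            cx = 100.0 + 30.0 * i / n
            cy = 100.0 + 10.0 * i / n
            u = (cx + rng.normal(0, 3), cy + rng.normal(0, 3))
            update_tracker(tr, u, i, eta_mu=0.05)
        assert math.hypot(tr.mu_x - 130.0, tr.mu_y - 110.0) < 2.0

    def test_covariance_converges_to_generating_covariance(self):
        """Static Gaussian cloud: Sigma estimate within 25% at 10,000 events."""
        rng = np.random.default_rng(7)
        true_sigma = np.array([[36.0, 8.0], [8.0, 16.0]])
        chol = np.linalg.cholesky(true_sigma)
        tr = GaussianTracker(50.0, 50.0)
        for i in range(10_000):
            u = np.array([50.0, 50.0]) + chol @ rng.normal(0, 1, 2)
            update_tracker(tr, tuple(u), i)
        est = np.array([[tr.sxx, tr.sxy], [tr.sxy, tr.syy]])
        assert np.abs(est - true_sigma).max() / np.abs(true_sigma).max() < 0.25

    def test_sigma_eigenvalues_stay_clamped(self):
        tr = GaussianTracker(0.0, 0.0)
        for i in range(200):
            update_tracker(tr, (500.0 * (-1) ** i, 500.0), i, eta_sigma=0.5)
        eig = np.linalg.eigvalsh(np.array([[tr.sxx, tr.sxy], [tr.sxy, tr.syy]]))
        assert eig.min() >= 1.0 - 1e-9
        assert eig.max() <= 256.0 + 1e-9

    def test_mean_stays_in_convex_hull_of_inputs(self):
        rng = np.random.default_rng(3)
        tr = GaussianTracker(50.0, 50.0)
        xs = [50.0]
        for i in range(500):
            u = (rng.uniform(40, 90), 50.0)
            xs.append(u[0])
            update_tracker(tr, u, i)
            assert min(xs) <= tr.mu_x <= max(xs)


class TestFaceLifecycle:
    @pytest.mark.parametrize(
        "left,right,expected_scale",
        [((66.0, 97.0), (161.0, 97.0), 1.0),
         ((23.5, 97.0), (213.5, 97.0), 2.0),
         ((90.0, 97.0), (137.5, 97.0), 0.5)],
    )
    def test_init_face_scale_from_eye_distance(self, left, right, expected_scale):
        face = init_face(detection(left, right), face_id=0)
        assert face.scale == pytest.approx(expected_scale)
        assert face.left.mu == left
        assert face.right.mu == right
        assert face.status == ACTIVE

    def test_blink_correction_resets_eye_positions_exactly(self):
        face = init_face(detection((66.0, 97.0), (161.0, 97.0)), face_id=0)
        face.left.mu_x += 30.0  # simulated drift
        face.right.mu_y -= 12.0
        det = detection((70.0, 95.0), (160.0, 99.0), t=10)
        correct_with_blink(face, det)
        assert face.left.mu == (70.0, 95.0)
        assert face.right.mu == (160.0, 99.0)
        assert face.scale == pytest.approx(det.eye_distance / 95.0)
        assert face.last_blink_t == 10

    def test_single_eye_correction_moves_only_that_eye(self):
        face = init_face(detection((66.0, 97.0), (161.0, 97.0)), face_id=0)
        correct_single_eye(face, "right", (170.0, 99.0), t=20)
        assert face.left.mu == (66.0, 97.0)
        assert face.right.mu == (170.0, 99.0)
        assert face.scale == pytest.approx(1.0)  # unchanged

    def test_face_box_geometry(self):
        face = init_face(detection((66.0, 97.0), (161.0, 97.0)), face_id=0)
        x, y, w, h = face_box(face)
        assert w == pytest.approx(2.2 * 95)
        assert h == pytest.approx(2.8 * 95)
        assert x + w / 2 == pytest.approx(113.5)       # centered on eye midpoint
        assert y + 0.35 * h == pytest.approx(97.0)     # eyes at 35% height
        cx, cy = box_center((x, y, w, h))
        assert cx == pytest.approx(113.5)
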