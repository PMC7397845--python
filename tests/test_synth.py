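"""Statistical and structural properties of the scene simulator."""

import numpy as np
import pytest

from blinktrack.events import OFF, ON
from blinktrack.synth import (
    FaceSpec,
    SceneSpec,
    load_scene_spec,
    make_annotated_blinks,
    save_scene_spec,
    scene_spec_from_dict,
    scene_spec_to_dict,
    simulate_blink_events,
    simulate_scene,
)

S = 1_000_000


class TestBlinkEvents:
    def test_all_event_times_inside_the_blink_window(self, geometry):
        rng = np.random.default_rng(0)
        ev = simulate_blink_events((150.0, 120.0), t0=1_000_000, rng=rng)
        assert ev.t.min() >= 1_000_000
        assert ev.t.max() <= 1_250_000

    def test_on_phase_precedes_off_phase(self, geometry):
        rng = np.random.default_rng(1)
        ev = simulate_blink_events((150.0, 120.0), t0=0, rng=rng)
        assert ev.t[ev.p == ON].max() <= 100_000
        assert ev.t[ev.p == OFF].min() >= 100_000

    def test_event_count_concentrates_around_configured_intensity(self):
        """Mean count over 100 seeded runs lies within the Poisson band
        lambda +- 3 sqrt(lambda)/sqrt(100) for lambda = 600."""
        counts = [
            len(simulate_blink_events((150.0, 120.0), 0, np.random.default_rng(s)))
            for s in range(100)
        ]
        lam = 600.0
        assert abs(np.mean(counts) - lam) <= 3 * np.sqrt(lam) / 10

    def test_double_scale_quadruples_the_count(self):
        """Counts scale with the face area (scale^2), within 10% over 100 seeds."""
        c1 = np.mean([
            len(simulate_blink_events((150.0, 120.0), 0, np.random.default_rng(s), scale=1))
            for s in range(100)
        ])
        c2 = np.mean([
            len(simulate_blink_events((150.0, 120.0), 0, np.random.default_rng(1000 + s),
                                      scale=2))
            for s in range(100)
        ])
        assert c2 / c1 == pytest.approx(4.0, rel=0.10)

    def test_indoor_is_more_on_dominant_than_outdoor(self):
        rng = np.random.default_rng(5)
        indoor = simulate_blink_events((150.0, 120.0), 0, rng, condition="indoor")
        outdoor = simulate_blink_events((150.0, 120.0), 0, rng, condition="outdoor")
        r_in = (indoor.p == ON).sum() / (indoor.p == OFF).sum()
        r_out = (outdoor.p == ON).sum() / (outdoor.p == OFF).sum()
        assert r_in > r_out


class TestScene:
    def test_noise_only_scene_has_poisson_count(self):
        spec = SceneSpec(duration_us=10 * S, faces=[], noise_rate=1000.0, seed=3)
        stream, truth = simulate_scene(spec)
        assert abs(len(stream) - 10_000) <= 3 * np.sqrt(10_000)
        assert truth.faces == []

    def test_ground_truth_lists_every_blink(self):
        spec = SceneSpec(
            duration_us=10 * S,
            faces=[FaceSpec(
                trajectory=[(0, 113.5, 127.0), (10 * S, 113.5, 127.0)],
                eye_distance=95.0,
                blink_times=[1 * S, 3 * S, 5 * S, 7 * S, 9 * S],
            )],
            noise_rate=0.0,
            seed=4,
        )
        stream, truth = simulate_scene(spec)
        assert truth.faces[0].blink_times == [1 * S, 3 * S, 5 * S, 7 * S, 9 * S]
        assert len(truth.faces[0].blink_eyes) == 5

    def test_stream_and_truth_are_mutually_consistent(self):
        """Every blink time has events concentrated near its eye positions."""
        spec = SceneSpec(
            duration_us=5 * S,
            faces=[FaceSpec(
                trajectory=[(0, 113.5, 127.0), (5 * S, 113.5, 127.0)],
                eye_distance=95.0, blink_times=[2 * S],
            )],
            noise_rate=0.0, seed=6,
        )
        stream, truth = simulate_scene(spec)
        (lx, ly), (rx, ry) = truth.faces[0].blink_eyes[0]
        win = (stream.t >= 2 * S) & (stream.t <= 2 * S + 250_000)
        near_left = win & (np.hypot(stream.x - lx, stream.y - ly) < 30)
        near_right = win & (np.hypot(stream.x - rx, stream.y - ry) < 30)
        assert near_left.sum() > 300 and near_right.sum() > 300

    def test_same_seed_reproduces_identical_stream(self):
        spec = SceneSpec(duration_us=3 * S, faces=[FaceSpec(
            trajectory=[(0, 100.0, 100.0), (3 * S, 140.0, 100.0)],
            eye_distance=95.0, blink_times=[1 * S])], noise_rate=500.0, seed=9)
        s1, _ = simulate_scene(spec)
        s2, _ = simulate_scene(spec)
        assert s1 == s2

    def test_blink_outside_duration_rejected(self):
        spec = SceneSpec(duration_us=1 * S, faces=[FaceSpec(
            trajectory=[(0, 100.0, 100.0), (S, 100.0, 100.0)],
            eye_distance=95.0, blink_times=[900_000])])
        with pytest.raises(ValueError):
            simulate_scene(spec)

    def test_events_in_bounds_and_sorted(self):
        spec = SceneSpec(duration_us=3 * S, faces=[FaceSpec(
            trajectory=[(0, 30.0, 30.0), (3 * S, 280.0, 210.0)],
            eye_distance=95.0, blink_times=[1 * S])], noise_rate=2000.0, seed=12)
        stream, _ = simulate_scene(spec)
        stream.validate()
        assert np.all(np.diff(stream.t) >= 0)


class TestAnnotatedBlinks:
    def test_requires_at_least_one(self):
        with pytest.raises(ValueError):
            make_annotated_blinks(0)

    def test_windows_are_valid_and_cycle_subjects(self):
        rng = np.random.default_rng(2)
        blinks = make_annotated_blinks(8, rng=rng)
        assert {b.subject_id for b in blinks} == {f"s{i}" for i in range(6)}
        for b in blinks:
            assert b.events.t.min() >= 0
            assert b.events.t.max() <= b.window_length


def test_scene_spec_json_round_trip(tmp_path):
    spec = SceneSpec(
        duration_us=5 * S,
        faces=[FaceSpec(
            trajectory=[(0, 100.0, 100.0), (5 * S, 150.0, 100.0)],
            eye_distance=[(0, 95.0), (5 * S, 120.0)],
            blink_times=[S], tilt=[(0, 0.0), (5 * S, -0.1)],
        )],
        noise_rate=250.0, seed=5,
    )
    path = tmp_path / "scene.json"
    save_scene_spec(spec, path)
    back = load_scene_spec(path)
    assert scene_spec_to_dict(back) == scene_spec_to_dict(spec)
    s1, _ = simulate_scene(spec)
    s2, _ = simulate_scene(back)
    assert s1 == s2
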