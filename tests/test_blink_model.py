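"""Blink-template averaging, interpolation and serialization."""

import math

import numpy as np
import pytest

from blinktrack.blink_model import (
    BlinkModel,
    build_model,
    load_model,
    model_value,
    save_model,
)
from blinktrack.events import OFF, ON, AnnotatedBlink, Event, EventStream
from blinktrack.synth import make_annotated_blinks

from test_activity import direct_sum_activity

TAU = 50_000.0


def one_event_blink(geometry, t=0, p=ON):
    ev = EventStream.from_events([Event(150, 120, t, p)], geometry)
    return AnnotatedBlink(events=ev, window_start=0)


class TestBuildModel:
    def test_identical_blinks_average_to_the_single_curve(self, geometry):
        rng = np.random.default_rng(3)
        blink = make_annotated_blinks(1, rng=rng, geometry=geometry)[0]
        single = build_model([blink])
        averaged = build_model([blink] * 7)
        np.testing.assert_allclose(averaged.b_on, single.b_on, rtol=1e-12, atol=1e-12)
        np.testing.assert_allclose(averaged.b_off, single.b_off, rtol=1e-12, atol=1e-12)
        assert averaged.m_blinks == 7

    def test_single_on_event_gives_pure_exponential(self, geometry):
        model = build_model([one_event_blink(geometry)])
        expected = np.exp(-model.grid_times / TAU)
        np.testing.assert_allclose(model.b_on, expected, rtol=1e-12)
        assert (model.b_off == 0).all()

    def test_jittered_blinks_match_direct_sum_oracle_mean(self, geometry):
        """Every grid sample equals the mean of the per-blink direct sums."""
        rng = np.random.default_rng(11)
        blinks = make_annotated_blinks(10, rng=rng, geometry=geometry)
        model = build_model(blinks)
        for p, curve in ((ON, model.b_on), (OFF, model.b_off)):
            expected = np.zeros_like(model.grid_times)
            for blink in blinks:
                times = blink.events.t[blink.events.p == p]
                expected += [
                    direct_sum_activity(times, g, TAU, 1.0) for g in model.grid_times
                ]
            np.testing.assert_allclose(curve, expected / len(blinks), rtol=1e-9)

    def test_order_invariance(self, geometry):
        rng = np.random.default_rng(5)
        blinks = make_annotated_blinks(6, rng=rng, geometry=geometry)
        a = build_model(blinks)
        b = build_model(list(reversed(blinks)))
        np.testing.assert_allclose(a.b_on, b.b_on, rtol=1e-12)
        np.testing.assert_allclose(a.b_off, b.b_off, rtol=1e-12)
        assert a.n_events == b.n_events

    def test_model_bounded_by_per_blink_envelope(self, geometry):
        rng = np.random.default_rng(13)
        blinks = make_annotated_blinks(8, rng=rng, geometry=geometry)
        model = build_model(blinks)
        per_blink = [build_model([b]) for b in blinks]
        for curve, attr in ((model.b_on, "b_on"), (model.b_off, "b_off")):
            stack = np.stack([getattr(m, attr) for m in per_blink])
            assert (curve >= stack.min(axis=0) - 1e-12).all()
            assert (curve <= stack.max(axis=0) + 1e-12).all()

    def test_empty_and_mixed_condition_inputs_rejected(self, geometry):
        with pytest.raises(ValueError):
            build_model([])
        rng = np.random.default_rng(1)
        indoor = make_annotated_blinks(1, "indoor", rng, geometry)
        outdoor = make_annotated_blinks(1, "outdoor", rng, geometry)
        with pytest.raises(ValueError, match="condition"):
            build_model(indoor + outdoor)


@pytest.fixture(scope="module")
def model(geometry):
    rng = np.random.default_rng(2)
    return build_model(make_annotated_blinks(3, rng=rng, geometry=geometry))


class TestModelValue:
    def test_on_grid_point_returns_stored_value(self, model):
        k = 17
        assert model_value(model, model.grid_times[k], ON) == model.b_on[k]

    def test_outside_support_is_zero(self, model):
        assert model_value(model, -1, ON) == 0.0
        assert model_value(model, model.T_us + 1, OFF) == 0.0

    def test_midpoint_is_mean_of_neighbors(self, model):
        k = 40
        mid = (model.grid_times[k] + model.grid_times[k + 1]) / 2
        expected = (model.b_off[k] + model.b_off[k + 1]) / 2
        assert model_value(model, mid, OFF) == pytest.approx(expected, rel=1e-12)


class TestSerialization:
    def test_json_round_trip_identity(self, tmp_path, geometry):
        rng = np.random.default_rng(8)
        model = build_model(make_annotated_blinks(4, rng=rng, geometry=geometry))
        model.threshold = 123.5
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.grid_times, model.grid_times)
        np.testing.assert_array_equal(back.b_on, model.b_on)
        np.testing.assert_array_equal(back.b_off, model.b_off)
        for field in ("n_events", "condition", "m_blinks", "tau_us", "T_us",
                      "grid_step_us", "threshold", "reference_distance_px"):
            assert getattr(back, field) == getattr(model, field)

    def test_schema_violation_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"condition": "indoor"}')
        with pytest.raises(ValueError, match="missing"):
            load_model(path)

    def test_shipped_models_are_calibrated(self, indoor_model, outdoor_model):
        for model in (indoor_model, outdoor_model):
            assert model.threshold is not None and model.threshold > 0
            assert model.m_blinks == 120
            assert model.n_events >= 1
        # lighting conditions differ in their ON:OFF balance
        assert indoor_model.b_on.max() / indoor_model.b_off.max() > \
            outdoor_model.b_on.max() / outdoor_model.b_off.max()
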