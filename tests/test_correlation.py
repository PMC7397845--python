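"""Sparse cross-correlation against the blink template."""

import numpy as np
import pytest

from blinktrack.activity import ActivityState
from blinktrack.blink_model import build_model, model_value
from blinktrack.correlation import (
    correlation_score,
    count_gate,
    maybe_emit_candidate,
)
from blinktrack.events import OFF, ON
from blinktrack.synth import make_annotated_blinks

T = 250_000


def manual_interp(grid, curve, t):
    """Independent linear interpolation (zero outside support)."""
    if t < grid[0] or t > grid[-1]:
        return 0.0
    k = int(np.searchsorted(grid, t, "right")) - 1
    if k == len(grid) - 1:
        return float(curve[-1])
    frac = (t - grid[k]) / (grid[k + 1] - grid[k])
    return float(curve[k] * (1 - frac) + curve[k + 1] * frac)


def state_with_buffer(times, pols, samples):
    st = ActivityState()
    for t, p, s in zip(times, pols, samples):
        st.buffer.append((int(t), int(p), float(s)))
    return st


@pytest.fixture(scope="module")
def model(geometry):
    rng = np.random.default_rng(21)
    return build_model(make_annotated_blinks(5, rng=rng, geometry=geometry))


class TestCorrelationScore:
    def test_empty_buffer_scores_zero(self, model):
        assert correlation_score(ActivityState(), model, 10**6) == 0.0

    def test_self_correlation_is_sum_of_squared_template(self, model):
        """Buffer samples equal to the model at the same relative times with
        alpha=1 give C = sum B_ON(t_i - t_k)^2."""
        t_now = 10 * T
        t_k = t_now - T
        rel = np.arange(5_000, 245_000, 10_000)
        samples = [model_value(model, r, ON) for r in rel]
        st = state_with_buffer(t_k + rel, [ON] * len(rel), samples)
        got = correlation_score(st, model, t_now, alpha=1.0)
        assert got == pytest.approx(sum(s * s for s in samples), rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_double_loop_oracle(self, model, seed):
        rng = np.random.default_rng(seed)
        n = 200
        t_now = 3 * T
        t_k = t_now - T
        times = np.sort(rng.integers(t_k, t_now + 1, n))
        pols = rng.integers(0, 2, n)
        samples = rng.uniform(0, 50, n)
        st = state_with_buffer(times, pols, samples)
        alpha = 2.0 / 3.0
        expected = 0.0
        for t, p, s in zip(times, pols, samples):
            curve = model.b_on if p == ON else model.b_off
            w = alpha if p == ON else 1 - alpha
            expected += w * s * manual_interp(model.grid_times, curve, t - t_k)
        got = correlation_score(st, model, t_now, alpha)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_linear_in_activity_samples(self, model):
        rng = np.random.default_rng(7)
        times = np.sort(rng.integers(0, T, 50))
        pols = rng.integers(0, 2, 50)
        samples = rng.uniform(0, 10, 50)
        c1 = correlation_score(state_with_buffer(times, pols, samples), model, T)
        c3 = correlation_score(state_with_buffer(times, pols, 3.0 * samples), model, T)
        assert c3 == pytest.approx(3.0 * c1, rel=1e-12)

    def test_alpha_extremes_ignore_the_other_polarity(self, model):
        rng = np.random.default_rng(9)
        times = np.sort(rng.integers(0, T, 60))
        pols = rng.integers(0, 2, 60)
        samples = rng.uniform(0, 10, 60)
        st = state_with_buffer(times, pols, samples)
        on_only = state_with_buffer(
            times[pols == ON], [ON] * int((pols == ON).sum()), samples[pols == ON]
        )
        off_only = state_with_buffer(
            times[pols == OFF], [OFF] * int((pols == OFF).sum()), samples[pols == OFF]
        )
        assert correlation_score(st, model, T, 1.0) == pytest.approx(
            correlation_score(on_only, model, T, 1.0), rel=1e-12
        )
        assert correlation_score(st, model, T, 0.0) == pytest.approx(
            correlation_score(off_only, model, T, 0.0), rel=1e-12
        )


class TestCandidateEmission:
    def test_count_below_gate_never_emits(self, model):
        n = count_gate(model, 1.0, gate_fraction=1.0)  # gate exactly n_events
        times = np.arange(n - 1)
        st = state_with_buffer(times, [ON] * (n - 1), [1e9] * (n - 1))
        cand = maybe_emit_candidate(
            st, model, T, "primary", 0, 0, (9.0, 7.0),
            threshold=0.0, gate_fraction=1.0,
        )
        assert cand is None

    def test_gate_scales_with_face_scale(self, model):
        assert count_gate(model, 2.0) == 2 * count_gate(model, 1.0) or \
            count_gate(model, 2.0) >= count_gate(model, 1.0)
        assert count_gate(model, 1.0, n_override=100) == int(np.ceil(0.12 * 100))

    def test_emits_above_threshold_with_full_buffer(self, model):
        rel = np.arange(0, T, 1000)
        samples = [model_value(model, r, ON) for r in rel]
        st = state_with_buffer(rel, [ON] * len(rel), samples)
        cand = maybe_emit_candidate(
            st, model, int(rel[-1]) + (T - int(rel[-1])), "primary", 2, 3, (66.0, 37.0),
            threshold=1.0, gate_fraction=0.1,
        )
        assert cand is not None
        assert (cand.grid_id, cand.r, cand.c) == ("primary", 2, 3)
        assert cand.score >= 1.0
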