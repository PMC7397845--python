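"""The canonical blink template and its serialization.

An eyelid closure produces a burst of ON events within ~100 ms followed by
a slower OFF-dominant burst as the eye reopens. Averaging the per-blink
ON/OFF activity traces of a set of annotated blink windows (250 ms each)
yields a canonical template ``B_ON(t), B_OFF(t)`` against which live tile
activity is correlated. The template is stored on a uniform time grid
(1 ms step by default, much finer than the 50 ms decay constant) and read
back by linear interpolation; it is zero outside ``[0, T]``.

The model also carries ``n_events`` — the mean in-window event count of the
training blinks — which gates the correlation: a tile is only scored once
its recent-event count reaches a fraction of ``n_events`` (scaled by the
matched face's scale factor), and ``threshold``, the correlation score
below which no candidate is emitted. Separate models are built for indoor
and outdoor recordings because the ON:OFF event ratio shifts with lighting.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np

from .activity import DEFAULT_TAU_US, DEFAULT_WINDOW_US
from .events import OFF, ON, AnnotatedBlink

DEFAULT_GRID_STEP_US = 1_000
DEFAULT_REFERENCE_DISTANCE_PX = 95.0

_CONDITIONS = ("indoor", "outdoor")


@dataclasses.dataclass
class BlinkModel:
    """Averaged ON/OFF blink activity template.

    Attributes
    ----------
    grid_times : uniform sample times in microseconds over ``[0, T]``.
    b_on, b_off : template values at ``grid_times`` (dimensionless, >= 0).
    n_events : expected in-window event count at scale 1 (>= 1).
    condition : ``"indoor"`` or ``"outdoor"``.
    m_blinks : number of annotated blinks averaged.
    threshold : correlation score required to emit a blink candidate
        (``None`` until calibrated).
    reference_distance_px : inter-eye distance that defines scale = 1 for
        faces detected with this model.
    """

    grid_times: np.ndarray
    b_on: np.ndarray
    b_off: np.ndarray
    n_events: int
    condition: str
    m_blinks: int
    tau_us: float = DEFAULT_TAU_US
    T_us: int = DEFAULT_WINDOW_US
    grid_step_us: int = DEFAULT_GRID_STEP_US
    threshold: float | None = None
    reference_distance_px: float = DEFAULT_REFERENCE_DISTANCE_PX

    def __post_init__(self) -> None:
        self.grid_times = np.asarray(self.grid_times, dtype=np.float64)
        self.b_on = np.asarray(self.b_on, dtype=np.float64)
        self.b_off = np.asarray(self.b_off, dtype=np.float64)
        if not (len(self.grid_times) == len(self.b_on) == len(self.b_off)):
            raise ValueError("grid_times, b_on and b_off must have equal length")
        if (self.b_on < 0).any() or (self.b_off < 0).any():
            raise ValueError("template values must be non-negative")
        if self.n_events < 1:
            raise ValueError(f"n_events must be >= 1, got {self.n_events}")
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {_CONDITIONS}")


def build_model(
    blinks: list[AnnotatedBlink],
    tau: float = DEFAULT_TAU_US,
    T: int = DEFAULT_WINDOW_US,
    grid_step: int = DEFAULT_GRID_STEP_US,
) -> BlinkModel:
    """Average the activity traces of annotated blinks into a template.

    Each blink is shifted so its window starts at 0, converted to ON/OFF
    activity at unit scale, sampled on the uniform grid (reading the decayed
    value between events), and the per-blink curves are averaged pointwise.
    All blinks must share one lighting condition; mixed input is an error
    because indoor and outdoor scenes get separate models.
    """
    if not blinks:
        raise ValueError("need at least one annotated blink to build a model")
    conditions = {b.condition for b in blinks}
    if len(conditions) > 1:
        raise ValueError(
            f"mixed conditions {sorted(conditions)}: build one model per condition"
        )
    grid = np.arange(0, T + 1, grid_step, dtype=np.float64)
    sum_on = np.zeros_like(grid)
    sum_off = np.zeros_like(grid)
    counts = []
    for blink in blinks:
        b = blink.shifted_to_origin()
        on_curve = _sampled_activity(b.events.t[b.events.p == ON], tau, grid)
        off_curve = _sampled_activity(b.events.t[b.events.p == OFF], tau, grid)
        sum_on += on_curve
        sum_off += off_curve
        counts.append(len(b.events))
    m = len(blinks)
    n_events = max(1, int(np.floor(float(np.mean(counts)))))
    return BlinkModel(
        grid_times=grid,
        b_on=sum_on / m,
        b_off=sum_off / m,
        n_events=n_events,
        condition=blinks[0].condition,
        m_blinks=m,
        tau_us=tau,
        T_us=T,
        grid_step_us=grid_step,
    )


def _sampled_activity(event_times: np.ndarray, tau: float, grid: np.ndarray) -> np.ndarray:
    """Activity of a single-polarity event train read at the grid times.

    At grid time g the activity is the decayed value of the recursion at the
    last event <= g: ``A(t_last) * exp(-(g - t_last)/tau)``, zero before the
    first event.
    """
    if len(event_times) == 0:
        return np.zeros_like(grid)
    times = np.sort(np.asarray(event_times, dtype=np.float64))
    # Event-time activity values via the exact recursion.
    values = np.empty(len(times))
    a = 0.0
    prev = None
    for i, t in enumerate(times):
        if prev is not None:
            a *= np.exp(-(t - prev) / tau)
        a += 1.0
        values[i] = a
        prev = t
    idx = np.searchsorted(times, grid, side="right") - 1
    out = np.zeros_like(grid)
    has = idx >= 0
    out[has] = values[idx[has]] * np.exp(-(grid[has] - times[idx[has]]) / tau)
    return out


def model_value(model: BlinkModel, t_rel: float, p: int) -> float:
    """Template value at relative time ``t_rel`` (linear interpolation,
    zero outside ``[0, T]``)."""
    if t_rel < model.grid_times[0] or t_rel > model.grid_times[-1]:
        return 0.0
    curve = model.b_on if p == ON else model.b_off
    return float(np.interp(t_rel, model.grid_times, curve))


def model_values(model: BlinkModel, t_rel: np.ndarray, p: int) -> np.ndarray:
    """Vectorized :func:`model_value`."""
    curve = model.b_on if p == ON else model.b_off
    out = np.interp(t_rel, model.grid_times, curve, left=0.0, right=0.0)
    out = np.where((t_rel < model.grid_times[0]) | (t_rel > model.grid_times[-1]), 0.0, out)
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def model_to_dict(model: BlinkModel) -> dict:
    return {
        "condition": model.condition,
        "tau_us": model.tau_us,
        "T_us": model.T_us,
        "grid_step_us": model.grid_step_us,
        "grid_times": model.grid_times.tolist(),
        "b_on": model.b_on.tolist(),
        "b_off": model.b_off.tolist(),
        "n_events": model.n_events,
        "m_blinks": model.m_blinks,
        "threshold": model.threshold,
        "reference_distance_px": model.reference_distance_px,
    }


def model_from_dict(data: dict) -> BlinkModel:
    required = {"condition", "tau_us", "T_us", "grid_step_us", "grid_times", "b_on",
                "b_off", "n_events", "m_blinks"}
    missing = required - set(data)
    if missing:
        raise ValueError(f"blink model JSON missing fields: {sorted(missing)}")
    return BlinkModel(
        grid_times=np.asarray(data["grid_times"], dtype=np.float64),
        b_on=np.asarray(data["b_on"], dtype=np.float64),
        b_off=np.asarray(data["b_off"], dtype=np.float64),
        n_events=int(data["n_events"]),
        condition=data["condition"],
        m_blinks=int(data["m_blinks"]),
        tau_us=float(data["tau_us"]),
        T_us=int(data["T_us"]),
        grid_step_us=int(data["grid_step_us"]),
        threshold=None if data.get("threshold") is None else float(data["threshold"]),
        reference_distance_px=float(
            data.get("reference_distance_px", DEFAULT_REFERENCE_DISTANCE_PX)
        ),
    )


def save_model(model: BlinkModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path: str | Path) -> BlinkModel:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON: {exc}") from exc
    return model_from_dict(data)


def load_default_model(condition: str = "indoor") -> BlinkModel:
    """Load one of the two shipped synthetic-trained templates.

    These were built by ``scripts/build_default_models.py`` from the
    package's own blink simulator (120 jittered blinks each) and differ in
    their ON:OFF ratio, emulating the lighting dependence of real indoor
    and outdoor recordings. They are synthetic stand-ins, not models fit to
    recorded data.
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"condition must be one of {_CONDITIONS}")
    ref = resources.files("blinktrack") / "models" / f"synthetic_{condition}.json"
    return model_from_dict(json.loads(ref.read_text()))
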