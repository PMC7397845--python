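"""Synthetic event-scene simulator with ground truth.

Generates the phenomenology an event camera sees when filming blinking
faces, without any rendering: per blink, an ON-event burst under a
raised-cosine envelope while the eyelid closes (~100 ms) followed by a
slower OFF-dominant burst while it reopens (~150 ms), both spatially
Gaussian around the eye; face-outline motion events while the head
translates; optional whole-scene motion bursts; and uniform background
noise. Every intensity is Poisson and every draw comes from one
``numpy.random.Generator``, so a scene is fully reproducible from its
seed.

The generator's knobs are deliberately explicit — expected event count per
eye and blink (600 at scale 1), ON:OFF ratio (2:1 indoor, 1.4:1 outdoor,
encoding the lighting dependence of real sensors), spatial spread (0.4 of
a tile, scaled with face scale), blink phase durations — because the
detector is calibrated against this generator the same way the original
method was calibrated against annotated recordings.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .events import OFF, ON, AnnotatedBlink, EventStream, SensorGeometry

DEFAULT_BLINK_COUNT = 600.0        # expected events per eye per blink, scale 1
ON_OFF_RATIO = {"indoor": 2.0, "outdoor": 1.4}
DEFAULT_ON_DURATION_US = 100_000   # eyelid closure
DEFAULT_OFF_DURATION_US = 150_000  # slower reopening
DEFAULT_WINDOW_US = 250_000
DEFAULT_SPATIAL_STD_FRAC = 0.4     # of a tile dimension, at scale 1
#: Face-outline motion events emitted per pixel of face-center travel.
DEFAULT_EDGE_EVENTS_PER_PX = 60.0


# ---------------------------------------------------------------------------
# Scene description
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FaceSpec:
    """One face: a piecewise-linear center trajectory, an (optionally
    time-varying) inter-eye distance, and explicit blink onset times."""

    trajectory: list[tuple[int, float, float]]      # (t_us, center_x, center_y)
    eye_distance: float | list[tuple[int, float]]   # px, constant or (t_us, d)
    blink_times: list[int]                          # blink onsets, us
    condition: str = "indoor"
    eye_offset_y: float = 0.0                       # eyes relative to center
    tilt: float | list[tuple[int, float]] = 0.0     # head roll, radians

    def center_at(self, t: float) -> tuple[float, float]:
        knots = self.trajectory
        ts = [k[0] for k in knots]
        return (
            float(np.interp(t, ts, [k[1] for k in knots])),
            float(np.interp(t, ts, [k[2] for k in knots])),
        )

    def eye_distance_at(self, t: float) -> float:
        if isinstance(self.eye_distance, (int, float)):
            return float(self.eye_distance)
        ts = [k[0] for k in self.eye_distance]
        ds = [k[1] for k in self.eye_distance]
        return float(np.interp(t, ts, ds))

    def tilt_at(self, t: float) -> float:
        if isinstance(self.tilt, (int, float)):
            return float(self.tilt)
        ts = [k[0] for k in self.tilt]
        vs = [k[1] for k in self.tilt]
        return float(np.interp(t, ts, vs))

    def eyes_at(self, t: float) -> tuple[tuple[float, float], tuple[float, float]]:
        cx, cy = self.center_at(t)
        d = self.eye_distance_at(t)
        theta = self.tilt_at(t)
        dx = 0.5 * d * math.cos(theta)
        dy = 0.5 * d * math.sin(theta)
        y = cy + self.eye_offset_y
        return (cx - dx, y - dy), (cx + dx, y + dy)


@dataclasses.dataclass
class MotionBurst:
    """Whole-scene activity burst: the background rate is multiplied by
    ``rate_multiplier`` over ``[t_start, t_end]`` (subject moving as a
    whole, camera bump, ...)."""

    t_start: int
    t_end: int
    rate_multiplier: float


@dataclasses.dataclass
class SceneSpec:
    duration_us: int
    faces: list[FaceSpec] = dataclasses.field(default_factory=list)
    noise_rate: float = 1_000.0            # events/s over the whole sensor
    motion_bursts: list[MotionBurst] = dataclasses.field(default_factory=list)
    seed: int = 0
    geometry: SensorGeometry = dataclasses.field(default_factory=SensorGeometry)
    n: int = 16                            # tile count, fixes the spatial spread unit
    blink_count: float = DEFAULT_BLINK_COUNT
    edge_events_per_px: float = DEFAULT_EDGE_EVENTS_PER_PX

    def validate(self) -> None:
        for f, face in enumerate(self.faces):
            for t0 in face.blink_times:
                if not (0 <= t0 and t0 + DEFAULT_WINDOW_US <= self.duration_us):
                    raise ValueError(
                        f"face {f}: blink at {t0} us does not fit in the "
                        f"{self.duration_us} us scene"
                    )


@dataclasses.dataclass
class FaceTruth:
    face_id: int
    blink_times: list[int]
    blink_eyes: list[tuple[tuple[float, float], tuple[float, float]]]
    sample_t: np.ndarray       # trajectory sample times
    center_x: np.ndarray       # face *box* center (same convention as face_box)
    center_y: np.ndarray
    box_width: np.ndarray

    def blink_midpoints(self) -> list[tuple[int, float, float]]:
        out = []
        for t0, (le, re) in zip(self.blink_times, self.blink_eyes):
            out.append((t0, (le[0] + re[0]) / 2.0, (le[1] + re[1]) / 2.0))
        return out


@dataclasses.dataclass
class GroundTruth:
    faces: list[FaceTruth]
    geometry: SensorGeometry

    def blink_midpoints(self) -> list[tuple[int, float, float]]:
        out = []
        for f in self.faces:
            out.extend(f.blink_midpoints())
        out.sort()
        return out


# ---------------------------------------------------------------------------
# Event generation
# ---------------------------------------------------------------------------


def _raised_cosine_times(rng: np.random.Generator, count: int, t0: float,
                         duration: float) -> np.ndarray:
    """Sample event times under a raised-cosine envelope on [t0, t0+duration]
    by inverse-CDF interpolation."""
    if count == 0:
        return np.empty(0)
    s = np.linspace(0.0, 1.0, 513)
    cdf = s - np.sin(2.0 * np.pi * s) / (2.0 * np.pi)
    u = rng.random(count)
    return t0 + duration * np.interp(u, cdf, s)


def simulate_blink_events(
    eye_center: tuple[float, float],
    t0: int,
    rng: np.random.Generator,
    scale: float = 1.0,
    condition: str = "indoor",
    geometry: SensorGeometry | None = None,
    n: int = 16,
    blink_count: float = DEFAULT_BLINK_COUNT,
    on_duration_us: float = DEFAULT_ON_DURATION_US,
    off_duration_us: float = DEFAULT_OFF_DURATION_US,
    spatial_std_frac: float = DEFAULT_SPATIAL_STD_FRAC,
) -> EventStream:
    """Events of a single eye's blink starting at ``t0``.

    Expected total count is ``blink_count * scale**2`` (a nearer face covers
    more pixels), split ON:OFF by the condition's ratio; ON events fall in
    the closure phase, OFF events in the slower reopening phase, and all
    events lie within ``[t0, t0 + on + off]``. Positions are Gaussian
    around ``eye_center`` with per-axis std ``spatial_std_frac * tile * scale``,
    clipped to the sensor.
    """
    g = geometry or SensorGeometry()
    ratio = ON_OFF_RATIO[condition]
    lam = blink_count * scale * scale
    lam_on = lam * ratio / (1.0 + ratio)
    lam_off = lam / (1.0 + ratio)
    n_on = int(rng.poisson(lam_on))
    n_off = int(rng.poisson(lam_off))
    t_on = _raised_cosine_times(rng, n_on, t0, on_duration_us)
    t_off = _raised_cosine_times(rng, n_off, t0 + on_duration_us, off_duration_us)
    times = np.concatenate([t_on, t_off])
    pols = np.concatenate([np.full(n_on, ON), np.full(n_off, OFF)])
    tw, th = g.width // n, g.height // n
    xs = rng.normal(eye_center[0], spatial_std_frac * tw * scale, len(times))
    ys = rng.normal(eye_center[1], spatial_std_frac * th * scale, len(times))
    xs = np.clip(np.rint(xs), 0, g.width - 1)
    ys = np.clip(np.rint(ys), 0, g.height - 1)
    stream = EventStream(xs, ys, np.rint(times), pols, g)
    return stream.sorted_by_time()


def _uniform_noise(rng: np.random.Generator, rate: float, t_start: float, t_end: float,
                   g: SensorGeometry) -> EventStream:
    duration_s = max(0.0, (t_end - t_start) / 1e6)
    count = int(rng.poisson(rate * duration_s))
    xs = rng.integers(0, g.width, count)
    ys = rng.integers(0, g.height, count)
    ts = np.rint(rng.uniform(t_start, t_end, count))
    ps = rng.integers(0, 2, count)
    return EventStream(xs, ys, ts, ps, g)


def _face_motion_events(face: FaceSpec, rng: np.random.Generator, g: SensorGeometry,
                        edge_events_per_px: float) -> EventStream:
    """Events along the face outline while the center moves.

    The outline is the face-box ellipse (semi-axes 1.1 d, 1.4 d around the
    box center); the event rate is proportional to the speed, emulating how
    a moving head lights up its contours on an event sensor.
    """
    xs, ys, ts = [], [], []
    knots = face.trajectory
    for (ta, xa, ya), (tb, xb, yb) in zip(knots[:-1], knots[1:]):
        dist = math.hypot(xb - xa, yb - ya)
        if dist <= 0.0 or tb <= ta:
            continue
        count = int(rng.poisson(edge_events_per_px * dist))
        t = rng.uniform(ta, tb, count)
        frac = (t - ta) / (tb - ta)
        cx = xa + frac * (xb - xa)
        cy = ya + frac * (yb - ya)
        d = np.array([face.eye_distance_at(ti) for ti in t])
        ey = face.eye_offset_y
        theta = rng.uniform(0.0, 2.0 * np.pi, count)
        jitter = rng.normal(0.0, 2.0, count)
        # ellipse around the face-box center (0.42 d below the eye line)
        bx = cx
        by = cy + ey + 0.42 * d
        xs.append(bx + (1.1 * d + jitter) * np.cos(theta))
        ys.append(by + (1.4 * d + jitter) * np.sin(theta))
        ts.append(np.rint(t))
    if not xs:
        return EventStream.empty(g)
    x = np.clip(np.rint(np.concatenate(xs)), 0, g.width - 1)
    y = np.clip(np.rint(np.concatenate(ys)), 0, g.height - 1)
    t = np.concatenate(ts)
    p = rng.integers(0, 2, len(t))
    return EventStream(x, y, t, p, g)


def simulate_scene(spec: SceneSpec) -> tuple[EventStream, GroundTruth]:
    """Render a scene spec into a time-sorted event stream plus ground truth.

    Ground-truth trajectory samples are taken every 50 ms; the truth center
    is the face-*box* center under the same anthropometric convention the
    tracker uses (box width 2.2 d, height 2.8 d, eyes at 35% height), so a
    perfect tracker scores zero error.
    """
    spec.validate()
    g = spec.geometry
    rng = np.random.default_rng(spec.seed)
    parts: list[EventStream] = []
    truths: list[FaceTruth] = []
    for face_id, face in enumerate(spec.faces):
        blink_eyes = []
        for t0 in face.blink_times:
            left, right = face.eyes_at(t0)
            scale = face.eye_distance_at(t0) / 95.0
            for eye in (left, right):
                parts.append(
                    simulate_blink_events(
                        eye, t0, rng, scale=scale, condition=face.condition,
                        geometry=g, n=spec.n, blink_count=spec.blink_count,
                    )
                )
            blink_eyes.append((left, right))
        parts.append(_face_motion_events(face, rng, g, spec.edge_events_per_px))
        sample_t = np.arange(0, spec.duration_us + 1, 50_000, dtype=np.int64)
        centers = np.array([face.center_at(t) for t in sample_t])
        d = np.array([face.eye_distance_at(t) for t in sample_t])
        truths.append(
            FaceTruth(
                face_id=face_id,
                blink_times=list(face.blink_times),
                blink_eyes=blink_eyes,
                sample_t=sample_t,
                center_x=centers[:, 0],
                center_y=centers[:, 1] + face.eye_offset_y + 0.42 * d,
                box_width=2.2 * d,
            )
        )
    parts.append(_uniform_noise(rng, spec.noise_rate, 0, spec.duration_us, g))
    for burst in spec.motion_bursts:
        extra = spec.noise_rate * (burst.rate_multiplier - 1.0)
        if extra > 0:
            parts.append(_uniform_noise(rng, extra, burst.t_start, burst.t_end, g))
    x = np.concatenate([p.x for p in parts])
    y = np.concatenate([p.y for p in parts])
    t = np.concatenate([p.t for p in parts])
    p_ = np.concatenate([p.p for p in parts])
    stream = EventStream(x, y, t, p_, g).sorted_by_time()
    return stream, GroundTruth(faces=truths, geometry=g)


# ---------------------------------------------------------------------------
# Annotated training blinks
# ---------------------------------------------------------------------------


def make_annotated_blinks(
    m: int,
    condition: str = "indoor",
    rng: np.random.Generator | None = None,
    geometry: SensorGeometry | None = None,
    jitter: float = 0.2,
    blink_count: float = DEFAULT_BLINK_COUNT,
    window_us: int = DEFAULT_WINDOW_US,
) -> list[AnnotatedBlink]:
    """Synthetic stand-ins for manually annotated single-eye blink windows.

    Envelope durations and counts are jittered by +-``jitter`` around their
    defaults, emulating inter-subject variability; six synthetic subjects
    cycle through the annotations.
    """
    if m < 1:
        raise ValueError(f"need m >= 1 annotated blinks, got {m}")
    rng = rng if rng is not None else np.random.default_rng(0)
    g = geometry or SensorGeometry()
    blinks = []
    for i in range(m):
        on_dur = DEFAULT_ON_DURATION_US * rng.uniform(1 - jitter, 1 + jitter)
        off_dur = min(
            DEFAULT_OFF_DURATION_US * rng.uniform(1 - jitter, 1 + jitter),
            window_us - on_dur,
        )
        count = blink_count * rng.uniform(1 - jitter, 1 + jitter)
        events = simulate_blink_events(
            (g.width / 2.0, g.height / 2.0), 0, rng, scale=1.0,
            condition=condition, geometry=g, blink_count=count,
            on_duration_us=on_dur, off_duration_us=off_dur,
        )
        blinks.append(
            AnnotatedBlink(
                events=events,
                window_start=0,
                window_length=window_us,
                subject_id=f"s{i % 6}",
                condition=condition,
            )
        )
    return blinks


def train_default_model(condition: str = "indoor", m: int = 120, seed: int = 7):
    """Build a calibrated synthetic-trained blink model (see the shipped
    ``models/synthetic_*.json`` files, generated exactly this way)."""
    from .blink_model import build_model
    from .correlation import calibrate_threshold

    rng = np.random.default_rng(seed + (0 if condition == "indoor" else 1))
    blinks = make_annotated_blinks(m, condition=condition, rng=rng)
    model = build_model(blinks)
    model.threshold = calibrate_threshold(blinks, model)
    return model


# ---------------------------------------------------------------------------
# JSON round-trips for the CLI
# ---------------------------------------------------------------------------


def scene_spec_to_dict(spec: SceneSpec) -> dict:
    return {
        "duration_us": spec.duration_us,
        "noise_rate": spec.noise_rate,
        "seed": spec.seed,
        "geometry": {"width": spec.geometry.width, "height": spec.geometry.height},
        "n": spec.n,
        "blink_count": spec.blink_count,
        "edge_events_per_px": spec.edge_events_per_px,
        "faces": [
            {
                "trajectory": [list(k) for k in f.trajectory],
                "eye_distance": f.eye_distance
                if isinstance(f.eye_distance, (int, float))
                else [list(k) for k in f.eye_distance],
                "blink_times": list(f.blink_times),
                "condition": f.condition,
                "eye_offset_y": f.eye_offset_y,
                "tilt": f.tilt
                if isinstance(f.tilt, (int, float))
                else [list(k) for k in f.tilt],
            }
            for f in spec.faces
        ],
        "motion_bursts": [
            {"t_start": b.t_start, "t_end": b.t_end, "rate_multiplier": b.rate_multiplier}
            for b in spec.motion_bursts
        ],
    }


def scene_spec_from_dict(data: dict) -> SceneSpec:
    if "duration_us" not in data:
        raise ValueError("scene spec missing 'duration_us'")
    geom = data.get("geometry", {})
    faces = [
        FaceSpec(
            trajectory=[tuple(k) for k in f["trajectory"]],
            eye_distance=f["eye_distance"]
            if isinstance(f["eye_distance"], (int, float))
            else [tuple(k) for k in f["eye_distance"]],
            blink_times=list(f["blink_times"]),
            condition=f.get("condition", "indoor"),
            eye_offset_y=f.get("eye_offset_y", 0.0),
            tilt=f.get("tilt", 0.0)
            if isinstance(f.get("tilt", 0.0), (int, float))
            else [tuple(k) for k in f["tilt"]],
        )
        for f in data.get("faces", [])
    ]
    bursts = [
        MotionBurst(b["t_start"], b["t_end"], b["rate_multiplier"])
        for b in data.get("motion_bursts", [])
    ]
    return SceneSpec(
        duration_us=int(data["duration_us"]),
        faces=faces,
        noise_rate=float(data.get("noise_rate", 1000.0)),
        motion_bursts=bursts,
        seed=int(data.get("seed", 0)),
        geometry=SensorGeometry(int(geom.get("width", 304)), int(geom.get("height", 240))),
        n=int(data.get("n", 16)),
        blink_count=float(data.get("blink_count", DEFAULT_BLINK_COUNT)),
        edge_events_per_px=float(data.get("edge_events_per_px", DEFAULT_EDGE_EVENTS_PER_PX)),
    )


def load_scene_spec(path: str | Path) -> SceneSpec:
    with open(path) as fh:
        return scene_spec_from_dict(json.load(fh))


def save_scene_spec(spec: SceneSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(scene_spec_to_dict(spec), fh, indent=1, sort_keys=True)
        fh.write("\n")


def ground_truth_to_dict(gt: GroundTruth) -> dict:
    return {
        "geometry": {"width": gt.geometry.width, "height": gt.geometry.height},
        "faces": [
            {
                "face_id": f.face_id,
                "blink_times": list(f.blink_times),
                "blink_eyes": [[list(le), list(re)] for le, re in f.blink_eyes],
                "sample_t": f.sample_t.tolist(),
                "center_x": f.center_x.tolist(),
                "center_y": f.center_y.tolist(),
                "box_width": f.box_width.tolist(),
            }
            for f in gt.faces
        ],
    }


def ground_truth_from_dict(data: dict) -> GroundTruth:
    faces = [
        FaceTruth(
            face_id=f["face_id"],
            blink_times=list(f["blink_times"]),
            blink_eyes=[(tuple(le), tuple(re)) for le, re in f["blink_eyes"]],
            sample_t=np.asarray(f["sample_t"]),
            center_x=np.asarray(f["center_x"]),
            center_y=np.asarray(f["center_y"]),
            box_width=np.asarray(f["box_width"]),
        )
        for f in data["faces"]
    ]
    geom = data.get("geometry", {})
    return GroundTruth(
        faces=faces,
        geometry=SensorGeometry(int(geom.get("width", 304)), int(geom.get("height", 240))),
    )


def save_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth_to_dict(gt), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        return ground_truth_from_dict(json.load(fh))
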