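"""The global per-event detection-and-tracking loop plus evaluation metrics.

For every event, in time order:

1. the event is offered to the active faces' eye trackers (highest-density
   assignment inside the Mahalanobis gate) and, if accepted, blended in;
2. the tile activities of the grids containing the event are updated, using
   the assigned face's scale factor (1 when unassigned);
3. the touched tiles are scored against the blink template and may emit
   blink candidates;
4. new candidates are paired under the physiological constraints; accepted
   detections either initialize a new face track or drift-correct (and
   possibly revive) the matched one.

Tracking first, detection second: a blink on an already-tracked face must
correct that face, not spawn a duplicate, so the matched-face lookup has to
see the current tracker state. All control flow is event-driven — candidate
pruning and lost-face bookkeeping piggyback on event processing, there are
no timers — and the whole loop is deterministic for fixed inputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from . import tracking
from .blink_model import BlinkModel
from .correlation import (
    DEFAULT_ALPHA,
    DEFAULT_GATE_FRACTION,
    BlinkCandidate,
    correlation_score,
    count_gate,
)
from .events import EventStream
from .pairing import BlinkDetection, PairingParams, pair_candidates
from .tiling import TileActivity, TileKey, tile_center, tile_diagonal
from .tracking import ACTIVE, FaceTrack, LOST


@dataclasses.dataclass
class PipelineConfig:
    """Every tunable constant of the detector and tracker in one place.

    ``None`` geometry-derived fields resolve at run time: ``dh_max_px`` to
    half the sensor width, ``dv_max_px`` to a fifth of its height,
    ``min_sep_px`` and ``init_std_px`` to one primary tile width, the
    correlation threshold and reference eye distance to the model's stored
    values.
    """

    n: int = 16
    tau_us: float = 50_000.0
    window_us: int = 250_000
    alpha: float = DEFAULT_ALPHA
    # pairing constraints
    dt_max_us: int = 50_000
    dh_max_px: float | None = None
    dv_max_px: float | None = None
    min_sep_px: float | None = None
    merge_dt_us: int = 10_000
    # candidate emission
    correlation_threshold: float | None = None
    n_override: int | None = None
    gate_fraction: float = DEFAULT_GATE_FRACTION
    # trackers
    eta_mu: float = 0.05
    eta_sigma: float = 0.01
    mahal_gate: float = 9.0
    min_eig: float = 1.0
    max_eig: float = 256.0
    init_std_px: float | None = None
    reference_distance_px: float | None = None
    # face lifecycle
    eye_silence_lost_us: int = 2_000_000
    blink_silence_lost_us: int = 10_000_000
    blink_refractory_us: int = 400_000
    blink_correction: bool = True
    # output
    track_decimation_us: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        for name in ("n", "tau_us", "window_us", "dt_max_us", "gate_fraction",
                     "mahal_gate", "track_decimation_us"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclasses.dataclass
class TrackSample:
    t: int
    face_id: int
    lx: float
    ly: float
    rx: float
    ry: float
    scale: float
    box: tuple[float, float, float, float]


@dataclasses.dataclass
class TrackingResult:
    detections: list[BlinkDetection]
    tracks: list[TrackSample]
    counters: dict[str, int]
    faces: list[FaceTrack]

    def tracks_by_face(self) -> dict[int, list[TrackSample]]:
        out: dict[int, list[TrackSample]] = {}
        for s in self.tracks:
            out.setdefault(s.face_id, []).append(s)
        return out


def process(stream: EventStream, model: BlinkModel, config: PipelineConfig | None = None
            ) -> TrackingResult:
    """Run the full event-driven loop over a time-sorted stream."""
    config = config or PipelineConfig()
    if len(stream) and np.any(np.diff(stream.t) < 0):
        raise ValueError("event stream must be sorted by time")
    g = stream.geometry
    threshold = (
        config.correlation_threshold
        if config.correlation_threshold is not None
        else model.threshold
    )
    if threshold is None:
        raise ValueError(
            "no correlation threshold: calibrate the model or set "
            "config.correlation_threshold"
        )
    tw = g.width // config.n
    init_std = config.init_std_px if config.init_std_px is not None else float(tw)
    reference = (
        config.reference_distance_px
        if config.reference_distance_px is not None
        else model.reference_distance_px
    )
    params = PairingParams.from_geometry(
        g, config.n, config.dt_max_us, config.dh_max_px, config.dv_max_px,
        config.min_sep_px, config.merge_dt_us,
    )
    tiles = TileActivity(g, config.n, config.tau_us, config.window_us)
    centers: dict[TileKey, tuple[float, float]] = {}
    faces: list[FaceTrack] = []
    faces_by_id: dict[int, FaceTrack] = {}
    last_detection_t: dict[int, int] = {}
    pending: dict[TileKey, BlinkCandidate] = {}
    detections: list[BlinkDetection] = []
    tracks: list[TrackSample] = []
    counters = {
        "events": 0,
        "candidates": 0,
        "pairings": 0,
        "detections": 0,
        "suppressed_detections": 0,
        "faces_created": 0,
        "corrections": 0,
        "single_eye_corrections": 0,
        "buffer_evictions": 0,
    }

    def emit_sample(face: FaceTrack, t: int) -> None:
        tracks.append(
            TrackSample(
                t=t,
                face_id=face.face_id,
                lx=face.left.mu_x, ly=face.left.mu_y,
                rx=face.right.mu_x, ry=face.right.mu_y,
                scale=face.scale,
                box=tracking.face_box(face),
            )
        )

    def tile_pos(key: TileKey) -> tuple[float, float]:
        pos = centers.get(key)
        if pos is None:
            pos = tile_center(key[0], key[1], key[2], g, config.n)
            centers[key] = pos
        return pos

    def single_eye_check(cand: BlinkCandidate, t_now: int) -> None:
        # A lone expired candidate inside an active face's eye gate is a
        # single-eye blink (pose variation): correct that eye only.
        for face in faces:
            if face.status != ACTIVE:
                continue
            if t_now - last_detection_t.get(face.face_id, -(10**12)) < config.blink_refractory_us:
                continue
            for side, tracker in face.trackers():
                if tracker.mahalanobis2(cand.pos_x, cand.pos_y) <= config.mahal_gate:
                    last_detection_t[face.face_id] = cand.t
                    if config.blink_correction:
                        tracking.correct_single_eye(
                            face, side, (cand.pos_x, cand.pos_y), cand.t, init_std
                        )
                        counters["single_eye_corrections"] += 1
                        emit_sample(face, cand.t)
                    return

    def apply_detection(det: BlinkDetection, t_now: int) -> None:
        if det.matched_face is not None:
            face = faces_by_id[det.matched_face]
            if t_now - last_detection_t.get(face.face_id, -(10**12)) < config.blink_refractory_us:
                counters["suppressed_detections"] += 1
                return
            last_detection_t[face.face_id] = det.t
            detections.append(det)
            counters["detections"] += 1
            if config.blink_correction:
                tracking.correct_with_blink(face, det, init_std)
                counters["corrections"] += 1
                emit_sample(face, det.t)
        else:
            detections.append(det)
            counters["detections"] += 1
            face_id = len(faces_by_id)
            face = tracking.init_face(det, face_id, init_std, reference)
            faces.append(face)
            faces_by_id[face_id] = face
            last_detection_t[face_id] = det.t
            counters["faces_created"] += 1
            emit_sample(face, det.t)

    def handle_candidate(cand: BlinkCandidate, t_now: int) -> None:
        counters["candidates"] += 1
        # prune stale candidates; expired loners may be single-eye blinks
        cutoff = t_now - config.dt_max_us
        for key in list(pending):
            if pending[key].t < cutoff:
                stale = pending.pop(key)
                single_eye_check(stale, t_now)
        key = (cand.grid_id, cand.r, cand.c)
        held = pending.get(key)
        if held is None or cand.score >= held.score:
            pending[key] = cand
        counters["pairings"] += 1
        dets, consumed = pair_candidates(list(pending.values()), params, faces)
        if dets:
            gone = {id(c) for c in consumed}
            for key in [k for k, v in pending.items() if id(v) in gone]:
                del pending[key]
            for det in dets:
                apply_detection(det, t_now)

    xs = stream.x.tolist()
    ys = stream.y.tolist()
    ts = stream.t.tolist()
    ps = stream.p.tolist()
    gate1 = count_gate(model, 1.0, config.gate_fraction, config.n_override)
    next_tick = 0
    for x, y, t, p in zip(xs, ys, ts, ps):
        counters["events"] += 1
        # event-time bookkeeping tick: snapshot tracks and retire starved
        # faces before this event mutates any state
        if t >= next_tick:
            for face in faces:
                if face.status == ACTIVE:
                    if (
                        t - face.last_event_t() > config.eye_silence_lost_us
                        and t - face.last_blink_t > config.blink_silence_lost_us
                    ):
                        face.status = LOST
                    else:
                        emit_sample(face, next_tick)
            next_tick = (t // config.track_decimation_us + 1) * config.track_decimation_us
        # (1) tracker assignment
        scale = 1.0
        gate_n = gate1
        if faces:
            hit = tracking.assign_event(faces, x, y, config.mahal_gate)
            if hit is not None:
                face = faces_by_id[hit[0]]
                tracker = face.left if hit[1] == tracking.LEFT else face.right
                tracking.update_tracker(
                    tracker, (x, y), t, config.eta_mu, config.eta_sigma,
                    config.min_eig, config.max_eig,
                )
                scale = face.scale
                gate_n = count_gate(model, scale, config.gate_fraction, config.n_override)
        # (2) tile activity updates, (3) candidate emission
        for key, st, _sample in tiles.update(x, y, t, p, scale):
            if st.count() < gate_n:
                continue
            score = correlation_score(st, model, t, config.alpha)
            if score >= threshold:
                pos = tile_pos(key)
                cand = BlinkCandidate(key[0], key[1], key[2], t, score, pos[0], pos[1])
                handle_candidate(cand, t)
    return TrackingResult(detections=detections, tracks=tracks, counters=counters,
                          faces=faces)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_detection(
    result: TrackingResult,
    truth_blinks: list[tuple[int, float, float]],
    geometry,
    n: int = 16,
    match_window_us: int = 250_000,
) -> tuple[float, int]:
    """Fraction of ground-truth blinks detected, plus false positives.

    A truth blink ``(t, mid_x, mid_y)`` counts as detected when at least
    one detection lies within ``match_window_us`` of its onset and within
    two tile diagonals of its eye midpoint; detections matching no truth
    blink are false positives. With no truth blinks the fraction is
    vacuously 1.
    """
    max_dist = 2.0 * tile_diagonal(geometry, n)

    def matches(det: BlinkDetection, truth: tuple[int, float, float]) -> bool:
        t0, mx, my = truth
        if abs(det.t - t0) > match_window_us:
            return False
        dx, dy = det.midpoint
        return math.hypot(dx - mx, dy - my) <= max_dist

    detected = sum(
        1 for truth in truth_blinks if any(matches(d, truth) for d in result.detections)
    )
    false_pos = sum(
        1 for d in result.detections if not any(matches(d, truth) for truth in truth_blinks)
    )
    fraction = detected / len(truth_blinks) if truth_blinks else 1.0
    return fraction, false_pos


def evaluate_tracking(
    result: TrackingResult,
    truth_t: np.ndarray,
    truth_cx: np.ndarray,
    truth_cy: np.ndarray,
    truth_box_w: np.ndarray,
    face_id: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalized tracking-error series against a reference trajectory.

    At every truth sample time from the first detection onward, the error
    is the distance between the estimated face-box center (the latest track
    sample at or before that time) and the reference center, divided by the
    reference box width. Returns ``(times, errors, mean_error)``; with no
    track samples the series is empty and the mean is NaN. When ``face_id``
    is None the face with the most samples is evaluated.
    """
    by_face = result.tracks_by_face()
    if not by_face:
        return np.empty(0), np.empty(0), float("nan")
    if face_id is None:
        face_id = max(by_face, key=lambda k: (len(by_face[k]), -k))
    samples = by_face[face_id]
    s_t = np.array([s.t for s in samples])
    s_cx = np.array([tracking.box_center(s.box)[0] for s in samples])
    s_cy = np.array([tracking.box_center(s.box)[1] for s in samples])
    start = result.detections[0].t if result.detections else s_t[0]
    times, errors = [], []
    truth_t = np.asarray(truth_t)
    for i in range(len(truth_t)):
        t = truth_t[i]
        if t < start:
            continue
        k = np.searchsorted(s_t, t, side="right") - 1
        if k < 0:
            continue
        err = math.hypot(s_cx[k] - truth_cx[i], s_cy[k] - truth_cy[i]) / truth_box_w[i]
        times.append(t)
        errors.append(err)
    times = np.asarray(times)
    errors = np.asarray(errors)
    mean = float(errors.mean()) if len(errors) else float("nan")
    return times, errors, mean
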