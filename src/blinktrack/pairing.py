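"""Validation of blink candidates into blink detections.

Two eyes of one face blink together, so a physiological blink appears as a
*pair* of near-simultaneous tile candidates with a plausible geometric
arrangement. A pair is accepted iff

* ``|t1 - t2| <= dT_max``      (50 ms default — blinks are synchronous),
* ``min_sep <= |x1 - x2| <= dH_max``  (half the sensor width default;
  ``min_sep`` is one tile width, so a single eye firing both overlapping
  grids cannot pair with itself),
* ``|y1 - y2| <= dV_max``      (a fifth of the sensor height default).

For candidates matched to an already-tracked face the three spatial bounds
are multiplied by that face's scale factor. Candidates from the two grids
that describe the same physical eye (tile centers within one tile diagonal
and 10 ms) are merged beforehand, keeping the highest score. Valid pairs
are consumed greedily in increasing ``(|t1-t2|, |x1-x2|)`` order, so each
candidate joins at most one detection and the result does not depend on
input ordering when the gaps are distinct.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

from .correlation import BlinkCandidate
from .events import SensorGeometry

DEFAULT_DT_MAX_US = 50_000
DEFAULT_MERGE_DT_US = 10_000


@dataclasses.dataclass
class BlinkDetection:
    """A validated candidate pair interpreted as the two eyes of one face."""

    t: int                             # mean of the two candidate times
    left_eye: tuple[float, float]      # smaller x
    right_eye: tuple[float, float]
    eye_distance: float
    candidate_pair: tuple[BlinkCandidate, BlinkCandidate] | None = None
    matched_face: int | None = None    # face_id, or None => new face

    @property
    def midpoint(self) -> tuple[float, float]:
        return (
            (self.left_eye[0] + self.right_eye[0]) / 2.0,
            (self.left_eye[1] + self.right_eye[1]) / 2.0,
        )


@dataclasses.dataclass(frozen=True)
class PairingParams:
    """Geometric/temporal acceptance bounds (pixel units, microseconds)."""

    dt_max_us: int
    dh_max_px: float
    dv_max_px: float
    min_sep_px: float
    merge_dt_us: int = DEFAULT_MERGE_DT_US
    merge_dist_px: float = 0.0  # one tile diagonal; set by from_geometry

    @classmethod
    def from_geometry(
        cls,
        geometry: SensorGeometry,
        n: int = 16,
        dt_max_us: int = DEFAULT_DT_MAX_US,
        dh_max_px: float | None = None,
        dv_max_px: float | None = None,
        min_sep_px: float | None = None,
        merge_dt_us: int = DEFAULT_MERGE_DT_US,
    ) -> "PairingParams":
        tw, th = geometry.width // n, geometry.height // n
        return cls(
            dt_max_us=dt_max_us,
            dh_max_px=geometry.width / 2.0 if dh_max_px is None else dh_max_px,
            dv_max_px=geometry.height / 5.0 if dv_max_px is None else dv_max_px,
            min_sep_px=float(tw) if min_sep_px is None else min_sep_px,
            merge_dt_us=merge_dt_us,
            merge_dist_px=math.hypot(tw, th),
        )


def merge_cross_grid(
    candidates: Sequence[BlinkCandidate],
    merge_dist_px: float,
    merge_dt_us: int = DEFAULT_MERGE_DT_US,
) -> tuple[list[BlinkCandidate], dict[int, list[BlinkCandidate]]]:
    """Collapse same-eye duplicates from the two grids.

    Returns the surviving candidates (highest score of each duplicate
    cluster) and a map from survivor identity to its absorbed duplicates.
    """
    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i].score, i))
    survivors: list[BlinkCandidate] = []
    absorbed: dict[int, list[BlinkCandidate]] = {}
    for i in order:
        cand = candidates[i]
        host = None
        for s in survivors:
            if (
                abs(cand.t - s.t) <= merge_dt_us
                and math.hypot(cand.pos_x - s.pos_x, cand.pos_y - s.pos_y)
                <= merge_dist_px
            ):
                host = s
                break
        if host is None:
            survivors.append(cand)
            absorbed[id(cand)] = []
        else:
            absorbed[id(host)].append(cand)
    # restore deterministic input order among survivors
    pos = {id(c): i for i, c in enumerate(candidates)}
    survivors.sort(key=lambda c: pos[id(c)])
    return survivors, absorbed


def _match_face(midpoint: tuple[float, float], faces, dh_max_px: float):
    """Nearest face whose eye midpoint lies within one dH_max, else None."""
    best = None
    best_d = None
    for face in faces:
        fx, fy = face.eye_midpoint()
        d = math.hypot(midpoint[0] - fx, midpoint[1] - fy)
        if d <= dh_max_px and (best_d is None or d < best_d):
            best, best_d = face, d
    return best


def pair_candidates(
    pending: Sequence[BlinkCandidate],
    params: PairingParams,
    faces: Sequence = (),
) -> tuple[list[BlinkDetection], list[BlinkCandidate]]:
    """Validate pending candidates into detections.

    ``faces`` is any sequence of objects exposing ``face_id``, ``scale`` and
    ``eye_midpoint()`` (active or lost face tracks). Returns the accepted
    detections and every candidate consumed by them (pair members plus
    their merged-away duplicates), which the caller drops from its pending
    set.
    """
    merged, absorbed = merge_cross_grid(pending, params.merge_dist_px, params.merge_dt_us)
    valid = []
    for i in range(len(merged)):
        for j in range(i + 1, len(merged)):
            a, b = merged[i], merged[j]
            dt = abs(a.t - b.t)
            if dt > params.dt_max_us:
                continue
            dx = abs(a.pos_x - b.pos_x)
            dy = abs(a.pos_y - b.pos_y)
            mid = ((a.pos_x + b.pos_x) / 2.0, (a.pos_y + b.pos_y) / 2.0)
            face = _match_face(mid, faces, params.dh_max_px)
            s = face.scale if face is not None else 1.0
            if not (params.min_sep_px * s <= dx <= params.dh_max_px * s):
                continue
            if dy > params.dv_max_px * s:
                continue
            valid.append((dt, dx, i, j, a, b, face))
    valid.sort(key=lambda v: (v[0], v[1], v[2], v[3]))
    used: set[int] = set()
    detections: list[BlinkDetection] = []
    consumed: list[BlinkCandidate] = []
    for dt, dx, i, j, a, b, face in valid:
        if i in used or j in used:
            continue
        used.update((i, j))
        left, right = (a, b) if a.pos_x < b.pos_x else (b, a)
        det = BlinkDetection(
            t=(a.t + b.t) // 2,
            left_eye=(left.pos_x, left.pos_y),
            right_eye=(right.pos_x, right.pos_y),
            eye_distance=math.hypot(a.pos_x - b.pos_x, a.pos_y - b.pos_y),
            candidate_pair=(left, right),
            matched_face=None if face is None else face.face_id,
        )
        detections.append(det)
        for cand in (a, b):
            consumed.append(cand)
            consumed.extend(absorbed.get(id(cand), ()))
    return detections, consumed
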