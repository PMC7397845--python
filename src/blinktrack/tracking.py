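"""Bivariate-Gaussian eye trackers grouped into face tracks.

Each detected face carries two trackers, one per eye, each a bivariate
normal distribution (mean mu, covariance Sigma) over the pixel plane. An
incoming event is scored by every tracker's density

    p(u) = (2 pi)^-1 |Sigma|^-1/2 exp(-1/2 (u - mu)^T Sigma^-1 (u - mu))

and assigned to the highest-density tracker provided its squared
Mahalanobis distance is inside the gate (default 9 ~ 3 sigma); gated-out
events are background. Assigned events blend into the tracker:

    mu    <- (1 - eta_mu) mu + eta_mu u
    Sigma <- (1 - eta_S) Sigma + eta_S (u - mu')(u - mu')^T

with mu' the post-update mean. Sigma's eigenvalues are clamped to
[1, 256] px^2 (std 1..16 px): the floor keeps the density well conditioned,
the cap keeps the Mahalanobis gate local so diffuse background activity
cannot inflate a tracker into a sensor-wide attractor.

Blink detections initialize faces and correct their drift: a matched
detection re-initializes the eye trackers (mean and covariance) at the
detected eye positions and refreshes the face's scale factor
(eye distance / reference distance). A face whose trackers starve of
events and blinks long enough is flagged lost; a later matching blink
revives it.
"""

from __future__ import annotations

import dataclasses
import math

from .pairing import BlinkDetection

TWO_PI = 2.0 * math.pi

DEFAULT_ETA_MU = 0.05
DEFAULT_ETA_SIGMA = 0.01
DEFAULT_MAHAL_GATE = 9.0
DEFAULT_MIN_EIG = 1.0
DEFAULT_MAX_EIG = 256.0
DEFAULT_INIT_STD = 19.0  # one primary tile width
DEFAULT_REFERENCE_DISTANCE = 95.0

LEFT = "left"
RIGHT = "right"

ACTIVE = "active"
LOST = "lost"


class GaussianTracker:
    """One eye's bivariate normal tracker (scalar 2x2 algebra for speed)."""

    __slots__ = (
        "mu_x", "mu_y", "sxx", "sxy", "syy", "last_t", "support",
        "_det", "_ixx", "_ixy", "_iyy",
    )

    def __init__(self, mu_x: float, mu_y: float, var: float = DEFAULT_INIT_STD ** 2,
                 t: int = 0) -> None:
        self.mu_x = float(mu_x)
        self.mu_y = float(mu_y)
        self.sxx = float(var)
        self.sxy = 0.0
        self.syy = float(var)
        self.last_t = int(t)
        self.support = 0
        self._refresh_inverse()

    # -- covariance bookkeeping ------------------------------------------

    def _refresh_inverse(self) -> None:
        det = self.sxx * self.syy - self.sxy * self.sxy
        self._det = det
        self._ixx = self.syy / det
        self._iyy = self.sxx / det
        self._ixy = -self.sxy / det

    @property
    def mu(self) -> tuple[float, float]:
        return (self.mu_x, self.mu_y)

    @property
    def sigma(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return ((self.sxx, self.sxy), (self.sxy, self.syy))

    def set_sigma(self, sxx: float, sxy: float, syy: float,
                  min_eig: float = DEFAULT_MIN_EIG,
                  max_eig: float = DEFAULT_MAX_EIG) -> None:
        self.sxx, self.sxy, self.syy = _clamp_spd(sxx, sxy, syy, min_eig, max_eig)
        self._refresh_inverse()

    # -- scoring ----------------------------------------------------------

    def mahalanobis2(self, x: float, y: float) -> float:
        dx = x - self.mu_x
        dy = y - self.mu_y
        return dx * dx * self._ixx + 2.0 * dx * dy * self._ixy + dy * dy * self._iyy

    def density(self, x: float, y: float) -> float:
        """Bivariate normal density p(u) at pixel u = (x, y)."""
        return math.exp(-0.5 * self.mahalanobis2(x, y)) / (TWO_PI * math.sqrt(self._det))


def event_score(tracker: GaussianTracker, u: tuple[float, float]) -> float:
    """Density of the tracker's bivariate normal at ``u`` (pixels^-2)."""
    return tracker.density(u[0], u[1])


def update_tracker(
    tracker: GaussianTracker,
    u: tuple[float, float],
    t: int,
    eta_mu: float = DEFAULT_ETA_MU,
    eta_sigma: float = DEFAULT_ETA_SIGMA,
    min_eig: float = DEFAULT_MIN_EIG,
    max_eig: float = DEFAULT_MAX_EIG,
) -> GaussianTracker:
    """Blend an assigned event into the tracker (in place)."""
    x, y = u
    tracker.mu_x = (1.0 - eta_mu) * tracker.mu_x + eta_mu * x
    tracker.mu_y = (1.0 - eta_mu) * tracker.mu_y + eta_mu * y
    dx = x - tracker.mu_x  # deviation from the post-update mean
    dy = y - tracker.mu_y
    sxx = (1.0 - eta_sigma) * tracker.sxx + eta_sigma * dx * dx
    sxy = (1.0 - eta_sigma) * tracker.sxy + eta_sigma * dx * dy
    syy = (1.0 - eta_sigma) * tracker.syy + eta_sigma * dy * dy
    tracker.set_sigma(sxx, sxy, syy, min_eig, max_eig)
    tracker.last_t = t
    tracker.support += 1
    return tracker


def _clamp_spd(sxx: float, sxy: float, syy: float,
               min_eig: float, max_eig: float) -> tuple[float, float, float]:
    """Clamp the eigenvalues of a symmetric 2x2 matrix to [min_eig, max_eig]."""
    tr = sxx + syy
    diff = sxx - syy
    disc = math.sqrt(diff * diff + 4.0 * sxy * sxy)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    c1 = min(max(l1, min_eig), max_eig)
    c2 = min(max(l2, min_eig), max_eig)
    if c1 == l1 and c2 == l2:
        return sxx, sxy, syy
    if disc < 1e-12:
        return c1, 0.0, c2
    # eigenvector for l1
    if abs(sxy) > 1e-12:
        vx, vy = l1 - syy, sxy
    else:
        vx, vy = (1.0, 0.0) if sxx >= syy else (0.0, 1.0)
    norm = math.hypot(vx, vy)
    vx, vy = vx / norm, vy / norm
    # recompose c1 v v^T + c2 w w^T with w orthogonal to v
    return (
        c1 * vx * vx + c2 * vy * vy,
        (c1 - c2) * vx * vy,
        c1 * vy * vy + c2 * vx * vx,
    )


@dataclasses.dataclass
class FaceTrack:
    """Two eye trackers plus the scale factor and face bookkeeping."""

    face_id: int
    left: GaussianTracker
    right: GaussianTracker
    scale: float
    status: str = ACTIVE
    created_t: int = 0
    last_blink_t: int = 0
    reference_distance: float = DEFAULT_REFERENCE_DISTANCE

    def eye_midpoint(self) -> tuple[float, float]:
        return (
            (self.left.mu_x + self.right.mu_x) / 2.0,
            (self.left.mu_y + self.right.mu_y) / 2.0,
        )

    def eye_distance(self) -> float:
        return math.hypot(self.right.mu_x - self.left.mu_x,
                          self.right.mu_y - self.left.mu_y)

    def trackers(self):
        yield LEFT, self.left
        yield RIGHT, self.right

    def last_event_t(self) -> int:
        return max(self.left.last_t, self.right.last_t)


def assign_event(
    faces,
    x: float,
    y: float,
    gate: float = DEFAULT_MAHAL_GATE,
) -> tuple[int, str] | None:
    """Assign an event to the highest-density eye tracker within the gate.

    Only active faces compete. Ties on density break deterministically on
    (face_id, left-before-right). Returns ``(face_id, side)`` or ``None``
    for background events.
    """
    best = None
    best_density = -1.0
    for face in faces:
        if face.status != ACTIVE:
            continue
        for side, tracker in face.trackers():
            if tracker.mahalanobis2(x, y) > gate:
                continue
            d = tracker.density(x, y)
            if d > best_density:
                best_density = d
                best = (face.face_id, side)
    return best


def init_face(
    detection: BlinkDetection,
    face_id: int,
    init_std: float = DEFAULT_INIT_STD,
    reference_distance: float = DEFAULT_REFERENCE_DISTANCE,
) -> FaceTrack:
    """Start a face track from a new-face blink detection.

    Eye trackers are centered on the detected eye positions with isotropic
    covariance (std = one tile width); the scale factor is the detected eye
    distance over the reference distance.
    """
    var = init_std * init_std
    t = detection.t
    return FaceTrack(
        face_id=face_id,
        left=GaussianTracker(*detection.left_eye, var=var, t=t),
        right=GaussianTracker(*detection.right_eye, var=var, t=t),
        scale=detection.eye_distance / reference_distance,
        status=ACTIVE,
        created_t=t,
        last_blink_t=t,
        reference_distance=reference_distance,
    )


def correct_with_blink(
    face: FaceTrack,
    detection: BlinkDetection,
    init_std: float = DEFAULT_INIT_STD,
) -> FaceTrack:
    """Drift-correct a face from a matched blink detection.

    Both eye trackers are re-initialized (mean and covariance) at the
    detected eye positions, the scale is recomputed from the new eye
    distance, and a lost face comes back active.
    """
    var = init_std * init_std
    for tracker, pos in ((face.left, detection.left_eye), (face.right, detection.right_eye)):
        tracker.mu_x, tracker.mu_y = pos
        tracker.set_sigma(var, 0.0, var)
        tracker.last_t = detection.t
    face.scale = detection.eye_distance / face.reference_distance
    face.last_blink_t = detection.t
    face.status = ACTIVE
    return face


def correct_single_eye(
    face: FaceTrack,
    side: str,
    pos: tuple[float, float],
    t: int,
    init_std: float = DEFAULT_INIT_STD,
) -> FaceTrack:
    """Single-eye drift correction (pose variation: one eye occluded).

    Moves only the named eye's tracker; the scale is left untouched because
    a lone candidate carries no eye-distance information.
    """
    tracker = face.left if side == LEFT else face.right
    tracker.mu_x, tracker.mu_y = pos
    var = init_std * init_std
    tracker.set_sigma(var, 0.0, var)
    tracker.last_t = t
    face.last_blink_t = t
    face.status = ACTIVE
    return face


def face_box(
    face: FaceTrack,
    width_factor: float = 2.2,
    height_factor: float = 2.8,
    eye_level: float = 0.35,
) -> tuple[float, float, float, float]:
    """Face bounding box ``(x, y, w, h)`` derived from the eye positions.

    Anthropometric convention: box width 2.2x and height 2.8x the eye
    distance, centered horizontally on the eye midpoint, with the eyes at
    35% of the box height from the top.
    """
    d = face.eye_distance()
    w = width_factor * d
    h = height_factor * d
    mx, my = face.eye_midpoint()
    return (mx - w / 2.0, my - eye_level * h, w, h)


def box_center(box: tuple[float, float, float, float]) -> tuple[float, float]:
    x, y, w, h = box
    return (x + w / 2.0, y + h / 2.0)
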