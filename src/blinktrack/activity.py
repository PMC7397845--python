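"""Exponentially decaying ON/OFF activity functions.

Each spatial tile keeps two scalar activity traces, one per polarity. On
every event the trace of the matching polarity is decayed from its own last
event time and incremented:

    A_p(t_i) = A_p(t_last) * exp(-(t_i - t_last) / tau) + 1 / scale

which is the exact incremental form of the direct sum
``(1/scale) * sum_j exp(-(t_i - t_j) / tau)`` over past same-polarity
events. ``tau`` defaults to 50 ms; ``scale`` (>= 0, supplied by the
pipeline from the matched face, 1 when no face is known) normalizes the
event flux of nearer, larger faces so that one template fits all distances.

The state also buffers the trailing-window events together with the
activity sample taken *just after* each increment; the correlation stage
consumes those cached samples and never recomputes decays.
"""

from __future__ import annotations

import math
from collections import deque

from .events import OFF, ON, EventOrderError

DEFAULT_TAU_US = 50_000
DEFAULT_WINDOW_US = 250_000


class ActivityState:
    """Per-tile, per-polarity decaying activity with a trailing event buffer.

    Attributes
    ----------
    a_on, a_off:
        Activity values at the last update of the respective polarity.
    t_u, t_v:
        Timestamps (us) of the last ON and OFF event, or ``None``.
    scale:
        Read-mostly corrective factor; each event adds ``1/scale``.
    buffer:
        deque of ``(t, p, sample)`` for events in ``[t_last - window, t_last]``.
    """

    __slots__ = ("a_on", "a_off", "t_u", "t_v", "tau", "window", "scale", "buffer")

    def __init__(
        self,
        tau: float = DEFAULT_TAU_US,
        window: int = DEFAULT_WINDOW_US,
        scale: float = 1.0,
    ) -> None:
        if tau <= 0:
            raise ValueError(f"tau must be positive, got {tau}")
        if window <= 0:
            raise ValueError(f"window must be positive, got {window}")
        if scale <= 0:
            raise ValueError(f"scale must be positive, got {scale}")
        self.tau = float(tau)
        self.window = int(window)
        self.scale = float(scale)
        self.a_on = 0.0
        self.a_off = 0.0
        self.t_u: int | None = None
        self.t_v: int | None = None
        self.buffer: deque[tuple[int, int, float]] = deque()

    def update(self, t: int, p: int) -> float:
        """Apply one event; returns the post-increment activity sample."""
        if p == ON:
            if self.t_u is not None:
                if t < self.t_u:
                    raise EventOrderError(
                        f"ON event at t={t} precedes last ON event at t={self.t_u}"
                    )
                self.a_on *= math.exp(-(t - self.t_u) / self.tau)
            self.a_on += 1.0 / self.scale
            self.t_u = t
            sample = self.a_on
        elif p == OFF:
            if self.t_v is not None:
                if t < self.t_v:
                    raise EventOrderError(
                        f"OFF event at t={t} precedes last OFF event at t={self.t_v}"
                    )
                self.a_off *= math.exp(-(t - self.t_v) / self.tau)
            self.a_off += 1.0 / self.scale
            self.t_v = t
            sample = self.a_off
        else:
            raise ValueError(f"polarity must be 0 or 1, got {p}")
        self.buffer.append((t, p, sample))
        self.prune(t)
        return sample

    def read(self, t: int, p: int) -> float:
        """Decayed activity at time ``t`` without mutating the state."""
        if p == ON:
            if self.t_u is None:
                return 0.0
            if t < self.t_u:
                raise EventOrderError(f"read at t={t} precedes last ON event {self.t_u}")
            return self.a_on * math.exp(-(t - self.t_u) / self.tau)
        if p == OFF:
            if self.t_v is None:
                return 0.0
            if t < self.t_v:
                raise EventOrderError(f"read at t={t} precedes last OFF event {self.t_v}")
            return self.a_off * math.exp(-(t - self.t_v) / self.tau)
        raise ValueError(f"polarity must be 0 or 1, got {p}")

    def prune(self, t_now: int) -> None:
        """Drop buffered events older than ``t_now - window`` (lazy)."""
        cutoff = t_now - self.window
        buf = self.buffer
        while buf and buf[0][0] < cutoff:
            buf.popleft()

    def count(self) -> int:
        """Number of events currently buffered (both polarities)."""
        return len(self.buffer)
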