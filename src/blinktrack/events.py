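"""Event data model and stream I/O.

An event camera (silicon retina) emits an asynchronous stream of change
events ``ev = (x, y, t, p)``: pixel coordinates, a microsecond timestamp and
an ON/OFF polarity flagging a local increase or decrease in log-luminance.
This module defines the in-memory containers shared by every other module
and the two on-disk dialects:

* ``csv`` — plain text, header ``x,y,t,p`` with ``p`` in {0, 1}, optionally
  preceded by a ``# geometry <W> <H>`` comment line;
* ``packed`` — an HDF5 container with a single ``(N, 4)`` int64 dataset
  ``events`` and ``width``/``height`` attributes.

Timestamps are integer microseconds; floats are rejected at parse time.
Loaders always return a stream sorted by time (stable, preserving file
order among ties) with coordinates validated against the sensor geometry.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import h5py
import numpy as np

#: Polarity codes: ON = luminance increase, OFF = decrease.
ON = 1
OFF = 0

DEFAULT_WIDTH = 304
DEFAULT_HEIGHT = 240


class EventStreamError(ValueError):
    """Base class for event-stream parsing/validation failures."""


class ParseError(EventStreamError):
    """A row of an event file could not be parsed."""


class ValidationError(EventStreamError):
    """An event violates the sensor geometry or polarity contract."""


class EventOrderError(EventStreamError):
    """An operation received an event older than the state it updates."""


class Event(NamedTuple):
    """A single change event ``(x, y, t, p)``."""

    x: int
    y: int
    t: int
    p: int


@dataclasses.dataclass(frozen=True)
class SensorGeometry:
    """Pixel dimensions of the event sensor (default ATIS, 304 x 240)."""

    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"sensor geometry must be positive, got {self.width}x{self.height}"
            )

    def contains(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height


@dataclasses.dataclass
class EventStream:
    """A time-sorted column-wise event stream.

    Coordinates follow the sensor convention used throughout the package:
    0-based, origin at the top-left corner, ``y`` growing downward.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    p: np.ndarray
    geometry: SensorGeometry = dataclasses.field(default_factory=SensorGeometry)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=np.int64)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.p) == n):
            raise ValidationError("event stream columns have mismatched lengths")

    # -- constructors ----------------------------------------------------

    @classmethod
    def empty(cls, geometry: SensorGeometry | None = None) -> "EventStream":
        g = geometry or SensorGeometry()
        z = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy(), z.copy(), g)

    @classmethod
    def from_events(
        cls, events: Sequence[Event], geometry: SensorGeometry | None = None
    ) -> "EventStream":
        g = geometry or SensorGeometry()
        if not events:
            return cls.empty(g)
        arr = np.asarray(events, dtype=np.int64)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], g)

    # -- container protocol ----------------------------------------------

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[Event]:
        for i in range(len(self)):
            yield Event(int(self.x[i]), int(self.y[i]), int(self.t[i]), int(self.p[i]))

    def __getitem__(self, i: int) -> Event:
        return Event(int(self.x[i]), int(self.y[i]), int(self.t[i]), int(self.p[i]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.geometry == other.geometry
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.p, other.p)
        )

    # -- contracts --------------------------------------------------------

    def validate(self) -> None:
        """Raise unless coordinates/polarities fit the geometry contract."""
        if len(self) == 0:
            return
        g = self.geometry
        bad = (self.x < 0) | (self.x >= g.width) | (self.y < 0) | (self.y >= g.height)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValidationError(
                f"event {i} at ({int(self.x[i])}, {int(self.y[i])}) outside "
                f"{g.width}x{g.height} sensor"
            )
        badp = (self.p != ON) & (self.p != OFF)
        if badp.any():
            i = int(np.argmax(badp))
            raise ValidationError(f"event {i} has polarity {int(self.p[i])}, expected 0 or 1")

    def sorted_by_time(self) -> "EventStream":
        """Stable time sort (file order preserved among equal timestamps)."""
        if len(self) and np.any(np.diff(self.t) < 0):
            order = np.argsort(self.t, kind="stable")
            return EventStream(
                self.x[order], self.y[order], self.t[order], self.p[order], self.geometry
            )
        return self


@dataclasses.dataclass
class AnnotatedBlink:
    """Events of one eye's region inside a fixed blink annotation window.

    The canonical blink template is averaged from a set of these windows
    (250 ms by default, the nominal duration of an eyelid closure plus
    reopening). Event timestamps must lie inside
    ``[window_start, window_start + window_length]``.
    """

    events: EventStream
    window_start: int
    window_length: int = 250_000
    subject_id: str = ""
    condition: str = "indoor"

    def __post_init__(self) -> None:
        if len(self.events):
            t = self.events.t
            lo, hi = self.window_start, self.window_start + self.window_length
            if t.min() < lo or t.max() > hi:
                raise ValidationError(
                    "annotated blink has events outside its window "
                    f"[{lo}, {hi}]: [{int(t.min())}, {int(t.max())}]"
                )
        if self.condition not in ("indoor", "outdoor"):
            raise ValidationError(f"unknown condition {self.condition!r}")

    def shifted_to_origin(self) -> "AnnotatedBlink":
        """Return a copy with the window start moved to t = 0."""
        ev = self.events
        shifted = EventStream(ev.x, ev.y, ev.t - self.window_start, ev.p, ev.geometry)
        return AnnotatedBlink(
            shifted, 0, self.window_length, self.subject_id, self.condition
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_HEADER = "x,y,t,p"
_DIALECTS = ("csv", "packed")


def read_events(
    path: str | Path,
    dialect: str = "csv",
    geometry: SensorGeometry | None = None,
) -> tuple[EventStream, SensorGeometry]:
    """Read an event stream; returns ``(stream, geometry)``.

    ``geometry`` overrides anything stored in the file. An empty file is an
    empty stream, not an error. The returned stream is time-sorted and
    bounds-validated.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "csv":
        stream = _read_csv(path, geometry)
    else:
        stream = _read_packed(path, geometry)
    stream = stream.sorted_by_time()
    stream.validate()
    return stream, stream.geometry


def write_events(stream: EventStream, path: str | Path, dialect: str = "csv") -> None:
    """Write a stream so that ``read_events`` round-trips it bit-exactly."""
    path = Path(path)
    if dialect == "csv":
        g = stream.geometry
        with open(path, "w") as fh:
            fh.write(f"# geometry {g.width} {g.height}\n")
            fh.write(_CSV_HEADER + "\n")
            for i in range(len(stream)):
                fh.write(
                    f"{stream.x[i]},{stream.y[i]},{stream.t[i]},{stream.p[i]}\n"
                )
    elif dialect == "packed":
        with h5py.File(path, "w") as fh:
            data = np.column_stack([stream.x, stream.y, stream.t, stream.p])
            dset = fh.create_dataset("events", data=data.astype(np.int64))
            dset.attrs["columns"] = "x,y,t,p"
            fh.attrs["width"] = stream.geometry.width
            fh.attrs["height"] = stream.geometry.height
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def _read_csv(path: Path, geometry: SensorGeometry | None) -> EventStream:
    file_geometry = None
    rows: list[tuple[int, int, int, int]] = []
    with open(path) as fh:
        lineno = 0
        header_seen = False
        for line in fh:
            lineno += 1
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                file_geometry = _parse_geometry_comment(line, lineno) or file_geometry
                continue
            if not header_seen:
                if line.replace(" ", "") != _CSV_HEADER:
                    raise ParseError(
                        f"{path}:{lineno}: expected header '{_CSV_HEADER}', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                rows.append((int(parts[0]), int(parts[1]), int(parts[2]), int(parts[3])))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer field in {line!r} "
                    "(timestamps are integer microseconds)"
                ) from exc
    g = geometry or file_geometry or SensorGeometry()
    if not rows:
        return EventStream.empty(g)
    arr = np.asarray(rows, dtype=np.int64)
    return EventStream(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], g)


def _parse_geometry_comment(line: str, lineno: int) -> SensorGeometry | None:
    parts = line.lstrip("#").split()
    if not parts or parts[0] != "geometry":
        return None
    if len(parts) != 3:
        raise ParseError(f"line {lineno}: malformed geometry comment {line!r}")
    return SensorGeometry(int(parts[1]), int(parts[2]))


def _read_packed(path: Path, geometry: SensorGeometry | None) -> EventStream:
    with h5py.File(path, "r") as fh:
        if "events" not in fh:
            raise ParseError(f"{path}: missing 'events' dataset")
        data = np.asarray(fh["events"], dtype=np.int64)
        if data.ndim != 2 or data.shape[1] != 4:
            raise ParseError(
                f"{path}: 'events' must be an (N, 4) array, got shape {data.shape}"
            )
        file_geometry = None
        if "width" in fh.attrs and "height" in fh.attrs:
            file_geometry = SensorGeometry(int(fh.attrs["width"]), int(fh.attrs["height"]))
    g = geometry or file_geometry or SensorGeometry()
    if len(data) == 0:
        return EventStream.empty(g)
    return EventStream(data[:, 0], data[:, 1], data[:, 2], data[:, 3], g)
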