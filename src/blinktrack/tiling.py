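"""Dual overlapping tile grids over the sensor plane.

The focal plane is divided into a primary grid of ``n x n`` rectangular
tiles and a secondary grid of ``(n - 1) x (n - 1)`` tiles shifted by half a
tile in each direction, so that an eye landing on a primary tile boundary
still falls near the center of some secondary tile. With the default
304 x 240 sensor and ``n = 16`` the tiles are 19 x 15 px and the secondary
offset is (9, 7) px (half tile, floored to integer pixels).

Each tile owns one :class:`~blinktrack.activity.ActivityState`; an event
updates the one primary tile containing it plus the secondary tile when it
lies inside the secondary grid's extent. Remainder pixels of geometries not
divisible by ``n`` are absorbed by the last row/column of the primary grid.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

from .activity import DEFAULT_TAU_US, DEFAULT_WINDOW_US, ActivityState
from .events import SensorGeometry, ValidationError

PRIMARY = "primary"
SECONDARY = "secondary"

DEFAULT_N = 16

TileKey = tuple[str, int, int]


@dataclasses.dataclass(frozen=True)
class TileGrid:
    grid_id: str
    n_rows: int
    n_cols: int
    tile_w: int
    tile_h: int
    offset_x: int
    offset_y: int


def make_grids(geometry: SensorGeometry, n: int = DEFAULT_N) -> tuple[TileGrid, TileGrid]:
    """Primary ``n x n`` grid plus the half-shifted ``(n-1) x (n-1)`` grid."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    tw, th = geometry.width // n, geometry.height // n
    if tw < 1 or th < 1:
        raise ValueError(f"n={n} too large for {geometry.width}x{geometry.height} sensor")
    primary = TileGrid(PRIMARY, n, n, tw, th, 0, 0)
    secondary = TileGrid(SECONDARY, n - 1, n - 1, tw, th, tw // 2, th // 2)
    return primary, secondary


def tiles_for_event(
    x: int, y: int, geometry: SensorGeometry, n: int = DEFAULT_N
) -> list[TileKey]:
    """Tiles containing pixel ``(x, y)``: the primary one, plus the secondary
    one when the pixel lies inside the secondary grid's extent."""
    if not geometry.contains(x, y):
        raise ValidationError(
            f"event at ({x}, {y}) outside {geometry.width}x{geometry.height} sensor"
        )
    tw, th = geometry.width // n, geometry.height // n
    # Remainder pixels fold into the last primary row/column.
    c = min(x // tw, n - 1)
    r = min(y // th, n - 1)
    out: list[TileKey] = [(PRIMARY, r, c)]
    ox, oy = tw // 2, th // 2
    if ox <= x < ox + (n - 1) * tw and oy <= y < oy + (n - 1) * th:
        out.append((SECONDARY, (y - oy) // th, (x - ox) // tw))
    return out


def tile_center(
    grid_id: str, r: int, c: int, geometry: SensorGeometry, n: int = DEFAULT_N
) -> tuple[float, float]:
    """Pixel-coordinate center of a tile rectangle.

    Used as the eye-position estimate when a tile fires a blink candidate.
    """
    tw, th = geometry.width // n, geometry.height // n
    if grid_id == PRIMARY:
        if not (0 <= r < n and 0 <= c < n):
            raise ValueError(f"invalid primary tile ({r}, {c}) for n={n}")
        span_w = tw + (geometry.width - n * tw) if c == n - 1 else tw
        span_h = th + (geometry.height - n * th) if r == n - 1 else th
        return (c * tw + (span_w - 1) / 2.0, r * th + (span_h - 1) / 2.0)
    if grid_id == SECONDARY:
        if not (0 <= r < n - 1 and 0 <= c < n - 1):
            raise ValueError(f"invalid secondary tile ({r}, {c}) for n={n}")
        ox, oy = tw // 2, th // 2
        return (ox + c * tw + (tw - 1) / 2.0, oy + r * th + (th - 1) / 2.0)
    raise ValueError(f"unknown grid {grid_id!r}")


def tile_diagonal(geometry: SensorGeometry, n: int = DEFAULT_N) -> float:
    tw, th = geometry.width // n, geometry.height // n
    return (tw * tw + th * th) ** 0.5


class TileActivity:
    """Owner of the per-tile activity states for both grids.

    States are created lazily on first touch; an event updates one or two
    states (`tiles_for_event`) and the per-event result carries the cached
    activity samples the correlation stage needs.
    """

    def __init__(
        self,
        geometry: SensorGeometry,
        n: int = DEFAULT_N,
        tau: float = DEFAULT_TAU_US,
        window: int = DEFAULT_WINDOW_US,
    ) -> None:
        self.geometry = geometry
        self.n = n
        self.tau = tau
        self.window = window
        self._states: dict[TileKey, ActivityState] = {}

    def state(self, key: TileKey) -> ActivityState:
        st = self._states.get(key)
        if st is None:
            st = ActivityState(tau=self.tau, window=self.window)
            self._states[key] = st
        return st

    def update(self, x: int, y: int, t: int, p: int, scale: float = 1.0) -> list[
        tuple[TileKey, ActivityState, float]
    ]:
        """Apply one event to every grid containing it; returns the touched
        ``(key, state, sample)`` triples."""
        out = []
        for key in tiles_for_event(x, y, self.geometry, self.n):
            st = self.state(key)
            st.scale = scale
            sample = st.update(t, p)
            out.append((key, st, sample))
        return out

    def __iter__(self) -> Iterator[tuple[TileKey, ActivityState]]:
        return iter(self._states.items())
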