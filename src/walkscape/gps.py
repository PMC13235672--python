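"""Walking-trip reconstruction from raw GPS fixes.

Raw positional fixes are chronologically ordered per trip, cleaned of
teleport artifacts (any fix more than 500 m from the previously retained
fix is dropped), segmented into walking trips by a simplified stop
detector, converted to planar LineStrings in a local metric frame,
buffered (25 m by default) and intersected with a 25-m hexagonal
exposure grid.

All geometry is computed in a local equirectangular frame centred on the
data, so shapely operates in metres; coordinates are exchanged as WGS84
latitude/longitude degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timezone

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.strtree import STRtree

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "GpsPointStream",
    "WalkingTrip",
    "HexGrid",
    "LocalFrame",
    "haversine_m",
    "clean_stream",
    "segment_trips",
    "buffer_route",
    "build_hex_grid",
    "cells_for_route",
]


def haversine_m(p1, p2):
    """Great-circle distance in metres between two (lat, lon) points in degrees.

    Uses the Haversine formula on a sphere of radius 6,371,000 m.
    Symmetric and non-negative; raises ValueError for latitudes outside
    [-90, 90] or longitudes outside [-180, 360).
    """
    lat1, lon1 = float(p1[0]), float(p1[1])
    lat2, lon2 = float(p2[0]), float(p2[1])
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon < 360.0:
            raise ValueError(f"longitude {lon} outside [-180, 360)")
    return float(
        _haversine_arrays(
            np.array([lat1]), np.array([lon1]), np.array([lat2]), np.array([lon2])
        )[0]
    )


def _haversine_arrays(lat1, lon1, lat2, lon2):
    """Vectorised Haversine distance (degrees in, metres out)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class LocalFrame:
    """Equirectangular metric frame anchored at a reference (lat, lon).

    x grows east, y grows north, both in metres. Adequate at the
    city-block scales handled here (buffers of tens of metres).
    """

    ref_lat: float
    ref_lon: float

    def to_xy(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        m_per_deg = EARTH_RADIUS_M * np.pi / 180.0
        x = (lon - self.ref_lon) * m_per_deg * np.cos(np.radians(self.ref_lat))
        y = (lat - self.ref_lat) * m_per_deg
        return x, y

    def to_latlon(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        m_per_deg = EARTH_RADIUS_M * np.pi / 180.0
        lat = self.ref_lat + y / m_per_deg
        lon = self.ref_lon + x / (m_per_deg * np.cos(np.radians(self.ref_lat)))
        return lat, lon


@dataclass
class GpsPointStream:
    """Ordered positional fixes for one recorded trip."""

    trip_id: str
    participant_id: str
    t: np.ndarray  # seconds (unix or session-relative), monotone after cleaning
    lat: np.ndarray  # degrees
    lon: np.ndarray  # degrees

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (len(self.t) == len(self.lat) == len(self.lon)):
            raise ValueError("t, lat, lon must have equal length")

    def __len__(self):
        return len(self.t)


@dataclass
class WalkingTrip:
    """A validated walking trip: route polyline, buffer, duration, metadata."""

    trip_id: str
    participant_id: str
    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    frame: LocalFrame = field(repr=False, default=None)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.frame is None:
            self.frame = LocalFrame(float(np.mean(self.lat)), float(np.mean(self.lon)))

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def length_m(self) -> float:
        d = _haversine_arrays(self.lat[:-1], self.lon[:-1], self.lat[1:], self.lon[1:])
        return float(np.sum(d))

    @property
    def date(self) -> date:
        return datetime.fromtimestamp(float(self.t[0]), tz=timezone.utc).date()

    def route_xy(self) -> np.ndarray:
        x, y = self.frame.to_xy(self.lat, self.lon)
        return np.column_stack([x, y])

    def route(self) -> LineString:
        """Route as a LineString in the trip's local metric frame."""
        return LineString(self.route_xy())


def clean_stream(stream: GpsPointStream, gap_exclusion_m: float = 500.0):
    """Order fixes by time and drop teleport fixes.

    A fix is dropped when its Haversine distance from the previously
    *retained* fix is strictly greater than ``gap_exclusion_m`` (500 m by
    default). The rule is applied sequentially in a single pass, so the
    comparison baseline only advances on retained fixes.

    Returns ``(cleaned_stream, n_dropped)``.
    """
    if len(stream) == 0:
        return GpsPointStream(stream.trip_id, stream.participant_id, [], [], []), 0
    order = np.argsort(stream.t, kind="stable")
    t, lat, lon = stream.t[order], stream.lat[order], stream.lon[order]
    consecutive = _haversine_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])
    if np.all(consecutive <= gap_exclusion_m):  # fast path: nothing to drop
        keep = np.arange(len(t))
    else:
        keep = [0]
        for i in range(1, len(t)):
            j = keep[-1]
            d = consecutive[i - 1] if j == i - 1 else _haversine_arrays(
                lat[j : j + 1], lon[j : j + 1], lat[i : i + 1], lon[i : i + 1]
            )[0]
            if d <= gap_exclusion_m:
                keep.append(i)
        keep = np.array(keep)
    cleaned = GpsPointStream(
        stream.trip_id, stream.participant_id, t[keep], lat[keep], lon[keep]
    )
    return cleaned, len(t) - len(keep)


def _rolling_mean(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or len(x) < 2:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    out = np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]
    return out


def segment_trips(
    stream: GpsPointStream,
    stop_speed_mps: float = 0.5,
    stop_dwell_s: float = 120.0,
    min_duration_s: float = 120.0,
    max_speed_mps: float = 3.0,
    speed_window_s: float = 5.0,
) -> list[WalkingTrip]:
    """Split a cleaned stream into valid walking trips.

    Fixes are classified as moving when their rolling speed lies in
    [stop_speed_mps, max_speed_mps]; speeds above the ceiling flag
    non-walking locomotion. Stationary (or non-walking) stretches lasting
    at least ``stop_dwell_s`` split the stream; shorter pauses are
    absorbed. Candidate trips shorter than ``min_duration_s`` are
    discarded.
    """
    if len(stream) < 2:
        return []
    t, lat, lon = stream.t, stream.lat, stream.lon
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-monotone timestamps: stream must be cleaned first")
    d = _haversine_arrays(lat[:-1], lon[:-1], lat[1:], lon[1:])
    speed = d / dt
    # per-fix speed: speed of the incoming segment, first fix copies the second
    fix_speed = np.concatenate([[speed[0]], speed])
    w = max(1, int(round(speed_window_s / np.median(dt))))
    smooth = _rolling_mean(fix_speed, w)
    moving = (smooth >= stop_speed_mps) & (smooth <= max_speed_mps)

    # stationary runs >= stop_dwell_s split the stream
    segments = []
    start = None
    still_start = None
    for i in range(len(t)):
        if moving[i]:
            if start is None:
                start = i
            still_start = None
        else:
            if still_start is None:
                still_start = i
            if start is not None and t[i] - t[still_start] >= stop_dwell_s:
                segments.append((start, still_start))
                start = None
    if start is not None:
        end = still_start if still_start is not None else len(t)
        segments.append((start, end))

    trips = []
    for k, (i0, i1) in enumerate(segments):
        if i1 - i0 < 2:
            continue
        if t[i1 - 1] - t[i0] < min_duration_s:
            continue
        trips.append(
            WalkingTrip(
                trip_id=f"{stream.trip_id}" if len(segments) == 1 else f"{stream.trip_id}-{k}",
                participant_id=stream.participant_id,
                t=t[i0:i1],
                lat=lat[i0:i1],
                lon=lon[i0:i1],
            )
        )
    return trips


def buffer_route(trip_or_line, radius_m: float = 25.0) -> Polygon:
    """Planar Euclidean buffer around the route with round caps and joins.

    Accepts a :class:`WalkingTrip` (buffered in its local frame) or a
    shapely LineString already in metres. Routes with fewer than two
    vertices, or a non-positive radius, are rejected.
    """
    if radius_m <= 0:
        raise ValueError("buffer radius must be positive")
    if isinstance(trip_or_line, WalkingTrip):
        line = trip_or_line.route()
    else:
        line = trip_or_line
    if len(line.coords) < 2:
        raise ValueError("route must have at least 2 vertices")
    return line.buffer(radius_m, quad_segs=8)


@dataclass
class HexGrid:
    """Flat-topped hexagonal tiling of a rectangular extent.

    Cell diameter is the circumscribed-circle (vertex-to-vertex)
    diameter. Cells share edges only; together they cover the extent.
    """

    cell_ids: np.ndarray
    centers: np.ndarray  # (n, 2) metres
    polygons: list
    diameter_m: float
    extent: tuple  # (xmin, ymin, xmax, ymax)
    _tree: STRtree = field(default=None, repr=False)

    def __post_init__(self):
        if self._tree is None:
            self._tree = STRtree(self.polygons)

    def __len__(self):
        return len(self.cell_ids)

    def query(self, geom):
        """Indices of cells whose polygon intersects ``geom``."""
        idx = self._tree.query(geom, predicate="intersects")
        return np.sort(idx)


def build_hex_grid(extent, diameter_m: float = 25.0) -> HexGrid:
    """Tile ``extent = (xmin, ymin, xmax, ymax)`` metres with hexagons.

    Flat-topped layout: columns spaced 1.5 R apart, rows spaced sqrt(3) R,
    odd columns shifted half a row; one extra ring beyond the extent so
    every interior point is covered.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate extent")
    R = diameter_m / 2.0
    # half-step lattice units: every vertex is (xmin + i*hx, ymin + j*hy)
    # with integer i, j, so shared edges are bitwise identical
    hx = R / 2.0
    hy = np.sqrt(3.0) * R / 2.0
    dx = 1.5 * R
    dy = 2.0 * hy
    ncol = int(np.ceil((xmax - xmin) / dx)) + 2
    nrow = int(np.ceil((ymax - ymin) / dy)) + 2
    # flat-topped hexagon vertex offsets in (hx, hy) units
    offsets = [(2, 0), (1, 1), (-1, 1), (-2, 0), (-1, -1), (1, -1)]
    ids, centers, polys = [], [], []
    k = 0
    for col in range(-1, ncol):
        ci = 3 * col  # centre x in hx units
        for row in range(-1, nrow):
            cj = 2 * row + (col & 1)  # centre y in hy units
            verts = [(xmin + (ci + oi) * hx, ymin + (cj + oj) * hy)
                     for oi, oj in offsets]
            polys.append(Polygon(verts))
            centers.append((xmin + ci * hx, ymin + cj * hy))
            ids.append(k)
            k += 1
    return HexGrid(
        cell_ids=np.array(ids),
        centers=np.array(centers),
        polygons=polys,
        diameter_m=diameter_m,
        extent=(xmin, ymin, xmax, ymax),
    )


def cells_for_route(grid: HexGrid, buffer: Polygon) -> np.ndarray:
    """Ids of all grid cells intersecting the buffered route (no duplicates)."""
    idx = grid.query(buffer)
    if len(idx) == 0:
        warnings.warn("buffer does not intersect the grid extent", stacklevel=2)
        return np.array([], dtype=int)
    return grid.cell_ids[idx]
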