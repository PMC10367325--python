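"""GPS track regularization and movement metrics.

Raw biologging GPS tracks are irregular: loggers are programmed to fix at a
constant interval (here 5 min) but poor satellite reception leaves gaps.
Movement HMMs assume an evenly spaced observation grid, so tracks are
linearly interpolated onto a fixed-interval grid anchored at each trip's
first fix. Gaps longer than ``max_gap_s`` are never interpolated across:
the track is split into separate segments which the HMM treats as
independent realizations of the same state-switching process.

From each regularized segment the bivariate observation series is derived:
step length (distance from fix *t* to *t+1*, forward convention) and
turning angle (signed change of heading at *t*, counter-clockwise positive,
wrapped to (-pi, pi]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawTrack",
    "Segment",
    "RegularTrack",
    "MoveSeries",
    "regularize",
    "compute_move_metrics",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class RawTrack:
    """Ordered GPS fixes for one foraging trip.

    Timestamps are seconds (epoch or trip-relative) and must be strictly
    increasing; ``x``/``y`` are planar meters or lon/lat degrees depending
    on the coordinate mode used downstream.
    """

    trip_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError(f"trip {self.trip_id}: field lengths differ")

    @property
    def n_fixes(self) -> int:
        return len(self.times)


@dataclass
class Segment:
    """A gap-free run of fixes on an exact fixed-interval grid."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    interpolated: np.ndarray  # bool per fix

    @property
    def n_fixes(self) -> int:
        return len(self.times)

    @property
    def usable(self) -> bool:
        """Segments with < 3 fixes yield no turning angle."""
        return self.n_fixes >= 3


@dataclass
class RegularTrack:
    trip_id: str
    segments: list[Segment]
    interval_s: float
    crs_mode: str = "planar_m"  # or "lonlat"

    @property
    def n_fixes(self) -> int:
        return sum(s.n_fixes for s in self.segments)


@dataclass
class MoveSeries:
    """Per-fix step lengths and turning angles, NaN where undefined.

    Arrays are aligned with the concatenation of the track's segments;
    ``segment_bounds`` holds (start, stop) index pairs into them. The step
    at the last fix of a segment is missing; angles are missing at both
    segment boundaries and wherever an adjacent step is exactly zero
    (heading undefined).
    """

    trip_id: str
    step: np.ndarray
    angle: np.ndarray
    segment_bounds: list[tuple[int, int]] = field(default_factory=list)

    def per_segment(self):
        for a, b in self.segment_bounds:
            yield self.step[a:b], self.angle[a:b]


def regularize(
    raw: RawTrack, interval_s: float = 300.0, max_gap_s: float = 1200.0
) -> RegularTrack:
    """Interpolate a raw track onto a fixed grid, splitting at long gaps.

    The grid is anchored at the trip's first raw timestamp. Raw inter-fix
    gaps of at most ``max_gap_s`` are filled by linear interpolation of the
    coordinates; any longer gap splits the output into discrete segments
    with nothing interpolated across it.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    if max_gap_s < interval_s:
        raise ValueError("max_gap_s must be >= interval_s")
    t = raw.times
    if np.any(np.diff(t) <= 0):
        raise ValueError(
            f"trip {raw.trip_id}: timestamps not strictly increasing"
        )
    if len(t) < 2:
        warnings.warn(f"trip {raw.trip_id}: fewer than 2 fixes, dropped")
        return RegularTrack(raw.trip_id, [], interval_s)

    # runs of raw fixes separated by gaps <= max_gap_s
    gap = np.diff(t)
    breaks = np.flatnonzero(gap > max_gap_s)
    run_edges = np.concatenate(([0], breaks + 1, [len(t)]))

    t0 = t[0]
    segments: list[Segment] = []
    for a, b in zip(run_edges[:-1], run_edges[1:]):
        tt, xx, yy = t[a:b], raw.x[a:b], raw.y[a:b]
        # grid points anchored at t0 that fall inside this run
        k_lo = int(np.ceil((tt[0] - t0) / interval_s - 1e-9))
        k_hi = int(np.floor((tt[-1] - t0) / interval_s + 1e-9))
        if k_hi < k_lo:
            continue
        grid = t0 + interval_s * np.arange(k_lo, k_hi + 1)
        gx = np.interp(grid, tt, xx)
        gy = np.interp(grid, tt, yy)
        pos = np.searchsorted(tt, grid - 1e-6)
        pos = np.clip(pos, 0, len(tt) - 1)
        interp_flag = np.abs(tt[pos] - grid) > 1e-6
        segments.append(Segment(grid, gx, gy, interp_flag))
    return RegularTrack(raw.trip_id, segments, interval_s)


def _heading_planar(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return np.arctan2(dy, dx)


def _greatcircle_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine distance in meters between lon/lat degree pairs."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    dp = p2 - p1
    h = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _bearing_rad(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial great-circle bearing, converted to CCW-from-east radians."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    y = np.sin(dl) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    # navigation bearing is CW from north; same wrap-invariant differences
    return np.arctan2(x, y)


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    out = np.mod(-a + np.pi, 2 * np.pi)
    return np.pi - out


def compute_move_metrics(track: RegularTrack) -> MoveSeries:
    """Step-length / turning-angle series from a regularized track.

    Steps are Euclidean in ``planar_m`` mode and great-circle (haversine)
    in ``lonlat`` mode; angles are differences of successive headings
    wrapped to (-pi, pi].
    """
    steps: list[np.ndarray] = []
    angles: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    pos = 0
    for seg in track.segments:
        n = seg.n_fixes
        step = np.full(n, np.nan)
        angle = np.full(n, np.nan)
        if n >= 2:
            if track.crs_mode == "lonlat":
                d = _greatcircle_m(
                    seg.x[:-1], seg.y[:-1], seg.x[1:], seg.y[1:]
                )
                head = _bearing_rad(
                    seg.x[:-1], seg.y[:-1], seg.x[1:], seg.y[1:]
                )
            else:
                dx, dy = np.diff(seg.x), np.diff(seg.y)
                d = np.hypot(dx, dy)
                head = _heading_planar(dx, dy)
            step[:-1] = d
            if n >= 3:
                turn = wrap_angle(head[1:] - head[:-1])
                # heading undefined where either adjacent step is zero
                bad = (d[:-1] == 0) | (d[1:] == 0)
                turn = np.where(bad, np.nan, turn)
                angle[1:-1] = turn
        steps.append(step)
        angles.append(angle)
        bounds.append((pos, pos + n))
        pos += n
    if steps:
        return MoveSeries(
            track.trip_id, np.concatenate(steps), np.concatenate(angles), bounds
        )
    return MoveSeries(track.trip_id, np.empty(0), np.empty(0), [])
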