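"""Operational volume geometry and measurement-grid segmentation.

The sampling method operates inside a rectangular cuboid ("operational
volume") anchored at a geodetic origin and rotated in the horizontal plane.
Raw sensor streams are segmented onto a shared ``n_x x n_y x n_z`` grid so
that every agent in the fleet works with, and communicates about, the same
discretisation of the water volume.

Conventions (part of the wire protocol shared between vehicles):

* Local frame: right-handed; ``x`` along the volume orientation ``V_theta``
  measured counter-clockwise from east; ``y`` 90 degrees counter-clockwise
  from ``x``; ``z`` is depth, positive downward, ``z = 0`` at the surface.
* Flat-earth local tangent projection about the origin. Operational areas
  are a few kilometres across, so projection error is far below cell size.
* Linear cell index: x fastest, then y, then z;
  ``id = ix + n_x * (iy + n_y * iz)``.
* Cells are half-open ``[lo, hi)`` except the last cell along each axis,
  which is closed so the far volume face maps to a valid cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Mean Earth radius used by the local tangent projection, metres.
EARTH_RADIUS = 6_371_000.0

#: Grid-size bounds imposed by the 2-byte cell number on the wire.
MIN_GRID_CELLS = 256
MAX_GRID_CELLS = 65_536


@dataclass(frozen=True)
class VolumeConfig:
    """Operational volume: geodetic anchor, orientation, extent and grid.

    Parameters
    ----------
    origin_lat, origin_lon : float
        Geodetic position of the local-frame origin, decimal degrees.
    orientation_theta : float
        Rotation of the volume x-axis, degrees counter-clockwise from east.
    extent : (V_x, V_y, V_z)
        Volume extent in metres; ``V_z`` is the maximum depth.
    grid_dims : (n_x, n_y, n_z)
        Number of grid cells along each axis. The total cell count must fit
        the telemetry cell-number field: 256 <= n_x*n_y*n_z <= 65536.
    """

    origin_lat: float
    origin_lon: float
    orientation_theta: float
    extent: tuple[float, float, float]
    grid_dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.extent) != 3 or len(self.grid_dims) != 3:
            raise ValueError("extent and grid_dims must have three entries")
        if any(e <= 0 for e in self.extent):
            raise ValueError(f"volume extents must be positive, got {self.extent}")
        if any(int(n) < 1 or int(n) != n for n in self.grid_dims):
            raise ValueError(f"grid dims must be positive integers, got {self.grid_dims}")
        n = int(np.prod(self.grid_dims))
        if not MIN_GRID_CELLS <= n <= MAX_GRID_CELLS:
            raise ValueError(
                f"total cell count {n} outside [{MIN_GRID_CELLS}, {MAX_GRID_CELLS}] "
                "(cell numbers are sent as UInt16)"
            )
        object.__setattr__(self, "extent", tuple(float(e) for e in self.extent))
        object.__setattr__(self, "grid_dims", tuple(int(n) for n in self.grid_dims))

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.grid_dims
        return nx * ny * nz

    @property
    def cell_size(self) -> tuple[float, float, float]:
        """Cell extent (dx, dy, dz) in metres."""
        return tuple(e / n for e, n in zip(self.extent, self.grid_dims))


@dataclass(frozen=True)
class LocalPosition:
    """Position in the rotated volume frame; metres, depth positive down."""

    x: float
    y: float
    z: float = 0.0

    def in_volume(self, cfg: VolumeConfig) -> bool:
        vx, vy, vz = cfg.extent
        return 0.0 <= self.x <= vx and 0.0 <= self.y <= vy and 0.0 <= self.z <= vz

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def horizontal_distance(self, other: "LocalPosition") -> float:
        return float(np.hypot(self.x - other.x, self.y - other.y))


@dataclass(frozen=True)
class Measurement:
    """One timestamped, geolocated multi-channel sensor reading.

    ``channels[0]`` is chlorophyll fluorescence (ug/L-equivalent) and must be
    non-negative; further channels (oxygen, temperature, ...) are free-form.
    """

    position: LocalPosition
    time: float
    channels: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(float(c) for c in self.channels))
        if not np.isfinite(self.time):
            raise ValueError("measurement time must be finite")
        if len(self.channels) < 1:
            raise ValueError("at least one channel required")
        if self.channels[0] < 0:
            raise ValueError("channel 0 (fluorescence) must be >= 0")


def _rotation(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])


def latlon_to_local(
    lat: float, lon: float, cfg: VolumeConfig, depth: float = 0.0
) -> LocalPosition:
    """Project geodetic coordinates into the rotated volume frame.

    Out-of-volume positions are returned unchanged (use
    :meth:`LocalPosition.in_volume` to test), never rejected: GPS jitter
    routinely places surface fixes slightly outside the box.
    """
    d_east = np.deg2rad(lon - cfg.origin_lon) * EARTH_RADIUS * np.cos(
        np.deg2rad(cfg.origin_lat)
    )
    d_north = np.deg2rad(lat - cfg.origin_lat) * EARTH_RADIUS
    x, y = _rotation(cfg.orientation_theta) @ (d_east, d_north)
    return LocalPosition(float(x), float(y), float(depth))


def local_to_latlon(p: LocalPosition, cfg: VolumeConfig) -> tuple[float, float]:
    """Inverse of :func:`latlon_to_local` (exact inverse of the projection)."""
    d_east, d_north = _rotation(cfg.orientation_theta).T @ (p.x, p.y)
    lat = cfg.origin_lat + np.rad2deg(d_north / EARTH_RADIUS)
    lon = cfg.origin_lon + np.rad2deg(
        d_east / (EARTH_RADIUS * np.cos(np.deg2rad(cfg.origin_lat)))
    )
    return float(lat), float(lon)


def _axis_index(coord: float, extent: float, n: int) -> int:
    i = int(np.floor(coord / (extent / n)))
    # last cell is closed so the far face maps inside
    return min(max(i, 0), n - 1)


def cell_index(p: LocalPosition, cfg: VolumeConfig) -> int:
    """Linear cell id of an in-volume position (x fastest, then y, then z)."""
    if not p.in_volume(cfg):
        raise ValueError(f"position {p} outside operational volume")
    nx, ny, nz = cfg.grid_dims
    vx, vy, vz = cfg.extent
    ix = _axis_index(p.x, vx, nx)
    iy = _axis_index(p.y, vy, ny)
    iz = _axis_index(p.z, vz, nz)
    return ix + nx * (iy + ny * iz)


def cell_indices(xyz: np.ndarray, cfg: VolumeConfig) -> np.ndarray:
    """Vectorised :func:`cell_index` for an (n, 3) array of in-volume points."""
    nx, ny, nz = cfg.grid_dims
    dims = np.array(cfg.grid_dims)
    sizes = np.asarray(cfg.extent) / dims
    ijk = np.floor(xyz / sizes).astype(int)
    ijk = np.clip(ijk, 0, dims - 1)
    return ijk[:, 0] + nx * (ijk[:, 1] + ny * ijk[:, 2])


def cell_center(idx: int | np.ndarray, cfg: VolumeConfig) -> np.ndarray:
    """Centre coordinates of cell(s) ``idx``; returns (3,) or (n, 3) array."""
    nx, ny, _ = cfg.grid_dims
    idx = np.asarray(idx)
    ix = idx % nx
    iy = (idx // nx) % ny
    iz = idx // (nx * ny)
    dx, dy, dz = cfg.cell_size
    out = np.stack(
        [(ix + 0.5) * dx, (iy + 0.5) * dy, (iz + 0.5) * dz], axis=-1
    ).astype(float)
    return out


def all_cell_centers(cfg: VolumeConfig) -> np.ndarray:
    """(n_cells, 3) array of every cell centre, in linear-index order."""
    return cell_center(np.arange(cfg.n_cells), cfg)


class GridState:
    """Per-cell averaged sensor values and segmentation timestamps.

    Each cell is either empty or carries exactly one value vector (the
    arithmetic mean of the measurements assigned to it in its most recent
    non-empty segmentation batch) plus one timestamp (the mean acquisition
    time of that batch) and the count of contributing measurements.
    """

    def __init__(self, cfg: VolumeConfig, n_channels: int = 1):
        self.cfg = cfg
        self.n_channels = int(n_channels)
        n = cfg.n_cells
        self.values = np.full((n, self.n_channels), np.nan)
        self.times = np.full(n, np.nan)
        self.counts = np.zeros(n, dtype=int)

    def copy(self) -> "GridState":
        out = GridState(self.cfg, self.n_channels)
        out.values = self.values.copy()
        out.times = self.times.copy()
        out.counts = self.counts.copy()
        return out

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of non-empty cells."""
        return ~np.isnan(self.times)

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())

    def set_cell(self, idx: int, values: Sequence[float], time: float, count: int = 1):
        """Overwrite one cell (used when merging telemetry from other agents)."""
        self.values[idx] = np.asarray(values, dtype=float)
        self.times[idx] = float(time)
        self.counts[idx] = int(count)

    def training_arrays(self, cfg: VolumeConfig | None = None):
        """(locations (m,3), times (m,), values (m, n_c), cell ids (m,)) of
        occupied cells, locations at cell centres."""
        cfg = cfg or self.cfg
        ids = np.flatnonzero(self.occupied)
        return cell_center(ids, cfg), self.times[ids], self.values[ids], ids

    def __eq__(self, other) -> bool:
        if not isinstance(other, GridState):
            return NotImplemented
        return (
            self.cfg == other.cfg
            and np.array_equal(self.values, other.values, equal_nan=True)
            and np.array_equal(self.times, other.times, equal_nan=True)
            and np.array_equal(self.counts, other.counts)
        )


def segment(
    measurements: Iterable[Measurement],
    state: GridState,
) -> GridState:
    """Assign a batch of measurements to grid cells; return the new state.

    Cells receiving one or more new measurements are overwritten with the
    mean of the *new* measurements only — temporal de-correlation makes the
    superseded values irrelevant next to fresh data. Untouched cells keep
    their data intact. Cell timestamp is the mean acquisition time of the
    contributing batch. Out-of-volume measurements are dropped (and counted
    in a log warning), not treated as errors.
    """
    cfg = state.cfg
    ms = list(measurements)
    new = state.copy()
    if not ms:
        return new

    inside = [m for m in ms if m.position.in_volume(cfg)]
    n_dropped = len(ms) - len(inside)
    if n_dropped:
        logger.warning("segment: dropped %d out-of-volume measurement(s)", n_dropped)
    if not inside:
        return new

    xyz = np.array([[m.position.x, m.position.y, m.position.z] for m in inside])
    times = np.array([m.time for m in inside])
    chans = np.array([m.channels for m in inside], dtype=float)
    if chans.shape[1] != state.n_channels:
        raise ValueError(
            f"measurements have {chans.shape[1]} channels, grid expects {state.n_channels}"
        )
    ids = cell_indices(xyz, cfg)

    for cid in np.unique(ids):
        sel = ids == cid
        new.values[cid] = chans[sel].mean(axis=0)
        new.times[cid] = times[sel].mean()
        new.counts[cid] = int(sel.sum())
    return new
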