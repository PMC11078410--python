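"""Pilot-survey path generation and the myopic adaptive waypoint chooser.

Each vehicle first runs a deterministic *pilot survey* — parallel crossings
of the operational area with the fleet spread evenly across x:

    x_v = V_x (2 n_v + 1) / (2 N_v),   n_v = 0 .. N_v - 1,

undulating between the surface and the maximum depth to seed the on-board
model at all depths. Afterwards it plans myopically: from the current
position it generates ``3 n_theta`` candidate waypoints on a circle of
radius r at three depth offsets (-z_d, 0, +z_d), screens out candidates that
leave the volume, and picks the one maximising the utility

    U(x) = k_mu * y_hat(x) + k_sigma * Sigma_y^2(x)
           - sum_{k != v} (k_l / d_k(x))^2,

where d_k is the *horizontal* distance to the last known position of
vehicle k (the vertical extent is negligible next to the horizontal). The
separation weight k_l is the standoff radius at which the penalty per
neighbour equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import LocalPosition, VolumeConfig
from .lgp import LogGPResults


@dataclass
class PlannerConfig:
    """Waypoint-planner parameters.

    ``radius`` and ``z_step`` default (when None) to one horizontal /
    vertical grid-cell extent of the volume they are used with, so a planning
    step matches the segmentation resolution. ``undulation`` is
    (min depth m, max depth m, period m of along-track distance per full
    down-up cycle); None entries default to (0, V_z, V_y / 2), i.e. two full
    cycles per volume crossing.
    """

    n_theta: int = 8
    radius: float | None = None
    z_step: float | None = None
    k_mu: float = 1.0
    k_sigma: float = 1.0
    k_l: float = 300.0
    undulation: tuple[float | None, float | None, float | None] = (None, None, None)
    max_fleet_age: float | None = None  # seconds; None = use stale positions as-is

    def __post_init__(self) -> None:
        if self.n_theta < 3:
            raise ValueError("n_theta must be >= 3")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.k_l < 0:
            raise ValueError("k_l must be >= 0")

    def effective_radius(self, cfg: VolumeConfig) -> float:
        return self.radius if self.radius is not None else cfg.extent[0] / cfg.grid_dims[0]

    def effective_z_step(self, cfg: VolumeConfig) -> float:
        return self.z_step if self.z_step is not None else cfg.extent[2] / cfg.grid_dims[2]


@dataclass
class FleetState:
    """Last known positions/report times of the *other* vehicles."""

    own_id: int
    positions: dict[int, tuple[LocalPosition, float]] = field(default_factory=dict)

    def update(self, vehicle_id: int, position: LocalPosition, time: float) -> None:
        if vehicle_id == self.own_id:
            return  # never track self
        self.positions[vehicle_id] = (position, float(time))

    def others(self, now: float | None = None, max_age: float | None = None):
        """Positions to use for separation, optionally dropping stale ones."""
        out = []
        for vid, (pos, t) in sorted(self.positions.items()):
            if max_age is not None and now is not None and now - t > max_age:
                continue
            out.append((vid, pos, t))
        return out


def pilot_x(n_v: int, N_v: int, V_x: float) -> float:
    """x-coordinate of vehicle ``n_v`` (0-indexed) of a fleet of ``N_v``."""
    if not 0 <= n_v < N_v:
        raise ValueError(f"vehicle index {n_v} not in [0, {N_v})")
    return V_x * (2 * n_v + 1) / (2 * N_v)


def pilot_path(
    cfg: VolumeConfig, plan: PlannerConfig, n_v: int, N_v: int
) -> list[LocalPosition]:
    """Undulating crossing from y = 0 to y = V_y at the vehicle's pilot x.

    Waypoints sit at the depth extremes of the sawtooth; y increases strictly
    monotonically across the volume.
    """
    vx, vy, vz = cfg.extent
    x = pilot_x(n_v, N_v, vx)
    z_min, z_max, period = plan.undulation
    z_min = 0.0 if z_min is None else float(z_min)
    z_max = vz if z_max is None else float(z_max)
    period = vy / 2 if period is None else float(period)
    if not (0 <= z_min < z_max <= vz):
        raise ValueError("undulation depths must satisfy 0 <= min < max <= V_z")

    # one waypoint per half-cycle: surface -> deep -> surface -> ...
    n_half = max(1, int(round(2 * vy / period)))
    ys = np.linspace(0.0, vy, n_half + 1)
    return [
        LocalPosition(x, float(y), z_min if i % 2 == 0 else z_max)
        for i, y in enumerate(ys)
    ]


def candidate_waypoints(
    x_v: LocalPosition, plan: PlannerConfig, cfg: VolumeConfig
) -> list[LocalPosition]:
    """The <= 3 n_theta in-volume candidates around the current position.

    Candidates are x_v + (r cos theta_i, r sin theta_i, dz) for n_theta
    uniformly spaced headings and dz in (-z_d, 0, +z_d); those falling
    outside the operational volume are discarded. Ordering is deterministic:
    depth layer (-z_d, 0, +z_d) outermost, then heading index.
    """
    if not x_v.in_volume(cfg):
        raise ValueError(f"vehicle position {x_v} outside operational volume")
    r = plan.effective_radius(cfg)
    z_d = plan.effective_z_step(cfg)
    thetas = 2 * np.pi * np.arange(plan.n_theta) / plan.n_theta
    out: list[LocalPosition] = []
    for dz in (-z_d, 0.0, z_d):
        for th in thetas:
            c = LocalPosition(
                x_v.x + r * np.cos(th), x_v.y + r * np.sin(th), x_v.z + dz
            )
            if c.in_volume(cfg):
                out.append(c)
    if not out:
        raise ValueError(
            "no feasible candidate waypoints (candidate radius exceeds volume?)"
        )
    return out


def utility(
    x_c: LocalPosition,
    y_hat: float,
    sigma_y2: float,
    fleet: FleetState,
    plan: PlannerConfig,
    now: float | None = None,
) -> float:
    """Myopic utility of one candidate given the model output there.

    A candidate exactly at another vehicle's horizontal position scores
    -inf so a collision course is never chosen.
    """
    score = plan.k_mu * float(y_hat) + plan.k_sigma * float(sigma_y2)
    for _, pos, _t in fleet.others(now=now, max_age=plan.max_fleet_age):
        d = x_c.horizontal_distance(pos)
        if d == 0.0:
            return float("-inf")
        score -= (plan.k_l / d) ** 2
    return score


def choose_waypoint(
    x_v: LocalPosition,
    results: LogGPResults,
    tau_now: float,
    fleet: FleetState,
    plan: PlannerConfig,
    cfg: VolumeConfig,
) -> tuple[LocalPosition, float]:
    """Highest-utility feasible candidate; ties break to the lowest index."""
    cands = candidate_waypoints(x_v, plan, cfg)
    locs = np.array([[c.x, c.y, c.z] for c in cands])
    pred = results.predict(locs, tau_now)
    scores = [
        utility(c, yh, s2, fleet, plan, now=tau_now)
        for c, yh, s2 in zip(cands, np.atleast_1d(pred.y_hat), np.atleast_1d(pred.sigma_y2))
    ]
    best = int(np.argmax(scores))  # argmax returns the first (lowest-index) max
    return cands[best], float(scores[best])
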