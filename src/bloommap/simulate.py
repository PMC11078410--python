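"""Synthetic patchy-bloom fields and the multi-vehicle mission simulator.

The ground-truth generator emulates a spring phytoplankton bloom: a strictly
positive fluorescence field whose log-values combine (i) a smooth vertical
profile with a subsurface maximum, (ii) an anisotropic Gaussian random field
giving horizontal patchiness, and (iii) optional discrete Gaussian patches.
The log field is standardised to a target mean/sd, so the marginal
distribution is (approximately) log-normal by construction — the working
assumption of the on-board model.

The simulator runs the full mission cycle per vehicle — pilot survey, then
alternating adaptive sampling and bandwidth-constrained data exchange through
the operator hub — against a static truth field, and scores each vehicle's
on-board model against the truth at every grid-cell centre (RMSE), the
convergence diagnostic used to study fleet-size benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .comms import (
    MSG_VEHICLE_REPORT,
    CellRecord,
    MessageHeader,
    OperatorHub,
    QuantizationScheme,
    encode_message,
)
from .geometry import (
    GridState,
    LocalPosition,
    Measurement,
    VolumeConfig,
    all_cell_centers,
    latlon_to_local,
    local_to_latlon,
    segment,
)
from .lgp import LGPHyperparams, LogGPModel
from .planner import FleetState, PlannerConfig, choose_waypoint, pilot_path


# ---------------------------------------------------------------------------
# Ground-truth field
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldParams:
    """Synthetic bloom-field generator parameters.

    ``log_mean``/``log_sd`` are the mean and sd of ln(fluorescence) over the
    volume (defaults: median 2 ug/L, sd matching the model's process scale).
    ``corr_xy``/``corr_z`` are squared-exponential de-correlation lengths of
    the random component; ``n_patches`` discrete bloom patches of horizontal
    scale ``patch_scale`` are added near the subsurface maximum at
    ``profile_depth`` (m) with vertical spread ``profile_width``.
    """

    log_mean: float = float(np.log(2.0))
    log_sd: float = 1.6
    corr_xy: float = 300.0
    corr_z: float = 15.0
    n_patches: int = 2
    patch_scale: float = 250.0
    patch_amp: float = 1.5
    profile_depth: float = 30.0
    profile_width: float = 15.0
    profile_weight: float = 1.0
    resolution: tuple[int, int, int] = (40, 40, 25)


class TruthField:
    """Static ground-truth fluorescence field over the operational volume."""

    def __init__(self, cfg: VolumeConfig, log_grid: np.ndarray, axes, params: FieldParams):
        self.cfg = cfg
        self.params = params
        self.log_grid = log_grid
        self.axes = axes
        self._interp = RegularGridInterpolator(
            axes, log_grid, method="linear", bounds_error=False, fill_value=None
        )

    def log_at(self, xyz: np.ndarray) -> np.ndarray:
        """ln(fluorescence) at (n, 3) or (3,) local positions."""
        xyz = np.asarray(xyz, dtype=float)
        single = xyz.ndim == 1
        out = self._interp(np.atleast_2d(xyz))
        return float(out[0]) if single else out

    def at(self, xyz: np.ndarray) -> np.ndarray:
        """Fluorescence (ug/L) at local positions; strictly positive."""
        return np.exp(self.log_at(xyz))

    def cell_truth(self) -> np.ndarray:
        """Truth values at every grid-cell centre (linear-index order)."""
        return self.at(all_cell_centers(self.cfg))

    def plot_slice(self, path, z: float = None) -> None:
        """Write a horizontal slice of the field (log colour scale) to a file."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if z is None:
            z = self.params.profile_depth
        xs, ys, _ = self.axes
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        vals = self.log_at(np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)]))
        fig, ax = plt.subplots(figsize=(5.5, 4.5))
        im = ax.pcolormesh(X, Y, vals.reshape(X.shape), shading="auto")
        fig.colorbar(im, ax=ax, label="ln fluorescence")
        ax.set_xlabel("x [m]")
        ax.set_ylabel("y [m]")
        ax.set_title(f"truth field at z = {z:g} m")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def make_truth_field(
    cfg: VolumeConfig, params: FieldParams | None = None, seed: int = 0
) -> TruthField:
    """Generate a reproducible patchy log-normal bloom field."""
    params = params or FieldParams()
    rng = np.random.default_rng(seed)
    rx, ry, rz = params.resolution
    vx, vy, vz = cfg.extent
    xs = np.linspace(0, vx, rx)
    ys = np.linspace(0, vy, ry)
    zs = np.linspace(0, vz, rz)

    # (i) random component: white noise smoothed to the target length scales.
    # A Gaussian filter of sd s yields squared-exponential correlation of
    # length sqrt(2) s, so divide by sqrt(2).
    spacing = np.array([vx / (rx - 1), vy / (ry - 1), vz / (rz - 1)])
    sigmas = np.array([params.corr_xy, params.corr_xy, params.corr_z]) / (
        np.sqrt(2.0) * spacing
    )
    noise = rng.standard_normal((rx, ry, rz))
    grf = gaussian_filter(noise, sigma=sigmas, mode="wrap")
    sd = grf.std()
    if sd > 0:
        grf /= sd

    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    # (ii) smooth vertical profile with a subsurface maximum
    profile = params.profile_weight * np.exp(
        -0.5 * ((Z - params.profile_depth) / params.profile_width) ** 2
    )

    # (iii) discrete bloom patches near the subsurface maximum
    patches = np.zeros_like(X)
    for _ in range(params.n_patches):
        cx = rng.uniform(0.15 * vx, 0.85 * vx)
        cy = rng.uniform(0.15 * vy, 0.85 * vy)
        cz = rng.uniform(
            max(0.0, params.profile_depth - params.profile_width),
            min(vz, params.profile_depth + params.profile_width),
        )
        patches += params.patch_amp * np.exp(
            -0.5
            * (
                ((X - cx) ** 2 + (Y - cy) ** 2) / params.patch_scale**2
                + ((Z - cz) / params.profile_width) ** 2
            )
        )

    raw = grf + profile + patches
    raw = (raw - raw.mean()) / raw.std()
    log_grid = params.log_mean + params.log_sd * raw
    return TruthField(cfg, log_grid, (xs, ys, zs), params)


def sense(
    position: LocalPosition | np.ndarray,
    field: TruthField,
    sigma_n: float,
    rng: np.random.Generator,
) -> float:
    """One noisy reading: truth times a multiplicative log-normal nugget.

    reading = field(position) * exp(eps), eps ~ N(0, sigma_n^2) — the
    multiplicative form matches the log-space nugget of the on-board model
    and keeps readings strictly positive.
    """
    xyz = position.as_array() if isinstance(position, LocalPosition) else position
    eps = rng.normal(0.0, sigma_n) if sigma_n > 0 else 0.0
    return float(np.exp(field.log_at(xyz) + eps))


# ---------------------------------------------------------------------------
# Mission simulation
# ---------------------------------------------------------------------------


@dataclass
class SimSettings:
    """Mission-loop settings (scaled-down defaults sized for a workstation)."""

    n_vehicles: int = 4
    duration: float = 2400.0
    tick: float = 10.0
    exchange_period: float = 600.0
    speed_range: tuple[float, float] = (1.0, 1.5)


@dataclass
class ModelSnapshot:
    """One vehicle's model evaluated at all cell centres at one instant."""

    time: float
    vehicle: int
    f_star_mean: np.ndarray
    y_hat: np.ndarray
    n_train: int


class _SimVehicle:
    def __init__(
        self,
        vid: int,
        n_v: int,
        cfg: VolumeConfig,
        plan: PlannerConfig,
        speed: float,
        rng: np.random.Generator,
    ):
        self.id = vid
        self.speed = speed
        self.rng = rng
        self.pilot = pilot_path(cfg, plan, vid, n_v)
        self.pos = self.pilot[0].as_array()
        self.targets = list(self.pilot[1:])
        self.phase = "pilot"
        self.grid: GridState | None = None  # set by simulator
        self.results = None
        self.fleet = FleetState(own_id=vid)
        self.buffer: list[Measurement] = []
        self.send_queue: list[CellRecord] = []  # newest first
        self.last_exchange = 0.0


class MissionSimulator:
    """Multi-vehicle adaptive sampling mission against a static truth field.

    The per-tick cycle: each vehicle advances toward its current waypoint at
    its nominal speed, sensing once per tick while submerged. On waypoint
    arrival the buffered measurements are segmented into the shared grid,
    the on-board model is refitted, and (in the adaptive phase) the next
    waypoint is chosen by the utility maximiser. When the exchange period
    has elapsed the vehicle surfaces (instantaneously — no travel time is
    charged), reports its unsent cell records to the operator hub within the
    SBD budget, and merges the reply (other vehicles' records and positions)
    into its own grid and fleet state.
    """

    def __init__(
        self,
        field: TruthField,
        hyperparams: LGPHyperparams | None = None,
        planner: PlannerConfig | None = None,
        quant: QuantizationScheme | None = None,
        settings: SimSettings | None = None,
    ):
        self.field = field
        self.cfg = field.cfg
        self.hp = hyperparams or LGPHyperparams()
        self.plan = planner or PlannerConfig()
        self.settings = settings or SimSettings()
        self.quant = quant or QuantizationScheme(time_step=60.0)

    def run(self, seed: int = 0) -> "MissionResult":
        st = self.settings
        cfg = self.cfg
        n_v = st.n_vehicles
        if n_v < 1:
            raise ValueError("need at least one vehicle")
        master = np.random.SeedSequence(seed)
        streams = master.spawn(n_v)
        speed_rng = np.random.default_rng(master.spawn(1)[0])

        vehicles = []
        for vid in range(n_v):
            speed = float(speed_rng.uniform(*st.speed_range))
            v = _SimVehicle(
                vid, n_v, cfg, self.plan, speed, np.random.default_rng(streams[vid])
            )
            v.grid = GridState(cfg, n_channels=1)
            v.results = None
            vehicles.append(v)

        log = MissionResult(self.field, cfg, self.hp, st)
        hub = OperatorHub(n_c=1)
        log._hub = hub  # single hub instance shared by all exchange paths

        t = 0.0
        n_ticks = int(np.ceil(st.duration / st.tick))
        for _ in range(n_ticks):
            t_next = t + st.tick
            for v in vehicles:
                self._advance(v, t_next, log)
            t = t_next
            for v in vehicles:
                # exchanges are checked once per tick so surfacing cadence is
                # regular regardless of waypoint spacing
                if v.phase == "adaptive" and t - v.last_exchange >= st.exchange_period:
                    self._ingest(v, t)
                    self._exchange(v, hub, t, log)
                    self._replan(v, t, log)

        # terminal bookkeeping: ingest remaining data and snapshot every model
        for v in vehicles:
            self._ingest(v, t)
            self._snapshot(v, t, log)
        log._finalise()
        return log

    # -- vehicle sub-steps --------------------------------------------------
    def _advance(self, v: _SimVehicle, t: float, log: "MissionResult") -> None:
        st = self.settings
        if v.targets:
            target = v.targets[0].as_array()
            delta = target - v.pos
            dist = float(np.linalg.norm(delta))
            step = v.speed * st.tick
            if dist <= step:
                v.pos = target.copy()
                arrived = True
            else:
                v.pos = v.pos + delta * (step / dist)
                arrived = False
        else:
            arrived = True

        log._positions.append(
            (t, v.id, v.pos[0], v.pos[1], v.pos[2], v.phase)
        )
        if v.pos[2] > 0:  # sampling only while submerged
            reading = sense(v.pos, self.field, self.hp.sigma_n, v.rng)
            v.buffer.append(
                Measurement(LocalPosition(*v.pos), t, (reading,))
            )
            log._measurements.append((t, v.id, v.pos[0], v.pos[1], v.pos[2], reading))

        if arrived:
            self._on_arrival(v, t, log)

    def _on_arrival(self, v: _SimVehicle, t: float, log: "MissionResult") -> None:
        self._ingest(v, t)
        if v.phase == "pilot":
            if v.targets:
                v.targets.pop(0)
            if not v.targets:
                # pilot complete: first exchange, then go adaptive
                v.phase = "adaptive"
                self._exchange(v, log._hub, t, log)
                self._replan(v, t, log)
        else:
            self._replan(v, t, log)

    def _ingest(self, v: _SimVehicle, t: float) -> None:
        """Segment buffered measurements, queue the refreshed cell records,
        and refit the on-board model."""
        if v.buffer:
            before_times = v.grid.times.copy()
            v.grid = segment(v.buffer, v.grid)
            v.buffer = []
            changed = np.flatnonzero(
                ~np.isclose(v.grid.times, before_times, equal_nan=True)
            )
            new_records = [
                self.quant.make_record(
                    int(c), v.grid.values[c], float(v.grid.times[c])
                )
                for c in changed
            ]
            # newest first; a re-observed cell replaces its queued record
            changed_set = set(int(c) for c in changed)
            v.send_queue = sorted(
                new_records, key=lambda r: -r.time_code
            ) + [r for r in v.send_queue if r.cell_no not in changed_set]
        v.results = LogGPModel.from_grid(v.grid, self.hp).fit() if v.grid.n_occupied else None

    def _exchange(self, v: _SimVehicle, hub: OperatorHub, t: float, log) -> None:
        lat, lon = local_to_latlon(LocalPosition(v.pos[0], v.pos[1], 0.0), self.cfg)
        header = MessageHeader(MSG_VEHICLE_REPORT, v.id, lat, lon)
        msg = encode_message(header, v.send_queue, n_c=1)
        n_sent = (len(msg) - 10) // 4
        v.send_queue = v.send_queue[n_sent:]
        positions, reply = hub.exchange(msg, now=t)
        log._messages.append((t, v.id, "up", msg))
        log._messages.append((t, v.id, "down", reply))

        from .comms import decode_message

        _, records = decode_message(reply, n_c=1)
        merged = 0
        for rec in records:
            vals, rt = self.quant.record_values(rec)
            old_t = v.grid.times[rec.cell_no]
            if np.isnan(old_t) or rt > old_t:
                v.grid.set_cell(rec.cell_no, vals, rt)
                merged += 1
        for other, (plat, plon, ptime) in positions.items():
            p = latlon_to_local(plat, plon, self.cfg)
            v.fleet.update(other, p, ptime)
        v.last_exchange = t
        if merged:
            v.results = LogGPModel.from_grid(v.grid, self.hp).fit()
        self._snapshot(v, t, log)

    def _replan(self, v: _SimVehicle, t: float, log) -> None:
        if v.results is None:
            # no data yet: hold position (cannot happen after the pilot)
            return
        wp, score = choose_waypoint(
            LocalPosition(*v.pos), v.results, t, v.fleet, self.plan, self.cfg
        )
        v.targets = [wp]
        log._waypoints.append((t, v.id, wp.x, wp.y, wp.z, score))

    def _snapshot(self, v: _SimVehicle, t: float, log) -> None:
        centers = all_cell_centers(self.cfg)
        if v.results is None:
            f = np.zeros(len(centers))
            y = np.ones(len(centers))
            n = 0
        else:
            pred = v.results.predict(centers, t)
            f, y, n = pred.f_star_mean, pred.y_hat, v.results.model.n_train
        log.snapshots.append(ModelSnapshot(t, v.id, f, y, n))


class MissionResult:
    """Logs, model snapshots and RMSE diagnostics of one simulated mission."""

    def __init__(self, field: TruthField, cfg: VolumeConfig, hp, settings):
        self.field = field
        self.cfg = cfg
        self.hyperparams = hp
        self.settings = settings
        self._positions: list[tuple] = []
        self._measurements: list[tuple] = []
        self._waypoints: list[tuple] = []
        self._messages: list[tuple] = []
        self.snapshots: list[ModelSnapshot] = []
        self._hub = OperatorHub(n_c=1)

    def _finalise(self) -> None:
        self.positions = pd.DataFrame(
            self._positions, columns=["time", "vehicle", "x", "y", "z", "phase"]
        )
        self.measurements = pd.DataFrame(
            self._measurements, columns=["time", "vehicle", "x", "y", "z", "value"]
        )
        self.waypoints = pd.DataFrame(
            self._waypoints, columns=["time", "vehicle", "x", "y", "z", "score"]
        )
        self.messages = pd.DataFrame(
            [
                (t, vid, direction, len(raw), raw.hex())
                for t, vid, direction, raw in self._messages
            ],
            columns=["time", "vehicle", "direction", "n_bytes", "hex"],
        )

    # -- diagnostics ---------------------------------------------------------
    def rmse_curve(self, scale: str = "log") -> pd.DataFrame:
        """Per-vehicle and fleet-mean RMSE vs truth at each model snapshot.

        ``scale="log"`` compares the log-space posterior mean with
        ln(truth) — the scale on which the nugget sd is defined and on which
        the convergence floor is meaningful; ``scale="linear"`` compares
        y_hat with truth in ug/L.
        """
        truth = self.field.cell_truth()
        rows = []
        for s in self.snapshots:
            if scale == "log":
                err = s.f_star_mean - np.log(truth)
            elif scale == "linear":
                err = s.y_hat - truth
            else:
                raise ValueError("scale must be 'log' or 'linear'")
            rows.append((s.time, s.vehicle, float(np.sqrt(np.mean(err**2)))))
        df = pd.DataFrame(rows, columns=["time", "vehicle", "rmse"])
        wide = df.pivot_table(index="time", columns="vehicle", values="rmse")
        wide["fleet"] = wide.mean(axis=1)
        return wide

    def terminal_rmse(self, scale: str = "log") -> float:
        """Fleet-mean RMSE at each vehicle's final snapshot."""
        curve = self.rmse_curve(scale)
        per_vehicle = [
            curve[c].dropna().iloc[-1] for c in curve.columns if c != "fleet"
        ]
        return float(np.mean(per_vehicle))

    def summary(self) -> str:
        st = self.settings
        lines = [
            "Adaptive-sampling mission",
            "=" * 40,
            f"vehicles               {st.n_vehicles}",
            f"duration [s]           {st.duration:g}",
            f"tick / exchange [s]    {st.tick:g} / {st.exchange_period:g}",
            f"grid cells             {self.cfg.n_cells}",
            f"measurements           {len(self.measurements)}",
            f"messages               {len(self.messages)}"
            f" (max {self.messages['n_bytes'].max() if len(self.messages) else 0} B)",
            f"terminal RMSE (log)    {self.terminal_rmse('log'):.4f}",
            f"terminal RMSE (ug/L)   {self.terminal_rmse('linear'):.4f}",
        ]
        return "\n".join(lines)

    def plot_rmse(self, path, scale: str = "log") -> None:
        """Write the per-vehicle and fleet RMSE convergence curves to a file."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        curve = self.rmse_curve(scale)
        fig, ax = plt.subplots(figsize=(7, 4))
        for col in curve.columns:
            series = curve[col].dropna()
            style = dict(lw=2.5, color="k") if col == "fleet" else dict(alpha=0.6)
            ax.plot(series.index, series.values, label=str(col), **style)
        ax.set_xlabel("mission time [s]")
        unit = "log units" if scale == "log" else "ug/L"
        ax.set_ylabel(f"RMSE vs truth [{unit}]")
        ax.legend(title="vehicle", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def to_csv(self, outdir) -> None:
        """Write positions/measurements/waypoints/messages CSVs to a directory."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.positions.to_csv(os.path.join(outdir, "positions.csv"), index=False)
        self.measurements.to_csv(os.path.join(outdir, "measurements.csv"), index=False)
        self.waypoints.to_csv(os.path.join(outdir, "waypoints.csv"), index=False)
        self.messages.to_csv(os.path.join(outdir, "messages.csv"), index=False)
        self.rmse_curve("log").to_csv(os.path.join(outdir, "rmse_log.csv"))
        self.rmse_curve("linear").to_csv(os.path.join(outdir, "rmse_linear.csv"))


def run_mission(
    n_vehicles: int,
    field: TruthField,
    hyperparams: LGPHyperparams | None = None,
    planner: PlannerConfig | None = None,
    settings: SimSettings | None = None,
    duration: float | None = None,
    seed: int = 0,
) -> MissionResult:
    """Convenience wrapper: build a :class:`MissionSimulator` and run it."""
    st = settings or SimSettings()
    st = SimSettings(
        n_vehicles=n_vehicles,
        duration=duration if duration is not None else st.duration,
        tick=st.tick,
        exchange_period=st.exchange_period,
        speed_range=st.speed_range,
    )
    sim = MissionSimulator(field, hyperparams, planner, settings=st)
    return sim.run(seed=seed)
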