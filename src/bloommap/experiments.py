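"""Reproducible convergence experiments on the scaled-down mission setup.

The canonical experiment: generate a static patchy log-normal bloom on the
reduced volume (1000 x 1000 x 50 m, 10 x 10 x 5 grid), run an N-vehicle
adaptive mission (pilot -> exchange -> adaptive cycles) at nugget sd 0.7,
and score the fleet's terminal on-board-model RMSE against the truth at all
grid-cell centres, on the log scale where the nugget floor lives. Replicated
over independently seeded fields and missions; the median is the headline
number used to study fleet-size benefit.
"""

from __future__ import annotations

import numpy as np

from .config import MissionConfig, default_config_dict
from .simulate import MissionSimulator, SimSettings, make_truth_field


def _replicate_seeds(seed: int, i: int) -> tuple[int, int]:
    """Independent (field, mission) seeds < 2^31 for replicate ``i``."""
    state = np.random.SeedSequence([seed, i]).generate_state(2) % (2**31)
    return int(state[0]), int(state[1])


def convergence_experiment(
    n_vehicles: int,
    n_seeds: int = 10,
    seed: int = 0,
    config: MissionConfig | None = None,
    scale: str = "log",
) -> dict:
    """Terminal fleet RMSE of the scaled-down mission, replicated over seeds.

    Returns a dict with the per-replicate values, their median, and the
    problem size (number of grid cells scored).
    """
    cfg = config or MissionConfig.from_dict(default_config_dict())
    st = SimSettings(
        n_vehicles=n_vehicles,
        duration=cfg.sim.duration,
        tick=cfg.sim.tick,
        exchange_period=cfg.sim.exchange_period,
        speed_range=cfg.sim.speed_range,
    )
    values = []
    for i in range(n_seeds):
        field_seed, mission_seed = _replicate_seeds(seed, i)
        field = make_truth_field(cfg.volume, cfg.field, seed=field_seed)
        sim = MissionSimulator(field, cfg.hyperparams, cfg.planner, cfg.quant, st)
        result = sim.run(seed=mission_seed)
        values.append(result.terminal_rmse(scale))
    return {
        "n_vehicles": n_vehicles,
        "values": values,
        "median": float(np.median(values)),
        "n_cells": cfg.volume.n_cells,
        "n_seeds": n_seeds,
    }


def fleet_size_sweep(
    fleet_sizes=(1, 2, 3, 4), n_seeds: int = 10, seed: int = 0
) -> dict[int, dict]:
    """The fleet-benefit experiment: one convergence run per fleet size."""
    return {
        n: convergence_experiment(n, n_seeds=n_seeds, seed=seed)
        for n in fleet_sizes
    }
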