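"""Mission configuration: schema, defaults, loading and validation.

One flat-sectioned YAML (or JSON) file configures every component, with the
operator-input symbols kept under their conventional names::

    volume:    V_lat, V_lon, V_theta, V_x, V_y, V_z, n_x, n_y, n_z
    model:     M_x, M_y, M_z, M_tau, sigma_c, sigma_n,
               sigma_values_are (std | variance), value_floor
    planner:   n_theta, r, z_d, k_mu, k_sigma, k_l, undulation
    comms:     channel_min, channel_max, time_step
    simulator: n_vehicles, duration, tick, exchange_period, speed_min,
               speed_max, field {log_mean, log_sd, corr_xy, corr_z,
               n_patches, patch_scale, patch_amp, profile_depth,
               profile_width}
    seed:      one top-level seed; module substreams are spawned from it
    csv_columns: column mapping for external measurement logs (optional)

Defaults mirror the field-trial operator inputs; the simulator section
defaults to the reduced workstation-scale experiment (1000x1000x50 m volume,
10x10x5 grid) used throughout the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .comms import QuantizationScheme
from .geometry import VolumeConfig
from .lgp import DEFAULT_VALUE_FLOOR, LGPHyperparams
from .planner import PlannerConfig
from .simulate import FieldParams, SimSettings


#: Field-trial operator inputs (full-scale volume and model settings).
FIELD_TRIAL_DEFAULTS: dict = {
    "volume": {
        "V_lat": 78.9548,  # 78N 57.29
        "V_lon": 11.9475,  # 11E 56.85
        "V_theta": -45.0,
        "V_x": 1500.0,
        "V_y": 1500.0,
        "V_z": 50.0,
        "n_x": 15,
        "n_y": 15,
        "n_z": 10,
    },
    "model": {
        "M_x": 600.0,
        "M_y": 600.0,
        "M_z": 3.0,
        "M_tau": 10_000.0,
        "sigma_c": 1.6,
        "sigma_n": 0.7,
        "sigma_values_are": "std",
        "value_floor": DEFAULT_VALUE_FLOOR,
    },
    "planner": {
        "n_theta": 8,
        "r": None,  # None -> one horizontal grid-cell extent
        "z_d": None,  # None -> one vertical grid-cell extent
        "k_mu": 1.0,
        "k_sigma": 1.0,
        "k_l": 300.0,
        "undulation": [None, None, None],
    },
    "comms": {
        "channel_min": 0.01,
        "channel_max": 100.0,
        "time_step": 60.0,
    },
    "simulator": {
        "n_vehicles": 4,
        "duration": 2400.0,
        "tick": 10.0,
        "exchange_period": 600.0,
        "speed_min": 1.0,
        "speed_max": 1.5,
        "field": {
            "log_mean": 0.6931,
            "log_sd": 1.6,
            "corr_xy": 300.0,
            "corr_z": 15.0,
            "n_patches": 2,
            "patch_scale": 250.0,
            "patch_amp": 1.5,
            "profile_depth": 30.0,
            "profile_width": 15.0,
        },
    },
    "seed": 0,
}

#: Reduced workstation-scale experiment: volume and grid shrink, and the
#: de-correlation lengths scale with them (horizontal with the volume extent,
#: vertical with the cell height) — operator guidance ties the lengths to the
#: grid cell size and the operational-area size.
SIM_VOLUME = {"V_x": 1000.0, "V_y": 1000.0, "V_z": 50.0, "n_x": 10, "n_y": 10, "n_z": 5}
SIM_MODEL = {"M_x": 400.0, "M_y": 400.0, "M_z": 6.0}

REQUIRED_KEYS = {
    "volume": ["V_lat", "V_lon", "V_theta", "V_x", "V_y", "V_z", "n_x", "n_y", "n_z"],
    "model": ["M_x", "M_y", "M_z", "M_tau", "sigma_c", "sigma_n"],
    "planner": ["n_theta", "k_mu", "k_sigma", "k_l"],
}


class ConfigError(ValueError):
    """Raised on invalid or incomplete mission configuration."""


@dataclass
class MissionConfig:
    """Validated mission configuration bundling every component's settings."""

    volume: VolumeConfig
    hyperparams: LGPHyperparams
    planner: PlannerConfig
    quant: QuantizationScheme
    sim: SimSettings
    field: FieldParams
    seed: int = 0
    csv_columns: dict | None = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "MissionConfig":
        for section, keys in REQUIRED_KEYS.items():
            if section not in d:
                raise ConfigError(f"missing config section '{section}'")
            for k in keys:
                if k not in d[section]:
                    raise ConfigError(f"missing config key '{section}.{k}'")
        vol = d["volume"]
        mod = d["model"]
        pln = d["planner"]
        com = d.get("comms", FIELD_TRIAL_DEFAULTS["comms"])
        sim = d.get("simulator", FIELD_TRIAL_DEFAULTS["simulator"])
        fld = sim.get("field", FIELD_TRIAL_DEFAULTS["simulator"]["field"])

        try:
            volume = VolumeConfig(
                origin_lat=float(vol["V_lat"]),
                origin_lon=float(vol["V_lon"]),
                orientation_theta=float(vol["V_theta"]),
                extent=(float(vol["V_x"]), float(vol["V_y"]), float(vol["V_z"])),
                grid_dims=(int(vol["n_x"]), int(vol["n_y"]), int(vol["n_z"])),
            )
        except ValueError as e:
            raise ConfigError(f"invalid volume section: {e}") from e

        sigma_c, sigma_n = float(mod["sigma_c"]), float(mod["sigma_n"])
        reading = mod.get("sigma_values_are", "std")
        if reading == "variance":
            sigma_c, sigma_n = sigma_c**0.5, sigma_n**0.5
        elif reading != "std":
            raise ConfigError("model.sigma_values_are must be 'std' or 'variance'")
        try:
            hyper = LGPHyperparams(
                M=(float(mod["M_x"]), float(mod["M_y"]), float(mod["M_z"]),
                   float(mod["M_tau"])),
                sigma_c=sigma_c,
                sigma_n=sigma_n,
            )
        except ValueError as e:
            raise ConfigError(f"invalid model section: {e}") from e

        und = pln.get("undulation", [None, None, None])
        try:
            planner = PlannerConfig(
                n_theta=int(pln["n_theta"]),
                radius=None if pln.get("r") is None else float(pln["r"]),
                z_step=None if pln.get("z_d") is None else float(pln["z_d"]),
                k_mu=float(pln["k_mu"]),
                k_sigma=float(pln["k_sigma"]),
                k_l=float(pln["k_l"]),
                undulation=tuple(None if u is None else float(u) for u in und),
            )
        except ValueError as e:
            raise ConfigError(f"invalid planner section: {e}") from e

        quant = QuantizationScheme(
            channel_ranges=((float(com["channel_min"]), float(com["channel_max"])),),
            time_step=float(com.get("time_step", 60.0)),
        )
        settings = SimSettings(
            n_vehicles=int(sim.get("n_vehicles", 4)),
            duration=float(sim.get("duration", 4000.0)),
            tick=float(sim.get("tick", 10.0)),
            exchange_period=float(sim.get("exchange_period", 600.0)),
            speed_range=(float(sim.get("speed_min", 1.0)),
                         float(sim.get("speed_max", 1.5))),
        )
        fp = FieldParams(
            log_mean=float(fld.get("log_mean", 0.6931)),
            log_sd=float(fld.get("log_sd", 1.6)),
            corr_xy=float(fld.get("corr_xy", 300.0)),
            corr_z=float(fld.get("corr_z", 15.0)),
            n_patches=int(fld.get("n_patches", 2)),
            patch_scale=float(fld.get("patch_scale", 250.0)),
            patch_amp=float(fld.get("patch_amp", 1.5)),
            profile_depth=float(fld.get("profile_depth", 30.0)),
            profile_width=float(fld.get("profile_width", 15.0)),
        )
        return cls(
            volume=volume,
            hyperparams=hyper,
            planner=planner,
            quant=quant,
            sim=settings,
            field=fp,
            seed=int(d.get("seed", 0)),
            csv_columns=d.get("csv_columns"),
            raw=d,
        )


def default_config_dict(simulation_scale: bool = True) -> dict:
    """Full default config; ``simulation_scale`` applies the reduced volume."""
    d = json.loads(json.dumps(FIELD_TRIAL_DEFAULTS))  # deep copy
    if simulation_scale:
        d["volume"].update(SIM_VOLUME)
        d["model"].update(SIM_MODEL)
    return d


def load_config(path) -> MissionConfig:
    """Load and validate a YAML/JSON mission config file."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    return MissionConfig.from_dict(d)


def write_config(d: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
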