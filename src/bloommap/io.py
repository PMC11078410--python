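"""CSV measurement-log loading with user-supplied column mapping.

Field measurement logs come as CSV rows of (timestamp, latitude, longitude,
depth, fluorescence, optional extra channels). Schemas vary between vehicles
and payloads, so the column mapping is always supplied by the user (in the
mission config under ``csv_columns``), e.g.::

    csv_columns:
      time: timestamp
      lat: latitude
      lon: longitude
      depth: depth_m
      channels: [chlorophyll]

Logs already expressed in the local volume frame may map ``x``/``y``
instead of ``lat``/``lon``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import LocalPosition, Measurement, VolumeConfig, latlon_to_local


def load_measurements_csv(
    path,
    cfg: VolumeConfig,
    columns: dict,
) -> list[Measurement]:
    """Load a measurement log into local-frame :class:`Measurement` objects.

    ``columns`` must name ``time``, either (``lat``, ``lon``) or (``x``,
    ``y``), ``depth`` (optional; 0 if absent) and a list ``channels`` of at
    least one channel column (channel 0 = fluorescence). Times may be
    numeric seconds or parseable datetimes (converted to seconds from the
    earliest row).
    """
    df = pd.read_csv(path)
    required = ["time", "channels"]
    for key in required:
        if key not in columns:
            raise ValueError(f"column mapping is missing required key '{key}'")
    geodetic = "lat" in columns and "lon" in columns
    if not geodetic and not ("x" in columns and "y" in columns):
        raise ValueError("column mapping needs either lat/lon or x/y")

    chan_cols = list(columns["channels"])
    needed = [columns["time"]] + chan_cols
    needed += [columns["lat"], columns["lon"]] if geodetic else [columns["x"], columns["y"]]
    if columns.get("depth"):
        needed.append(columns["depth"])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing columns: {missing}")

    t_raw = df[columns["time"]]
    if np.issubdtype(t_raw.dtype, np.number):
        times = t_raw.to_numpy(dtype=float)
    else:
        ts = pd.to_datetime(t_raw)
        times = (ts - ts.min()).dt.total_seconds().to_numpy()

    depth = (
        df[columns["depth"]].to_numpy(dtype=float)
        if columns.get("depth")
        else np.zeros(len(df))
    )

    out = []
    for i in range(len(df)):
        if geodetic:
            pos = latlon_to_local(
                float(df[columns["lat"]].iloc[i]),
                float(df[columns["lon"]].iloc[i]),
                cfg,
                depth=float(depth[i]),
            )
        else:
            pos = LocalPosition(
                float(df[columns["x"]].iloc[i]),
                float(df[columns["y"]].iloc[i]),
                float(depth[i]),
            )
        channels = tuple(float(df[c].iloc[i]) for c in chan_cols)
        out.append(Measurement(pos, float(times[i]), channels))
    return out


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Tidy frame (time, x, y, z, value, channel columns) from Measurements."""
    rows = []
    for m in measurements:
        row = {"time": m.time, "x": m.position.x, "y": m.position.y, "z": m.position.z}
        for i, c in enumerate(m.channels):
            row[f"channel_{i}"] = c
        rows.append(row)
    df = pd.DataFrame(rows)
    if "channel_0" in df:
        df["value"] = df["channel_0"]
    return df
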