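"""Readers and writers: multi-page TIFF stacks with JSON sidecars, tidy CSV.

An image stack is stored as an 8-bit multi-page TIFF plus a JSON sidecar
``<stem>.json`` holding ``pixel_size_um``, ``frame_times_min`` and
(optionally) the generative parameters.  All tabular outputs are tidy CSV
with unit-suffixed column names.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .colony_sim import ImageStack, SimulationResult, states_to_names
from .params import ColonyParams

__all__ = ["read_stack", "write_stack", "write_agents_csv", "read_agents_csv",
           "write_profiles_csv", "read_profiles_csv"]

log = logging.getLogger("coronakit")

DEFAULT_PIXEL_SIZE = 2.0  # μm/px fallback when the sidecar is missing


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path, params: Optional[ColonyParams] = None) -> None:
    """Write a stack as multi-page TIFF + JSON sidecar (lossless round trip)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.uint8), photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_times_min": [float(t) for t in stack.frame_times],
    }
    if params is not None:
        meta["params"] = params.to_dict()
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF + sidecar back into an :class:`ImageStack`.

    A missing sidecar falls back to pixel_size 2.0 μm/px and 1-min frame
    times, with a logged warning.  Non-monotonic frame times or pages of
    differing shape are format errors.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D multi-page TIFF stack")
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        pixel_size = float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE))
        frame_times = np.asarray(meta.get("frame_times_min",
                                          np.arange(frames.shape[0], dtype=float)))
    else:
        msg = f"{side} missing; assuming pixel_size {DEFAULT_PIXEL_SIZE} μm/px, 1-min frames"
        log.warning(msg)
        warnings.warn(msg)
        pixel_size = DEFAULT_PIXEL_SIZE
        frame_times = np.arange(frames.shape[0], dtype=float)
    if len(frame_times) != frames.shape[0]:
        raise ValueError(f"{path}: sidecar lists {len(frame_times)} frame times "
                         f"for {frames.shape[0]} pages")
    if len(frame_times) > 1 and np.any(np.diff(frame_times) <= 0):
        raise ValueError(f"{path}: frame_times must be strictly increasing")
    return ImageStack(frames=frames, pixel_size=pixel_size, frame_times=frame_times)


def write_agents_csv(sim: SimulationResult, path) -> None:
    """Ground-truth trajectories as tidy CSV (id, t_min, x_um, y_um, state)."""
    df = sim.agents.copy()
    df["state"] = states_to_names(df["state"])
    df.to_csv(path, index=False)


def read_agents_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_profiles_csv(profiles, path) -> None:
    """Radial-profile series as tidy CSV (time_min, bin_center_um, value_pct)."""
    rows = []
    for p in profiles:
        rows.append(pd.DataFrame({
            "time_min": p.time,
            "bin_center_um": p.bin_centers,
            "value_pct": p.relative_density,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path, center=(0.0, 0.0)):
    """Rebuild a list of :class:`RadialProfile` from tidy CSV."""
    from .density_field import RadialProfile

    df = pd.read_csv(path)
    profiles = []
    for t, g in df.groupby("time_min", sort=True):
        bc = g["bin_center_um"].to_numpy()
        bw = float(np.median(np.diff(bc))) if len(bc) > 1 else 30.0
        profiles.append(RadialProfile(center=tuple(center), bin_centers=bc,
                                      relative_density=g["value_pct"].to_numpy(),
                                      time=float(t), bin_width=bw))
    return profiles
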