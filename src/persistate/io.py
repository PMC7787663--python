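"""File interfaces: HDF5 for trajectories, features and traces; CSV for
synapse tables; YAML echoes of configurations.

Column schemas follow the module conventions: track tables carry
(frame, fly_id, x_mm, y_mm, heading_x, heading_y, flag), feature tables
the 17 canonical parameter columns, synapse tables the detection-level
columns of :data:`persistate.synthio.SYNAPSE_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import List

import h5py
import numpy as np
import pandas as pd
import yaml

from .calcium import RoiTrace
from .kinematics import Trajectory


def save_trajectory(path, traj: Trajectory) -> None:
    with h5py.File(path, "w") as f:
        for name in ("f_pos", "m_pos", "f_head", "m_head"):
            f.create_dataset(name, data=getattr(traj, name))
        f.create_dataset("flags", data=traj.flags)
        f.attrs["fps"] = traj.fps
        f.attrs["condition"] = traj.condition
        f.attrs["copulation_frame"] = (-1 if traj.copulation_frame is None
                                       else traj.copulation_frame)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        cop = int(f.attrs["copulation_frame"])
        return Trajectory(
            f_pos=f["f_pos"][:], m_pos=f["m_pos"][:],
            f_head=f["f_head"][:], m_head=f["m_head"][:],
            flags=f["flags"][:], fps=float(f.attrs["fps"]),
            condition=str(f.attrs["condition"]),
            copulation_frame=None if cop < 0 else cop)


def save_feature_table(path, features: pd.DataFrame) -> None:
    features.to_hdf(path, key="features", mode="w")


def load_feature_table(path) -> pd.DataFrame:
    return pd.read_hdf(path, key="features")


def save_traces(path, traces: List[RoiTrace]) -> None:
    with h5py.File(path, "w") as f:
        for tr in traces:
            g = f.create_group(f"roi_{tr.fly_id}_{tr.roi_id}")
            g.create_dataset("f_green", data=tr.f_green)
            g.create_dataset("f_red", data=tr.f_red)
            g.create_dataset("timebase", data=tr.timebase)
            if tr.footprint is not None:
                g.create_dataset("footprint", data=np.asarray(tr.footprint))
            g.attrs["stim_on"] = tr.stim_on
            g.attrs["stim_off"] = tr.stim_off
            g.attrs["fly_id"] = tr.fly_id
            g.attrs["roi_id"] = tr.roi_id


def load_traces(path) -> List[RoiTrace]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f):
            g = f[key]
            out.append(RoiTrace(
                f_green=g["f_green"][:], f_red=g["f_red"][:],
                timebase=g["timebase"][:],
                stim_on=float(g.attrs["stim_on"]),
                stim_off=float(g.attrs["stim_off"]),
                fly_id=int(g.attrs["fly_id"]),
                roi_id=int(g.attrs["roi_id"]),
                footprint=g["footprint"][:] if "footprint" in g else None))
    return sorted(out, key=lambda t: (t.fly_id, t.roi_id))


def save_synapse_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_synapse_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def echo_config(path, cfg) -> None:
    """Write a dataclass configuration as YAML next to its outputs."""
    if not is_dataclass(cfg):
        raise TypeError("expected a dataclass configuration")
    payload = {}
    for k, v in asdict(cfg).items():
        if isinstance(v, np.ndarray):
            payload[k] = v.tolist()
        elif isinstance(v, tuple):
            payload[k] = list(v)
        elif is_dataclass(v):
            payload[k] = asdict(v)
        elif isinstance(v, list) and v and is_dataclass(v[0]):
            payload[k] = [asdict(s) for s in v]
        else:
            payload[k] = v
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_config_echo(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
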