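"""Per-frame kinematic featurization of two-fly trajectories.

Seventeen parameters summarize each video frame: five egocentric motion
parameters per fly (forward velocity, lateral speed, forward/lateral
acceleration, rotational speed), and seven interaction parameters
(male-female distance, each fly's heading angle relative to the axis
joining the two flies, and each fly's velocity decomposed along/orthogonal
to that axis).  These are the substrate for frame-level classification and
clustering of courtship/aggression behavior.

Conventions
-----------
* Positions in mm, time in seconds, angles in degrees.
* Velocities by central differences, ``v_i = (p_{i+1} - p_{i-1}) * fps / 2``;
  endpoints use one-sided differences and are flagged.
* "Velocity" features (fFV, mFV, fmFV, mfFV) are signed projections;
  "speed" features (fLS, mLS, fmLS, mfLS, fRS, mRS) are magnitudes.
* fmAngle/mfAngle are unsigned angles in [0, 180] degrees: the number of
  degrees the fly would need to turn to point at its partner's centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical column order of the 17 per-frame parameters.
FEATURE_NAMES = [
    "fFV", "fLS", "fFA", "fLA", "fRS",
    "mFV", "mLS", "mFA", "mLA", "mRS",
    "mfDist", "fmAngle", "mfAngle",
    "fmFV", "fmLS", "mfFV", "mfLS",
]


@dataclass
class Trajectory:
    """Two-fly pose time series.

    Attributes
    ----------
    f_pos, m_pos : (n, 2) float arrays
        Female / male centroid positions in mm.
    f_head, m_head : (n, 2) float arrays
        Unit heading vectors.
    fps : float
        Frames per second (60 in the experiments this models).
    condition : str
        Session label, e.g. ``control``/``d0``/``d3``/``d6``.
    copulation_frame : int or None
        Frame at which copulation occurred; behavior is not scored after it.
    flags : (n,) bool array
        True on frames where tracking was unreliable (NaNs allowed there).
    """

    f_pos: np.ndarray
    m_pos: np.ndarray
    f_head: np.ndarray
    m_head: np.ndarray
    fps: float = 60.0
    condition: str = "control"
    copulation_frame: Optional[int] = None
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.f_pos = np.asarray(self.f_pos, dtype=float)
        self.m_pos = np.asarray(self.m_pos, dtype=float)
        self.f_head = np.asarray(self.f_head, dtype=float)
        self.m_head = np.asarray(self.m_head, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        n = len(self.f_pos)
        if not (len(self.m_pos) == len(self.f_head) == len(self.m_head) == n):
            raise ValueError("all track arrays must have equal length")
        if self.flags is None:
            self.flags = np.zeros(n, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
        for h in (self.f_head, self.m_head):
            norms = np.linalg.norm(h, axis=1)
            ok = ~np.isnan(norms)
            if np.any(np.abs(norms[ok] - 1.0) > 1e-6):
                raise ValueError("heading vectors must be unit length (tol 1e-6)")

    def __len__(self) -> int:
        return len(self.f_pos)

    def swapped(self) -> "Trajectory":
        """Return a copy with male and female labels exchanged."""
        return Trajectory(
            f_pos=self.m_pos.copy(), m_pos=self.f_pos.copy(),
            f_head=self.m_head.copy(), m_head=self.f_head.copy(),
            fps=self.fps, condition=self.condition,
            copulation_frame=self.copulation_frame, flags=self.flags.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Track table: frame, fly_id, x_mm, y_mm, heading_x, heading_y, flags."""
        n = len(self)
        rows = []
        for fly, pos, head in (("female", self.f_pos, self.f_head),
                               ("male", self.m_pos, self.m_head)):
            rows.append(pd.DataFrame({
                "frame": np.arange(n), "fly_id": fly,
                "x_mm": pos[:, 0], "y_mm": pos[:, 1],
                "heading_x": head[:, 0], "heading_y": head[:, 1],
                "flag": self.flags,
            }))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fps: float = 60.0, **kw) -> "Trajectory":
        """Rebuild a Trajectory from the track-table layout of :meth:`to_frame`."""
        parts = {}
        for fly in ("female", "male"):
            sub = df[df["fly_id"] == fly].sort_values("frame")
            parts[fly] = sub
        f, m = parts["female"], parts["male"]
        return cls(
            f_pos=f[["x_mm", "y_mm"]].to_numpy(),
            m_pos=m[["x_mm", "y_mm"]].to_numpy(),
            f_head=f[["heading_x", "heading_y"]].to_numpy(),
            m_head=m[["heading_x", "heading_y"]].to_numpy(),
            fps=fps, flags=f["flag"].to_numpy(dtype=bool), **kw,
        )


def _central_diff(x: np.ndarray, fps: float) -> np.ndarray:
    """Central differences along axis 0; one-sided at the endpoints."""
    x = np.asarray(x, dtype=float)
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) * (fps / 2.0)
    d[0] = (x[1] - x[0]) * fps
    d[-1] = (x[-1] - x[-2]) * fps
    return d


def _perp(v: np.ndarray) -> np.ndarray:
    """Rotate 2-vectors by +90 degrees."""
    return np.stack([-v[..., 1], v[..., 0]], axis=-1)


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle between row vectors, degrees in [0, 180]."""
    dot = np.einsum("ij,ij->i", u, v)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = dot / (nu * nv)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def compute_frame_features(traj: Trajectory) -> pd.DataFrame:
    """Compute the 17 per-frame parameters for a two-fly trajectory.

    Returns a DataFrame with the columns of :data:`FEATURE_NAMES` plus an
    ``edge_flag`` boolean column marking frames where one-sided differences
    were used (the first and last frame).

    Frames where the two flies coincide (``mfDist == 0``) get NaN interaction
    angles/projections; NaN positions propagate NaN features.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames for central differences")
    fps = traj.fps
    out = {}

    for prefix, pos, head in (("f", traj.f_pos, traj.f_head),
                              ("m", traj.m_pos, traj.m_head)):
        v = _central_diff(pos, fps)                      # mm/s
        fwd = np.einsum("ij,ij->i", v, head)             # signed forward component
        lat_signed = np.einsum("ij,ij->i", v, _perp(head))
        out[f"{prefix}FV"] = fwd
        out[f"{prefix}LS"] = np.abs(lat_signed)
        out[f"{prefix}FA"] = _central_diff(fwd, fps)
        out[f"{prefix}LA"] = np.abs(_central_diff(lat_signed, fps))
        theta = np.unwrap(np.arctan2(head[:, 1], head[:, 0]))
        out[f"{prefix}RS"] = np.abs(np.degrees(_central_diff(theta, fps)))

    sep = traj.m_pos - traj.f_pos                        # female -> male
    dist = np.linalg.norm(sep, axis=1)
    out["mfDist"] = dist
    with np.errstate(invalid="ignore", divide="ignore"):
        u = sep / dist[:, None]                          # unit female->male
    zero = dist == 0
    u[zero] = np.nan

    out["fmAngle"] = _angle_between_deg(traj.f_head, sep)
    out["mfAngle"] = _angle_between_deg(traj.m_head, -sep)

    v_f = _central_diff(traj.f_pos, fps)
    v_m = _central_diff(traj.m_pos, fps)
    out["fmFV"] = np.einsum("ij,ij->i", v_f, u)          # + toward male
    out["fmLS"] = np.abs(np.einsum("ij,ij->i", v_f, _perp(u)))
    out["mfFV"] = np.einsum("ij,ij->i", v_m, -u)         # + toward female
    out["mfLS"] = np.abs(np.einsum("ij,ij->i", v_m, _perp(u)))

    df = pd.DataFrame({k: out[k] for k in FEATURE_NAMES})
    edge = np.zeros(len(traj), dtype=bool)
    edge[[0, -1]] = True
    df["edge_flag"] = edge
    return df


def speed_series(traj: Trajectory, fly: str) -> np.ndarray:
    """Absolute centroid speed (mm/s) of ``fly`` in {"female", "male"}."""
    if fly not in ("female", "male"):
        raise ValueError("fly must be 'female' or 'male'")
    pos = traj.f_pos if fly == "female" else traj.m_pos
    v = _central_diff(pos, traj.fps)
    return np.linalg.norm(v, axis=1)
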