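"""Synthetic data generators for every stage of the pipeline.

Each generator is a pure function of (config, seed) and emits ground-truth
labels sufficient to score the downstream analysis it feeds:

* :func:`gen_pair_trajectories` -- state-switching two-fly courtship
  trajectories whose per-state kinematic signatures (target distance,
  heading angles relative to the partner axis, approach velocity) mirror the
  behavioral clusters recovered from real data ("female shoving" = both
  flies facing each other at close range, "female chasing" = female behind
  a retreating male).
* :func:`gen_calcium_traces` -- dual-channel ROI fluorescence with
  transient and persistent (fast/slow-decay) optogenetic responses, shared
  slow drift, and a stimulus-locked red-channel artifact.
* :func:`gen_synapse_table` -- EM synapse detections with duplicate
  detections (< 150 nm apart) and false positives, plus the hand-built
  :func:`qc115_fixture` whose dedup outcome is forced by construction.
* :func:`gen_tracking_video` -- two elliptical flies over a static textured
  background, for the centroid tracker.
* :func:`gen_song_trial` -- male song bout tables and female speed series
  with a controllable window-level correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinematics import Trajectory
from .calcium import RoiTrace

# ---------------------------------------------------------------------------
# Trial design
# ---------------------------------------------------------------------------


@dataclass
class TrialDesign:
    """Timing of an optogenetic-activation behavior session.

    ``delay`` is the interval between activation offset and male
    introduction (0 / 180 / 360 s for the d0 / d3 / d6 conditions).
    """

    activation_duration: float = 300.0
    delay: float = 0.0
    session_length: float = 600.0
    fps: float = 60.0

    def __post_init__(self) -> None:
        if min(self.activation_duration, self.delay, self.session_length) < 0:
            raise ValueError("durations must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def condition(self) -> str:
        return {0.0: "d0", 180.0: "d3", 360.0: "d6"}.get(self.delay, f"d{self.delay:g}s")


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


@dataclass
class StateSignature:
    """Kinematic signature of one behavioral state.

    Angles follow the frame-feature conventions: ``fm_angle_deg`` is the
    unsigned angle between the female heading and the female-to-male axis,
    ``mf_angle_deg`` the male analogue. ``fm_fv`` is the mean female
    velocity toward the male (mm/s), realized by the pair drifting together
    along the separation axis. ``wander_speed`` is undirected roaming speed.
    """

    name: str
    mf_dist: float = 5.0
    fm_angle_deg: float = 90.0
    mf_angle_deg: float = 90.0
    fm_fv: float = 0.0
    wander_speed: float = 0.0

    def __post_init__(self) -> None:
        if self.mf_dist <= 0:
            raise ValueError(f"state {self.name!r}: target distance must be > 0")
        if not (0 <= self.fm_angle_deg <= 180 and 0 <= self.mf_angle_deg <= 180):
            raise ValueError(f"state {self.name!r}: angles must lie in [0, 180] deg")
        if self.wander_speed < 0:
            raise ValueError(f"state {self.name!r}: wander_speed must be >= 0")


def default_states() -> List[StateSignature]:
    """The three canonical states used throughout the test-bed.

    Shoving: flies face each other at close range, female pushes toward the
    male. Chasing: female behind the male, both moving in the male's
    direction. Disengaged: large separation, uncorrelated headings.
    """
    return [
        StateSignature("shoving", mf_dist=2.0, fm_angle_deg=10.0,
                       mf_angle_deg=15.0, fm_fv=4.0, wander_speed=2.0),
        StateSignature("chasing", mf_dist=3.0, fm_angle_deg=10.0,
                       mf_angle_deg=170.0, fm_fv=6.0, wander_speed=2.0),
        StateSignature("disengaged", mf_dist=9.0, fm_angle_deg=90.0,
                       mf_angle_deg=90.0, fm_fv=0.0, wander_speed=3.0),
    ]


def _default_transition_matrix(n: int) -> np.ndarray:
    p = np.full((n, n), 0.05 / max(n - 1, 1))
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(p, 1.0 - p.sum(axis=1))
    return p


@dataclass
class BehaviorSynthConfig:
    """Configuration for the two-fly trajectory generator."""

    seed: int = 0
    states: List[StateSignature] = field(default_factory=default_states)
    #: Row-stochastic state-switching probabilities per second.
    transition_matrix: Optional[np.ndarray] = None
    dwell_min: float = 1.0
    heading_noise_deg: float = 2.0
    dist_noise: float = 0.2       # mm / sqrt(s), OU fluctuation of separation
    bearing_noise: float = 0.5    # rad / sqrt(s), rotation of the pair axis
    arena_diameter: float = 25.0

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("need at least one state")
        n = len(self.states)
        if self.transition_matrix is None:
            self.transition_matrix = _default_transition_matrix(n)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (n, n):
            raise ValueError("transition_matrix shape must match number of states")
        if np.any(self.transition_matrix < 0):
            raise ValueError("transition probabilities must be non-negative")
        if np.any(np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition_matrix rows must sum to 1 (tol 1e-9)")
        if self.dwell_min <= 0:
            raise ValueError("dwell_min must be positive")
        if min(self.heading_noise_deg, self.dist_noise, self.bearing_noise) < 0:
            raise ValueError("noise SDs must be non-negative")
        max_dist = max(s.mf_dist for s in self.states)
        if max_dist + 1.0 >= self.arena_diameter / 2:
            raise ValueError("arena too small for the configured separations")


def _rot(v: np.ndarray, ang: float) -> np.ndarray:
    c, s = math.cos(ang), math.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def gen_pair_trajectories(
    cfg: BehaviorSynthConfig, design: TrialDesign
) -> Tuple[Trajectory, np.ndarray]:
    """Simulate a state-switching two-fly session.

    State switching is a continuous-time Markov chain discretized at the
    frame rate (per-frame matrix ``I + (P - I)/fps`` where ``P`` is the
    per-second matrix), with a minimum dwell time. Within a state the male
    roams toward random waypoints while the pair drifts along its
    separation axis at the state's approach velocity; the female rides the
    (slowly rotating, OU-regulated) separation vector, and both headings
    are set relative to the partner axis per the state signature.

    Returns the trajectory and the per-frame true state indices.
    """
    rng = np.random.default_rng(cfg.seed)
    fps, dt = design.fps, 1.0 / design.fps
    n = int(round(design.session_length * design.fps))
    if n < 3:
        raise ValueError("session too short")
    n_states = len(cfg.states)
    p_frame = np.eye(n_states) + (cfg.transition_matrix - np.eye(n_states)) / fps
    dwell_frames = int(round(cfg.dwell_min * fps))

    # state sequence
    labels = np.empty(n, dtype=int)
    state = int(rng.integers(n_states))
    since_switch = 0
    sign_fm, sign_mf = 1.0, 1.0
    signs_fm = np.empty(n)
    signs_mf = np.empty(n)
    for i in range(n):
        if since_switch >= dwell_frames:
            new = int(rng.choice(n_states, p=p_frame[state]))
            if new != state:
                state, since_switch = new, 0
                sign_fm = rng.choice([-1.0, 1.0])
                sign_mf = rng.choice([-1.0, 1.0])
        labels[i] = state
        signs_fm[i] = sign_fm
        signs_mf[i] = sign_mf
        since_switch += 1

    radius = cfg.arena_diameter / 2.0
    max_dist = max(s.mf_dist for s in cfg.states)
    roam_r = radius - max_dist - 0.5    # confinement radius for the male

    m_pos = np.empty((n, 2))
    f_pos = np.empty((n, 2))
    f_head = np.empty((n, 2))
    m_head = np.empty((n, 2))

    pos = np.zeros(2)
    phi = rng.uniform(0, 2 * math.pi)       # direction male -> female
    d = cfg.states[labels[0]].mf_dist
    waypoint = rng.uniform(-roam_r, roam_r, 2)
    noisy = (cfg.dist_noise > 0 or cfg.bearing_noise > 0
             or cfg.heading_noise_deg > 0)
    for i in range(n):
        sig = cfg.states[labels[i]]
        # male roams toward a waypoint and the pair drifts along its axis
        to_wp = waypoint - pos
        dist_wp = np.linalg.norm(to_wp)
        if dist_wp < 0.5 and noisy:
            waypoint = rng.uniform(-roam_r, roam_r, 2)
            to_wp = waypoint - pos
            dist_wp = np.linalg.norm(to_wp)
        step = np.zeros(2)
        if sig.wander_speed > 0 and dist_wp > 1e-9:
            step = step + sig.wander_speed * dt * to_wp / dist_wp
        e_phi = np.array([math.cos(phi), math.sin(phi)])   # male -> female
        step = step - sig.fm_fv * dt * e_phi               # pair drifts; female closes in
        pos = pos + step
        r = np.linalg.norm(pos)
        if r > roam_r:                                      # reflect inward
            pos = pos * (2 * roam_r - r) / r
            waypoint = rng.uniform(-roam_r, roam_r, 2)
            r = np.linalg.norm(pos)
        # near the wall, steer the pair axis so the drift points inward
        # (female ends up on the outside); keeps fmFV realized at the wall
        if sig.fm_fv > 0 and r > 0.5 * roam_r:
            desired = math.atan2(pos[1], pos[0])
            delta = (desired - phi + math.pi) % (2 * math.pi) - math.pi
            phi += delta * min(1.0, 3.0 * dt * (r / roam_r))
        # separation axis rotates slowly; distance is OU-regulated
        if cfg.bearing_noise > 0:
            phi += cfg.bearing_noise * math.sqrt(dt) * rng.standard_normal()
        d += 2.0 * (sig.mf_dist - d) * dt
        if cfg.dist_noise > 0:
            d += cfg.dist_noise * math.sqrt(dt) * rng.standard_normal()
        d = max(d, 0.2)
        e_phi = np.array([math.cos(phi), math.sin(phi)])
        m_pos[i] = pos
        f_pos[i] = pos + d * e_phi
        # headings relative to the partner axis
        noise = math.radians(cfg.heading_noise_deg)
        a_f = signs_fm[i] * math.radians(sig.fm_angle_deg)
        a_m = signs_mf[i] * math.radians(sig.mf_angle_deg)
        if noise > 0:
            a_f += noise * rng.standard_normal()
            a_m += noise * rng.standard_normal()
        f_head[i] = _rot(-e_phi, a_f)       # female: toward male, rotated
        m_head[i] = _rot(e_phi, a_m)        # male: toward female, rotated

    traj = Trajectory(f_pos=f_pos, m_pos=m_pos, f_head=f_head, m_head=m_head,
                      fps=design.fps, condition=design.condition)
    return traj, labels


# ---------------------------------------------------------------------------
# Calcium
# ---------------------------------------------------------------------------


@dataclass
class CalciumSynthConfig:
    """Configuration for the dual-channel ROI trace generator.

    Amplitudes are in multiples of the baseline noise SD (``noise_sd``,
    arbitrary fluorescence units). ``frame_rate`` is in volumes/s; the
    default 0.1 matches slow volumetric scanning of a whole hemisphere.
    Responsive ROIs split evenly between persistent and transient per
    ``fraction_persistent``, and each group splits evenly again into its
    two sub-dynamics (slow/fast decay for persistent, sustained/adapting
    during the stimulus for transient), giving four plantable response
    types.
    """

    seed: int = 0
    n_rois: int = 200
    fraction_responsive: float = 0.5
    fraction_persistent: float = 0.5
    response_amplitude: float = 6.0      # multiples of baseline sigma
    tau_transient: float = 30.0          # s, post-offset decay of transient ROIs
    tau_persistent_fast: float = 300.0   # s
    tau_persistent_slow: float = 1000.0  # s
    tau_adapt: float = 60.0              # s, within-stimulus adaptation (type 4)
    adapt_floor: float = 0.5             # plateau fraction for adapting ROIs
    rise_tau: float = 1.0                # s, indicator onset
    drift_amplitude: float = 2.0         # multiples of noise_sd, shared drift
    artifact_amplitude: float = 5.0      # multiples of noise_sd, red channel
    noise_sd: float = 2.0                # a.u.
    f0_green: float = 100.0
    f0_red: float = 200.0
    frame_rate: float = 0.1              # volumes / s
    stim_window: Tuple[float, float] = (300.0, 600.0)
    session_length: float = 1170.0       # 5 min baseline + 5 min stim + 9.5 min post

    def __post_init__(self) -> None:
        for name in ("fraction_responsive", "fraction_persistent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not (self.tau_transient < self.tau_persistent_fast
                < self.tau_persistent_slow):
            raise ValueError(
                "need tau_transient < tau_persistent_fast < tau_persistent_slow")
        if min(self.tau_transient, self.tau_adapt, self.rise_tau) <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0 or self.drift_amplitude < 0 or self.artifact_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        on, off = self.stim_window
        if not (0 <= on < off <= self.session_length):
            raise ValueError("stim_window must lie within the session")


def _response_kernel(t: np.ndarray, cfg: CalciumSynthConfig, rtype: int) -> np.ndarray:
    """Unit-amplitude response time course for response type 1-4.

    1: persistent, slow decay.  2: persistent, fast decay.
    3: transient, sustained during the stimulus.  4: transient, adapting
    during the stimulus.  All decay exponentially after offset from their
    value at offset; types 3-4 decay with ``tau_transient``.
    """
    on, off = cfg.stim_window
    z = np.zeros_like(t)
    stim = (t >= on) & (t <= off)
    post = t > off
    rise = 1.0 - np.exp(-np.maximum(t - on, 0.0) / cfg.rise_tau)
    if rtype == 4:
        level = cfg.adapt_floor + (1 - cfg.adapt_floor) * np.exp(
            -np.maximum(t - on, 0.0) / cfg.tau_adapt)
    else:
        level = np.ones_like(t)
    z[stim] = (rise * level)[stim]
    at_off = (1.0 - math.exp(-(off - on) / cfg.rise_tau))
    if rtype == 4:
        at_off *= cfg.adapt_floor + (1 - cfg.adapt_floor) * math.exp(
            -(off - on) / cfg.tau_adapt)
    tau_post = {1: cfg.tau_persistent_slow, 2: cfg.tau_persistent_fast,
                3: cfg.tau_transient, 4: cfg.tau_transient}[rtype]
    z[post] = at_off * np.exp(-(t[post] - off) / tau_post)
    return z


def _smooth_drift(rng: np.random.Generator, n: int, dt: float) -> np.ndarray:
    """Slow zero-mean drift with unit SD.

    Modeled as motion drift over tens of minutes: a random walk smoothed
    on a ~300 s window, so within a session it is a slowly bending ramp
    rather than fluctuation at the response timescale.
    """
    w = np.cumsum(rng.standard_normal(n))
    k = max(int(round(300.0 / dt)), 3)
    kern = np.ones(k) / k
    w = np.convolve(w, kern, mode="same")
    w -= w.mean()
    sd = w.std()
    return w / sd if sd > 0 else w


def gen_calcium_traces(
    cfg: CalciumSynthConfig,
) -> Tuple[List[RoiTrace], pd.DataFrame]:
    """Generate ROI traces and their true response classes.

    Returns (traces, labels) where labels has columns ``roi``,
    ``true_class`` in {nonresponsive, transient, persistent} and
    ``true_type`` in {0 (none), 1, 2, 3, 4}.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.frame_rate
    t = np.arange(0.0, cfg.session_length, dt)
    on, off = cfg.stim_window

    # red-channel optogenetic artifact: stimulus-locked square with short rise
    artifact = np.zeros_like(t)
    in_stim = (t >= on) & (t <= off)
    artifact[in_stim] = 1.0 - np.exp(-(t[in_stim] - on) / cfg.rise_tau)

    types = np.zeros(cfg.n_rois, dtype=int)
    if cfg.response_amplitude > 0:
        n_resp = int(round(cfg.fraction_responsive * cfg.n_rois))
        n_pers = int(round(cfg.fraction_persistent * n_resp))
        resp_idx = rng.permutation(cfg.n_rois)[:n_resp]
        pers = resp_idx[:n_pers]
        trans = resp_idx[n_pers:]
        types[pers[: len(pers) // 2]] = 1
        types[pers[len(pers) // 2:]] = 2
        types[trans[: len(trans) // 2]] = 3
        types[trans[len(trans) // 2:]] = 4

    traces: List[RoiTrace] = []
    rows = []
    # amplitudes are in units of the baseline SD; in the noiseless limit
    # one arbitrary unit stands in for sigma so responses remain visible
    sigma_ref = cfg.noise_sd if cfg.noise_sd > 0 else 1.0
    for roi in range(cfg.n_rois):
        rtype = types[roi]
        z = np.zeros_like(t)
        if rtype > 0:
            z = cfg.response_amplitude * _response_kernel(t, cfg, rtype)
        drift = (cfg.drift_amplitude * sigma_ref
                 * _smooth_drift(rng, len(t), dt)) if cfg.drift_amplitude > 0 \
            else np.zeros_like(t)
        truth = (cfg.f0_green + sigma_ref * z
                 + (cfg.noise_sd * rng.standard_normal(len(t))
                    if cfg.noise_sd > 0 else 0.0))
        green = truth + drift
        red = (cfg.f0_red + drift
               + cfg.artifact_amplitude * sigma_ref * artifact
               + (cfg.noise_sd * rng.standard_normal(len(t))
                  if cfg.noise_sd > 0 else 0.0))
        traces.append(RoiTrace(
            f_green=green, f_red=red, timebase=t.copy(),
            stim_on=on, stim_off=off, fly_id=0, roi_id=roi, truth=truth))
        cls = ("nonresponsive" if rtype == 0
               else "persistent" if rtype <= 2 else "transient")
        rows.append({"roi": roi, "true_class": cls, "true_type": rtype})
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Connectome
# ---------------------------------------------------------------------------

SYNAPSE_COLUMNS = [
    "id", "pre_cell", "post_cell",
    "pre_x_nm", "pre_y_nm", "pre_z_nm",
    "post_x_nm", "post_y_nm", "post_z_nm",
    "source", "qc_label", "parent_id",
]


@dataclass
class ConnectomeSynthConfig:
    """Configuration for the synapse-detection table generator."""

    seed: int = 0
    cell_counts: Dict[str, int] = field(
        default_factory=lambda: {"pC1d": 1, "aIPg-a": 6, "aIPg-b": 24, "aIPg-c": 8})
    #: Expected total synapse count per ordered (pre_type, post_type) pair.
    block_connectivity: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {
            ("pC1d", "aIPg-a"): 120.0, ("pC1d", "aIPg-b"): 80.0,
            ("pC1d", "aIPg-c"): 40.0, ("aIPg-b", "pC1d"): 40.0,
            ("aIPg-c", "pC1d"): 15.0,
        })
    duplicate_rate: float = 0.2
    duplicate_jitter: float = 100.0     # nm, strictly below the dedup threshold
    fp_rate: float = 0.1
    coordinate_extent: float = 50_000.0  # nm
    #: Keep true detections of the same cell pair >= 2x the dedup threshold
    #: apart so label-based scoring of dedup is exact.
    enforce_separation: bool = True
    source: str = "auto"

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "fp_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.duplicate_jitter < 150.0:
            raise ValueError("duplicate_jitter must be in (0, 150) nm")
        if self.coordinate_extent <= 0:
            raise ValueError("coordinate_extent must be positive")


def gen_synapse_table(cfg: ConnectomeSynthConfig) -> pd.DataFrame:
    """Generate a synapse-detection table with truth labels.

    True synapse counts per cell pair are Poisson with mean
    ``block_connectivity[type pair] / (n_pre * n_post)``. Each true
    detection spawns a redundant duplicate (same cell pair, presynaptic
    coordinate jittered by < ``duplicate_jitter``) with probability
    ``duplicate_rate``; false positives are added at rate ``fp_rate`` per
    true detection with random cell pairs and coordinates. The ``qc_label``
    column holds {TP, redundant, FP}; ``parent_id`` links duplicates to
    their parent.
    """
    rng = np.random.default_rng(cfg.seed)
    cells = {t: [f"{t}.{i}" for i in range(n)] for t, n in cfg.cell_counts.items()}
    rows: List[dict] = []
    next_id = 0

    def rand_xyz() -> np.ndarray:
        return rng.uniform(0, cfg.coordinate_extent, 3)

    for (pre_t, post_t), total in cfg.block_connectivity.items():
        pre_cells, post_cells = cells[pre_t], cells[post_t]
        mean = total / (len(pre_cells) * len(post_cells))
        for pre in pre_cells:
            for post in post_cells:
                if pre == post:
                    continue
                k = rng.poisson(mean)
                placed: List[np.ndarray] = []
                for _ in range(k):
                    xyz = rand_xyz()
                    if cfg.enforce_separation:
                        for _ in range(100):
                            if not placed or min(
                                np.linalg.norm(xyz - q) for q in placed
                            ) >= 300.0:
                                break
                            xyz = rand_xyz()
                    placed.append(xyz)
                    post_xyz = xyz + rng.normal(0, 50, 3)
                    rows.append(dict(
                        id=next_id, pre_cell=pre, post_cell=post,
                        pre_x_nm=xyz[0], pre_y_nm=xyz[1], pre_z_nm=xyz[2],
                        post_x_nm=post_xyz[0], post_y_nm=post_xyz[1],
                        post_z_nm=post_xyz[2], source=cfg.source,
                        qc_label="TP", parent_id=-1))
                    next_id += 1

    tp_rows = list(rows)
    for r in tp_rows:
        if rng.random() < cfg.duplicate_rate:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            offset = direction * rng.uniform(10.0, cfg.duplicate_jitter)
            xyz = np.array([r["pre_x_nm"], r["pre_y_nm"], r["pre_z_nm"]]) + offset
            rows.append(dict(
                id=next_id, pre_cell=r["pre_cell"], post_cell=r["post_cell"],
                pre_x_nm=xyz[0], pre_y_nm=xyz[1], pre_z_nm=xyz[2],
                post_x_nm=r["post_x_nm"], post_y_nm=r["post_y_nm"],
                post_z_nm=r["post_z_nm"], source=cfg.source,
                qc_label="redundant", parent_id=r["id"]))
            next_id += 1

    all_cells = [c for cs in cells.values() for c in cs]
    n_fp = rng.poisson(cfg.fp_rate * len(tp_rows))
    for _ in range(n_fp):
        pre, post = rng.choice(all_cells, 2, replace=False)
        xyz, post_xyz = rand_xyz(), rand_xyz()
        rows.append(dict(
            id=next_id, pre_cell=pre, post_cell=post,
            pre_x_nm=xyz[0], pre_y_nm=xyz[1], pre_z_nm=xyz[2],
            post_x_nm=post_xyz[0], post_y_nm=post_xyz[1], post_z_nm=post_xyz[2],
            source=cfg.source, qc_label="FP", parent_id=-1))
        next_id += 1

    return pd.DataFrame(rows, columns=SYNAPSE_COLUMNS)


def qc115_fixture() -> pd.DataFrame:
    """Hand-built 115-detection QC table (synthetic stand-in geometry).

    Composition: 71 true positives, 28 redundant duplicates, 16 false
    positives, split over two postsynaptic partner cells. 27 of the 28
    duplicates sit < 150 nm from their parent's presynaptic coordinate (one
    sits farther); two true detections chain through a duplicate and three
    true detections are mutually < 150 nm apart, so that distance-based
    deduplication at 150 nm removes exactly 27 duplicates and 3 true
    synapses. All other detections are >= 1 um apart.
    """
    rows: List[dict] = []
    next_id = [0]

    def add(pre, post, x, y, z, label, parent=-1):
        rows.append(dict(
            id=next_id[0], pre_cell=pre, post_cell=post,
            pre_x_nm=float(x), pre_y_nm=float(y), pre_z_nm=float(z),
            post_x_nm=float(x) + 40.0, post_y_nm=float(y), post_z_nm=float(z),
            source="auto", qc_label=label, parent_id=parent))
        next_id[0] += 1
        return next_id[0] - 1

    def build_pair(post_cell, z0, n_dup_pairs, n_iso_tp, n_fp,
                   chain=False, triple=False, far_red=False):
        x = 0.0
        for _ in range(n_dup_pairs):
            p = add("pC1d", post_cell, x, 0, z0, "TP")
            add("pC1d", post_cell, x + 100, 0, z0, "redundant", p)
            x += 2000.0
        if chain:       # TP -- redundant -- TP, linked at 100 nm steps
            p = add("pC1d", post_cell, x, 0, z0, "TP")
            add("pC1d", post_cell, x + 100, 0, z0, "redundant", p)
            add("pC1d", post_cell, x + 200, 0, z0, "TP")
            x += 2000.0
        if triple:      # three mutually-linked TPs
            add("pC1d", post_cell, x, 0, z0, "TP")
            add("pC1d", post_cell, x + 100, 0, z0, "TP")
            add("pC1d", post_cell, x + 200, 0, z0, "TP")
            x += 2000.0
        if far_red:     # annotated duplicate placed beyond the threshold
            p = add("pC1d", post_cell, x, 0, z0, "TP")
            add("pC1d", post_cell, x + 800, 0, z0, "redundant", p)
            x += 2000.0
        for _ in range(n_iso_tp - (1 if far_red else 0)):
            add("pC1d", post_cell, x, 0, z0, "TP")
            x += 2000.0
        for _ in range(n_fp):
            add("pC1d", post_cell, x, 0, z0, "FP")
            x += 2000.0

    build_pair("aIPg-b.1", 0.0, n_dup_pairs=13, n_iso_tp=20, n_fp=8, chain=True)
    build_pair("pC2like.1", 100_000.0, n_dup_pairs=13, n_iso_tp=20, n_fp=8,
               triple=True, far_red=True)
    df = pd.DataFrame(rows, columns=SYNAPSE_COLUMNS)
    assert len(df) == 115
    assert (df.qc_label == "TP").sum() == 71
    assert (df.qc_label == "redundant").sum() == 28
    assert (df.qc_label == "FP").sum() == 16
    return df


# ---------------------------------------------------------------------------
# Tracking video
# ---------------------------------------------------------------------------


@dataclass
class VideoSynthConfig:
    """Two elliptical flies over a static textured background."""

    seed: int = 0
    height: int = 120
    width: int = 120
    n_frames: int = 60
    fly_axes_px: Tuple[float, float] = (6.0, 3.0)   # semi-major, semi-minor
    fly_intensity: float = 1.0
    texture_low: float = 0.2
    texture_high: float = 0.6
    texture_smooth_px: float = 2.0
    orbit_radius_px: float = 30.0
    orbit_period_frames: int = 120
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        a = max(self.fly_axes_px)
        if 2 * a >= min(self.height, self.width) / 2:
            raise ValueError("arena smaller than fly")


def _draw_ellipse(img: np.ndarray, cx: float, cy: float,
                  a: float, b: float, theta: float, value: float) -> None:
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    c, s = math.cos(theta), math.sin(theta)
    u = (xx - cx) * c + (yy - cy) * s
    v = -(xx - cx) * s + (yy - cy) * c
    img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = value


def gen_tracking_video(
    cfg: VideoSynthConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render a synthetic two-fly video.

    The two flies orbit the arena center on opposite sides, headings
    tangent to the orbit, over a static smooth random texture. Returns
    ``(frames, background, centroids, orientations)`` with frames of shape
    (n_frames, H, W), centroids (n_frames, 2, 2) as (x, y), and
    orientations (n_frames, 2) in radians.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(cfg.seed)
    background = rng.uniform(cfg.texture_low, cfg.texture_high,
                             (cfg.height, cfg.width))
    if cfg.texture_smooth_px > 0:
        background = gaussian_filter(background, cfg.texture_smooth_px)
    cx0, cy0 = cfg.width / 2.0, cfg.height / 2.0
    a, b = cfg.fly_axes_px

    frames = np.empty((cfg.n_frames, cfg.height, cfg.width))
    centroids = np.empty((cfg.n_frames, 2, 2))
    orientations = np.empty((cfg.n_frames, 2))
    for i in range(cfg.n_frames):
        ang = 2 * math.pi * i / cfg.orbit_period_frames
        img = background.copy()
        for j, offset in enumerate((0.0, math.pi if not cfg.allow_overlap else 0.0)):
            theta = ang + offset
            cx = cx0 + cfg.orbit_radius_px * math.cos(theta)
            cy = cy0 + cfg.orbit_radius_px * math.sin(theta)
            heading = theta + math.pi / 2        # tangent to the orbit
            _draw_ellipse(img, cx, cy, a, b, heading, cfg.fly_intensity)
            centroids[i, j] = (cx, cy)
            orientations[i, j] = heading
        frames[i] = img
    return frames, background, centroids, orientations


# ---------------------------------------------------------------------------
# Song
# ---------------------------------------------------------------------------


@dataclass
class SongSynthConfig:
    """Song-bout table plus female speed series with planted correlation.

    ``target_rho`` is the window-level Pearson correlation between female
    mean speed and total song per 1-min window.
    """

    seed: int = 0
    n_windows: int = 30
    window_s: float = 60.0
    target_rho: float = 0.0
    speed_mean: float = 4.0           # mm/s
    speed_sd: float = 1.0             # across-window SD
    speed_noise_sd: float = 0.0       # within-window sample noise
    bout_amount_mean: float = 20.0    # s of song per window
    bout_amount_sd: float = 8.0
    bout_duration_s: float = 2.0
    sample_rate: float = 10.0         # Hz of the speed series

    def __post_init__(self) -> None:
        if abs(self.target_rho) > 1:
            raise ValueError("|target_rho| must be <= 1")
        if self.n_windows < 1 or self.window_s <= 0:
            raise ValueError("session must contain at least one window")
        if self.bout_duration_s <= 0 or self.bout_duration_s > self.window_s:
            raise ValueError("bout duration must be in (0, window]")


def gen_song_trial(
    cfg: SongSynthConfig,
) -> Tuple[pd.DataFrame, np.ndarray, float]:
    """Generate (bout table, speed series, true rho).

    Per window, the total song amount is drawn, quantized into
    non-overlapping bouts of fixed duration, and the window's mean speed is
    built from the standardized quantized amount so that the realized
    window-level correlation equals ``target_rho`` up to sampling noise
    (exactly +/-1 in the noiseless limits).
    """
    rng = np.random.default_rng(cfg.seed)
    g = rng.standard_normal(cfg.n_windows)
    amounts = np.clip(cfg.bout_amount_mean + cfg.bout_amount_sd * g,
                      0.0, 0.9 * cfg.window_s)
    n_bouts = np.round(amounts / cfg.bout_duration_s).astype(int)
    amounts_q = n_bouts * cfg.bout_duration_s

    sd = amounts_q.std()
    zq = (amounts_q - amounts_q.mean()) / sd if sd > 0 else np.zeros_like(amounts_q)
    e = rng.standard_normal(cfg.n_windows)
    rho = cfg.target_rho
    speed_w = cfg.speed_mean + cfg.speed_sd * (
        rho * zq + math.sqrt(max(0.0, 1 - rho ** 2)) * e)
    speed_w = np.clip(speed_w, 0.0, None)

    rows = []
    for w in range(cfg.n_windows):
        k = n_bouts[w]
        if k == 0:
            continue
        gap = (cfg.window_s - k * cfg.bout_duration_s) / (k + 1)
        t = w * cfg.window_s + gap
        for j in range(k):
            rows.append({"onset_s": t, "offset_s": t + cfg.bout_duration_s,
                         "mode": "pulse" if (w + j) % 2 else "sine"})
            t += cfg.bout_duration_s + gap
    bouts = pd.DataFrame(rows, columns=["onset_s", "offset_s", "mode"])

    per_window = int(round(cfg.window_s * cfg.sample_rate))
    speed = np.repeat(speed_w, per_window)
    if cfg.speed_noise_sd > 0:
        speed = np.clip(speed + cfg.speed_noise_sd
                        * rng.standard_normal(len(speed)), 0.0, None)
    return bouts, speed, rho
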