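"""Epoch-level behavior analytics.

Covers the longer-timescale layer above per-frame features: sliding
window features for epoch classifiers, epoch extraction from per-frame
labels, conditioned transition statistics between behaviors, moving-average
behavior time courses, windowed song-speed correlation, and empirical
copulation (cumulative-incidence) curves with right-censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

WINDOW_FEATURE_NAMES = [
    "mean", "min", "max", "change", "std",
    "diff_neighbor_mean", "diff_neighbor_min", "diff_neighbor_max",
    "zscore_neighbors",
]


@dataclass
class WindowFeatureConfig:
    radius: int = 10
    features: List[str] = field(default_factory=lambda: list(WINDOW_FEATURE_NAMES))

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        unknown = set(self.features) - set(WINDOW_FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown window features: {sorted(unknown)}")


def window_features(
    series: np.ndarray, cfg: Optional[WindowFeatureConfig] = None
) -> pd.DataFrame:
    """Sliding-window statistics of a per-frame series.

    For window W_i = [i-r, i+r]: mean/min/max/std over W_i;
    ``change`` = x_{i+r} - x_{i-r}; ``diff_neighbor_<stat>`` = stat over
    the trailing half-window [i+1, i+r] minus stat over the leading
    half-window [i-r, i-1]; ``zscore_neighbors`` = (x_i - mean of
    W_i minus {i}) / std of W_i minus {i}, with 0/0 -> 0 flagged.
    Edge frames use truncated windows and carry ``edge_flag``.
    """
    cfg = cfg or WindowFeatureConfig()
    x = np.asarray(series, dtype=float)
    n, r = len(x), cfg.radius
    if n <= 2 * r:
        raise ValueError("series must be longer than the full window")
    out: Dict[str, np.ndarray] = {f: np.empty(n) for f in cfg.features}
    zero_div = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - r), min(n - 1, i + r)
        w = x[lo:hi + 1]
        before = x[lo:i]                      # [i-r, i-1]
        after = x[i + 1:hi + 1]               # [i+1, i+r]
        neighbors = np.concatenate([before, after])
        for f in cfg.features:
            if f == "mean":
                v = w.mean()
            elif f == "min":
                v = w.min()
            elif f == "max":
                v = w.max()
            elif f == "std":
                v = w.std(ddof=0)
            elif f == "change":
                v = x[hi] - x[lo]
            elif f == "diff_neighbor_mean":
                v = (after.mean() if len(after) else 0.0) \
                    - (before.mean() if len(before) else 0.0)
            elif f == "diff_neighbor_min":
                v = (after.min() if len(after) else 0.0) \
                    - (before.min() if len(before) else 0.0)
            elif f == "diff_neighbor_max":
                v = (after.max() if len(after) else 0.0) \
                    - (before.max() if len(before) else 0.0)
            elif f == "zscore_neighbors":
                if len(neighbors) == 0:
                    v, zero_div[i] = 0.0, True
                else:
                    mu, sd = neighbors.mean(), neighbors.std(ddof=0)
                    if sd <= 1e-12 * max(1.0, abs(mu)):
                        v, zero_div[i] = 0.0, True
                    else:
                        v = (x[i] - mu) / sd
            out[f][i] = v
    df = pd.DataFrame(out)
    edge = np.zeros(n, dtype=bool)
    edge[:r] = True
    edge[n - r:] = True
    df["edge_flag"] = edge
    df["zero_division_flag"] = zero_div
    return df


@dataclass
class EpochSet:
    """Non-overlapping, sorted behavior intervals [start, end) in frames."""

    state: str
    intervals: List[Tuple[int, int]]
    fps: float = 60.0
    session_id: str = ""
    condition: str = ""
    n_dropped: int = 0                    # sub-min_bout runs discarded

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([(b - a) / self.fps for a, b in self.intervals])

    @property
    def total_frames(self) -> int:
        return sum(b - a for a, b in self.intervals)


def epochs_from_labels(
    labels: np.ndarray, min_bout: int = 5, state: str = "behavior",
    fps: float = 60.0, **kw,
) -> EpochSet:
    """Maximal runs of positive frames, dropping runs shorter than
    ``min_bout`` (default 5 frames, ~83 ms at 60 fps, to suppress
    single-frame flicker)."""
    lab = np.asarray(labels).astype(bool)
    padded = np.concatenate([[False], lab, [False]])
    starts = np.where(~padded[:-1] & padded[1:])[0]
    ends = np.where(padded[:-1] & ~padded[1:])[0]
    intervals, dropped = [], 0
    for a, b in zip(starts, ends):
        if b - a >= min_bout:
            intervals.append((int(a), int(b)))
        else:
            dropped += b - a
    return EpochSet(state=state, intervals=intervals, fps=fps,
                    n_dropped=dropped, **kw)


@dataclass
class TransitionStats:
    states: List[str]
    counts: pd.DataFrame               # raw transition counts
    conditioned: pd.DataFrame          # P(dest | source, transition occurred)
    frame_states: np.ndarray


def transition_matrix(
    shoving: EpochSet,
    chasing: EpochSet,
    session_length: int,
    precedence: str = "shoving",
) -> TransitionStats:
    """Three-state (shoving/chasing/other) transition statistics.

    Frames are labeled from the two epoch sets (overlaps resolved by
    ``precedence``); transitions are counted at state changes and each
    row of the conditioned matrix is normalized over destinations, so it
    gives the probability of the destination given that a transition out
    of the source occurred (NaN rows where a state never transitions).
    """
    states = ["shoving", "chasing", "other"]
    seq = np.full(session_length, 2, dtype=int)   # other
    first, second = (shoving, chasing) if precedence == "shoving" \
        else (chasing, shoving)
    for a, b in second.intervals:
        seq[a:b] = states.index(second.state if second.state in states
                                else "chasing")
    for a, b in first.intervals:
        seq[a:b] = states.index(first.state if first.state in states
                                else "shoving")
    counts = np.zeros((3, 3), dtype=int)
    changes = np.where(np.diff(seq) != 0)[0]
    for i in changes:
        counts[seq[i], seq[i + 1]] += 1
    cond = np.full((3, 3), np.nan)
    for s in range(3):
        row = counts[s].astype(float)
        row[s] = 0.0
        total = row.sum()
        if total > 0:
            cond[s] = row / total
            cond[s, s] = 0.0
    return TransitionStats(
        states=states,
        counts=pd.DataFrame(counts, index=states, columns=states),
        conditioned=pd.DataFrame(cond, index=states, columns=states),
        frame_states=seq)


def behavior_time_course(
    labels_by_session: Sequence[np.ndarray],
    fps: float = 60.0,
    window_s: float = 120.0,
    copulation_frames: Optional[Sequence[Optional[int]]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Across-session mean probability of a behavior over time.

    Each session's binary label series is truncated at its copulation
    frame (behavior is not scored after copulation), smoothed with a
    centered moving average of ``window_s``, and sessions are averaged at
    each time point over the sessions still available there.

    Returns (time_s, mean_probability) on the longest session's time base.
    """
    if copulation_frames is None:
        copulation_frames = [None] * len(labels_by_session)
    win = max(int(round(window_s * fps)), 1)
    smoothed = []
    for lab, cop in zip(labels_by_session, copulation_frames):
        x = np.asarray(lab, dtype=float)
        if cop is not None:
            x = x[:cop]
        if len(x) == 0:
            smoothed.append(np.array([]))
            continue
        if win >= len(x):
            smoothed.append(np.full(len(x), x.mean()))
            continue
        c = np.convolve(x, np.ones(win), mode="same")
        norm = np.convolve(np.ones(len(x)), np.ones(win), mode="same")
        smoothed.append(c / norm)
    n_max = max((len(s) for s in smoothed), default=0)
    mean = np.full(n_max, np.nan)
    for t in range(n_max):
        vals = [s[t] for s in smoothed if len(s) > t]
        if vals:
            mean[t] = float(np.mean(vals))
    return np.arange(n_max) / fps, mean


def song_response_correlation(
    bouts: pd.DataFrame,
    speed: np.ndarray,
    speed_rate_hz: float,
    window_s: float = 60.0,
) -> pd.DataFrame:
    """Window-level correlation of female speed with male song features.

    The session is cut into non-overlapping windows of ``window_s``; per
    window the mean absolute speed, total song (bout amount, s), bout
    number, and mean bout duration are computed (bout seconds are credited
    to the window(s) they overlap). Returns one row per song feature with
    the Pearson r, least-squares slope of speed on the feature, and the
    number of windows paired (windows with no song are excluded from the
    duration pairing and counted). A zero-variance guard reports r = 0
    with a flag.
    """
    n_windows = int(len(speed) / (speed_rate_hz * window_s))
    if n_windows < 3:
        raise ValueError("need at least 3 full windows")
    per = int(round(window_s * speed_rate_hz))
    speed_w = np.array([
        np.abs(speed[w * per:(w + 1) * per]).mean() for w in range(n_windows)
    ])
    amount = np.zeros(n_windows)
    number = np.zeros(n_windows)
    dur_sum = np.zeros(n_windows)
    for _, b in bouts.iterrows():
        on, off = float(b["onset_s"]), float(b["offset_s"])
        w0 = int(on // window_s)
        for w in range(w0, n_windows):
            lo, hi = w * window_s, (w + 1) * window_s
            if lo >= off:
                break
            overlap = max(0.0, min(off, hi) - max(on, lo))
            amount[w] += overlap
        if w0 < n_windows:
            number[w0] += 1
            dur_sum[w0] += off - on

    rows = []
    features = {
        "bout_amount": (amount, np.ones(n_windows, dtype=bool)),
        "bout_number": (number, np.ones(n_windows, dtype=bool)),
        "bout_duration": (np.divide(dur_sum, number,
                                    out=np.zeros(n_windows),
                                    where=number > 0),
                          number > 0),
    }
    for name, (vals, mask) in features.items():
        xs, ys = vals[mask], speed_w[mask]
        flags = []
        if (~mask).sum():
            flags.append(f"excluded_windows:{int((~mask).sum())}")
        if len(xs) < 2 or xs.std() == 0 or ys.std() == 0:
            r, slope = 0.0, 0.0
            flags.append("zero_variance")
        else:
            r = float(np.corrcoef(xs, ys)[0, 1])
            slope = float(np.cov(xs, ys)[0, 1] / np.var(xs, ddof=1))
        rows.append({"feature": name, "r": r, "slope": slope,
                     "n_windows": int(mask.sum()), "flags": ";".join(flags)})
    return pd.DataFrame(rows)


def copulation_curve(
    times_s: Sequence[float],
    events: Optional[Sequence[bool]] = None,
    censor_time_s: float = 1800.0,
) -> pd.DataFrame:
    """Empirical cumulative percent of pairs copulated versus time.

    Pairs that did not copulate within the session are right-censored at
    ``censor_time_s`` and contribute to the denominator throughout.
    Returns a step function as a DataFrame (time_s, percent_copulated).
    """
    t = np.asarray(times_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative copulation times")
    if events is None:
        events = t < censor_time_s
    events = np.asarray(events, dtype=bool)
    n = len(t)
    event_times = np.sort(t[events])
    steps = [(0.0, 0.0)]
    for i, et in enumerate(event_times, start=1):
        pct = 100.0 * i / n
        if steps and steps[-1][0] == float(et):
            steps[-1] = (float(et), pct)         # simultaneous events: one step
        else:
            steps.append((float(et), pct))
    steps.append((censor_time_s, steps[-1][1]))
    return pd.DataFrame(steps, columns=["time_s", "percent_copulated"])


def cox_regression(
    durations_s: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame,
):
    """Thin wrapper over lifelines' Cox proportional-hazards fit."""
    from lifelines import CoxPHFitter

    df = covariates.copy()
    df["duration"] = np.asarray(durations_s, dtype=float)
    df["event"] = np.asarray(events, dtype=bool).astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="duration", event_col="event")
    return cph
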