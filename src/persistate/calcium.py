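"""Post-segmentation calcium-trace analytics.

Works on per-ROI dual-channel fluorescence traces (activity channel, e.g.
GCaMP; structural channel, e.g. tdTomato) around a single optogenetic
stimulation window:

* baseline statistics and z-scoring, ``z = (F - F0) / sigma0`` with the
  baseline window running from trace start to stimulus onset;
* two-component ICA removal of shared slow drift using the structural
  channel as the background reference;
* the 3-sigma response classification: responsive iff the mean z during
  the stimulus (Ft1) exceeds 3, persistent iff additionally the mean z over
  the first 5 min after offset (Ft2) exceeds 3, transient otherwise;
* consensus hierarchical clustering of responsive traces into response
  types (two persistent + two transient dynamics in the data this models);
* across-animal voxel consistency maps and label-mask overlaps;
* post-offset decay profiles and patch-clamp tuning integrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


class DegenerateRoiError(ValueError):
    """Raised when a ROI's baseline is unusable (sigma0 == 0 or F0 <= 0)."""


@dataclass
class RoiTrace:
    """Dual-channel fluorescence trace of one segmented ROI."""

    f_green: np.ndarray
    f_red: np.ndarray
    timebase: np.ndarray          # s, strictly increasing
    stim_on: float
    stim_off: float
    fly_id: int = 0
    roi_id: int = 0
    footprint: Optional[np.ndarray] = None   # voxel indices on a common grid
    #: ground-truth activity channel (drift- and artifact-free), when the
    #: trace was synthesized; None for real data
    truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.f_green = np.asarray(self.f_green, dtype=float)
        self.f_red = np.asarray(self.f_red, dtype=float)
        self.timebase = np.asarray(self.timebase, dtype=float)
        if not (len(self.f_green) == len(self.f_red) == len(self.timebase)):
            raise ValueError("channels and timebase must have equal length")
        if np.any(np.diff(self.timebase) <= 0):
            raise ValueError("timebase must be strictly increasing")
        if not (self.timebase[0] <= self.stim_on < self.stim_off
                <= self.timebase[-1]):
            raise ValueError("stimulus window must lie within the trace")


@dataclass
class BaselineStats:
    f0: float
    sigma0: float
    n_samples: int


def baseline_and_zscore(
    trace: RoiTrace, signal: Optional[np.ndarray] = None
) -> Tuple[BaselineStats, np.ndarray, np.ndarray]:
    """Baseline statistics plus z-scored and dF/F traces.

    The baseline window is [trace start, stim_on). ``signal`` overrides the
    green channel (e.g. the ICA-cleaned trace). Raises
    :class:`DegenerateRoiError` for unusable ROIs.
    """
    f = trace.f_green if signal is None else np.asarray(signal, dtype=float)
    base = f[trace.timebase < trace.stim_on]
    if len(base) < 10:
        raise ValueError("baseline window must contain at least 10 samples")
    f0 = float(base.mean())
    sigma0 = float(base.std(ddof=0))
    if sigma0 == 0:
        raise DegenerateRoiError("sigma0 == 0")
    if f0 <= 0:
        raise DegenerateRoiError("F0 <= 0")
    z = (f - f0) / sigma0
    dff = (f - f0) / f0
    return BaselineStats(f0, sigma0, len(base)), z, dff


# ---------------------------------------------------------------------------
# ICA drift removal
# ---------------------------------------------------------------------------


def _ica_two_component(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Reference-guided two-component ICA.

    Whitens the two observed channels, then rotates the whitened pair so
    that the first source is maximally correlated with ``ref`` (closed
    form: in whitened space every rotation has unit variance, so the
    optimum is the normalized covariance direction). Returns the (n, 2)
    source matrix, background first. Deterministic.
    """
    xc = x - x.mean(axis=0)
    cov = np.cov(xc.T)
    vals, vecs = np.linalg.eigh(cov)
    if np.min(vals) <= 1e-12 * np.max(vals):
        raise np.linalg.LinAlgError("degenerate channel covariance")
    w = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    z = xc @ w.T
    r = ref - ref.mean()
    a = float(z[:, 0] @ r)
    b = float(z[:, 1] @ r)
    norm = math.hypot(a, b)
    if norm == 0:
        raise np.linalg.LinAlgError("reference uncorrelated with both channels")
    a, b = a / norm, b / norm
    s1 = a * z[:, 0] + b * z[:, 1]        # background candidate
    s2 = -b * z[:, 0] + a * z[:, 1]       # signal candidate
    return np.column_stack([s1, s2])


def ica_clean(
    trace: RoiTrace,
    interp_pad_s: float = 20.0,
    smooth_s: float = 50.0,
    corr_threshold: float = 0.9,
    seed: int = 0,
) -> Tuple[np.ndarray, List[str]]:
    """Remove shared slow drift from the activity channel via 2-component ICA.

    The structural channel is linearly interpolated across
    [stim_on - pad, stim_off + pad] (so the stimulus-locked bleed-through
    artifact is ignored) with zero-mean noise added at the interpolated
    points, then smoothed with a ``smooth_s`` moving average. A
    two-component reference-guided ICA (:func:`_ica_two_component`) is run
    on (processed red, green); the component whose absolute correlation
    with the processed red channel exceeds ``corr_threshold`` is the
    background, the other is the signal. The signal's sign is set by its
    correlation with the green channel and it is mapped back to green
    units by least squares.

    Returns (cleaned trace, flags). On failure (no background component
    reaching the threshold, or a degenerate red channel) the green channel
    is returned unchanged with flag ``"ica_failed"``. ``seed`` only drives
    the interpolation noise.
    """
    rng = np.random.default_rng(seed)
    t = trace.timebase
    green = trace.f_green
    red = trace.f_red.copy()
    flags: List[str] = []

    lo, hi = trace.stim_on - interp_pad_s, trace.stim_off + interp_pad_s
    inside = (t >= lo) & (t <= hi)
    outside = ~inside
    if outside.sum() >= 2:
        red[inside] = np.interp(t[inside], t[outside], red[outside])
        noise_sd = float(np.std(np.diff(trace.f_red[outside])) / math.sqrt(2)) \
            if outside.sum() > 2 else 0.0
        if noise_sd > 0:
            red[inside] += rng.normal(0.0, noise_sd, inside.sum())
    dt = float(np.median(np.diff(t)))
    k = max(int(round(smooth_s / dt)), 1)
    pre_smooth_var = float(np.var(red))
    if k > 1:
        # edge-normalized moving average (plain 'same' convolution would
        # zero-pad and smear the DC offset into the trace ends)
        red = (np.convolve(red, np.ones(k), mode="same")
               / np.convolve(np.ones(len(red)), np.ones(k), mode="same"))

    if red.std() < 1e-12 or green.std() < 1e-12:
        return green.copy(), ["ica_failed"]

    # the reference must itself carry slow structure: white shot noise
    # loses ~k-fold variance under the moving average, genuine drift does
    # not — without drift there is nothing to subtract, and removing a
    # chance projection would only corrupt the signal
    if k > 1 and pre_smooth_var > 0 \
            and float(np.var(red)) / pre_smooth_var < 0.6:
        return green.copy(), ["ica_skipped_no_drift"]

    try:
        sources = _ica_two_component(np.column_stack([red, green]), red)
    except np.linalg.LinAlgError:
        return green.copy(), ["ica_failed"]

    corrs = []
    for j in range(2):
        s = sources[:, j]
        if s.std() < 1e-12:
            corrs.append(0.0)
        else:
            corrs.append(float(np.corrcoef(s, red)[0, 1]))
    passing = [j for j in range(2) if abs(corrs[j]) > corr_threshold]
    if len(passing) != 1:
        return green.copy(), ["ica_failed"]
    sig = sources[:, 1 - passing[0]]
    if np.corrcoef(sig, green)[0, 1] < 0:
        sig = -sig
    # map back to green fluorescence units
    a, b = np.polyfit(sig, green, 1)
    cleaned = a * sig + b
    return cleaned, flags


# ---------------------------------------------------------------------------
# Response classification
# ---------------------------------------------------------------------------


@dataclass
class ResponseWindows:
    """Stimulus (t1) and first-5-min-post-offset (t2) window means of z."""

    t1: Tuple[float, float]
    t2: Tuple[float, float]
    ft1: float
    ft2: float
    t2_truncated_fraction: float = 0.0

    @classmethod
    def from_trace(cls, z: np.ndarray, t: np.ndarray, stim_on: float,
                   stim_off: float, post_s: float = 300.0) -> "ResponseWindows":
        in1 = (t >= stim_on) & (t <= stim_off)
        t2_end = stim_off + post_s
        in2 = (t > stim_off) & (t <= t2_end)
        if in1.sum() == 0 or in2.sum() == 0:
            raise ValueError("response windows contain no samples")
        covered = min(t[-1], t2_end) - stim_off
        trunc = 1.0 - covered / post_s
        return cls(t1=(stim_on, stim_off), t2=(stim_off, t2_end),
                   ft1=float(z[in1].mean()), ft2=float(z[in2].mean()),
                   t2_truncated_fraction=max(0.0, trunc))


@dataclass
class ResponseClass:
    """Outcome of the 3-sigma classification."""

    label: str                     # nonresponsive / transient / persistent
    ft1: float
    ft2: float
    flags: List[str] = field(default_factory=list)


def classify_response(
    z: np.ndarray, windows: ResponseWindows, threshold: float = 3.0
) -> ResponseClass:
    """Classify one z-scored trace by its window means.

    Nonresponsive if Ft1 <= threshold; transient if Ft1 > threshold and
    Ft2 <= threshold; persistent if both exceed it.
    """
    flags: List[str] = []
    if windows.t2_truncated_fraction > 0.5:
        flags.append("t2_truncated")
    if windows.ft1 <= threshold:
        label = "nonresponsive"
    elif windows.ft2 <= threshold:
        label = "transient"
    else:
        label = "persistent"
    return ResponseClass(label, windows.ft1, windows.ft2, flags)


# ---------------------------------------------------------------------------
# Response-type clustering
# ---------------------------------------------------------------------------


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def _hier_labels(x: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage labels at ``k`` clusters.

    Ward linkage on the euclidean geometry of z-scored traces: response
    dynamics that share on/off timing but differ in sustained level (e.g.
    sustained vs adapting stimulus responses) are nearly collinear, so a
    correlation distance would merge them, and single/average linkage
    tends to chain into outlier-vs-rest splits; Ward favors the compact,
    comparably sized clusters that distinct response dynamics form.
    """
    if k >= len(x):
        return np.arange(len(x))
    z = linkage(x, method="ward")
    return fcluster(z, t=k, criterion="maxclust")


def _gap_statistic_k(x: np.ndarray, k_max: int, rng: np.random.Generator,
                     n_ref: int = 20) -> int:
    """Tibshirani gap statistic with a uniform-box reference, hierarchical
    clustering throughout; returns the chosen cluster count in 1..k_max."""
    ks = list(range(1, k_max + 1))
    logw = []
    for k in ks:
        labels = np.ones(len(x), dtype=int) if k == 1 else _hier_labels(x, k)
        logw.append(math.log(max(_within_dispersion(x, labels), 1e-300)))
    lo, hi = x.min(axis=0), x.max(axis=0)
    ref_logw = np.empty((n_ref, len(ks)))
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=x.shape)
        for i, k in enumerate(ks):
            labels = np.ones(len(ref), dtype=int) if k == 1 \
                else _hier_labels(ref, k)
            ref_logw[b, i] = math.log(max(_within_dispersion(ref, labels),
                                          1e-300))
    gap = ref_logw.mean(axis=0) - np.array(logw)
    s = ref_logw.std(axis=0, ddof=0) * math.sqrt(1 + 1 / n_ref)
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            return ks[i]
    return ks[-1]


def _consensus_k(x: np.ndarray, k_max: int, rng: np.random.Generator) -> Tuple[int, Dict[str, int]]:
    """Modal cluster count across Calinski-Harabasz, Silhouette, Gap and
    Davies-Bouldin over candidate counts 1..k_max (ties -> smaller)."""
    from sklearn.metrics import (calinski_harabasz_score,
                                 davies_bouldin_score, silhouette_score)

    k_max = min(k_max, len(x) - 1)
    if k_max < 2 or np.allclose(x, x[0]):
        return 1, {"degenerate": 1}
    votes: Dict[str, int] = {}
    scores = {"ch": {}, "sil": {}, "db": {}}
    for k in range(2, k_max + 1):
        labels = _hier_labels(x, k)
        if len(np.unique(labels)) < 2:
            continue
        scores["ch"][k] = calinski_harabasz_score(x, labels)
        scores["sil"][k] = silhouette_score(x, labels)
        scores["db"][k] = davies_bouldin_score(x, labels)
    if scores["ch"]:
        votes["calinski_harabasz"] = max(sorted(scores["ch"]),
                                         key=lambda k: scores["ch"][k])
        votes["silhouette"] = max(sorted(scores["sil"]),
                                  key=lambda k: scores["sil"][k])
        votes["davies_bouldin"] = min(sorted(scores["db"]),
                                      key=lambda k: scores["db"][k])
    votes["gap"] = _gap_statistic_k(x, k_max, rng)
    vals = list(votes.values())
    counts = {k: vals.count(k) for k in set(vals)}
    best = max(counts.values())
    return min(k for k, c in counts.items() if c == best), votes


def cluster_response_types(
    z: np.ndarray,
    persistent_mask: np.ndarray,
    ft1: np.ndarray,
    ft2: np.ndarray,
    k_max: int = 6,
    split_type2: bool = False,
    seed: int = 0,
) -> Tuple[np.ndarray, dict]:
    """Cluster responsive z-traces into numbered response types.

    Persistent and transient traces are clustered separately
    (average-linkage hierarchical clustering on correlation distance); the
    cluster count per set is the modal choice of four internal criteria
    over candidate counts 1..``k_max``. Types are numbered with persistent
    clusters first, each set ordered by descending mean Ft2 then Ft1 (so
    with two clusters per set the types are 1-4). With ``split_type2`` the
    second persistent type is re-clustered once more into sub-dynamics.

    Returns (type labels aligned with rows of ``z``, info dict).
    """
    z = np.asarray(z, dtype=float)
    persistent_mask = np.asarray(persistent_mask, dtype=bool)
    if len(z) < 4:
        raise ValueError("need at least 4 responsive traces")
    rng = np.random.default_rng(seed)
    types = np.zeros(len(z), dtype=int)
    info: dict = {"flags": []}
    next_type = 1
    for set_name, mask in (("persistent", persistent_mask),
                           ("transient", ~persistent_mask)):
        idx = np.where(mask)[0]
        if len(idx) == 0:
            info[set_name] = {"k": 0}
            continue
        xs = z[idx]
        k, votes = _consensus_k(xs, k_max, rng)
        if k == 1:
            info["flags"].append(f"{set_name}_collapsed")
        labels = np.ones(len(xs), dtype=int) if k == 1 else _hier_labels(xs, k)
        # order clusters by descending mean Ft2, then Ft1
        order = sorted(np.unique(labels),
                       key=lambda c: (-ft2[idx][labels == c].mean(),
                                      -ft1[idx][labels == c].mean()))
        for c in order:
            types[idx[labels == c]] = next_type
            next_type += 1
        info[set_name] = {"k": k, "votes": votes}
    if split_type2 and np.sum(types == 2) >= 4:
        idx2 = np.where(types == 2)[0]
        k2, votes2 = _consensus_k(z[idx2], 2, rng)
        sub = np.ones(len(idx2), dtype=int) if k2 == 1 \
            else _hier_labels(z[idx2], 2)
        info["type2_subtypes"] = {"k": k2, "votes": votes2,
                                  "labels": dict(zip(idx2.tolist(),
                                                     sub.tolist()))}
    return types, info


# ---------------------------------------------------------------------------
# Voxel maps
# ---------------------------------------------------------------------------


@dataclass
class VoxelMap:
    """Across-animal response-consistency map on a common voxel grid."""

    fraction: np.ndarray           # per-voxel fraction of flies with the type
    consistent: np.ndarray         # fraction > threshold
    imaged: np.ndarray             # voxels in the denominator volume
    threshold: float
    volume_fraction_pct: float     # 100 * |consistent & imaged| / |imaged|


def consistency_map(
    footprints_by_fly: Dict[int, np.ndarray],
    n_voxels: int,
    imaged_by_fly: Optional[Dict[int, np.ndarray]] = None,
    threshold: float = 0.30,
    coverage_threshold: float = 0.30,
) -> VoxelMap:
    """Fraction of flies showing a response type at each voxel.

    ``footprints_by_fly`` maps fly id -> voxel indices covered by
    type-positive ROIs. ``imaged_by_fly`` maps fly id -> voxel indices that
    fly imaged (defaults to the whole grid). Per voxel, the fraction is
    computed over the flies that imaged it; a voxel is *consistent* when
    the fraction strictly exceeds ``threshold``. The reported volume
    fraction uses as denominator the voxels imaged by at least
    ``coverage_threshold`` of the flies.
    """
    flies = sorted(footprints_by_fly)
    if not flies:
        return VoxelMap(np.zeros(n_voxels), np.zeros(n_voxels, bool),
                        np.zeros(n_voxels, bool), threshold, 0.0)
    pos = np.zeros(n_voxels)
    imaged_count = np.zeros(n_voxels)
    for fly in flies:
        im = np.zeros(n_voxels, dtype=bool)
        if imaged_by_fly is None or fly not in imaged_by_fly:
            im[:] = True
        else:
            im[np.asarray(imaged_by_fly[fly], dtype=int)] = True
        fp = np.asarray(footprints_by_fly[fly], dtype=int)
        hit = np.zeros(n_voxels, dtype=bool)
        if len(fp):
            hit[fp] = True
        pos += (hit & im)
        imaged_count += im
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(imaged_count > 0, pos / imaged_count, 0.0)
    consistent = fraction > threshold
    imaged = imaged_count / len(flies) >= coverage_threshold
    denom = int(imaged.sum())
    vol = 100.0 * int((consistent & imaged).sum()) / denom if denom else 0.0
    return VoxelMap(fraction, consistent, imaged, threshold, vol)


def mask_overlap(consistent: np.ndarray, mask: np.ndarray) -> float:
    """Percent of ``mask`` voxels inside the consistent set."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty label mask")
    return 100.0 * float((np.asarray(consistent, bool) & mask).sum()) / mask.sum()


# ---------------------------------------------------------------------------
# Decay profiles & patch-clamp tuning
# ---------------------------------------------------------------------------


def decay_profile(
    z: np.ndarray,
    t: np.ndarray,
    stim_off: float,
    offsets: Sequence[float] = (0.0, 180.0, 360.0),
) -> pd.DataFrame:
    """Instantaneous group activity at fixed delays after stimulus offset.

    For each ROI (row of ``z``) the value at ``stim_off + offset`` is the
    mean over samples within one volume period of that time (NaN when the
    trace does not cover it). Returns a DataFrame with per-offset group
    mean, SD and n.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    t = np.asarray(t, dtype=float)
    dt = float(np.median(np.diff(t)))
    rows = []
    for off in offsets:
        target = stim_off + off
        sel = np.abs(t - target) <= dt
        if sel.sum() == 0 or target > t[-1] or target < t[0]:
            vals = np.full(len(z), np.nan)
        else:
            vals = z[:, sel].mean(axis=1)
        ok = ~np.isnan(vals)
        rows.append({"offset_s": off,
                     "mean": float(vals[ok].mean()) if ok.any() else np.nan,
                     "sd": float(vals[ok].std(ddof=0)) if ok.any() else np.nan,
                     "n": int(ok.sum())})
    return pd.DataFrame(rows)


def tuning_integral(
    voltage: np.ndarray,
    t: np.ndarray,
    stimulus_windows: Sequence[Tuple[float, float]],
    baseline_window: Tuple[float, float],
) -> Tuple[np.ndarray, List[str]]:
    """Duration-normalized integral-voltage tuning curve.

    Per stimulus, the response is the integral of (V - baseline mean) over
    the stimulus window divided by the stimulus duration; the curve is then
    normalized to peak at 1.0. If all responses are zero, normalization is
    skipped and the result flagged.
    """
    voltage = np.asarray(voltage, dtype=float)
    t = np.asarray(t, dtype=float)
    b0, b1 = baseline_window
    base = voltage[(t >= b0) & (t <= b1)]
    if len(base) == 0:
        raise ValueError("baseline window contains no samples")
    vb = base.mean()
    responses = []
    for (w0, w1) in stimulus_windows:
        if w1 <= w0:
            raise ValueError("stimulus window must have positive duration")
        sel = (t >= w0) & (t <= w1)
        if sel.sum() < 2:
            raise ValueError("stimulus window contains too few samples")
        responses.append(np.trapezoid(voltage[sel] - vb, t[sel]) / (w1 - w0))
    curve = np.array(responses)
    flags: List[str] = []
    peak = np.max(np.abs(curve)) if len(curve) else 0.0
    if peak == 0:
        flags.append("all_zero")
        return curve, flags
    return curve / curve.max(), flags
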