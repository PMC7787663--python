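"""Centroid tracking of two flies on an inhomogeneous background.

The tracker models a chamber whose floor texture (e.g. microphone grids)
defeats naive thresholding. Its stages:

1. :func:`estimate_background` -- split the video into segments, take the
   per-pixel median frame of each, then the median across segment medians,
   so that a fly sitting still for part of the video does not leak into the
   background.
2. :func:`segment_flies` -- subtract the background, smooth, threshold,
   discard connected components outside [0.5, 2] times the typical fly
   area, then cluster the remaining pixels with k-means, increasing k until
   every cluster is compact, dropping the least-compact clusters and
   re-clustering the survivors at k = 2; each final cluster is summarized
   by a moment-based ellipse fit.
3. :func:`link_tracks` -- frame-to-frame identity assignment minimizing
   summed centroid displacement, with tie flagging, interpolation over
   short losses and splitting at long gaps.

Heading from an ellipse has a 180-degree ambiguity; it is resolved from
the motion direction over a short window (:func:`resolve_headings`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage


@dataclass
class BackgroundModel:
    image: np.ndarray
    n_segments: int


@dataclass
class Detection:
    """One fly candidate: moment-based ellipse fit of a pixel cluster."""

    centroid: Tuple[float, float]          # (x, y) px
    major_axis: float                      # full length, px
    minor_axis: float
    orientation_deg: float                 # [0, 180)
    pixel_count: int
    compactness: float


def estimate_background(frames: np.ndarray, n_segments: int = 10) -> BackgroundModel:
    """Per-pixel median of segment medians.

    ``frames`` is (n, H, W). The video is divided into ``n_segments``
    near-equal contiguous segments; each contributes a per-pixel median
    frame, and the background is the per-pixel median across those.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("frames must be a non-empty (n, H, W) stack")
    if len(frames) < n_segments:
        raise ValueError("need at least n_segments frames")
    bounds = np.linspace(0, len(frames), n_segments + 1).astype(int)
    medians = np.stack([
        np.median(frames[bounds[i]:bounds[i + 1]], axis=0)
        for i in range(n_segments)
    ])
    return BackgroundModel(np.median(medians, axis=0), n_segments)


def _ellipse_fit(ys: np.ndarray, xs: np.ndarray) -> Tuple[Tuple[float, float], float, float, float]:
    """Moment-based ellipse fit of a pixel set -> (centroid, major, minor, deg)."""
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    cxx = (dx * dx).mean() + 1 / 12.0    # pixel extent regularization
    cyy = (dy * dy).mean() + 1 / 12.0
    cxy = (dx * dy).mean()
    common = math.sqrt(max((cxx - cyy) ** 2 / 4 + cxy ** 2, 0.0))
    l1 = (cxx + cyy) / 2 + common
    l2 = (cxx + cyy) / 2 - common
    theta = 0.5 * math.atan2(2 * cxy, cxx - cyy)
    return (float(cx), float(cy)), 4 * math.sqrt(max(l1, 0)), \
        4 * math.sqrt(max(l2, 0)), math.degrees(theta) % 180.0


def _compactness(ys: np.ndarray, xs: np.ndarray) -> float:
    """Mean squared distance of cluster pixels to their centroid, divided by
    the pixel count (so it is scale-comparable across cluster sizes)."""
    cx, cy = xs.mean(), ys.mean()
    msd = float(((xs - cx) ** 2 + (ys - cy) ** 2).mean())
    return msd / len(xs)


class LostFrame(Exception):
    """Raised when fewer than two fly candidates survive in a frame."""


def segment_flies(
    frame: np.ndarray,
    background: BackgroundModel,
    typical_fly_area: float,
    compactness_threshold: float = 1.0,
    smooth_sigma: float = 1.0,
    intensity_threshold: Optional[float] = None,
    seed: int = 0,
) -> Tuple[Detection, Detection]:
    """Detect exactly two flies in one frame.

    Background-subtracted absolute difference is Gaussian-smoothed
    (sigma = ``smooth_sigma`` px) and thresholded (Otsu when
    ``intensity_threshold`` is None). Connected components smaller than
    half or larger than twice ``typical_fly_area`` are discarded. The
    surviving pixels are k-means clustered with k increased from 2 until
    every cluster's compactness (mean squared pixel distance to the
    cluster centroid over pixel count) falls below
    ``compactness_threshold``; the least-compact clusters are dropped and
    the rest re-clustered at k = 2. Detections are ordered by centroid x,
    then y. Raises :class:`LostFrame` when two flies cannot be found.
    """
    from sklearn.cluster import KMeans
    from skimage.filters import gaussian, threshold_otsu

    diff = np.abs(np.asarray(frame, dtype=float) - background.image)
    if smooth_sigma > 0:
        diff = gaussian(diff, sigma=smooth_sigma, preserve_range=True)
    if intensity_threshold is None:
        if diff.max() <= 0:
            raise LostFrame("empty frame")
        intensity_threshold = threshold_otsu(diff)
    mask = diff > intensity_threshold
    labeled, n = ndimage.label(mask)
    if n == 0:
        raise LostFrame("no candidate pixels")
    keep = np.zeros_like(mask)
    for lab in range(1, n + 1):
        area = int((labeled == lab).sum())
        if 0.5 * typical_fly_area <= area <= 2.0 * typical_fly_area:
            keep |= labeled == lab
    ys, xs = np.nonzero(keep)
    if len(ys) < 4:
        raise LostFrame("fewer than two flies after area filter")
    pts = np.column_stack([xs, ys]).astype(float)

    # iterative k-means: grow k until all clusters are compact
    best_labels, k = None, 2
    max_k = 8
    while k <= max_k:
        km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(pts)
        comp = [
            _compactness(pts[km.labels_ == c][:, 1], pts[km.labels_ == c][:, 0])
            for c in range(k)
        ]
        best_labels = (km.labels_, comp)
        if max(comp) <= compactness_threshold:
            break
        k += 1
    labels, comp = best_labels
    order = np.argsort(comp)            # most compact first
    survivors = np.isin(labels, order[:2]) if len(order) > 2 \
        else np.ones(len(pts), dtype=bool)
    pts2 = pts[survivors]
    if len(pts2) < 4:
        raise LostFrame("insufficient pixels after compactness filter")
    km2 = KMeans(n_clusters=2, n_init=3, random_state=seed).fit(pts2)

    dets = []
    for c in range(2):
        sel = km2.labels_ == c
        if sel.sum() < 2:
            raise LostFrame("degenerate cluster")
        cys, cxs = pts2[sel][:, 1], pts2[sel][:, 0]
        centroid, major, minor, deg = _ellipse_fit(cys, cxs)
        dets.append(Detection(centroid, major, minor, deg,
                              int(sel.sum()), _compactness(cys, cxs)))
    dets.sort(key=lambda d: (d.centroid[0], d.centroid[1]))
    return dets[0], dets[1]


@dataclass
class TrackResult:
    """Linked two-fly tracks with per-frame flags."""

    positions: np.ndarray          # (n, 2, 2): frame, fly, (x, y)
    orientations_deg: np.ndarray   # (n, 2)
    lost: np.ndarray               # (n,) bool, interpolated frames
    tie_flag: np.ndarray           # (n,) bool, ambiguous assignment
    segments: List[Tuple[int, int]]  # [start, end) runs split at long gaps


def link_tracks(
    detections: List[Optional[Tuple[Detection, Detection]]],
    max_gap: int = 5,
    tie_tolerance: float = 1e-6,
) -> TrackResult:
    """Assign per-frame detection pairs to two persistent identities.

    Each frame's pair is matched to the previous frame's positions by
    whichever of the two assignments minimizes the summed centroid
    displacement; when both assignments are within ``tie_tolerance`` the
    frame is tie-flagged. ``None`` entries (lost frames) are filled by
    linear interpolation and flagged; runs of more than ``max_gap``
    consecutive losses split the track into segments.
    """
    n = len(detections)
    if n == 0:
        raise ValueError("no frames")
    pos = np.full((n, 2, 2), np.nan)
    ori = np.full((n, 2), np.nan)
    lost = np.zeros(n, dtype=bool)
    tie = np.zeros(n, dtype=bool)

    prev = None
    for i, det in enumerate(detections):
        if det is None:
            lost[i] = True
            continue
        d0, d1 = det
        cands = np.array([d0.centroid, d1.centroid])
        os = np.array([d0.orientation_deg, d1.orientation_deg])
        if prev is None:
            order = [0, 1]
        else:
            straight = (np.linalg.norm(cands[0] - prev[0])
                        + np.linalg.norm(cands[1] - prev[1]))
            crossed = (np.linalg.norm(cands[1] - prev[0])
                       + np.linalg.norm(cands[0] - prev[1]))
            if abs(straight - crossed) <= tie_tolerance:
                tie[i] = True
            order = [0, 1] if straight <= crossed else [1, 0]
        pos[i] = cands[order]
        ori[i] = os[order]
        prev = pos[i]

    # interpolate short gaps; split at long ones
    segments: List[Tuple[int, int]] = []
    valid = np.where(~lost)[0]
    if len(valid) == 0:
        raise ValueError("no valid frames to link")
    start = valid[0]
    for a, b in zip(valid[:-1], valid[1:]):
        gap = b - a - 1
        if gap == 0:
            continue
        if gap <= max_gap:
            for fly in range(2):
                for dim in range(2):
                    pos[a + 1:b, fly, dim] = np.interp(
                        np.arange(a + 1, b), [a, b],
                        [pos[a, fly, dim], pos[b, fly, dim]])
                ori[a + 1:b, fly] = np.interp(
                    np.arange(a + 1, b), [a, b], [ori[a, fly], ori[b, fly]])
        else:
            segments.append((start, a + 1))
            start = b
    segments.append((start, valid[-1] + 1))
    return TrackResult(pos, ori, lost, tie, segments)


def resolve_headings(
    positions: np.ndarray, orientations_deg: np.ndarray,
    window: int = 5,
) -> np.ndarray:
    """Resolve the 180-degree ellipse-orientation ambiguity by motion.

    For each fly, the axis direction is flipped wherever it opposes the
    average displacement direction over a centered ``window``-frame span.
    Returns (n, 2, 2) unit heading vectors.
    """
    n, n_fly = orientations_deg.shape
    head = np.empty((n, n_fly, 2))
    half = window // 2
    for fly in range(n_fly):
        for i in range(n):
            a = math.radians(orientations_deg[i, fly])
            axis = np.array([math.cos(a), math.sin(a)])
            j0, j1 = max(0, i - half), min(n - 1, i + half)
            disp = positions[j1, fly] - positions[j0, fly]
            if np.dot(axis, disp) < 0:
                axis = -axis
            head[i, fly] = axis
    return head
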